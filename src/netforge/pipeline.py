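"""End-to-end construction pipeline on a synthetic world.

Glues the stages together the way a real build would: derive the gold
standard from annotations, score every evidence channel, calibrate each
channel to LLS with bootstrap smoothing, integrate by weighted sum, and
evaluate planted-truth recovery and guilt-by-association performance.
Problem sizes default to the small synthetic-world scale so a full run
takes seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import evidence
from .calibration import apply_lls_model, bootstrap_lls_model
from .datamodel import AnnotationSet, ComponentNetwork, GenePair, IntegratedNetwork
from .fixtures import SyntheticWorld
from .gold import GoldStandard, TermFilter, build_gold_standard
from .integration import WSParams, integrate, optimize_params
from .netstats import rewired_null, to_networkx
from .prioritize import GBABenchmark, gba_benchmark

logger = logging.getLogger("netforge")


@dataclass
class PipelineResult:
    gold: GoldStandard
    components: list[ComponentNetwork]
    params: WSParams
    network: IntegratedNetwork
    truth_recovery: float
    gba: GBABenchmark


def score_evidence(world: SyntheticWorld):
    """All evidence channels of a world as ScoredPairTables."""
    return [
        evidence.coexpression_scores(world.expression),
        evidence.phylo_profile_scores(world.phylo_profiles),
        evidence.domain_cooccurrence_scores(world.domain_ann, len(world.genes)),
        evidence.neighborhood_distance_scores(world.gene_orders),
        evidence.neighborhood_probability_scores(world.gene_orders),
    ]


def calibrate_components(
    tables,
    gold: GoldStandard,
    bin_size: int = 100,
    B: int = 20,
    seed: int = 0,
    min_lls: float = 1.0,
) -> list[ComponentNetwork]:
    """Bootstrap-calibrate each evidence table that overlaps the gold
    standard enough to bin; tables that do not are skipped with a log."""
    components = []
    for i, spt in enumerate(tables):
        try:
            model = bootstrap_lls_model(
                spt, gold, bin_size=bin_size, B=B, seed=seed + i
            )
        except Exception as exc:  # insufficient overlap
            logger.warning("skipping %s: %s", spt.dataset_id, exc)
            continue
        comp = apply_lls_model(model, spt, min_lls=min_lls)
        if comp.edges:
            components.append(comp)
    return components


def truth_recovery(network, truth: set[GenePair]) -> float:
    """Fraction of planted truth pairs among the top |truth| edges."""
    top = [p for p, _ in network.ranked_edges()[: len(truth)]]
    return len(set(top) & truth) / len(truth)


def run_pipeline(
    world: SyntheticWorld,
    bin_size: int = 100,
    B: int = 20,
    seed: int = 0,
    optimize: bool = True,
    min_lls: float = 1.0,
) -> PipelineResult:
    """Gold standard -> evidence -> calibration -> integration -> evaluation.

    ``min_lls`` is the component-network inclusion floor: an edge whose
    calibrated LLS is below it carries (next to) no evidence of
    co-function over the gold prior and is excluded; 1 nat demands an
    e-fold (~2.7x) likelihood enrichment.
    """
    gold = build_gold_standard(world.annotations, TermFilter())
    tables = score_evidence(world)
    components = calibrate_components(
        tables, gold, bin_size=bin_size, B=B, seed=seed, min_lls=min_lls
    )
    if optimize:
        params = optimize_params(components, gold, bin=bin_size)
    else:
        params = WSParams()
    network = integrate(components, params)
    recovery = truth_recovery(network, world.truth)
    module_ann = AnnotationSet(
        terms={t: world.annotations.terms[t] for t in world.module_terms()}
    )
    gba = gba_benchmark(network, module_ann, min_term=5)
    return PipelineResult(
        gold=gold,
        components=components,
        params=params,
        network=network,
        truth_recovery=recovery,
        gba=gba,
    )


def rewired_network(network: IntegratedNetwork, seed: int = 0) -> IntegratedNetwork:
    """Degree-preserving rewired copy with unit edge weights (GBA null)."""
    g = to_networkx(network)
    null = rewired_null(g, np.random.default_rng(seed))
    edges = {}
    for a, b in null.edges():
        pair = (a, b) if a < b else (b, a)
        edges[pair] = 1.0
    return IntegratedNetwork(edges=edges)
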