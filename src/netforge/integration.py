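"""Weighted-sum integration of component networks.

Evidence datasets are not mutually independent, so a naive Bayes sum of
LLS values over-counts correlated evidence.  The weighted sum (WS)
down-weights all but the strongest support:

    WS = L0 + sum_{i>=1} Li / D**i

with L0 >= L1 >= ... the supporting LLS values at or above a threshold
T, D >= 1 a weight factor (D = 1 recovers the naive sum, D -> inf keeps
only the best dataset).  D and T are chosen by grid search maximizing
the area under the cumulative-LLS versus number-of-pairs curve of the
integrated network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .calibration import lls_vs_pairs_area
from .datamodel import ComponentNetwork, DataError, GenePair, IntegratedNetwork
from .gold import GoldStandard

logger = logging.getLogger("netforge")


@dataclass
class WSParams:
    """Weighted-sum free parameters: weight factor D and LLS threshold T."""

    D: float = 2.0
    T: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 1:
            raise DataError("D must be >= 1")
        if not (self.T == self.T and abs(self.T) != float("inf")):
            raise DataError("T must be finite")


def weighted_sum(lls_values: list[float], params: WSParams) -> float | None:
    """WS of one edge's supporting LLS values.

    Values below T are dropped first; if none survive the edge does not
    exist and ``None`` is returned (distinct from a WS of 0).
    """
    kept = sorted((v for v in lls_values if v >= params.T), reverse=True)
    if not kept:
        return None
    ws = kept[0]
    for i, v in enumerate(kept[1:], start=1):
        ws += v / params.D**i
    return ws


def integrate(
    components: list[ComponentNetwork], params: WSParams
) -> IntegratedNetwork:
    """Combine component networks into a single WS-weighted network.

    Every unordered pair appearing in any component is scored by the
    weighted sum of its supporting LLS values; provenance records the
    supporting (dataset_id, lls) entries that passed T.
    """
    if not components:
        raise DataError("integrate requires >= 1 component network")
    support: dict[GenePair, list[tuple[str, float]]] = {}
    for comp in components:
        for pair, w in comp.edges.items():
            support.setdefault(pair, []).append((comp.dataset_id, w))
    edges: dict[GenePair, float] = {}
    provenance: dict[GenePair, list[tuple[str, float]]] = {}
    for pair, entries in support.items():
        ws = weighted_sum([w for _, w in entries], params)
        if ws is None:
            continue
        edges[pair] = ws
        provenance[pair] = sorted(
            (e for e in entries if e[1] >= params.T), key=lambda e: (-e[1], e[0])
        )
    return IntegratedNetwork(edges=edges, provenance=provenance)


def optimize_params(
    components: list[ComponentNetwork],
    gold: GoldStandard,
    D_grid: list[float] | None = None,
    T_grid: list[float] | None = None,
    bin: int = 1000,
) -> WSParams:
    """Grid-search (D, T) maximizing the LLS-versus-pairs area.

    For each grid point the components are integrated, edges ranked by
    WS, and the area under the cumulative-LLS curve (binned like the PR
    analysis) is computed on the gold standard.  Ties prefer smaller D,
    then larger T.
    """
    if D_grid is None:
        D_grid = [1.0, 1.5, 2.0, 3.0, 4.0]
    if T_grid is None:
        T_grid = [0.0, 0.5, 1.0, 1.5, 2.0]
    if not D_grid or not T_grid:
        raise DataError("parameter grids must be non-empty")
    if not gold.positives or not gold.negatives:
        raise DataError("gold standard must be non-empty")
    best: tuple[float, float, float] | None = None  # (area, -?); track params
    best_params: WSParams | None = None
    for D in sorted(D_grid):
        for T in sorted(T_grid, reverse=True):
            params = WSParams(D=D, T=T)
            net = integrate(components, params)
            if not net.edges:
                continue
            try:
                area = lls_vs_pairs_area(net, gold, bin=bin)
            except DataError:
                continue
            if best is None or area > best[0] + 1e-12:
                best = (area, D, T)
                best_params = params
    if best_params is None:
        raise DataError("no grid point produced a network overlapping the gold standard")
    logger.info(
        "optimal integration parameters D=%g T=%g (area %.4g)",
        best_params.D,
        best_params.T,
        best[0],
    )
    return best_params
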