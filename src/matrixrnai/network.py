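"""Edge calling and hub analysis for the signed directed regulatory network.

A perturbation-matrix cell becomes an edge source→target when the replicate
test is significant (p < alpha, strict) AND the effect size passes the gate.
Two gate modes exist because published Matrix-RNAi studies state both:

``log2_threshold`` (default)
    |log2 ratio| >= log2_cutoff (default 1.5, i.e. ~2.83-fold); the criterion
    attached to published network figures.
``sd_multiple``
    |mean ΔΔCT| > sd_multiplier x SD(ΔΔCT) (default 3).

Sign convention: the measured gene going DOWN when its regulator is depleted
(log2_ratio < 0) is an activating edge; going UP is inhibiting. The diagonal
(self-knockdown) measures siRNA efficacy, not autoregulation, and is excluded
by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .ddct import PerturbationMatrix
from .errors import ConfigurationError, InputError, ParameterError

__all__ = [
    "EdgeCriteria",
    "RegulatoryEdge",
    "RegulatoryNetwork",
    "CoverageReport",
    "call_edges",
    "assemble_network",
    "influential_set",
    "edge_coverage",
    "classify_nodes",
    "first_neighbors",
    "select_combination",
    "fold_to_log2_cutoff",
]

ACTIVATING = "activating"
INHIBITING = "inhibiting"


@dataclass
class EdgeCriteria:
    """Significance criteria for edge calling."""

    mode: str = "log2_threshold"
    log2_cutoff: float = 1.5
    sd_multiplier: float = 3.0
    alpha: float | None = 0.05  # None disables the p-value gate
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("log2_threshold", "sd_multiple"):
            raise ParameterError(f"unknown edge-calling mode {self.mode!r}")
        if self.log2_cutoff < 0 or self.sd_multiplier < 0:
            raise ParameterError("cutoffs must be >= 0")
        if self.alpha is not None and not (0 < self.alpha <= 1):
            raise ParameterError("alpha must be in (0, 1]")


def fold_to_log2_cutoff(fold: float) -> float:
    """Convenience for users who mean an N-fold change rather than N log2 units."""
    if fold <= 0:
        raise ParameterError("fold-change must be > 0")
    return abs(math.log2(fold))


@dataclass
class RegulatoryEdge:
    source: str  # knocked-down TF
    target: str  # measured gene
    sign: str  # activating | inhibiting
    log2_ratio: float
    p_value: float


@dataclass
class RegulatoryNetwork:
    """Signed directed graph of called edges over the full TF panel.

    Nodes with zero edges are retained; degree tallies are materialized at
    construction.
    """

    nodes: list[str]
    edges: list[RegulatoryEdge]
    out_degree: dict[str, int] = field(init=False)
    in_degree: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.source not in node_set or e.target not in node_set:
                raise InputError(
                    f"edge {e.source}->{e.target} has an endpoint outside the node list"
                )
        self.out_degree = {n: 0 for n in self.nodes}
        self.in_degree = {n: 0 for n in self.nodes}
        for e in self.edges:
            self.out_degree[e.source] += 1
            self.in_degree[e.target] += 1

    @property
    def n_activating(self) -> int:
        return sum(1 for e in self.edges if e.sign == ACTIVATING)

    @property
    def n_inhibiting(self) -> int:
        return sum(1 for e in self.edges if e.sign == INHIBITING)

    def targets_of(self, node: str) -> set[str]:
        return {e.target for e in self.edges if e.source == node}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                sign=e.sign,
                log2_ratio=e.log2_ratio,
                p_value=e.p_value,
                # |log2 ratio| doubles as edge thickness (regulation strength)
                weight=abs(e.log2_ratio) if math.isfinite(e.log2_ratio) else 0.0,
            )
        return g


def call_edges(
    matrix: PerturbationMatrix, criteria: EdgeCriteria | None = None
) -> list[RegulatoryEdge]:
    """Apply the significance criteria to every present matrix cell.

    Missing cells never yield edges. Criteria referencing statistics absent
    from a summarized matrix (p-values, SDs) raise a configuration error
    rather than silently passing.
    """
    criteria = criteria or EdgeCriteria()
    edges: list[RegulatoryEdge] = []
    for kd in matrix.tfs:
        for gene in matrix.tfs:
            if criteria.exclude_self and kd == gene:
                continue
            stat = matrix.cell(kd, gene)
            if stat is None:
                continue
            if criteria.alpha is not None:
                if math.isnan(stat.p_value):
                    raise ConfigurationError(
                        f"cell ({kd!r}, {gene!r}) carries no p-value; "
                        "drop the alpha gate for summarized ratio-only input"
                    )
                if not stat.p_value < criteria.alpha:
                    continue
            if criteria.mode == "log2_threshold":
                if not abs(stat.log2_ratio) >= criteria.log2_cutoff:
                    continue
            else:  # sd_multiple
                if math.isnan(stat.sd_ddct):
                    raise ConfigurationError(
                        f"cell ({kd!r}, {gene!r}) carries no SD; "
                        "sd_multiple mode needs replicate statistics"
                    )
                if not abs(stat.mean_ddct) > criteria.sd_multiplier * stat.sd_ddct:
                    continue
            if stat.log2_ratio == 0:
                continue  # no direction: cannot sign the edge
            sign = ACTIVATING if stat.log2_ratio < 0 else INHIBITING
            edges.append(
                RegulatoryEdge(
                    source=kd,
                    target=gene,
                    sign=sign,
                    log2_ratio=stat.log2_ratio,
                    p_value=stat.p_value,
                )
            )
    return edges


def assemble_network(
    edges: list[RegulatoryEdge], nodes: list[str]
) -> RegulatoryNetwork:
    """Build the network over the full panel, keeping edge-less nodes."""
    return RegulatoryNetwork(nodes=list(nodes), edges=list(edges))


def influential_set(network: RegulatoryNetwork, min_targets: int = 5) -> list[str]:
    """Hub TFs: nodes with out-degree >= ``min_targets``.

    Ordered by descending out-degree, then lexicographic.
    """
    if min_targets < 0:
        raise ParameterError("min_targets must be >= 0")
    hubs = [n for n in network.nodes if network.out_degree[n] >= min_targets]
    return sorted(hubs, key=lambda n: (-network.out_degree[n], n))


@dataclass
class CoverageReport:
    fraction: float | None  # None when the network has no edges
    covered_edges: int
    total_edges: int
    targets: list[str]
    target_count: int
    node_count: int


def edge_coverage(network: RegulatoryNetwork, tf_set) -> CoverageReport:
    """Fraction of all edges sourced from ``tf_set`` and their target union."""
    tf_set = set(tf_set)
    unknown = tf_set - set(network.nodes)
    if unknown:
        raise InputError(f"TFs not in network: {sorted(unknown)}")
    covered = [e for e in network.edges if e.source in tf_set]
    total = len(network.edges)
    targets = sorted({e.target for e in covered})
    return CoverageReport(
        fraction=(len(covered) / total) if total else None,
        covered_edges=len(covered),
        total_edges=total,
        targets=targets,
        target_count=len(targets),
        node_count=len(network.nodes),
    )


def classify_nodes(
    network: RegulatoryNetwork, bins: tuple[int, int] = (4, 6)
) -> pd.DataFrame:
    """Bin nodes by out-degree: low (<= bins[0]), mid, high (> bins[1])."""
    low, mid = bins
    if not 0 <= low < mid:
        raise ParameterError("bins must satisfy 0 <= low < mid")
    rows = []
    for node in network.nodes:
        od = network.out_degree[node]
        cls = "low" if od <= low else ("mid" if od <= mid else "high")
        rows.append(
            {
                "node": node,
                "out_degree": od,
                "in_degree": network.in_degree[node],
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


def first_neighbors(
    network: RegulatoryNetwork, seeds, direction: str = "out"
) -> RegulatoryNetwork:
    """Subnetwork of the seeds plus their first neighbors.

    direction ``out`` keeps edges sourced at a seed (targets are the
    neighbors), ``in`` keeps edges pointing at a seed, ``both`` keeps either.
    """
    seeds = set(seeds)
    unknown = seeds - set(network.nodes)
    if unknown:
        raise InputError(f"unknown seed nodes: {sorted(unknown)}")
    if direction not in ("out", "in", "both"):
        raise ParameterError(f"unknown direction {direction!r}")
    if direction == "out":
        kept = [e for e in network.edges if e.source in seeds]
    elif direction == "in":
        kept = [e for e in network.edges if e.target in seeds]
    else:
        kept = [e for e in network.edges if e.source in seeds or e.target in seeds]
    members = set(seeds)
    for e in kept:
        members.add(e.source)
        members.add(e.target)
    nodes = [n for n in network.nodes if n in members]
    return RegulatoryNetwork(nodes=nodes, edges=kept)


def select_combination(
    network: RegulatoryNetwork, k: int, strategy: str = "top_out_degree"
) -> tuple[list[str], int]:
    """Pick a k-TF knockdown combination and report its covered-target count.

    ``top_out_degree`` takes the k highest out-degree nodes (ties broken
    lexicographically); ``greedy_cover`` iteratively adds the node covering
    the most yet-uncovered targets. Returns (combination, #distinct targets).
    """
    if not 1 <= k <= len(network.nodes):
        raise ParameterError(f"k must be in [1, {len(network.nodes)}]")
    if strategy == "top_out_degree":
        ranked = sorted(network.nodes, key=lambda n: (-network.out_degree[n], n))
        chosen = ranked[:k]
    elif strategy == "greedy_cover":
        chosen = []
        covered: set[str] = set()
        remaining = list(network.nodes)
        for _ in range(k):
            best = min(
                remaining,
                key=lambda n: (-len(network.targets_of(n) - covered), n),
            )
            chosen.append(best)
            covered |= network.targets_of(best)
            remaining.remove(best)
    else:
        raise ParameterError(f"unknown strategy {strategy!r}")
    coverage = set().union(*(network.targets_of(n) for n in chosen)) if chosen else set()
    return chosen, len(coverage)
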