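"""Synthetic Matrix-RNAi studies with planted ground truth.

The generator plants a signed regulatory adjacency over a TF panel and emits
CT-level qPCR data that behave like the real assay: per-replicate Gaussian
noise sits on the measured CT values (not on derived ratios), the reference
gene is a noiseless CT 20.0 so planted log2 effects stay exactly
interpretable, and each TF's own knockdown shifts its ΔCT by
log2(1/(1−efficacy)) cycles.

Only direct (first-order) effects are simulated — no propagation through the
planted network — because the perturbation assay measures the combined
direct+indirect response and the inference draws no distinction; the
simulator tests the inference contract, not cascade biology.

Defaults mirror the fibroblast study design: an 18-TF panel, edge density
0.235 (~72 of 306 possible edges), 19/72 of edges inhibiting, effects of
1.8–3.0 cycles, four biological replicates, 0.25-cycle CT noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .io import (
    DEFAULT_CONTROL_LABEL,
    CtTable,
    ExpressionCompendium,
    _read_tsv,
    _write_tsv,
)
from .network import ACTIVATING, INHIBITING

__all__ = [
    "SyntheticTruth",
    "RecoveryReport",
    "sample_truth",
    "simulate_ct",
    "simulate_compendium",
    "score_recovery",
    "write_truth",
    "read_truth",
]

# Study-design defaults (see module docstring).
DEFAULT_N_TFS = 18
DEFAULT_DENSITY = 0.235
DEFAULT_INHIBIT_FRACTION = 19 / 72
DEFAULT_EFFECT_RANGE = (1.8, 3.0)
DEFAULT_EFFICACY_RANGE = (0.7, 0.95)
DEFAULT_REPLICATES = 4
DEFAULT_CT_NOISE_SD = 0.25
DEFAULT_BASELINE_DCT_RANGE = (-2.0, 8.0)


@dataclass
class SyntheticTruth:
    """Planted signed adjacency with effect sizes and knockdown efficacies.

    ``adjacency[(source, target)] = (sign, effect)`` where effect is the
    absolute log2 expression change of the target under source knockdown
    (equivalently, the ΔCT shift in cycles). No self pairs.
    """

    tfs: list[str]
    adjacency: dict[tuple[str, str], tuple[str, float]]
    efficacy: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for (s, t), (sign, effect) in self.adjacency.items():
            if s == t:
                raise ParameterError("self pairs are not representable as edges")
            if effect <= 0:
                raise ParameterError("effects must be > 0")
            if sign not in (ACTIVATING, INHIBITING):
                raise ParameterError(f"unknown sign {sign!r}")
        for tf, eff in self.efficacy.items():
            if not 0 < eff < 1:
                raise ParameterError(f"efficacy of {tf!r} must be in (0, 1)")

    @property
    def n_edges(self) -> int:
        return len(self.adjacency)


def sample_truth(
    n_tfs: int = DEFAULT_N_TFS,
    density: float = DEFAULT_DENSITY,
    inhibit_fraction: float = DEFAULT_INHIBIT_FRACTION,
    effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE,
    efficacy_range: tuple[float, float] = DEFAULT_EFFICACY_RANGE,
    seed: int = None,
) -> SyntheticTruth:
    """Draw a random planted network.

    Each ordered off-diagonal pair carries an edge independently with
    probability ``density``; the sign is inhibiting with probability
    ``inhibit_fraction``; effects are uniform in ``effect_range`` (cycles).
    """
    if seed is None:
        raise ParameterError("seed is mandatory")
    if not (0 <= density <= 1 and 0 <= inhibit_fraction <= 1):
        raise ParameterError("density and inhibit_fraction must be in [0, 1]")
    if not (0 < effect_range[0] <= effect_range[1]):
        raise ParameterError("effect_range must be positive and ordered")
    if not (0 < efficacy_range[0] <= efficacy_range[1] < 1):
        raise ParameterError("efficacy_range must sit inside (0, 1)")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    adjacency: dict[tuple[str, str], tuple[str, float]] = {}
    for s in tfs:
        for t in tfs:
            if s == t:
                continue
            if rng.random() < density:
                sign = INHIBITING if rng.random() < inhibit_fraction else ACTIVATING
                effect = float(rng.uniform(*effect_range))
                adjacency[(s, t)] = (sign, effect)
    efficacy = {tf: float(rng.uniform(*efficacy_range)) for tf in tfs}
    return SyntheticTruth(tfs=tfs, adjacency=adjacency, efficacy=efficacy, seed=seed)


def simulate_ct(
    truth: SyntheticTruth,
    replicates: int = DEFAULT_REPLICATES,
    ct_noise_sd: float = DEFAULT_CT_NOISE_SD,
    baseline_dct_range: tuple[float, float] = DEFAULT_BASELINE_DCT_RANGE,
    seed: int = None,
    control_label: str = DEFAULT_CONTROL_LABEL,
) -> CtTable:
    """Emit CT-level data for the all-against-all knockdown design.

    Per gene a baseline ΔCT is drawn once (uniform in ``baseline_dct_range``).
    Under knockdown of s, measured gene t has
    ΔCT = baseline_t + effect (activating edge s→t) | − effect (inhibiting)
    | 0 (no edge), plus per-replicate Gaussian noise; gene s itself shifts by
    log2(1/(1−efficacy_s)). ct_reference is fixed at 20.0 and
    ct_target = 20.0 + ΔCT.
    """
    if seed is None:
        raise ParameterError("seed is mandatory")
    if replicates < 2:
        raise ParameterError("need >= 2 replicates")
    if ct_noise_sd < 0:
        raise ParameterError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    baseline = {g: float(rng.uniform(*baseline_dct_range)) for g in truth.tfs}
    rows = []

    def emit(condition: str, gene: str, shift: float) -> None:
        for rep in range(1, replicates + 1):
            noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd else 0.0
            dct = baseline[gene] + shift + noise
            rows.append(
                {
                    "condition": condition,
                    "gene": gene,
                    "replicate": rep,
                    "ct_target": 20.0 + dct,
                    "ct_reference": 20.0,
                }
            )

    for gene in truth.tfs:
        emit(control_label, gene, 0.0)
    for kd in truth.tfs:
        for gene in truth.tfs:
            if gene == kd:
                shift = math.log2(1.0 / (1.0 - truth.efficacy[kd]))
            else:
                entry = truth.adjacency.get((kd, gene))
                if entry is None:
                    shift = 0.0
                else:
                    sign, effect = entry
                    # knocking down an activator lowers the target: ΔCT up
                    shift = effect if sign == ACTIVATING else -effect
            emit(kd, gene, shift)
    return CtTable(records=pd.DataFrame(rows), control_label=control_label)


def simulate_compendium(
    n_genes: int,
    group_sizes: Mapping[str, int],
    enriched_genes: Mapping[str, float] | None = None,
    noise_cv: float = 0.2,
    seed: int = None,
    target_group: str | None = None,
    zero_inflation: float = 0.0,
    baseline_median: float = 50.0,
    baseline_log_sd: float = 1.0,
) -> ExpressionCompendium:
    """Generate an expression compendium with planted enriched genes.

    Baselines are log-normal per gene; samples of the ``target_group``
    (default: first key of ``group_sizes``) have enriched genes multiplied by
    their planted fold; multiplicative log-normal noise with coefficient of
    variation ``noise_cv`` is applied per measurement. ``zero_inflation``
    randomly zeroes that fraction of entries (to exercise zero flooring).
    """
    if seed is None:
        raise ParameterError("seed is mandatory")
    if len(group_sizes) < 2:
        raise ParameterError("need >= 2 groups")
    enriched_genes = dict(enriched_genes or {})
    if any(f <= 0 for f in enriched_genes.values()):
        raise ParameterError("planted folds must be > 0")
    if not 0 <= zero_inflation < 1:
        raise ParameterError("zero_inflation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    unknown = set(enriched_genes) - set(genes)
    if unknown:
        raise ParameterError(f"enriched genes not in gene list: {sorted(unknown)}")
    target_group = target_group or next(iter(group_sizes))
    if target_group not in group_sizes:
        raise ParameterError(f"target group {target_group!r} not in group_sizes")

    samples, labels = [], []
    for group, size in group_sizes.items():
        for i in range(size):
            samples.append(f"{group}_{i + 1}")
            labels.append(group)
    baseline = rng.lognormal(mean=math.log(baseline_median), sigma=baseline_log_sd, size=n_genes)
    # log-normal multiplicative noise with unit mean and the requested CV
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    values = np.empty((n_genes, len(samples)))
    fold = np.ones(n_genes)
    for gi, g in enumerate(genes):
        if g in enriched_genes:
            fold[gi] = enriched_genes[g]
    for si, group in enumerate(labels):
        col = baseline * (fold if group == target_group else 1.0)
        if sigma > 0:
            col = col * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n_genes)
        values[:, si] = col
    if zero_inflation > 0:
        mask = rng.random(values.shape) < zero_inflation
        values[mask] = 0.0
    df = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(labels, index=samples)
    return ExpressionCompendium(values=df, groups=groups)


@dataclass
class RecoveryReport:
    """Called-vs-planted confusion summary (directed, unsigned matching)."""

    tp: int
    fp: int
    fn: int
    precision: float | None  # None when nothing was called
    recall: float
    f1: float | None
    sign_accuracy: float | None  # over true positives only

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def score_recovery(called, truth: SyntheticTruth) -> RecoveryReport:
    """Score a called edge list against the planted adjacency."""
    unknown = {e.source for e in called} | {e.target for e in called}
    unknown -= set(truth.tfs)
    if unknown:
        raise InputError(f"called edges mention nodes outside the truth: {sorted(unknown)}")
    called_pairs = {(e.source, e.target): e.sign for e in called}
    true_pairs = set(truth.adjacency)
    tp_pairs = set(called_pairs) & true_pairs
    tp, fp = len(tp_pairs), len(called_pairs) - len(tp_pairs)
    fn = len(true_pairs) - tp
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if precision is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if tp:
        correct = sum(
            1 for pair in tp_pairs if called_pairs[pair] == truth.adjacency[pair][0]
        )
        sign_accuracy = correct / tp
    else:
        sign_accuracy = None
    return RecoveryReport(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall, f1=f1,
        sign_accuracy=sign_accuracy,
    )


def write_truth(truth: SyntheticTruth, edges_path: str | Path, efficacy_path: str | Path) -> None:
    """Serialize as an edge-list TSV plus a per-TF efficacy TSV."""
    edge_rows = [
        {"source": s, "target": t, "sign": sign, "effect": effect}
        for (s, t), (sign, effect) in sorted(truth.adjacency.items())
    ]
    _write_tsv(pd.DataFrame(edge_rows, columns=["source", "target", "sign", "effect"]), edges_path)
    eff_rows = [{"tf": tf, "efficacy": truth.efficacy[tf]} for tf in truth.tfs]
    _write_tsv(pd.DataFrame(eff_rows), efficacy_path)


def read_truth(edges_path: str | Path, efficacy_path: str | Path, seed: int = 0) -> SyntheticTruth:
    eff = _read_tsv(efficacy_path)
    efficacy = {str(r.tf): float(r.efficacy) for r in eff.itertuples()}
    tfs = list(efficacy)
    edges = _read_tsv(edges_path)
    adjacency = {
        (str(r.source), str(r.target)): (str(r.sign), float(r.effect))
        for r in edges.itertuples()
    }
    return SyntheticTruth(tfs=tfs, adjacency=adjacency, efficacy=efficacy, seed=seed)
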