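"""Tissue-enriched TF selection from an expression compendium.

Two scoring modes mirror the two platforms a panel is typically assembled
from:

``enrich_group_mean``
    score = mean expression in the target group / mean expression in all
    other samples (e.g. 41 fibroblast vs 947 non-fibroblast CAGE libraries).
    The p-value comes from Welch's unequal-variance t-test on log2 values
    (robust to very unequal group sizes), optionally Mann-Whitney.

``enrich_pairwise_mean``
    The reference group's mean is compared to every other group one by one;
    score = arithmetic mean of the per-group ratios (e.g. one fibroblast
    line against 13 other primary cell types on a microarray panel).

Zeros are floored (default 0.1) before any averaging so ratios stay finite.
Selection uses strict inequalities: score > fc_threshold and p < alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .io import ExpressionCompendium

__all__ = [
    "EnrichmentRecord",
    "floor_zeros",
    "enrich_group_mean",
    "enrich_pairwise_mean",
    "intersect_selections",
]


@dataclass
class EnrichmentRecord:
    gene: str
    score: float
    p_value: float  # NaN when no test is computable
    selected: bool


def floor_zeros(
    compendium: ExpressionCompendium, floor: float = 0.1
) -> ExpressionCompendium:
    """Replace exact zeros by ``floor``; all other values are untouched."""
    if floor <= 0:
        raise ParameterError("floor must be > 0")
    values = compendium.values.copy()
    values[values == 0] = floor
    return ExpressionCompendium(values=values, groups=compendium.groups.copy())


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    mask = np.isfinite(pvals)
    out = np.array(pvals, dtype=float)
    if mask.any():
        out[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return out


def _records(
    genes, scores, pvals, fc_threshold: float, alpha: float, correct: str
) -> list[EnrichmentRecord]:
    pvals = np.asarray(pvals, dtype=float)
    if correct == "bh":
        pvals = _bh_adjust(pvals)
    elif correct != "none":
        raise ParameterError(f"unknown correction {correct!r}")
    out = []
    for gene, score, p in zip(genes, scores, pvals):
        if math.isnan(p):
            selected = score > fc_threshold
        else:
            selected = score > fc_threshold and p < alpha
        out.append(EnrichmentRecord(gene=gene, score=float(score), p_value=float(p), selected=bool(selected)))
    return out


def enrich_group_mean(
    compendium: ExpressionCompendium,
    target_group: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    test: str = "welch",
    correct: str = "none",
) -> list[EnrichmentRecord]:
    """Score each gene as target-group mean over background mean.

    Background = all samples outside ``target_group``. Requires >= 2 samples
    on each side so the between-group test is defined. Zeros must already be
    floored (see :func:`floor_zeros`).
    """
    target = compendium.group_samples(target_group)
    background = [s for s in compendium.samples if s not in set(target)]
    if len(target) < 2 or len(background) < 2:
        raise InputError(
            f"need >= 2 samples in {target_group!r} and in the background "
            f"(got {len(target)} vs {len(background)})"
        )
    tv = compendium.values[target].to_numpy(dtype=float)
    bv = compendium.values[background].to_numpy(dtype=float)
    scores = tv.mean(axis=1) / bv.mean(axis=1)
    if test == "welch":
        pvals = stats.ttest_ind(
            np.log2(tv), np.log2(bv), axis=1, equal_var=False
        ).pvalue
    elif test == "mannwhitney":
        pvals = stats.mannwhitneyu(tv, bv, axis=1, alternative="two-sided").pvalue
    else:
        raise ParameterError(f"unknown test {test!r}")
    # constant rows (identical values everywhere) have no variance to test
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    return _records(compendium.genes, scores, pvals, fc_threshold, alpha, correct)


def enrich_pairwise_mean(
    compendium: ExpressionCompendium,
    reference_group: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    correct: str = "none",
) -> list[EnrichmentRecord]:
    """Score each gene as the mean of per-group expression ratios.

    For every non-reference group g: ratio_g = reference mean / group-g mean;
    score = mean over g. With >= 2 reference samples a Welch test (reference
    vs all other samples, log2 scale) supplies the p-value; with a single
    reference sample no test is computable, p is reported as NaN and
    selection falls back to the ratio criterion alone (with a warning).
    """
    ref_samples = compendium.group_samples(reference_group)
    if not ref_samples:
        raise InputError(f"reference group {reference_group!r} is empty")
    other_groups = [
        g for g in dict.fromkeys(compendium.groups) if g != reference_group
    ]
    if not other_groups:
        raise InputError("need at least one comparison group")
    ref_mean = compendium.values[ref_samples].to_numpy(dtype=float).mean(axis=1)
    ratios = np.column_stack(
        [
            ref_mean
            / compendium.values[compendium.group_samples(g)]
            .to_numpy(dtype=float)
            .mean(axis=1)
            for g in other_groups
        ]
    )
    scores = ratios.mean(axis=1)
    if len(ref_samples) >= 2:
        others = [s for s in compendium.samples if s not in set(ref_samples)]
        pvals = stats.ttest_ind(
            np.log2(compendium.values[ref_samples].to_numpy(dtype=float)),
            np.log2(compendium.values[others].to_numpy(dtype=float)),
            axis=1,
            equal_var=False,
        ).pvalue
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    else:
        warnings.warn(
            "single reference sample: no between-group test is computable; "
            "selecting on the ratio criterion alone",
            stacklevel=2,
        )
        pvals = np.full(len(scores), np.nan)
    return _records(compendium.genes, scores, pvals, fc_threshold, alpha, correct)


def intersect_selections(a, b) -> list[str]:
    """Genes selected in both record lists, in lexicographic order."""
    sel_a = {r.gene for r in a if r.selected}
    sel_b = {r.gene for r in b if r.selected}
    return sorted(sel_a & sel_b)


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "score": [r.score for r in records],
            "p_value": [r.p_value for r in records],
            "selected": [r.selected for r in records],
        }
    )
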