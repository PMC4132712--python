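"""2^−ΔΔCT quantification of Matrix-RNAi qPCR data.

Each measured gene's cycle threshold (CT) is normalized to the GAPDH
reference within its sample (ΔCT = ct_target − ct_reference), then calibrated
against the negative-control condition (ΔΔCT = ΔCT_knockdown − ΔCT_control).
The linear fold-change of the measured gene is 2^−ΔΔCT and the canonical
effect size stored on edges is log2_ratio = −ΔΔCT.

Replicate statistics support two pairing modes:

``paired`` (default)
    Biological replicates are matched by replicate index (transfections run
    in matched batches); ΔΔCT is computed per replicate and tested against 0
    with a one-sample t-test.
``unpaired``
    ΔΔCT is the difference of condition means; the SD is pooled and the
    p-value comes from a two-sample Student's t-test on the ΔCTs.

Both modes yield the same mean ΔΔCT (means commute); only SD and p differ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .io import CtTable

__all__ = [
    "DdctStat",
    "PerturbationMatrix",
    "delta_ct",
    "ddct_stats",
    "build_perturbation_matrix",
    "knockdown_efficacy",
]


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """ΔCT: target-gene CT minus reference-gene CT, in cycles."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("CT values must be finite")
    return ct_target - ct_reference


@dataclass
class DdctStat:
    """Summary statistics of ΔΔCT for one (knockdown, measured gene) cell.

    ``log2_ratio = −mean_ddct`` and ``ratio = 2^−mean_ddct`` are derived at
    construction so the three representations never drift apart.
    """

    knockdown: str
    measured_gene: str
    mean_ddct: float
    sd_ddct: float
    p_value: float
    n: int
    log2_ratio: float = field(init=False)
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.log2_ratio = -self.mean_ddct
        self.ratio = 2.0 ** self.log2_ratio


def ddct_stats(
    kd_dcts,
    nc_dcts,
    pairing: str = "paired",
    knockdown: str = "KD",
    measured_gene: str = "gene",
) -> DdctStat:
    """Summarize replicate ΔCTs of a knockdown cell against the control.

    Zero-variance conventions: identical ΔΔCTs with zero mean give p = 1;
    identical ΔΔCTs with non-zero mean give p = 0 (an exact, noiseless shift).
    """
    kd = np.asarray(kd_dcts, dtype=float)
    nc = np.asarray(nc_dcts, dtype=float)
    if kd.size < 2 or nc.size < 2:
        raise InputError("need >= 2 replicates per condition for a variance")
    if pairing == "paired":
        if kd.size != nc.size:
            raise InputError(
                f"paired mode needs matched replicates ({kd.size} vs {nc.size})"
            )
        ddct = kd - nc
        mean = float(ddct.mean())
        sd = float(ddct.std(ddof=1))
        n = int(ddct.size)
        if sd == 0.0:
            p = 1.0 if mean == 0.0 else 0.0
        else:
            p = float(stats.ttest_1samp(ddct, 0.0).pvalue)
    elif pairing == "unpaired":
        mean = float(kd.mean() - nc.mean())
        v1, v2 = kd.var(ddof=1), nc.var(ddof=1)
        n1, n2 = kd.size, nc.size
        sd = float(math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)))
        n = int(min(n1, n2))
        if sd == 0.0:
            p = 1.0 if mean == 0.0 else 0.0
        else:
            p = float(stats.ttest_ind(kd, nc, equal_var=True).pvalue)
    else:
        raise ParameterError(f"unknown pairing mode {pairing!r}")
    return DdctStat(
        knockdown=knockdown,
        measured_gene=measured_gene,
        mean_ddct=mean,
        sd_ddct=sd,
        p_value=p,
        n=n,
    )


@dataclass
class PerturbationMatrix:
    """Knockdown x measured-gene grid of ΔΔCT statistics.

    Square over the TF panel; the diagonal cell (self-knockdown) measures
    knockdown efficacy. Cells can be missing (flagged, never treated as a
    zero effect).
    """

    tfs: list[str]
    cells: dict[tuple[str, str], DdctStat]

    def cell(self, knockdown: str, measured_gene: str) -> DdctStat | None:
        return self.cells.get((knockdown, measured_gene))

    @property
    def missing(self) -> list[tuple[str, str]]:
        return [
            (kd, g)
            for kd in self.tfs
            for g in self.tfs
            if (kd, g) not in self.cells
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame, one row per present cell, in TF order."""
        rows = [
            {
                "knockdown": s.knockdown,
                "measured_gene": s.measured_gene,
                "mean_ddct": s.mean_ddct,
                "sd_ddct": s.sd_ddct,
                "log2_ratio": s.log2_ratio,
                "ratio": s.ratio,
                "p_value": s.p_value,
                "n": s.n,
            }
            for kd in self.tfs
            for g in self.tfs
            if (s := self.cells.get((kd, g))) is not None
        ]
        return pd.DataFrame(rows)

    def log2_frame(self) -> pd.DataFrame:
        """Wide knockdown x measured-gene matrix of log2 ratios (NaN = missing)."""
        wide = pd.DataFrame(np.nan, index=self.tfs, columns=self.tfs)
        for (kd, g), s in self.cells.items():
            wide.loc[kd, g] = s.log2_ratio
        return wide


def build_perturbation_matrix(
    table: CtTable,
    pairing: str = "paired",
    tf_order: list[str] | None = None,
) -> PerturbationMatrix:
    """Summarize a CT table into the all-against-all perturbation matrix.

    Every knockdown cell is calibrated against the negative control's
    replicate ΔCTs for the same measured gene. Cells with fewer than two
    replicates on either side are flagged missing with a warning.
    """
    knockdowns = table.knockdowns
    if not knockdowns:
        raise InputError("CT table contains only the control condition")
    gene_sets = {
        cond: frozenset(table.records.loc[table.records["condition"] == cond, "gene"])
        for cond in table.conditions
    }
    ref_genes = gene_sets[table.control_label]
    for cond, genes in gene_sets.items():
        if genes != ref_genes:
            raise InputError(
                f"measured-gene set of condition {cond!r} differs from the control's"
            )
    tfs = tf_order if tf_order is not None else sorted(set(knockdowns) | ref_genes)
    # one pass over the records instead of 2 filters per cell
    rec = table.records
    dct_by_cell = {
        key: pd.Series(
            (sub["ct_target"] - sub["ct_reference"]).to_numpy(),
            index=sub["replicate"].to_numpy(),
        ).sort_index()
        for key, sub in rec.groupby(["condition", "gene"], sort=False)
    }
    cells: dict[tuple[str, str], DdctStat] = {}
    for kd in knockdowns:
        for gene in sorted(ref_genes):
            kd_d = dct_by_cell[(kd, gene)]
            nc_d = dct_by_cell[(table.control_label, gene)]
            if pairing == "paired":
                common = kd_d.index.intersection(nc_d.index)
                kd_vals, nc_vals = kd_d.loc[common], nc_d.loc[common]
            else:
                kd_vals, nc_vals = kd_d, nc_d
            if len(kd_vals) < 2 or len(nc_vals) < 2:
                warnings.warn(
                    f"cell ({kd!r}, {gene!r}) has < 2 usable replicates; "
                    "flagged missing",
                    stacklevel=2,
                )
                continue
            cells[(kd, gene)] = ddct_stats(
                kd_vals.to_numpy(),
                nc_vals.to_numpy(),
                pairing=pairing,
                knockdown=kd,
                measured_gene=gene,
            )
    return PerturbationMatrix(tfs=tfs, cells=cells)


def knockdown_efficacy(
    matrix: PerturbationMatrix, max_residual_ratio: float = 0.5
) -> pd.DataFrame:
    """Per-TF knockdown QC from the matrix diagonal.

    The diagonal ratio is the TF's own expression under its own siRNA
    relative to control; efficacy = 1 − ratio. A TF passes when the residual
    ratio is strictly below ``max_residual_ratio``.
    """
    if max_residual_ratio <= 0:
        raise ParameterError("max_residual_ratio must be > 0")
    rows = []
    for tf in matrix.tfs:
        stat = matrix.cell(tf, tf)
        if stat is None:
            rows.append(
                {
                    "tf": tf,
                    "residual_ratio": math.nan,
                    "efficacy": math.nan,
                    "passed": False,
                    "reason": "diagonal cell missing",
                }
            )
            continue
        rows.append(
            {
                "tf": tf,
                "residual_ratio": stat.ratio,
                "efficacy": 1.0 - stat.ratio,
                "passed": stat.ratio < max_residual_ratio,
                "reason": "",
            }
        )
    return pd.DataFrame(rows)
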