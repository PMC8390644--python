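"""Expression-matrix preprocessing and differential-expression statistics.

Matrices are genes x samples of RPKM (single-end quantification) or FPKM
(paired-end quantification).  A fixed pseudocount is added once — 0.1 for
RPKM, 1 for FPKM — to damp fold changes of low-expression genes; the wrapper
tracks whether the pseudocount has been applied so it cannot be applied
twice.  Differential expression uses an unpaired two-sided t-test on the
pseudocounted values with a fold-change gate (default p < 0.05 and fold
change > 2 in either direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNTS = {"single_end_RPKM": 0.1, "paired_end_FPKM": 1.0}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with quantification metadata."""

    values: pd.DataFrame
    quant_type: str = "paired_end_FPKM"
    pseudocount_applied: bool = False
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.quant_type not in PSEUDOCOUNTS:
            raise ValueError(
                f"quant_type must be one of {sorted(PSEUDOCOUNTS)}, got {self.quant_type!r}"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


def add_pseudocount(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Add the quantification-appropriate pseudocount (RPKM+0.1 / FPKM+1) once."""
    if matrix.pseudocount_applied:
        raise ValueError("pseudocount already applied to this matrix")
    pc = PSEUDOCOUNTS[matrix.quant_type]
    return replace(matrix, values=matrix.values + pc, pseudocount_applied=True)


def low_expression_filter(matrix: ExpressionMatrix, min_mean_log2: float = 1.0) -> ExpressionMatrix:
    """Drop genes with mean over samples of log2(FPKM+1) strictly below 1.

    Operates on raw (non-pseudocounted) FPKM; a gene at FPKM 1 in every
    sample sits exactly on the boundary and is retained.
    """
    if matrix.pseudocount_applied:
        raise ValueError("apply the low-expression filter before the pseudocount")
    mean_log = np.log2(matrix.values + 1.0).mean(axis=1)
    keep = mean_log >= min_mean_log2
    return replace(matrix, values=matrix.values.loc[keep])


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> np.ndarray:
    res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups with equal means -> p = 1 by convention
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return p


def call_degs(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    p_max: float = 0.05,
    fc_min: float = 2.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Differential expression: unpaired two-sided t-test plus a fold-change gate.

    Fold change is mean_B / mean_A on pseudocounted values.  A gene is
    significant iff p < ``p_max`` (strict) and its fold change exceeds
    ``fc_min`` in either direction (> fc_min or < 1/fc_min, strict).
    Direction is 'up' when group B exceeds group A.
    """
    if not matrix.pseudocount_applied:
        raise ValueError("apply the pseudocount before calling DEGs")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    a = matrix.values[list(group_a)].to_numpy(dtype=float)
    b = matrix.values[list(group_b)].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fc = mean_b / mean_a
    p = _two_sample_t(a, b, equal_var=equal_var)
    significant = (p < p_max) & ((fc > fc_min) | (fc < 1.0 / fc_min))
    return pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "fold_change": fc,
            "p_value": p,
            "direction": np.where(fc >= 1.0, "up", "down"),
            "significant": significant,
        }
    ).set_index("gene_id", drop=False)


def _percent(numerator: int, denominator: int) -> float:
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def repriming_response_fraction(total: int, responding: int) -> float:
    """Percent of state-specific DEGs responding during repriming (1 decimal)."""
    if total == 0:
        raise ValueError("total DEG count must be positive")
    if responding > total:
        raise ValueError("responding count exceeds total")
    return _percent(responding, total)


def repriming_response(
    state_degs: pd.DataFrame,
    repriming_degs: pd.DataFrame,
    direction: str,
) -> tuple[set[str], float]:
    """State-specific DEGs that significantly respond in ``direction`` during repriming.

    ``state_degs`` are the significant genes of one pluripotent state (e.g.
    naive-upregulated); ``repriming_degs`` is a DegTable from the repriming
    time-course comparison.  Returns the responding gene subset and its
    percentage of the state DEG set.
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    state_genes = set(state_degs.loc[state_degs["significant"], "gene_id"])
    responding = set(
        repriming_degs.loc[
            repriming_degs["significant"] & (repriming_degs["direction"] == direction),
            "gene_id",
        ]
    ) & state_genes
    if not state_genes:
        raise ValueError("no significant state-specific DEGs supplied")
    return responding, repriming_response_fraction(len(state_genes), len(responding))


def mann_whitney_group_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value for two expression groups.

    Exact enumeration when both groups have <= 8 untied observations;
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
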