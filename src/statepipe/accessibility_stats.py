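"""Differential chromatin accessibility on per-peak ATAC count matrices.

The differential caller here is a deliberately transparent procedure:
counts-per-million library normalization, a log2(x+1) transform, an unpaired
two-sided t-test per peak, and Benjamini-Hochberg adjustment across peaks
with a strict q < 0.05 call.  It is a defined, self-contained stage rather
than a re-implementation of any particular differential-binding package, so
its behaviour is fully specified by this module.

Downstream, significant peaks are partitioned over chromatin-state clusters:
the expected count per cluster is the total number of significant peaks
scaled by the cluster's share of all peaks, and enrichment is a one-sided
Fisher exact test of observed against the remainder.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .apms_scoring import bh_fdr
from .interval_ops import fisher_overlap_test


def normalize_counts(
    counts: pd.DataFrame, library_sizes: Sequence[float] | None = None
) -> pd.DataFrame:
    """Counts-per-million per sample followed by log2(x + 1).

    ``library_sizes`` defaults to column sums; column order is preserved and
    doubling every count together with every library size is a no-op.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if library_sizes is None:
        libs = counts.sum(axis=0).to_numpy(dtype=float)
    else:
        libs = np.asarray(list(library_sizes), dtype=float)
        if libs.size != counts.shape[1]:
            raise ValueError("one library size per sample required")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = counts.to_numpy(dtype=float) / libs[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)


def median_of_ratios_library_sizes(counts: pd.DataFrame) -> np.ndarray:
    """Robust effective library sizes via median-of-ratios size factors.

    Raw column sums are distorted when many peaks change in one direction
    (losing 10% of the signal in one arm inflates every other peak's CPM
    there).  The median over peaks of each sample's ratio to the per-peak
    geometric mean is insensitive to such composition shifts; factors are
    rescaled so their geometric mean matches the column sums'.
    """
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_x = np.log(x)
    finite = np.isfinite(log_x).all(axis=1)
    if not finite.any():
        return counts.sum(axis=0).to_numpy(dtype=float)
    log_geo = log_x[finite].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(log_x[finite] - log_geo, axis=0))
    col_sums = counts.sum(axis=0).to_numpy(dtype=float)
    scale = np.exp(np.mean(np.log(col_sums))) / np.exp(np.mean(np.log(sf)))
    return sf * scale


def call_dars(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr_max: float = 0.05,
    library_sizes: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Differential accessibility: CPM -> log2 -> per-peak t-test -> BH q < 0.05.

    ``group_a`` is the reference (e.g. WT/HET), ``group_b`` the comparison
    (e.g. knockout); log2 fold change is mean(B) - mean(A) of normalized
    values, so peaks losing accessibility in B carry direction 'down'.
    Library sizes default to median-of-ratios effective sizes rather than raw
    column sums, so a one-sided accessibility collapse does not masquerade as
    genome-wide gains elsewhere.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    if library_sizes is None:
        ordered = counts[list(group_a) + list(group_b)]
        libs = median_of_ratios_library_sizes(ordered)
        library_sizes = pd.Series(libs, index=ordered.columns).reindex(counts.columns)
        library_sizes = library_sizes.fillna(counts.sum(axis=0)).to_numpy()
    norm = normalize_counts(counts, library_sizes)
    a = norm[list(group_a)].to_numpy()
    b = norm[list(group_b)].to_numpy()
    res = stats.ttest_ind(b, a, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    degenerate = np.isnan(p)
    if degenerate.any():
        p[degenerate & np.isclose(lfc, 0.0)] = 1.0
        p[degenerate & ~np.isclose(lfc, 0.0)] = 0.0
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "peak_id": counts.index,
            "log2_fold_change": lfc,
            "p_value": p,
            "q_value": q,
            "direction": np.where(lfc >= 0, "up", "down"),
            "significant": q < fdr_max,
        }
    ).set_index("peak_id", drop=False)


def dar_direction_fraction(n_down: int, n_total: int) -> float:
    """Percent of significant peaks in one direction, half-up to 1 decimal."""
    if n_total <= 0:
        raise ValueError("total DAR count must be positive")
    if n_down > n_total:
        raise ValueError("directional count exceeds total")
    pct = Decimal(100 * n_down) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def expected_cluster_dars(
    n_significant: int,
    cluster_proportions: Mapping[object, float],
    observed_counts: Mapping[object, int] | None = None,
    n_total_peaks: int | None = None,
) -> pd.DataFrame:
    """Expected significant-peak counts per cluster, with optional Fisher enrichment.

    Expected count for cluster c is ``n_significant * proportion_c``
    (reported unrounded).  When observed per-cluster counts and the total
    peak universe are supplied, each cluster is tested for enrichment with a
    one-sided (greater) Fisher exact test on the 2x2 table
    [[observed_c, significant_elsewhere], [nonsig_in_c, nonsig_elsewhere]].
    """
    props = dict(cluster_proportions)
    total_prop = float(sum(props.values()))
    if abs(total_prop - 1.0) > 1e-9:
        raise ValueError(f"cluster proportions must sum to 1, got {total_prop}")
    rows = []
    for cluster, prop in props.items():
        row: dict[str, object] = {
            "cluster": cluster,
            "proportion": prop,
            "expected": n_significant * prop,
        }
        if observed_counts is not None:
            if n_total_peaks is None:
                raise ValueError("n_total_peaks required alongside observed counts")
            obs = int(observed_counts.get(cluster, 0))
            size_c = int(round(prop * n_total_peaks))
            n11 = obs
            n12 = n_significant - obs
            n21 = size_c - obs
            n22 = (n_total_peaks - size_c) - n12
            row["observed"] = obs
            row["fisher_p"] = fisher_overlap_test(n11, n12, max(n21, 0), max(n22, 0))
        rows.append(row)
    return pd.DataFrame(rows)
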