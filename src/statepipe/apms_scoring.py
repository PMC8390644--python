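"""Bait-interactor calling from replicated AP-MS spectral counts.

The caller implements a filter-then-score cascade for affinity-purification
mass spectrometry with matched control IPs across replicate experiments:

1. identification filters (identification score, peptide count, named
   common contaminants such as trypsin/keratins);
2. a replicate detection gate (detected in >= ``min_experiments`` of the
   experiment roster);
3. a contaminant-frequency (CRAPome-style) filter;
4. a per-experiment enrichment statistic
   ``s = (bait / (control + c)) * bait`` — the bait/control spectral-count
   ratio re-weighted by the bait counts, which rewards preys with strong
   absolute evidence on sensitive instruments;
5. an empirical p-value of ``s`` against the within-experiment score
   distribution of all surviving proteins;
6. a combined cumulative probability (CCP) across experiments — the exact
   probability that a product of k independent Uniform(0,1) p-values falls
   at or below the observed product;
7. Benjamini-Hochberg adjustment across proteins and an FDR call.

Input spectral-count tables are tidy DataFrames with one row per protein and
experiment: columns ``protein_id, experiment_id, bait_counts, control_counts,
identification_score, n_peptides``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

RECORD_COLUMNS = [
    "protein_id",
    "experiment_id",
    "bait_counts",
    "control_counts",
    "identification_score",
    "n_peptides",
]


@dataclass(frozen=True)
class ApmsConfig:
    """Thresholds of the interactor-calling cascade (defaults as published)."""

    score_min: float = 10.0
    peptide_min: int = 2
    min_experiments: int = 3
    crapome_max_freq: float = 0.20
    control_pseudocount: float = 1.0
    fdr_threshold: float = 0.10
    fdr_method: str = "bh"  # "bh" or "by"
    contaminant_ids: frozenset[str] = field(default_factory=frozenset)


class InteractomeOverlap(NamedTuple):
    a_only: set[str]
    b_only: set[str]
    shared: set[str]


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"spectral-count table lacks columns {missing}")
    if len(records) and (
        (records["bait_counts"] < 0).any() or (records["control_counts"] < 0).any()
    ):
        raise ValueError("spectral counts must be non-negative")
    return records


def collapse_duplicates(records: pd.DataFrame, how: str = "max") -> pd.DataFrame:
    """Collapse duplicate rows per (protein, experiment).

    ``how="max"`` keeps the record with the largest bait count; ``how="sum"``
    sums bait/control counts across rows (e.g. gel slices) and keeps the max
    identification score / peptide count.
    """
    _check_records(records)
    if how == "max":
        idx = records.groupby(["protein_id", "experiment_id"], sort=False)[
            "bait_counts"
        ].idxmax()
        return records.loc[idx].reset_index(drop=True)
    if how == "sum":
        return (
            records.groupby(["protein_id", "experiment_id"], sort=False, as_index=False)
            .agg(
                bait_counts=("bait_counts", "sum"),
                control_counts=("control_counts", "sum"),
                identification_score=("identification_score", "max"),
                n_peptides=("n_peptides", "max"),
            )
        )
    raise ValueError("how must be 'max' or 'sum'")


def filter_identifications(
    records: pd.DataFrame,
    score_min: float = 10.0,
    peptide_min: int = 2,
    contaminant_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Identification-quality filter: score > score_min, peptides > peptide_min.

    Both inequalities are strict; proteins named in ``contaminant_ids``
    (common contaminants: trypsin, keratins, actin, tubulins) are removed.
    """
    if score_min < 0 or peptide_min < 0:
        raise ValueError("thresholds must be non-negative")
    _check_records(records)
    contaminants = set(contaminant_ids)
    keep = (
        (records["identification_score"] > score_min)
        & (records["n_peptides"] > peptide_min)
        & ~records["protein_id"].isin(contaminants)
    )
    return records.loc[keep].reset_index(drop=True)


def detection_filter(
    records: pd.DataFrame,
    min_experiments: int = 3,
    total_experiments: int = 4,
) -> set[str]:
    """Proteins detected in >= min_experiments distinct experiments."""
    if min_experiments > total_experiments:
        raise ValueError("min_experiments cannot exceed total_experiments")
    n_exp = records.groupby("protein_id")["experiment_id"].nunique()
    return set(n_exp.index[n_exp >= min_experiments])


def crapome_filter(
    proteins: set[str],
    profiles: pd.DataFrame,
    max_freq: float = 0.20,
) -> set[str]:
    """Remove proteins with contaminant frequency strictly above ``max_freq``.

    ``profiles`` has columns protein_id, contaminant_frequency; proteins
    without a profile are treated as frequency 0 (retained).
    """
    if profiles.empty:
        return set(proteins)
    freqs = profiles.set_index("protein_id")["contaminant_frequency"]
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("contaminant frequencies must lie in [0, 1]")
    flagged = set(freqs.index[freqs > max_freq])
    return {p for p in proteins if p not in flagged}


def enrichment_statistic(
    bait_counts: float, control_counts: float, control_pseudocount: float = 1.0
) -> float:
    """Modified spectral-count enrichment: (x / (y + c)) * x.

    Zero iff the bait counts are zero; strictly increasing in bait counts and
    strictly decreasing in control counts for positive bait counts.
    """
    if control_pseudocount <= 0:
        raise ValueError("control pseudocount must be positive")
    x = float(bait_counts)
    y = float(control_counts)
    return (x / (y + control_pseudocount)) * x


def empirical_pvalue(statistic: float, background: Sequence[float]) -> float:
    """Right-tail empirical p: fraction of background scores >= statistic.

    The background must include the query's own score, so p is bounded below
    by 1/N and equals 1 at the minimum score.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background distribution is empty")
    return float(np.count_nonzero(bg >= statistic) / bg.size)


def combine_ccp(p_values: Sequence[float]) -> float:
    """Combined cumulative probability of k per-experiment p-values.

    With z the product of the p-values, returns
    ``z * sum_{j=0}^{k-1} (-ln z)^j / j!`` — the probability that a product of
    k independent Uniform(0,1) variables is <= z (a regularized upper
    incomplete gamma function in -ln z).  Reduces to p itself for k = 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    log_z = float(np.log(p).sum())
    if log_z == 0.0:
        return 1.0
    k = p.size
    # stable evaluation: CCP = exp(log_z) * sum_j exp(j*log(-log_z) - log j!)
    t = -log_z
    term = 1.0
    total = 1.0
    for j in range(1, k):
        term *= t / j
        total += term
    ccp = math.exp(log_z) * total
    return min(ccp, 1.0)


def bh_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (Benjamini-Yekutieli via method="by").

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; order-preserving.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    # (p * m) / j association matches the step-up definition digit for digit
    adjusted = (ranked * m) / np.arange(1, m + 1)
    if method == "by":
        adjusted = adjusted * np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise ValueError("method must be 'bh' or 'by'")
    q_sorted = np.minimum.accumulate(adjusted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_interactors(
    records: pd.DataFrame,
    crapome: pd.DataFrame | None = None,
    config: ApmsConfig | None = None,
    experiment_roster: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the full interactor-calling cascade and return an InteractorScore table.

    Columns: protein_id, n_experiments_detected, stat_<exp> and p_<exp> per
    roster experiment, product_p, ccp, q_value, called.  Experiments in which
    a surviving protein is undetected contribute p = 1 (conservative), so the
    combination is always over the full roster.
    """
    cfg = config or ApmsConfig()
    _check_records(records)
    if crapome is None:
        crapome = pd.DataFrame({"protein_id": [], "contaminant_frequency": []})
    if experiment_roster is None:
        experiment_roster = sorted(records["experiment_id"].unique())
    roster = list(experiment_roster)
    extra = set(records["experiment_id"].unique()) - set(roster)
    if extra:
        raise ValueError(f"records reference experiments outside the roster: {sorted(extra)}")

    tidy = collapse_duplicates(records, how="max")
    tidy = filter_identifications(
        tidy, cfg.score_min, cfg.peptide_min, cfg.contaminant_ids
    )
    detected = detection_filter(tidy, cfg.min_experiments, len(roster))
    surviving = crapome_filter(detected, crapome, cfg.crapome_max_freq)
    proteins = sorted(surviving)
    if not proteins:
        cols = (
            ["protein_id", "n_experiments_detected"]
            + [f"stat_{e}" for e in roster]
            + [f"p_{e}" for e in roster]
            + ["product_p", "ccp", "q_value", "called"]
        )
        return pd.DataFrame(columns=cols)

    tidy = tidy[tidy["protein_id"].isin(surviving)]
    stat_tbl = pd.DataFrame(np.nan, index=proteins, columns=roster)
    p_tbl = pd.DataFrame(1.0, index=proteins, columns=roster)
    for exp, grp in tidy.groupby("experiment_id", sort=False):
        stats_e = np.array(
            [
                enrichment_statistic(b, c, cfg.control_pseudocount)
                for b, c in zip(grp["bait_counts"], grp["control_counts"])
            ]
        )
        # empirical p against the within-experiment distribution (query included)
        order = np.argsort(stats_e, kind="mergesort")
        # p = count(s' >= s)/N computed via ranks over the sorted array
        n = stats_e.size
        sorted_stats = stats_e[order]
        ge_counts = n - np.searchsorted(sorted_stats, stats_e, side="left")
        pvals = ge_counts / n
        stat_tbl.loc[list(grp["protein_id"]), exp] = stats_e
        p_tbl.loc[list(grp["protein_id"]), exp] = pvals

    ccp = np.array([combine_ccp(p_tbl.loc[p, roster].to_numpy()) for p in proteins])
    product_p = p_tbl[roster].prod(axis=1).to_numpy()
    q = bh_fdr(ccp, method=cfg.fdr_method)
    n_detected = tidy.groupby("protein_id")["experiment_id"].nunique()

    out = pd.DataFrame({"protein_id": proteins})
    out["n_experiments_detected"] = n_detected.reindex(proteins).fillna(0).astype(int).to_numpy()
    for e in roster:
        out[f"stat_{e}"] = stat_tbl[e].to_numpy()
    for e in roster:
        out[f"p_{e}"] = p_tbl[e].to_numpy()
    out["product_p"] = product_p
    out["ccp"] = ccp
    out["q_value"] = q
    out["called"] = out["q_value"] <= cfg.fdr_threshold
    return out


def interactome_overlap(
    calls_a: pd.DataFrame | Iterable[str], calls_b: pd.DataFrame | Iterable[str]
) -> InteractomeOverlap:
    """Partition two interactor call sets into exclusive and shared proteins."""

    def _to_set(calls) -> set[str]:
        if isinstance(calls, pd.DataFrame):
            return set(calls.loc[calls["called"], "protein_id"])
        return set(calls)

    a, b = _to_set(calls_a), _to_set(calls_b)
    return InteractomeOverlap(a_only=a - b, b_only=b - a, shared=a & b)
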