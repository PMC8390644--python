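"""Synthetic study generators with planted ground truth.

Every generator is a pure function of its config (seed included) and returns
truth labels alongside the data, so each downstream stage has a recovery
test:

* :func:`simulate_apms` — replicated bait/control spectral-count tables with
  planted true preys over a contaminant background (negative-binomial
  counts), plus a CRAPome-style contaminant-frequency table from
  :func:`simulate_crapome`;
* :func:`simulate_peak_landscape` — a 3-chromosome pseudo-genome of disjoint
  peaks carrying planted chromatin-state classes (naive/primed/shared
  enhancers, active and bivalent promoters, unmarked background) as
  factor/state track peak sets plus a mark-intensity matrix and TSS
  annotation;
* :func:`simulate_expression` — two-condition expression matrices with
  planted up/down DEGs;
* :func:`simulate_atac_counts` — per-peak negative-binomial ATAC counts with
  planted accessibility gains/losses in a comparison (e.g. knockout) arm.

Counts are negative-binomial (gamma-Poisson; Poisson in the limit
dispersion -> 0).  Peak widths are log-normal around 500 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occupancy_states import STATES, TRACKS

DEFAULT_CHROM_SIZES = {"chrS1": 60_000_000, "chrS2": 40_000_000, "chrS3": 25_000_000}

# track patterns of the planted chromatin-state classes: which (factor, state)
# tracks are "on" for a peak of each class
CLASS_PATTERNS: dict[str, frozenset[str]] = {
    "naive_enhancer": frozenset({"OCT4_naive", "H3K27ac_naive"}),
    "primed_enhancer": frozenset({"OCT4_primed", "H3K27ac_primed"}),
    "shared_enhancer": frozenset(
        {"OCT4_naive", "H3K27ac_naive", "OCT4_primed", "H3K27ac_primed"}
    ),
    "active_promoter_shared": frozenset(
        {
            "OCT4_naive",
            "H3K27ac_naive",
            "H3K4me3_naive",
            "OCT4_primed",
            "H3K27ac_primed",
            "H3K4me3_primed",
        }
    ),
    "bivalent_promoter": frozenset(
        {"H3K4me3_naive", "H3K27me3_naive", "H3K4me3_primed", "H3K27me3_primed"}
    ),
    "background": frozenset(),
}

PROMOTER_CLASSES = ("active_promoter_shared", "bivalent_promoter")


def _nb_counts(
    rng: np.random.Generator, mean: float | np.ndarray, dispersion: float, size=None
) -> np.ndarray:
    """Negative-binomial via gamma-Poisson; Poisson when dispersion ~ 0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), np.shape(mean) if size is None else size)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


@dataclass(frozen=True)
class ApmsSimConfig:
    """Replicated AP-MS design with planted true preys.

    ``enrichment_fold`` is the mean bait/control count ratio of true preys;
    1 is the null configuration (no enrichment anywhere).  ``dropout_rate``
    is the per-experiment probability that a true prey goes undetected.
    ``id_fail_rate`` is the fraction of records sampled to fail the
    identification-quality gate (score <= 10 or peptides <= 2).
    """

    n_proteins: int = 2000
    n_true_interactors: int = 30
    n_experiments: int = 4
    enrichment_fold: float = 10.0
    background_mean: float = 10.0
    crapome_runs: int = 400
    dropout_rate: float = 0.10
    dispersion: float = 0.2
    id_fail_rate: float = 0.05
    sticky_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_interactors > self.n_proteins:
            raise ValueError("n_true_interactors cannot exceed n_proteins")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1 (1 is the null)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")
        if self.crapome_runs < 1:
            raise ValueError("crapome_runs must be >= 1")
        if self.n_experiments < 1:
            raise ValueError("need at least one experiment")


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def simulate_apms(config: ApmsSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated bait/control spectral-count records plus truth labels.

    Returns a tidy record table (protein_id, experiment_id, bait_counts,
    control_counts, identification_score, n_peptides) containing one row per
    protein detected (bait count > 0 after dropout) in each experiment, and a
    truth table (protein_id, is_true_interactor, is_sticky).
    """
    rng = np.random.default_rng(config.seed)
    proteins = np.array(_protein_ids(config.n_proteins))
    is_true = np.zeros(config.n_proteins, dtype=bool)
    is_true[: config.n_true_interactors] = True
    # sticky contaminants drawn from the background proteins
    n_sticky = int(round(config.sticky_fraction * (config.n_proteins - config.n_true_interactors)))
    is_sticky = np.zeros(config.n_proteins, dtype=bool)
    bg_idx = np.where(~is_true)[0]
    is_sticky[rng.choice(bg_idx, size=n_sticky, replace=False)] = True

    bait_mean = np.where(
        is_true, config.enrichment_fold * config.background_mean, config.background_mean
    )
    experiments = [f"IP{j + 1}" for j in range(config.n_experiments)]
    rows = []
    for exp in experiments:
        bait = _nb_counts(rng, bait_mean, config.dispersion)
        control = _nb_counts(
            rng, np.full(config.n_proteins, config.background_mean), config.dispersion
        )
        dropped = is_true & (rng.random(config.n_proteins) < config.dropout_rate)
        bait = np.where(dropped, 0, bait)
        detected = bait > 0
        n_det = int(detected.sum())
        fails = rng.random(n_det) < config.id_fail_rate
        score = np.where(fails, rng.uniform(1.0, 10.0, n_det), rng.uniform(15.0, 80.0, n_det))
        peptides = np.where(
            fails, rng.integers(1, 3, n_det), rng.integers(3, 26, n_det)
        )
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": proteins[detected],
                    "experiment_id": exp,
                    "bait_counts": bait[detected],
                    "control_counts": control[detected],
                    "identification_score": np.round(score, 2),
                    "n_peptides": peptides,
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {"protein_id": proteins, "is_true_interactor": is_true, "is_sticky": is_sticky}
    )
    return records, truth


def simulate_crapome(config: ApmsSimConfig) -> pd.DataFrame:
    """Contaminant-frequency table aligned to :func:`simulate_apms` truth.

    Sticky contaminants get frequencies strictly above 0.2; true preys and
    ordinary background stay at or below 0.2.  Frequencies live on the
    k / crapome_runs grid.  Uses a seed offset so the table is independent of
    the count draws yet still a pure function of the config.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth_rng = np.random.default_rng(config.seed)
    proteins = np.array(_protein_ids(config.n_proteins))
    is_true = np.zeros(config.n_proteins, dtype=bool)
    is_true[: config.n_true_interactors] = True
    n_sticky = int(round(config.sticky_fraction * (config.n_proteins - config.n_true_interactors)))
    is_sticky = np.zeros(config.n_proteins, dtype=bool)
    bg_idx = np.where(~is_true)[0]
    is_sticky[truth_rng.choice(bg_idx, size=n_sticky, replace=False)] = True

    runs = config.crapome_runs
    lo = int(np.floor(0.2 * runs)) + 1  # smallest count with frequency > 0.2
    max_low = int(np.floor(0.2 * runs))  # largest count with frequency <= 0.2
    k = np.where(
        is_sticky,
        rng.integers(lo, runs + 1, config.n_proteins),
        rng.integers(0, max_low + 1, config.n_proteins),
    )
    return pd.DataFrame(
        {"protein_id": proteins, "contaminant_frequency": k / runs}
    )


@dataclass(frozen=True)
class GenomeSimConfig:
    """Planted chromatin-state landscape on a small pseudo-genome."""

    n_peaks_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "naive_enhancer": 700,
            "primed_enhancer": 700,
            "shared_enhancer": 500,
            "active_promoter_shared": 400,
            "bivalent_promoter": 300,
            "background": 400,
        }
    )
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    mark_signal: float = 10.0
    mark_noise: float = 1.0
    intensity_cv: float = 0.25
    peak_width_median: float = 500.0
    peak_width_log_sd: float = 0.25
    track_jitter: int = 50
    n_genes: int = 400
    tss_near_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_peaks_per_class) - set(CLASS_PATTERNS)
        if unknown:
            raise ValueError(f"unknown peak classes: {sorted(unknown)}")
        if any(v < 0 for v in self.n_peaks_per_class.values()):
            raise ValueError("peak counts must be non-negative")
        if self.mark_signal <= self.mark_noise:
            raise ValueError("mark_signal must exceed mark_noise")
        if not 0 <= self.tss_near_fraction <= 1:
            raise ValueError("tss_near_fraction must lie in [0, 1]")


def simulate_peak_landscape(
    config: GenomeSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Planted peak landscape.

    Returns ``(track_peaksets, landscape, intensities, tss)`` where

    * ``track_peaksets`` maps each (factor, state) track label to a BED-like
      peak DataFrame (intervals of peaks where that track is "on", slightly
      jittered);
    * ``landscape`` is the full disjoint peak universe (chrom, start, end,
      name, class_label) — the merged-peak analogue, with truth labels;
    * ``intensities`` is peaks x tracks mean signal (signal mean for "on"
      tracks, noise mean for "off", multiplicative log-normal noise);
    * ``tss`` is a TSS annotation (gene_id, chrom, tss_position, strand) with
      ``tss_near_fraction`` of promoter-class peaks within 20 kb of a TSS.
    """
    rng = np.random.default_rng(config.seed)
    classes = [
        cls
        for cls, n in sorted(config.n_peaks_per_class.items())
        for _ in range(n)
    ]
    n_peaks = len(classes)
    if n_peaks == 0:
        raise ValueError("no peaks requested")
    classes = list(np.array(classes)[rng.permutation(n_peaks)])

    widths = np.maximum(
        50,
        rng.lognormal(np.log(config.peak_width_median), config.peak_width_log_sd, n_peaks),
    ).astype(np.int64)
    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_of = rng.choice(len(chroms), size=n_peaks, p=sizes / sizes.sum())

    chrom_col, start_col, end_col = [], [], []
    order = np.argsort(chrom_of, kind="mergesort")
    pos_cursor = {c: 0 for c in range(len(chroms))}
    starts = np.zeros(n_peaks, dtype=np.int64)
    for idx in order:
        ci = chrom_of[idx]
        gap = int(rng.integers(1_000, 8_000))
        start = pos_cursor[ci] + gap
        end = start + int(widths[idx])
        if end > config.chrom_sizes[chroms[ci]]:
            raise ValueError(
                f"peaks overflow chromosome {chroms[ci]}; enlarge chrom_sizes or reduce counts"
            )
        starts[idx] = start
        pos_cursor[ci] = end
    for i in range(n_peaks):
        chrom_col.append(chroms[chrom_of[i]])
        start_col.append(int(starts[i]))
        end_col.append(int(starts[i] + widths[i]))

    landscape = pd.DataFrame(
        {
            "chrom": chrom_col,
            "start": start_col,
            "end": end_col,
            "name": [f"peak_{i:05d}" for i in range(1, n_peaks + 1)],
            "class_label": classes,
        }
    )

    log_sd = np.sqrt(np.log1p(config.intensity_cv**2))
    intensities = pd.DataFrame(index=landscape["name"], columns=list(TRACKS), dtype=float)
    on_matrix = {}
    for track in TRACKS:
        on = np.array([track in CLASS_PATTERNS[c] for c in classes])
        on_matrix[track] = on
        mean = np.where(on, config.mark_signal, config.mark_noise)
        intensities[track] = mean * rng.lognormal(-0.5 * log_sd**2, log_sd, n_peaks)

    track_peaksets: dict[str, pd.DataFrame] = {}
    for track in TRACKS:
        on = on_matrix[track]
        sub = landscape.loc[on, ["chrom", "start", "end", "name"]].reset_index(drop=True)
        if len(sub) and config.track_jitter > 0:
            jit_s = rng.integers(-config.track_jitter, config.track_jitter + 1, len(sub))
            jit_e = rng.integers(-config.track_jitter, config.track_jitter + 1, len(sub))
            sub["start"] = np.maximum(0, sub["start"] + jit_s)
            sub["end"] = np.maximum(sub["start"] + 50, sub["end"] + jit_e)
        track_peaksets[track] = sub

    # TSS annotation: promoter-class peaks get a nearby TSS for a configurable
    # fraction; remaining genes scatter uniformly over the genome
    tss_rows = []
    gene_i = 0
    prom_idx = landscape.index[landscape["class_label"].isin(PROMOTER_CLASSES)]
    for idx in prom_idx:
        if rng.random() >= config.tss_near_fraction:
            continue
        gene_i += 1
        mid = (landscape.at[idx, "start"] + landscape.at[idx, "end"]) // 2
        offset = int(rng.integers(-15_000, 15_001))
        tss_rows.append(
            {
                "gene_id": f"G{gene_i:05d}",
                "chrom": landscape.at[idx, "chrom"],
                "tss_position": max(0, int(mid + offset)),
                "strand": rng.choice(["+", "-"]),
            }
        )
    while gene_i < config.n_genes:
        gene_i += 1
        ci = int(rng.integers(0, len(chroms)))
        tss_rows.append(
            {
                "gene_id": f"G{gene_i:05d}",
                "chrom": chroms[ci],
                "tss_position": int(rng.integers(0, config.chrom_sizes[chroms[ci]])),
                "strand": rng.choice(["+", "-"]),
            }
        )
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "tss_position", "strand"])
    return track_peaksets, landscape, intensities, tss


@dataclass(frozen=True)
class ExprSimConfig:
    """Two-condition expression design with planted DEGs.

    Values emulate FPKM on a linear scale: per-gene baseline means are
    log-normal, replicate noise is Gaussian with coefficient of variation
    ``dispersion``, and planted DEGs shift the comparison-condition mean by
    ``effect_log2fc`` in log2 units.
    """

    n_genes: int = 5000
    n_replicates: int = 2
    n_deg_up: int = 0
    n_deg_down: int = 0
    effect_log2fc: float = 3.0
    dispersion: float = 0.1
    base_mean: float = 20.0
    base_log_sd: float = 0.5
    quant_type: str = "paired_end_FPKM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ValueError("planted DEGs exceed gene count")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition (t-test undefined)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def simulate_expression(config: ExprSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) plus truth DEG labels.

    Samples are named ``A_1..A_r`` (reference condition) and ``B_1..B_r``
    (comparison); planted 'up' genes are higher in B.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    base = rng.lognormal(np.log(config.base_mean), config.base_log_sd, config.n_genes)
    effect = np.zeros(config.n_genes)
    effect[: config.n_deg_up] = config.effect_log2fc
    effect[config.n_deg_up : config.n_deg_up + config.n_deg_down] = -config.effect_log2fc
    perm = rng.permutation(config.n_genes)
    base, effect = base[perm], effect[perm]

    mean_a = base
    mean_b = base * np.power(2.0, effect)
    sd = config.dispersion * base  # common per-gene sd keeps the null t exact
    r = config.n_replicates
    a = mean_a[:, None] + rng.normal(0.0, 1.0, (config.n_genes, r)) * sd[:, None]
    b = mean_b[:, None] + rng.normal(0.0, 1.0, (config.n_genes, r)) * sd[:, None]
    values = np.clip(np.concatenate([a, b], axis=1), 0.0, None)
    cols = [f"A_{j + 1}" for j in range(r)] + [f"B_{j + 1}" for j in range(r)]
    matrix = pd.DataFrame(values, index=genes, columns=cols)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_deg": effect != 0,
            "direction": np.where(effect > 0, "up", np.where(effect < 0, "down", "null")),
            "effect_log2fc": effect,
        }
    )
    return matrix, truth


@dataclass(frozen=True)
class AtacSimConfig:
    """Two-arm per-peak ATAC count design with planted accessibility changes."""

    n_peaks: int = 10_000
    n_replicates: int = 3
    n_dar_up: int = 0
    n_dar_down: int = 0
    effect_log2fc: float = 3.0
    dispersion: float = 0.1
    mean_count: float = 400.0
    mean_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dar_up + self.n_dar_down > self.n_peaks:
            raise ValueError("planted DARs exceed peak count")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per arm (t-test undefined)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def simulate_atac_counts(
    config: AtacSimConfig,
    peak_classes: pd.Series | None = None,
    affected_classes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak count matrix (peaks x samples) plus truth DAR labels.

    Arms are ``ref_1..ref_r`` and ``ko_1..ko_r``.  By default
    ``n_dar_down`` / ``n_dar_up`` peaks are planted at random positions; when
    ``peak_classes`` (a class label per peak, e.g. from the peak landscape)
    and ``affected_classes`` are given, accessibility loss is planted in
    exactly the peaks of the affected classes instead, emulating a knockout
    that collapses specific enhancer classes.
    """
    rng = np.random.default_rng(config.seed)
    if peak_classes is not None:
        if len(peak_classes) != config.n_peaks:
            raise ValueError("peak_classes must align with n_peaks")
        peaks = [str(p) for p in peak_classes.index]
    else:
        peaks = [f"peak_{i:05d}" for i in range(1, config.n_peaks + 1)]
    base = rng.lognormal(np.log(config.mean_count), config.mean_log_sd, config.n_peaks)

    effect = np.zeros(config.n_peaks)
    if peak_classes is not None and affected_classes:
        affected = peak_classes.isin(list(affected_classes)).to_numpy()
        effect[affected] = -config.effect_log2fc
    else:
        effect[: config.n_dar_up] = config.effect_log2fc
        effect[config.n_dar_up : config.n_dar_up + config.n_dar_down] = -config.effect_log2fc
        effect = effect[rng.permutation(config.n_peaks)]

    r = config.n_replicates
    mean_ref = base
    mean_ko = base * np.power(2.0, effect)
    ref = np.column_stack(
        [_nb_counts(rng, mean_ref, config.dispersion) for _ in range(r)]
    )
    ko = np.column_stack([_nb_counts(rng, mean_ko, config.dispersion) for _ in range(r)])
    cols = [f"ref_{j + 1}" for j in range(r)] + [f"ko_{j + 1}" for j in range(r)]
    counts = pd.DataFrame(
        np.concatenate([ref, ko], axis=1), index=peaks, columns=cols, dtype=np.int64
    )
    truth = pd.DataFrame(
        {
            "peak_id": peaks,
            "is_dar": effect != 0,
            "direction": np.where(effect > 0, "up", np.where(effect < 0, "down", "null")),
            "effect_log2fc": effect,
        }
    )
    return counts, truth
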