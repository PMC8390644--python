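"""Chromatin-state clustering over merged peak occupancy profiles.

Builds a peaks x (factor, state) occupancy matrix over a merged peak set —
binary reciprocal-overlap flags and/or mean track intensities — partitions it
with best-of-restarts k-means (Lloyd), and annotates the resulting clusters
with rule-based chromatin-state labels from the centroid mark patterns:
enhancers carry OCT4 and H3K27ac without H3K4me3/H3K27me3, active promoters
add H3K4me3, bivalent promoters carry both H3K4me3 and H3K27me3.  State
specificity (naive / primed / shared) comes from whether the pattern holds in
one or both cell states' tracks.

k-means is implemented directly (not delegated) because the contract here
pins semantics a generic implementation does not expose: within-run
monotonicity of the objective is asserted every iteration, empty clusters are
re-seeded from the point farthest from its assigned centroid, and the
returned model is the best over ``n_restarts`` independent seedings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interval_ops import reciprocal_overlap_mask

FACTORS = ("OCT4", "H3K27ac", "H3K4me3", "H3K27me3")
STATES = ("naive", "primed")
TRACKS = tuple(f"{f}_{s}" for f in FACTORS for s in STATES)

CLASS_LABELS = (
    "naive_enhancer",
    "primed_enhancer",
    "shared_enhancer",
    "active_promoter_shared",
    "active_promoter_naive",
    "bivalent_promoter",
    "other",
)


@dataclass
class OccupancyMatrix:
    """Peaks x tracks occupancy: binary overlap flags and optional intensities."""

    peak_ids: list[str]
    binary: pd.DataFrame
    intensity: pd.DataFrame | None = None

    def features(self) -> pd.DataFrame:
        """Clustering feature layer: intensities when available, else flags."""
        return self.intensity if self.intensity is not None else self.binary


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray
    centroids: pd.DataFrame  # k x tracks
    inertia: float
    seed: int
    n_iter_max: int
    n_restarts: int


def build_occupancy_matrix(
    merged_peaks: pd.DataFrame,
    track_peaksets: dict[str, pd.DataFrame],
    track_intensities: pd.DataFrame | None = None,
    min_frac: float = 0.25,
) -> OccupancyMatrix:
    """Binary (and optionally intensity) occupancy of tracks over merged peaks.

    The binary flag for (peak, track) is 1 iff the peak has a qualifying
    reciprocal overlap (either-mode, ``min_frac``) with some interval of that
    track's peak set.  ``track_intensities``, if given, is a peaks x tracks
    DataFrame of mean per-base signal aligned to ``merged_peaks`` order.
    """
    if "name" in merged_peaks.columns:
        peak_ids = [str(n) for n in merged_peaks["name"]]
    else:
        peak_ids = [f"peak_{i}" for i in range(1, len(merged_peaks) + 1)]
    flags = {}
    for track, peaks in track_peaksets.items():
        flags[track] = reciprocal_overlap_mask(
            merged_peaks, peaks, min_frac=min_frac, either=True
        ).astype(np.int8)
    binary = pd.DataFrame(flags, index=peak_ids)
    intensity = None
    if track_intensities is not None:
        if len(track_intensities) != len(merged_peaks):
            raise ValueError("intensity table does not align with merged peaks")
        intensity = track_intensities.copy()
        intensity.index = peak_ids
    return OccupancyMatrix(peak_ids=peak_ids, binary=binary, intensity=intensity)


def normalize_tracks(features: pd.DataFrame, quantile: float = 0.95) -> pd.DataFrame:
    """Scale each track by its upper quantile and clip to [0, 1].

    Bounds outliers so a handful of extreme peaks cannot dominate the
    clustering geometry; binary layers pass through unchanged.
    """
    out = features.astype(float).copy()
    for col in out.columns:
        ref = out[col].quantile(quantile)
        if ref > 0:
            out[col] = np.clip(out[col] / ref, 0.0, 1.0)
    return out


def _lloyd_once(
    x: np.ndarray, k: int, n_iter_max: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    prev_inertia = np.inf
    assign = np.zeros(n, dtype=np.int64)
    for _ in range(n_iter_max):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        point_d2 = d2[np.arange(n), new_assign]
        # re-seed empty clusters from the current farthest point
        for c in range(k):
            if not (new_assign == c).any():
                far = int(point_d2.argmax())
                centroids[c] = x[far]
                new_assign[far] = c
                point_d2[far] = 0.0
        inertia = float(point_d2.sum())
        if inertia > prev_inertia + 1e-9 * max(prev_inertia, 1.0):
            raise AssertionError("k-means objective increased within a run")
        if (new_assign == assign).all() and np.isfinite(prev_inertia):
            break
        assign = new_assign
        prev_inertia = inertia
        for c in range(k):
            centroids[c] = x[assign == c].mean(axis=0)
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), assign].sum())
    return assign, centroids, inertia


def kmeans_cluster(
    matrix: OccupancyMatrix | pd.DataFrame,
    k: int = 10,
    n_iter_max: int = 1000,
    n_restarts: int = 1000,
    seed: int = 0,
) -> ClusterModel:
    """Best-of-restarts Lloyd k-means on the occupancy feature layer.

    Deterministic under ``seed``; the returned model has the smallest
    within-cluster sum of squares over all restarts.
    """
    features = matrix.features() if isinstance(matrix, OccupancyMatrix) else matrix
    x = features.to_numpy(dtype=float)
    if x.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        assign, centroids, inertia = _lloyd_once(x, k, n_iter_max, rng)
        if best is None or inertia < best[2]:
            best = (assign, centroids, inertia)
    assert best is not None
    assign, centroids, inertia = best
    return ClusterModel(
        k=k,
        assignments=assign,
        centroids=pd.DataFrame(centroids, columns=features.columns),
        inertia=inertia,
        seed=seed,
        n_iter_max=n_iter_max,
        n_restarts=n_restarts,
    )


def _pattern(c: pd.Series, state: str, tau: float) -> dict[str, bool]:
    return {
        "oct4": c[f"OCT4_{state}"] >= tau,
        "k27ac": c[f"H3K27ac_{state}"] >= tau,
        "k4me3": c[f"H3K4me3_{state}"] >= tau,
        "k27me3": c[f"H3K27me3_{state}"] >= tau,
    }


def _classify_centroid(c: pd.Series, tau: float) -> str:
    pat = {s: _pattern(c, s, tau) for s in STATES}

    def enhancer(s: str) -> bool:
        p = pat[s]
        return p["oct4"] and p["k27ac"] and not p["k4me3"] and not p["k27me3"]

    def promoter(s: str) -> bool:
        p = pat[s]
        return p["oct4"] and p["k27ac"] and p["k4me3"] and not p["k27me3"]

    def bivalent(s: str) -> bool:
        p = pat[s]
        return p["k4me3"] and p["k27me3"]

    if bivalent("naive") and bivalent("primed"):
        return "bivalent_promoter"
    if enhancer("naive") and enhancer("primed"):
        return "shared_enhancer"
    if enhancer("naive"):
        return "naive_enhancer"
    if enhancer("primed"):
        return "primed_enhancer"
    if promoter("naive") and promoter("primed"):
        return "active_promoter_shared"
    if promoter("naive"):
        return "active_promoter_naive"
    return "other"


def annotate_clusters(
    model: ClusterModel, matrix: OccupancyMatrix | None = None, tau: float = 0.5
) -> dict[int, str]:
    """Rule-based chromatin-state labels from normalized centroid mark patterns.

    Centroid values must be on a [0, 1] per-track scale (fit the model on
    ``normalize_tracks`` output or on the binary layer).  ``tau`` is the
    enrichment threshold separating "present" from "absent".
    """
    required = set(TRACKS)
    have = set(model.centroids.columns)
    if not required <= have:
        raise ValueError(f"missing required tracks: {sorted(required - have)}")
    return {
        cluster: _classify_centroid(row, tau)
        for cluster, row in model.centroids.iterrows()
    }


def cluster_composition(
    model: ClusterModel, annotation: dict[int, str] | None = None
) -> pd.DataFrame:
    """Per-cluster peak counts and proportions of the total peak set."""
    counts = np.bincount(model.assignments, minlength=model.k)
    total = counts.sum()
    out = pd.DataFrame(
        {
            "cluster": np.arange(model.k),
            "n_peaks": counts,
            "proportion": counts / total,
        }
    )
    if annotation is not None:
        out["class_label"] = [annotation.get(c, "other") for c in out["cluster"]]
    return out
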