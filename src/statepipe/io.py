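"""Readers and writers for the plain-text formats the pipeline consumes.

Peak sets travel as BED (3-6 columns, tab-separated, no header); spectral
counts travel as a tidy TSV in long "role" form (one row per protein,
experiment and role in {bait, control}); matrices travel as TSV with the id
column first and a header row of sample ids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3-6 column BED file into a peak DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write a peak DataFrame as 6-column BED (name/score/strand filled in)."""
    out = peaks.copy()
    if "name" not in out.columns:
        out["name"] = [f"peak_{i}" for i in range(1, len(out) + 1)]
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_tss(path: str | Path) -> pd.DataFrame:
    """Read a TSS annotation BED (chrom, start, end, gene_id, score, strand).

    The TSS position is the interval start (a 1-bp BED feature).
    """
    bed = read_bed(path)
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "tss_position": bed["start"],
            "strand": bed.get("strand", "."),
        }
    )


def write_tss(tss: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["tss_position"],
            "end": tss["tss_position"] + 1,
            "name": tss["gene_id"],
            "score": 0,
            "strand": tss.get("strand", "."),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_spectral_counts(path: str | Path) -> pd.DataFrame:
    """Read long-form spectral counts and pivot to the tidy record layout.

    Expected columns: protein_id, experiment_id, role (bait|control), counts,
    id_score, n_peptides.  Control rows supply control_counts; a protein
    without a control row in an experiment gets control_counts 0.
    """
    long = pd.read_csv(path, sep="\t")
    required = {"protein_id", "experiment_id", "role", "counts", "id_score", "n_peptides"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"spectral-count TSV lacks columns {sorted(missing)}")
    bait = long[long["role"] == "bait"]
    control = long[long["role"] == "control"]
    records = bait.rename(
        columns={"counts": "bait_counts", "id_score": "identification_score"}
    )[["protein_id", "experiment_id", "bait_counts", "identification_score", "n_peptides"]]
    ctrl = control.set_index(["protein_id", "experiment_id"])["counts"]
    key = pd.MultiIndex.from_frame(records[["protein_id", "experiment_id"]])
    records["control_counts"] = ctrl.reindex(key).fillna(0).astype(int).to_numpy()
    return records.reset_index(drop=True)


def write_spectral_counts(records: pd.DataFrame, path: str | Path) -> None:
    """Write tidy records in the long role form."""
    bait = pd.DataFrame(
        {
            "protein_id": records["protein_id"],
            "experiment_id": records["experiment_id"],
            "role": "bait",
            "counts": records["bait_counts"],
            "id_score": records["identification_score"],
            "n_peptides": records["n_peptides"],
        }
    )
    control = bait.copy()
    control["role"] = "control"
    control["counts"] = records["control_counts"].to_numpy()
    pd.concat([bait, control], ignore_index=True).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes/peaks x samples TSV matrix (first column = row ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
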