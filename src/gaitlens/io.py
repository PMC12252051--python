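"""Readers and writers for skeleton-sequence and embedding tables.

Two dialects are supported, both long-form (one row per frame-joint):

* ``csv`` — human-readable delimited text, convenient for fixtures and
  inspection; coordinates are written with 12 significant digits.
* ``parquet`` — compressed columnar container for cohorts; coordinates
  round-trip at full float64 precision.

Both carry a format tag column so files are self-describing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, JointSchema
from .types import EmbeddingVector, SkeletonSequence

FORMAT_TAG = "gaitlens-skeleton-v1"
FormatName = Literal["csv", "parquet"]

_COLUMNS = ["subject", "recording", "label", "dataset", "frame_rate",
            "frame", "joint", "x", "y", "z"]


class SkeletonIOError(ValueError):
    """Raised for malformed skeleton files (schema or parse problems)."""


def _to_frame(seqs: list[SkeletonSequence]) -> pd.DataFrame:
    parts = []
    for s in seqs:
        f, j, _ = s.positions.shape
        frames = np.repeat(np.arange(f), j)
        joints = np.tile(np.arange(j), f)
        flat = s.positions.reshape(f * j, 3)
        parts.append(pd.DataFrame({
            "subject": s.subject_id,
            "recording": s.recording_id,
            "label": "" if s.class_label is None else s.class_label,
            "dataset": s.dataset_tag,
            "frame_rate": s.frame_rate,
            "frame": frames,
            "joint": joints,
            "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2],
        }))
    if not parts:
        return pd.DataFrame(columns=_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def write_sequences(seqs: list[SkeletonSequence], path: str | Path,
                    format_name: FormatName = "csv") -> None:
    """Serialize sequences to ``path`` in the named dialect."""
    path = Path(path)
    df = _to_frame(seqs)
    if format_name == "csv":
        with open(path, "w") as fh:
            fh.write(f"# format: {FORMAT_TAG}\n")
            df.to_csv(fh, index=False, float_format="%.12g")
    elif format_name == "parquet":
        df.attrs["format"] = FORMAT_TAG
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown format {format_name!r}")


def read_sequences(path: str | Path, format_name: FormatName = "csv",
                   schema: JointSchema = DEFAULT_SCHEMA) -> list[SkeletonSequence]:
    """Parse a skeleton file into sequences grouped by (subject, recording).

    Frame order is preserved.  A recording whose frames do not all have
    exactly ``schema.n_joints`` joints raises :class:`SkeletonIOError` naming
    the offending recording; a non-numeric coordinate raises one naming the
    line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_name == "csv":
        df = pd.read_csv(path, comment="#",
                         dtype={"subject": str, "recording": str,
                                "label": str, "dataset": str})
        for col in ("x", "y", "z"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                # +3: 1-based, header line, format comment line
                line = int(bad.idxmax()) + 3
                raise SkeletonIOError(
                    f"non-numeric coordinate in column {col!r} at line {line}")
            df[col] = coerced
    elif format_name == "parquet":
        df = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown format {format_name!r}")

    if df.empty:
        return []
    df["label"] = df["label"].fillna("")
    seqs = []
    for (subject, recording), grp in df.groupby(["subject", "recording"], sort=True):
        counts = grp.groupby("frame")["joint"].count()
        if (counts != schema.n_joints).any():
            frame = int(counts[counts != schema.n_joints].index[0])
            raise SkeletonIOError(
                f"recording {subject}/{recording}: frame {frame} has "
                f"{int(counts.loc[frame])} joints, expected {schema.n_joints}")
        grp = grp.sort_values(["frame", "joint"], kind="stable")
        n_frames = grp["frame"].nunique()
        pos = grp[["x", "y", "z"]].to_numpy(float).reshape(
            n_frames, schema.n_joints, 3)
        label = str(grp["label"].iloc[0])
        seqs.append(SkeletonSequence(
            positions=pos,
            frame_rate=float(grp["frame_rate"].iloc[0]),
            subject_id=str(subject),
            class_label=label if label else None,
            dataset_tag=str(grp["dataset"].iloc[0]) if grp["dataset"].notna().all() else "",
            recording_id=str(recording),
        ))
    return seqs


def write_embeddings(embeddings: list[EmbeddingVector], path: str | Path) -> None:
    """Write 54-dim embedding vectors as delimited text with ids and labels."""
    rows = []
    for e in embeddings:
        row = {"instance": e.instance_id,
               "subject": "" if e.subject_id is None else e.subject_id,
               "label": "" if e.class_label is None else e.class_label}
        row.update({f"d{i:02d}": v for i, v in enumerate(e.flat)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_embeddings(path: str | Path) -> list[EmbeddingVector]:
    df = pd.read_csv(path, dtype={"instance": str, "subject": str, "label": str})
    dims = [f"d{i:02d}" for i in range(54)]
    out = []
    for _, row in df.iterrows():
        label = row.get("label")
        subject = row.get("subject")
        out.append(EmbeddingVector(
            values=row[dims].to_numpy(float).reshape(18, 3),
            instance_id=str(row["instance"]),
            class_label=None if pd.isna(label) or label == "" else str(label),
            subject_id=None if pd.isna(subject) or subject == "" else str(subject),
        ))
    return out
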