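"""File formats: wide TSV matrices, BED regions, SEG segments, Newick
dendrograms, clinical CSV, JSON reports.

Matrices are written with Python's shortest-roundtrip float repr, so a
write/read cycle reproduces values to full precision and outputs are
byte-stable under a fixed config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

__all__ = [
    "read_matrix", "write_matrix", "read_regions", "write_regions",
    "write_segments", "linkage_to_newick", "read_clinical", "write_json",
]


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a samples x probes matrix as TSV (first column sample ids)."""
    df = df.copy()
    df.index.name = df.index.name or "sample_id"
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    """Read a wide TSV matrix; header row of probe ids, first column
    sample ids.  Duplicate ids, ragged rows or non-numeric cells raise
    with row/column context."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids: {dupes[:5]}")
    if df.isna().any().any():
        bad = df.isna().stack()
        row, col = bad[bad].index[0]
        raise ValueError(f"missing/ragged cell at row {row!r}, column {col!r}")
    try:
        out = df.astype(float)
    except ValueError:
        for col in df.columns:
            mask = pd.to_numeric(df[col], errors="coerce").isna()
            if mask.any():
                row = df.index[mask.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r}: "
                    f"{df.loc[row, col]!r}") from None
        raise
    return out


def write_regions(regions: pd.DataFrame, path) -> None:
    """Write chrom/start/end(/name) regions as BED (0-based half-open)."""
    cols = ["chrom", "start", "end"] + (["name"] if "name" in regions else [])
    regions[cols].to_csv(path, sep="\t", header=False, index=False)


def read_regions(path) -> pd.DataFrame:
    """Read a BED file (3+ columns, 0-based half-open) into a sorted
    DataFrame with chrom/start/end[/name].  Overlaps are permitted and
    preserved; start >= end is an error."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: invalid interval {start}-{end}")
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "name": parts[3] if len(parts) > 3 else f"region_{ln}"})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start", "end"], kind="stable",
                          ignore_index=True)


def write_segments(profiles: dict, path) -> None:
    """Emit per-sample segments in SEG format
    (sample, chrom, start, end, n_markers, seg.mean)."""
    rows = []
    for sid, prof in profiles.items():
        for s in prof.segments:
            rows.append((sid, s.chrom, s.start, s.end, s.n_bins,
                         round(s.mean_log2, 6)))
    seg = pd.DataFrame(rows, columns=["ID", "chrom", "loc.start", "loc.end",
                                      "num.mark", "seg.mean"])
    seg.to_csv(path, sep="\t", index=False)


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "os_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (df["os_months"] < 0).any():
        raise ValueError("negative survival times in clinical table")
    df["event"] = df["event"].astype(bool)
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray,)):
        return x.tolist()
    if isinstance(x, (pd.Series,)):
        return x.to_dict()
    raise TypeError(f"not JSON serializable: {type(x)}")
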