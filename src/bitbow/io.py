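"""Plain-text I/O: cluster tables, code counts, SWC traces, TIFF volumes.

All tabular formats are header-bearing TSV/CSV so they can be inspected and
edited by hand; image volumes go through tifffile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_cluster_table",
    "write_cluster_table",
    "read_code_counts",
    "write_code_counts",
    "read_swc",
    "write_swc",
    "read_volume",
    "write_volume",
]

CLUSTER_COLUMNS = ["brain_id", "cluster_id", "code"]
SWC_COLUMNS = ["node_id", "type", "x", "y", "z", "radius", "parent"]

#: SWC structure-type code for somata (column 2 of the standard format).
SWC_SOMA_TYPE = 1


def read_cluster_table(path) -> pd.DataFrame:
    """Read a cluster observation table (TSV, one row per labeled clone)."""
    df = pd.read_csv(path, sep="\t", dtype={"code": str})
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cluster table missing columns {missing}")
    if df.duplicated(subset=["brain_id", "cluster_id"]).any():
        raise ValueError("(brain_id, cluster_id) pairs must be unique")
    if (df["code"].str.replace("-", "", regex=False).str.strip("0") == "").any():
        raise ValueError("cluster codes must be nonzero")
    return df


def write_cluster_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_code_counts(path) -> dict[str, int]:
    """Two-column TSV (code, count) -> count table."""
    df = pd.read_csv(path, sep="\t", dtype={"code": str})
    if not {"code", "count"}.issubset(df.columns):
        raise ValueError("code-count TSV must have columns code, count")
    return dict(zip(df["code"], df["count"].astype(int)))


def write_code_counts(counts: dict[str, int], path) -> None:
    pd.DataFrame(
        {"code": list(counts.keys()), "count": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


def read_swc(path) -> pd.DataFrame:
    """Read a standard 7-column SWC trace (comments start with '#')."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=SWC_COLUMNS,
    )
    df["node_id"] = df["node_id"].astype(int)
    df["type"] = df["type"].astype(int)
    df["parent"] = df["parent"].astype(int)
    return df


def write_swc(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + " ".join(SWC_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{int(row.node_id)} {int(row.type)} {row.x:.3f} {row.y:.3f} "
                f"{row.z:.3f} {row.radius:.3f} {int(row.parent)}\n"
            )


def read_volume(path) -> np.ndarray:
    """Read a channel-first (C, Z, Y, X) multichannel TIFF volume."""
    vol = tifffile.imread(path)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4-D (C, Z, Y, X) volume, got shape {vol.shape}")
    return vol


def write_volume(volume: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32))
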