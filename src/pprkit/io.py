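"""Delimited-text I/O with provenance headers.

All tabular formats are plain delimited text (comma or tab, auto-detected).
Output tables carry ``#``-prefixed provenance comment lines (tool version,
config hash, seed, generation timestamp); readers skip them. The
``generated_at`` line is excluded when hashing outputs, so identically
seeded runs are hash-identical.
"""

from __future__ import annotations

import hashlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome
from .ppr import AtrophyTrajectory

__all__ = [
    "read_connectome",
    "write_connectome",
    "read_atrophy_long",
    "read_table",
    "write_table",
    "file_digest",
]

ATROPHY_COLUMNS = ("subject_id", "region", "t_years", "atrophy")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","
    return ","


def _provenance_lines(meta: dict | None) -> list[str]:
    from . import __version__

    lines = [f"# pprkit_version: {__version__}"]
    for key, val in (meta or {}).items():
        lines.append(f"# {key}: {val}")
    stamp = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    lines.append(f"# generated_at: {stamp}")
    return lines


def read_connectome(
    path, labels_path=None, delimiter: str | None = None
) -> Connectome:
    """Read a square connectivity matrix; labels from a header row or file.

    A non-numeric first row is taken as region labels; a separate
    one-label-per-line file overrides it.
    """
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    rows = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split(delimiter)]
            try:
                rows.append([float(f) for f in fields])
            except ValueError:
                if header is None and not rows:
                    header = fields
                else:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric matrix row"
                    ) from None
    if not rows:
        raise ValueError(f"{path}: no matrix rows found")
    M = np.asarray(rows, dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is {M.shape[0]}x{M.shape[1]}, not square")
    labels = header
    if labels_path is not None:
        labels = [
            ln.strip()
            for ln in Path(labels_path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    if labels is not None and len(labels) != M.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for a {M.shape[0]}-region matrix"
        )
    return Connectome.from_matrix(M, labels=labels)


def write_connectome(
    conn: Connectome, path, delimiter: str = ",", meta: dict | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_lines(meta):
            fh.write(line + "\n")
        fh.write(delimiter.join(conn.labels) + "\n")
        for row in conn.C:
            fh.write(delimiter.join(f"{v:.10g}" for v in row) + "\n")


def read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited table, skipping provenance comment lines."""
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    return pd.read_csv(path, sep=delimiter, comment="#")


def write_table(
    df: pd.DataFrame, path, delimiter: str = ",", meta: dict | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep=delimiter, index=False)


def read_atrophy_long(path, region_labels, delimiter: str | None = None) -> list:
    """Read a long-format atrophy table into per-subject trajectories.

    Columns: subject_id, region, t_years, atrophy. Region labels are
    validated against the connectome ordering; unknown labels and malformed
    rows raise with the offending names.
    """
    df = read_table(path, delimiter=delimiter)
    missing = [c for c in ATROPHY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad = ~np.isfinite(pd.to_numeric(df["atrophy"], errors="coerce"))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]
        raise ValueError(f"{path}: malformed atrophy values near data rows {lines}")
    labels = list(region_labels)
    unknown = sorted(set(df["region"]) - set(labels))
    if unknown:
        raise ValueError(
            f"{path}: region label(s) not in the connectome: {unknown[:10]}"
        )
    trajectories = []
    for sid, sub in df.groupby("subject_id", sort=True):
        wide = sub.pivot_table(
            index="t_years", columns="region", values="atrophy", aggfunc="first"
        )
        absent = sorted(set(labels) - set(wide.columns))
        if absent:
            raise ValueError(
                f"{path}: subject {sid} missing region(s) {absent[:10]}"
            )
        wide = wide[labels].sort_index()
        t = wide.index.to_numpy(dtype=float)
        trajectories.append(
            AtrophyTrajectory(
                subject_id=str(sid),
                t_long=t - t[0],
                phi=wide.to_numpy(dtype=float),
                region_labels=tuple(labels),
            )
        )
    return trajectories


def file_digest(path) -> str:
    """SHA-256 of a text file, ignoring the generation-timestamp line."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for line in fh:
            if line.startswith(b"# generated_at:"):
                continue
            h.update(line)
    return h.hexdigest()
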