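"""Delimited-text readers and writers for every artifact the pipeline emits.

All formats are plain text: tab-delimited square matrices (with optional
``# key=value`` comment headers), a tab-delimited atlas table with header
``node_id label x y z``, a profiles CSV, a cohort manifest of
``subject_id group path`` lines, and a checksummed output manifest.
Writers format floats at full round-trip precision so write-then-read is
an identity.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .construction import BinaryNetwork, CorrelationMatrix
from .errors import ParseError
from .metrics import TopologyProfile
from .synthetic import SubjectTimeSeries

PROFILE_COLUMNS = [
    "subject_id",
    "group",
    "threshold",
    "global_efficiency",
    "clustering_coefficient",
    "edge_count",
    "transitivity",
    "long_distance_edge_count",
]


# ---------------------------------------------------------------------------
# matrices


def write_matrix(path, values: np.ndarray, header: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        for row in np.asarray(values):
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    header[key.strip()] = val.strip()
                continue
            cells = line.split("\t")
            parsed = []
            for col, cell in enumerate(cells):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric cell in column {col}: {cell!r}")
            if rows and len(parsed) != len(rows[0]):
                raise ParseError(
                    path, lineno, f"row has {len(parsed)} columns, expected {len(rows[0])}"
                )
            rows.append(parsed)
    if not rows:
        raise ParseError(path, 1, "empty matrix file")
    values = np.array(rows)
    if values.shape[0] != values.shape[1]:
        raise ParseError(path, len(rows), f"matrix is {values.shape[0]}x{values.shape[1]}, not square")
    return values, header


def write_network(path, net: BinaryNetwork) -> None:
    header = {"subject_id": net.subject_id, "group": net.group}
    header["threshold"] = "none" if net.threshold is None else f"{net.threshold:.2f}"
    write_matrix(path, net.adjacency, header=header)


def read_network(path) -> BinaryNetwork:
    values, header = read_matrix(path)
    raw = header.get("threshold", "none")
    threshold = None if raw == "none" else float(raw)
    return BinaryNetwork(
        adjacency=values,
        threshold=threshold,
        subject_id=header.get("subject_id", ""),
        group=header.get("group", ""),
    )


def write_correlation(path, corr: CorrelationMatrix) -> None:
    write_matrix(path, corr.values, header={"subject_id": corr.subject_id, "group": corr.group})


def read_correlation(path) -> CorrelationMatrix:
    values, header = read_matrix(path)
    return CorrelationMatrix(
        values=values, subject_id=header.get("subject_id", ""), group=header.get("group", "")
    )


# ---------------------------------------------------------------------------
# atlas


def write_atlas(path, atlas: RegionAtlas) -> None:
    with Path(path).open("w") as fh:
        fh.write("node_id\tlabel\tx\ty\tz\n")
        for i, label in enumerate(atlas.labels):
            x, y, z = atlas.coords[i]
            fh.write(f"{i}\t{label}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")


def read_atlas(path) -> RegionAtlas:
    path = Path(path)
    labels, coords = [], []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["node_id", "label", "x", "y", "z"]:
            raise ParseError(path, 1, f"unexpected atlas header: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 5:
                raise ParseError(path, lineno, f"expected 5 columns, got {len(cells)}")
            try:
                coords.append([float(c) for c in cells[2:5]])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric coordinate")
            labels.append(cells[1])
    return RegionAtlas(labels=tuple(labels), coords=np.array(coords))


# ---------------------------------------------------------------------------
# time series + cohort manifest


def write_timeseries(path, ts: SubjectTimeSeries) -> None:
    with Path(path).open("w") as fh:
        for row in ts.signal:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")


def read_timeseries(path, subject_id: str, group: str) -> SubjectTimeSeries:
    rows = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(c) for c in line.rstrip("\n").split("\t")])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric cell")
    return SubjectTimeSeries(subject_id=subject_id, group=group, signal=np.array(rows))


def write_cohort(out_dir, subjects: list[SubjectTimeSeries]) -> Path:
    """Write one time-series file per subject plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "cohort_manifest.tsv"
    with manifest.open("w") as fh:
        for ts in subjects:
            rel = f"ts_{ts.subject_id}.tsv"
            write_timeseries(out_dir / rel, ts)
            fh.write(f"{ts.subject_id}\t{ts.group}\t{rel}\n")
    return manifest


def read_cohort(manifest_path) -> list[SubjectTimeSeries]:
    manifest_path = Path(manifest_path)
    subjects = []
    with manifest_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise ParseError(manifest_path, lineno, "expected 'subject_id group path'")
            sid, group, rel = cells
            subjects.append(read_timeseries(manifest_path.parent / rel, sid, group))
    return subjects


# ---------------------------------------------------------------------------
# profiles


def profiles_to_frame(profiles: list[TopologyProfile]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": p.subject_id,
            "group": p.group,
            "threshold": p.threshold,
            "global_efficiency": p.global_efficiency,
            "clustering_coefficient": p.clustering_coefficient,
            "edge_count": p.edge_count,
            "transitivity": p.transitivity,
            "long_distance_edge_count": p.long_distance_edge_count,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profiles(path, profiles: list[TopologyProfile]) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False, float_format="%.17g")


def read_profiles(path) -> list[TopologyProfile]:
    frame = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(Path(path), 1, f"missing profile columns: {missing}")
    return [
        TopologyProfile(
            global_efficiency=row.global_efficiency,
            clustering_coefficient=row.clustering_coefficient,
            edge_count=row.edge_count,
            transitivity=row.transitivity,
            long_distance_edge_count=row.long_distance_edge_count,
            threshold=None if pd.isna(row.threshold) else float(row.threshold),
            subject_id=row.subject_id,
            group=row.group,
        )
        for row in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# output manifest


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_output_manifest(out_dir, files: list[Path]) -> Path:
    out_dir = Path(out_dir)
    manifest = out_dir / "MANIFEST.tsv"
    with manifest.open("w") as fh:
        for f in sorted(files, key=lambda p: str(p)):
            fh.write(f"{Path(f).relative_to(out_dir)}\t{sha256_of(f)}\n")
    return manifest
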