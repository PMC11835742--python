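"""Readers and writers for the package's delimited-text interchange formats.

Tab-separated text is the canonical container: BOLD matrices are regions x
volumes, coordinates are N x 3 mm, connectomes are square matrices.  Profiles
and reports serialize to JSON.  All writers round-trip through their readers
to full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import ParcelGeometry
from .synthetic import SubjectRecord
from .turbulence import BoldTimeseries, TurbulenceProfile

_FMT = "%.17g"  # lossless for float64


def _parse_matrix(path: Path | str, what: str) -> np.ndarray:
    """Parse a delimited-text matrix with row/column-resolved errors."""
    path = Path(path)
    rows: list[list[float]] = []
    width = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.split()
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(cells)} cells, expected {width})"
                )
            row = []
            for col, cell in enumerate(cells, start=1):
                try:
                    value = float(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                        f"column {col}"
                    ) from exc
                if not np.isfinite(value):
                    raise ValueError(
                        f"{path}: non-finite value at line {lineno}, column {col}"
                    )
                row.append(value)
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty {what} file")
    return np.asarray(rows)


def read_timeseries(path: Path | str, tr: float, transpose: bool = False) -> BoldTimeseries:
    """Read a regions x volumes matrix (``transpose=True`` for volumes x regions)."""
    data = _parse_matrix(path, "timeseries")
    if transpose:
        data = data.T
    return BoldTimeseries(data=data, tr=tr)


def write_timeseries(path: Path | str, bold: BoldTimeseries) -> None:
    np.savetxt(path, bold.data, fmt=_FMT, delimiter="\t")


def read_coords(path: Path | str, rsn_labels=None) -> ParcelGeometry:
    """Read N x 3 centroid coordinates (mm) and derive the distance matrix."""
    coords = _parse_matrix(path, "coordinates")
    if coords.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns of mm coordinates")
    return ParcelGeometry.from_coords(coords, rsn_labels=rsn_labels)


def write_coords(path: Path | str, geom: ParcelGeometry) -> None:
    np.savetxt(path, geom.coords, fmt=_FMT, delimiter="\t")


def read_matrix(path: Path | str) -> np.ndarray:
    """Read a square delimited-text matrix (e.g. a connectome)."""
    m = _parse_matrix(path, "matrix")
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {m.shape}")
    return m


def write_matrix(path: Path | str, m: np.ndarray) -> None:
    np.savetxt(path, np.asarray(m), fmt=_FMT, delimiter="\t")


def read_labels(path: Path | str) -> np.ndarray:
    with Path(path).open() as fh:
        labels = [line.strip() for line in fh if line.strip()]
    return np.asarray(labels, dtype=object)


def write_labels(path: Path | str, labels) -> None:
    Path(path).write_text("\n".join(str(x) for x in labels) + "\n")


# ---------------------------------------------------------------------------
# profiles and cohorts
# ---------------------------------------------------------------------------

def profile_to_dict(profile: TurbulenceProfile) -> dict:
    return {
        "turbulence": {repr(k): v for k, v in profile.turbulence.items()},
        "node_metastability": {
            repr(k): list(v) for k, v in profile.node_metastability.items()
        },
        "cascade_flow": {f"{k[0]!r}|{k[1]!r}": v for k, v in profile.cascade_flow.items()},
        "information_cascade": profile.information_cascade,
        "information_transfer": {
            repr(k): v for k, v in profile.information_transfer.items()
        },
        "tr": profile.tr,
        "info_transfer_convention": profile.info_transfer_convention,
    }


def profile_from_dict(d: dict) -> TurbulenceProfile:
    return TurbulenceProfile(
        turbulence={float(k): v for k, v in d["turbulence"].items()},
        node_metastability={
            float(k): np.asarray(v) for k, v in d["node_metastability"].items()
        },
        cascade_flow={
            tuple(float(x) for x in k.split("|")): v
            for k, v in d["cascade_flow"].items()
        },
        information_cascade=d["information_cascade"],
        information_transfer={
            float(k): v for k, v in d["information_transfer"].items()
        },
        tr=d["tr"],
        info_transfer_convention=d.get("info_transfer_convention", ""),
    )


def write_profile(path: Path | str, profile: TurbulenceProfile) -> None:
    Path(path).write_text(json.dumps(profile_to_dict(profile), indent=1))


def read_profile(path: Path | str) -> TurbulenceProfile:
    return profile_from_dict(json.loads(Path(path).read_text()))


def write_cohort(directory: Path | str, records: list[SubjectRecord], spec_echo: dict | None = None) -> None:
    """Write one BOLD matrix per subject plus a JSON cohort manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": [], "spec": spec_echo or {}}
    for rec in records:
        fname = f"{rec.subject_id}_bold.tsv"
        write_timeseries(directory / fname, rec.bold)
        manifest["subjects"].append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "bold_file": fname,
                "tr": rec.bold.tr,
                "hamd6_baseline": rec.hamd6_baseline,
                "hamd6_pct_change": (
                    None if np.isnan(rec.hamd6_pct_change) else rec.hamd6_pct_change
                ),
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(directory: Path | str) -> list[SubjectRecord]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    records = []
    for entry in manifest["subjects"]:
        bold = read_timeseries(directory / entry["bold_file"], tr=entry["tr"])
        pct = entry["hamd6_pct_change"]
        records.append(
            SubjectRecord(
                subject_id=entry["subject_id"],
                group=entry["group"],
                bold=bold,
                hamd6_baseline=entry["hamd6_baseline"],
                hamd6_pct_change=float("nan") if pct is None else pct,
            )
        )
    return records
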