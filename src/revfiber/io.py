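"""CSV/TIFF readers and writers plus the run manifest.

CSV schemas
-----------
fibers.csv   section_id, fiber_id, x_um, y_um, csa_um2, stain_fraction, revertant
edges.csv    section_id, fiber_a, fiber_b
design.csv   mouse_id, age_group, muscle, section_id, section_area_mm2[, z_position_um]

Files are comma-separated UTF-8 with a mandatory header row.  Numeric
fields use a decimal point; a decimal comma is accepted on input and
normalized.
"""

from __future__ import annotations

import hashlib
import json
import platform
from importlib import metadata
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import FiberRecord, SectionGraph, StudyKey, ValidationError, validate_section
from .simulate import CohortTables

PathLike = Union[str, Path]

FIBER_COLUMNS = ("section_id", "fiber_id", "x_um", "y_um", "csa_um2", "stain_fraction", "revertant")
EDGE_COLUMNS = ("section_id", "fiber_a", "fiber_b")
DESIGN_COLUMNS = ("mouse_id", "age_group", "muscle", "section_id", "section_area_mm2")


def _read_csv(path: PathLike, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, column: str, path: PathLike) -> pd.Series:
    """Parse a numeric column, accepting decimal commas; report bad rows by line."""
    raw = df[column].str.replace(",", ".", regex=False)
    values = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    bad = values.isna() & (raw != "")
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header row, 1-based
        raise ValidationError(f"{path}: malformed {column!r} values at lines {lines}")
    return values


def _parse_bool(series: pd.Series, path: PathLike, column: str) -> pd.Series:
    mapping = {"0": False, "1": True, "false": False, "true": True}
    lowered = series.str.strip().str.lower()
    bad = ~lowered.isin(mapping)
    if bad.any():
        lines = (series.index[bad] + 2).tolist()[:10]
        raise ValidationError(f"{path}: malformed {column!r} values at lines {lines}")
    return lowered.map(mapping)


def read_fiber_tables(
    fibers_path: PathLike,
    edges_path: PathLike,
    design_path: PathLike,
) -> list[tuple[StudyKey, SectionGraph]]:
    """Load and validate a cohort's fiber, edge and design tables.

    Returns one ``(StudyKey, SectionGraph)`` per section, ordered as in
    the design table.  Any schema violation, malformed row or dangling
    edge raises :class:`ValidationError` with the offending location.
    """
    fibers = _read_csv(fibers_path, FIBER_COLUMNS)
    edges = _read_csv(edges_path, EDGE_COLUMNS)
    design = _read_csv(design_path, DESIGN_COLUMNS)

    fibers = fibers.assign(
        fiber_id=_numeric(fibers, "fiber_id", fibers_path).astype("Int64"),
        x_um=_numeric(fibers, "x_um", fibers_path),
        y_um=_numeric(fibers, "y_um", fibers_path),
        csa_um2=_numeric(fibers, "csa_um2", fibers_path),
        stain_fraction=_numeric(fibers, "stain_fraction", fibers_path),
        revertant=_parse_bool(fibers["revertant"], fibers_path, "revertant"),
    )
    edges = edges.assign(
        fiber_a=_numeric(edges, "fiber_a", edges_path).astype("Int64"),
        fiber_b=_numeric(edges, "fiber_b", edges_path).astype("Int64"),
    )
    design = design.assign(
        age_group=_numeric(design, "age_group", design_path).astype("Int64"),
        section_area_mm2=_numeric(design, "section_area_mm2", design_path),
    )
    if "z_position_um" in design.columns:
        design = design.assign(z_position_um=_numeric(design, "z_position_um", design_path))
    else:
        design = design.assign(z_position_um=0.0)

    fiber_groups = dict(tuple(fibers.groupby("section_id", sort=False)))
    edge_groups = dict(tuple(edges.groupby("section_id", sort=False)))

    out: list[tuple[StudyKey, SectionGraph]] = []
    for row in design.itertuples(index=False):
        key = StudyKey(mouse_id=row.mouse_id, age_group=int(row.age_group), muscle=row.muscle)
        section_id = row.section_id
        if section_id not in fiber_groups:
            raise ValidationError(f"{design_path}: section {section_id!r} has no fibers")
        fsub = fiber_groups[section_id]
        records = tuple(
            FiberRecord(
                fiber_id=int(r.fiber_id),
                centroid_xy=(float(r.x_um), float(r.y_um)),
                csa=float(r.csa_um2),
                revertant=bool(r.revertant),
                stain_fraction=None if pd.isna(r.stain_fraction) else float(r.stain_fraction),
            )
            for r in fsub.itertuples(index=False)
        )
        known = {r.fiber_id for r in records}
        section_edges = []
        if section_id in edge_groups:
            esub = edge_groups[section_id]
            for r in esub.itertuples(index=False):
                a, b = int(r.fiber_a), int(r.fiber_b)
                for endpoint in (a, b):
                    if endpoint not in known:
                        raise ValidationError(
                            f"{edges_path}: section {section_id!r} has an edge to "
                            f"missing fiber {endpoint}"
                        )
                section_edges.append((a, b))
        graph = SectionGraph(
            section_id=section_id,
            fibers=records,
            edges=tuple(section_edges),
            section_area_mm2=float(row.section_area_mm2),
            z_position=float(row.z_position_um),
        )
        problems = validate_section(graph)
        if problems:
            raise ValidationError(f"section {section_id!r}: " + "; ".join(problems))
        out.append((key, graph))
    return out


def write_cohort(cohort: CohortTables, out_dir: PathLike) -> dict[str, Path]:
    """Write a simulated cohort's tables as CSV files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("fibers", cohort.fibers),
        ("edges", cohort.edges),
        ("design", cohort.design),
        ("ground_truth", cohort.ground_truth),
    ):
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_labelmap(path: PathLike) -> np.ndarray:
    """Read a single-channel integer label map from TIFF."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a single-channel 2D label map, got shape {arr.shape}")
    return np.asarray(arr)


def write_labelmap(path: PathLike, label_map: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(label_map, dtype=np.uint16))


def _package_version(name: str) -> str:
    try:
        return metadata.version(name)
    except metadata.PackageNotFoundError:
        return "unknown"


def write_manifest(out_dir: PathLike, config: dict, seed: Optional[int] = None) -> Path:
    """Write a machine-readable run manifest enabling exact replay."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "python": platform.python_version(),
        "versions": {
            name: _package_version(name)
            for name in ("revfiber", "numpy", "pandas", "statsmodels", "networkx")
        },
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
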