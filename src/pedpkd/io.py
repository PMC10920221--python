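"""File readers/writers, run configuration and provenance.

CSV dialect is pinned: UTF-8, comma-delimited, period decimal separator,
locale-independent. Missing values are empty cells on write; "NA" is
accepted on read, never written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import bp as bp_mod
from . import cohort as cohort_mod
from . import lic as lic_mod
from . import renal as renal_mod
from .errors import SchemaError
from .volumetry import SliceAreaSeries, areas_from_mask

logger = logging.getLogger("pedpkd")

SLICE_AREA_COLUMNS = ["patient_id", "kidney_side", "slice_index", "area_mm2"]


def read_cohort(path, strict: bool = True) -> pd.DataFrame:
    """Read a cohort CSV against the documented flat schema.

    Unknown columns raise :class:`SchemaError` under ``strict`` (the
    default) and a warning otherwise; known-but-absent columns are added
    as missing so downstream code can rely on the full schema.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: required column 'patient_id' is missing")
    unknown = [c for c in df.columns if c not in cohort_mod.COHORT_COLUMNS
               and c not in cohort_mod.DERIVED_COLUMNS]
    if unknown:
        msg = f"{path}: unknown columns {unknown}"
        if strict:
            raise SchemaError(msg)
        logger.warning(msg)
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"{path}: duplicate patient_ids {dupes}")
    for col in cohort_mod.COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[cohort_mod.COHORT_COLUMNS
              + [c for c in cohort_mod.DERIVED_COLUMNS if c in df.columns]]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table; empty cells encode missing values."""
    cohort.to_csv(path, index=False, na_rep="")


def read_slice_areas(path, thickness_mm: Optional[float] = None) -> Dict[Tuple[str, str], SliceAreaSeries]:
    """Read a long-format slice-area CSV into per-kidney series.

    Columns: patient_id, kidney_side, slice_index, area_mm2 and optionally
    thickness_mm (else pass ``thickness_mm``). Slices are ordered by
    slice_index within each (patient, side).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in SLICE_AREA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: slice-area file missing columns {missing}")
    has_thickness = "thickness_mm" in df.columns
    if not has_thickness and thickness_mm is None:
        raise SchemaError(f"{path}: no thickness_mm column and no thickness given")
    out: Dict[Tuple[str, str], SliceAreaSeries] = {}
    for (pid, side), sub in df.groupby(["patient_id", "kidney_side"], sort=True):
        sub = sub.sort_values("slice_index")
        t = float(sub["thickness_mm"].iloc[0]) if has_thickness else float(thickness_mm)
        out[(pid, side)] = SliceAreaSeries(
            kidney_side=side, areas_mm2=tuple(sub["area_mm2"].astype(float)),
            slice_thickness_mm=t,
        )
    return out


def write_slice_areas(slice_areas: Dict[Tuple[str, str], SliceAreaSeries], path) -> None:
    rows = []
    for (pid, side), series in sorted(slice_areas.items()):
        for i, a in enumerate(series.areas_mm2):
            rows.append({"patient_id": pid, "kidney_side": side, "slice_index": i,
                         "area_mm2": a, "thickness_mm": series.slice_thickness_mm})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mask_nifti(path, label_value: int = 1, slice_axis: int = 2,
                    kidney_side: str = "left") -> SliceAreaSeries:
    """Per-slice areas from a NIfTI label mask; voxel spacing comes from
    the header."""
    import nibabel as nib

    img = nib.load(str(path))
    spacing = img.header.get_zooms()[:3]
    data = np.asarray(img.dataobj).astype(int)
    return areas_from_mask(data, spacing, label_value=label_value,
                           slice_axis=slice_axis, kidney_side=kidney_side)


@dataclass
class RunConfig:
    """End-to-end run configuration (see README for the YAML layout)."""

    cohort: Optional[str] = None
    slice_areas: Optional[str] = None
    norms: Optional[str] = None
    coefficients: Optional[str] = None
    out_dir: str = "."
    lic: lic_mod.LICParameters = field(default_factory=lic_mod.LICParameters)
    seed: int = 0
    strict: bool = True
    decimals: int = 1
    log_level: str = "INFO"


_KNOWN_KEYS = {"paths", "lic", "seed", "strict", "decimals", "log_level"}
_KNOWN_PATHS = {"cohort", "slice_areas", "norms", "coefficients", "out_dir"}
_KNOWN_LIC = {"A", "B", "age_exponent", "boundary"}


def load_config(path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys and checking that
    referenced files exist."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    paths = raw.get("paths", {}) or {}
    bad = set(paths) - _KNOWN_PATHS
    if bad:
        raise SchemaError(f"unknown path keys: {sorted(bad)}")
    lic_raw = raw.get("lic", {}) or {}
    bad = set(lic_raw) - _KNOWN_LIC
    if bad:
        raise SchemaError(f"unknown lic keys: {sorted(bad)}")
    params = lic_mod.LICParameters(
        A=tuple(lic_raw.get("A", lic_mod.DEFAULT_PARAMETERS.A)),
        B=tuple(lic_raw.get("B", lic_mod.DEFAULT_PARAMETERS.B)),
        age_exponent=lic_raw.get("age_exponent", lic_mod.DEFAULT_PARAMETERS.age_exponent),
        boundary=lic_raw.get("boundary", lic_mod.DEFAULT_PARAMETERS.boundary),
    )
    cfg = RunConfig(
        cohort=paths.get("cohort"), slice_areas=paths.get("slice_areas"),
        norms=paths.get("norms"), coefficients=paths.get("coefficients"),
        out_dir=paths.get("out_dir", "."), lic=params,
        seed=int(raw.get("seed", 0)), strict=bool(raw.get("strict", True)),
        decimals=int(raw.get("decimals", 1)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    for name in ("cohort", "slice_areas", "norms", "coefficients"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise SchemaError(f"configured {name} file does not exist: {p}")
    return cfg


def config_digest(config: RunConfig) -> str:
    """A stable SHA-256 over the canonicalized configuration."""
    payload = {
        "cohort": config.cohort, "slice_areas": config.slice_areas,
        "norms": config.norms, "coefficients": config.coefficients,
        "lic": {"A": list(config.lic.A), "B": list(config.lic.B),
                "age_exponent": config.lic.age_exponent, "boundary": config.lic.boundary},
        "seed": config.seed, "strict": config.strict, "decimals": config.decimals,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def provenance_manifest(config: RunConfig) -> dict:
    return {
        "tool": "pedpkd",
        "version": __version__,
        "config_sha256": config_digest(config),
        "seed": config.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """volumetry -> LIC -> renal -> BP phenotype -> summary, end to end.

    Writes the derived cohort, the JSON report, a per-record error report
    and a provenance manifest into ``out_dir``; returns the manifest with
    output paths added.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.cohort is None:
        raise SchemaError("run config must name a cohort file")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    df = read_cohort(config.cohort, strict=config.strict)
    slice_areas = read_slice_areas(config.slice_areas) if config.slice_areas else None
    norms = bp_mod.NormativeTable.from_csv(config.norms) if config.norms else None
    table = (renal_mod.U25CoefficientTable.from_csv(config.coefficients)
             if config.coefficients else renal_mod.U25CoefficientTable.default())

    derived, errors = cohort_mod.derive_all(
        df, slice_areas=slice_areas, lic_params=config.lic,
        u25_table=table, norms=norms,
    )
    report = cohort_mod.build_report(derived, decimals=config.decimals)

    manifest = provenance_manifest(config)
    paths = {
        "derived_cohort": str(out_dir / "derived_cohort.csv"),
        "report": str(out_dir / "report.json"),
        "errors": str(out_dir / "errors.json"),
        "manifest": str(out_dir / "manifest.json"),
    }
    write_cohort(derived, paths["derived_cohort"])
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2)
    with open(paths["errors"], "w") as fh:
        json.dump(errors, fh, indent=2)
    manifest["outputs"] = paths
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    if errors:
        logger.warning("%d per-record derivation problems; see %s", len(errors), paths["errors"])
    return manifest
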