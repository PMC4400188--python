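"""Cardiac structure and function from short-axis CINE segmentation areas.

Volumes are Simpson-style slice summations: per frame, the cavity volume is
the sum over slices of endocardial area times slice thickness (mm^3 == uL).
End-diastole and end-systole are the frames with the largest and smallest
cavity volume.  Derived indices::

    SV = EDV - ESV            stroke volume, uL
    EF = SV / EDV             ejection fraction
    CO = SV * HR / 1000       cardiac output, mL/min
    CI = CO / body weight     cardiac index, mL/min/g
    LVM = sum_slices (epi - endo area) * thickness * 1.05   LV mass, mg

1.05 mg/mm^3 is the myocardial specific gravity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CardiacFunction",
    "MYOCARDIAL_SPECIFIC_GRAVITY",
    "validate_cine_table",
    "cavity_volume_per_frame",
    "select_ed_es",
    "functional_indices",
    "lv_mass",
    "analyze_cine",
    "areas_from_masks",
    "format_report",
]

MYOCARDIAL_SPECIFIC_GRAVITY = 1.05  # mg/mm^3

REQUIRED_COLUMNS = ("slice", "frame", "endo_area_mm2", "epi_area_mm2", "thickness_mm")


@dataclass(frozen=True)
class CardiacFunction:
    """Volumetric and functional indices for one heart."""

    edv_ul: float
    esv_ul: float
    sv_ul: float
    ef: float                      # fraction in [0, 1]
    hr_bpm: float | None = None
    co_ml_min: float | None = None
    ci_ml_min_g: float | None = None
    lv_mass_mg: float | None = None
    ed_frame: int | None = None
    es_frame: int | None = None


def validate_cine_table(table: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"cine table lacks columns: {missing_cols}")
    t = table.copy()
    if t[["endo_area_mm2", "epi_area_mm2"]].lt(0).any().any():
        raise ValidationError("areas must be non-negative")
    if (t["epi_area_mm2"] < t["endo_area_mm2"] - 1e-9).any():
        raise ValidationError("epicardial area must be >= endocardial area")
    thickness = t["thickness_mm"].unique()
    if len(thickness) != 1 or thickness[0] <= 0:
        raise ValidationError("slice thickness must be positive and uniform")
    if t.duplicated(["slice", "frame"]).any():
        raise ValidationError("duplicate (slice, frame) rows")
    slices = sorted(t["slice"].unique())
    frames = sorted(t["frame"].unique())
    cells = set(zip(t["slice"], t["frame"]))
    gaps = [(int(s), int(f)) for s in slices for f in frames if (s, f) not in cells]
    if gaps:
        raise ValidationError(f"missing (slice, frame) cells: {gaps[:5]}")
    return t


def cavity_volume_per_frame(table: pd.DataFrame) -> pd.Series:
    """Cavity volume per frame (uL): sum over slices of endo area x thickness."""
    t = validate_cine_table(table)
    thickness = float(t["thickness_mm"].iloc[0])
    vol = t.groupby("frame")["endo_area_mm2"].sum() * thickness
    return vol.sort_index()


def select_ed_es(volumes: pd.Series | np.ndarray) -> tuple[int, int]:
    """End-diastolic (largest volume) and end-systolic (smallest volume)
    frames; ties broken by the earliest frame index."""
    if isinstance(volumes, pd.Series):
        idx = volumes.sort_index()
        frames = idx.index.to_numpy()
        v = idx.to_numpy(dtype=float)
    else:
        v = np.asarray(volumes, dtype=float)
        frames = np.arange(len(v))
    if len(v) < 2:
        raise ValidationError("need at least 2 frames to select ED/ES")
    if np.ptp(v) == 0:
        warnings.warn("all cavity volumes equal: degenerate cycle", stacklevel=2)
        return int(frames[0]), int(frames[0])
    return int(frames[np.argmax(v)]), int(frames[np.argmin(v)])


def functional_indices(
    edv_ul: float,
    esv_ul: float,
    hr_bpm: float | None = None,
    body_weight_g: float | None = None,
) -> CardiacFunction:
    """Derived functional indices from EDV/ESV (uL), heart rate and weight."""
    if not (edv_ul >= esv_ul >= 0):
        raise ValidationError("need EDV >= ESV >= 0")
    if edv_ul == 0:
        raise ValidationError("EDV = 0: ejection fraction undefined")
    sv = edv_ul - esv_ul
    ef = sv / edv_ul
    co = ci = None
    if hr_bpm is not None:
        if hr_bpm <= 0:
            raise ValidationError("heart rate must be positive")
        co = sv * hr_bpm / 1000.0          # uL/min -> mL/min
        if body_weight_g is not None:
            if body_weight_g <= 0:
                raise ValidationError("body weight must be positive")
            ci = co / body_weight_g
    return CardiacFunction(
        edv_ul=edv_ul, esv_ul=esv_ul, sv_ul=sv, ef=ef,
        hr_bpm=hr_bpm, co_ml_min=co, ci_ml_min_g=ci,
    )


def lv_mass(table: pd.DataFrame, frame: int) -> float:
    """LV mass (mg) at one frame: myocardial area x thickness x 1.05."""
    t = validate_cine_table(table)
    sel = t[t["frame"] == frame]
    if sel.empty:
        raise ValidationError(f"frame {frame} not present in table")
    myo = sel["epi_area_mm2"].to_numpy() - sel["endo_area_mm2"].to_numpy()
    if (myo < -1e-9).any():
        raise ValidationError("negative myocardial area")
    thickness = float(sel["thickness_mm"].iloc[0])
    return float(np.clip(myo, 0.0, None).sum() * thickness * MYOCARDIAL_SPECIFIC_GRAVITY)


def analyze_cine(
    table: pd.DataFrame,
    hr_bpm: float | None = None,
    body_weight_g: float | None = None,
    mass_frame: int | None = None,
) -> CardiacFunction:
    """Full volumetric analysis of one heart's area table.

    LV mass is evaluated at the end-diastolic frame unless ``mass_frame``
    overrides it.
    """
    volumes = cavity_volume_per_frame(table)
    ed, es = select_ed_es(volumes)
    base = functional_indices(
        float(volumes.loc[ed]), float(volumes.loc[es]), hr_bpm, body_weight_g
    )
    mass = lv_mass(table, ed if mass_frame is None else mass_frame)
    return CardiacFunction(
        edv_ul=base.edv_ul, esv_ul=base.esv_ul, sv_ul=base.sv_ul, ef=base.ef,
        hr_bpm=base.hr_bpm, co_ml_min=base.co_ml_min, ci_ml_min_g=base.ci_ml_min_g,
        lv_mass_mg=mass, ed_frame=ed, es_frame=es,
    )


def areas_from_masks(directory: str | Path) -> pd.DataFrame:
    """Build a cine area table from per-slice per-frame label masks.

    The directory must contain images named ``slice<SS>_frame<FF>.png`` (or
    .tif) with labels 0=background, 1=cavity, 2=myocardium, and a
    ``metadata.json`` sidecar with ``pixel_size_mm`` (edge length) and
    ``thickness_mm``.  Areas are pixel counts times pixel area.
    """
    import re

    from PIL import Image

    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise ValidationError(f"no metadata.json in {directory}")
    meta = json.loads(meta_path.read_text())
    px = float(meta["pixel_size_mm"]) ** 2
    thickness = float(meta["thickness_mm"])
    pattern = re.compile(r"slice(\d+)_frame(\d+)\.(png|tif|tiff)$")
    rows = []
    for path in sorted(directory.iterdir()):
        m = pattern.match(path.name)
        if not m:
            continue
        labels = np.asarray(Image.open(path))
        cavity = int((labels == 1).sum())
        myo = int((labels == 2).sum())
        rows.append(
            (int(m.group(1)), int(m.group(2)), cavity * px, (cavity + myo) * px, thickness)
        )
    if not rows:
        raise ValidationError(f"no mask images found in {directory}")
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _round_to(value: float, unit: float) -> float:
    return round(value / unit) * unit


def format_report(cf: CardiacFunction) -> dict[str, float]:
    """Reporting-precision view (volumes to nearest 10 uL, EF to integer %,
    CO to nearest 10 mL/min); stored values are never rounded."""
    out: dict[str, float] = {
        "edv_ul": _round_to(cf.edv_ul, 10),
        "esv_ul": _round_to(cf.esv_ul, 10),
        "sv_ul": _round_to(cf.sv_ul, 10),
        "ef_pct": round(cf.ef * 100),
    }
    if cf.co_ml_min is not None:
        out["co_ml_min"] = _round_to(cf.co_ml_min, 10)
    if cf.ci_ml_min_g is not None:
        out["ci_ml_min_g"] = round(cf.ci_ml_min_g, 2)
    if cf.lv_mass_mg is not None:
        out["lv_mass_mg"] = _round_to(cf.lv_mass_mg, 10)
    return out
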