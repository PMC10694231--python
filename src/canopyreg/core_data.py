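"""Domain types, file I/O, dataset assembly and treatment-held-out splitting.

The on-disk layout is two CSV tables plus an image tree:

* metadata CSV: one row per image, columns
  ``microplot_id,treatment_id,date,thermal_time,camera,image_path``
  with ``camera`` one of ``rgb``/``ms``/``height`` and ISO-8601 dates;
* reference CSV: one row per destructive sample, columns
  ``microplot_id,date,dm_total,lai,n_conc,n_upt,
  dm_stem,dm_linf,dm_l1,dm_ear,nupt_stem,nupt_linf,nupt_l1,nupt_ear,
  nconc_stem,nconc_linf,nconc_l1,nconc_ear``
  (per-organ dry matter and N uptake are absolute values; proportions are
  derived on load).

References join to acquisitions on the exact ``(microplot_id, date)`` key;
nearest-date joining is deliberately not supported.
"""

from __future__ import annotations

import datetime as _dt
import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Organ",
    "ORGANS",
    "TraitVector",
    "Acquisition",
    "ReferenceSample",
    "TrialDataset",
    "SchemaError",
    "ImageFormatError",
    "load_dataset",
    "save_dataset",
    "split_by_treatment",
    "read_image",
    "write_image",
]


class SchemaError(ValueError):
    """A CSV table does not match the documented column schema."""


class ImageFormatError(ValueError):
    """An image file does not match the expected layout for its kind."""


class Organ(enum.Enum):
    """The four partitioning compartments, in canonical vector order."""

    STEM = "stem"
    LINF = "linf"  # inferior leaves
    L1 = "l1"  # flag leaf
    EAR = "ear"


#: Canonical organ ordering used by every 4-vector in the package.
ORGANS: tuple[Organ, ...] = (Organ.STEM, Organ.LINF, Organ.L1, Organ.EAR)
ORGAN_NAMES: tuple[str, ...] = tuple(o.value for o in ORGANS)

#: Relative tolerance of the Nupt = DM x %N x 10 unit identity.
NUPT_IDENTITY_RTOL = 0.01
PROP_SUM_ATOL = 1e-6


@dataclass
class TraitVector:
    """Whole-plant targets and per-organ partitioning for one sample.

    ``dm_prop`` and ``nupt_prop`` are proportions over ``ORGANS`` (sum to 1
    when the corresponding total is positive); ``n_conc_organ`` holds
    per-organ %N with absent organs encoded as 0.
    """

    dm_total: float
    lai: float
    n_conc: float
    n_upt: float
    dm_prop: np.ndarray
    nupt_prop: np.ndarray
    n_conc_organ: np.ndarray

    def __post_init__(self) -> None:
        self.dm_prop = np.asarray(self.dm_prop, dtype=float)
        self.nupt_prop = np.asarray(self.nupt_prop, dtype=float)
        self.n_conc_organ = np.asarray(self.n_conc_organ, dtype=float)
        for name in ("dm_prop", "nupt_prop", "n_conc_organ"):
            if getattr(self, name).shape != (4,):
                raise ValueError(f"{name} must be a 4-vector over {ORGAN_NAMES}")

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        for name in ("dm_total", "lai", "n_conc", "n_upt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dm_total > 0 and abs(self.dm_prop.sum() - 1.0) > PROP_SUM_ATOL:
            raise ValueError(f"dm_prop sums to {self.dm_prop.sum()}, expected 1")
        if self.n_upt > 0 and abs(self.nupt_prop.sum() - 1.0) > PROP_SUM_ATOL:
            raise ValueError(f"nupt_prop sums to {self.nupt_prop.sum()}, expected 1")
        expected = self.dm_total * self.n_conc * 10.0
        if expected > 0 and abs(self.n_upt - expected) > NUPT_IDENTITY_RTOL * expected:
            raise ValueError(
                f"n_upt={self.n_upt} violates DM x %N x 10 = {expected} beyond 1%"
            )

    def scalar(self, trait: str) -> float:
        return float(getattr(self, trait))


@dataclass
class Acquisition:
    """All images taken on one microplot on one date."""

    microplot_id: str
    treatment_id: str
    date: _dt.date
    thermal_time: float
    rgb_paths: list[str] = field(default_factory=list)
    ms_paths: list[str] = field(default_factory=list)
    height_map_path: str | None = None
    #: optional precomputed 20-feature vector (feature-mode trials)
    features: np.ndarray | None = None

    @property
    def key(self) -> tuple[str, _dt.date]:
        return (self.microplot_id, self.date)


@dataclass
class ReferenceSample:
    """A destructive reference measurement (Ytrue) for one microplot/date."""

    microplot_id: str
    date: _dt.date
    thermal_time: float
    traits: TraitVector


@dataclass
class TrialDataset:
    """Acquisitions joined to sparse reference labels, plus the split map.

    ``m = len(acquisitions)`` images-dates, ``n = len(references)`` labels.
    ``split`` maps treatment_id to ``"train"`` or ``"val"``; ``meta`` carries
    trial-level side information such as organ appearance thermal times.
    """

    acquisitions: list[Acquisition]
    references: list[ReferenceSample]
    split: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.acquisitions)

    @property
    def n(self) -> int:
        return len(self.references)

    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.acquisitions:
            seen.setdefault(a.treatment_id, None)
        return list(seen)

    def microplot_treatment(self) -> dict[str, str]:
        return {a.microplot_id: a.treatment_id for a in self.acquisitions}

    def acquisitions_in(self, part: str) -> list[Acquisition]:
        if not self.split:
            return list(self.acquisitions) if part == "train" else []
        return [a for a in self.acquisitions if self.split.get(a.treatment_id) == part]

    def references_in(self, part: str) -> list[ReferenceSample]:
        plot2trt = self.microplot_treatment()
        if not self.split:
            return list(self.references) if part == "train" else []
        return [
            r
            for r in self.references
            if self.split.get(plot2trt.get(r.microplot_id, ""), "train") == part
        ]

    def reference_lookup(self) -> dict[tuple[str, _dt.date], ReferenceSample]:
        return {(r.microplot_id, r.date): r for r in self.references}

    def validate(self) -> None:
        if self.split:
            trains = {t for t, p in self.split.items() if p == "train"}
            vals = {t for t, p in self.split.items() if p == "val"}
            if trains & vals:
                raise ValueError(f"treatments in both splits: {trains & vals}")
        keys = {a.key for a in self.acquisitions}
        for r in self.references:
            if (r.microplot_id, r.date) not in keys:
                raise ValueError(
                    f"reference {r.microplot_id}@{r.date} has no acquisition"
                )
        # thermal time strictly increasing with date within each microplot
        by_plot: dict[str, list[Acquisition]] = {}
        for a in self.acquisitions:
            by_plot.setdefault(a.microplot_id, []).append(a)
        for plot, acqs in by_plot.items():
            acqs = sorted(acqs, key=lambda a: a.date)
            tt = [a.thermal_time for a in acqs]
            if any(b <= a for a, b in zip(tt, tt[1:])):
                raise ValueError(f"thermal_time not increasing for {plot}")


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "microplot_id",
    "treatment_id",
    "date",
    "thermal_time",
    "camera",
    "image_path",
]
_ORGAN_COLS = [f"{p}_{o}" for p in ("dm", "nupt", "nconc") for o in ORGAN_NAMES]
REFERENCE_COLUMNS = ["microplot_id", "date", "dm_total", "lai", "n_conc", "n_upt"] + _ORGAN_COLS


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def _props(values: np.ndarray, total: float) -> np.ndarray:
    if total > 0:
        return values / total if values.sum() == 0 else values / values.sum()
    return np.zeros(4)


def _traits_from_row(row: pd.Series) -> TraitVector:
    dm_abs = np.array([row[f"dm_{o}"] for o in ORGAN_NAMES], dtype=float)
    nupt_abs = np.array([row[f"nupt_{o}"] for o in ORGAN_NAMES], dtype=float)
    nconc = np.array([row[f"nconc_{o}"] for o in ORGAN_NAMES], dtype=float)
    return TraitVector(
        dm_total=float(row["dm_total"]),
        lai=float(row["lai"]),
        n_conc=float(row["n_conc"]),
        n_upt=float(row["n_upt"]),
        dm_prop=_props(dm_abs, float(row["dm_total"])),
        nupt_prop=_props(nupt_abs, float(row["n_upt"])),
        n_conc_organ=nconc,
    )


def load_dataset(
    metadata_csv: str | Path,
    reference_csv: str | Path,
    image_root: str | Path | None = None,
) -> TrialDataset:
    """Join the metadata and reference tables into a :class:`TrialDataset`.

    Reference rows whose ``(microplot_id, date)`` key matches no acquisition
    are dropped with a warning listing them; ``m`` and ``n`` are logged.
    """
    meta = pd.read_csv(metadata_csv, float_precision="round_trip")
    refs = pd.read_csv(reference_csv, float_precision="round_trip")
    _require_columns(meta, METADATA_COLUMNS, "metadata CSV")
    _require_columns(refs, REFERENCE_COLUMNS, "reference CSV")
    root = Path(image_root) if image_root is not None else None

    acq_map: dict[tuple[str, _dt.date], Acquisition] = {}
    for _, row in meta.iterrows():
        date = _dt.date.fromisoformat(str(row["date"]))
        key = (str(row["microplot_id"]), date)
        acq = acq_map.get(key)
        if acq is None:
            acq = Acquisition(
                microplot_id=key[0],
                treatment_id=str(row["treatment_id"]),
                date=date,
                thermal_time=float(row["thermal_time"]),
            )
            acq_map[key] = acq
        path = str(row["image_path"])
        if root is not None:
            path = str(root / path)
        camera = str(row["camera"])
        if camera == "rgb":
            acq.rgb_paths.append(path)
        elif camera == "ms":
            acq.ms_paths.append(path)
        elif camera == "height":
            acq.height_map_path = path
        else:
            raise SchemaError(f"unknown camera kind {camera!r}")

    references: list[ReferenceSample] = []
    unmatched: list[str] = []
    for idx, row in refs.iterrows():
        date = _dt.date.fromisoformat(str(row["date"]))
        key = (str(row["microplot_id"]), date)
        acq = acq_map.get(key)
        if acq is None:
            unmatched.append(f"row {idx}: {key[0]}@{key[1]}")
            continue
        references.append(
            ReferenceSample(
                microplot_id=key[0],
                date=date,
                thermal_time=acq.thermal_time,
                traits=_traits_from_row(row),
            )
        )
    if unmatched:
        warnings.warn(
            "reference rows with no matching acquisition were dropped: "
            + "; ".join(unmatched),
            stacklevel=2,
        )
    acquisitions = sorted(acq_map.values(), key=lambda a: (a.microplot_id, a.date))
    ds = TrialDataset(acquisitions=acquisitions, references=references)
    logger.info("loaded dataset: m=%d acquisitions, n=%d references", ds.m, ds.n)
    return ds


def save_dataset(
    ds: TrialDataset, metadata_csv: str | Path, reference_csv: str | Path
) -> None:
    """Write the two CSV tables; inverse of :func:`load_dataset` on metadata."""
    rows = []
    for a in ds.acquisitions:
        for camera, paths in (
            ("rgb", a.rgb_paths),
            ("ms", a.ms_paths),
            ("height", [a.height_map_path] if a.height_map_path else []),
        ):
            for p in paths:
                rows.append(
                    {
                        "microplot_id": a.microplot_id,
                        "treatment_id": a.treatment_id,
                        "date": a.date.isoformat(),
                        "thermal_time": a.thermal_time,
                        "camera": camera,
                        "image_path": p,
                    }
                )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_csv, index=False)

    ref_rows = []
    for r in ds.references:
        t = r.traits
        row = {
            "microplot_id": r.microplot_id,
            "date": r.date.isoformat(),
            "dm_total": t.dm_total,
            "lai": t.lai,
            "n_conc": t.n_conc,
            "n_upt": t.n_upt,
        }
        for i, o in enumerate(ORGAN_NAMES):
            row[f"dm_{o}"] = t.dm_total * t.dm_prop[i]
            row[f"nupt_{o}"] = t.n_upt * t.nupt_prop[i]
            row[f"nconc_{o}"] = t.n_conc_organ[i]
        ref_rows.append(row)
    pd.DataFrame(ref_rows, columns=REFERENCE_COLUMNS).to_csv(reference_csv, index=False)


def split_by_treatment(ds: TrialDataset, val_treatments: list[str]) -> TrialDataset:
    """Assign every treatment to train or validation (held-out treatments).

    Returns a shallow copy of ``ds`` with ``split`` set; the validation
    fraction of references is logged.
    """
    present = set(ds.treatments())
    unknown = [t for t in val_treatments if t not in present]
    if unknown:
        raise ValueError(f"unknown treatment ids: {unknown}")
    split = {t: ("val" if t in val_treatments else "train") for t in present}
    out = replace(ds, split=split)
    n_val = len(out.references_in("val"))
    if ds.n:
        logger.info(
            "split: %d/%d references (%.1f%%) in validation",
            n_val,
            ds.n,
            100.0 * n_val / ds.n,
        )
    return out


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

#: multispectral band centers in nm, fixed ordering
MS_BANDS = (490, 550, 680, 720, 800, 900)


def read_image(path: str | Path, kind: str) -> np.ndarray:
    """Read an image as ``rgb`` (HxWx3 in [0,255]), ``ms`` (HxWx6 BRF in
    [0,1], values above 1 clipped with a logged count) or ``height``
    (HxW meters)."""
    import tifffile

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)

    if kind == "rgb":
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise ImageFormatError(
                f"{path}: expected HxWx3 RGB, got shape {arr.shape}"
            )
        return arr.astype(float)
    if kind == "ms":
        if arr.ndim == 3 and arr.shape[0] == 6 and arr.shape[-1] != 6:
            arr = np.moveaxis(arr, 0, -1)  # multi-page TIFF: pages are bands
        if arr.ndim != 3 or arr.shape[-1] != 6:
            raise ImageFormatError(
                f"{path}: expected 6 bands at {MS_BANDS} nm, got shape {arr.shape}"
            )
        brf = arr.astype(float)
        if np.issubdtype(arr.dtype, np.integer):
            brf = brf / 255.0  # 8-bit on-disk encoding -> BRF
        n_clip = int((brf > 1.0).sum())
        if n_clip:
            logger.warning("%s: clipped %d BRF values > 1", path, n_clip)
        return np.clip(brf, 0.0, 1.0)
    if kind == "height":
        if arr.ndim != 2:
            raise ImageFormatError(f"{path}: expected HxW height map, got {arr.shape}")
        return arr.astype(float)
    raise ValueError(f"unknown image kind {kind!r}")


def write_image(path: str | Path, arr: np.ndarray, kind: str) -> None:
    """Write an image in the on-disk encoding :func:`read_image` expects."""
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "rgb":
        data = np.clip(np.asarray(arr), 0, 255).astype(np.uint8)
    elif kind == "ms":
        data = np.asarray(arr, dtype=np.float32)
    elif kind == "height":
        data = np.asarray(arr, dtype=np.float32)
    else:
        raise ValueError(f"unknown image kind {kind!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        photometric = "rgb" if kind == "rgb" else "minisblack"
        tifffile.imwrite(path, data, photometric=photometric)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)
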