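"""Engineered features for the PLSr baseline and the LAI reference protocol.

Twenty features per acquisition: the six band-mean BRFs over plant pixels,
twelve vegetation indices computed from those means, the 95th percentile of
the height map, and the plant cover ratio from Otsu thresholding of the
800 nm band.  The index registry is user-overridable; the default set
covers the standard six-band indices (NDVI, GNDVI, NDRE, mNDB, GR, MCARI,
OSAVI, EVI2, CI-green, CI-red-edge, MTCI, SAVI).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_VI_REGISTRY",
    "FeatureVector",
    "LAICalibration",
    "otsu_threshold",
    "plant_ratio",
    "height_p95",
    "compute_features",
    "calibrate_lai",
]

BAND_NAMES = ("b490", "b550", "b680", "b720", "b800", "b900")

#: guard threshold below which a VI denominator is treated as zero
_DENOM_EPS = 1e-9


def _safe_div(num: float, den: float) -> float:
    if abs(den) < _DENOM_EPS:
        logger.warning("vegetation-index denominator ~0; index set to 0")
        return 0.0
    return num / den


def _b(bands: Mapping[str, float], name: str) -> float:
    return float(bands[name])


# Formulas take the dict of plant-pixel mean BRFs keyed by BAND_NAMES.
DEFAULT_VI_REGISTRY: dict[str, Callable[[Mapping[str, float]], float]] = {
    "ndvi": lambda b: _safe_div(b["b800"] - b["b680"], b["b800"] + b["b680"]),
    "gndvi": lambda b: _safe_div(b["b800"] - b["b550"], b["b800"] + b["b550"]),
    "ndre": lambda b: _safe_div(b["b800"] - b["b720"], b["b800"] + b["b720"]),
    "mndb": lambda b: _safe_div(b["b800"] - b["b490"], b["b800"] + b["b490"]),
    "gr": lambda b: _safe_div(b["b550"], b["b680"]),
    "mcari": lambda b: ((b["b720"] - b["b680"]) - 0.2 * (b["b720"] - b["b550"]))
    * _safe_div(b["b720"], b["b680"]),
    "osavi": lambda b: 1.16 * _safe_div(b["b800"] - b["b680"], b["b800"] + b["b680"] + 0.16),
    "evi2": lambda b: 2.5 * _safe_div(b["b800"] - b["b680"], b["b800"] + 2.4 * b["b680"] + 1.0),
    "ci_green": lambda b: _safe_div(b["b800"], b["b550"]) - 1.0,
    "ci_red_edge": lambda b: _safe_div(b["b800"], b["b720"]) - 1.0,
    "mtci": lambda b: _safe_div(b["b800"] - b["b720"], b["b720"] - b["b680"]),
    "savi": lambda b: 1.5 * _safe_div(b["b800"] - b["b680"], b["b800"] + b["b680"] + 0.5),
}

#: canonical ordering of the twenty features
FEATURE_NAMES: tuple[str, ...] = BAND_NAMES + tuple(DEFAULT_VI_REGISTRY) + (
    "height_p95",
    "plant_ratio",
)


@dataclass
class FeatureVector:
    """The 20 engineered features of one acquisition, in canonical order."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} features, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def otsu_threshold(gray: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the image.

    Maximizes between-class variance; ties resolve to the lowest threshold.
    A constant image has no two classes and raises ``ValueError``.
    """
    gray = np.asarray(gray, dtype=float)
    gray = gray[np.isfinite(gray)]
    if gray.size == 0 or gray.min() == gray.max():
        raise ValueError("cannot threshold a constant image")

    counts, edges = np.histogram(gray, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts.astype(float)
    p = w / w.sum()
    omega0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * omega0 - mu) ** 2 / (omega0 * omega1)
    var_between[~np.isfinite(var_between)] = -np.inf
    idx = int(np.argmax(var_between))  # argmax -> first (lowest) maximizer
    return float(centers[idx])


def plant_ratio(nir: np.ndarray, min_range: float = 0.06) -> float:
    """Fraction of pixels above the Otsu threshold of the 800 nm band.

    Otsu always splits a histogram, even of bare-soil sensor noise, so a
    band whose robust dynamic range (p99 - p1) is below ``min_range`` BRF is
    treated as vegetation-free and returns 0.  Constant bands are errors.
    """
    nir = np.asarray(nir, dtype=float)
    thr = otsu_threshold(nir)
    valid = nir[np.isfinite(nir)]
    lo, hi = np.percentile(valid, [1, 99])
    if hi - lo < min_range:
        return 0.0
    return float((valid > thr).mean())


def height_p95(height_map: np.ndarray) -> float:
    """95th percentile of the height map (linear interpolation), NaN-aware."""
    h = np.asarray(height_map, dtype=float)
    if h.size == 0:
        raise ValueError("empty height map")
    if np.all(np.isnan(h)):
        raise ValueError("height map is all-NaN")
    return float(np.nanpercentile(h, 95, method="linear"))


def compute_features(
    ms: np.ndarray,
    height_map: np.ndarray,
    registry: Mapping[str, Callable[[Mapping[str, float]], float]] | None = None,
) -> FeatureVector:
    """Compute the 20-feature vector from a 6-band BRF image + height map.

    Band means and indices are computed over plant pixels (Otsu mask on the
    800 nm band); with zero plant pixels the means fall back to the whole
    frame with a warning.
    """
    registry = dict(registry) if registry is not None else DEFAULT_VI_REGISTRY
    ms = np.asarray(ms, dtype=float)
    if ms.ndim != 3 or ms.shape[-1] != 6:
        raise ValueError(f"expected HxWx6 BRF image, got {ms.shape}")

    nir = ms[:, :, 4]
    try:
        ratio = plant_ratio(nir)
        mask = (nir > otsu_threshold(nir)) if ratio > 0 else np.zeros(nir.shape, bool)
    except ValueError:
        mask = np.zeros(nir.shape, dtype=bool)
        ratio = 0.0
    if not mask.any():
        warnings.warn(
            "no plant pixels found; band means fall back to the whole frame",
            stacklevel=2,
        )
        mask = np.ones(nir.shape, dtype=bool)

    means = {name: float(ms[:, :, i][mask].mean()) for i, name in enumerate(BAND_NAMES)}
    vis = [float(fn(means)) for fn in registry.values()]
    values = np.array(
        [means[n] for n in BAND_NAMES] + vis + [height_p95(height_map), ratio]
    )
    names = BAND_NAMES + tuple(registry) + ("height_p95", "plant_ratio")
    return FeatureVector(values=values, names=names)


@dataclass
class LAICalibration:
    """Linear map from sample fresh mass to LAI, with its fit correlation."""

    slope: float
    intercept: float
    r: float

    def predict(self, fresh_mass: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(fresh_mass, dtype=float) + self.intercept


def calibrate_lai(scan_areas, fresh_masses) -> LAICalibration:
    """OLS fit of scan-derived LAI on fresh mass; warns when r < 0.9."""
    y = np.asarray(scan_areas, dtype=float)
    x = np.asarray(fresh_masses, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {x.shape}")
    if y.size < 3:
        raise ValueError("calibration needs at least 3 points")
    fit = _stats.linregress(x, y)
    if abs(fit.rvalue) < 0.9:
        warnings.warn(
            f"LAI calibration correlation |r|={abs(fit.rvalue):.3f} is below 0.9",
            stacklevel=2,
        )
    return LAICalibration(slope=float(fit.slope), intercept=float(fit.intercept), r=float(fit.rvalue))
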