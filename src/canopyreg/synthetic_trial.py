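"""Synthetic wheat trial generator.

Emulates the statistical structure of a multi-year fertilization trial:
logistic dry-matter accumulation, unimodal LAI, an N-dilution curve for
whole-plant %N, organ partitioning with appearance times (flag leaf, ear),
sparse destructive reference sampling against dense image acquisition, and
treatment-driven contrasts.  Two render modes are supported:

* ``image`` — low-fidelity procedural canopy scenes (RGB, 6-band
  multispectral BRF, height map) whose only contract is a monotone, noisy
  trait-to-appearance mapping;
* ``feature`` — a documented 20-entry engineered-feature response used by
  the PLSr path.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .core_data import (
    ORGAN_NAMES,
    Acquisition,
    ReferenceSample,
    TraitVector,
    TrialDataset,
    write_image,
)

__all__ = [
    "TrajectoryParams",
    "OrganSchedule",
    "RenderConfig",
    "simulate_trajectories",
    "trait_at",
    "organ_proportions",
    "canopy_height",
    "invert_feature_lai",
    "generate_trial",
    "render_canopy",
    "feature_response",
    "SOIL_BRF",
]

# Per-organ relative N-concentration factors (stem poor, flag leaf rich);
# they tie organ %N to the whole-plant dilution value so that the
# Nupt = DM x %N x 10 identity holds exactly by construction.
N_FACTORS = np.array([0.6, 1.0, 1.6, 1.3])  # stem, linf, l1, ear


@dataclass
class TrajectoryParams:
    """Parameters of one microplot's trait trajectories over thermal time."""

    dm_max: float = 22.0  # t/ha asymptote before treatment scaling
    dm_rate: float = 0.004  # logistic rate, per degC-day
    dm_mid: float = 1100.0  # logistic inflection, degC-days
    lai_peak: float = 5.5
    lai_peak_time: float = 900.0
    lai_senescence_rate: float = 0.0035  # per degC-day
    ndil_a: float = 5.35  # %N dilution coefficient (a . DM^-b)
    ndil_b: float = 0.442
    n_max: float = 4.6  # %N cap at low biomass
    treatment_factor: float = 1.0  # scales dm_max and ndil_a

    def __post_init__(self) -> None:
        for name in (
            "dm_max",
            "dm_rate",
            "dm_mid",
            "lai_peak",
            "lai_peak_time",
            "lai_senescence_rate",
            "ndil_a",
            "ndil_b",
            "n_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.treatment_factor < 0:
            raise ValueError("treatment_factor must be >= 0")


def _logistic(t: np.ndarray, mid: float, rate: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (t - mid)))


def _default_basis(schedule: "OrganSchedule") -> dict[str, Callable[[float], float]]:
    """Smooth positive share bases; renormalized over present organs."""
    return {
        "stem": lambda t: 0.45 + 0.15 * _logistic(np.asarray(t), 600.0, 0.01),
        "linf": lambda t: 0.10 + 0.55 * math.exp(-max(float(t), 0.0) / 900.0),
        "l1": lambda t: 0.12,
        "ear": lambda t: 0.10 + 0.65 * _logistic(np.asarray(t), 1500.0, 0.004),
    }


@dataclass
class OrganSchedule:
    """Organ appearance thermal times and share bases.

    A proportion is exactly 0 before its organ's appearance time; present
    organs are renormalized to sum to 1.
    """

    t_l1_appear: float = 800.0
    t_ear_appear: float = 1000.0
    share_basis: dict[str, Callable[[float], float]] | None = None

    def __post_init__(self) -> None:
        if self.t_l1_appear < 0 or self.t_ear_appear < 0:
            raise ValueError("appearance times must be non-negative")
        if self.share_basis is None:
            self.share_basis = _default_basis(self)

    def appearance_time(self, organ: str) -> float:
        return {
            "stem": 0.0,
            "linf": 0.0,
            "l1": self.t_l1_appear,
            "ear": self.t_ear_appear,
        }[organ]


def organ_proportions(t: float, schedule: OrganSchedule) -> np.ndarray:
    """Dry-matter proportions over (stem, linf, l1, ear) at thermal time t."""
    raw = np.array(
        [
            float(schedule.share_basis[o](t)) if t >= schedule.appearance_time(o) else 0.0
            for o in ORGAN_NAMES
        ]
    )
    total = raw.sum()
    if total <= 0:
        raise ValueError(f"no organ present at t={t}")
    return raw / total


def _organ_n(dm_prop: np.ndarray, n_conc: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-organ %N and Nupt proportions consistent with the plant totals."""
    present = dm_prop > 0
    w = float((dm_prop * N_FACTORS).sum())
    nconc_organ = np.where(present, n_conc * N_FACTORS / w, 0.0)
    nupt_prop = dm_prop * N_FACTORS / w
    return nconc_organ, nupt_prop


def trait_at(t: float, params: TrajectoryParams, schedule: OrganSchedule) -> TraitVector:
    """Noiseless trait vector at a single thermal time."""
    tf = params.treatment_factor
    dm = float(params.dm_max * tf * _logistic(np.asarray(t), params.dm_mid, params.dm_rate))
    rise = float(_logistic(np.asarray(t), params.lai_peak_time * 0.55, 0.008))
    sen = math.exp(-params.lai_senescence_rate * max(0.0, t - params.lai_peak_time))
    lai = params.lai_peak * math.sqrt(max(tf, 1e-9)) * rise * sen
    n_conc = min(params.n_max, params.ndil_a * tf * dm ** (-params.ndil_b)) if dm > 0 else params.n_max
    n_upt = dm * n_conc * 10.0
    dm_prop = organ_proportions(t, schedule)
    nconc_organ, nupt_prop = _organ_n(dm_prop, n_conc)
    return TraitVector(
        dm_total=dm,
        lai=lai,
        n_conc=n_conc,
        n_upt=n_upt,
        dm_prop=dm_prop,
        nupt_prop=nupt_prop,
        n_conc_organ=nconc_organ,
    )


def simulate_trajectories(
    params: TrajectoryParams, schedule: OrganSchedule, times: list[float]
) -> list[TraitVector]:
    """Evaluate the noiseless trait trajectory at each thermal time."""
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("times must be sorted ascending")
    return [trait_at(float(t), params, schedule) for t in times]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

#: soil reflectance per band (490..900 nm), brightening toward the NIR
SOIL_BRF = np.array([0.10, 0.13, 0.18, 0.22, 0.26, 0.28])
_LEAF_BRF = np.array([0.04, 0.10, 0.05, 0.28, 0.46, 0.46])


@dataclass
class RenderConfig:
    """Rendering configuration; ``image`` mode yields RGB + MS + height."""

    mode: str = "image"  # {image, feature}
    image_size: int = 64
    noise_sd: float = 0.01
    #: sd of the per-image lognormal illumination gain (uncalibrated light)
    illumination_sd: float = 0.10
    leaf_density_scale: float = 30.0  # ellipses per unit LAI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("image", "feature"):
            raise ValueError(f"unknown render mode {self.mode!r}")
        if self.mode == "image" and self.image_size < 16:
            raise ValueError("image_size must be >= 16")


def _leaf_brf(n_conc: float, dm_total: float = 12.0) -> np.ndarray:
    """Leaf spectrum; red-edge/NIR increases with %N, overall brightness
    with canopy density (a stand with more dry matter scatters more)."""
    leaf = _LEAF_BRF.copy()
    gain = 0.6 + 0.12 * n_conc
    leaf[3:] *= gain
    leaf[1] *= 0.8 + 0.08 * n_conc  # greener with N
    leaf *= 0.7 + 0.6 * min(max(dm_total, 0.0), 30.0) / 25.0
    return np.clip(leaf, 0.0, 1.0)


def canopy_height(dm_total: float) -> float:
    """Canopy surface height in meters, allometric in dry matter."""
    return 0.9 * (max(dm_total, 0.0) / 25.0) ** (1.0 / 3.0)


def render_canopy(
    traits: TraitVector, cfg: RenderConfig, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Render a procedural canopy scene for one acquisition.

    Returns ``{"rgb": HxWx3 in [0,255], "ms": HxWx6 BRF, "height": HxW m}``.
    Ellipse parameters are drawn sequentially so that increasing LAI only
    appends ellipses at a fixed seed (monotone plant-cover contract).
    """
    from skimage.draw import ellipse as _ellipse

    if cfg.mode != "image":
        raise ValueError("render_canopy requires image mode")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    size = cfg.image_size
    mask = np.zeros((size, size), dtype=bool)
    n_leaves = int(round(cfg.leaf_density_scale * traits.lai))
    size_gain = 0.6 + 0.8 * (max(traits.dm_total, 0.0) / 25.0) ** (1.0 / 3.0)
    for _ in range(n_leaves):
        cy, cx = rng.uniform(0, size, 2)
        r_a = rng.uniform(1.2, 2.6) * size_gain * size / 64.0
        r_b = rng.uniform(1.2, 2.6) * size_gain * size / 64.0
        angle = rng.uniform(0, np.pi)
        rr, cc = _ellipse(cy, cx, r_a, r_b, shape=(size, size), rotation=angle)
        mask[rr, cc] = True

    leaf = _leaf_brf(traits.n_conc, traits.dm_total)
    # a taller, denser stand shades the visible soil between rows
    shade = 1.0 - 0.45 * min(max(traits.dm_total, 0.0), 30.0) / 25.0
    ms = np.empty((size, size, 6))
    for b in range(6):
        base = np.where(mask, leaf[b], SOIL_BRF[b] * shade)
        ms[:, :, b] = base + rng.normal(0.0, cfg.noise_sd, (size, size))
    # whole-scene illumination gain: the nuisance growth-curve correction
    # is meant to average out across acquisition dates
    if cfg.illumination_sd > 0:
        ms *= rng.lognormal(0.0, cfg.illumination_sd)
    ms = np.clip(ms, 0.0, 1.0)

    # RGB from the 680/550/490 bands, brightness-stretched to 8-bit
    rgb = np.clip(ms[:, :, [2, 1, 0]] * 3.2 * 255.0, 0, 255)

    height = np.where(mask, canopy_height(traits.dm_total), 0.0)
    return {"rgb": rgb, "ms": ms, "height": height}


# ---------------------------------------------------------------------------
# Feature-mode response
# ---------------------------------------------------------------------------

# (amplitude, lai half-saturation, %N sensitivity) per synthetic index
_VI_TABLE = [
    (0.90, 1.5, 0.00),
    (0.75, 1.8, 0.05),
    (0.60, 2.2, 0.10),
    (0.55, 1.6, 0.08),
    (0.80, 2.0, 0.12),
    (0.70, 1.4, 0.00),
    (0.65, 2.5, 0.06),
    (0.85, 1.7, 0.00),
    (0.50, 2.8, 0.15),
    (0.60, 1.9, 0.10),
    (0.75, 2.3, 0.04),
    (0.55, 1.5, 0.00),
]
_VI_SOIL = np.array([0.05, 0.04, 0.06, 0.03, 0.05, 0.07, 0.04, 0.05, 0.02, 0.04, 0.06, 0.03])


def feature_response(
    traits: TraitVector, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Deterministic 20-feature response to a trait vector, plus noise.

    Layout matches :mod:`canopy_features`: 6 band means, 12 index-like
    entries saturating in LAI (``soil + amp * lai/(lai+k) * n-modulation``),
    height 95th percentile (allometric in DM), and plant cover ratio
    (``0.98 * (1 - exp(-0.8 * lai))``).  Only the height entry depends on
    dry matter, which makes the mapping invertible in expectation.
    """
    rng = np.random.default_rng(seed)
    cover = 1.0 - math.exp(-0.5 * traits.lai)
    leaf = _leaf_brf(traits.n_conc)
    bands = SOIL_BRF + (leaf - SOIL_BRF) * cover

    lai = traits.lai
    vis = np.array(
        [
            soil + amp * (lai / (lai + k)) * (1.0 + g * (traits.n_conc - 2.0))
            for (amp, k, g), soil in zip(_VI_TABLE, _VI_SOIL)
        ]
    )
    height = canopy_height(traits.dm_total)
    ratio = 0.98 * (1.0 - math.exp(-0.8 * lai))
    x = np.concatenate([bands, vis, [height, ratio]])
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.shape)
    return x


def invert_feature_lai(value: float, index: int = 0) -> float:
    """Invert a VI-like feature entry back to LAI (expectation, %N = 2)."""
    amp, k, _ = _VI_TABLE[index]
    soil = _VI_SOIL[index]
    y = (value - soil) / amp
    y = min(max(y, 0.0), 0.999)
    return k * y / (1.0 - y)


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

_BASE_DATE = _dt.date(2022, 3, 1)


def _noisy_reference(
    traits: TraitVector, rng: np.random.Generator, cv: float
) -> TraitVector:
    """Multiplicative lognormal measurement noise preserving all identities."""
    sigma = math.sqrt(math.log(1.0 + cv**2))
    dm = traits.dm_total * rng.lognormal(0.0, sigma)
    lai = traits.lai * rng.lognormal(0.0, sigma)
    n_conc = traits.n_conc * rng.lognormal(0.0, sigma)
    n_upt = dm * n_conc * 10.0  # identity enforced exactly
    raw = traits.dm_prop * rng.lognormal(0.0, sigma, 4)
    raw[traits.dm_prop == 0] = 0.0
    dm_prop = raw / raw.sum()
    nconc_organ, nupt_prop = _organ_n(dm_prop, n_conc)
    return TraitVector(dm, lai, n_conc, n_upt, dm_prop, nupt_prop, nconc_organ)


def generate_trial(
    n_treatments: int,
    n_replicates: int,
    n_acq_dates: int,
    n_ref_dates: int,
    render: RenderConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    reference_cv: float = 0.05,
    images_per_date: int = 1,
) -> TrialDataset:
    """Generate one synthetic trial.

    One microplot per treatment x replicate; treatment factors spread over
    [0.4, 1.2]; references only at ``n_ref_dates`` of the ``n_acq_dates``
    acquisition dates, with multiplicative measurement noise.  In ``image``
    mode the scenes are written under ``out_dir``; in ``feature`` mode the
    20-feature vectors are attached to each acquisition in memory.

    The returned dataset's ``meta`` records organ appearance times and the
    noiseless true traits per (microplot, date) for oracle tests.
    """
    if n_ref_dates > n_acq_dates:
        raise ValueError("n_ref_dates must be <= n_acq_dates")
    if n_treatments < 1 or n_replicates < 1 or n_acq_dates < 1:
        raise ValueError("counts must be >= 1")
    render = render or RenderConfig(mode="feature")
    if render.mode == "image" and out_dir is None:
        raise ValueError("image mode requires out_dir")
    rng = np.random.default_rng(seed)
    out = Path(out_dir) if out_dir is not None else None

    schedule = OrganSchedule()
    factors = np.linspace(0.4, 1.2, n_treatments)
    times = np.linspace(150.0, 2000.0, n_acq_dates)
    ref_idx = np.unique(np.round(np.linspace(0, n_acq_dates - 1, n_ref_dates)).astype(int))
    dates = [_BASE_DATE + _dt.timedelta(days=int(t / 10.0)) for t in times]

    acquisitions: list[Acquisition] = []
    references: list[ReferenceSample] = []
    true_traits: dict[tuple[str, _dt.date], TraitVector] = {}

    for ti in range(n_treatments):
        for rep in range(n_replicates):
            plot = f"T{ti + 1}R{rep + 1}"
            # small replicate-level agronomic variability
            jitter = float(rng.uniform(0.95, 1.05))
            params = TrajectoryParams(treatment_factor=float(factors[ti]) * jitter)
            traj = simulate_trajectories(params, schedule, list(times))
            for di, (t, date, tv) in enumerate(zip(times, dates, traj)):
                true_traits[(plot, date)] = tv
                acq = Acquisition(
                    microplot_id=plot,
                    treatment_id=f"T{ti + 1}",
                    date=date,
                    thermal_time=float(t),
                )
                if render.mode == "feature":
                    acq.features = feature_response(
                        tv, render.noise_sd, seed=int(rng.integers(2**31))
                    )
                else:
                    assert out is not None
                    for img_i in range(images_per_date):
                        scene = render_canopy(tv, render, seed=int(rng.integers(2**31)))
                        stem = f"{plot}_{date.isoformat()}_{img_i}"
                        rgb_p = out / "images" / f"{stem}_rgb.tif"
                        ms_p = out / "images" / f"{stem}_ms.tif"
                        write_image(rgb_p, scene["rgb"], "rgb")
                        write_image(ms_p, scene["ms"], "ms")
                        acq.rgb_paths.append(str(rgb_p))
                        acq.ms_paths.append(str(ms_p))
                        if img_i == 0:
                            h_p = out / "images" / f"{stem}_height.tif"
                            write_image(h_p, scene["height"], "height")
                            acq.height_map_path = str(h_p)
                acquisitions.append(acq)
                if di in ref_idx:
                    references.append(
                        ReferenceSample(
                            microplot_id=plot,
                            date=date,
                            thermal_time=float(t),
                            traits=_noisy_reference(tv, rng, reference_cv),
                        )
                    )

    ds = TrialDataset(
        acquisitions=acquisitions,
        references=references,
        meta={
            "t_l1_appear": schedule.t_l1_appear,
            "t_ear_appear": schedule.t_ear_appear,
            "treatment_factors": {f"T{i + 1}": float(f) for i, f in enumerate(factors)},
            "true_traits": true_traits,
            "render_mode": render.mode,
        },
    )
    ds.validate()
    return ds
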