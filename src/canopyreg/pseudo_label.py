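"""Growth-curve corrected pseudo-labeling pipeline.

Model 1 is trained on the sparse reference labels (Ytrue), then predicts
every acquisition of the training treatments (Ypred).  Per microplot and
trait, the predictions are plotted against thermal time and smoothed by a
growth curve — a heavily-smoothed cubic B-spline for LAI, a cubic
polynomial for the other variables.  The curve is evaluated back at every
acquisition time, basic corrections are applied (non-negativity, organ
values forced to 0 before the organ appears, proportion renormalization),
and the corrected pseudo-labels (Ypseu) train Model 2 from a fresh
initialization.  The pipeline is model-agnostic: any trainer satisfying
the fit/predict contract (deep CNN, PLSr, oracle) can ride it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Protocol

import numpy as np
import pandas as pd

from . import evaluation
from .core_data import ORGAN_NAMES, Acquisition, TrialDataset

__all__ = [
    "PredictionSeries",
    "GrowthCurve",
    "CorrectionRules",
    "PseudoLabelSet",
    "PipelineConfig",
    "PipelineResult",
    "Trainer",
    "DeepTrainer",
    "PLSRTrainer",
    "OracleTrainer",
    "fit_curve",
    "correct",
    "predict_all",
    "run_pipeline",
]

#: trait name -> curve family (the B-spline is reserved for LAI)
_FAMILY_FOR_TRAIT = {"lai": "cubic_bspline"}
_VECTOR_TRAITS = ("dm_prop", "nupt_prop", "n_conc_organ")
_PROPORTION_TRAITS = ("dm_prop", "nupt_prop")


@dataclass
class PredictionSeries:
    """Per-microplot predicted trajectory of one trait component."""

    microplot_id: str
    trait: str
    points: list[tuple[float, float]]  # (thermal_time, y_pred), sorted

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p[0])

    @property
    def times(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class GrowthCurve:
    """A fitted growth curve evaluable on its thermal-time support."""

    family: str  # {cubic_bspline, cubic_polynomial}
    coefficients: Any  # poly coefficients or spline tck
    smoothing: float
    support: tuple[float, float]
    residual_rmse: float = float("nan")

    def __call__(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        lo, hi = self.support
        if np.any(times < lo) or np.any(times > hi):
            warnings.warn(
                f"evaluating growth curve outside support [{lo}, {hi}]", stacklevel=2
            )
        if self.family == "cubic_polynomial":
            return np.polyval(self.coefficients, times)
        from scipy.interpolate import splev

        return np.asarray(splev(times, self.coefficients))


def _noise_variance(y: np.ndarray) -> float:
    """Robust local-noise variance estimate from second differences."""
    if len(y) < 4:
        return float(np.var(y)) * 0.01
    d2 = np.diff(y, 2)
    # Var(second difference of iid noise) = 6 sigma^2
    return float(np.median(d2**2) / 6.0)


def fit_curve(
    series: PredictionSeries,
    family: str | None = None,
    stiffness: float = 10.0,
) -> GrowthCurve:
    """Penalized least-squares growth-curve fit to a prediction series.

    ``cubic_polynomial`` is a plain degree-3 fit (already stiff);
    ``cubic_bspline`` uses a smoothing spline whose condition is the
    second-difference noise estimate scaled by ``stiffness`` (the "high
    smoothing" interpretation).
    """
    t, y = series.times, series.values
    if len(t) < 5:
        raise ValueError(
            f"microplot {series.microplot_id}: {len(t)} points are too few "
            "for a cubic fit (need >= 5)"
        )
    family = family or _FAMILY_FOR_TRAIT.get(series.trait, "cubic_polynomial")
    support = (float(t[0]), float(t[-1]))
    if family == "cubic_polynomial":
        coeffs = np.polyfit(t, y, 3)
        fitted = np.polyval(coeffs, t)
        s = 0.0
    elif family == "cubic_bspline":
        from scipy.interpolate import splev, splrep

        s = stiffness * len(t) * _noise_variance(y)
        tck = splrep(t, y, k=3, s=s)
        coeffs = tck
        fitted = np.asarray(splev(t, tck))
    else:
        raise ValueError(f"unknown curve family {family!r}")
    return GrowthCurve(
        family=family,
        coefficients=coeffs,
        smoothing=float(s),
        support=support,
        residual_rmse=float(np.sqrt(np.mean((fitted - y) ** 2))),
    )


@dataclass
class CorrectionRules:
    """Basic pseudo-label correction conditions."""

    clip_nonnegative: bool = True
    organ_presence: dict[str, float] = field(default_factory=dict)  # organ -> t_appear
    renormalize_proportions: bool = True

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.organ_presence.values()):
            raise ValueError("appearance times must be non-negative")


def correct(
    curve: GrowthCurve,
    times,
    rules: CorrectionRules,
    organ: str | None = None,
) -> np.ndarray:
    """Evaluate the curve and apply the correction rules.

    Negatives are clipped to 0; an organ's values are forced to exactly 0
    before its appearance time.  Proportion renormalization happens across
    organs in :func:`correct_proportions`.
    """
    times = np.asarray(times, dtype=float)
    values = curve(times)
    if rules.clip_nonnegative:
        values = np.maximum(values, 0.0)
    if organ is not None and organ in rules.organ_presence:
        values = np.where(times < rules.organ_presence[organ], 0.0, values)
    return values


def correct_proportions(rows: np.ndarray) -> np.ndarray:
    """Renormalize each 4-vector of organ proportions to sum to 1."""
    rows = np.asarray(rows, dtype=float)
    sums = rows.sum(axis=1, keepdims=True)
    out = np.divide(rows, sums, out=np.zeros_like(rows), where=sums > 0)
    return out


@dataclass
class PseudoLabelSet:
    """Corrected pseudo-labels (Ypseu) beside the raw predictions (Ypred)."""

    records: pd.DataFrame  # microplot_id, date, thermal_time, trait, component, y_pred, y_pseu

    def validate(self) -> None:
        if not np.all(np.isfinite(self.records["y_pseu"])):
            raise ValueError("non-finite pseudo-labels")
        trait = self.records["trait"].iloc[0] if len(self.records) else ""
        if trait in _PROPORTION_TRAITS:
            sums = self.records.groupby(["microplot_id", "date"])["y_pseu"].sum()
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("proportion pseudo-labels do not sum to 1")


# ---------------------------------------------------------------------------
# Trainer contract and implementations
# ---------------------------------------------------------------------------


class Trainer(Protocol):
    """What run_pipeline needs from a model family."""

    def fit(self, acquisitions: list[Acquisition], y: np.ndarray, seed: int,
            initial: bool, label_source: str) -> Any: ...

    def predict(self, fitted: Any, acquisitions: list[Acquisition]) -> np.ndarray: ...


def trait_values(refs, trait: str) -> np.ndarray:
    """Stack a trait from reference samples: (n,) scalar or (n, 4) vector."""
    vals = [np.asarray(getattr(r.traits, trait), dtype=float) for r in refs]
    return np.stack(vals) if trait in _VECTOR_TRAITS else np.array(vals)


class DeepTrainer:
    """CNN trainer over rendered images; caches preprocessed tensors."""

    def __init__(
        self,
        kind: str = "rgb",
        backbone=None,
        head=None,
        phases=None,
        pseudo_phases=None,
        batch_size: int = 16,
        augment_data: bool = True,
    ):
        from . import deep_regression as dr

        self.kind = kind
        self.backbone = backbone or dr.BackboneSpec("tiny_test_cnn")
        self.head = head or dr.HeadSpec("single_linear", 1)
        self.phases = phases or dr.default_phases(self.backbone)
        if pseudo_phases is None:
            pseudo_phases = [dr.pseudo_phase(self.backbone)]
            if not self.backbone.pretrained:
                # mirror Model 1's annealed finish so Model 2 converges too
                pseudo_phases.append(dr.TrainPhase("pseudo_anneal", 10, 3e-4, "all"))
        self.pseudo_phases = pseudo_phases
        self.batch_size = batch_size
        self.augment_data = augment_data
        self._cache: dict[str, np.ndarray] = {}
        self._stats = None

    def _paths(self, acq: Acquisition) -> list[str]:
        return acq.rgb_paths if self.kind == "rgb" else acq.ms_paths

    def _ensure_stats(self, acquisitions: list[Acquisition]) -> None:
        from . import deep_regression as dr
        from .core_data import read_image

        if self.kind != "ms" or self._stats is not None:
            return
        images = [read_image(p, "ms") for a in acquisitions for p in a.ms_paths]
        self._stats = dr.ChannelStats.from_images(images, source_split="train")

    def _tensor(self, path: str) -> np.ndarray:
        from . import deep_regression as dr
        from .core_data import read_image

        if path not in self._cache:
            img = read_image(path, self.kind)
            self._cache[path] = dr.preprocess(img, self.kind, self.backbone, self._stats)
        return self._cache[path]

    def _samples(self, acquisitions, y=None):
        xs, ys = [], []
        for i, acq in enumerate(acquisitions):
            for p in self._paths(acq):
                xs.append(self._tensor(p))
                if y is not None:
                    ys.append(y[i])
        X = np.stack(xs)
        return (X, np.asarray(ys)) if y is not None else X

    def fit(self, acquisitions, y, seed, initial=True, label_source="ytrue"):
        from . import deep_regression as dr

        if initial:
            self._ensure_stats(acquisitions)
        X, yy = self._samples(acquisitions, y)
        # scale-only target normalization for linear heads (keeps the mean
        # within Adam's reach at desk scale and preserves the >0 loss mask)
        if self.head.kind == "multi_softmax":
            scale = 1.0
        else:
            scale = float(np.std(yy)) or 1.0
        model = dr.build_model(self.backbone, self.head, 3 if self.kind == "rgb" else 6, seed=seed)
        phases = self.phases if initial else self.pseudo_phases
        bundle = dr.train(
            model, X, yy / scale, phases, seed=seed, batch_size=self.batch_size,
            label_source=label_source, augment_data=self.augment_data,
            train_stats=self._stats,
        )
        bundle.y_scale = scale
        return bundle

    def predict(self, bundle, acquisitions) -> np.ndarray:
        from . import deep_regression as dr

        out = []
        for acq in acquisitions:
            X = np.stack([self._tensor(p) for p in self._paths(acq)])
            pred = dr.predict(bundle.model, X).mean(axis=0)  # mean over plot images
            pred = pred * bundle.y_scale
            out.append(pred[0] if bundle.model.head.n_outputs == 1 else pred)
        return np.asarray(out)


class PLSRTrainer:
    """PLSr trainer over attached 20-feature vectors (feature-mode trials)."""

    def __init__(self, n_components: int = 2, select: bool = False, folds: int = 5):
        self.n_components = n_components
        self.select = select
        self.folds = folds

    def _frame(self, acquisitions) -> pd.DataFrame:
        from .canopy_features import FEATURE_NAMES

        rows = []
        for acq in acquisitions:
            if acq.features is None:
                raise ValueError(f"acquisition {acq.microplot_id}@{acq.date} has no features")
            rows.append(acq.features)
        return pd.DataFrame(np.stack(rows), columns=list(FEATURE_NAMES))

    def fit(self, acquisitions, y, seed, initial=True, label_source="ytrue"):
        from .plsr_baseline import backward_select, fit_pls

        Xf = self._frame(acquisitions)
        y = np.asarray(y, dtype=float)
        features = tuple(Xf.columns)
        if self.select and y.ndim == 1:
            groups = [a.microplot_id for a in acquisitions]
            trace = backward_select(
                Xf, y, folds=self.folds, seed=seed, n_components=self.n_components,
                groups=groups,
            )
            features = trace.best_set
        return fit_pls(
            Xf[list(features)], y, n_components=min(self.n_components, len(features)),
            training_label_source=label_source,
        )

    def predict(self, model, acquisitions) -> np.ndarray:
        from .plsr_baseline import predict_pls

        return predict_pls(model, self._frame(acquisitions))


class OracleTrainer:
    """Returns the noiseless truth; fixed point of the pipeline."""

    def __init__(self, ds: TrialDataset, trait: str):
        self.truth = ds.meta["true_traits"]
        self.trait = trait

    def fit(self, acquisitions, y, seed, initial=True, label_source="ytrue"):
        return "oracle"

    def predict(self, fitted, acquisitions) -> np.ndarray:
        vals = [
            np.asarray(getattr(self.truth[(a.microplot_id, a.date)], self.trait), dtype=float)
            for a in acquisitions
        ]
        return np.stack(vals) if self.trait in _VECTOR_TRAITS else np.array(vals)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    trait: str = "dm_total"
    seed: int = 0
    curve_family: str | None = None  # default: B-spline for lai, cubic otherwise
    stiffness: float = 10.0
    rules: CorrectionRules | None = None
    #: substitute Ytrue at reference-matched acquisitions when retraining
    overwrite_with_ytrue: bool = False
    model_name: str = "model"


@dataclass
class PipelineResult:
    model1: Any
    model2: Any
    pseudo_labels: PseudoLabelSet
    diagnostics: dict
    metrics: "evaluation.MetricReport"


def predict_all(
    trainer: Trainer, fitted: Any, acquisitions: list[Acquisition], trait: str
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Predict every acquisition; returns values and per-microplot indices."""
    preds = trainer.predict(fitted, acquisitions)
    by_plot: dict[str, list[int]] = {}
    for i, acq in enumerate(acquisitions):
        by_plot.setdefault(acq.microplot_id, []).append(i)
    return np.asarray(preds), by_plot


def _series_for(
    acquisitions, preds, by_plot, trait, component: int | None
) -> list[PredictionSeries]:
    out = []
    for plot, idxs in by_plot.items():
        pts = [
            (
                acquisitions[i].thermal_time,
                float(preds[i] if component is None else preds[i, component]),
            )
            for i in idxs
        ]
        out.append(PredictionSeries(plot, trait, pts))
    return out


def _default_rules(ds: TrialDataset) -> CorrectionRules:
    presence = {}
    if "t_l1_appear" in ds.meta:
        presence["l1"] = float(ds.meta["t_l1_appear"])
    if "t_ear_appear" in ds.meta:
        presence["ear"] = float(ds.meta["t_ear_appear"])
    return CorrectionRules(organ_presence=presence)


def run_pipeline(trainer: Trainer, ds: TrialDataset, config: PipelineConfig) -> PipelineResult:
    """Execute the full two-stage pseudo-labeling pipeline for one trait."""
    trait = config.trait
    rules = config.rules or _default_rules(ds)
    is_vector = trait in _VECTOR_TRAITS
    acq_by_key = {a.key: a for a in ds.acquisitions}

    # --- stage 1: Model 1 on (n, Ytrue) -----------------------------------
    train_refs = ds.references_in("train")
    if not train_refs:
        raise RuntimeError("pipeline stage 'train-model1': no training references")
    labeled_acqs = [acq_by_key[(r.microplot_id, r.date)] for r in train_refs]
    y_true = trait_values(train_refs, trait)
    model1 = trainer.fit(labeled_acqs, y_true, seed=config.seed, initial=True,
                         label_source="ytrue")

    # --- stage 2: Ypred on all m training acquisitions --------------------
    train_acqs = ds.acquisitions_in("train")
    preds, by_plot = predict_all(trainer, model1, train_acqs, trait)

    # --- stage 3: growth-curve fit + corrections -> Ypseu -----------------
    n_comp = 4 if is_vector else 1
    ypseu = np.zeros((len(train_acqs), n_comp))
    curves: dict[tuple[str, int], GrowthCurve] = {}
    for comp in range(n_comp):
        organ = ORGAN_NAMES[comp] if is_vector else None
        for series in _series_for(train_acqs, preds, by_plot, trait, comp if is_vector else None):
            curve = fit_curve(series, family=config.curve_family, stiffness=config.stiffness)
            curves[(series.microplot_id, comp)] = curve
            idxs = by_plot[series.microplot_id]
            times = [train_acqs[i].thermal_time for i in idxs]
            vals = correct(curve, times, rules, organ=organ)
            for i, v in zip(idxs, vals):
                ypseu[i, comp] = v
    if is_vector and trait in _PROPORTION_TRAITS:
        ypseu = correct_proportions(ypseu)
    y2 = ypseu if is_vector else ypseu[:, 0]

    if config.overwrite_with_ytrue:
        ref_pos = {(r.microplot_id, r.date): j for j, r in enumerate(train_refs)}
        for i, acq in enumerate(train_acqs):
            j = ref_pos.get(acq.key)
            if j is not None:
                y2[i] = y_true[j]

    records = pd.DataFrame(
        [
            {
                "microplot_id": a.microplot_id,
                "date": a.date.isoformat(),
                "thermal_time": a.thermal_time,
                "trait": trait,
                "component": ORGAN_NAMES[c] if is_vector else "total",
                "y_pred": float(preds[i, c] if is_vector else preds[i]),
                "y_pseu": float(y2[i, c] if is_vector else y2[i]),
            }
            for i, a in enumerate(train_acqs)
            for c in range(n_comp)
        ]
    )
    pseudo = PseudoLabelSet(records=records)
    pseudo.validate()

    # --- stage 4: Model 2 from fresh initialization on (m, Ypseu) ---------
    model2 = trainer.fit(train_acqs, y2, seed=config.seed + 1, initial=False,
                         label_source="ypseu")

    # --- evaluation on both splits ----------------------------------------
    results = []
    for split in ("train", "val"):
        refs = ds.references_in(split)
        if not refs:
            continue
        acqs = [acq_by_key[(r.microplot_id, r.date)] for r in refs]
        yt = trait_values(refs, trait)
        for name, model in (("ytrue", model1), ("ypseu", model2)):
            yp = trainer.predict(model, acqs)
            results.append(
                {
                    "trait": trait,
                    "model": config.model_name,
                    "label_source": name,
                    "split": split,
                    "y_true": np.asarray(yt, dtype=float).ravel(),
                    "y_pred": np.asarray(yp, dtype=float).ravel(),
                }
            )
    metrics = evaluation.report(results)

    diagnostics = {
        "curves": curves,
        "pred_pseu_delta": records.eval("y_pseu - y_pred").abs().describe().to_dict(),
        "n_labeled": len(train_refs),
        "m_images": len(train_acqs),
    }
    return PipelineResult(model1=model1, model2=model2, pseudo_labels=pseudo,
                          diagnostics=diagnostics, metrics=metrics)
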