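import numpy as np
import pytest

from canopyreg.core_data import ORGAN_NAMES
from canopyreg.pseudo_label import (
    CorrectionRules,
    OracleTrainer,
    PLSRTrainer,
    PipelineConfig,
    PredictionSeries,
    correct,
    correct_proportions,
    fit_curve,
    predict_all,
    run_pipeline,
    trait_values,
)


def _cubic(t):
    return 2.0 + 0.01 * t - 1e-6 * t**2 - 1e-10 * t**3


def _series(times, values, trait="dm_total", plot="p1"):
    return PredictionSeries(plot, trait, list(zip(times, values)))


class TestFitCurve:
    def test_exact_cubic_recovery(self):
        t = np.linspace(0, 2000, 15)
        curve = fit_curve(_series(t, _cubic(t)), family="cubic_polynomial")
        np.testing.assert_allclose(
            curve.coefficients, [-1e-10, -1e-6, 0.01, 2.0], rtol=1e-6
        )
        np.testing.assert_allclose(curve(t), _cubic(t), rtol=1e-9)

    def test_smoothing_beats_raw_points(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 2000, 15)
        truth = _cubic(t)
        noisy = truth + rng.normal(0, 0.5, len(t))
        curve = fit_curve(_series(t, noisy), family="cubic_polynomial")
        rmse_curve = np.sqrt(np.mean((curve(t) - truth) ** 2))
        rmse_raw = np.sqrt(np.mean((noisy - truth) ** 2))
        assert rmse_curve < rmse_raw

    def test_bspline_unimodal_compatible(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 2000, 15)
        truth = 5.0 * np.exp(-(((t - 900) / 450) ** 2))
        noisy = truth + rng.normal(0, 0.3, len(t))
        curve = fit_curve(_series(t, noisy, trait="lai"), family="cubic_bspline")
        dense = np.linspace(t[0], t[-1], 400)
        deriv = np.diff(curve(dense))
        sign_changes = int((np.diff(np.sign(deriv[np.abs(deriv) > 1e-9])) != 0).sum())
        assert sign_changes <= 2

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="p1"):
            fit_curve(_series([0, 1, 2, 3], [1, 2, 3, 4]))

    def test_lai_defaults_to_bspline(self):
        t = np.linspace(0, 2000, 12)
        curve = fit_curve(_series(t, np.sin(t / 500) + 2, trait="lai"))
        assert curve.family == "cubic_bspline"


class TestCorrect:
    def test_negative_clipped(self):
        t = np.linspace(0, 1000, 10)
        curve = fit_curve(_series(t, np.linspace(-0.3, 2, 10)), family="cubic_polynomial")
        vals = correct(curve, [0.0], CorrectionRules())
        assert vals[0] == 0.0

    def test_organ_zero_before_appearance(self):
        t = np.linspace(0, 2000, 10)
        curve = fit_curve(_series(t, np.full(10, 0.5)), family="cubic_polynomial")
        rules = CorrectionRules(organ_presence={"ear": 1000.0})
        vals = correct(curve, [500.0, 1500.0], rules, organ="ear")
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(0.5, abs=1e-6)

    def test_proportions_renormalized(self):
        rows = np.array([[0.5, 0.4, 0.3, 0.0]])
        out = correct_proportions(rows)
        assert out.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(out, [[5 / 12, 4 / 12, 3 / 12, 0.0]])

    def test_negative_appearance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            CorrectionRules(organ_presence={"ear": -5.0})

    def test_extrapolation_flagged(self):
        t = np.linspace(0, 1000, 10)
        curve = fit_curve(_series(t, np.linspace(1, 2, 10)), family="cubic_polynomial")
        with pytest.warns(UserWarning, match="outside support"):
            correct(curve, [1500.0], CorrectionRules())


class TestSmoothingBenefitProperty:
    def test_pseudo_labels_beat_predictions(self):
        """Seeded property: curve correction denoises in >= 95% of runs."""
        wins = 0
        runs = 100
        t = np.linspace(100, 2000, 15)
        for run in range(runs):
            rng = np.random.default_rng(run)
            better = []
            for plot in range(20):
                coeffs = rng.uniform([-2e-10, -2e-6, 0.005, 1], [0, 0, 0.02, 3])
                truth = np.polyval(coeffs[::-1], t)
                sd = 0.15 * truth.std()
                noisy = truth + rng.normal(0, sd, len(t))
                gross = rng.random(len(t)) < 0.05
                noisy[gross] += rng.normal(0, 8 * sd, gross.sum())
                curve = fit_curve(_series(t, noisy), family="cubic_polynomial")
                pseu = correct(curve, t, CorrectionRules(clip_nonnegative=False))
                better.append(
                    np.mean((pseu - truth) ** 2) < np.mean((noisy - truth) ** 2)
                )
            if np.mean(better) > 0.5:
                wins += 1
        assert wins >= 95


class TestPipeline:
    def test_oracle_fixed_point(self, feature_trial):
        trainer = OracleTrainer(feature_trial, "dm_total")
        res = run_pipeline(trainer, feature_trial, PipelineConfig(trait="dm_total"))
        truth = feature_trial.meta["true_traits"]
        import datetime as dt

        true_vals, pseu_vals = [], []
        for _, row in res.pseudo_labels.records.iterrows():
            tv = truth[(row.microplot_id, dt.date.fromisoformat(row.date))]
            true_vals.append(tv.dm_total)
            pseu_vals.append(row.y_pseu)
            # within the cubic family's approximation error of a logistic
            assert row.y_pseu == pytest.approx(tv.dm_total, abs=1.5)
        from canopyreg.evaluation import r2 as _r2

        assert _r2(np.array(true_vals), np.array(pseu_vals)) > 0.99
        # metrics near-oracle (reference noise only)
        val_r2 = res.metrics.row(label_source="ypseu", split="val")["r2"]
        assert val_r2 > 0.97

    def test_plsr_trainer_end_to_end(self, feature_trial):
        res = run_pipeline(
            PLSRTrainer(n_components=3), feature_trial, PipelineConfig(trait="lai")
        )
        table = res.metrics.table
        assert set(table["label_source"]) == {"ytrue", "ypseu"}
        assert set(table["split"]) == {"train", "val"}
        assert len(table) == 4
        res.pseudo_labels.validate()

    def test_predict_all_counts(self, feature_trial):
        trainer = OracleTrainer(feature_trial, "lai")
        acqs = feature_trial.acquisitions_in("train")
        preds, by_plot = predict_all(trainer, "oracle", acqs, "lai")
        assert len(preds) == len(acqs)
        for plot, idxs in by_plot.items():
            assert len(idxs) == 12  # one per acquisition date

    def test_proportion_pipeline_sums_to_one(self, feature_trial):
        trainer = OracleTrainer(feature_trial, "dm_prop")
        res = run_pipeline(trainer, feature_trial, PipelineConfig(trait="dm_prop"))
        sums = res.pseudo_labels.records.groupby(["microplot_id", "date"])["y_pseu"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        # no ear pseudo-label before appearance
        rec = res.pseudo_labels.records
        early_ear = rec[
            (rec.component == "ear")
            & (rec.thermal_time < feature_trial.meta["t_ear_appear"])
        ]
        assert (early_ear.y_pseu == 0.0).all()

    def test_model_agnostic_structure(self, feature_trial):
        out = {}
        for name, trainer in (
            ("plsr", PLSRTrainer(n_components=3)),
            ("oracle", OracleTrainer(feature_trial, "lai")),
        ):
            res = run_pipeline(trainer, feature_trial, PipelineConfig(trait="lai"))
            out[name] = res
        for name, res in out.items():
            assert set(res.pseudo_labels.records.columns) == {
                "microplot_id", "date", "thermal_time", "trait",
                "component", "y_pred", "y_pseu",
            }
            assert list(res.metrics.table.columns) == [
                "trait", "model", "label_source", "split", "rmse", "r2", "n",
            ]

    def test_pseudo_labels_finite_nonnegative(self, feature_trial):
        res = run_pipeline(
            PLSRTrainer(n_components=3), feature_trial, PipelineConfig(trait="n_upt")
        )
        vals = res.pseudo_labels.records["y_pseu"]
        assert np.all(np.isfinite(vals))
        assert np.all(vals >= 0)

    def test_no_training_references_error(self, feature_trial):
        from canopyreg.core_data import split_by_treatment

        all_val = split_by_treatment(
            feature_trial, list(feature_trial.treatments())
        )
        with pytest.raises(RuntimeError, match="model1"):
            run_pipeline(PLSRTrainer(), all_val, PipelineConfig(trait="lai"))


def test_trait_values_shapes(feature_trial):
    refs = feature_trial.references[:5]
    assert trait_values(refs, "dm_total").shape == (5,)
    assert trait_values(refs, "dm_prop").shape == (5, 4)
    assert list(ORGAN_NAMES) == ["stem", "linf", "l1", "ear"]
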