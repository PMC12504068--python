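"""EC classification design/fit and Lasso length regression."""

import numpy as np
import pandas as pd
import pytest

import ctikin as ck
from ctikin.errors import DegenerateInputError
from ctikin.predict import lasso_feature_names, lasso_kkt_residual
from sklearn.linear_model import Lasso
from sklearn.preprocessing import StandardScaler


def _kinetics_map(cohort, n=None):
    cines = cohort.cines if n is None else cohort.cines[:n]
    return {c.patient_id: ck.segment_kinetics(c) for c in cines}


class TestBuildECDesign:
    def test_one_observation_per_patient_segment(self, default_cohort):
        sks = _kinetics_map(default_cohort, n=2)
        ec = {pid: i % 2 == 0 for i, pid in enumerate(sks)}
        X, y, obs = ck.build_ec_design(sks, ec, axis="x")
        assert X.shape[0] == len(y) == len(obs) == 2 * 5
        assert {seg for _, seg in obs} == {1, 2, 3, 4, 5}

    def test_plane_features_are_norms(self, default_cohort):
        sks = _kinetics_map(default_cohort, n=2)
        ec = {pid: True for pid in sks}
        ec[next(iter(ec))] = False
        X, _, _ = ck.build_ec_design(sks, ec, axis="plane")
        assert (X >= 0.0).all()

    def test_zero_motion_patient_gives_zero_vector(self):
        frames = np.tile(np.linspace(0, 9, 11)[None, :, None], (4, 1, 2))
        cine = ck.ContourCine("Z", frames, cti_index_range=(1, 11))
        sk = ck.segment_kinetics(cine, dt=0.04)
        X, _, _ = ck.build_ec_design({"Z": sk, "Z2": sk}, {"Z": True, "Z2": False})
        assert np.all(X == 0.0)

    def test_ragged_lengths_need_padding(self, default_cohort):
        # 13 CTI points -> segment sizes (2,2,3,3,3): ragged by design
        cine = default_cohort.cines[0]
        small = ck.ContourCine(
            "S", cine.frames[:, :13, :], cti_index_range=(0, 13)
        )
        sk = ck.segment_kinetics(small)
        ec = {"S": True, "S2": False}
        sks = {"S": sk, "S2": sk}
        with pytest.raises(DegenerateInputError, match="ragged"):
            ck.build_ec_design(sks, ec, axis="x", pad=False)
        X, _, _ = ck.build_ec_design(sks, ec, axis="x", pad=True)
        assert X.shape[1] == 3 * (small.n_frames - 1)


class TestFitECClassifier:
    def test_separable_toy_problem(self, rng):
        X = np.vstack([rng.normal(-3, 0.2, (30, 4)), rng.normal(3, 0.2, (30, 4))])
        y = np.repeat([0, 1], 30)
        fit = ck.fit_ec_classifier(X, y, seed=0, C=1.0)
        assert fit.accuracy == 1.0
        tn, fp, fn, tp = fit.confusion
        assert tn + fp + fn + tp == fit.n_test

    def test_single_class_training_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([1, 1, 1, 1, 1, 1])
        with pytest.raises(DegenerateInputError):
            ck.fit_ec_classifier(X, y, seed=0)

    def test_shuffled_labels_score_at_chance(self, rng):
        accs = []
        X = rng.normal(size=(60, 10))
        for seed in range(30):
            y = np.random.default_rng(seed).permutation(np.repeat([0, 1], 30))
            fit = ck.fit_ec_classifier(X, y, seed=seed)
            accs.append(fit.accuracy)
        assert 0.35 < np.mean(accs) < 0.65

    def test_grouped_split_keeps_patients_together(self, default_cohort):
        sks = _kinetics_map(default_cohort, n=10)
        ec = {pid: i % 2 == 0 for i, pid in enumerate(sks)}
        X, y, obs = ck.build_ec_design(sks, ec)
        groups = [p for p, _ in obs]
        fit = ck.fit_ec_classifier(X, y, groups=groups, seed=1)
        # test-set size must be a multiple of the 5 segments per patient
        assert fit.n_test % 5 == 0
        assert fit.observation_unit == "patient-segment"


def _toy_cohort(n=40, seed=0):
    rng = np.random.default_rng(seed)
    dia = rng.normal(40, 10, n)
    pouch = rng.normal(3.2, 1.5, n).clip(0.3)
    linear = dia * 0.9 + rng.normal(0, 1, n)
    ec = rng.random(n) < 0.5
    sysl = 0.6 * dia - 2.0 * ec + rng.normal(0, 2, n)
    df = pd.DataFrame(
        {
            "curvilinear_diastolic_mm": dia,
            "curvilinear_systolic_mm": sysl,
            "pouch_depth_mm": pouch,
            "linear_diastolic_mm": linear,
            "ec_within_12h": ec.astype(int),
            "smoker": (rng.random(n) < 0.5).astype(int),
            "dyslipidaemia": (rng.random(n) < 0.5).astype(int),
        },
        index=[f"P{i}" for i in range(n)],
    )
    return df


class TestFitLassoLength:
    def test_feature_sets_swap_complementary_length(self):
        sys_names = lasso_feature_names("systolic")
        dia_names = lasso_feature_names("diastolic")
        assert "curvilinear_diastolic_mm" in sys_names
        assert "curvilinear_systolic_mm" in dia_names
        assert lasso_feature_names("systolic", include_clinical=False) == [
            "curvilinear_diastolic_mm", "pouch_depth_mm", "linear_diastolic_mm",
        ]

    def test_alpha_zero_recovers_exact_linear_data(self):
        rng = np.random.default_rng(1)
        df = _toy_cohort()
        df["curvilinear_systolic_mm"] = 2.0 * df["curvilinear_diastolic_mm"] + 1.0
        fit = ck.fit_lasso_length(df, "systolic", alpha=0.0, include_clinical=False)
        raw = dict(zip(fit.features, fit.coefficients_raw))
        assert raw["curvilinear_diastolic_mm"] == pytest.approx(2.0, abs=1e-6)
        assert abs(raw["pouch_depth_mm"]) < 1e-6
        assert fit.intercept_raw == pytest.approx(1.0, abs=1e-6)
        assert fit.mae_mm == pytest.approx(0.0, abs=1e-6)

    def test_huge_alpha_shrinks_everything_to_the_mean(self):
        df = _toy_cohort()
        fit = ck.fit_lasso_length(df, "systolic", alpha=1e6)
        assert np.all(fit.coefficients_std == 0.0)
        y = df["curvilinear_systolic_mm"]
        assert fit.intercept_raw == pytest.approx(y.mean(), rel=1e-6)

    def test_kkt_conditions_hold_on_random_problems(self, rng):
        df = _toy_cohort(seed=3)
        X = df[lasso_feature_names("systolic")].to_numpy(float)
        Xs = StandardScaler().fit_transform(X)
        y = df["curvilinear_systolic_mm"].to_numpy()
        for alpha in (0.05, 0.17, 0.65, 2.0):
            model = Lasso(alpha=alpha, tol=1e-12, max_iter=500_000).fit(Xs, y)
            viol = lasso_kkt_residual(Xs, y, model.coef_, model.intercept_, alpha)
            assert viol <= 1e-6

    def test_sparsity_monotone_in_alpha(self):
        df = _toy_cohort(seed=5)
        nnz = []
        for alpha in (0.01, 0.1, 0.5, 1.0, 3.0, 10.0):
            fit = ck.fit_lasso_length(df, "systolic", alpha=alpha)
            nnz.append(int(np.count_nonzero(fit.coefficients_std)))
        assert all(a >= b for a, b in zip(nnz[:-1], nnz[1:]))

    def test_cv_alpha_selection_is_deterministic(self):
        df = _toy_cohort(seed=7)
        f1 = ck.fit_lasso_length(df, "diastolic", alpha="cv", seed=4)
        f2 = ck.fit_lasso_length(df, "diastolic", alpha="cv", seed=4)
        assert f1.alpha == f2.alpha and f1.mae_mm == f2.mae_mm

    def test_too_few_rows_rejected(self):
        df = _toy_cohort(n=6)
        with pytest.raises(DegenerateInputError):
            ck.fit_lasso_length(df, "systolic", folds=10)

    def test_constant_target_rejected(self):
        df = _toy_cohort()
        df["curvilinear_systolic_mm"] = 21.0
        with pytest.raises(DegenerateInputError):
            ck.fit_lasso_length(df, "systolic", alpha=0.1)


class TestAblationReport:
    def test_identical_fits_give_zero_deltas(self):
        df = _toy_cohort()
        fit = ck.fit_lasso_length(df, "systolic", alpha=0.17)
        rep = ck.ablation_report(fit, fit)
        assert rep["delta_mae_mm"] == 0.0 and rep["delta_r2"] == 0.0

    def test_mismatched_targets_rejected(self):
        df = _toy_cohort()
        a = ck.fit_lasso_length(df, "systolic", alpha=0.17)
        b = ck.fit_lasso_length(df, "diastolic", alpha=0.65)
        with pytest.raises(ValueError):
            ck.ablation_report(a, b)

    def test_true_clinical_effect_improves_systolic_prediction(self):
        """EC genuinely shifts systolic length in the toy generator, so
        including the clinical flags should usually lower the MAE."""
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            df = _toy_cohort(seed=100 + rep)
            fw = ck.fit_lasso_length(df, "systolic", alpha=0.17, seed=rep)
            fo = ck.fit_lasso_length(
                df, "systolic", alpha=0.17, seed=rep, include_clinical=False
            )
            if ck.ablation_report(fw, fo)["delta_mae_mm"] <= 0:
                wins += 1
        assert wins / n_rep >= 0.8
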