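"""Agreement metrics: R², RMSE, Spearman, Bland–Altman, CMC and bands."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cutkin.modeling import DEFAULT_HYPERPARAMETERS, train_target_model
from cutkin.preprocess import TARGET_NAMES
from cutkin.validation import (
    AgreementReport,
    bland_altman,
    build_report,
    classify_cmc,
    cmc,
    moving_average,
    r_squared,
    rmse,
    spearman,
)
from .test_modeling import make_synthetic_dataset


class TestScalarMetrics:
    def test_r_squared_perfect_and_mean_predictor(self):
        y = np.array([1.0, 2.0, 3.0, 5.0])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_r_squared_constant_actual_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            r_squared(np.ones(5), np.arange(5.0))

    def test_report_formats_three_decimals(self):
        """Table rendering keeps three decimals (e.g. 0.766 -> '0.766')."""
        assert f"{0.766:.3f}" == "0.766"
        assert round(0.7664, 3) == 0.766

    def test_rmse_closed_forms_and_brute_force(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0
        assert rmse(y, y + 0.5) == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=50), rng.normal(size=50)
        brute = math.sqrt(sum((x - z) ** 2 for x, z in zip(a, b)) / 50)
        assert rmse(a, b) == pytest.approx(brute)

    def test_spearman_rank_invariance_and_reversal(self):
        y = np.array([0.3, 1.2, 2.0, 3.5, 7.0])
        r, _ = spearman(y, np.exp(y))  # strictly monotone transform
        assert r == pytest.approx(1.0)
        r, _ = spearman(y, -y)
        assert r == pytest.approx(-1.0)

    def test_spearman_midranks_against_hand_computation(self):
        """n=5 with ties on both sides, midranks computed by hand.

        actual [1,2,2,3,4] -> ranks [1, 2.5, 2.5, 4, 5];
        predicted [10,20,30,20,50] -> ranks [1, 2.5, 4, 2.5, 5];
        Pearson of the rank vectors = 7.25/9.5 = 29/38.
        """
        r, p = spearman(np.array([1, 2, 2, 3, 4.0]), np.array([10, 20, 30, 20, 50.0]))
        assert r == pytest.approx(29 / 38)
        assert 0 < p < 1

    def test_spearman_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5.0))


class TestBlandAltman:
    def test_identical_series(self):
        y = np.arange(5.0)
        assert bland_altman(y, y) == (0.0, 0.0, 0.0)

    def test_two_point_closed_form(self):
        """d = {-1, +1}: bias 0, SD = sqrt(2), LoA = +/- 1.96*sqrt(2)."""
        bias, lo, hi = bland_altman(np.zeros(2), np.array([-1.0, 1.0]))
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * math.sqrt(2))
        assert lo == pytest.approx(-1.96 * math.sqrt(2))

    def test_loa_rendering_and_ordering_fixture(self):
        """Bias must sit inside its limits; rendering keeps 3 decimals."""
        bias, lo, hi = -0.004, -0.811, 0.794
        assert lo <= bias <= hi
        assert f"{bias:.3f}" == "-0.004"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_loa_ordering_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        a, b = rng.normal(size=n), rng.normal(size=n)
        bias, lo, hi = bland_altman(a, b)
        assert lo <= bias <= hi


class TestCmc:
    def test_identical_nonconstant_waveforms(self):
        x = np.sin(np.linspace(0, 3, 101))
        assert cmc(x, x) == pytest.approx(1.0)

    def test_antiphase_gives_nan_classified_poor(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 101))
        value = cmc(x, -x)
        assert math.isnan(value)
        assert classify_cmc(value) == "poor"

    def test_identical_constant_pair_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cmc(np.ones(101), np.ones(101))

    def test_decreases_monotonically_with_noise(self):
        """Median CMC over replicates falls as predictor noise grows."""
        rng = np.random.default_rng(1)
        x = np.sin(np.linspace(0, 2 * np.pi, 101))
        medians = []
        for sigma in (0.05, 0.2, 0.6):
            vals = [
                cmc(x, x + rng.normal(0, sigma, 101)) for _ in range(100)
            ]
            medians.append(np.nanmedian(vals))
        assert medians[0] > medians[1] > medians[2]

    def test_constant_offset_strictly_decreases_cmc(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = np.cumsum(rng.normal(size=101))
            prev = cmc(x, x)
            for c in (0.5, 1.5, 4.0):
                cur = cmc(x, x + c * np.std(x))
                cur = -1.0 if math.isnan(cur) else cur
                assert cur < prev
                prev = cur

    @pytest.mark.parametrize(
        "value, band",
        [
            (1.0, "excellent"),
            (0.95, "excellent"),
            (0.93, "very good"),
            (0.85, "very good"),
            (0.80, "good"),
            (0.75, "good"),
            (0.70, "moderate"),
            (0.65, "moderate"),
            (0.60, "poor"),
            (float("nan"), "poor"),
        ],
    )
    def test_band_classification(self, value, band):
        assert classify_cmc(value) == band

    def test_value_above_one_rejected(self):
        with pytest.raises(ValueError):
            classify_cmc(1.2)


@pytest.fixture(scope="module")
def trained_models_and_test():
    ds = make_synthetic_dataset(20, np.random.default_rng(3), noise=0.05)
    from cutkin.modeling import group_split

    train, test = group_split(ds, 0.2, seed=0)
    params = dict(n_estimators=60, max_depth=10, min_samples_split=2,
                  min_samples_leaf=1, max_features="sqrt")
    models = {t: train_target_model(train, t, params, seed=0) for t in TARGET_NAMES}
    return models, test


class TestReport:

    def test_report_complete_and_consistent(self, trained_models_and_test):
        models, test = trained_models_and_test
        report = build_report(models, test)
        assert set(report.per_target) == set(TARGET_NAMES)
        for t in report.per_target.values():
            assert t.loa_low <= t.bias <= t.loa_high
            assert t.r_squared <= 1
            assert len(t.top_features) == 3
            assert classify_cmc(t.cmc_median) == t.cmc_band

    def test_metric_cross_consistency(self, trained_models_and_test):
        """R2 == 1 - n*RMSE^2 / SS_tot on the same pooled rows."""
        models, test = trained_models_and_test
        report = build_report(models, test)
        actual = np.concatenate([kt.vgrf_bw for _, kt in test.trials])
        ss_tot = np.sum((actual - actual.mean()) ** 2)
        t = report.per_target["vgrf"]
        n = actual.size
        assert t.r_squared == pytest.approx(1 - n * t.rmse**2 / ss_tot, abs=1e-9)

    def test_missing_model_named(self, trained_models_and_test):
        models, test = trained_models_and_test
        partial = {k: v for k, v in models.items() if k != "knee_frontal"}
        with pytest.raises(ValueError, match="knee_frontal"):
            build_report(partial, test)

    def test_round_trip_serialization(self, trained_models_and_test):
        models, test = trained_models_and_test
        report = build_report(models, test)
        back = AgreementReport.from_json(report.to_json())
        assert back.to_json() == report.to_json()

    def test_perfect_predictor_baseline(self):
        """A model that memorizes a single repeated waveform scores perfectly."""

        class _Echo:
            def __init__(self, y):
                self.y = y

            def predict(self, X):
                return self.y.copy()

        from cutkin.modeling import TrainedModel

        rng = np.random.default_rng(4)
        ds = make_synthetic_dataset(3, rng)
        y = ds.trials[0][1].vgrf_bw
        trials = [(fm, type(kt)(vgrf_bw=y, moments=np.tile(y[:, None], (1, 6)),
                                participant_id=kt.participant_id, trial_id=kt.trial_id))
                  for fm, kt in ds.trials]
        from cutkin.modeling import Dataset

        same = Dataset(trials)
        models = {
            t: TrainedModel(target_name=t, hyperparameters={}, ensemble=_Echo(y),
                            importances=np.full(12, 1 / 12))
            for t in TARGET_NAMES
        }
        report = build_report(models, same)
        for t in report.per_target.values():
            assert t.r_squared == pytest.approx(1.0)
            assert t.bias == pytest.approx(0.0)
            assert t.cmc_band == "excellent"

    def test_write_emits_tables(self, tmp_path, trained_models_and_test):
        models, test = trained_models_and_test
        report = build_report(models, test)
        report.write(tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "performance.tsv").exists()
        assert (tmp_path / "agreement.tsv").exists()
        assert (tmp_path / "waveform_vgrf.tsv").exists()


def test_moving_average_is_presentation_only_smoother():
    x = np.array([0.0, 0, 10, 0, 0])
    sm = moving_average(x, 5)
    assert sm[2] == pytest.approx(2.0)
    assert sm.sum() == pytest.approx(x.sum(), rel=0.5)  # mass roughly preserved
    assert sm[0] == pytest.approx(10 / 3)
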