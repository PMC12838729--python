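import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evmetrics import RunConfig
from evmetrics.psd import (BinnedPSD, PSDModel, bin_diameters,
                           bootstrap_replicate_uncertainty, mean_psd,
                           psd_summary, single_measurement_relative_uncertainty)


def make_psd(counts):
    counts = np.asarray(counts)
    edges = 5.0 * np.arange(len(counts) + 1)
    return BinnedPSD(edges, counts)


class TestBinning:
    def test_hand_enumerated_counts(self, config):
        psd = bin_diameters([31.2, 34.9, 67.0], config)
        assert psd.n == 3
        assert psd.counts[6] == 2       # [30, 35)
        assert psd.counts[13] == 1      # [65, 70)
        assert psd.counts.sum() == 3

    def test_upper_edge_excluded_half_open(self, config):
        psd = bin_diameters([400.0], config)
        assert psd.n == 0 and psd.n_excluded == 1

    def test_lower_edge_included(self, config):
        psd = bin_diameters([0.0], config)
        assert psd.counts[0] == 1 and psd.n_excluded == 0

    def test_empty_input_flags_undefined_probabilities(self, config):
        psd = bin_diameters([], config)
        assert psd.n == 0
        assert np.isnan(psd.probabilities).all()

    @given(st.lists(st.floats(min_value=0.01, max_value=399.99), max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_probabilities_sum_to_one(self, diameters):
        psd = bin_diameters(diameters, RunConfig())
        if psd.n > 0:
            assert psd.probabilities.sum() == pytest.approx(1.0)


class TestSingleMeasurementUncertainty:
    def test_closed_form_at_half_and_hundred(self):
        rel = single_measurement_relative_uncertainty(make_psd([50, 50]))
        assert rel == pytest.approx([0.10, 0.10])

    def test_single_occupied_bin_has_zero_uncertainty(self):
        rel = single_measurement_relative_uncertainty(make_psd([100, 0]))
        assert rel[0] == 0.0
        assert np.isnan(rel[1])

    def test_empty_replicate_errors(self):
        with pytest.raises(ValueError, match="N = 0"):
            single_measurement_relative_uncertainty(make_psd([0, 0]))

    def test_inverse_sqrt_n_scaling(self):
        r1 = single_measurement_relative_uncertainty(make_psd([30, 70]))
        r4 = single_measurement_relative_uncertainty(make_psd([120, 280]))
        assert r1[0] / r4[0] == pytest.approx(2.0, abs=1e-12)
        assert r1[1] / r4[1] == pytest.approx(2.0, abs=1e-12)


class TestMeanPSD:
    def test_identical_replicates_mean_equals_each(self):
        reps = [make_psd([20, 80]) for _ in range(3)]
        m = mean_psd(reps)
        assert m.mean_p == pytest.approx([0.2, 0.8])
        assert m.n_replicates == 3

    def test_arithmetic_mean_of_probability_vectors(self):
        reps = [make_psd([20, 80]), make_psd([40, 60]), make_psd([60, 40])]
        assert mean_psd(reps).mean_p == pytest.approx([0.4, 0.6])

    def test_single_replicate_allowed(self):
        m = mean_psd([make_psd([500, 0])])
        assert m.n_replicates == 1
        assert m.mean_p == pytest.approx([1.0, 0.0])

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError, match="grid"):
            mean_psd([make_psd([1, 1]), make_psd([1, 1, 1])])


class TestBootstrap:
    def test_matches_closed_form_for_equal_replicates(self):
        # three identical replicates p=(0.5, 0.5), N=1000: the SD of the mean
        # proportion is (1/3) sqrt(3 p (1-p) / N), so rel = SD / 0.5
        reps = [make_psd([500, 500]) for _ in range(3)]
        out = bootstrap_replicate_uncertainty(reps, draws=100_000, seed=7)
        expected = (1 / 3) * np.sqrt(3 * 0.25 / 1000) / 0.5
        assert out.replicate_rel == pytest.approx([expected, expected], rel=0.02)

    def test_degenerate_bin_has_zero_uncertainty(self):
        reps = [make_psd([1000, 0]) for _ in range(3)]
        out = bootstrap_replicate_uncertainty(reps, draws=2000, seed=3)
        assert out.sd[0] == 0.0 and out.replicate_rel[0] == 0.0
        assert np.isnan(out.replicate_rel[1])

    def test_same_seed_bit_identical(self):
        reps = [make_psd([300, 700]), make_psd([350, 650]), make_psd([280, 720])]
        a = bootstrap_replicate_uncertainty(reps, draws=5000, seed=11)
        b = bootstrap_replicate_uncertainty(reps, draws=5000, seed=11)
        assert np.array_equal(a.sd, b.sd)
        assert np.array_equal(a.replicate_rel, b.replicate_rel, equal_nan=True)

    def test_invalid_draws_error(self):
        with pytest.raises(ValueError, match="draws"):
            bootstrap_replicate_uncertainty([make_psd([10, 10])], draws=0)

    def test_single_replicate_bootstrap_permitted(self):
        # the Cryo-EM case: one analysis, SD of simulated p from one multinomial
        out = bootstrap_replicate_uncertainty([make_psd([250, 250])], draws=50_000, seed=5)
        expected = np.sqrt(0.25 / 500) / 0.5
        assert out.replicate_rel[0] == pytest.approx(expected, rel=0.03)

    def test_inverse_correlation_with_mean_probability(self, rng):
        # occupied-bin relative uncertainty falls as the bin probability rises
        base = np.array([400, 250, 150, 100, 60, 25, 10, 5])
        reps = [make_psd(rng.multinomial(1000, base / base.sum())) for _ in range(3)]
        out = bootstrap_replicate_uncertainty(reps, draws=20_000, seed=2)
        mean_p = np.mean([r.probabilities for r in reps], axis=0)
        occ = mean_p > 0
        rho = stats.spearmanr(mean_p[occ], out.replicate_rel[occ]).statistic
        assert rho < 0


class TestSummary:
    def test_constant_sample(self, config):
        mean, sd, mode = psd_summary([100.0, 100.0, 100.0], config)
        assert (mean, sd, mode) == (100.0, 0.0, 102.5)

    def test_two_point_sample_sd(self, config):
        mean, sd, _ = psd_summary([90.0, 110.0], config)
        assert mean == 100.0
        assert sd == pytest.approx(14.1421, abs=1e-3)

    def test_lognormal_mean_closed_form(self, config, rng):
        d = np.exp(rng.normal(np.log(100), 0.25, 50_000))
        mean, _, _ = psd_summary(d, config)
        assert mean == pytest.approx(100 * np.exp(0.25**2 / 2), rel=0.01)

    def test_empty_after_filtering_errors(self, config):
        with pytest.raises(ValueError, match="range"):
            psd_summary([450.0], config)


class TestPSDModel:
    def test_fit_produces_consistent_results(self, config, rng):
        reps = [rng.normal(100, 20, 800).clip(1) for _ in range(3)]
        res = PSDModel(reps, config, label="toy").fit(draws=5000, seed=1)
        assert res.mean_p.sum() == pytest.approx(1.0)
        assert res.single_rel.shape == (3, 80)
        frame = res.frame()
        assert len(frame) == 80
        assert "replicate_rel" in frame.columns
        assert "toy" in res.summary()

    def test_from_dataframe_groups_by_replicate(self, config, rng):
        import pandas as pd

        df = pd.DataFrame(
            {
                "sample_id": "s",
                "method": "pta",
                "replicate": np.repeat([1, 2, 3], 200),
                "diameter_nm": rng.normal(120, 25, 600).clip(30),
            }
        )
        model = PSDModel.from_dataframe(df, config, sample_id="s", method="pta")
        assert len(model.binned) == 3
        res = model.fit(draws=1000, seed=0)
        assert res.mean_psd.n_replicates == 3
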