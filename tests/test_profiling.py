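"""Profile correlation: Pearson R, replicate aggregation, peak statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acp import assay, gradient, profiling
from acp.gradient import MixtureConfig, ProfileMatrix, Species
from acp.profiling import (
    InsufficientOverlap,
    aggregate_replicates,
    correlate_profiles,
    mean_mass_by_peak,
    peak_fraction,
    pearson_r,
)


def brute_force_pearson(x, y):
    """Textbook product-moment formula, written independently."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5
    return num / den


class TestPearsonR:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((0, 1, 2), (0, 2, 4), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(3, 21))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson_r(x, y) == pytest.approx(
                brute_force_pearson(x, y), abs=1e-12
            )

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        c=st.floats(0.1, 10), d=st.floats(-5, 5),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_affine_invariance(self, a, b, c, d):
        x = np.array([0.3, 1.7, 0.9, 2.4, 1.1])
        y = np.array([1.0, 0.2, 2.2, 0.5, 1.9])
        assert pearson_r(a * x + b, c * y + d) == pytest.approx(
            pearson_r(x, y), abs=1e-9
        )

    def test_zero_variance_is_missing_not_zero(self):
        assert np.isnan(pearson_r([1, 1, 1], [0, 1, 2]))
        assert np.isnan(pearson_r([0, 1, 2], [5, 5, 5]))

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])


def _activity_from(values, fractions, readout="capture"):
    df = pd.DataFrame({"fraction": list(fractions), "replicate": 1,
                       "value": list(values)})
    return assay.ActivityProfile(df, readout)


class TestCorrelateProfiles:
    def test_profile_equal_to_activity_gives_one(self):
        fr = [5, 6, 7, 8, 9, 10]
        act_vals = [50.0, 55.0, 70.0, 68.0, 56.0, 51.0]
        pm = ProfileMatrix(pd.DataFrame([act_vals], index=["p"], columns=fr))
        r = correlate_profiles(pm, _activity_from(act_vals, fr))
        assert r["p"] == pytest.approx(1.0, abs=1e-12)

    def test_flat_profile_undefined(self):
        fr = [5, 6, 7, 8, 9, 10]
        pm = ProfileMatrix(
            pd.DataFrame([[1.0] * 6, [0, 1, 5, 4, 1, 0]],
                         index=["flat", "peaked"], columns=fr)
        )
        r = correlate_profiles(pm, _activity_from([50, 55, 70, 68, 56, 51], fr))
        assert np.isnan(r["flat"])
        assert np.isfinite(r["peaked"])

    def test_duplicate_activity_measurements_averaged_first(self):
        fr = [5, 6, 7, 8, 9, 10]
        dup = pd.DataFrame({
            "fraction": fr * 2,
            "replicate": [1] * 6 + [2] * 6,
            "value": [50, 55, 70, 68, 56, 51, 52, 57, 72, 66, 54, 53],
        })
        act = assay.ActivityProfile(dup, "capture")
        pm = ProfileMatrix(pd.DataFrame([[0, 1, 5, 4, 1, 0]],
                                        index=["p"], columns=fr))
        r_dup = correlate_profiles(pm, act)
        mean_vals = dup.groupby("fraction")["value"].mean()
        r_mean = correlate_profiles(pm, _activity_from(mean_vals.values, fr))
        assert r_dup["p"] == pytest.approx(r_mean["p"], abs=1e-12)

    def test_early_decoy_fails_threshold(self, grad, cal):
        """A decoy peaking in fraction 5 against an activity peak at 7-8
        correlates well below 0.9; checked against the direct formula."""
        active = Species("act", mass=103.0, s_value=6.5, is_active=True)
        decoy = Species("decoy", mass=40.0)  # peaks around fraction 5
        pool = [active, decoy]
        truth = gradient.species_profiles(pool, grad, cal).restrict(grad.ms)
        amounts = gradient.active_amounts(pool, grad, cal)
        params = assay.ReconstitutionParams(
            occupancy_scale=assay.scale_for_peak_capture(amounts)
        )
        act = assay.activity_profile(amounts, params)
        r = correlate_profiles(truth, act)
        assert r["decoy"] < 0.9
        oracle = brute_force_pearson(
            list(truth.data.loc["decoy"]),
            list(act.mean_by_fraction()[truth.fractions]),
        )
        assert r["decoy"] == pytest.approx(oracle, abs=1e-12)

    def test_scale_invariance_per_protein(self):
        fr = [5, 6, 7, 8, 9, 10]
        base = np.array([0.1, 1.0, 5.0, 4.0, 1.0, 0.2])
        pm = ProfileMatrix(pd.DataFrame([base, base * 1e3],
                                        index=["a", "b"], columns=fr))
        r = correlate_profiles(pm, _activity_from([50, 55, 70, 68, 56, 51], fr))
        assert r["a"] == pytest.approx(r["b"], abs=1e-12)

    def test_insufficient_overlap(self):
        pm = ProfileMatrix(pd.DataFrame([[1.0, 2.0]], index=["p"], columns=[5, 6]))
        with pytest.raises(InsufficientOverlap):
            correlate_profiles(pm, _activity_from([50, 60], [5, 6]))

    def test_missing_value_propagates_to_undefined(self):
        fr = [5, 6, 7, 8, 9, 10]
        pm = ProfileMatrix(pd.DataFrame([[0, 1, np.nan, 4, 1, 0]],
                                        index=["p"], columns=fr))
        r = correlate_profiles(pm, _activity_from([50, 55, 70, 68, 56, 51], fr))
        assert np.isnan(r["p"])


class TestAggregateReplicates:
    def test_mean_and_sample_sd(self):
        reps = [pd.Series({"p": 0.61}, name="rep1"),
                pd.Series({"p": 0.71}, name="rep2")]
        agg = aggregate_replicates(reps)
        assert agg.loc["p", "r_mean"] == pytest.approx(0.66)
        assert agg.loc["p", "r_sd"] == pytest.approx(0.0707, abs=1e-4)
        assert agg.loc["p", "n_defined"] == 2

    def test_identical_replicates(self):
        reps = [pd.Series({"p": 0.9}, name="rep1"),
                pd.Series({"p": 0.9}, name="rep2")]
        agg = aggregate_replicates(reps)
        assert agg.loc["p", "r_mean"] == pytest.approx(0.9)
        assert agg.loc["p", "r_sd"] == pytest.approx(0.0)

    def test_single_replicate_sd_zero_by_convention(self):
        agg = aggregate_replicates([pd.Series({"p": 0.5}, name="rep1")])
        assert agg.loc["p", "r_mean"] == pytest.approx(0.5)
        assert agg.loc["p", "r_sd"] == 0.0

    def test_partially_and_fully_undefined(self):
        reps = [pd.Series({"p": np.nan, "q": np.nan}, name="rep1"),
                pd.Series({"p": 0.8, "q": np.nan}, name="rep2")]
        agg = aggregate_replicates(reps)
        assert agg.loc["p", "r_mean"] == pytest.approx(0.8)
        assert agg.loc["p", "r_sd"] == 0.0
        assert agg.loc["p", "n_defined"] == 1
        assert np.isnan(agg.loc["q", "r_mean"]) and agg.loc["q", "n_defined"] == 0


class TestPeakStatistics:
    def test_peak_fraction_and_tie_break(self):
        assert peak_fraction(pd.Series([1, 5, 2], index=[5, 6, 7])) == 6
        assert peak_fraction(pd.Series([3, 3, 3], index=[5, 6, 7])) == 5

    def test_mean_mass_by_peak_small_cases(self, grad, cal):
        fr = [5, 6, 7]
        pm = ProfileMatrix(pd.DataFrame(
            [[5, 1, 0], [4, 1, 0], [0, 1, 5]],
            index=["a", "b", "c"], columns=fr))
        masses = pd.Series({"a": 40.0, "b": 80.0, "c": 100.0})
        out = mean_mass_by_peak(pm, masses)
        assert out[5] == pytest.approx(60.0)   # (40+80)/2
        assert np.isnan(out[6])                # nobody peaks here
        assert out[7] == pytest.approx(100.0)

    def test_missing_mass_excluded_with_warning(self):
        pm = ProfileMatrix(pd.DataFrame([[1, 2, 3], [3, 2, 1]],
                                        index=["a", "b"], columns=[5, 6, 7]))
        with pytest.warns(UserWarning, match="without mass"):
            out = mean_mass_by_peak(pm, pd.Series({"a": 40.0}))
        assert out[7] == pytest.approx(40.0)

    def test_mean_mass_rises_along_the_gradient(self, grad, cal):
        """In a paper-scale mixture, the average mass of proteins peaking in
        each fraction is nondecreasing from early to late fractions —
        monomers early, higher-order complexes late."""
        pool = gradient.generate_mixture(MixtureConfig(n_decoys=2999, seed=11))
        truth = gradient.species_profiles(pool, grad, cal).restrict(grad.ms)
        masses = pd.Series({sp.ms_id: sp.mass for sp in pool})
        curve = mean_mass_by_peak(truth, masses).dropna()
        assert (curve.diff().dropna() >= 0).all()

    def test_active_species_attains_max_r_noise_free(self, grad, cal):
        """Without noise or pools, the activity carrier out-correlates every
        decoy (its R is 1 up to the end-point transform's compression)."""
        pool = gradient.generate_mixture(MixtureConfig(n_decoys=500, seed=5))
        truth = gradient.species_profiles(pool, grad, cal).restrict(grad.ms)
        amounts = gradient.active_amounts(pool, grad, cal)
        params = assay.ReconstitutionParams(
            occupancy_scale=assay.scale_for_peak_capture(amounts)
        )
        act = assay.activity_profile(amounts, params)
        r = correlate_profiles(truth, act)
        assert r.idxmax() == "scramblase"
        assert r["scramblase"] > 0.99
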