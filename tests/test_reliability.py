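"""Correlation levels, Fisher-z averaging, and the sensitivity table."""

import numpy as np
import pytest

from stimrel.containers import ChannelGeometry, EnvelopeSet
from stimrel.reliability import (
    ComparisonSpec,
    UndefinedCorrelationError,
    between_method_set,
    between_subject_set,
    correlate_pair,
    fisher_z,
    grand_average,
    temporal_resolution_sensitivity,
    within_subject_set,
)


def make_envset(arrays, modality="ephys", band="theta", fs=20.0):
    """arrays: {(subject, viewing): (channels, T)}"""
    n = next(iter(arrays.values())).shape[0]
    geometry = ChannelGeometry(
        coords=np.column_stack([np.arange(n) * 8.0, np.zeros(n), np.zeros(n)]),
        labels=[f"c{i}" for i in range(n)],
        region_tags=["x"] * n,
        kind="montage" if modality == "montage" else "grid",
        spacing_mm=None if modality == "montage" else 8.0,
    )
    return EnvelopeSet(
        envelopes={(band, s, v): a for (s, v), a in arrays.items()},
        geometry=geometry,
        fs=fs,
        modality=modality,
    )


class TestCorrelatePair:
    def test_identity_and_antiidentity(self, rng):
        x = rng.standard_normal(50)
        for method in ("pearson", "spearman"):
            assert correlate_pair(x, x, method) == pytest.approx(1.0)
            assert correlate_pair(x, -x, method) == pytest.approx(-1.0)

    def test_monotone_nonlinear_series(self, rng):
        x = rng.permutation(np.linspace(-2, 2, 10))
        y = x**3
        assert correlate_pair(x, y, "spearman") == pytest.approx(1.0)
        assert correlate_pair(x, y, "pearson") < 1.0

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        base = correlate_pair(x, y, "spearman")
        assert correlate_pair(np.exp(x), y, "spearman") == pytest.approx(base)
        assert correlate_pair(x, y**3, "spearman") == pytest.approx(base)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate_pair(np.ones(10), np.arange(10.0))


class TestFisherZ:
    def test_clamps_unit_correlation(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z > 13  # atanh(1 - 1e-12)


class TestWithinSubject:
    def test_one_entry_per_subject(self, ephys_envelopes):
        cs = within_subject_set(ComparisonSpec("within_subject", ephys_envelopes, "theta"))
        assert cs.n_entries == 6
        assert cs.z.shape[1] == ephys_envelopes.geometry.n_channels

    def test_identical_viewings_clamped(self, rng):
        a = rng.standard_normal((3, 100))
        env = make_envset({(1, 1): a, (1, 2): a.copy()})
        with pytest.warns(RuntimeWarning, match="clamped"):
            cs = within_subject_set(ComparisonSpec("within_subject", env, "theta"))
        assert np.all(np.isfinite(cs.z))

    def test_missing_viewing_skipped_with_warning(self, rng):
        env = make_envset({(1, 1): rng.standard_normal((2, 60)),
                           (1, 2): rng.standard_normal((2, 60)),
                           (2, 1): rng.standard_normal((2, 60))})
        with pytest.warns(RuntimeWarning, match="skipped"):
            cs = within_subject_set(ComparisonSpec("within_subject", env, "theta"))
        assert cs.entry_ids == [1]


class TestBetweenSubject:
    def test_pair_count_per_entry(self, rng):
        arrays = {(s, v): rng.standard_normal((2, 80)) for s in range(10) for v in (1, 2)}
        cs = between_subject_set(ComparisonSpec("between_subject", make_envset(arrays), "theta"))
        assert cs.meta["n_pairs_per_entry"] == 18
        assert cs.n_entries == 10

    def test_needs_two_subjects(self, rng):
        env = make_envset({(1, 1): rng.standard_normal((2, 60)),
                           (1, 2): rng.standard_normal((2, 60))})
        with pytest.raises(ValueError, match=">= 2"):
            between_subject_set(ComparisonSpec("between_subject", env, "theta"))

    def test_within_viewing_equals_cross_viewing_on_viewing_identical_data(self, rng):
        arrays = {}
        for s in range(4):
            a = rng.standard_normal((3, 90))
            arrays[(s, 1)] = a
            arrays[(s, 2)] = a.copy()
        env = make_envset(arrays)
        cs_x = between_subject_set(ComparisonSpec("between_subject", env, "theta", pairing="cross_viewing"))
        cs_w = between_subject_set(ComparisonSpec("between_subject", env, "theta", pairing="within_viewing"))
        assert np.allclose(cs_x.z, cs_w.z)

    def test_ga_invariant_under_channel_permutation(self, ephys_envelopes, rng):
        cs = between_subject_set(ComparisonSpec("between_subject", ephys_envelopes, "theta"))
        ga = grand_average(cs)
        perm = rng.permutation(ephys_envelopes.geometry.n_channels)
        permuted = make_envset(
            {(s, v): arr[perm] for (b, s, v), arr in ephys_envelopes.envelopes.items() if b == "theta"}
        )
        ga_p = grand_average(between_subject_set(ComparisonSpec("between_subject", permuted, "theta")))
        assert np.allclose(ga_p.z, ga.z[perm])


class TestBetweenMethod:
    def test_entry_count(self, rng):
        a = {(s, v): rng.standard_normal((2, 70)) for s in range(10) for v in (1, 2)}
        b = {(s, v): rng.standard_normal((2, 70)) for s in range(11) for v in (1, 2)}
        spec = ComparisonSpec("between_method", make_envset(a), "theta", cohort_b=make_envset(b))
        cs = between_method_set(spec)
        assert cs.n_entries == 2 * 10 * 11

    def test_sign_flip_antisymmetry(self, rng):
        a = {(1, 1): rng.standard_normal((3, 100)), (1, 2): rng.standard_normal((3, 100))}
        b = {(1, 1): rng.standard_normal((3, 100)), (1, 2): rng.standard_normal((3, 100))}
        flipped = {k: -v for k, v in b.items()}
        ga1 = grand_average(between_method_set(
            ComparisonSpec("between_method", make_envset(a), "theta", cohort_b=make_envset(b))))
        ga2 = grand_average(between_method_set(
            ComparisonSpec("between_method", make_envset(a), "theta", cohort_b=make_envset(flipped))))
        assert np.allclose(ga1.z, -ga2.z)

    def test_montage_cohort_forces_spearman_single_counterpart(self, rng):
        a = {(s, v): rng.standard_normal((2, 80)) for s in range(3) for v in (1, 2)}
        b = {("pooled", 1): rng.standard_normal((2, 80)), ("pooled", 2): rng.standard_normal((2, 80))}
        spec = ComparisonSpec(
            "between_method", make_envset(a), "theta", cohort_b=make_envset(b, modality="montage")
        )
        assert spec.method == "spearman"
        cs = between_method_set(spec)
        assert cs.n_entries == 2 * 3 * 1

    def test_two_stage_average_reduces_to_cohort_a_subjects(self, rng):
        a = {(s, v): rng.standard_normal((2, 80)) for s in range(3) for v in (1, 2)}
        b = {(s, v): rng.standard_normal((2, 80)) for s in range(4) for v in (1, 2)}
        spec = ComparisonSpec("between_method", make_envset(a), "theta",
                              cohort_b=make_envset(b), two_stage_average=True)
        cs = between_method_set(spec)
        assert cs.n_entries == 3


class TestGrandAverage:
    def test_mean_of_fisher_entries(self):
        from stimrel.reliability import CorrelationSet

        cs = CorrelationSet(
            z=np.array([[0.1], [0.3]]), entry_ids=[1, 2],
            channel_mask=np.array([True]), method="pearson", level="within_subject", band="theta",
        )
        assert grand_average(cs).z[0] == pytest.approx(0.2)

    def test_single_entry_identity(self):
        from stimrel.reliability import CorrelationSet

        cs = CorrelationSet(
            z=np.array([[0.42, -0.1]]), entry_ids=[1],
            channel_mask=np.array([True, True]), method="pearson", level="within_subject", band="theta",
        )
        assert np.allclose(grand_average(cs).z, [0.42, -0.1])

    def test_fisher_average_differs_from_raw_average(self):
        rs = np.array([0.1, 0.5, 0.9])
        ga_r = np.tanh(np.mean(np.arctanh(rs)))
        assert ga_r != pytest.approx(rs.mean())
        assert ga_r > rs.mean()  # z-averaging upweights strong correlations


class TestTemporalResolutionSensitivity:
    def test_native_rate_reproduces_within_subject(self, ephys_envelopes):
        cs = within_subject_set(ComparisonSpec("within_subject", ephys_envelopes, "theta"))
        table = temporal_resolution_sensitivity(ephys_envelopes, "theta", [20.0])
        expect = np.tanh(cs.z[:, cs.channel_mask]).mean()
        assert table.loc[0, "mean_r"] == pytest.approx(expect, abs=1e-12)

    def test_low_rate_sample_count(self, ephys_envelopes):
        table = temporal_resolution_sensitivity(ephys_envelopes, "theta", [0.67])
        assert table.loc[0, "n_samples"] == round(297 * 0.67)

    def test_rate_above_native_rejected(self, ephys_envelopes):
        with pytest.raises(ValueError, match="exceeds"):
            temporal_resolution_sensitivity(ephys_envelopes, "theta", [40.0])

    def test_downsampling_helps_slow_signal(self, rng):
        # slow shared signal + white noise: fewer samples average away the
        # wideband noise, raising r
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, 0.1, btype="lowpass", fs=20.0, output="sos")
        T = 5940
        arrays = {}
        for s in range(4):
            g = sosfiltfilt(sos, rng.standard_normal((3, T)), axis=1)
            g /= g.std(axis=1, keepdims=True)
            for v in (1, 2):
                arrays[(s, v)] = 0.6 * g + 0.8 * rng.standard_normal((3, T))
        env = make_envset(arrays)
        table = temporal_resolution_sensitivity(env, "theta", [20.0, 0.67])
        r20 = table.set_index("rate_hz").loc[20.0, "mean_r"]
        r067 = table.set_index("rate_hz").loc[0.67, "mean_r"]
        assert r067 > r20

    def test_grand_average_series_boosts_r_further(self, rng):
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, 0.1, btype="lowpass", fs=20.0, output="sos")
        T = 3000
        g = sosfiltfilt(sos, rng.standard_normal((3, T)), axis=1)
        g /= g.std(axis=1, keepdims=True)
        arrays = {(s, v): 0.5 * g + 0.87 * rng.standard_normal((3, T)) for s in range(6) for v in (1, 2)}
        env = make_envset(arrays)
        plain = temporal_resolution_sensitivity(env, "theta", [20.0])
        pooled = temporal_resolution_sensitivity(env, "theta", [20.0], grand_average_series=True)
        assert pooled.loc[0, "mean_r"] > plain.loc[0, "mean_r"]
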