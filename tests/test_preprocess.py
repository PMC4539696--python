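import numpy as np
import pytest

from simgc.chromatogram import ChannelTrace, SIMRun
from simgc.preprocess import (
    PreprocessConfig,
    baseline_correct,
    build_peak_groups,
    find_apexes,
    gaussian_quality_score,
    peak_candidate,
    preprocess_run,
    smooth,
)
from simgc.selection import TargetDefinition
from simgc.spectra import FragmentSpectrum

from conftest import gaussian_trace

CFG = PreprocessConfig()


class TestBaseline:
    def test_constant_offset_removed(self):
        t = np.arange(0, 300, 0.5)
        tr = ChannelTrace(mass=1, times=t, intensities=np.full(t.size, 37.0))
        out = baseline_correct(tr, CFG)
        assert np.allclose(out.intensities, 0.0, atol=1e-9)

    def test_gaussian_apex_preserved_on_offset(self):
        tr = gaussian_trace(height=1000.0, sigma=2.0, offset=50.0)
        out = baseline_correct(tr, CFG)
        apex = out.intensities.max()
        assert apex == pytest.approx(1000.0, rel=0.02)

    def test_apex_preserved_under_drifting_baseline(self):
        tr = gaussian_trace(height=1000.0, sigma=2.0, offset=50.0, drift=0.1)
        out = baseline_correct(tr, CFG)
        assert out.intensities.max() == pytest.approx(1000.0, rel=0.02)

    def test_all_zero_trace_unchanged(self):
        t = np.arange(0, 100, 0.5)
        tr = ChannelTrace(mass=1, times=t, intensities=np.zeros(t.size))
        out = baseline_correct(tr, CFG)
        assert np.allclose(out.intensities, 0.0)


class TestSmooth:
    def test_quadratic_signal_reproduced_exactly(self):
        t = np.arange(0.0, 50.0, 0.5)
        y = 3.0 + 2.0 * t - 0.02 * t**2
        tr = ChannelTrace(mass=1, times=t, intensities=np.clip(y, 0, None))
        out = smooth(tr, PreprocessConfig(smooth_window=7, smooth_order=2))
        np.testing.assert_allclose(out.intensities, tr.intensities, atol=1e-9)

    def test_noise_variance_reduced(self, rng):
        t = np.arange(0.0, 500.0, 0.5)
        y = rng.normal(0.0, 1.0, t.size) + 10.0
        tr = ChannelTrace(mass=1, times=t, intensities=np.clip(y, 0, None))
        out = smooth(tr, CFG)
        assert np.var(out.intensities) < np.var(tr.intensities)

    def test_window_longer_than_trace_raises(self):
        tr = ChannelTrace(mass=1, times=np.array([0.0, 1.0, 2.0]),
                          intensities=np.ones(3))
        with pytest.raises(ValueError, match="window"):
            smooth(tr, PreprocessConfig(smooth_window=5, smooth_order=2))


class TestApexes:
    def test_single_gaussian_one_apex_at_mu(self):
        tr = gaussian_trace(mu=150.0, dt=0.5)
        apexes = find_apexes(tr, CFG)
        assert len(apexes) == 1
        assert tr.times[apexes[0]] == pytest.approx(150.0, abs=0.25)

    def test_two_gaussians_six_sigma_apart_two_apexes(self):
        t = np.arange(0, 300, 0.5)
        y = (1000 * np.exp(-0.5 * ((t - 150) / 2.0) ** 2)
             + 700 * np.exp(-0.5 * ((t - 162) / 2.0) ** 2))
        tr = ChannelTrace(mass=1, times=t, intensities=y)
        assert len(find_apexes(tr, CFG)) == 2

    def test_flat_trace_has_no_apexes(self):
        t = np.arange(0, 100, 0.5)
        tr = ChannelTrace(mass=1, times=t, intensities=np.full(t.size, 5.0))
        assert find_apexes(tr, CFG) == []

    def test_plateau_reports_center(self):
        y = np.array([0, 0, 1, 5, 5, 5, 1, 0, 0], dtype=float)
        tr = ChannelTrace(mass=1, times=np.arange(9.0), intensities=y)
        assert find_apexes(tr, CFG) == [4]


class TestQualityScore:
    def test_exact_gaussian_scores_near_one(self):
        tr = gaussian_trace(height=1000.0, mu=150.0, sigma=2.0)
        apex = int(np.argmax(tr.intensities))
        qs, fit = gaussian_quality_score(tr, apex)
        assert qs >= 0.999
        assert fit.mu == pytest.approx(150.0, rel=0.01)
        assert fit.sigma == pytest.approx(2.0, rel=0.01)

    def test_monotone_ramp_scores_poorly(self):
        t = np.arange(0.0, 20.5, 0.5)
        tr = ChannelTrace(mass=1, times=t, intensities=np.linspace(0, 100, t.size))
        qs, _ = gaussian_quality_score(tr, t.size // 2)
        assert qs < 0.8

    def test_degenerate_input_scores_zero(self):
        tr = ChannelTrace(mass=1, times=np.arange(5.0), intensities=np.zeros(5))
        qs, fit = gaussian_quality_score(tr, 2)
        assert qs == 0.0 and fit is None

    def test_qs_bounded_for_random_traces(self, rng):
        for _ in range(25):
            y = np.clip(rng.normal(10, 5, size=60), 0, None)
            tr = ChannelTrace(mass=1, times=np.arange(60.0) * 0.5, intensities=y)
            qs, _ = gaussian_quality_score(tr, int(rng.integers(3, 57)))
            assert 0.0 <= qs <= 1.0


class TestMetrology:
    def test_noiseless_auc_within_one_percent_of_analytic(self):
        h, sigma = 1000.0, 2.0
        run = SIMRun("r", [gaussian_trace(mass=100, height=h, sigma=sigma)])
        tr = preprocess_run(run, CFG).traces[0]
        cand = peak_candidate(tr, find_apexes(tr, CFG)[0])
        assert cand.auc == pytest.approx(h * sigma * np.sqrt(2 * np.pi), rel=0.01)
        assert cand.apex_intensity == pytest.approx(h, rel=0.005)

    def test_apex_recovery_under_noise(self):
        """At SNR 20 the apex scan is recovered within +/-1 scan in at
        least 95% of seeded replicates."""
        h, mu, dt = 1000.0, 150.0, 0.5
        hits = 0
        for seed in range(50):
            tr = gaussian_trace(height=h, mu=mu, offset=50.0, drift=0.02,
                                noise=h / 20.0, seed=seed)
            run = preprocess_run(SIMRun("r", [tr]), CFG)
            prepped = run.traces[0]
            apexes = [i for i in find_apexes(prepped, CFG)
                      if abs(prepped.times[i] - mu) <= 4.0]
            true_idx = int(np.argmin(np.abs(prepped.times - mu)))
            if apexes and min(abs(i - true_idx) for i in apexes) <= 1:
                hits += 1
        assert hits >= 48  # >= 95% of 50


def _target(name, masses, rel, rt):
    spec = FragmentSpectrum.from_pairs(zip(masses, rel))
    return TargetDefinition(
        name=name, quantifier=masses[0], qualifiers=tuple(masses[1:]),
        reference_spectrum=spec, rt=rt,
    )


class TestGrouping:
    def _run(self, masses, rel, mu=150.0, ramp_mass=None):
        t = np.arange(0.0, 300.0, 0.5)
        traces = []
        for m, a in zip(masses, rel):
            if m == ramp_mass:
                # sawtooth: slow linear rise, instant fall — a local max
                # with a decidedly non-Gaussian shape
                y = np.where(t <= mu, np.clip((t - 120.0) * 10.0, 0.0, None), 0.0)
            else:
                y = a * np.exp(-0.5 * ((t - mu) / 2.0) ** 2)
            traces.append(ChannelTrace(mass=m, times=t, intensities=y))
        return preprocess_run(SIMRun("r", traces), CFG)

    def test_coeluting_fragments_form_one_complete_group(self):
        masses, rel = (100, 120, 140), (1000.0, 500.0, 250.0)
        run = self._run(masses, rel)
        target = _target("t", masses, rel, rt=150.0)
        groups = build_peak_groups(run, target, 150.0, CFG)
        assert len(groups) == 1
        assert set(groups[0].members) == set(masses)
        assert groups[0].excluded_masses == ()
        assert set(groups[0].apex_spectrum.masses) == set(masses)

    def test_no_quantifier_apex_in_window_gives_no_groups(self):
        masses, rel = (100, 120), (1000.0, 500.0)
        run = self._run(masses, rel, mu=150.0)
        target = _target("t", masses, rel, rt=220.0)  # peak is 70 s away
        assert build_peak_groups(run, target, 220.0, CFG) == []

    def test_sawtooth_qualifier_is_excluded_not_dropped(self):
        masses, rel = (100, 120, 140), (1000.0, 500.0, 250.0)
        run = self._run(masses, rel, ramp_mass=140)
        target = _target("t", masses, rel, rt=150.0)
        groups = build_peak_groups(run, target, 150.0, CFG)
        assert groups, "anchor group expected"
        g = groups[0]
        assert 140 in g.excluded_masses
        assert 140 not in g.apex_spectrum.masses
        assert 100 in g.apex_spectrum.masses

    def test_missing_quantifier_channel_raises_named_error(self):
        masses, rel = (100, 120), (1000.0, 500.0)
        run = self._run(masses, rel)
        target = _target("t", (999, 120), (1000.0, 500.0), rt=150.0)
        with pytest.raises(KeyError, match="999"):
            build_peak_groups(run, target, 150.0, CFG)

    def test_groups_sorted_by_distance_to_expected_time(self):
        t = np.arange(0.0, 300.0, 0.5)
        y = (1000 * np.exp(-0.5 * ((t - 148) / 2.0) ** 2)
             + 900 * np.exp(-0.5 * ((t - 152.5) / 2.0) ** 2))
        run = preprocess_run(
            SIMRun("r", [ChannelTrace(mass=100, times=t, intensities=y)]), CFG
        )
        target = _target("t", (100,), (1000.0,), rt=152.0)
        groups = build_peak_groups(run, target, 152.0, CFG)
        assert len(groups) == 2
        assert abs(groups[0].consensus_time - 152.0) <= abs(
            groups[1].consensus_time - 152.0
        )
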