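import math

import numpy as np
import pytest

from simgc.selection import (
    SelectionConfig,
    assign_rt_windows,
    fragment_penalty,
    overlapping_analytes,
    rank_fragments,
    select_fragments,
)
from simgc.spectra import (
    FragmentSpectrum,
    LibraryEntry,
    SpectralLibrary,
    TargetRequest,
)

from conftest import random_library


def entry(name, pairs, ri=None, rt=None):
    return LibraryEntry(
        name=name, spectrum=FragmentSpectrum.from_pairs(pairs), ri=ri, rt=rt
    )


def brute_force_penalty(target, mass, intensity, library, cfg):
    """Independent oracle: double loop over all fragments of all entries
    within RI tolerance, accumulating the exponential RI-distance terms."""
    total = 0.0
    for other in library:
        if other.name == target.name:
            continue
        if abs(other.ri - target.ri) > cfg.ri_tolerance:
            continue
        for m2 in other.spectrum.masses:
            if m2 == mass:
                total += math.exp(-abs(target.ri - other.ri) / cfg.delta_r)
    return total / intensity


class TestOverlap:
    def test_ri_within_tolerance_included_and_self_excluded(self):
        a = entry("a", [(100, 1000)], ri=700.0)
        b = entry("b", [(200, 1000)], ri=703.0)
        lib = SpectralLibrary([a, b])
        cfg = SelectionConfig(ri_tolerance=5.0)
        assert [e.name for e in overlapping_analytes(a, lib, cfg)] == ["b"]
        assert overlapping_analytes(a, lib, SelectionConfig(ri_tolerance=2.0)) == []
        only = SpectralLibrary([a])
        assert overlapping_analytes(a, only, cfg) == []

    def test_rt_fallback_when_ri_missing(self):
        a = entry("a", [(100, 1000)], rt=600.0)
        b = entry("b", [(200, 1000)], rt=605.0)
        lib = SpectralLibrary([a, b])
        assert len(overlapping_analytes(a, lib, SelectionConfig(rt_tolerance=10.0))) == 1

    def test_entry_without_retention_raises(self):
        s = FragmentSpectrum((100,), (1000.0,))
        a = LibraryEntry("a", s)
        with pytest.raises(ValueError, match="neither RT nor RI"):
            overlapping_analytes(a, SpectralLibrary([a]), SelectionConfig())


class TestPenalty:
    def test_analytic_values(self):
        # no sharers -> empty sum
        assert fragment_penalty(500.0, 700.0, [], 10.0) == 0.0
        # one sharer at identical RI, intensity 2 -> exp(0)/2
        assert fragment_penalty(2.0, 700.0, [700.0], 10.0) == pytest.approx(0.5)
        # |delta r| = delta_R, intensity 1 -> 1/e
        assert fragment_penalty(1.0, 700.0, [710.0], 10.0) == pytest.approx(
            math.exp(-1.0), abs=1e-12
        )

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            fragment_penalty(0.0, 700.0, [700.0], 10.0)

    def test_monotone_in_intensity_and_ri_distance(self):
        p1 = fragment_penalty(100.0, 700.0, [705.0], 10.0)
        p2 = fragment_penalty(200.0, 700.0, [705.0], 10.0)
        p3 = fragment_penalty(100.0, 700.0, [715.0], 10.0)
        assert p2 < p1 and p3 < p1

    def test_scale_invariance_of_delta_r(self):
        p = fragment_penalty(50.0, 700.0, [712.0, 695.0], 10.0)
        p_scaled = fragment_penalty(50.0, 7000.0, [7120.0, 6950.0], 100.0)
        assert p_scaled == pytest.approx(p, rel=1e-12)

    def test_matches_brute_force_on_random_libraries(self, rng):
        cfg = SelectionConfig(ri_tolerance=50.0, delta_r=10.0)
        for _ in range(30):
            lib = random_library(rng, n=20)
            target = lib.entries[int(rng.integers(0, len(lib)))]
            scores = rank_fragments(target, lib, cfg)
            for s in scores:
                expected = brute_force_penalty(
                    target, s.mass, s.intensity, lib, cfg
                )
                assert s.penalty == pytest.approx(expected, abs=1e-12)


class TestRanking:
    def test_low_relative_intensity_filtered(self):
        # 30 is 3% of the top-3 mean (1000+950+900)/3 = 950
        t = entry("t", [(100, 1000), (110, 950), (120, 900), (130, 30)], ri=700.0)
        lib = SpectralLibrary([t])
        scores = rank_fragments(t, lib, SelectionConfig(min_rel_intensity=0.05))
        assert [s.mass for s in scores] == [100, 110, 120]

    def test_penalty_tie_broken_by_intensity_then_mass(self):
        t = entry("t", [(200, 500), (100, 1000), (150, 500)], ri=700.0)
        lib = SpectralLibrary([t])
        scores = rank_fragments(t, lib, SelectionConfig())
        assert [s.mass for s in scores] == [100, 150, 200]
        assert all(s.penalty == 0.0 for s in scores)

    def test_zero_intensity_fragments_never_ranked(self):
        t = entry("t", [(100, 0.0), (110, 1000.0)], ri=700.0)
        lib = SpectralLibrary([t])
        scores = rank_fragments(t, lib, SelectionConfig(min_rel_intensity=0.99))
        assert [s.mass for s in scores] == [110]

    def test_shared_mass_with_near_ri_neighbor_is_penalized(self):
        t = entry("t", [(100, 1000), (110, 900)], ri=700.0)
        other = entry("o", [(100, 800)], ri=702.0)
        lib = SpectralLibrary([t, other])
        scores = rank_fragments(t, lib, SelectionConfig())
        by_mass = {s.mass: s.penalty for s in scores}
        assert by_mass[110] == 0.0 and by_mass[100] > 0.0
        assert [s.mass for s in scores] == [110, 100]


class TestModes:
    def _background(self):
        return SpectralLibrary(
            [
                entry("glutamic acid d5",
                      [(161, 1000), (235, 400), (263, 300), (280, 250), (281, 25)],
                      ri=1289.0),
                entry("background x", [(161, 900), (73, 1000)], ri=1291.0),
            ]
        )

    def test_library_mode_pinned_masses_pass_through(self):
        req = TargetRequest(
            name="glutamic acid d5", masses=(161, 235, 263), quantifier=161
        )
        [d] = select_fragments([req], background=self._background(), mode="library")
        assert d.quantifier == 161
        assert set(d.masses) == {161, 235, 263}
        assert d.reference_spectrum.masses == (161, 235, 263)

    def test_library_mode_name_only_gets_n_default_ranked(self):
        req = TargetRequest(name="glutamic acid d5")
        cfg = SelectionConfig(n_default=4)
        [d] = select_fragments(
            [req], background=self._background(), mode="library", config=cfg
        )
        assert len(d.masses) == 4
        # 161 is shared with a near-RI background compound: not quantifier
        assert d.quantifier != 161
        assert 281 not in d.masses  # below the relative-intensity floor

    def test_force_optimize_overrides_pinned_masses(self):
        req = TargetRequest(name="glutamic acid d5", masses=(161, 235))
        cfg = SelectionConfig(force_optimize=True, n_default=3)
        [d] = select_fragments(
            [req], background=self._background(), mode="library", config=cfg
        )
        assert len(d.masses) == 3 and d.quantifier != 161

    def test_target_mode_optimizes_against_other_targets(self):
        lib = self._background()
        defs = select_fragments(None, targets_msl=lib, mode="target")
        assert {d.name for d in defs} == {"glutamic acid d5", "background x"}
        glu = next(d for d in defs if d.name == "glutamic acid d5")
        assert glu.quantifier != 161  # shared with 'background x' at close RI

    def test_combined_mode_merges_each_compound_once(self):
        targets_msl = SpectralLibrary(
            [entry("glutamic acid d5", [(161, 1000), (235, 400)], ri=1289.0)]
        )
        reqs = [TargetRequest(name="glutamic acid d5")]
        [d] = select_fragments(
            reqs, targets_msl=targets_msl, background=self._background(),
            mode="combined",
        )
        # the merged library must not double-count the target itself,
        # otherwise its own spectrum would penalize every fragment
        assert d.quantifier in (161, 235)

    def test_mode_input_mismatch_raises(self):
        with pytest.raises(ValueError, match="background"):
            select_fragments([], mode="library")
        with pytest.raises(KeyError, match="not found"):
            select_fragments(
                [TargetRequest(name="nope")], background=self._background(),
                mode="library",
            )

    def test_selection_is_deterministic(self):
        reqs = [TargetRequest(name="glutamic acid d5")]
        a = select_fragments(reqs, background=self._background(), mode="library")
        b = select_fragments(reqs, background=self._background(), mode="library")
        assert [(d.name, d.masses) for d in a] == [(d.name, d.masses) for d in b]


class TestWindows:
    def _target(self, name, rt, n_masses=4, base=100):
        masses = tuple(range(base, base + n_masses))
        spec = FragmentSpectrum(masses, tuple([1000.0] * n_masses))
        from simgc.selection import TargetDefinition

        return TargetDefinition(
            name=name, quantifier=masses[0], qualifiers=masses[1:],
            reference_spectrum=spec, rt=rt,
        )

    def test_close_targets_share_a_window(self):
        t1 = self._target("a", 300.0, base=100)
        t2 = self._target("b", 330.0, base=200)
        plan = assign_rt_windows([t1, t2], max_channels_per_window=16, min_gap=60.0)
        assert len(plan) == 1

    def test_channel_budget_splits_windows(self):
        ts = [self._target(f"t{i}", 300.0 + i * 10, base=100 + 10 * i) for i in range(3)]
        plan = assign_rt_windows(ts, max_channels_per_window=8, min_gap=60.0)
        assert all(len(w.masses) <= 8 for w in plan)
        assert sum(len(w.targets) for w in plan) == 3
        assert len(plan) == 2

    def test_windows_sorted_nonoverlapping_for_random_targets(self, rng):
        ts = [
            self._target(f"t{i}", float(rng.uniform(300, 2000)), base=100 + 4 * i)
            for i in range(100)
        ]
        plan = assign_rt_windows(ts, max_channels_per_window=24, min_gap=45.0)
        windows = list(plan)
        assert all(w.start < w.end for w in windows)
        assert all(
            windows[i].end <= windows[i + 1].start + 1e-9
            for i in range(len(windows) - 1)
        )
        assert sum(len(w.targets) for w in windows) == 100

    def test_single_target_over_budget_raises(self):
        t = self._target("big", 300.0, n_masses=10)
        with pytest.raises(ValueError, match="budget"):
            assign_rt_windows([t], max_channels_per_window=4, min_gap=60.0)
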