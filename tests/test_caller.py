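import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skimcnv as sc
from skimcnv.caller import (
    CnvCall,
    FlagTrack,
    call_events,
    call_line,
    estimate_deleted_bp_within_window,
    find_runs,
)
from skimcnv.depth import DepthMatrix, WindowStats
from skimcnv.runs import RunStatParams

from conftest import brute_force_runs


def _stats(grid, mu=1.0, sigma=0.1):
    n = grid.n_windows
    return WindowStats(
        grid=grid,
        mu=np.full(n, mu),
        sigma=np.full(n, sigma),
        mask=np.zeros(n, dtype=bool),
    )


def _norm(grid, rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = ids or [f"l{i}" for i in range(len(rows))]
    return DepthMatrix(grid=grid, values=rows, line_ids=ids, state="normalized")


class TestFlagWindows:
    @pytest.fixture()
    def grid(self):
        return sc.make_genome({"c": 50_000})

    @pytest.mark.parametrize("x,mode,flagged", [
        (1.0, "hom_del", False),
        (1.0, "hemi_del", False),
        (1.0, "dup", False),
        (0.5, "hemi_del", True),  # exactly half depth: distance 0
        (2.0, "dup", True),  # boundary inclusive: "at least twice"
        (1.99, "dup", False),
        (0.65, "hom_del", True),  # 0.65 < 1 - 3*0.1
        (0.71, "hom_del", False),
        (0.75, "hemi_del", False),  # equidistant tie is NOT flagged
        (0.7499, "hemi_del", True),
    ])
    def test_class_rules(self, grid, x, mode, flagged):
        depth = _norm(grid, [[x] * grid.n_windows])
        track = sc.flag_windows(depth, _stats(grid), mode)[0]
        assert bool(track.flags[0]) is flagged

    def test_masked_windows_never_flagged(self, grid):
        stats = _stats(grid)
        stats.mask[2] = True
        depth = _norm(grid, [[0.0] * grid.n_windows])
        track = sc.flag_windows(depth, stats, "hom_del")[0]
        assert not track.flags[2] and track.flags[0]

    def test_unknown_mode_rejected(self, grid):
        with pytest.raises(ValueError, match="mode"):
            sc.flag_windows(_norm(grid, [[1.0] * grid.n_windows]), _stats(grid), "dunno")


class TestFindRuns:
    def _track(self, flags, mask=None, window_size=10_000):
        flags = np.asarray(flags, dtype=bool)
        grid = sc.make_genome({"c": len(flags) * window_size}, window_size=window_size)
        mask = np.zeros(len(flags), dtype=bool) if mask is None else np.asarray(mask, bool)
        flags = flags & ~mask
        return FlagTrack(line_id="l", mode="hom_del", flags=flags, mask=mask, grid=grid)

    def test_single_interruption_bridged(self):
        runs = find_runs(self._track([1, 1, 1, 0, 1, 1, 1]), gap_tolerance=1)
        assert len(runs) == 1
        assert runs[0].n_flagged == 6 and runs[0].n_interruptions == 1

    def test_double_gap_breaks(self):
        runs = find_runs(self._track([1, 1, 0, 0, 1, 1, 0, 0, 1, 1]), gap_tolerance=1)
        assert [r.n_flagged for r in runs] == [2, 2, 2]

    def test_no_flags_empty(self):
        assert find_runs(self._track([0] * 8)) == []

    def test_masked_windows_transparent(self):
        # flags 1 1 [masked] 1: the masked window is neither flag nor gap
        runs = find_runs(self._track([1, 1, 0, 1], mask=[0, 0, 1, 0]), gap_tolerance=0)
        assert len(runs) == 1 and runs[0].n_flagged == 3

    def test_runs_never_cross_chromosomes(self):
        grid = sc.make_genome({"a": 30_000, "b": 30_000})
        flags = np.ones(6, dtype=bool)
        track = FlagTrack(
            line_id="l", mode="hom_del", flags=flags,
            mask=np.zeros(6, dtype=bool), grid=grid,
        )
        runs = find_runs(track, gap_tolerance=1)
        assert [r.n_flagged for r in runs] == [3, 3]

    @given(
        st.lists(st.booleans(), min_size=1, max_size=40),
        st.integers(0, 3),
    )
    @settings(max_examples=300, derandomize=True)
    def test_agrees_with_enumeration_oracle(self, flags, tol):
        runs = find_runs(self._track(flags), gap_tolerance=tol)
        expected = brute_force_runs(flags, tol)
        got = [
            {
                "first": r.first,
                "last": r.last,
                "n_flagged": r.n_flagged,
                "n_interruptions": r.n_interruptions,
            }
            for r in runs
        ]
        assert got == expected


class TestCallEvents:
    def _runs(self, flags, grid, tol=1):
        track = FlagTrack(
            line_id="l", mode="hom_del", flags=np.asarray(flags, bool),
            mask=np.zeros(len(flags), bool), grid=grid,
        )
        return find_runs(track, tol)

    def test_three_window_run_at_study_scale(self):
        grid = sc.make_genome({"c": 60_000})
        runs = self._runs([0, 1, 1, 1, 0, 0], grid)
        calls = call_events(runs, RunStatParams(0.004, 445_000), grid=grid, line_id="l")
        assert len(calls) == 1
        c = calls[0]
        assert c.E == pytest.approx(445_000 * 0.004**3 * 0.996**2)
        assert c.E == pytest.approx(0.02825, abs=2e-4)
        assert c.sig_tags == (0.05,)
        assert (c.start, c.end) == (10_000, 40_000)

    def test_isolated_flag_is_error_not_call(self):
        grid = sc.make_genome({"c": 40_000})
        runs = self._runs([0, 1, 0, 0], grid)
        calls = call_events(runs, RunStatParams(0.01, 100_000), grid=grid)
        assert calls[0].E == pytest.approx(100_000 * 0.01 * 0.99**2)
        assert calls[0].E == pytest.approx(980.1)
        assert calls[0].sig_tags == ()

    def test_zero_p_tags_everything(self):
        grid = sc.make_genome({"c": 40_000})
        runs = self._runs([1, 1, 0, 0], grid)
        calls = call_events(runs, RunStatParams(0.0, 100_000), grid=grid)
        assert calls[0].E == 0.0
        assert calls[0].sig_tags == (0.05, 0.01)

    def test_span_uses_flagged_extremes_not_interruptions(self):
        grid = sc.make_genome({"c": 80_000})
        runs = self._runs([0, 1, 0, 1, 0, 0, 0, 0], grid, tol=1)
        calls = call_events(runs, RunStatParams(0.01, 1000), grid=grid)
        assert (calls[0].start, calls[0].end) == (10_000, 40_000)
        assert calls[0].n_interruptions == 1


class TestCallLine:
    def test_p_re_estimated_excluding_accepted_runs(self):
        """A big real run must not inflate the error-rate estimate."""
        grid = sc.make_genome({"c": 10_000 * 1000})
        flags = np.zeros(1000, dtype=bool)
        flags[100:150] = True  # real event
        flags[[300, 600, 900]] = True  # stray errors
        track = FlagTrack(
            line_id="l", mode="hemi_del", flags=flags,
            mask=np.zeros(1000, bool), grid=grid,
        )
        calls, params = call_line(track)
        assert params.p == pytest.approx(3 / 950)
        big = max(calls, key=lambda c: c.n_windows)
        assert big.sig_tags == (0.05, 0.01)

    def test_hom_run_at_half_depth_reassigned_to_hemi_screen(self):
        """A run below mu-3sigma but sitting at half depth is not a
        homozygous call (one homologue is still present)."""
        grid = sc.make_genome({"c": 10_000 * 20})
        vals = np.ones((1, 20))
        vals[0, 5:10] = 0.5
        depth = _norm(grid, vals)
        stats = _stats(grid, sigma=0.05)  # mu - 3 sigma = 0.85 > 0.5
        track = sc.flag_windows(depth, stats, "hom_del")[0]
        assert track.flags[5:10].all()
        calls, _ = call_line(track, depth, stats)
        assert calls == []
        # at true zero depth the same machinery does call homozygous
        vals[0, 5:10] = 0.0
        depth0 = _norm(grid, vals)
        track0 = sc.flag_windows(depth0, stats, "hom_del")[0]
        calls0, _ = call_line(track0, depth0, stats)
        assert len(calls0) == 1 and calls0[0].mode == "hom_del"


class TestMergeNearby:
    def _call(self, start, end, line="l", mode="hom_del", E=1e-4, chrom="c"):
        return CnvCall(
            line_id=line, chrom=chrom, start=start, end=end, mode=mode,
            n_windows=(end - start) // 10_000, n_interruptions=0, E=E,
            sig_tags=(0.05,),
        )

    def test_within_gap_merges_with_components(self):
        merged = sc.merge_nearby(
            [self._call(0, 100_000), self._call(150_000, 250_000)], max_gap_bp=200_000
        )
        assert len(merged) == 1
        assert merged[0].components == [(0, 100_000), (150_000, 250_000)]
        assert (merged[0].start, merged[0].end) == (0, 250_000)

    def test_beyond_gap_unmerged(self):
        merged = sc.merge_nearby(
            [self._call(0, 100_000), self._call(600_000, 700_000)], max_gap_bp=200_000
        )
        assert len(merged) == 2

    def test_transitive_chain(self):
        calls = [self._call(0, 100_000), self._call(250_000, 350_000), self._call(500_000, 600_000)]
        merged = sc.merge_nearby(calls, max_gap_bp=200_000)
        assert len(merged) == 1 and len(merged[0].components) == 3

    def test_merged_E_is_strongest_component(self):
        merged = sc.merge_nearby(
            [self._call(0, 100_000, E=1e-3), self._call(150_000, 250_000, E=1e-8)],
            max_gap_bp=200_000,
        )
        assert merged[0].E == 1e-8

    def test_different_modes_never_merge(self):
        merged = sc.merge_nearby(
            [self._call(0, 100_000, mode="hom_del"), self._call(150_000, 250_000, mode="hemi_del")],
            max_gap_bp=200_000,
        )
        assert len(merged) == 2


class TestHomWithinHemi:
    def _call(self, start, end, mode, line="l"):
        return CnvCall(
            line_id=line, chrom="c", start=start, end=end, mode=mode,
            n_windows=1, n_interruptions=0, E=0.0,
        )

    def test_contained_is_associated(self):
        table = sc.hom_within_hemi(
            [self._call(100_000, 200_000, "hom_del"), self._call(0, 1_000_000, "hemi_del")]
        )
        assert table.loc[0, "hemi_index"] == 0

    def test_disjoint_not_associated(self):
        table = sc.hom_within_hemi(
            [self._call(0, 100_000, "hom_del"), self._call(500_000, 900_000, "hemi_del")]
        )
        assert table.loc[0, "hemi_index"] is None

    def test_partial_overlap_needs_half_containment(self):
        hemi = self._call(0, 100_000, "hemi_del")
        # 40% of the hom span inside the hemi call -> no association
        assert sc.hom_within_hemi([self._call(60_000, 160_000, "hom_del"), hemi]).loc[0, "hemi_index"] is None
        # 60% inside -> associated
        assert sc.hom_within_hemi([self._call(40_000, 140_000, "hom_del"), hemi]).loc[0, "hemi_index"] == 0


class TestUniqueDeletions:
    def _call(self, start, end, line, mode="hom_del", chrom="c"):
        return CnvCall(
            line_id=line, chrom=chrom, start=start, end=end, mode=mode,
            n_windows=1, n_interruptions=0, E=0.0, sig_tags=(0.05,),
        )

    def test_identical_sibling_calls_collapse(self):
        calls = [self._call(0, 100_000, f"sib{i}") for i in range(3)]
        summary = sc.unique_deletions(calls, genome_bp=1_000_000)
        assert summary.n_unique == 1
        assert summary.unique_deleted_bp == 100_000
        assert summary.genome_fraction == pytest.approx(0.1)

    def test_disjoint_calls_sum(self):
        calls = [self._call(0, 100_000, "a"), self._call(500_000, 600_000, "b")]
        summary = sc.unique_deletions(calls, genome_bp=10_000_000)
        assert summary.n_unique == 2
        assert summary.unique_deleted_bp == 200_000

    def test_counts_sum_to_unique_deletions(self):
        rng = np.random.default_rng(9)
        calls = [
            self._call(int(s), int(s) + int(l), f"l{i}")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 10**7, 30), rng.integers(30_000, 500_000, 30))
            )
        ]
        summary = sc.unique_deletions(calls, genome_bp=10**8)
        assert summary.counts.sum() == summary.n_unique

    def test_order_independent_and_idempotent(self):
        rng = np.random.default_rng(10)
        calls = [
            self._call(int(s), int(s) + 100_000, f"l{i}")
            for i, s in enumerate(rng.integers(0, 10**7, 20))
        ]
        a = sc.unique_deletions(calls, genome_bp=10**8)
        b = sc.unique_deletions(calls[::-1], genome_bp=10**8)
        assert a.n_unique == b.n_unique
        assert a.unique_deleted_bp == b.unique_deleted_bp
        np.testing.assert_array_equal(np.sort(a.unique_sizes), np.sort(b.unique_sizes))


class TestDuplicationSpacing:
    def _dup(self, start, end, line="l", chrom="c"):
        return CnvCall(
            line_id=line, chrom=chrom, start=start, end=end, mode="dup",
            n_windows=1, n_interruptions=0, E=0.0, sig_tags=(0.05,),
        )

    def test_single_dup_no_gaps(self):
        out = sc.duplication_spacing([self._dup(0, 10_000)])
        assert len(out["gaps"]) == 0

    def test_one_megabase_boundary_inclusive(self):
        out = sc.duplication_spacing([self._dup(0, 10_000), self._dup(1_010_000, 1_020_000)])
        assert list(out["gaps"]) == [1_000_000]
        assert out["n_at_or_above_threshold"] == 1
        assert out["n_below_threshold"] == 0

    def test_fragmented_dup_gaps_below_merge_threshold(self):
        """A truth duplication split into k called pieces shows k-1 short
        gaps, and merging at the default distance restores one event."""
        pieces = [self._dup(i * 60_000, i * 60_000 + 20_000) for i in range(5)]
        out = sc.duplication_spacing(pieces)
        assert len(out["gaps"]) == 4
        assert (out["gaps"] < 200_000).all()
        assert out["merged_dup_counts"][200_000] == 1


class TestSubWindowDiagnostic:
    def test_depth_ratio_to_deleted_bp(self):
        # a 1.4-fold depth reduction in one 10 kb window
        est = estimate_deleted_bp_within_window(1 / 1.4, 1.0)
        assert est == pytest.approx(10_000 * (1 - 1 / 1.4))
        assert est == pytest.approx(2857, abs=1)

    def test_no_reduction_no_deletion(self):
        assert estimate_deleted_bp_within_window(1.0, 1.0) == 0.0


class TestPopulationInvariants:
    def test_hom_flags_subset_of_hemi_flags_near_ideal(self, small_population):
        """Wherever sigma is in the band where mu - 3 sigma <= 3 mu / 4,
        a window below the homozygous line is necessarily also closer to
        half depth, so the homozygous flag set nests in the hemizygous one."""
        norm, stats = small_population["norm"], small_population["stats"]
        hom = sc.flag_windows(norm, stats, "hom_del")
        hemi = sc.flag_windows(norm, stats, "hemi_del")
        band = (stats.sigma >= stats.mu / 12) & (stats.sigma < stats.mu / 6) & ~stats.mask
        assert band.sum() > 100  # the simulated noise level lives in this band
        for h, z in zip(hom, hemi):
            assert not (h.flags[band] & ~z.flags[band]).any()

    def test_no_event_population_rarely_calls(self):
        """On an event-free population, significant calls are rare
        (chance expectation per line per mode is capped by alpha)."""
        grid = sc.make_genome({"c1": 50_000_000, "c2": 50_000_000}, mappability_sd=0.1, seed=23)
        cfg = sc.SimConfig(n_lines=12, mean_reads_per_window=67.0, seed=23)
        norm = sc.normalize(sc.simulate_depth(grid, sc.TruthSet([]), cfg))
        stats = sc.window_stats(norm)
        calls, _ = sc.call_population(norm, stats)
        # 12 lines x 3 modes at alpha = 0.05 -> ~1.8 expected chance calls
        assert len(calls) <= 2

    def test_recovered_genome_fraction_matches_truth(self, small_population):
        """The unique-deletion genome fraction agrees with the truth
        ledger within one window per event edge."""
        truth, grid = small_population["truth"], small_population["grid"]
        calls, _ = sc.call_population(small_population["norm"], small_population["stats"])
        summary = sc.unique_deletions(calls, genome_bp=grid.total_bp)
        del_events = [e for e in truth.events if e.kind in ("hom_del", "hemi_del")]
        spans = {}
        for e in del_events:
            spans.setdefault(e.chrom, []).append((e.start, e.end))
        truth_bp = 0
        for ivs in spans.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e:
                    truth_bp += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            truth_bp += cur_e - cur_s
        tolerance = 2 * grid.window_size * max(len(del_events), 1)
        assert abs(summary.unique_deleted_bp - truth_bp) <= tolerance
        assert summary.genome_fraction == pytest.approx(truth_bp / grid.total_bp,
                                                        abs=tolerance / grid.total_bp)
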