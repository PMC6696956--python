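"""Coverage-enrichment detection, quantification and boundary refinement."""

import math

import numpy as np
import pytest

from prophagekit import synth
from prophagekit.enrichment import (
    _best_split,
    detect_enriched_segments,
    enrichment_ratio,
    estimate_background,
    fold_enrichment,
    refine_boundaries,
    report_enrichment,
)
from prophagekit.io import CoverageTrack, ProphageRegion


def make_track(depth):
    return CoverageTrack("chr1", np.asarray(depth, dtype=float))


def step_track(length, region, bg, fold, rng=None, size=10.0):
    mean = np.full(length, float(bg))
    mean[region[0] : region[1]] = bg * fold
    if rng is None:
        return make_track(mean)
    p = size / (size + mean)
    return make_track(rng.negative_binomial(size, p).astype(float))


class TestBackground:
    def test_uniform_track(self):
        assert estimate_background(make_track(np.full(1000, 10.0))) == 10.0

    def test_excluding_enriched_region(self):
        track = step_track(10_000, (2000, 4000), 10, 70)
        region = ProphageRegion("chr1", 2000, 4000)
        assert estimate_background(track, [region]) == 10.0

    def test_matches_sort_based_median_oracle(self, rng):
        for _ in range(10):
            depth = rng.integers(0, 50, size=501).astype(float)
            got = estimate_background(make_track(depth))
            s = np.sort(depth)
            oracle = (s[250] if len(s) % 2 else (s[249] + s[250]) / 2)
            assert got == oracle

    def test_everything_excluded_rejected(self):
        track = make_track(np.full(100, 5.0))
        with pytest.raises(ValueError):
            estimate_background(track, [ProphageRegion("chr1", 0, 100)])


class TestFoldEnrichment:
    def test_uniform_track_gives_unity(self):
        track = make_track(np.full(5000, 7.0))
        assert fold_enrichment(track, ProphageRegion("chr1", 100, 900), 7.0) == 1.0

    def test_forced_arithmetic(self):
        track = step_track(10_000, (2000, 4000), 10, 7)
        assert fold_enrichment(track, ProphageRegion("chr1", 2000, 4000), 10.0) == 7.0

    def test_recovers_closed_form_on_simulated_coverage(self, truth):
        # fold estimate vs 1 + f*b using a mean background outside the regions
        n_seeds = 20
        folds = {r.name: [] for r in truth.regions}
        for seed in range(n_seeds):
            cov = synth.simulate_supernatant_coverage(truth, seed=100 + seed)
            bg = estimate_background(cov, truth.regions, method="mean")
            for r in truth.regions:
                folds[r.name].append(fold_enrichment(cov, r, bg))
        for r in truth.regions:
            observed = np.array(folds[r.name])
            se = observed.std(ddof=1) / math.sqrt(n_seeds)
            assert abs(observed.mean() - truth.expected_fold(r.name)) <= 3 * se


class TestDetect:
    def test_uniform_track_yields_nothing(self):
        assert detect_enriched_segments(make_track(np.full(20_000, 10.0))) == []

    def test_noise_free_plateaus_recovered_exactly(self):
        mean = np.full(50_000, 10.0)
        mean[10_000:20_000] = 100.0
        mean[30_000:42_000] = 640.0
        segs = detect_enriched_segments(make_track(mean), background=10.0, smooth_window=1)
        assert [(s.start, s.end) for s in segs] == [(10_000, 20_000), (30_000, 42_000)]
        # with smoothing, boundaries may shift by at most half a window
        smoothed = detect_enriched_segments(make_track(mean), background=10.0)
        for seg, (lo, hi) in zip(smoothed, [(10_000, 20_000), (30_000, 42_000)]):
            assert abs(seg.start - lo) <= 250 and abs(seg.end - hi) <= 250

    def test_short_plateau_dropped(self):
        track = step_track(50_000, (10_000, 13_000), 10, 10)
        assert detect_enriched_segments(track, min_len=5000, background=10.0) == []

    def test_parameter_validation(self):
        track = make_track(np.full(100, 1.0))
        with pytest.raises(ValueError):
            detect_enriched_segments(track, min_fold=1.0)
        with pytest.raises(ValueError):
            detect_enriched_segments(track, min_len=0)

    def test_scale_invariance(self, truth):
        cov = synth.simulate_supernatant_coverage(truth, seed=4)
        segs = detect_enriched_segments(cov)
        scaled = detect_enriched_segments(cov.scaled(13.7))
        assert [(s.start, s.end) for s in segs] == [(s.start, s.end) for s in scaled]
        bg = estimate_background(cov)
        region = truth.regions[0]
        assert fold_enrichment(cov.scaled(13.7), region, 13.7 * bg) == pytest.approx(
            fold_enrichment(cov, region, bg)
        )


class TestRefineBoundaries:
    def test_noise_free_step_recovered_exactly(self):
        track = step_track(20_000, (5_000, 15_000), 10, 7)
        region = ProphageRegion("chr1", 5_300, 14_600)
        assert refine_boundaries(track, region) == (5_000, 15_000)

    def test_flat_signal_leaves_boundary_unchanged(self):
        track = make_track(np.full(10_000, 10.0))
        region = ProphageRegion("chr1", 3_000, 7_000)
        assert refine_boundaries(track, region) == (3_000, 7_000)

    def test_window_outside_track_rejected(self):
        track = make_track(np.full(5_000, 10.0))
        with pytest.raises(ValueError):
            refine_boundaries(track, ProphageRegion("chr1", 500, 4_000), search_window=1000)

    def test_split_matches_brute_force_scan(self, rng):
        for _ in range(5):
            x = rng.negative_binomial(10, 0.5, size=400).astype(float)
            x[250:] *= 5
            got = _best_split(x)
            sses = [
                np.sum((x[:t] - x[:t].mean()) ** 2) + np.sum((x[t:] - x[t:].mean()) ** 2)
                for t in range(1, len(x))
            ]
            assert got == int(np.argmin(sses)) + 1

    def test_median_error_under_noise_within_50_bp(self):
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            track = step_track(8_000, (2_000, 6_000), 10, 7, rng=rng)
            region = ProphageRegion("chr1", 2_250, 5_750)
            start, end = refine_boundaries(track, region, search_window=1000)
            errors += [abs(start - 2_000), abs(end - 6_000)]
        assert np.median(errors) <= 50


class TestEnrichmentRatio:
    def test_excess_ratio_arithmetic(self):
        from prophagekit.enrichment import EnrichmentReport

        region = ProphageRegion("chr1", 0, 10)
        a = EnrichmentReport(region, 710.0, 10.0, 71.0, 0, 10)
        b = EnrichmentReport(region, 110.0, 10.0, 11.0, 0, 10)
        assert enrichment_ratio(a, b) == 7.0
        assert enrichment_ratio(a, a) == 1.0
        assert enrichment_ratio(a, b, excess=False) == pytest.approx(71 / 11)

    def test_denominator_without_excess_is_undefined(self):
        from prophagekit.enrichment import EnrichmentReport

        region = ProphageRegion("chr1", 0, 10)
        a = EnrichmentReport(region, 710.0, 10.0, 71.0, 0, 10)
        b = EnrichmentReport(region, 10.0, 10.0, 1.0, 0, 10)
        assert math.isnan(enrichment_ratio(a, b))
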