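"""Circadian windows, peak detection/filtering, peak-to-peak statistics.

The filtering rules are cross-checked against a brute-force oracle that
re-implements the stated rules with plain loops and first-principles
definitions of local maxima, topographic prominence and half-height width.
"""

import numpy as np
import pytest

from circatree.peaks import (
    CircadianWindow,
    Peak,
    circadian_windows,
    detect_peaks,
    filter_peaks,
    peak_to_peak,
    amplitude_stats,
)
from circatree.traces import CosinorFit


def gauss(t, mu, sig=1.5):
    return np.exp(-((t - mu) ** 2) / (2 * sig**2))


class TestCircadianWindows:
    def test_24h_fit_tiles_120h_into_four_windows(self):
        fit = CosinorFit(alpha=0, beta=1, phi=0.0, tau=24.0, sse=0)
        wins = circadian_windows(fit, (0.0, 120.0))
        # troughs where the cosine is -1: 12, 36, 60, 84, 108
        assert len(wins) == 4
        assert wins[0] == pytest.approx((12.0, 36.0))
        assert wins[-1] == pytest.approx((84.0, 108.0))

    def test_27h_fit_on_60h_trace_gives_one_window(self):
        fit = CosinorFit(alpha=0, beta=1, phi=0.0, tau=27.0, sse=0)
        assert len(circadian_windows(fit, (0.0, 60.0))) == 1

    def test_trough_spacing_equals_tau(self):
        fit = CosinorFit(alpha=1, beta=2, phi=5.3, tau=22.4, sse=0)
        wins = circadian_windows(fit, (0.0, 120.0))
        for w0, w1 in wins:
            assert w1 - w0 == pytest.approx(22.4)

    def test_trace_shorter_than_one_period_gives_empty(self):
        fit = CosinorFit(alpha=0, beta=1, phi=0.0, tau=24.0, sse=0)
        assert circadian_windows(fit, (0.0, 20.0)) == []


class TestDetectPeaks:
    def test_two_well_separated_bumps_found_at_centres(self):
        t = np.arange(0.0, 24.0, 0.75)
        v = gauss(t, 6.0) + 0.6 * gauss(t, 15.0)
        ps = detect_peaks(t, v)
        assert len(ps) == 2
        assert ps[0].time_h == pytest.approx(6.0, abs=0.76)
        assert ps[1].time_h == pytest.approx(15.0, abs=0.76)

    def test_close_pair_keeps_only_the_taller(self):
        t = np.arange(0.0, 24.0, 0.25)
        v = gauss(t, 10.0, 0.8) + 0.8 * gauss(t, 12.0, 0.8)
        ps = detect_peaks(t, v)
        assert len(ps) == 1
        assert ps[0].time_h == pytest.approx(10.0, abs=0.3)

    def test_narrow_spike_rejected_by_fwhm_rule(self):
        t = np.arange(0.0, 24.0, 0.75)
        v = np.full_like(t, 0.1)
        v[12] = 5.0  # one-sample spike, FWHM ~ 0.75 h
        assert detect_peaks(t, v) == []

    def test_plateau_yields_centre_sample(self):
        t = np.arange(0.0, 15.0, 0.75)
        v = np.zeros_like(t)
        v[6:11] = 1.0
        ps = detect_peaks(t, v)
        assert len(ps) == 1
        assert ps[0].time_h == pytest.approx(t[8])


class TestFilterPeaks:
    def mk(self, time, h, prom, w):
        return Peak(time_h=time, height=h, prominence=prom, width_h=w)

    def test_low_height_discarded(self):
        ps = [self.mk(5, 1.0, 0.9, 4.0), self.mk(14, 0.20, 0.9, 4.0)]
        kept = filter_peaks(ps)
        assert [p.time_h for p in kept] == [5]

    def test_both_kept_when_rules_pass(self):
        ps = [self.mk(5, 1.0, 0.9, 4.0), self.mk(14, 0.6, 0.5, 3.5)]
        kept = filter_peaks(ps)
        assert [p.time_h for p in kept] == [5, 14]

    def test_width_difference_discards_non_major(self):
        ps = [self.mk(5, 1.0, 0.9, 3.0), self.mk(14, 0.6, 0.5, 9.5)]
        kept = filter_peaks(ps)
        assert [p.time_h for p in kept] == [5]

    def test_and_mode_is_laxer(self):
        ps = [self.mk(5, 1.0, 0.9, 4.0), self.mk(14, 0.20, 0.5, 4.0)]
        assert len(filter_peaks(ps, combine="or")) == 1
        assert len(filter_peaks(ps, combine="and")) == 2

    def test_empty_input(self):
        assert filter_peaks([]) == []


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_pipeline(t, v, min_sep=3.0, min_fwhm=2.0, hfrac=0.25, pfrac=0.10, wdiff=5.0):
    """Literal restatement of the detection and filtering rules."""
    n = len(v)
    # strict local maxima; plateaus -> centre sample
    cand = []
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j < n - 1 and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                cand.append((i + j) // 2)
            i = j + 1
        else:
            i += 1

    def prominence(k):
        h = v[k]
        lo_l = h
        m = h
        for j in range(k - 1, -1, -1):
            m = min(m, v[j])
            if v[j] > h:
                break
        lo_l = m
        m = h
        for j in range(k + 1, n):
            m = min(m, v[j])
            if v[j] > h:
                break
        lo_r = m
        return h - max(lo_l, lo_r)

    def fwhm(k):
        base = min(v)
        half = base + 0.5 * (v[k] - base)
        left = t[0]
        valley = k
        for j in range(k - 1, -1, -1):
            if v[j] < half <= v[j + 1]:
                frac = (v[j + 1] - half) / (v[j + 1] - v[j])
                left = t[j + 1] + frac * (t[j] - t[j + 1])
                break
            if v[j] > v[k]:
                left = t[valley]
                break
            if v[j] < v[valley]:
                valley = j
        right = t[-1]
        valley = k
        for j in range(k + 1, n):
            if v[j] < half <= v[j - 1]:
                frac = (v[j - 1] - half) / (v[j - 1] - v[j])
                right = t[j - 1] + frac * (t[j] - t[j - 1])
                break
            if v[j] > v[k]:
                right = t[valley]
                break
            if v[j] < v[valley]:
                valley = j
        return right - left

    # separation: highest first, ties by earlier time
    order = sorted(cand, key=lambda k: (-v[k], k))
    kept = []
    for k in order:
        if all(abs(t[k] - t[j]) >= min_sep for j in kept):
            kept.append(k)
    peaks = [
        (t[k], v[k], prominence(k), fwhm(k)) for k in sorted(kept) if fwhm(k) >= min_fwhm
    ]
    if not peaks:
        return []
    major = max(peaks, key=lambda p: (p[1], -p[0]))
    out = []
    for p in peaks:
        if p == major:
            out.append(p)
            continue
        if p[1] < hfrac * major[1] or p[2] < pfrac * major[2]:
            continue
        if abs(p[3] - major[3]) > wdiff:
            continue
        out.append(p)
    return sorted(out)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_windows_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 60))
        t = np.arange(n) * 0.75
        # smooth-ish random signal: a few bumps plus noise
        v = np.zeros(n)
        for _ in range(int(rng.integers(1, 4))):
            v += rng.uniform(0.3, 1.2) * gauss(t, rng.uniform(0, t[-1]), rng.uniform(1, 3))
        v += 0.05 * rng.normal(size=n)
        got = [
            (p.time_h, p.height, p.prominence, p.width_h)
            for p in filter_peaks(detect_peaks(t, v))
        ]
        want = oracle_pipeline(t, v)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1e-9)

    def test_retained_peaks_satisfy_all_constraints_post_hoc(self, wt_low_movie):
        from circatree.pipeline import analyze_movie_peaks

        a = analyze_movie_peaks(wt_low_movie)
        for wins in a.windows:
            for w in wins:
                ps = w.peaks or []
                if not ps:
                    continue
                major = max(p.height for p in ps)
                major_prom = max(p.prominence for p in ps)
                for i, p in enumerate(ps):
                    assert p.width_h >= 2.0
                    assert w.start_h - 1e-9 <= p.time_h <= w.end_h + 1e-9
                    assert p.height >= 0.25 * major or p.height == major
                    for q in ps[i + 1 :]:
                        assert abs(p.time_h - q.time_h) >= 3.0 - 1e-9


class TestPeakToPeak:
    def _window(self, lid, start, end, peak_times, cell=0):
        peaks = [
            Peak(time_h=pt, height=1.0, prominence=0.8, width_h=4.0, cell_id=cell)
            for pt in peak_times
        ]
        w = CircadianWindow(
            lineage_id=lid, start_h=start, end_h=end,
            times=np.array([start, end]), values=np.zeros(2),
            segment_ids=np.array([cell, cell]),
        )
        w.peaks = peaks
        return w

    def test_double_peak_windows_give_bimodal_distances(self):
        # peaks at trough+6 and trough+15 in every 24-h window: within-window
        # distance 9, lone-to-next complement 24 - 15 + 6 = 15
        wins = [
            self._window("l", s, s + 24.0, [s + 6.0, s + 15.0]) for s in (0.0, 24.0, 48.0)
        ]
        pairs = peak_to_peak([wins])
        within = sorted(p.distance_h for p in pairs if p.same_window)
        assert within == pytest.approx([9.0, 9.0, 9.0])

    def test_single_peak_windows_give_period_distances(self):
        wins = [self._window("l", s, s + 24.0, [s + 12.0]) for s in (0.0, 24.0, 48.0)]
        pairs = peak_to_peak([wins])
        assert sorted(p.distance_h for p in pairs) == pytest.approx([24.0, 24.0])
        assert all(not p.same_window for p in pairs)

    def test_distances_over_36h_dropped(self):
        wins = [
            self._window("l", 0.0, 40.0, [2.0]),
            self._window("l", 40.0, 80.0, [39.5]),
        ]
        assert peak_to_peak([wins]) == []

    def test_shared_prefix_pairs_deduplicated_across_lineages(self):
        # four lineages of a complete 2-generation tree carry the same
        # ancestral windows; the pair must be counted once (enumeration
        # oracle: one distinct pair per window pair)
        wins_per_lineage = [
            [self._window(f"l{k}", 0.0, 24.0, [6.0, 15.0], cell=0)] for k in range(4)
        ]
        pairs = peak_to_peak(wins_per_lineage)
        assert len(pairs) == 1

    def test_dedup_idempotent(self):
        wins = [self._window("l", 0.0, 24.0, [6.0, 15.0])]
        once = peak_to_peak([wins])
        again = peak_to_peak([wins])
        assert [(p.first.time_h, p.second.time_h) for p in once] == [
            (p.first.time_h, p.second.time_h) for p in again
        ]


class TestAmplitudeStats:
    def test_identical_peaks_give_zero_differences(self):
        w = TestPeakToPeak()._window("l", 0.0, 24.0, [6.0, 15.0])
        stats = amplitude_stats([[w]])
        assert stats["diffs"] == pytest.approx([0.0])

    def test_ko_windows_have_no_differences(self):
        w = TestPeakToPeak()._window("l", 0.0, 24.0, [12.0])
        stats = amplitude_stats([[w]])
        assert stats["diffs"].size == 0

    def test_secondary_amplitude_recovered_from_clean_movie(self, clean_wt_movie):
        from circatree.pipeline import analyze_movie_peaks

        a = analyze_movie_peaks(clean_wt_movie)
        stats = a.amplitude_summary()
        doubles = [
            (w.peaks[0].height, w.peaks[1].height)
            for wins in a.windows
            for w in wins
            if w.peaks and len(w.peaks) >= 2
        ]
        assert doubles, "no double-peak windows in a clean wild-type movie"
        rel = np.mean([(h1 - h2) / (h1 - clean_wt_movie.config.baseline_au) for h1, h2 in doubles])
        # generator: secondary bump at 0.6 of the primary -> relative drop 0.4
        assert rel == pytest.approx(0.4, abs=0.1)
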