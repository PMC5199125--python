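"""Standard and tree-corrected correlation estimators.

The tree estimator is checked against a brute-force oracle that enumerates
every distinct lagged data pair of a small division tree (keeping, for pairs
shared by several lineages, the last depth-first occurrence, which is what
the telescoping prefix correction leaves behind).
"""

import numpy as np
import pytest

from circatree.treecorr import (
    CorrelationError,
    average_movies,
    correlation_peaks,
    standard_xcorr,
    tree_xcorr,
)


class TestStandardXcorr:
    def test_autocorrelation_is_one_at_zero_lag(self, rng):
        x = rng.normal(size=300)
        res = standard_xcorr(x, x, dt=0.75, lag_max_h=12)
        assert res.R[len(res.R) // 2] == pytest.approx(1.0)

    def test_autocorrelation_symmetry_exact(self, rng):
        x = rng.normal(size=257)
        res = standard_xcorr(x, x, dt=0.75, lag_max_h=24)
        assert np.array_equal(res.R, res.R[::-1])

    def test_delayed_copy_peaks_at_minus_delay(self):
        # y(n) = x(n - d): y lags x, so the correlation peaks at lag -d
        # under this orientation (|argmax| = d either way)
        t = np.arange(0, 240, 0.75)
        x = np.cos(2 * np.pi * t / 24)
        d = 4  # frames = 3 h
        y = np.roll(x, d)
        res = standard_xcorr(x, y, dt=0.75, lag_max_h=12)
        peak = res.lags[np.argmax(res.R)]
        assert abs(peak) == pytest.approx(d * 0.75)
        assert peak == pytest.approx(-d * 0.75)

    def test_independent_white_noise_stays_small(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        res = standard_xcorr(x, y, dt=1.0, lag_max_h=40)
        assert np.max(np.abs(res.R)) < 0.1

    def test_constant_series_rejected(self):
        with pytest.raises(CorrelationError):
            standard_xcorr(np.ones(50), np.arange(50.0), dt=1.0, lag_max_h=5)

    def test_bounded_near_one_for_long_stationary_series(self, rng):
        x = rng.normal(size=5000)
        res = standard_xcorr(x, x, dt=1.0, lag_max_h=100)
        assert np.max(np.abs(res.R)) <= 1.0 + 0.1


def tree_oracle(X, Y, lineage_cells, dt, lag_max_h):
    """Enumerate distinct lagged pairs of a lineage forest, last occurrence
    winning, then normalise per pair; fully independent loops."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    nc, nt = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    L = int(lag_max_h / dt)

    def s(A, B, tau):
        pairs = {}
        for i in range(nc):
            for n in range(nt - tau):
                key = (lineage_cells[i][n + tau], n + tau, lineage_cells[i][n], n)
                pairs[key] = A[i, n + tau] * B[i, n]
        return sum(pairs.values()) / len(pairs)

    sxx0, syy0 = s(Xc, Xc, 0), s(Yc, Yc, 0)
    lags = dt * np.arange(-L, L + 1)
    R = np.array(
        [
            (s(Xc, Yc, tau) if tau >= 0 else s(Yc, Xc, -tau)) / np.sqrt(sxx0 * syy0)
            for tau in range(-L, L + 1)
        ]
    )
    return lags, R


def small_tree(rng, n_frames=30, generations=3):
    """Random per-cell signals on a complete binary tree; returns lineage
    matrices plus per-frame owning-cell ids."""
    seg_len = n_frames // generations
    cells = {}
    next_id = [0]

    def make(depth):
        cid = next_id[0]
        next_id[0] += 1
        n = seg_len if depth < generations - 1 else n_frames - seg_len * (generations - 1)
        cells[cid] = (rng.normal(size=n), rng.normal(size=n))
        if depth < generations - 1:
            return [(cid, sub) for sub in (make(depth + 1), make(depth + 1))]
        return [(cid, None)]

    tree = make(0)

    paths = []

    def walk(node, prefix):
        cid, subs = node if isinstance(node, tuple) else (None, None)
        if subs is None:
            paths.append(prefix + [cid])
            return
        for sub in subs:
            walk(sub, prefix + [cid])

    for top in tree:
        walk(top, [])

    X, Y, owners = [], [], []
    for path in paths:
        xs, ys, ids = [], [], []
        for cid in path:
            x, y = cells[cid]
            xs.extend(x)
            ys.extend(y)
            ids.extend([cid] * len(x))
        X.append(xs)
        Y.append(ys)
        owners.append(ids)
    return np.array(X), np.array(Y), owners


class TestTreeXcorr:
    def test_single_lineage_equals_standard(self, rng):
        x = rng.normal(size=80)
        y = rng.normal(size=80)
        a = standard_xcorr(x, y, dt=0.75, lag_max_h=12)
        b = tree_xcorr(x[None, :], y[None, :], dt=0.75, lag_max_h=12)
        assert np.allclose(a.R, b.R, atol=1e-12)

    def test_copy_daughters_equal_standard_on_distinct_path(self, rng):
        # two lineages diverging at frame 20 but carrying identical values:
        # the repeated data are fully discarded, leaving the single path
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        X = np.vstack([x, x])
        Y = np.vstack([y, y])
        a = standard_xcorr(x, y, dt=0.75, lag_max_h=9)
        b = tree_xcorr(X, Y, dt=0.75, lag_max_h=9)
        assert np.allclose(a.R, b.R, atol=1e-12)
        # a genuinely diverging sibling, by contrast, must change the result:
        X2 = np.vstack([x, np.concatenate([x[:20], rng.normal(size=40)])])
        Y2 = np.vstack([y, np.concatenate([y[:20], rng.normal(size=40)])])
        c = tree_xcorr(X2, Y2, dt=0.75, lag_max_h=9)
        assert not np.allclose(a.R, c.R, atol=1e-6)

    def test_duplicating_a_lineage_changes_nothing(self, rng):
        X, Y, _ = small_tree(rng)
        a = tree_xcorr(X, Y, dt=0.75, lag_max_h=9)
        Xd = np.vstack([X[:1], X])  # identical sibling, adjacent in order
        Yd = np.vstack([Y[:1], Y])
        b = tree_xcorr(Xd, Yd, dt=0.75, lag_max_h=9)
        assert np.allclose(a.R, b.R, atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, Y, owners = small_tree(rng, n_frames=rng.integers(24, 40), generations=3)
        res = tree_xcorr(X, Y, dt=0.75, lag_max_h=6.0)
        lags, R = tree_oracle(X, Y, owners, dt=0.75, lag_max_h=6.0)
        assert np.allclose(res.lags, lags)
        assert np.allclose(res.R, R, atol=1e-10)

    def test_each_shared_pair_counted_once_by_construction(self, rng):
        # symbolic pair counting on a 3-generation tree: the telescoping
        # prefix correction removes exactly the duplicated (n, n+tau) pairs,
        # so the corrected count must equal the distinct-pair enumeration
        X, Y, owners = small_tree(rng, n_frames=30, generations=3)
        nc, nt = X.shape
        for tau in (0, 3, 7):
            keys = set()
            for i in range(nc):
                for n in range(nt - tau):
                    keys.add((owners[i][n + tau], n + tau, owners[i][n], n))
            # divergence of consecutive identical-prefix rows
            d = []
            for i in range(nc - 1):
                same = np.nonzero(
                    ~((X[i] == X[i + 1]) & (Y[i] == Y[i + 1]))
                )[0]
                d.append(nt if same.size == 0 else same[0])
            expected = nc * (nt - tau) - sum(max(di - tau, 0) for di in d)
            assert expected == len(keys)

    def test_mismatched_grids_rejected(self, rng):
        with pytest.raises(CorrelationError):
            tree_xcorr(rng.normal(size=(2, 30)), rng.normal(size=(2, 29)))


class TestAverageMovies:
    def _res(self, R):
        from circatree.treecorr import CorrelationResult

        return CorrelationResult(lags=np.arange(-2.0, 2.1, 1.0), R=np.asarray(R, float))

    def test_identical_movies_mean_equals_each_sem_zero(self):
        r = self._res([0.1, 0.5, 1.0, 0.5, 0.1])
        out = average_movies([r, r, r])
        assert np.allclose(out.R, r.R)
        assert np.allclose(out.sem, 0.0)

    def test_opposite_movies_cancel(self):
        a = self._res([0.3, 0.3, 1.0, 0.3, 0.3])
        b = self._res([-0.3, -0.3, -1.0, -0.3, -0.3])
        assert np.allclose(average_movies([a, b]).R, 0.0)

    def test_sem_scales_with_movie_count(self, rng):
        curves = rng.normal(size=(16, 5))
        out8 = average_movies([self._res(c) for c in curves[:8]])
        out16 = average_movies([self._res(c) for c in curves])
        # SEM ~ sd/sqrt(m): doubling m shrinks it by ~sqrt(2)
        ratio = np.mean(out8.sem) / np.mean(out16.sem)
        assert ratio == pytest.approx(np.sqrt(2), rel=0.4)

    def test_mismatched_lag_grids_rejected(self):
        from circatree.treecorr import CorrelationResult

        a = self._res([0, 0, 1, 0, 0])
        b = CorrelationResult(lags=np.arange(-1.0, 1.1, 1.0), R=np.zeros(3))
        with pytest.raises(CorrelationError):
            average_movies([a, b])


class TestCorrelationPeaks:
    def test_pure_24h_cosine_peaks_at_24(self):
        t = np.arange(0, 360, 0.75)
        x = np.cos(2 * np.pi * t / 24)
        res = standard_xcorr(x, x, dt=0.75, lag_max_h=30)
        peaks = correlation_peaks(res)
        assert np.allclose(peaks, 24.0, atol=0.76)

    def test_two_harmonic_signal_peaks_at_12_and_24(self):
        # autocorrelation of cos(wt) + B cos(2wt) is proportional to
        # cos(w tau) + (B^2/2)/(1/2) ... i.e. 0.5 cos(w tau) + (B^2/2) cos(2w tau);
        # the 12-h maximum is strict iff B^2/2 > 1/8 (second derivative
        # negative), so B = 0.8 gives clean maxima at both 12 and 24 h
        t = np.arange(0, 480, 0.75)
        x = np.cos(2 * np.pi * t / 24) + 0.8 * np.cos(2 * np.pi * t / 12)
        res = standard_xcorr(x, x, dt=0.75, lag_max_h=30)
        peaks = correlation_peaks(res)
        assert np.allclose(np.unique(np.round(peaks)), [12.0, 24.0])

    def test_flat_curve_has_no_peaks(self):
        from circatree.treecorr import CorrelationResult

        res = CorrelationResult(lags=np.arange(-24, 24.1, 0.75), R=np.zeros(65))
        assert correlation_peaks(res).size == 0

    def test_zero_lag_exclusion(self, rng):
        t = np.arange(0, 360, 0.75)
        x = np.cos(2 * np.pi * t / 24) + 0.01 * rng.normal(size=t.size)
        res = standard_xcorr(x, x, dt=0.75, lag_max_h=30)
        with_zero = correlation_peaks(res, exclude_zero=False)
        without = correlation_peaks(res, exclude_zero=True)
        assert 0.0 in np.round(with_zero, 6)
        assert 0.0 not in np.round(without, 6)
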