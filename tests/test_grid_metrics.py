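"""Grid construction, per-square statistics against a brute-force oracle,
and the frame/square quality-control rules."""

import math

import numpy as np
import pytest

from swemuscle.elastogram import ElastogramFrame
from swemuscle.grid_metrics import (
    COLORED_PCT_CUTOFF,
    GridSizingError,
    apply_qc,
    build_grid,
    square_metrics,
)


def frame_from(swv, valid=None, sat=None, spacing=(0.1, 0.1), index=0):
    swv = np.asarray(swv, dtype=float)
    if valid is None:
        valid = ~np.isnan(swv)
    sat = np.zeros_like(valid) if sat is None else sat
    out = swv.copy()
    out[~valid] = np.nan
    return ElastogramFrame(
        swv=out, valid_mask=valid, saturated_mask=sat,
        pixel_spacing_mm=spacing, elasto_index=index,
    )


def brute_force_stats(values):
    """Independent implementation of the six square statistics: sorted-list
    quantiles with linear interpolation, n-1 standard deviation."""
    s = sorted(values)
    n = len(s)

    def quantile(p):
        h = (n - 1) * p
        lo, hi = math.floor(h), math.ceil(h)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    mean = sum(s) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in s) / (n - 1)) if n > 1 else 0.0
    return {
        "max_swv": s[-1],
        "mean_swv": mean,
        "median_swv": quantile(0.5),
        "sd_swv": sd,
        "iqr_swv": quantile(0.75) - quantile(0.25),
    }


class TestBuildGrid:
    def test_stated_arithmetic_at_tenth_mm(self):
        """0.1 mm/px: 10 rows discarded, 40 px squares, A1 at rows [10,50)
        cols [0,40); B row directly beneath."""
        grid = build_grid((200, 300), (0.1, 0.1))
        assert grid.discard_rows == 10
        assert grid.square_px == (40, 40)
        assert grid.squares["A1"] == (10, 50, 0, 40)
        assert grid.squares["A7"] == (10, 50, 240, 280)
        assert grid.squares["B1"] == (50, 90, 0, 40)

    def test_exact_boundary_fit(self):
        grid = build_grid((90, 280), (0.1, 0.1))
        assert grid.squares["B7"] == (50, 90, 240, 280)

    def test_too_narrow_region_raises_sizing_error(self):
        with pytest.raises(GridSizingError, match="mm"):
            build_grid((200, 150), (0.1, 0.1))

    def test_too_short_region_raises_sizing_error(self):
        with pytest.raises(GridSizingError):
            build_grid((89, 280), (0.1, 0.1))

    def test_determinism_and_center_anchor(self):
        g1 = build_grid((200, 300), (0.1, 0.1))
        g2 = build_grid((200, 300), (0.1, 0.1))
        assert g1.squares == g2.squares
        gc = build_grid((200, 300), (0.1, 0.1), anchor="center")
        assert gc.squares["A1"][2] == (300 - 280) // 2

    def test_anisotropic_spacing(self):
        grid = build_grid((60, 150), (0.2, 0.2))
        assert grid.discard_rows == 5
        assert grid.square_px == (20, 20)


class TestSquareMetrics:
    def test_constant_square(self):
        frame = frame_from(np.full((90, 280), 5.0))
        grid = build_grid(frame)
        for m in square_metrics(frame, grid):
            assert m.max_swv == m.mean_swv == m.median_swv == 5.0
            assert m.sd_swv == 0.0 and m.iqr_swv == 0.0
            assert m.colored_pct == 100.0 and m.included

    def test_four_value_square_quantiles(self):
        """Valid pixels {2,4,6,8}: median 5, mean 5, max 8, IQR 3 under the
        linear-interpolation convention."""
        swv = np.full((90, 280), np.nan)
        valid = np.zeros((90, 280), dtype=bool)
        swv[10, 0:4] = [2.0, 4.0, 6.0, 8.0]
        valid[10, 0:4] = True
        frame = frame_from(swv, valid)
        m = square_metrics(frame, build_grid(frame))[0]  # A1
        assert m.median_swv == 5.0
        assert m.mean_swv == 5.0
        assert m.max_swv == 8.0
        assert m.iqr_swv == 3.0
        oracle = brute_force_stats([2.0, 4.0, 6.0, 8.0])
        for key, val in oracle.items():
            assert getattr(m, key) == pytest.approx(val, rel=1e-12)

    def test_forty_percent_coverage_excluded(self):
        swv = np.full((90, 280), np.nan)
        valid = np.zeros((90, 280), dtype=bool)
        sq = np.zeros(1600, dtype=bool)
        sq[:640] = True  # 40% of the 40x40 A1 square
        valid[10:50, 0:40] = sq.reshape(40, 40)
        swv[valid] = 4.0
        m = square_metrics(frame_from(swv, valid), build_grid((90, 280), (0.1, 0.1)))[0]
        assert m.colored_pct == pytest.approx(40.0)
        assert not m.included

    def test_empty_square_flagged_undefined(self):
        frame = frame_from(np.full((90, 280), np.nan))
        m = square_metrics(frame, build_grid(frame))[0]
        assert not m.defined and m.colored_pct == 0.0
        assert math.isnan(m.median_swv)

    def test_saturated_pixels_counted_not_filtered(self):
        swv = np.full((90, 280), 4.0)
        sat = np.zeros((90, 280), dtype=bool)
        swv[10:50, 0:40] = 9.95
        sat[10:50, 0:40] = True
        frame = frame_from(swv, sat=sat)
        m = square_metrics(frame, build_grid(frame))[0]
        assert m.saturated_n == 1600 and m.saturated_pct == 100.0
        assert m.median_swv == pytest.approx(9.95)  # stays in the statistics

    def test_oracle_equivalence_on_random_small_sets(self, rng):
        """All six statistics match the brute-force oracle on random valid
        subsets of up to 10x10 pixels."""
        for trial in range(40):
            vals = rng.uniform(0.1, 9.9, size=rng.integers(1, 101))
            oracle = brute_force_stats(list(vals))
            swv = np.full((90, 280), np.nan)
            valid = np.zeros((90, 280), dtype=bool)
            flat = np.zeros(1600)
            mask = np.zeros(1600, dtype=bool)
            flat[: len(vals)] = vals
            mask[: len(vals)] = True
            swv[10:50, 0:40] = flat.reshape(40, 40)
            valid[10:50, 0:40] = mask.reshape(40, 40)
            m = square_metrics(frame_from(swv, valid), build_grid((90, 280), (0.1, 0.1)))[0]
            for key, val in oracle.items():
                assert getattr(m, key) == pytest.approx(val, rel=1e-11, abs=1e-11), key


class TestQC:
    def _metrics_with_coverage(self, coverages):
        swv = np.full((90, 280), np.nan)
        valid = np.zeros((90, 280), dtype=bool)
        grid = build_grid((90, 280), (0.1, 0.1))
        for (sid, (r0, r1, c0, c1)), cov in zip(grid.squares.items(), coverages):
            n = r1 - r0
            k = int(round(cov / 100 * n * n))
            block = np.zeros(n * n, dtype=bool)
            block[:k] = True
            valid[r0:r1, c0:c1] = block.reshape(n, n)
        swv[valid] = 4.0
        return square_metrics(frame_from(swv, valid), grid)

    def test_exactly_half_coverage_is_retained(self):
        m = self._metrics_with_coverage([50.0] * 14)
        assert all(x.included for x in m)
        assert not apply_qc(m).frame_discarded

    def test_just_below_half_coverage_is_excluded(self):
        m = self._metrics_with_coverage([49.9] * 14)
        assert not any(x.included for x in m)
        assert apply_qc(m).frame_discarded

    def test_seven_of_fourteen_excluded_retains_frame(self):
        m = self._metrics_with_coverage([30.0] * 7 + [90.0] * 7)
        qc = apply_qc(m)
        assert qc.n_squares_excluded == 7
        assert not qc.frame_discarded

    def test_eight_of_fourteen_excluded_discards_frame(self):
        m = self._metrics_with_coverage([30.0] * 8 + [90.0] * 6)
        qc = apply_qc(m)
        assert qc.n_squares_excluded == 8
        assert qc.frame_discarded

    def test_no_exclusions(self):
        qc = apply_qc(self._metrics_with_coverage([100.0] * 14))
        assert qc.n_squares_excluded == 0 and not qc.frame_discarded

    def test_wrong_square_count_rejected(self):
        with pytest.raises(ValueError):
            apply_qc(self._metrics_with_coverage([100.0] * 14)[:13])

    def test_raising_cutoff_is_monotone(self, rng):
        """A stricter coverage cutoff never includes more squares and never
        un-discards a frame."""
        covs = rng.uniform(0, 100, size=14)
        swv = np.full((90, 280), np.nan)
        grid = build_grid((90, 280), (0.1, 0.1))
        prev_included = 15
        prev_discarded = False
        for cutoff in (30.0, 50.0, 70.0, 90.0):
            valid = np.zeros((90, 280), dtype=bool)
            for (sid, (r0, r1, c0, c1)), cov in zip(grid.squares.items(), covs):
                n = r1 - r0
                block = np.zeros(n * n, dtype=bool)
                block[: int(round(cov / 100 * n * n))] = True
                valid[r0:r1, c0:c1] = block.reshape(n, n)
            s = np.full((90, 280), np.nan)
            s[valid] = 4.0
            m = square_metrics(frame_from(s, valid), grid, colored_cutoff_pct=cutoff)
            inc = sum(x.included for x in m)
            disc = apply_qc(m).frame_discarded
            assert inc <= prev_included
            assert disc or not prev_discarded
            prev_included, prev_discarded = inc, disc
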