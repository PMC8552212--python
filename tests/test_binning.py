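"""Binning arithmetic, count conservation, densify, peak picking."""

import numpy as np
import pytest

from overprint import BinSpec, bin_cube, densify, peak_pick, total_ion_map
from overprint.io import PeakList

from conftest import make_cube


class TestBinCube:
    def test_factor_one_is_identity(self, cube_2x2):
        assert bin_cube(cube_2x2, BinSpec(1)) == cube_2x2

    def test_paper_scale_shape(self):
        """A 7000 x 7000 macroraster binned 14 x 14 becomes a 500 x 500 grid
        (49 million pixels down to 250 thousand)."""
        cube = make_cube(7000, 7000, 2, [(0, 0, 0, 1), (6999, 6999, 1, 2)])
        out = bin_cube(cube, BinSpec(14))
        assert (out.height, out.width) == (500, 500)
        assert out.height * out.width == 250_000
        assert out.total_counts == cube.total_counts

    def test_block_sum_by_hand(self):
        events = [(r, c, 0, 1) for r in range(4) for c in range(4)]
        out = bin_cube(make_cube(4, 4, 1, events), BinSpec(2))
        np.testing.assert_array_equal(total_ion_map(out), np.full((2, 2), 4))

    def test_count_conservation_when_divisible(self):
        rng = np.random.default_rng(0)
        ev = {(int(r), int(c), int(k)): 1 for r, c, k in zip(
            rng.integers(0, 12, 200), rng.integers(0, 12, 200), rng.integers(0, 3, 200))}
        cube = make_cube(12, 12, 3, [(r, c, k, n) for (r, c, k), n in ev.items()])
        for B in (2, 3, 4, 6):
            assert bin_cube(cube, BinSpec(B)).total_counts == cube.total_counts

    def test_crop_warns_and_conserves_retained_region(self):
        cube = make_cube(5, 5, 1, [(0, 0, 0, 1), (4, 4, 0, 7)])
        with pytest.warns(UserWarning, match="crop"):
            out = bin_cube(cube, BinSpec(2))
        assert (out.height, out.width) == (2, 2)
        assert out.total_counts == 1  # event at (4,4) cropped

    def test_error_policy_requires_divisibility(self):
        cube = make_cube(5, 5, 1, [(0, 0, 0, 1)])
        with pytest.raises(ValueError, match="divide"):
            bin_cube(cube, BinSpec(2, "error"))

    def test_factor_exceeding_dims_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            bin_cube(make_cube(4, 4, 1, []), BinSpec(5))

    def test_composition_law(self):
        rng = np.random.default_rng(1)
        ev = {(int(r), int(c), 0): 1 for r, c in zip(
            rng.integers(0, 24, 150), rng.integers(0, 24, 150))}
        cube = make_cube(24, 24, 1, [(r, c, k, n) for (r, c, k), n in ev.items()])
        twice = bin_cube(bin_cube(cube, BinSpec(2)), BinSpec(3))
        once = bin_cube(cube, BinSpec(6))
        assert twice == once
        assert twice.meta["bin_factor"] == once.meta["bin_factor"] == 6

    def test_provenance_records_binning(self, cube_2x2):
        out = bin_cube(cube_2x2, BinSpec(2))
        assert "bin:2x2:crop" in out.meta["provenance"]


class TestDensify:
    def test_empty_cube_is_zero_matrix(self):
        X = densify(make_cube(3, 4, 2, []))
        assert X.shape == (12, 2) and X.sum() == 0

    def test_row_sums_equal_tic_row_major(self, cube_2x2):
        X = densify(cube_2x2)
        np.testing.assert_array_equal(
            X.sum(axis=1), total_ion_map(cube_2x2).ravel()
        )

    def test_single_event_index_arithmetic(self):
        X = densify(make_cube(2, 2, 4, [(1, 0, 2, 3)]))
        assert X[2, 2] == 3 and X.sum() == 3

    def test_memory_budget_enforced(self):
        with pytest.raises(MemoryError, match="row blocks"):
            densify(make_cube(100, 100, 10, []), max_elements=1000)


def brute_force_peaks(mz, intensity, min_prominence, min_separation):
    """Independent oracle: scan every sample, test local-maximum and
    prominence definitions directly, then greedy tallest-first separation."""
    n = len(mz)
    apexes = []
    for i in range(1, n - 1):
        if not (intensity[i] > intensity[i - 1] and intensity[i] >= intensity[i + 1]):
            continue
        # prominence: height above the higher of the two key saddles
        left_min = intensity[i]
        j = i - 1
        best_left = intensity[i]
        while j >= 0 and intensity[j] <= intensity[i]:
            best_left = min(best_left, intensity[j])
            j -= 1
        left_base = best_left if j >= 0 else min(intensity[: i + 1])
        j = i + 1
        best_right = intensity[i]
        while j < n and intensity[j] <= intensity[i]:
            best_right = min(best_right, intensity[j])
            j += 1
        right_base = best_right if j < n else min(intensity[i:])
        prom = intensity[i] - max(left_base, right_base)
        if prom >= min_prominence:
            apexes.append(i)
    keep = []
    for i in sorted(apexes, key=lambda i: -intensity[i]):
        if all(abs(mz[i] - mz[j]) >= min_separation for j in keep):
            keep.append(i)
    return sorted(mz[i] for i in keep)


class TestPeakPick:
    def test_flat_spectrum_has_no_peaks(self):
        mz = np.linspace(0, 100, 500)
        assert len(peak_pick(mz, np.full(500, 3.0))) == 0

    def test_single_gaussian_peak_at_apex(self):
        mz = np.linspace(0, 50, 1000)
        inten = 100 * np.exp(-0.5 * ((mz - 25.0) / 0.2) ** 2)
        pl = peak_pick(mz, inten)
        assert len(pl) == 1
        assert pl.mz[0] == pytest.approx(25.0, abs=0.06)

    def test_close_apexes_share_midpoint_boundary(self):
        mz = np.linspace(0, 20, 2001)  # 0.01 m/z grid
        inten = 50 * np.exp(-0.5 * ((mz - 10.0) / 0.05) ** 2)
        inten += 40 * np.exp(-0.5 * ((mz - 10.6) / 0.05) ** 2)
        pl = peak_pick(mz, inten, min_separation=0.5)
        assert len(pl) == 2
        assert pl.hi[0] == pytest.approx((pl.mz[0] + pl.mz[1]) / 2, abs=1e-9)
        assert pl.lo[1] == pytest.approx(pl.hi[0], abs=1e-9)

    def test_far_apexes_clip_to_half_dalton(self):
        mz = np.linspace(0, 30, 3001)
        inten = 50 * np.exp(-0.5 * ((mz - 10.0) / 0.05) ** 2)
        inten += 40 * np.exp(-0.5 * ((mz - 20.0) / 0.05) ** 2)
        pl = peak_pick(mz, inten, min_separation=1.0)
        assert len(pl) == 2
        np.testing.assert_allclose(pl.hi - pl.lo, 1.0, atol=0.02)

    def test_matches_brute_force_oracle_on_random_spectra(self):
        rng = np.random.default_rng(5)
        mz = np.linspace(0, 200, 4000)
        for trial in range(5):
            inten = np.zeros_like(mz)
            for center in rng.uniform(5, 195, 25):
                inten += rng.uniform(3, 60) * np.exp(
                    -0.5 * ((mz - center) / 0.08) ** 2
                )
            got = peak_pick(mz, inten, min_prominence=5.0, min_separation=0.5)
            want = brute_force_peaks(mz, inten, 5.0, 0.5)
            np.testing.assert_allclose(got.mz, want, atol=1e-9)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            peak_pick(np.array([]), np.array([]))

    def test_result_is_valid_peak_list(self):
        mz = np.linspace(0, 50, 1000)
        inten = 30 * np.exp(-0.5 * ((mz - 10) / 0.1) ** 2) + 30 * np.exp(
            -0.5 * ((mz - 10.4) / 0.1) ** 2
        )
        pl = peak_pick(mz, inten, min_separation=0.3)
        assert isinstance(pl, PeakList)
        assert np.all(pl.lo < pl.hi)
        assert np.all((pl.mz >= pl.lo) & (pl.mz < pl.hi))
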