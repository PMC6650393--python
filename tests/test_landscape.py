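"""Binned KDE, minus-log free energy, peaks, pooling and contours."""

import shutil
import subprocess

import numpy as np
import pytest

from hvmap import (
    HVMPoint,
    HVMSeries,
    LandscapeGrid,
    binned_kde2d,
    contour_polylines,
    peak_position,
    pool_runs,
    to_free_energy,
)
from hvmap.landscape import ZERO_DENSITY_CAP, write_grid_tsv, write_peaks_tsv
from .oracles import brute_force_peak


def _gauss_points(rng, mu, sd, n):
    return rng.normal(mu, sd, size=(n, 2))


class TestBinnedKde:
    def test_density_integrates_to_one(self, rng):
        for n in (50, 2000):
            g = binned_kde2d(_gauss_points(rng, [45, 5], [4, 6], n))
            assert g.values.min() >= 0
            assert g.values.sum() * g.cell_area() == pytest.approx(1.0, abs=1e-6)

    def test_single_tight_cluster_peaks_at_mean(self, rng):
        pts = _gauss_points(rng, [40.0, -10.0], [0.05, 0.05], 500)
        g = binned_kde2d(pts, bandwidths=(0.5, 0.5))
        pk = peak_position(g)
        assert pk.dE_phi == pytest.approx(40.0, abs=0.51)
        assert pk.dF_delta == pytest.approx(-10.0, abs=0.51)

    def test_explicit_bandwidths_respected(self, rng):
        g = binned_kde2d(_gauss_points(rng, [0, 0], [1, 1], 100),
                         bandwidths=(2.0, 3.0))
        assert g.bandwidths == (2.0, 3.0)

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            binned_kde2d(np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError, match="bandwidth"):
            binned_kde2d(np.ones((10, 2)))  # zero spread, no default bandwidth

    def test_matches_r_kernsmooth_bkde2d(self, rng, tmp_path):
        """Independent oracle: R's bkde2D on identical inputs and grid."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the KDE oracle check")
        pts = _gauss_points(rng, [45.0, 5.0], [4.0, 6.0], 2000)
        bw = (1.3, 1.9)
        g = binned_kde2d(pts, bandwidths=bw, gridsize=(64, 64))
        np.savetxt(tmp_path / "pts.tsv", pts, delimiter="\t")
        script = tmp_path / "kde.R"
        script.write_text(
            'library(KernSmooth)\n'
            f'x <- as.matrix(read.table("{tmp_path}/pts.tsv"))\n'
            f'est <- bkde2D(x, bandwidth=c({bw[0]}, {bw[1]}), '
            f'gridsize=c(64L, 64L), range.x=list('
            f'c({g.dE_grid[0]}, {g.dE_grid[-1]}), '
            f'c({g.dF_grid[0]}, {g.dF_grid[-1]})))\n'
            f'write.table(est$fhat, "{tmp_path}/fhat.tsv", '
            'row.names=FALSE, col.names=FALSE)\n')
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        fhat = np.loadtxt(tmp_path / "fhat.tsv")
        assert np.abs(g.values - fhat).max() <= 1e-3 * g.values.max()


class TestFreeEnergy:
    def _uniform_density(self):
        v = np.full((8, 8), 1.0)
        v /= v.sum() * 1.0
        return LandscapeGrid(np.arange(8.0), np.arange(8.0), v, (1.0, 1.0),
                             "density")

    def test_uniform_density_is_flat_zero(self):
        F = to_free_energy(self._uniform_density())
        assert F.kind == "free_energy"
        assert np.allclose(F.values, 0.0)

    def test_minimum_zero_at_density_mode(self, rng):
        g = binned_kde2d(_gauss_points(rng, [45, 5], [4, 6], 500))
        F = to_free_energy(g)
        assert F.values.min() == 0.0
        assert np.unravel_index(np.argmin(F.values), F.values.shape) == \
            np.unravel_index(np.argmax(g.values), g.values.shape)

    def test_density_ratio_e_gives_unit_difference(self):
        v = np.array([[np.e, 1.0], [1.0, 1.0]])
        v = v / (v.sum() * 1.0)
        g = LandscapeGrid(np.arange(2.0), np.arange(2.0), v, (1.0, 1.0), "density")
        F = to_free_energy(g)
        assert F.values[0, 1] - F.values[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_zero_density_capped(self):
        v = np.array([[1.0, 0.0], [0.5, 0.25]])
        v = v / v.sum()
        g = LandscapeGrid(np.arange(2.0), np.arange(2.0), v, (1.0, 1.0), "density")
        F = to_free_energy(g)
        assert F.values[0, 1] == ZERO_DENSITY_CAP

    def test_antitonic_with_density(self, rng):
        g = binned_kde2d(_gauss_points(rng, [0, 0], [2, 2], 300))
        F = to_free_energy(g)
        d = g.values.ravel()
        f = F.values.ravel()
        order = np.argsort(d)
        assert np.all(np.diff(f[order]) <= 1e-12)


class TestPeaks:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random((20, 25))
        g = LandscapeGrid(np.linspace(0, 19, 20), np.linspace(0, 24, 25),
                          v / v.sum(), (1.0, 1.0), "density")
        pk = peak_position(g, "r")
        i, j = brute_force_peak(g.values)
        assert pk.dE_phi == g.dE_grid[i] and pk.dF_delta == g.dF_grid[j]

    def test_tie_breaks_to_smallest_dE_then_dF(self):
        v = np.zeros((3, 3))
        v[2, 0] = v[0, 2] = v[0, 1] = 1.0  # three-way tie
        g = LandscapeGrid(np.arange(3.0), np.arange(3.0), v / v.sum(),
                          (1.0, 1.0), "density")
        pk = peak_position(g)
        assert (pk.dE_phi, pk.dF_delta) == (0.0, 1.0)


class TestPoolRuns:
    def _series(self, pts, run_id):
        return HVMSeries(
            [HVMPoint(a, b, frame_index=i, run_id=run_id, lobe="L")
             for i, (a, b) in enumerate(pts)], run_id=run_id, lobe="L")

    def test_identical_runs_share_the_pooled_peak(self, rng):
        pts = _gauss_points(rng, [45, 0], [2, 2], 400)
        runs = [self._series(pts, f"run{i}") for i in range(6)]
        pooled, peaks = pool_runs(runs, bandwidths=(1.0, 1.0))
        ii, jj = np.unravel_index(np.argmin(pooled.values), pooled.values.shape)
        pooled_peak = (pooled.dE_grid[ii], pooled.dF_grid[jj])
        for pk in peaks:
            assert pk.dE_phi == pytest.approx(pooled_peak[0], abs=1e-9)
            assert pk.dF_delta == pytest.approx(pooled_peak[1], abs=1e-9)

    def test_disjoint_modes_stay_bimodal(self, rng):
        a = self._series(_gauss_points(rng, [30, -10], [1.5, 1.5], 500), "a")
        b = self._series(_gauss_points(rng, [60, 10], [1.5, 1.5], 500), "b")
        pooled, peaks = pool_runs([a, b], bandwidths=(1.5, 1.5))
        assert {round(p.dE_phi, -1) for p in peaks} == {30.0, 60.0}
        # pooled density has a distinct local maximum near each mode
        dens = np.exp(-pooled.values)
        n_modes = _count_modes(dens, 0.2)
        assert n_modes == 2

    def test_single_run_identity(self, rng):
        s = self._series(_gauss_points(rng, [40, 0], [2, 2], 300), "solo")
        pooled, peaks = pool_runs([s], bandwidths=(1.0, 1.0))
        solo = to_free_energy(binned_kde2d(s.angles(), (1.0, 1.0)))
        assert np.allclose(pooled.values, solo.values)
        assert len(peaks) == 1

    def test_lobe_mismatch_rejected(self, rng):
        a = self._series(_gauss_points(rng, [30, 0], [1, 1], 50), "a")
        b = self._series(_gauss_points(rng, [30, 0], [1, 1], 50), "b")
        b.lobe = "other"
        for p in b.points:
            object.__setattr__(p, "lobe", "other")
        with pytest.raises(ValueError, match="lobes"):
            pool_runs([a, b])


def _count_modes(dens: np.ndarray, rel_floor: float) -> int:
    """Strict 8-neighbour local maxima above rel_floor × global max."""
    n = 0
    floor = rel_floor * dens.max()
    for i in range(1, dens.shape[0] - 1):
        for j in range(1, dens.shape[1] - 1):
            w = dens[i - 1:i + 2, j - 1:j + 2]
            if dens[i, j] >= floor and dens[i, j] == w.max() \
                    and np.sum(w == w.max()) == 1:
                n += 1
    return n


class TestContoursAndExport:
    def test_contours_enclose_the_basin(self, rng):
        g = binned_kde2d(_gauss_points(rng, [45, 0], [3, 3], 2000),
                         bandwidths=(1.5, 1.5))
        F = to_free_energy(g)
        lines = contour_polylines(F)
        assert 1.0 in lines and len(lines[1.0]) >= 1
        # the level-1 contour stays within ~one kernel width of the F=1 set
        ring = np.vstack(lines[1.0])
        assert ring[:, 0].min() > 35 and ring[:, 0].max() < 55

    def test_grid_and_peak_export(self, rng, tmp_path):
        g = binned_kde2d(_gauss_points(rng, [45, 0], [3, 3], 200),
                         gridsize=(16, 16))
        write_grid_tsv(g, tmp_path / "grid.tsv")
        write_peaks_tsv([peak_position(g, "r1")], tmp_path / "peaks.tsv")
        grid_rows = (tmp_path / "grid.tsv").read_text().strip().splitlines()
        assert len(grid_rows) == 16 * 16 + 1
        assert (tmp_path / "peaks.tsv").read_text().startswith("run_id")
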