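"""PSCF gridding against brute-force enumeration, weighting, end-to-end."""

import numpy as np
import pandas as pd
import pytest

from pahkit.data_model import TrajectorySet
from pahkit.pscf import (
    DEFAULT_WEIGHT_SCHEME, PscfGrid, compute_pscf, flag_exceedance_days,
    weight_pscf,
)
from pahkit.synthetic import SyntheticSpec, generate_samples, generate_trajectories
from tests.conftest import make_record


def traj_set(trajs):
    """trajs: {traj_id: (date, site, [(lat, lon), ...])}."""
    rows = []
    for tid, (date, site, pts) in trajs.items():
        for step, (lat, lon) in enumerate(pts):
            rows.append((tid, pd.Timestamp(date), site, step,
                         float(step - len(pts) + 1), lat, lon))
    return TrajectorySet(pd.DataFrame(
        rows, columns=["traj", "date", "site", "step", "age_h", "lat", "lon"]))


class TestFlags:
    def test_strict_threshold(self):
        recs = [make_record(date="2020-01-01", pm25=40.0),
                make_record(date="2020-01-02", pm25=35.0)]
        flags = flag_exceedance_days(recs, 35.0)
        assert flags[(pd.Timestamp("2020-01-01"), "A")]
        assert not flags[(pd.Timestamp("2020-01-02"), "A")]

    def test_all_clean_series_gives_zero_or_undefined_pscf(self):
        recs = [make_record(date=f"2020-01-{i+1:02d}", pm25=10.0) for i in range(4)]
        ts = traj_set({i + 1: (f"2020-01-{i+1:02d}", "A", [(40.2, 110.2)])
                       for i in range(4)})
        grid = compute_pscf(ts, flag_exceedance_days(recs, 35.0), resolution=1.0)
        defined = grid.pscf[~np.isnan(grid.pscf)]
        assert (defined == 0).all()


class TestComputePscf:
    def test_ten_trajectories_four_flagged(self):
        trajs, flags = {}, {}
        for i in range(10):
            d = pd.Timestamp(f"2020-02-{i+1:02d}")
            trajs[i + 1] = (d, "A", [(40.5, 110.5)])
            flags[(d, "A")] = i < 4
        grid = compute_pscf(traj_set(trajs), flags, resolution=1.0)
        cell = grid.pscf[~np.isnan(grid.pscf)]
        assert cell.item() == pytest.approx(0.4)

    def test_unvisited_cell_is_undefined_not_zero(self):
        d = pd.Timestamp("2020-02-01")
        grid = compute_pscf(traj_set({1: (d, "A", [(40.5, 110.5)])}),
                            {(d, "A"): True}, resolution=1.0)
        assert np.isnan(grid.pscf[grid.n == 0]).all()
        assert (grid.n == 0).any()

    def test_all_flagged_gives_unity_in_visited_cells(self):
        trajs, flags = {}, {}
        for i in range(5):
            d = pd.Timestamp(f"2020-03-{i+1:02d}")
            trajs[i + 1] = (d, "A", [(40.0 + i, 108.0 + i), (41.0 + i, 109.0 + i)])
            flags[(d, "A")] = True
        grid = compute_pscf(traj_set(trajs), flags, resolution=1.0)
        assert np.all(grid.pscf[grid.n > 0] == 1.0)

    def test_trajectory_counted_once_per_cell(self):
        d = pd.Timestamp("2020-02-01")
        # 3 endpoints in the same 1-degree cell
        ts = traj_set({1: (d, "A", [(40.1, 110.1), (40.2, 110.2), (40.3, 110.3)])})
        grid = compute_pscf(ts, {(d, "A"): False}, resolution=1.0)
        assert grid.n.max() == 1
        grid_ep = compute_pscf(ts, {(d, "A"): False}, resolution=1.0,
                               count_unit="endpoint")
        assert grid_ep.n.max() == 3

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed):
        """n, m, pscf on a 3x3 grid equal exhaustive per-trajectory counting."""
        rng = np.random.default_rng(seed)
        bounds = ((40.0, 43.0), (110.0, 113.0))
        n_traj = int(rng.integers(2, 6))
        trajs, flags = {}, {}
        for t in range(n_traj):
            d = pd.Timestamp(f"2020-04-{t+1:02d}")
            pts = [(rng.uniform(39.5, 43.5), rng.uniform(109.5, 113.5))
                   for _ in range(int(rng.integers(1, 11)))]
            trajs[t + 1] = (d, "A", pts)
            flags[(d, "A")] = bool(rng.integers(0, 2))
        grid = compute_pscf(traj_set(trajs), flags, resolution=1.0, bounds=bounds)
        assert grid.n.shape == (3, 3)

        n_o = np.zeros((3, 3), int)
        m_o = np.zeros((3, 3), int)
        for tid, (d, site, pts) in trajs.items():
            seen = set()
            for lat, lon in pts:
                i = int(np.floor(lat - 40.0))
                j = int(np.floor(lon - 110.0))
                if 0 <= i < 3 and 0 <= j < 3:
                    seen.add((i, j))
            for i, j in seen:
                n_o[i, j] += 1
                if flags[(d, site)]:
                    m_o[i, j] += 1
        np.testing.assert_array_equal(grid.n, n_o)
        np.testing.assert_array_equal(grid.m, m_o)
        expected = np.where(n_o > 0, m_o / np.maximum(n_o, 1), np.nan)
        np.testing.assert_allclose(grid.pscf, expected)

    def test_refining_resolution_never_loses_counts(self):
        rng = np.random.default_rng(7)
        trajs, flags = {}, {}
        for t in range(5):
            d = pd.Timestamp(f"2020-05-{t+1:02d}")
            pts = [(rng.uniform(40, 42), rng.uniform(110, 112)) for _ in range(8)]
            trajs[t + 1] = (d, "A", pts)
            flags[(d, "A")] = True
        bounds = ((40.0, 42.0), (110.0, 112.0))
        coarse = compute_pscf(traj_set(trajs), flags, resolution=1.0, bounds=bounds)
        fine = compute_pscf(traj_set(trajs), flags, resolution=0.5, bounds=bounds)
        for i in range(coarse.n.shape[0]):
            for j in range(coarse.n.shape[1]):
                child = fine.n[2 * i:2 * i + 2, 2 * j:2 * j + 2].sum()
                assert child >= coarse.n[i, j]

    def test_missing_flag_is_an_error(self):
        ts = traj_set({1: ("2020-02-01", "A", [(40.5, 110.5)])})
        with pytest.raises(KeyError):
            compute_pscf(ts, {}, resolution=1.0)


class TestWeighting:
    @staticmethod
    def _grid(n):
        n = np.asarray(n)
        m = (n > 0).astype(int)
        pscf = np.where(n > 0, m / np.maximum(n, 1), np.nan)
        return PscfGrid(np.arange(n.shape[0] + 1.0), np.arange(n.shape[1] + 1.0),
                        n, m, pscf, threshold=35.0, resolution=1.0)

    def test_high_count_cell_keeps_full_value(self):
        # one cell far above 3x the mean count over nonempty cells
        n = np.array([[40, 1], [1, 2]])  # mean over nonempty = 11
        g = self._grid(n)
        g.pscf = np.where(n > 0, 0.6, np.nan)
        weight_pscf(g)
        assert g.wpscf[0, 0] == pytest.approx(0.6)

    def test_sparse_cell_strongly_damped(self):
        n = np.array([[40, 1], [1, 1]])
        g = self._grid(n)
        g.pscf = np.where(n > 0, 1.0, np.nan)
        weight_pscf(g)
        assert g.wpscf[0, 1] == pytest.approx(0.05)

    def test_uniform_counts_all_damped_to_lowest_band(self):
        n = np.full((3, 3), 5)
        g = self._grid(n)
        g.pscf = np.full((3, 3), 0.8)
        weight_pscf(g)
        np.testing.assert_allclose(g.wpscf, 0.05 * 0.8)

    def test_wpscf_bounded_by_pscf(self):
        rng = np.random.default_rng(1)
        n = rng.integers(0, 20, (5, 5))
        g = self._grid(n)
        weight_pscf(g)
        defined = g.n > 0
        assert (g.wpscf[defined] <= g.pscf[defined] + 1e-12).all()
        assert (g.wpscf[defined] >= 0).all()


class TestEndToEnd:
    @pytest.mark.parametrize("seed", range(5))
    def test_argmax_wpscf_falls_in_the_emission_sector(self, seed):
        # a compact emission zone and a full campaign of arrivals: clean-day
        # dilution then separates the zone from its transport corridor
        sector = ((46.0, 48.0), (100.0, 102.0), 1.0)
        spec = SyntheticSpec(n_days=446, n_sites=1, seed=seed,
                             source_sectors=(sector,))
        records, _, _ = generate_samples(spec)
        ts = generate_trajectories(spec, records)
        flags = flag_exceedance_days(records, spec.exceed_threshold)
        grid = weight_pscf(compute_pscf(ts, flags, resolution=1.0))
        w = np.where(np.isnan(grid.wpscf), -1, grid.wpscf)
        i, j = np.unravel_index(np.argmax(w), w.shape)
        lat, lon = grid.lat_centers[i], grid.lon_centers[j]
        (la0, la1), (lo0, lo1), _ = sector
        assert la0 <= lat <= la1 and lo0 <= lon <= lo1
        # and the sector outranks the background on the median defined cell
        (i0, i1) = np.searchsorted(grid.lat_edges, (la0, la1))
        (j0, j1) = np.searchsorted(grid.lon_edges, (lo0, lo1))
        inside = grid.wpscf[i0:i1, j0:j1]
        mask = np.zeros_like(grid.wpscf, dtype=bool)
        mask[i0:i1, j0:j1] = True
        outside = grid.wpscf[~mask]
        assert (np.nanmedian(inside) > np.nanmedian(outside[~np.isnan(outside)]))
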