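import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioscatter.geometry import (
    CellStatus,
    HeightBands,
    RadarSite,
    assign_gates_to_columns,
    beam_height,
    build_cvp_lattice,
    gate_ground_position,
    terrain_mask,
)
from bioscatter.raster import Raster


class TestBeamHeight:
    @pytest.mark.parametrize(
        "rng_km, elev, alt, expected, tol",
        [
            (0.0, 0.5, 50.0, 50.0, 1e-9),  # zero range returns antenna altitude
            (30.0, 0.5, 0.0, 315.0, 1.0),  # 4/3-earth formula, low beam
            (10.0, 4.0, 0.0, 703.0, 1.0),  # 4/3-earth formula, steep beam
        ],
    )
    def test_reference_values(self, rng_km, elev, alt, expected, tol):
        assert beam_height(rng_km, elev, alt) == pytest.approx(expected, abs=tol)

    def test_negative_range_rejected(self):
        with pytest.raises(ValueError):
            beam_height(-1.0, 0.5)

    @given(
        r=st.floats(0.1, 200.0),
        el=st.floats(0.0, 10.0),
        dr=st.floats(0.1, 10.0),
        de=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_range_and_elevation(self, r, el, dr, de):
        h = beam_height(r, el)
        assert beam_height(r + dr, el) > h
        assert beam_height(r, el + de) > h

    def test_vertical_limit(self):
        # at 90 degrees elevation the beam goes straight up: h -> range
        h = beam_height(10.0, 89.999, 0.0)
        assert h == pytest.approx(10_000.0, rel=1e-3)


class TestLattice:
    def test_cell_counts(self, lattice):
        counts = lattice.counts()
        assert len(lattice.cells) == 144
        assert counts["retained"] == 127
        assert counts["central_clutter"] == 16
        assert counts["corner_unprocessed"] == 1

    def test_corner_is_upper_right(self, lattice):
        corner = [c for c in lattice.cells if c.status is CellStatus.CORNER_UNPROCESSED]
        assert len(corner) == 1
        assert (corner[0].easting, corner[0].northing) == (27.5, 27.5)

    def test_row_col_convention(self, lattice):
        # row 0 = northernmost, col 0 = westernmost
        assert (lattice.cell(0, 0).easting, lattice.cell(0, 0).northing) == (-27.5, 27.5)
        assert (lattice.cell(11, 11).easting, lattice.cell(11, 11).northing) == (27.5, -27.5)

    def test_offsets_are_odd_multiples_of_2p5(self, lattice):
        for c in lattice.cells:
            for v in (c.easting, c.northing):
                assert abs(v) in {2.5, 7.5, 12.5, 17.5, 22.5, 27.5}

    def test_central_block_is_4x4(self, lattice):
        clutter = [c for c in lattice.cells if c.status is CellStatus.CENTRAL_CLUTTER]
        assert all(abs(c.easting) <= 7.5 and abs(c.northing) <= 7.5 for c in clutter)

    def test_export_includes_coordinates(self, lattice, site, tmp_path):
        path = tmp_path / "lattice.csv"
        lattice.export_csv(path, site)
        import pandas as pd

        df = pd.read_csv(path)
        assert {"site_id", "grid_row", "grid_col", "easting_km", "northing_km", "lat",
                "lon", "status"} <= set(df.columns)
        assert len(df) == 144


class TestGateGroundPosition:
    @pytest.mark.parametrize(
        "az, r, el, east, north",
        [
            (0.0, 10.0, 0.0, 0.0, 10.0),  # due north
            (90.0, 10.0, 0.0, 10.0, 0.0),  # due east
            (45.0, 10.0, 4.0, 10.0 * np.cos(np.deg2rad(4.0)) / np.sqrt(2),
             10.0 * np.cos(np.deg2rad(4.0)) / np.sqrt(2)),
        ],
    )
    def test_projection(self, site, az, r, el, east, north):
        locus = gate_ground_position(site, el, az, r)
        assert locus.easting == pytest.approx(east, abs=1e-9)
        assert locus.northing == pytest.approx(north, abs=1e-9)

    def test_bad_azimuth_rejected(self, site):
        with pytest.raises(ValueError):
            gate_ground_position(site, 0.5, 360.0, 10.0)


class TestHeightBands:
    def test_half_open_membership(self):
        idx = HeightBands.band_index([99.9, 100.0, 299.9, 650.0, 2099.9, 2100.0])
        assert list(idx) == [-1, 0, 0, 2, 9, -1]

    def test_band_650m_is_band_500(self):
        assert HeightBands.lower_edge(HeightBands.band_index(np.array([650.0]))[0]) == 500


class TestGateAssignment:
    def test_each_gate_maps_to_at_most_one_cell(self, mapping):
        for el, ci in mapping.cell_index.items():
            assert ci.max() < 144
            # band defined exactly where a cell is assigned
            assert np.array_equal(ci >= 0, mapping.band_index[el] >= 0)

    def test_band_counts_sum_to_assigned_gates(self, mapping):
        total = sum(int((ci >= 0).sum()) for ci in mapping.cell_index.values())
        assert mapping.counts.sum() == total

    def test_no_gates_in_removed_cells(self, mapping, lattice):
        from bioscatter.geometry import LATTICE_N

        for cell in lattice.cells:
            if cell.status is not CellStatus.RETAINED:
                assert mapping.counts[cell.grid_row * LATTICE_N + cell.grid_col].sum() == 0

    def test_vertical_sampling_pattern(self, mapping, lattice):
        # far cells miss the lowest band (beam overshoots); near retained
        # cells miss the highest band (beam tops out below 2100 m)
        from bioscatter.geometry import LATTICE_N

        corner = mapping.counts[0]  # row 0, col 0: ~39 km from radar
        assert corner[0] == 0 and corner.sum() > 0
        near = lattice.cell(4, 2)  # (-17.5, 7.5): ~19 km
        counts = mapping.counts[near.grid_row * LATTICE_N + near.grid_col]
        assert counts[0] > 0

    def test_assigned_gate_within_radius(self, site, lattice, mapping):
        offsets = -27.5 + 5.0 * np.arange(12)
        el = site.elevation_angles[0]
        ci = mapping.cell_index[el]
        az = site.azimuths()
        rng_km = site.gate_ranges(45.0)
        g = rng_km[None, :] * np.cos(np.deg2rad(el))
        east = g * np.sin(np.deg2rad(az))[:, None]
        north = g * np.cos(np.deg2rad(az))[:, None]
        sel = ci >= 0
        rows, cols = ci[sel] // 12, ci[sel] % 12
        d2 = (east[sel] - offsets[cols]) ** 2 + (north[sel] + offsets[rows]) ** 2
        assert d2.max() <= 2.5**2 + 1e-9


class TestTerrainMask:
    def _flat(self, height=0.0):
        return Raster(np.full((121, 121), height), -30.25, -30.25, 0.5)

    def test_flat_terrain_blocks_nothing(self, lattice, site):
        masked = terrain_mask(lattice, self._flat(0.0), site)
        assert masked.counts()["terrain_blocked"] == 0

    def test_ridge_blocks_cells_behind_it(self, lattice, site):
        vals = np.zeros((121, 121))
        x = -30.25 + (np.arange(121) + 0.5) * 0.5
        vals[:, (x > 8.75) & (x < 10.75)] = 500.0  # 2 km-thick north-south wall
        masked = terrain_mask(lattice, Raster(vals, -30.25, -30.25, 0.5), site)
        behind = [c for c in masked.cells if c.easting > 10.75
                  and c.status in (CellStatus.RETAINED, CellStatus.TERRAIN_BLOCKED)]
        assert behind and all(c.status is CellStatus.TERRAIN_BLOCKED for c in behind)
        west = [c for c in masked.cells if c.easting < 8.75
                and c.status is CellStatus.TERRAIN_BLOCKED]
        assert not west

    def test_blocking_monotone_in_terrain(self, lattice, site, rng):
        vals = 200.0 * rng.random((121, 121))
        low = terrain_mask(lattice, Raster(vals, -30.25, -30.25, 0.5), site)
        high = terrain_mask(lattice, Raster(vals + 150.0, -30.25, -30.25, 0.5), site)
        low_blocked = {(c.grid_row, c.grid_col) for c in low.cells
                       if c.status is CellStatus.TERRAIN_BLOCKED}
        high_blocked = {(c.grid_row, c.grid_col) for c in high.cells
                        if c.status is CellStatus.TERRAIN_BLOCKED}
        assert low_blocked <= high_blocked

    def test_raster_must_cover_box(self, lattice, site):
        small = Raster(np.zeros((10, 10)), -5.0, -5.0, 1.0)
        with pytest.raises(ValueError):
            terrain_mask(lattice, small, site)


class TestRadarSite:
    def test_invalid_elevations_rejected(self):
        with pytest.raises(ValueError):
            RadarSite("x", elevation_angles=(2.0, 1.0))
        with pytest.raises(ValueError):
            RadarSite("x", elevation_angles=(0.0, 1.0))

    def test_default_azimuth_sectors(self, site):
        assert site.n_azimuths == 360
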