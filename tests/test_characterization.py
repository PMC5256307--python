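"""Zonal CF aggregation, pressure mapping, unit conversion, CF expansion."""

import numpy as np
import pytest

from ecofoot.characterization import (
    DEFAULT_MAPPING,
    CountryMaskSet,
    GeoTransform,
    RasterLayer,
    aggregate_cf,
    combine_pathway_cf,
    expand_cf,
    forestry_cf,
    map_pressures,
    uniform_cf,
)
from ecofoot.errors import (
    AlignmentError,
    AssemblyError,
    DataError,
    MappingError,
    ParameterError,
    StructuralError,
)
from ecofoot.mrio import RegionSectorIndex, SatelliteAccount


def _one_country(pressures, factors, nodata=None):
    p = RasterLayer(values=np.array([pressures], dtype=float), nodata=nodata)
    c = RasterLayer(values=np.array([factors], dtype=float), nodata=nodata)
    m = CountryMaskSet(mask=np.zeros((1, len(pressures)), dtype=int), regions=("A",))
    return p, c, m


class TestAggregateCF:
    def test_pressure_weighted_mean(self):
        p, c, m = _one_country([2.0, 3.0], [1.0, 2.0])
        assert aggregate_cf(p, c, m)[0] == pytest.approx((2 * 1 + 3 * 2) / 5)

    def test_constant_factor_recovered_exactly(self, rng):
        vals = rng.random((5, 5)) + 0.1
        p = RasterLayer(values=vals)
        c = RasterLayer(values=np.full((5, 5), 3.25))
        m = CountryMaskSet(mask=np.zeros((5, 5), dtype=int), regions=("A",))
        assert aggregate_cf(p, c, m)[0] == 3.25

    def test_zero_pressure_falls_back_to_arithmetic_mean(self):
        p, c, m = _one_country([0.0, 0.0], [1.0, 3.0])
        assert aggregate_cf(p, c, m)[0] == pytest.approx(2.0)

    def test_scale_invariance_in_pressure_weights(self, rng):
        vals = rng.random((4, 6))
        facs = rng.random((4, 6)) * 10
        m = CountryMaskSet(
            mask=np.repeat(np.arange(2), 12).reshape(4, 6), regions=("A", "B")
        )
        base = aggregate_cf(RasterLayer(values=vals), RasterLayer(values=facs), m)
        for scale in (1e-6, 3.7, 1e9):
            scaled = aggregate_cf(
                RasterLayer(values=vals * scale), RasterLayer(values=facs), m
            )
            np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_bounded_by_country_cell_extrema(self, rng):
        vals = rng.random((8, 8))
        facs = rng.random((8, 8))
        mask = (np.arange(64).reshape(8, 8) // 22).astype(int)
        m = CountryMaskSet(mask=mask, regions=("A", "B", "C"))
        out = aggregate_cf(RasterLayer(values=vals), RasterLayer(values=facs), m)
        for i in range(3):
            cells = facs[mask == i]
            assert cells.min() - 1e-12 <= out[i] <= cells.max() + 1e-12

    def test_nodata_cells_excluded_from_sums(self):
        p, c, m = _one_country([2.0, 3.0, -9999.0], [1.0, 2.0, 50.0], nodata=-9999.0)
        c.values[0, 2] = 50.0
        p.values[0, 2] = -9999.0
        assert aggregate_cf(p, c, m)[0] == pytest.approx(1.6)

    def test_grid_mismatch_raises(self):
        p = RasterLayer(values=np.zeros((2, 2)))
        c = RasterLayer(values=np.zeros((3, 3)))
        m = CountryMaskSet(mask=np.zeros((2, 2), dtype=int), regions=("A",))
        with pytest.raises(AlignmentError):
            aggregate_cf(p, c, m)

    def test_transform_mismatch_raises(self):
        p = RasterLayer(values=np.zeros((2, 2)), transform=GeoTransform(dx=0.5, dy=0.5))
        c = RasterLayer(values=np.zeros((2, 2)))
        m = CountryMaskSet(mask=np.zeros((2, 2), dtype=int), regions=("A",))
        with pytest.raises(AlignmentError):
            aggregate_cf(p, c, m)

    def test_negative_pressure_cell_raises(self):
        p, c, m = _one_country([2.0, -1.0], [1.0, 2.0])
        with pytest.raises(DataError):
            aggregate_cf(p, c, m)

    def test_country_without_cells_warns_and_returns_zero(self):
        p = RasterLayer(values=np.ones((2, 2)))
        c = RasterLayer(values=np.ones((2, 2)))
        m = CountryMaskSet(mask=np.zeros((2, 2), dtype=int), regions=("A", "B"))
        with pytest.warns(UserWarning, match="B"):
            out = aggregate_cf(p, c, m)
        assert out[1] == 0.0


class TestUniformCF:
    def test_every_country_gets_the_value(self):
        np.testing.assert_array_equal(uniform_cf(2.5, ["A", "B", "C"]), [2.5] * 3)
        np.testing.assert_array_equal(uniform_cf(0.0, ["A"]), [0.0])

    def test_negative_value_rejected(self):
        with pytest.raises(DataError):
            uniform_cf(-1.0, ["A"])


class TestExpandCF:
    def test_column_repetition(self):
        idx = RegionSectorIndex(["A", "B"], ["s1", "s2"])
        np.testing.assert_array_equal(
            expand_cf(np.array([[1.0, 3.0]]), idx), [[1.0, 1.0, 3.0, 3.0]]
        )

    def test_single_region(self):
        idx = RegionSectorIndex(["A"], ["s1", "s2", "s3"])
        np.testing.assert_array_equal(
            expand_cf(np.array([[7.0]]), idx), [[7.0, 7.0, 7.0]]
        )

    def test_block_sums_reproduce_country_totals(self, rng):
        idx = RegionSectorIndex(["A", "B", "C"], ["s1", "s2"])
        C = rng.random((4, 3))
        v = rng.random(idx.size)
        expanded = expand_cf(C, idx)
        # weighting any s-vector by the expanded factors and summing each
        # country block equals the country factor times the block total
        for i, region in enumerate(idx.regions):
            block = idx.region_slice(region)
            np.testing.assert_allclose(
                (expanded[:, block] * v[block]).sum(axis=1),
                C[:, i] * v[block].sum(),
                rtol=1e-12,
            )

    def test_region_count_mismatch_raises(self):
        idx = RegionSectorIndex(["A", "B"], ["s1"])
        with pytest.raises(StructuralError):
            expand_cf(np.ones((1, 3)), idx)


class TestMapPressures:
    def _satellite(self, labels, units, idx=None):
        idx = idx or RegionSectorIndex(["A"], ["s"])
        F = np.ones((len(labels), idx.size))
        return SatelliteAccount(index=idx, labels=labels, F=F, units=units)

    def test_gg_to_kg_conversion(self):
        sat = self._satellite(("CO2",), ("Gg",))
        mapped = map_pressures(sat)
        assert mapped.pathways == ("climate change",)
        assert mapped.units == ("kg",)
        np.testing.assert_array_equal(mapped.F, [[1e6]])

    def test_ha_to_km2_conversion(self):
        sat = self._satellite(("pasture",), ("Ha",))
        mapped = map_pressures(sat)
        assert mapped.units == ("km2",)
        np.testing.assert_allclose(mapped.F, [[1e-2]])
        assert mapped.pathways == ("land occupation, pasture",)

    def test_conversions_invert_to_machine_precision(self):
        from ecofoot.characterization import UNIT_CONVERSIONS

        for conv in UNIT_CONVERSIONS.values():
            assert (123.456 * conv) / conv == pytest.approx(123.456, rel=1e-15)

    def test_unmapped_label_raises_listing_it(self):
        sat = self._satellite(("unknown_gas",), ("Gg",))
        with pytest.raises(MappingError, match="unknown_gas"):
            map_pressures(sat)

    def test_ignore_directive_drops_row(self):
        sat = self._satellite(("CO2", "unknown_gas"), ("Gg", "Gg"))
        mapped = map_pressures(sat, ignore=("unknown_gas",))
        assert mapped.labels == ("CO2",)


class TestForestryCF:
    def test_weighted_mean(self):
        np.testing.assert_allclose(
            forestry_cf(np.array([2.0]), np.array([4.0]), (0.5, 0.5)), [3.0]
        )

    def test_degenerate_weight_returns_intensive(self):
        intensive = np.array([1.0, 2.0])
        np.testing.assert_array_equal(
            forestry_cf(intensive, np.array([9.0, 9.0]), (1.0, 0.0)), intensive
        )

    def test_identical_vectors_invariant_to_weights(self):
        v = np.array([1.5, 2.5])
        for w in [(0.3, 0.7), (0.9, 0.1)]:
            np.testing.assert_allclose(forestry_cf(v, v, w), v)

    def test_bad_weights_rejected(self):
        with pytest.raises(ParameterError):
            forestry_cf(np.array([1.0]), np.array([1.0]), (0.6, 0.5))


class TestCombinePathwayCF:
    def _mapped(self):
        idx = RegionSectorIndex(["A", "B"], ["s"])
        sat = SatelliteAccount(
            index=idx,
            labels=("CO2", "CH4"),
            F=np.ones((2, 2)),
            units=("Gg", "Gg"),
        )
        return map_pressures(sat)

    def test_rows_follow_satellite_order_regardless_of_input_order(self):
        mapped = self._mapped()
        rows = {"CH4": np.array([3.0, 4.0]), "CO2": np.array([1.0, 2.0])}
        cf = combine_pathway_cf(rows, mapped, ("A", "B"))
        np.testing.assert_array_equal(cf.C, [[1.0, 2.0], [3.0, 4.0]])
        assert cf.labels == ("CO2", "CH4")

    def test_shared_pathway_keeps_both_rows(self):
        mapped = self._mapped()
        assert mapped.pathways == ("climate change", "climate change")
        cf = combine_pathway_cf(
            {"CO2": np.array([1.0, 1.0]), "CH4": np.array([2.0, 2.0])},
            mapped,
            ("A", "B"),
        )
        assert cf.C.shape == (2, 2)

    def test_missing_row_raises(self):
        mapped = self._mapped()
        with pytest.raises(AssemblyError, match="CH4"):
            combine_pathway_cf({"CO2": np.array([1.0, 1.0])}, mapped, ("A", "B"))


def test_default_mapping_covers_thirteen_pressures_eight_pathways():
    labels = DEFAULT_MAPPING.pressures()
    assert len(labels) == 13
    assert len(set(e.pathway for e in DEFAULT_MAPPING.entries)) == 8
    assert all(not DEFAULT_MAPPING.entry(g).spatial for g in ("CO2", "CH4", "N2O"))
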