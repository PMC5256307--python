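"""Footprint tensors, source attribution, transfers, and conservation."""

import numpy as np
import pytest

from ecofoot.errors import GroupingError, StructuralError, UnitError
from ecofoot.footprint import (
    AttributionTable,
    domestic_share,
    group_transfers,
    impact_footprint,
    resource_footprint,
    source_attribution,
    total_impact,
)
from ecofoot.mrio import RegionSectorIndex, leontief_inverse


def _single():
    idx = RegionSectorIndex(["A"], ["s"])
    f = np.array([[0.5]])
    L = leontief_inverse(np.array([[0.5]])).L
    Y = np.array([[1.0]])
    return idx, f, L, Y


class TestResourceFootprint:
    def test_scalar_chain(self):
        idx, f, L, Y = _single()
        fp = resource_footprint(f, L, Y, idx, ["p"], ["kg"])
        assert fp.aggregate[0, 0] == pytest.approx(1.0)

    def test_zero_demand_zero_footprint(self):
        idx, f, L, _ = _single()
        fp = resource_footprint(f, L, np.zeros((1, 1)), idx, ["p"], ["kg"])
        assert (fp.aggregate == 0).all() and (fp.source_resolved == 0).all()

    def test_source_columns_sum_to_aggregate(self, result):
        assert result.pressure.consistency_error() < 1e-10

    def test_conservation_against_total_direct_pressure(self, result):
        # Leontief attribution redistributes pressure but never creates it
        for p in range(len(result.mapped.labels)):
            total_direct = result.mapped.F[p].sum()
            total_attributed = result.pressure.aggregate[p].sum()
            assert total_attributed == pytest.approx(total_direct, rel=1e-9)

    def test_linearity_in_demand(self, rng):
        idx = RegionSectorIndex(["A", "B"], ["s1", "s2"])
        f = rng.random((2, 4))
        A = rng.random((4, 4)) * 0.15
        L = leontief_inverse(A).L
        Y1, Y2 = rng.random((4, 2)), rng.random((4, 2))
        fp = lambda Y: resource_footprint(f, L, Y, idx, ["p", "q"], ["kg", "kg"]).aggregate
        np.testing.assert_allclose(fp(Y1 + Y2), fp(Y1) + fp(Y2), rtol=1e-12)


class TestImpactFootprint:
    def test_uniform_factor_reduction(self, rng):
        idx = RegionSectorIndex(["A", "B"], ["s1", "s2"])
        f = rng.random((2, 4))
        L = leontief_inverse(rng.random((4, 4)) * 0.2).L
        Y = rng.random((4, 2))
        c = 2.0
        press = resource_footprint(f, L, Y, idx, ["p", "q"], ["kg", "kg"])
        imp = impact_footprint(np.full((2, 4), c), f, L, Y, idx, ["p", "q"])
        np.testing.assert_allclose(imp.aggregate, c * press.aggregate, rtol=1e-12)
        assert imp.units == ("PDF·yr", "PDF·yr")

    def test_zero_factor_zero_impact(self):
        idx, f, L, Y = _single()
        imp = impact_footprint(np.zeros((1, 1)), f, L, Y, idx, ["p"])
        assert (imp.aggregate == 0).all()

    def test_matches_brute_force_triple_sum(self, rng):
        # 2 regions, 1 sector, distinct country factors
        idx = RegionSectorIndex(["A", "B"], ["s"])
        f = rng.random((1, 2))
        A = rng.random((2, 2)) * 0.3
        L = leontief_inverse(A).L
        Y = rng.random((2, 2))
        C = np.array([[1.0, 5.0]])
        imp = impact_footprint(C, f, L, Y, idx, ["p"])
        for cns in range(2):
            brute = sum(
                C[0, i] * f[0, i] * L[i, j] * Y[j, cns]
                for i in range(2)
                for j in range(2)
            )
            assert imp.aggregate[0, cns] == pytest.approx(brute, rel=1e-12)

    def test_raising_one_country_factor_only_raises_its_sourced_impact(self, rng):
        idx = RegionSectorIndex(["A", "B"], ["s"])
        f = rng.random((1, 2)) + 0.1
        L = leontief_inverse(rng.random((2, 2)) * 0.3).L
        Y = rng.random((2, 2)) + 0.1
        base = impact_footprint(np.array([[1.0, 1.0]]), f, L, Y, idx, ["p"])
        bumped = impact_footprint(np.array([[2.0, 1.0]]), f, L, Y, idx, ["p"])
        # impacts sourced from A weakly increase, those from B are untouched
        assert (bumped.source_resolved[0, 0] >= base.source_resolved[0, 0]).all()
        np.testing.assert_array_equal(
            bumped.source_resolved[0, 1], base.source_resolved[0, 1]
        )

    def test_shape_mismatch_raises(self):
        idx, f, L, Y = _single()
        with pytest.raises(StructuralError):
            impact_footprint(np.ones((1, 2)), f, L, Y, idx, ["p"])


class TestSourceAttribution:
    def test_single_country_is_diagonal(self):
        idx, f, L, Y = _single()
        fp = resource_footprint(f, L, Y, idx, ["p"], ["kg"])
        attr = source_attribution("p", fp, idx)
        assert attr.table.shape == (1, 1)
        assert attr.table[0, 0] == pytest.approx(1.0)

    def test_column_sums_reproduce_aggregate_row(self, result, bundle):
        idx = bundle.accounts.index
        for lab in result.pressure.labels[:4]:
            attr = source_attribution(lab, result.pressure, idx)
            p = result.pressure.row(lab)
            np.testing.assert_allclose(
                attr.table.sum(axis=0), result.pressure.aggregate[p], rtol=1e-10
            )

    def test_matches_brute_force_block_aggregation(self, result, bundle):
        idx = bundle.accounts.index
        lab = result.pressure.labels[0]
        attr = source_attribution(lab, result.pressure, idx)
        src = result.pressure.source_resolved[0]
        for i, region in enumerate(idx.regions):
            block = idx.region_slice(region)
            np.testing.assert_allclose(attr.table[i], src[block].sum(axis=0))

    def test_unknown_pressure_raises(self, result, bundle):
        with pytest.raises(StructuralError):
            source_attribution("no-such-pressure", result.pressure, bundle.accounts.index)


class TestDomesticShare:
    def test_diagonal_only_gives_one(self):
        attr = AttributionTable("p", ("A", "B"), np.diag([2.0, 5.0]), "kg")
        np.testing.assert_allclose(domestic_share(attr), [1.0, 1.0])

    def test_zero_diagonal_gives_zero(self):
        attr = AttributionTable("p", ("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]), "kg")
        np.testing.assert_allclose(domestic_share(attr), [0.0, 0.0])

    def test_hand_example(self):
        attr = AttributionTable("p", ("A", "B"), np.array([[3.0, 1.0], [1.0, 1.0]]), "kg")
        np.testing.assert_allclose(domestic_share(attr), [0.75, 0.5])

    def test_zero_column_yields_zero_share(self):
        attr = AttributionTable("p", ("A", "B"), np.array([[1.0, 0.0], [0.0, 0.0]]), "kg")
        np.testing.assert_allclose(domestic_share(attr), [1.0, 0.0])


class TestGroupTransfers:
    def test_single_group_totals_everything(self):
        attr = AttributionTable("p", ("A", "B"), np.arange(4.0).reshape(2, 2), "kg")
        tr = group_transfers(attr, {"A": "G", "B": "G"})
        assert tr.absolute[0, 0] == pytest.approx(6.0)
        assert tr.column_percent[0, 0] == pytest.approx(100.0)

    def test_hand_built_two_group_aggregation(self):
        table = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [5.0, 6.0, 7.0, 8.0],
                [9.0, 10.0, 11.0, 12.0],
                [13.0, 14.0, 15.0, 16.0],
            ]
        )
        attr = AttributionTable("p", ("A", "B", "C", "D"), table, "kg")
        grouping = {"A": "G1", "B": "G1", "C": "G2", "D": "G2"}
        tr = group_transfers(attr, grouping)
        np.testing.assert_allclose(
            tr.absolute, [[1 + 2 + 5 + 6, 3 + 4 + 7 + 8], [9 + 10 + 13 + 14, 11 + 12 + 15 + 16]]
        )
        np.testing.assert_allclose(tr.column_percent.sum(axis=0), [100.0, 100.0])

    def test_invariant_to_country_permutation(self, rng):
        table = rng.random((4, 4))
        regions = ("A", "B", "C", "D")
        grouping = {"A": "G1", "B": "G2", "C": "G1", "D": "G2"}
        tr = group_transfers(
            AttributionTable("p", regions, table, "kg"), grouping, groups=("G1", "G2")
        )
        perm = [2, 0, 3, 1]
        tr2 = group_transfers(
            AttributionTable(
                "p",
                tuple(regions[i] for i in perm),
                table[np.ix_(perm, perm)],
                "kg",
            ),
            grouping,
            groups=("G1", "G2"),
        )
        np.testing.assert_allclose(tr.absolute, tr2.absolute)

    def test_unmapped_country_raises(self):
        attr = AttributionTable("p", ("A", "B"), np.ones((2, 2)), "kg")
        with pytest.raises(GroupingError, match="B"):
            group_transfers(attr, {"A": "G"})

    def test_zero_column_gives_zero_percent_column(self):
        table = np.array([[1.0, 0.0], [1.0, 0.0]])
        attr = AttributionTable("p", ("A", "B"), table, "kg")
        tr = group_transfers(attr, {"A": "G1", "B": "G2"})
        np.testing.assert_array_equal(tr.column_percent[:, 1], [0.0, 0.0])


class TestTotalImpact:
    def test_totals_and_shares(self, result):
        tot = total_impact(result.impact, pathways=result.pathways)
        np.testing.assert_allclose(
            tot.per_consumer, result.impact.aggregate.sum(axis=0), rtol=1e-12
        )
        assert sum(tot.pathway_shares.values()) == pytest.approx(1.0)

    def test_single_row_equals_that_row(self):
        idx, f, L, Y = _single()
        imp = impact_footprint(np.array([[2.0]]), f, L, Y, idx, ["p"])
        tot = total_impact(imp)
        np.testing.assert_allclose(tot.per_consumer, imp.aggregate[0])

    def test_pressure_tensor_rejected(self, result):
        with pytest.raises(UnitError):
            total_impact(result.pressure)
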