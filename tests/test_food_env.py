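import networkx as nx
import numpy as np
import pandas as pd
import pytest

from saltscape.food_env import (
    OUTLET_LISTING_YEARS,
    StreetNetwork,
    assign_income_year,
    decay_weight,
    match_outlet_year,
    outlet_density,
    read_network_csv,
    read_outlets_csv,
    snap,
)
from saltscape.synthetic import RegionSpec, make_street_network


@pytest.fixture(scope="module")
def grid():
    # 2 km x 2 km, 100 m blocks
    return make_street_network(RegionSpec(extent=(2000.0, 2000.0),
                                          street_grid_spacing=100.0))


class TestSnap:
    def test_point_on_node_snaps_with_zero_distance(self, grid):
        idx, dist = snap(np.array([[300.0, 400.0]]), grid)
        assert dist[0] == 0.0
        assert tuple(grid.node_coords[idx[0]]) == (300.0, 400.0)

    def test_far_point_is_unsnapped(self, grid):
        idx, dist = snap(np.array([[-60.0, -60.0]]), grid)
        assert idx[0] == -1 and np.isnan(dist[0])

    def test_matches_brute_force_nearest_node_scan(self, grid):
        rng = np.random.default_rng(1)
        pts = rng.random((50, 2)) * 2000
        idx, dist = snap(pts, grid, max_snap=100.0)  # loose cap: all snap
        for p, i, d in zip(pts, idx, dist):
            d_all = np.hypot(*(grid.node_coords - p).T)
            assert d == pytest.approx(d_all.min(), abs=1e-9)
            assert d_all[i] == d_all.min()

    def test_snap_cap_respected(self, grid):
        """Points beyond the 50 m default cap are flagged unsnapped."""
        pts = np.array([[150.0, 150.0]])  # cell center: 70.7 m from any node
        idx, dist = snap(pts, grid)
        assert idx[0] == -1
        idx2, dist2 = snap(pts, grid, max_snap=75.0)
        assert idx2[0] >= 0 and dist2[0] == pytest.approx(np.sqrt(2) * 50, abs=1e-9)


class TestDecay:
    def test_kernel_closed_forms(self):
        assert decay_weight(0.0) == 1.0
        assert decay_weight(400.0) == 0.5
        assert decay_weight(800.0) == 0.0
        assert decay_weight(1200.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decay_weight(-1.0)
        with pytest.raises(ValueError):
            decay_weight(100.0, bandwidth=0)


class TestYearRules:
    @pytest.mark.parametrize(
        "year,expected",
        [(1993, 2003), (2006, 2005), (2007, 2008), (2010, 2010), (2030, 2018)],
    )
    def test_closest_listing_year_with_earlier_tiebreak(self, year, expected):
        assert match_outlet_year(year) == expected

    @pytest.mark.parametrize(
        "year,expected",
        [(1993, 2005), (2004, 2005), (2005, 2005), (2010, 2010),
         (2016, 2016), (2017, 2016), (2018, 2016)],
    )
    def test_income_year_assignment(self, year, expected):
        assert assign_income_year(year) == expected

    def test_out_of_range_year_rejected(self):
        with pytest.raises(ValueError):
            assign_income_year(1992)
        with pytest.raises(ValueError):
            assign_income_year(2019)

    def test_listing_years_skip_the_two_missing_ones(self):
        assert 2006 not in OUTLET_LISTING_YEARS
        assert 2007 not in OUTLET_LISTING_YEARS
        assert OUTLET_LISTING_YEARS[0] == 2003 and OUTLET_LISTING_YEARS[-1] == 2018


def _participants(xy, year=2010):
    return pd.DataFrame(
        {"id": [f"p{i}" for i in range(len(xy))],
         "x": xy[:, 0], "y": xy[:, 1], "year": year}
    )


def _outlets(rows):
    return pd.DataFrame(rows, columns=["id", "x", "y", "category", "year"])


class TestOutletDensity:
    def test_outlet_at_same_node_gives_unit_density(self, grid):
        parts = _participants(np.array([[500.0, 500.0]]))
        outs = _outlets([("o1", 500.0, 500.0, "grocery", 2010)])
        acc = outlet_density(parts, outs, grid)
        assert acc.densities.loc["p0", "grocery"] == pytest.approx(1.0)
        assert acc.densities.loc["p0", "supermarket"] == 0.0

    def test_duplicating_an_outlet_doubles_its_category_density(self, grid):
        rng = np.random.default_rng(2)
        parts = _participants(rng.random((20, 2)) * 1800)
        outs = _outlets([("o1", 600.0, 600.0, "convenience", 2010)])
        outs2 = pd.concat([outs, outs.assign(id="o2")], ignore_index=True)
        d1 = outlet_density(parts, outs, grid, max_snap=100.0).densities["convenience"]
        d2 = outlet_density(parts, outs2, grid, max_snap=100.0).densities["convenience"]
        assert np.allclose(d2, 2 * d1, atol=1e-12)

    def test_matches_per_source_shortest_path_oracle(self, grid):
        """Independent oracle: networkx single-source Dijkstra per participant."""
        rng = np.random.default_rng(3)
        parts = _participants(rng.random((40, 2)) * 1800)
        outs = _outlets(
            [(f"o{i}", *xy, cat, 2010)
             for i, (xy, cat) in enumerate(
                 zip(rng.random((15, 2)) * 1800,
                     ["supermarket", "grocery", "convenience"] * 5))]
        )
        acc = outlet_density(parts, outs, grid, max_snap=100.0)

        p_idx, _ = snap(parts[["x", "y"]].to_numpy(), grid, max_snap=100.0)
        o_idx, _ = snap(outs[["x", "y"]].to_numpy(), grid, max_snap=100.0)
        ids = grid.node_ids
        for pi in range(len(parts)):
            lengths = nx.single_source_dijkstra_path_length(
                grid.graph, ids[p_idx[pi]], weight="length"
            )
            for cat in ("supermarket", "grocery", "convenience"):
                expected = 0.0
                for oi in np.flatnonzero((outs["category"] == cat).to_numpy()):
                    d = lengths.get(ids[o_idx[oi]], np.inf)
                    expected += max(0.0, 1.0 - d / 800.0)
                assert acc.densities.iloc[pi][cat] == pytest.approx(expected, abs=1e-9)

    def test_adding_an_outlet_never_decreases_density(self, grid):
        rng = np.random.default_rng(4)
        parts = _participants(rng.random((15, 2)) * 1800)
        outs = _outlets([(f"o{i}", *xy, "grocery", 2010)
                         for i, xy in enumerate(rng.random((5, 2)) * 1800)])
        extra = pd.concat(
            [outs, _outlets([("onew", 900.0, 900.0, "grocery", 2010)])],
            ignore_index=True,
        )
        d1 = outlet_density(parts, outs, grid, max_snap=100.0).densities["grocery"]
        d2 = outlet_density(parts, extra, grid, max_snap=100.0).densities["grocery"]
        assert (d2 >= d1 - 1e-12).all()

    def test_density_bounded_by_matched_outlet_count(self, grid):
        rng = np.random.default_rng(5)
        parts = _participants(rng.random((10, 2)) * 1800)
        outs = _outlets([(f"o{i}", *xy, "convenience", 2010)
                         for i, xy in enumerate(rng.random((7, 2)) * 1800)])
        acc = outlet_density(parts, outs, grid, max_snap=100.0)
        assert (acc.densities["convenience"] <= 7 + 1e-12).all()

    def test_translation_invariance(self):
        spec0 = RegionSpec(extent=(2000.0, 2000.0), street_grid_spacing=100.0)
        net0 = make_street_network(spec0)
        rng = np.random.default_rng(6)
        xy = rng.random((12, 2)) * 1800
        out_xy = rng.random((6, 2)) * 1800
        outs0 = _outlets([(f"o{i}", *p, "grocery", 2010)
                          for i, p in enumerate(out_xy)])
        d0 = outlet_density(_participants(xy), outs0, net0, max_snap=100.0).densities

        shift = np.array([5000.0, -3000.0])
        g = nx.Graph()
        for nid in net0.graph.nodes:
            px, py = net0.graph.nodes[nid]["pos"]
            g.add_node(nid, pos=(px + shift[0], py + shift[1]))
        for u, v, d in net0.graph.edges(data=True):
            g.add_edge(u, v, length=d["length"])
        net1 = StreetNetwork(g)
        outs1 = _outlets([(f"o{i}", *(p + shift), "grocery", 2010)
                          for i, p in enumerate(out_xy)])
        d1 = outlet_density(_participants(xy + shift), outs1, net1, max_snap=100.0).densities
        assert np.allclose(d0.values, d1.values, atol=1e-9)

    def test_unsnapped_participant_gets_missing_densities(self, grid):
        parts = _participants(np.array([[500.0, 500.0], [-80.0, -80.0]]))
        outs = _outlets([("o1", 500.0, 500.0, "grocery", 2010)])
        acc = outlet_density(parts, outs, grid)
        assert acc.unsnapped == ["p1"]
        assert acc.densities.loc["p1"].isna().all()

    def test_unknown_category_rejected(self, grid):
        parts = _participants(np.array([[500.0, 500.0]]))
        outs = _outlets([("o1", 500.0, 500.0, "bakery", 2010)])
        with pytest.raises(ValueError, match="unknown outlet categories"):
            outlet_density(parts, outs, grid)


def test_network_validation_rejects_self_loops_and_zero_lengths():
    g = nx.Graph()
    g.add_node(0, pos=(0.0, 0.0))
    g.add_edge(0, 0, length=10.0)
    with pytest.raises(ValueError, match="self-loops"):
        StreetNetwork(g)
    g2 = nx.Graph()
    g2.add_node(0, pos=(0.0, 0.0))
    g2.add_node(1, pos=(1.0, 0.0))
    g2.add_edge(0, 1, length=0.0)
    with pytest.raises(ValueError, match="length"):
        StreetNetwork(g2)


def test_network_and_outlet_io_roundtrip(grid, tmp_path):
    grid.write_csv(tmp_path / "nodes.csv", tmp_path / "edges.csv")
    net2 = read_network_csv(tmp_path / "nodes.csv", tmp_path / "edges.csv")
    assert net2.graph.number_of_nodes() == grid.graph.number_of_nodes()
    assert net2.graph.number_of_edges() == grid.graph.number_of_edges()
    grid.write_geojson(tmp_path / "net.geojson")
    import json

    gj = json.loads((tmp_path / "net.geojson").read_text())
    assert len(gj["features"]) == grid.graph.number_of_edges()

    outs = _outlets([("o1", 1.0, 2.0, "grocery", 2010)])
    outs.to_csv(tmp_path / "o.csv", index=False)
    assert len(read_outlets_csv(tmp_path / "o.csv")) == 1
    bad = _outlets([("o1", 1.0, 2.0, "pharmacy", 2010)])
    bad.to_csv(tmp_path / "bad.csv", index=False)
    with pytest.raises(ValueError):
        read_outlets_csv(tmp_path / "bad.csv")
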