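"""Reach extraction, stream orders, hydraulic power laws, path statistics."""
import numpy as np
import pytest

from edith.dem import ElevationGrid, FlowGrid, d8_flow_directions, flow_accumulation
from edith.network import (
    THUR_LAWS,
    ConnectivityError,
    EmptyNetworkError,
    PowerLaw,
    assign_hydraulics,
    cluster_reaches,
    compose_velocity_law,
    extract_reaches,
    fit_power_law,
    map_sites_to_reaches,
    path_stats,
    strahler_orders,
)
from edith.synthetic import synthetic_dem

from conftest import build_network


# -- reach extraction -----------------------------------------------------


def test_linear_channel_single_reach():
    z = np.arange(10, 0, -1.0).reshape(1, -1)
    grid = ElevationGrid(z, 25.0)
    flow = flow_accumulation(d8_flow_directions(grid))
    net = extract_reaches(flow, grid, threshold_cells=3)
    assert len(net) == 1
    assert net.downstream[0] == -1
    # 8 channel cells: 7 inter-cell steps + the outlet cell itself
    assert net.length[0] == pytest.approx(8 * 25.0)


def test_y_channel_three_reaches():
    # hand-built flow field: two headwater cells converging on a 2-cell stem
    z = np.full((3, 3), -9999.0)
    for cell, h in (((0, 0), 9.0), ((0, 2), 9.0), ((1, 1), 5.0), ((2, 1), 4.0)):
        z[cell] = h
    grid = ElevationGrid(z, 25.0)
    direction = np.full((3, 3), -2, dtype=int)
    direction[0, 0] = 1   # SE into the junction
    direction[0, 2] = 3   # SW into the junction
    direction[1, 1] = 2   # S
    direction[2, 1] = -1  # outlet
    flow = flow_accumulation(FlowGrid(direction=direction))
    net = extract_reaches(flow, grid, threshold_cells=1)
    assert len(net) == 3
    assert len(net.outlets) == 1
    stem = net.outlets[0]
    assert sorted(len(net.children[k]) for k in range(3)) == [0, 0, 2]
    assert net.strahler[stem] == 2
    # headwater reach: one diagonal step into the junction cell
    head = net.index("r0000")
    assert net.length[head] == pytest.approx(25.0 * np.sqrt(2))
    # stem: cardinal step plus the outlet cell; area covers all 4 cells
    assert net.length[stem] == pytest.approx(50.0)
    assert net.area_km2[stem] == pytest.approx(4 * 25.0**2 / 1e6)


def oracle_trace(flow, grid, threshold):
    """Brute-force per-pixel trace of channel segmentation (independent of
    extract_reaches): returns frozenset of reach pixel paths."""
    acc = flow.accumulation
    channel = {(r, c)
               for r, c in zip(*np.nonzero((flow.direction != -2)
                                           & (acc >= threshold)))}
    inflows = {cell: 0 for cell in channel}
    for cell in channel:
        down = flow.downstream_cell(*cell)
        if down in inflows:
            inflows[down] += 1
    starts = sorted(c for c in channel if inflows[c] != 1)
    paths = []
    for start in starts:
        path = [start]
        while True:
            down = flow.downstream_cell(*path[-1])
            if down not in channel or inflows[down] >= 2:
                break
            path.append(down)
        paths.append(tuple(path))
    return frozenset(paths)


def test_extraction_matches_pixel_trace_oracle():
    grid = synthetic_dem(seed=5)
    flow = flow_accumulation(d8_flow_directions(grid))
    threshold = 12
    net = extract_reaches(flow, grid, threshold)
    assert frozenset(tuple(c) for c in net.cells) == oracle_trace(
        flow, grid, threshold)


def test_no_channel_cells_is_an_error():
    z = np.arange(5, 0, -1.0).reshape(1, -1)
    grid = ElevationGrid(z, 25.0)
    flow = flow_accumulation(d8_flow_directions(grid))
    with pytest.raises(EmptyNetworkError):
        extract_reaches(flow, grid, threshold_cells=100)


# -- Strahler orders ------------------------------------------------------


@pytest.mark.parametrize(
    "rows, expected",
    [
        # two order-1 reaches merge -> 2
        ([("a", "c", 1, 1), ("b", "c", 1, 1), ("c", None, 1, 2)], {"c": 2}),
        # order-1 joins order-2 -> 2
        (
            [("a", "c", 1, 1), ("b", "c", 1, 1), ("c", "e", 1, 2),
             ("d", "e", 1, 1), ("e", None, 1, 3)],
            {"c": 2, "e": 2},
        ),
    ],
)
def test_strahler_merge_rules(rows, expected):
    net = build_network(rows)
    for rid, order in expected.items():
        assert net.strahler[net.index(rid)] == order


def test_strahler_binary_tree_depth_three():
    rows = []
    # perfect binary tree: 4 leaves, 2 mid, 1 outlet
    for k in range(4):
        rows.append((f"leaf{k}", f"mid{k // 2}", 1.0, 1.0))
    for k in range(2):
        rows.append((f"mid{k}", "out", 1.0, 2.0))
    rows.append(("out", None, 1.0, 4.0))
    net = build_network(rows)
    assert net.strahler[net.index("out")] == 3


def test_order_and_area_nondecreasing_downstream(random_tree):
    net = random_tree
    for k in range(len(net)):
        d = net.downstream[k]
        if d >= 0:
            assert net.strahler[d] >= net.strahler[k]
            assert net.area_km2[d] >= net.area_km2[k] - 1e-12


# -- power laws -----------------------------------------------------------


def test_two_point_fit_is_exact():
    law = fit_power_law([1.0, 4.0], [2.0, 4.0])
    assert law.coefficient == pytest.approx(2.0, abs=1e-12)
    assert law.exponent == pytest.approx(0.5, abs=1e-12)


def test_noiseless_fit_recovers_parameters():
    A = np.geomspace(0.5, 100, 20)
    law = fit_power_law(A, 0.07 * A**1.05)
    assert law.coefficient == pytest.approx(0.07, abs=1e-10)
    assert law.exponent == pytest.approx(1.05, abs=1e-10)


def test_noisy_fit_recovers_exponent():
    rng = np.random.default_rng(3)
    A = np.exp(rng.uniform(np.log(0.5), np.log(200), size=50))
    y = 0.07 * A**1.05 * np.exp(rng.normal(0, 0.05, size=50))
    law = fit_power_law(A, y)
    assert abs(law.exponent - 1.05) < 0.05


def test_nonpositive_inputs_rejected():
    with pytest.raises(ValueError):
        fit_power_law([1.0, -1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_power_law([1.0], [1.0])


def test_velocity_law_from_rectangular_sections():
    v = compose_velocity_law(THUR_LAWS["Q"], THUR_LAWS["w"], THUR_LAWS["D"])
    assert v.coefficient == pytest.approx(0.623, abs=0.002)
    assert v.exponent == pytest.approx(0.067, abs=1e-12)


# -- hydraulics on the network -------------------------------------------


def test_unit_area_discharge(y_network):
    k = y_network.index("a")  # A = 1 km^2
    assert y_network.discharge[k] == pytest.approx(0.072)


def test_headwater_local_discharge_equals_total(y_network):
    for rid in ("a", "b"):
        k = y_network.index(rid)
        assert y_network.local_discharge[k] == pytest.approx(
            y_network.discharge[k])


def test_discharge_conservation_over_upstream_sets(random_tree):
    net = random_tree
    assert not net.q_clamped.any()
    for k in range(len(net)):
        gamma = net.upstream_set(k)
        total = net.local_discharge[gamma].sum()
        assert total == pytest.approx(net.discharge[k], rel=1e-9)


def test_source_area_is_length_times_width(random_tree):
    assert np.allclose(random_tree.source_area,
                       random_tree.length * random_tree.width)


def test_sublinear_law_clamps_negative_local_discharge():
    net = build_network(
        [("a", "c", 1000, 4.0), ("b", "c", 1000, 4.0), ("c", None, 1000, 8.0)]
    )
    laws = {"Q": PowerLaw(1.0, 0.3, "Q"), "w": THUR_LAWS["w"],
            "D": THUR_LAWS["D"]}
    with pytest.warns(RuntimeWarning, match="clamped"):
        assign_hydraulics(net, laws)
    k = net.index("c")
    assert net.q_clamped[k]
    assert net.local_discharge[k] == 0.0


# -- path statistics ------------------------------------------------------


def test_path_of_single_reach_is_local():
    net = build_network([("a", None, 500.0, 1.0)])
    net.velocity = np.array([1.0])
    L, v = path_stats(net, 0, 0)
    assert (L, v) == (500.0, 1.0)


def test_two_reach_harmonic_velocity():
    net = build_network([("a", "b", 1000.0, 1.0), ("b", None, 1000.0, 2.0)])
    net.velocity = np.array([1.0, 2.0])
    L, v = path_stats(net, net.index("a"), net.index("b"))
    assert L == pytest.approx(2000.0)
    assert v == pytest.approx(2000.0 / 1500.0)


def test_travel_time_additivity(random_tree):
    net = random_tree
    rng = np.random.default_rng(0)
    outlet = net.outlets[0]
    for i in rng.choice(len(net), size=10, replace=False):
        L, v = path_stats(net, int(i), int(outlet))
        idx = net.path(int(i), int(outlet))
        assert L / v == pytest.approx(
            float((net.length[idx] / net.velocity[idx]).sum()), rel=1e-12)


def test_disconnected_path_raises(y_network):
    with pytest.raises(ConnectivityError):
        path_stats(y_network, y_network.index("a"), y_network.index("b"))


# -- clustering and site mapping -----------------------------------------


def test_cluster_partition(random_tree):
    labels = cluster_reaches(random_tree, 5)
    assert len(set(labels)) == 5
    assert len(labels) == len(random_tree)


def test_sites_map_to_containing_reach():
    grid = synthetic_dem(seed=5)
    flow = flow_accumulation(d8_flow_directions(grid))
    net = extract_reaches(flow, grid, 12)
    k = max(range(len(net)), key=lambda j: len(net.cells[j]))
    cell = net.cells[k][0]
    xy = [grid.cell_center(*cell)]
    assert map_sites_to_reaches(net, grid, flow, xy) == [net.ids[k]]
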