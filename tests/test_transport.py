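"""Command codec, unit-step path planning and the drive state machine."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qclsim import (
    DriveState,
    PathPlan,
    TransportCommand,
    decode_command,
    drive_step,
    encode_command,
    plan_path,
    simulate_route,
)
from qclsim.transport import (
    InfeasiblePath,
    InvalidStepError,
    OutOfRangeError,
    SeparatorError,
    WrongLengthError,
)

coord = st.tuples(st.integers(0, 255), st.integers(0, 255))


@settings(derandomize=True, max_examples=200)
@given(
    add_t=st.integers(0, 255),
    add_p=st.integers(0, 255),
    init=coord,
    final=coord,
)
def test_codec_round_trip(add_t, add_p, init, final):
    cmd = TransportCommand(add_btT=add_t, add_btP=add_p,
                           init_coord=init, final_coord=final)
    assert decode_command(encode_command(cmd)) == cmd


def test_reference_pallet2_hop_encodes_losslessly():
    """Pallet 2's first hop, node (2,2) -> (2,4) on the 6x6 node grid."""
    cmd = TransportCommand(add_btT=1, add_btP=2, init_coord=(2, 2),
                           final_coord=(2, 4))
    data = encode_command(cmd)
    assert len(data) == 12 and data[0] == data[3] == 89
    assert decode_command(data, max1=5, max2=5) == cmd


def test_decode_rejections_are_distinct():
    good = encode_command(
        TransportCommand(add_btT=1, add_btP=2, init_coord=(2, 2), final_coord=(2, 3))
    )
    with pytest.raises(WrongLengthError):
        decode_command(good[:-1])
    corrupted = bytes([88]) + good[1:]
    with pytest.raises(SeparatorError):
        decode_command(corrupted)
    far = encode_command(
        TransportCommand(add_btT=1, add_btP=2, init_coord=(9, 2), final_coord=(2, 3))
    )
    with pytest.raises(OutOfRangeError):
        decode_command(far, max1=5, max2=5)


def test_command_field_range_validated():
    with pytest.raises(ValueError):
        TransportCommand(add_btT=300, add_btP=0, init_coord=(0, 0), final_coord=(0, 0))


def test_plan_path_trivial_cases():
    occ = np.zeros((5, 5), bool)
    assert plan_path((2, 2), (2, 2), occ).waypoints == ((2, 2),)
    straight = plan_path((0, 0), (2, 0), occ)
    assert len(straight) == 3  # two unit steps, Manhattan lower bound


def test_plan_path_detour_around_wall():
    occ = np.zeros((5, 5), bool)
    occ[2, :4] = True  # wall with a gap at column 4
    plan = plan_path((0, 0), (4, 0), occ)
    assert plan.waypoints[0] == (0, 0) and plan.waypoints[-1] == (4, 0)
    assert len(plan) - 1 == 12  # forced detour through the gap
    assert not any(occ[w] for w in plan.waypoints)


def _nx_shortest(occ, start, goal):
    import networkx as nx

    M1, M2 = occ.shape
    G = nx.grid_2d_graph(M1, M2)
    G.remove_nodes_from([(i, j) for i in range(M1) for j in range(M2) if occ[i, j]])
    try:
        return nx.shortest_path_length(G, start, goal)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None


def test_plan_path_optimal_exhaustive_3x3():
    """BFS length equals the graph-theoretic shortest path on every 3x3
    instance with up to 3 obstacles and every free start/goal pair."""
    cells = [(i, j) for i in range(3) for j in range(3)]
    for n_obs in range(4):
        for obs in itertools.combinations(cells, n_obs):
            occ = np.zeros((3, 3), bool)
            for c in obs:
                occ[c] = True
            free = [c for c in cells if not occ[c]]
            for start, goal in itertools.permutations(free, 2):
                expected = _nx_shortest(occ, start, goal)
                if expected is None:
                    with pytest.raises(InfeasiblePath):
                        plan_path(start, goal, occ)
                else:
                    assert len(plan_path(start, goal, occ)) - 1 == expected


def test_plan_path_optimal_random_4x4():
    rng = np.random.default_rng(17)
    for _ in range(500):
        occ = np.zeros((4, 4), bool)
        n_obs = int(rng.integers(0, 5))
        for idx in rng.choice(16, size=n_obs, replace=False):
            occ[divmod(int(idx), 4)] = True
        free = [(i, j) for i in range(4) for j in range(4) if not occ[i, j]]
        if len(free) < 2:
            continue
        start, goal = [free[int(k)] for k in rng.choice(len(free), 2, replace=False)]
        expected = _nx_shortest(occ, start, goal)
        if expected is None:
            with pytest.raises(InfeasiblePath):
                plan_path(start, goal, occ)
        else:
            plan = plan_path(start, goal, occ)
            assert len(plan) - 1 == expected
            assert not any(occ[w] for w in plan.waypoints)


class TestDriveStep:
    def test_zero_step_keeps_position(self):
        s = DriveState(heading=(1, 0))
        s1, out = drive_step(s, 0, 0)
        assert out.in1 == out.in2  # equal bits = keep position
        assert out.wheel_angle == s.cp
        assert s1.heading == (1, 0)

    def test_step_along_heading_goes_ahead(self):
        s = DriveState(heading=(1, 0))
        s1, out = drive_step(s, 1, 0)
        assert (out.in1, out.in2) == (0, 1)  # go ahead
        assert out.wheel_angle == s.cp
        assert s1.z == 0

    def test_step_against_heading_goes_backward(self):
        s = DriveState(heading=(1, 0))
        s1, out = drive_step(s, -1, 0)
        assert (out.in1, out.in2) == (1, 0)  # go backward
        assert s1.heading == (1, 0)

    def test_perpendicular_step_steers_and_updates_heading(self):
        s = DriveState(heading=(1, 0))
        s1, out = drive_step(s, 0, 1)
        assert out.wheel_angle in (s.cp - s.rs, s.cp + s.rs)
        assert s1.heading == (0, 1)
        assert s1.z == 1  # travel axis switched to y

    @pytest.mark.parametrize("dx, dy", [(1, 1), (-1, 1), (2, 0), (0, -2)])
    def test_diagonal_or_long_steps_rejected(self, dx, dy):
        with pytest.raises(InvalidStepError):
            drive_step(DriveState(), dx, dy)


def test_route_single_hop():
    trace = simulate_route(PathPlan(((0, 0), (1, 0))), initial_heading=(1, 0))
    assert trace.cells[-1] == (1, 0)
    assert len(trace.outputs) == 1
    assert trace.outputs[0].event == "ahead"


def test_route_l_shape_single_steering_event():
    plan = PathPlan(((0, 0), (1, 0), (2, 0), (2, 1), (2, 2)))
    trace = simulate_route(plan, initial_heading=(1, 0))
    assert trace.steering_events == 1
    assert trace.cells == list(plan.waypoints)


def test_route_replay_lands_on_goal_for_seeded_plans():
    rng = np.random.default_rng(23)
    done = 0
    while done < 100:
        occ = np.zeros((5, 5), bool)
        for idx in rng.choice(25, size=int(rng.integers(0, 5)), replace=False):
            occ[divmod(int(idx), 5)] = True
        free = [(i, j) for i in range(5) for j in range(5) if not occ[i, j]]
        start, goal = [free[int(k)] for k in rng.choice(len(free), 2, replace=False)]
        try:
            plan = plan_path(start, goal, occ)
        except InfeasiblePath:
            continue
        heading = [(1, 0), (-1, 0), (0, 1), (0, -1)][int(rng.integers(0, 4))]
        trace = simulate_route(plan, initial_heading=heading)
        assert trace.cells[-1] == goal
        assert trace.cells == list(plan.waypoints)
        done += 1


def test_reference_pallet3_path_replay():
    """Printed waypoints (1,4) -> (0,4) -> (0,2) on the node grid, expanded
    to unit steps, terminate at the printed final node (0,2)."""
    waypoints = ((1, 4), (0, 4), (0, 3), (0, 2))
    trace = simulate_route(PathPlan(waypoints), initial_heading=(-1, 0))
    assert trace.cells[-1] == (0, 2)
    assert len(trace.outputs) == 3
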