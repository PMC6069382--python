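"""QCL optimizer: cubes, trigger, greedy orders, iteration accounting."""

import numpy as np
import pytest

from qclsim import (
    TOMATO_FIRMNESS,
    Pallet,
    PalletRegistry,
    QualityState,
    ScalarField,
    build_cubes,
    displacement_trigger,
    evaluate_order,
    optimize,
    select_best,
)
from qclsim.monitor import CTH_PRESETS
from qclsim.qcl import ShelfLifeCube


def _registry(cells, shape=(5, 5)):
    pallets = [
        Pallet(
            pallet_id=i + 1,
            cell=c,
            state=QualityState(t=0.0, c=12.4, k_current=0.2, SL=7.0955),
            params=TOMATO_FIRMNESS,
        )
        for i, c in enumerate(cells)
    ]
    return PalletRegistry(pallets=pallets, lattice_shape=shape)


def _cube(sl_layers):
    """Cube from a list of per-pallet SL layers (ids 1..n)."""
    sl = np.dstack(sl_layers)
    return ShelfLifeCube(sl=sl, quality=np.zeros_like(sl),
                         pallet_ids=tuple(range(1, len(sl_layers) + 1)))


def test_registry_invariants():
    with pytest.raises(ValueError, match="distinct"):
        _registry([(0, 0), (0, 0)])
    with pytest.raises(ValueError, match="Np"):
        _registry([(i, j) for i in range(5) for j in range(5)][:22])


def test_build_cubes_uniform_field_constant_layers(scenario):
    field = ScalarField(np.full((5, 5), 21.0), np.ones((5, 5), bool))
    cube = build_cubes(field, scenario.registry)
    for pid in cube.pallet_ids:
        layer = cube.layer(pid)
        assert np.allclose(layer, layer[0, 0])
    assert cube.sl.shape == (5, 5, 4)
    assert np.all(cube.sl >= 0)


def test_build_cubes_cold_cell_is_argmax_for_every_pallet(scenario):
    vals = np.full((5, 5), 24.0)
    vals[3, 2] = 16.0
    field = ScalarField(vals, np.ones((5, 5), bool))
    cube = build_cubes(field, scenario.registry)
    for pid in cube.pallet_ids:
        assert np.unravel_index(np.argmax(cube.layer(pid)), (5, 5)) == (3, 2)
        # colder cell -> slower rate -> next-tick quality is also maximal there
        qidx = cube.pallet_ids.index(pid)
        assert np.unravel_index(np.argmax(cube.quality[:, :, qidx]), (5, 5)) == (3, 2)


def test_build_cubes_requires_complete_field(scenario):
    field = ScalarField.from_readings((5, 5), {(0, 0): 21.0})
    with pytest.raises(ValueError):
        build_cubes(field, scenario.registry)


class TestDisplacementTrigger:
    def test_no_change_no_trigger(self):
        assert not displacement_trigger([12.4, 12.4], CTH_PRESETS["24C"], 600)

    def test_decay_at_30C_exceeds_26C_preset(self, tomato):
        """Ten minutes of decay at 30 degC drops firmness faster than the
        26 degC preset threshold."""
        from qclsim import arrhenius_rate, decay_step

        k30 = arrhenius_rate(tomato, 30.0)
        s0 = QualityState(t=0, c=12.4, k_current=k30, SL=3.0)
        s1 = decay_step(s0, tomato, k30, 600 / 86400)
        assert displacement_trigger([s0.c, s1.c], CTH_PRESETS["26C"], 600)

    def test_both_presets_available(self):
        assert CTH_PRESETS["24C"] == 2.68e-5
        assert CTH_PRESETS["26C"] == 3.184e-5

    def test_needs_two_measurements(self):
        with pytest.raises(ValueError):
            displacement_trigger([12.4], 2.68e-5, 600)


def _greedy_oracle(order, layers, current, blocked):
    """Independent greedy replay: explicit max search, row-major ties."""
    assigned = {}
    for pid in order:
        best, best_v = None, -np.inf
        M1, M2 = layers[pid].shape
        for i in range(M1):
            for j in range(M2):
                cell = (i, j)
                if cell in blocked or cell in assigned.values():
                    continue
                if any(current[q] == cell for q in current if q != pid) and \
                        cell != current[pid]:
                    continue
                if layers[pid][cell] > best_v:
                    best, best_v = cell, layers[pid][cell]
        assigned[pid] = best
    return assigned, sum(layers[p][assigned[p]] for p in order)


def test_evaluate_order_matches_independent_replay():
    rng = np.random.default_rng(0)
    layers = {pid: rng.uniform(1, 8, (5, 5)) for pid in (1, 2, 3, 4)}
    cube = _cube([layers[p] for p in (1, 2, 3, 4)])
    current = {1: (0, 1), 2: (2, 2), 3: (4, 1), 4: (0, 3)}
    ev = evaluate_order((1, 2, 3, 4), cube, current)
    oracle_assign, oracle_sls = _greedy_oracle((1, 2, 3, 4), layers, current, set())
    assert ev.assignment == oracle_assign
    assert ev.sls == pytest.approx(oracle_sls)
    assert ev.iterations == 5  # 4 placements + 1 summation


def test_evaluate_order_symmetric_layers_order_independent():
    layer = np.arange(9, dtype=float).reshape(3, 3)
    cube = _cube([layer, layer])
    current = {1: (0, 0), 2: (1, 1)}
    a = evaluate_order((1, 2), cube, current)
    b = evaluate_order((2, 1), cube, current)
    assert a.sls == pytest.approx(b.sls)


def test_select_best_equals_shift_enumeration_oracle():
    """Winning score over cyclic shifts equals a brute-force enumeration
    with independent greedy replay (3 pallets, 3x3 lattice)."""
    rng = np.random.default_rng(9)
    for trial in range(10):
        layers = {pid: rng.uniform(1, 9, (3, 3)) for pid in (1, 2, 3)}
        cube = _cube([layers[p] for p in (1, 2, 3)])
        current = {1: (0, 0), 2: (1, 2), 3: (2, 1)}
        sel = select_best([1, 2, 3], cube, current)
        ids = [1, 2, 3]
        oracle = []
        for s in range(3):
            order = tuple(ids[s:] + ids[:s])
            oracle.append(_greedy_oracle(order, layers, current, set())[1])
        assert max(sel.sls_by_order) == pytest.approx(max(oracle))
        assert sel.sls_by_order == pytest.approx(oracle)
        assert sel.iterations == 12


@pytest.mark.parametrize("n, expected", [(4, 20), (3, 12), (2, 6)])
def test_selection_iteration_counts(n, expected):
    rng = np.random.default_rng(n)
    cube = _cube([rng.uniform(1, 9, (5, 5)) for _ in range(n)])
    current = {pid: (pid - 1, pid - 1) for pid in range(1, n + 1)}
    sel = select_best(list(range(1, n + 1)), cube, current)
    assert sel.iterations == expected


def test_select_best_tie_breaks_to_first_shift():
    cube = _cube([np.ones((3, 3)) for _ in range(3)])
    current = {1: (0, 0), 2: (1, 1), 3: (2, 2)}
    sel = select_best([1, 2, 3], cube, current)
    assert sel.winning_order == (1, 2, 3)
    assert sel.best_pallet == 1


@pytest.mark.parametrize("Np", [2, 3, 4, 5, 6])
def test_total_iterations_closed_form(Np):
    """Executed count equals sum_{n=2..Np} n(n+1) + 1."""
    rng = np.random.default_rng(Np)
    cells = [(0, 0), (1, 2), (2, 0), (3, 2), (4, 0), (0, 2)][:Np]
    reg = _registry(cells)
    cube = _cube([rng.uniform(1, 9, (5, 5)) for _ in range(Np)])
    plan = optimize(reg, cube)
    expected = sum(n * (n + 1) for n in range(2, Np + 1)) + 1
    assert plan.total_iterations == expected
    assert [s.iterations for s in plan.subroutines] == [
        n * (n + 1) for n in range(Np, 1, -1)
    ] + [1]


def test_single_pallet_direct_argmax():
    layer = np.zeros((5, 5))
    layer[1, 3] = 9.0
    reg = _registry([(4, 4)])
    plan = optimize(reg, _cube([layer]))
    assert plan.total_iterations == 1
    assert plan.final_cells[1] == (1, 3)
    assert plan.moves[0].to_cell == (1, 3)


def test_overall_sl_never_decreases_on_random_cubes():
    rng = np.random.default_rng(123)
    for _ in range(25):
        Np = int(rng.integers(2, 7))
        cells = []
        while len(cells) < Np:
            c = (int(rng.integers(0, 5)), int(rng.integers(0, 5)))
            if c not in cells:
                cells.append(c)
        reg = _registry(cells)
        cube = _cube([rng.uniform(0.5, 9, (5, 5)) for _ in range(Np)])
        plan = optimize(reg, cube)
        assert plan.overall_sl_after >= plan.overall_sl_before - 1e-9


def test_assignment_cells_distinct_and_in_lattice(scenario, random_field):
    cube = build_cubes(random_field, scenario.registry)
    plan = optimize(scenario.registry, cube)
    cells = list(plan.final_cells.values())
    assert len(set(cells)) == len(cells) == 4
    for i, j in cells:
        assert 0 <= i < 5 and 0 <= j < 5
    assert [s.iterations for s in plan.subroutines] == [20, 12, 6, 1]
    assert plan.total_iterations == 39
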