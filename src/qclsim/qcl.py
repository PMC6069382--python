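"""Quality-controlled logistics (FEFO) pallet-placement optimizer.

Given the reconstructed temperature field of the storage room, the
optimizer asks, for every pallet p and every lattice cell (i, j): what
would the pallet's quality and shelf life be if it sat at that cell?  The
answers form two M1 × M2 × Np cubes.  Placement then proceeds greedily
over cyclic orderings of the pallet IDs:

* for one ordering, each pallet in turn takes the free cell maximising
  its own shelf life (cells taken earlier in the order are excluded);
  summing the assigned shelf lives gives the ordering's overall score —
  n placements plus 1 summation = n + 1 iterations for n pallets;
* all n cyclic left-shifts of the ID vector are scored (n·(n+1)
  iterations); the best-scoring ordering's first pallet is the "best
  pallet" and is physically moved to its assigned cell;
* the moved pallet is retired from the active set and the selection
  repeats, until a single pallet remains — that one is placed directly at
  its shelf-life argmax among free cells (1 iteration, no summation).

For Np pallets the total count is Σ_{n=2..Np} n(n+1) + 1; with four
pallets: 20 + 12 + 6 + 1 = 39.  A pallet's own cell is always a legal
target, so no pallet's shelf life can decrease and the warehouse overall
shelf life is non-decreasing under optimization.

A per-interval firmness-decrease trigger gates the whole procedure: the
displacement machinery only starts when some pallet's quality drops
faster than the configured threshold C_th (N/s) between two consecutive
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envfield import ScalarField
from .kinetics import KineticParams, QualityState, arrhenius_rate, shelf_life
from .monitor import SECONDS_PER_DAY

__all__ = [
    "Pallet",
    "PalletRegistry",
    "EncumbranceMatrix",
    "ShelfLifeCube",
    "Move",
    "SubroutineRecord",
    "MovePlan",
    "InfeasibleAssignment",
    "build_cubes",
    "displacement_trigger",
    "evaluate_order",
    "select_best",
    "optimize",
]

Cell = tuple[int, int]


class InfeasibleAssignment(RuntimeError):
    """Raised when fewer free cells than pallets remain to be placed."""


@dataclass
class Pallet:
    """One managed pallet: identity, lattice cell, state and kinetics."""

    pallet_id: int
    cell: Cell
    state: QualityState
    params: KineticParams
    c_history: list[float] = field(default_factory=list)


@dataclass
class PalletRegistry:
    """The Np pallets under management on an M1 × M2 lattice.

    IDs and cells must be distinct and Np < M1·M2 − 3 (headroom the
    optimizer needs to shuffle pallets without deadlock).
    """

    pallets: list[Pallet]
    lattice_shape: tuple[int, int]

    def __post_init__(self) -> None:
        M1, M2 = self.lattice_shape
        ids = [p.pallet_id for p in self.pallets]
        cells = [p.cell for p in self.pallets]
        if len(set(ids)) != len(ids):
            raise ValueError("pallet IDs must be distinct")
        if len(set(cells)) != len(cells):
            raise ValueError("pallet cells must be distinct")
        for i, j in cells:
            if not (0 <= i < M1 and 0 <= j < M2):
                raise ValueError(f"pallet cell ({i}, {j}) outside the lattice")
        if len(self.pallets) >= M1 * M2 - 3:
            raise ValueError(
                f"Np = {len(self.pallets)} violates Np < M1*M2 - 3 = {M1 * M2 - 3}"
            )

    @property
    def Np(self) -> int:
        return len(self.pallets)

    def by_id(self, pallet_id: int) -> Pallet:
        for p in self.pallets:
            if p.pallet_id == pallet_id:
                return p
        raise KeyError(pallet_id)


@dataclass
class EncumbranceMatrix:
    """Boolean lattice of pallet-occupied cells, for collision-free paths."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)

    @classmethod
    def from_registry(cls, registry: PalletRegistry) -> "EncumbranceMatrix":
        occ = np.zeros(registry.lattice_shape, dtype=bool)
        for p in registry.pallets:
            occ[p.cell] = True
        return cls(occ)


@dataclass
class ShelfLifeCube:
    """M1 × M2 × Np hypothetical shelf lives (day), plus the quality cube.

    ``sl[i, j, p]`` is the shelf life pallet ``pallet_ids[p]`` would have
    at cell (i, j) of the current temperature field; ``quality[i, j, p]``
    the quality it would show after one sampling interval there.
    """

    sl: np.ndarray
    quality: np.ndarray
    pallet_ids: tuple[int, ...]

    def layer(self, pallet_id: int) -> np.ndarray:
        return self.sl[:, :, self.pallet_ids.index(pallet_id)]


def build_cubes(
    field_: ScalarField, registry: PalletRegistry, ts: float = 300.0
) -> ShelfLifeCube:
    """Evaluate every pallet's hypothetical quality and shelf life per cell."""
    if not field_.is_complete:
        raise ValueError("temperature field must be fully populated (interpolated)")
    M1, M2 = field_.values.shape
    ids = tuple(p.pallet_id for p in registry.pallets)
    sl = np.zeros((M1, M2, len(ids)))
    qual = np.zeros_like(sl)
    dt = ts / SECONDS_PER_DAY
    for p_idx, p in enumerate(registry.pallets):
        for i in range(M1):
            for j in range(M2):
                k = arrhenius_rate(p.params, float(field_.values[i, j]))
                sl[i, j, p_idx] = shelf_life(p.state.c, p.params, k)
                qual[i, j, p_idx] = p.state.c * np.exp(-k * dt)
    return ShelfLifeCube(sl=sl, quality=qual, pallet_ids=ids)


def displacement_trigger(
    history, c_th: float, interval_s: float
) -> bool:
    """True iff the firmness drop between the last two consecutive
    measurements meets/exceeds ``c_th`` (N/s) over ``interval_s``."""
    history = list(history)
    if len(history) < 2:
        raise ValueError("need at least two consecutive quality measurements")
    if interval_s <= 0:
        raise ValueError("measurement interval must be positive")
    rate = (history[-2] - history[-1]) / interval_s
    return rate >= c_th


def _argmax_free(layer: np.ndarray, forbidden: set[Cell]) -> Cell:
    """Row-major-first argmax over cells not in ``forbidden``."""
    masked = layer.copy()
    for cell in forbidden:
        masked[cell] = -np.inf
    flat = int(np.argmax(masked))
    if not np.isfinite(masked.flat[flat]):
        raise InfeasibleAssignment("no free cell available for placement")
    return tuple(int(v) for v in np.unravel_index(flat, layer.shape))


@dataclass
class OrderEvaluation:
    """Greedy outcome for one cyclic ordering of the active IDs."""

    order: tuple[int, ...]
    assignment: dict[int, Cell]
    sls: float
    iterations: int


def evaluate_order(
    order,
    cube: ShelfLifeCube,
    current_cells: dict[int, Cell],
    blocked: set[Cell] | None = None,
) -> OrderEvaluation:
    """Greedy placement of the active pallets in the given order.

    Each pallet takes the free cell maximising its shelf-life layer.  A
    cell is free when it is not blocked (occupied by an already-retired
    pallet), not the current cell of a *different* active pallet, and not
    already assigned within this order; a pallet's own cell is always
    allowed.  Iteration count: one per placement plus one for the final
    shelf-life summation (n + 1).
    """
    order = tuple(order)
    if sorted(order) != sorted(current_cells):
        raise ValueError("order must be a permutation of the active pallet IDs")
    blocked = set(blocked or ())
    assignment: dict[int, Cell] = {}
    iterations = 0
    for pid in order:
        forbidden = set(blocked)
        forbidden.update(c for q, c in current_cells.items() if q != pid)
        forbidden.update(assignment.values())
        forbidden.discard(current_cells[pid])
        assignment[pid] = _argmax_free(cube.layer(pid), forbidden)
        iterations += 1
    sls = float(sum(cube.layer(pid)[assignment[pid]] for pid in order))
    iterations += 1  # the summation defining SLs
    return OrderEvaluation(order=order, assignment=assignment, sls=sls,
                           iterations=iterations)


@dataclass
class SelectionResult:
    """Winner of one selection subroutine over the cyclic orderings."""

    winning_order: tuple[int, ...]
    best_pallet: int
    target_cell: Cell
    iterations: int
    sls_by_order: list[float]


def select_best(
    active_ids,
    cube: ShelfLifeCube,
    current_cells: dict[int, Cell],
    blocked: set[Cell] | None = None,
) -> SelectionResult:
    """Score the n cyclic left-shifts of the active ID vector; pick the best.

    Returns the winning ordering, the pallet to displace (its first ID)
    and that pallet's assigned cell.  Iterations: n orderings × (n + 1)
    = n(n + 1).  Ties are broken in favour of the earliest cyclic shift.
    """
    ids = list(active_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("selection needs at least 2 active pallets; "
                         "place a lone pallet directly")
    iterations = 0
    best: OrderEvaluation | None = None
    sls_by_order: list[float] = []
    for shift in range(n):
        order = tuple(ids[shift:] + ids[:shift])
        ev = evaluate_order(order, cube, current_cells, blocked)
        iterations += ev.iterations
        sls_by_order.append(ev.sls)
        if best is None or ev.sls > best.sls:
            best = ev
    first = best.order[0]
    return SelectionResult(
        winning_order=best.order,
        best_pallet=first,
        target_cell=best.assignment[first],
        iterations=iterations,
        sls_by_order=sls_by_order,
    )


@dataclass(frozen=True)
class Move:
    pallet_id: int
    from_cell: Cell
    to_cell: Cell


@dataclass
class SubroutineRecord:
    n_active: int
    iterations: int
    best_pallet: int
    target_cell: Cell
    sls_by_order: list[float]


@dataclass
class MovePlan:
    """Full optimization outcome: the move schedule and its accounting."""

    moves: list[Move]
    final_cells: dict[int, Cell]
    subroutines: list[SubroutineRecord]
    total_iterations: int
    overall_sl_before: float
    overall_sl_after: float


def optimize(
    registry: PalletRegistry,
    cube: ShelfLifeCube,
    em: EncumbranceMatrix | None = None,
) -> MovePlan:
    """Run the full recursive selection until every pallet is placed.

    The cube is frozen for the whole run (temperatures and qualities are
    not re-sampled mid-optimization).  Each round retires the selected
    best pallet at its target cell; the last pallet goes straight to its
    shelf-life argmax among the remaining free cells, counted as a single
    iteration.
    """
    active = [p.pallet_id for p in registry.pallets]
    current: dict[int, Cell] = {p.pallet_id: p.cell for p in registry.pallets}
    initial = dict(current)
    blocked: set[Cell] = set()
    if em is not None:
        # externally-declared obstructions beyond the managed pallets
        occ = em.occupancy
        pallet_cells = set(current.values())
        blocked |= {
            (i, j)
            for i in range(occ.shape[0])
            for j in range(occ.shape[1])
            if occ[i, j] and (i, j) not in pallet_cells
        }
    moves: list[Move] = []
    final: dict[int, Cell] = {}
    subroutines: list[SubroutineRecord] = []
    total = 0
    while len(active) >= 2:
        sel = select_best(active, cube, {pid: current[pid] for pid in active},
                          blocked)
        total += sel.iterations
        subroutines.append(
            SubroutineRecord(
                n_active=len(active),
                iterations=sel.iterations,
                best_pallet=sel.best_pallet,
                target_cell=sel.target_cell,
                sls_by_order=sel.sls_by_order,
            )
        )
        src = current.pop(sel.best_pallet)
        if sel.target_cell != src:
            moves.append(Move(sel.best_pallet, src, sel.target_cell))
        final[sel.best_pallet] = sel.target_cell
        blocked.add(sel.target_cell)
        active.remove(sel.best_pallet)
    # final lone pallet: direct placement, one iteration, no summation
    pid = active[0]
    forbidden = set(blocked)
    forbidden.discard(current[pid])
    target = _argmax_free(cube.layer(pid), forbidden)
    total += 1
    subroutines.append(
        SubroutineRecord(
            n_active=1, iterations=1, best_pallet=pid, target_cell=target,
            sls_by_order=[],
        )
    )
    if target != current[pid]:
        moves.append(Move(pid, current[pid], target))
    final[pid] = target
    before = float(
        sum(cube.layer(pid_)[initial[pid_]] for pid_ in initial)
    )
    after = float(sum(cube.layer(pid_)[final[pid_]] for pid_ in final))
    return MovePlan(
        moves=moves,
        final_cells=final,
        subroutines=subroutines,
        total_iterations=total,
        overall_sl_before=before,
        overall_sl_after=after,
    )
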