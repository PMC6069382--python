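"""Automated-transporter layer: command codec, path planning, drive logic.

The central unit drives each pallet transporter over a Bluetooth link with
a fixed 12-byte command string,

    [89, add_btT, add_btP, 89, 90, x1, y1, 90, 91, x2, y2, 91]

where 89/90/91 are separators, ``add_btT``/``add_btP`` address the
transporter and the pallet, and the coordinate pairs give the current and
next lattice node.  Transporters are driven strictly step-by-step: each
command's target differs from its start by exactly one unit along one
axis, so paths are planned as unit-step 4-neighbour walks around the
encumbrance matrix (breadth-first search, deterministic tie-breaks).

The drive logic is a small state machine over the transporter's heading
(one of four compass directions): a unit step along the heading actuates
the DC motors forward (IN1, IN2) = (0, 1) with the steering servo at its
central angle Cp; a step against the heading reverses (1, 0); a
perpendicular step steers the servo to Cp ± Rs and updates the heading.
The axis-of-travel memory bit Z (0 = x-axis, 1 = y-axis) is exposed as in
the on-board pseudocode.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SEPARATORS",
    "TransportCommand",
    "CommandDecodeError",
    "WrongLengthError",
    "SeparatorError",
    "OutOfRangeError",
    "AddressMismatch",
    "InfeasiblePath",
    "InvalidStepError",
    "PathPlan",
    "DriveState",
    "DriveOutputs",
    "encode_command",
    "decode_command",
    "plan_path",
    "drive_step",
    "simulate_route",
    "step_bits",
]

SEPARATORS = (89, 90, 91)

Cell = tuple[int, int]


class CommandDecodeError(ValueError):
    """Base class for command-string rejections."""


class WrongLengthError(CommandDecodeError):
    pass


class SeparatorError(CommandDecodeError):
    pass


class OutOfRangeError(CommandDecodeError):
    """Coordinates beyond (Max1, Max2): wait for the next communication."""


class AddressMismatch(CommandDecodeError):
    """Command addressed to a different transporter; close the channel."""


class InfeasiblePath(RuntimeError):
    pass


class InvalidStepError(ValueError):
    """A commanded step changes more than one coordinate by more than one."""


@dataclass(frozen=True)
class TransportCommand:
    """One displacement command (all fields byte-ranged)."""

    add_btT: int
    add_btP: int
    init_coord: tuple[int, int]
    final_coord: tuple[int, int]

    def __post_init__(self) -> None:
        fields = (self.add_btT, self.add_btP, *self.init_coord, *self.final_coord)
        for v in fields:
            if not (0 <= int(v) <= 255):
                raise ValueError(f"command field {v} outside byte range 0-255")


def encode_command(cmd: TransportCommand) -> bytes:
    """Serialise to the 12-byte separator-delimited layout."""
    s1, s2, s3 = SEPARATORS
    x1, y1 = cmd.init_coord
    x2, y2 = cmd.final_coord
    return bytes([s1, cmd.add_btT, cmd.add_btP, s1, s2, x1, y1, s2, s3, x2, y2, s3])


def decode_command(
    data: bytes, max1: int | None = None, max2: int | None = None
) -> TransportCommand:
    """Parse and validate a 12-byte command string.

    Distinct rejection types: wrong length, corrupted separator, and
    coordinates beyond the lattice bounds (Max1, Max2) when given.
    """
    data = bytes(data)
    if len(data) != 12:
        raise WrongLengthError(f"expected 12 bytes, got {len(data)}")
    s1, s2, s3 = SEPARATORS
    expected = {0: s1, 3: s1, 4: s2, 7: s2, 8: s3, 11: s3}
    for pos, val in expected.items():
        if data[pos] != val:
            raise SeparatorError(f"byte {pos} is {data[pos]}, expected separator {val}")
    cmd = TransportCommand(
        add_btT=data[1],
        add_btP=data[2],
        init_coord=(data[5], data[6]),
        final_coord=(data[9], data[10]),
    )
    if max1 is not None and max2 is not None:
        for (x, y) in (cmd.init_coord, cmd.final_coord):
            if x > max1 or y > max2:
                raise OutOfRangeError(
                    f"coordinate ({x}, {y}) beyond lattice bounds ({max1}, {max2})"
                )
    return cmd


@dataclass(frozen=True)
class PathPlan:
    """A unit-step waypoint sequence from start to goal (inclusive)."""

    waypoints: tuple[Cell, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.waypoints, self.waypoints[1:]):
            if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
                raise ValueError(f"non-unit hop {a} -> {b}")

    def __len__(self) -> int:
        return len(self.waypoints)


def plan_path(start: Cell, goal: Cell, occupancy: np.ndarray) -> PathPlan:
    """Shortest collision-free unit-step path by breadth-first search.

    ``occupancy`` is the encumbrance matrix (True = blocked); the start
    and goal cells must themselves be free of *other* pallets.  Neighbour
    expansion prefers x-axis (column) moves first, then increasing index,
    which fixes the tie-break among equally short paths.
    """
    occ = np.asarray(occupancy, dtype=bool)
    M1, M2 = occ.shape

    def in_bounds(c: Cell) -> bool:
        return 0 <= c[0] < M1 and 0 <= c[1] < M2

    if not (in_bounds(start) and in_bounds(goal)):
        raise ValueError("start/goal outside the lattice")
    if occ[goal] or (occ[start] and start != goal):
        raise InfeasiblePath("start or goal cell is occupied")
    if start == goal:
        return PathPlan((start,))
    parent: dict[Cell, Cell] = {start: start}
    queue: deque[Cell] = deque([start])
    while queue:
        i, j = queue.popleft()
        for ni, nj in ((i, j - 1), (i, j + 1), (i - 1, j), (i + 1, j)):
            nxt = (ni, nj)
            if not in_bounds(nxt) or nxt in parent or occ[nxt]:
                continue
            parent[nxt] = (i, j)
            if nxt == goal:
                path = [nxt]
                while path[-1] != start:
                    path.append(parent[path[-1]])
                return PathPlan(tuple(reversed(path)))
            queue.append(nxt)
    raise InfeasiblePath(f"no collision-free path from {start} to {goal}")


#: Two-bit encoding of a signed unit step: 0 -> 00, +1 -> 01, -1 -> 11.
def step_bits(d: int) -> tuple[int, int]:
    if d == 0:
        return (0, 0)
    if d == 1:
        return (0, 1)
    if d == -1:
        return (1, 1)
    raise InvalidStepError(f"step component must be in {{-1, 0, 1}}, got {d}")


@dataclass(frozen=True)
class DriveState:
    """Transporter drive state: heading vector, axis bit and servo angles.

    ``heading`` is a unit (dx, dy) vector in the lattice frame; ``z`` is 1
    when the last travel axis was y, 0 for x.  ``cp`` is the steering
    servo's central angle and ``rs`` the rotation increment (degrees).
    """

    heading: tuple[int, int] = (1, 0)
    z: int = 0
    cp: float = 90.0
    rs: float = 30.0

    def __post_init__(self) -> None:
        if self.heading not in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            raise ValueError(f"heading must be a unit axis vector, got {self.heading}")
        if self.z not in (0, 1):
            raise ValueError("z must be 0 or 1")


@dataclass(frozen=True)
class DriveOutputs:
    """Actuator outputs for one step: servo angle and DC-motor input pair."""

    wheel_angle: float
    in1: int
    in2: int

    @property
    def event(self) -> str:
        if self.in1 == self.in2:
            return "keep"
        return "ahead" if (self.in1, self.in2) == (0, 1) else "backward"


def drive_step(state: DriveState, dX: int, dY: int) -> tuple[DriveState, DriveOutputs]:
    """Actuate one unit grid step from the current drive state.

    Motor truth table: (IN1, IN2) = (0, 1) go ahead, (1, 0) go backward,
    equal bits keep position.  Steering: the servo stays at Cp for
    straight travel and swings to Cp ± Rs for a perpendicular step (sign
    by turn direction), after which the heading follows the step.
    """
    step_bits(dX), step_bits(dY)  # validates the components
    if abs(dX) + abs(dY) > 1:
        raise InvalidStepError(
            f"step ({dX}, {dY}) changes both axes; paths must be unit steps"
        )
    if (dX, dY) == (0, 0):
        return state, DriveOutputs(wheel_angle=state.cp, in1=0, in2=0)
    hx, hy = state.heading
    z_new = 1 if dY != 0 else 0
    if (dX, dY) == (hx, hy):  # straight ahead
        return (
            DriveState(heading=state.heading, z=z_new, cp=state.cp, rs=state.rs),
            DriveOutputs(wheel_angle=state.cp, in1=0, in2=1),
        )
    if (dX, dY) == (-hx, -hy):  # reverse without turning
        return (
            DriveState(heading=state.heading, z=z_new, cp=state.cp, rs=state.rs),
            DriveOutputs(wheel_angle=state.cp, in1=1, in2=0),
        )
    # perpendicular: steer, go ahead, heading follows the step
    cross = hx * dY - hy * dX  # +1 left turn, -1 right turn
    angle = state.cp - state.rs if cross > 0 else state.cp + state.rs
    return (
        DriveState(heading=(dX, dY), z=z_new, cp=state.cp, rs=state.rs),
        DriveOutputs(wheel_angle=angle, in1=0, in2=1),
    )


@dataclass
class RouteTrace:
    """Replay record: visited cells, actuations and the final drive state."""

    cells: list[Cell]
    outputs: list[DriveOutputs]
    final_state: DriveState

    @property
    def steering_events(self) -> int:
        cp = self.final_state.cp
        return sum(1 for o in self.outputs if o.wheel_angle != cp)


def simulate_route(
    plan: PathPlan, initial_heading: tuple[int, int] = (1, 0),
    cp: float = 90.0, rs: float = 30.0,
) -> RouteTrace:
    """Drive a planned route hop by hop and record the trajectory.

    Waypoints are (x, y) lattice nodes; each hop becomes one ``drive_step``
    actuation.  The trace ends exactly at the plan's goal cell.
    """
    state = DriveState(heading=initial_heading, cp=cp, rs=rs)
    cells = [plan.waypoints[0]]
    outputs: list[DriveOutputs] = []
    for a, b in zip(plan.waypoints, plan.waypoints[1:]):
        dX, dY = b[0] - a[0], b[1] - a[1]
        state, out = drive_step(state, dX, dY)
        outputs.append(out)
        cells.append(b)
    return RouteTrace(cells=cells, outputs=outputs, final_state=state)
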