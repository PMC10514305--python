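"""Bidirectional permeation-event counting through the pore.

A permeation event is a completed side-to-side traversal of the detection
cylinder (default radius 2 nm, −0.6 nm ≤ d_pore ≤ 0.6 nm): a molecule that
enters the cylinder from one axial side and exits on the other.  The large
radius (relative to the 0.7 nm occupancy cylinder) prevents spurious counts
from molecules that leave and re-enter laterally near the axial centre; we
additionally disarm a pending entry on any lateral exit.

Detection is a per-molecule finite-state machine over the frame-wise region
sequence (below / inside / above / outside-lateral):

* arming on a below→inside or above→inside transition (entry side recorded),
* firing one event on a subsequent inside→opposite-side transition,
* disarming without an event on inside→same-side or inside→lateral exits,
* molecules that start inside are unarmed until they first leave.

A molecule that jumps straight from below to above (or vice versa) within
one frame stride is counted only if the straight-line interpolated path
stays inside the cylinder radius where it crosses both axial faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .pore_frame import AlignedTrajectory, pore_coordinates

BELOW, INSIDE, ABOVE, LATERAL = 0, 1, 2, 3


@dataclass
class DetectionCylinder:
    """The permeation detection cylinder (radius and axial bounds, nm)."""

    radius: float = 2.0
    z_lo: float = -0.6
    z_hi: float = 0.6

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InputError("detection radius must be positive")
        if not self.z_lo < self.z_hi:
            raise InputError("detection bounds must satisfy z_lo < z_hi")


@dataclass
class PermeationEvent:
    """One completed side-to-side traversal of the detection cylinder."""

    species: str
    molecule_id: int
    entry_frame: int
    entry_side: str  # "below" | "above"
    exit_frame: int
    exit_side: str
    direction: int  # +1 = toward +z (concave/outer face), -1 = toward -z
    interpolated: bool = False

    def __post_init__(self) -> None:
        if self.entry_side == self.exit_side:
            raise InputError("entry and exit side must differ")
        if self.exit_frame <= self.entry_frame:
            raise InputError("exit frame must follow entry frame")


@dataclass
class PermeationRate:
    """Events per ns, aggregated over replicas."""

    species: str
    rate: float  # mean of per-replica rates, events/ns
    se: float  # sample SD / sqrt(n) across replicas
    total_events: int
    total_time_ns: float
    pooled_rate: float  # total events / total time
    n_replicas: int


def classify_region(d_pore, r, cyl: DetectionCylinder):
    """Region code for each point: below/inside/above (r ≤ radius) or lateral."""
    d_pore = np.asarray(d_pore)
    r = np.asarray(r)
    region = np.full(d_pore.shape, LATERAL, dtype=np.int8)
    radial_ok = r <= cyl.radius
    region[radial_ok & (d_pore < cyl.z_lo)] = BELOW
    region[radial_ok & (d_pore > cyl.z_hi)] = ABOVE
    region[radial_ok & (d_pore >= cyl.z_lo) & (d_pore <= cyl.z_hi)] = INSIDE
    return region


_SIDE_NAME = {BELOW: "below", ABOVE: "above"}


def _jump_crossing_ok(p0: np.ndarray, p1: np.ndarray, cyl: DetectionCylinder) -> bool:
    """Does the straight segment p0→p1 stay within the radius at both faces?"""
    dz = p1[2] - p0[2]
    if dz == 0:
        return False
    for z_face in (cyl.z_lo, cyl.z_hi):
        s = (z_face - p0[2]) / dz
        if not 0.0 <= s <= 1.0:
            return False
        x = p0[0] + s * (p1[0] - p0[0])
        y = p0[1] + s * (p1[1] - p0[1])
        if np.hypot(x, y) > cyl.radius:
            return False
    return True


def detect_events(
    aligned: AlignedTrajectory | np.ndarray,
    species: str | None = None,
    cyl: DetectionCylinder | None = None,
    times: np.ndarray | None = None,
    disarm_on_lateral: bool = True,
    box: np.ndarray | float | None = None,
) -> list[PermeationEvent]:
    """Run the permeation state machine over every molecule track.

    ``aligned`` may be an :class:`AlignedTrajectory` (with ``species``
    naming the tracks) or a raw (F, M, 3) aligned-position array.

    ``box`` (edge lengths, nm; scalar, (3,) or per-frame (F, 3)) lets the
    jump interpolation distinguish a genuine fast traversal from a periodic
    wrap: a molecule wrapping across the far z boundary appears to jump from
    far below to far above, but its minimum-image path never passes through
    the pore and must not be counted.
    """
    if cyl is None:
        cyl = DetectionCylinder()
    if isinstance(aligned, AlignedTrajectory):
        if species is None:
            raise InputError("species must be named for an AlignedTrajectory")
        tr = aligned.tracks[species]
        positions = tr.positions
        times = tr.times
        mol_ids = tr.molecule_ids
        label = species
    else:
        positions = np.asarray(aligned, dtype=float)
        mol_ids = np.arange(positions.shape[1])
        label = species or "species"
    if positions.shape[0] < 2:
        raise InputError("need at least two frames to detect events")
    if times is not None and len(times) > 1 and not np.all(np.diff(times) > 0):
        raise InputError("frames must be sorted by strictly increasing time")
    if box is not None:
        box = np.asarray(box, dtype=float)
        if box.ndim == 0:
            box = np.repeat(box, 3)

    d, r = pore_coordinates(positions)
    regions = classify_region(d, r, cyl)  # (F, M)
    F, M = regions.shape
    events: list[PermeationEvent] = []
    for m in range(M):
        seq = regions[:, m]
        armed_side = None  # BELOW or ABOVE while armed
        entry_frame = -1
        prev = seq[0]
        for f in range(1, F):
            cur = seq[f]
            if cur == prev:
                continue
            if prev in (BELOW, ABOVE) and cur == INSIDE:
                armed_side = prev
                entry_frame = f
            elif prev == INSIDE and cur in (BELOW, ABOVE):
                if armed_side is not None and cur != armed_side:
                    events.append(
                        PermeationEvent(
                            species=label,
                            molecule_id=int(mol_ids[m]),
                            entry_frame=entry_frame,
                            entry_side=_SIDE_NAME[armed_side],
                            exit_frame=f,
                            exit_side=_SIDE_NAME[cur],
                            direction=+1 if cur == ABOVE else -1,
                        )
                    )
                armed_side = None
            elif prev == INSIDE and cur == LATERAL:
                if disarm_on_lateral:
                    armed_side = None
            elif prev in (BELOW, ABOVE) and cur in (BELOW, ABOVE):
                # direct below<->above jump with no inside frame
                p0 = positions[f - 1, m]
                p1 = positions[f, m]
                if box is not None:
                    b = box[f] if box.ndim == 2 else box
                    disp = p1 - p0
                    p1 = p0 + disp - b * np.round(disp / b)
                crosses = (p0[2] < cyl.z_lo < cyl.z_hi < p1[2]) or (
                    p1[2] < cyl.z_lo < cyl.z_hi < p0[2]
                )
                if crosses and _jump_crossing_ok(p0, p1, cyl):
                    events.append(
                        PermeationEvent(
                            species=label,
                            molecule_id=int(mol_ids[m]),
                            entry_frame=f - 1,
                            entry_side=_SIDE_NAME[prev],
                            exit_frame=f,
                            exit_side=_SIDE_NAME[cur],
                            direction=+1 if p1[2] > p0[2] else -1,
                            interpolated=True,
                        )
                    )
                armed_side = None
            # lateral -> below/above/inside never arms
            prev = cur
    return events


def permeation_rate(
    events_per_replica: list[list[PermeationEvent]] | list[int],
    durations_ns: list[float],
    species: str = "species",
) -> PermeationRate:
    """Events-per-ns rate with mean ± SE across replicas and the pooled rate.

    ``events_per_replica`` may hold event lists or bare counts, paired with
    per-replica simulated durations in ns.
    """
    if len(events_per_replica) != len(durations_ns):
        raise InputError("one duration per replica is required")
    if any(d <= 0 for d in durations_ns):
        raise InputError("replica durations must be positive")
    counts = np.array(
        [e if isinstance(e, (int, np.integer)) else len(e) for e in events_per_replica],
        dtype=float,
    )
    durations = np.asarray(durations_ns, dtype=float)
    rates = counts / durations
    n = len(rates)
    se = 0.0 if n == 1 else float(rates.std(ddof=1) / np.sqrt(n))
    return PermeationRate(
        species=species,
        rate=float(rates.mean()),
        se=se,
        total_events=int(counts.sum()),
        total_time_ns=float(durations.sum()),
        pooled_rate=float(counts.sum() / durations.sum()),
        n_replicas=n,
    )


def events_table(events: list[PermeationEvent]):
    """Tidy events table for export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "species": e.species,
                "molecule_id": e.molecule_id,
                "entry_frame": e.entry_frame,
                "entry_side": e.entry_side,
                "exit_frame": e.exit_frame,
                "exit_side": e.exit_side,
                "direction": e.direction,
                "interpolated": e.interpolated,
            }
            for e in events
        ]
    )
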