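"""State assignment and detachment-path classification in CV space.

Detachment trajectories fall into three broad mechanism groups:

* ``LINEAR`` — direct detachment: distance grows while coordination drops,
  with no qualifying stop-over in an intermediate state;
* ``FLIPPED_INTERMEDIATE`` — the molecule passes through the orientation-
  reversed (angle ~ 0) in-lattice configuration on its way out;
* ``VIA_DISORDERED`` — the molecule lingers in orientationally disordered,
  partially coordinated configurations before leaving.

Because a disordered excursion can precede or follow a flipped one, labels
follow the documented precedence flipped > disordered > linear; the full
visited-state sequence is reported alongside so paths can be re-binned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .trajectory import CVTrajectory

PATH_LABELS = ("LINEAR", "FLIPPED_INTERMEDIATE", "VIA_DISORDERED")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Region:
    """An axis-aligned half-open box [lo, hi) in CV space.

    On a periodic (angle) dimension an interval with lo > hi wraps through
    the +-pi seam, e.g. (2.4, -2.4) covers |angle| >= 2.4.
    """

    intervals: tuple  # per-dim (lo, hi)

    def __post_init__(self):
        iv = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", iv)

    @property
    def ndim(self) -> int:
        return len(self.intervals)

    def contains_many(self, points, periodic) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ok = np.ones(len(pts), dtype=bool)
        for d, (lo, hi) in enumerate(self.intervals):
            x = pts[:, d]
            if periodic[d] and lo > hi:
                ok &= (x >= lo) | (x < hi)
            else:
                ok &= (x >= lo) & (x < hi)
        return ok

    def _arcs(self, d, periodic):
        """Plain half-open interval(s) on dimension d (split at the seam)."""
        lo, hi = self.intervals[d]
        if periodic[d] and lo > hi:
            return [(lo, math.pi), (-math.pi, hi)]
        return [(lo, hi)]


def _intervals_overlap(a, b) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class StatePartition:
    """Named disjoint regions over CV space (crystalline / flipped /
    disordered / detached for the detachment landscape)."""

    regions: dict
    periodic: tuple = None

    def __post_init__(self):
        if not self.regions:
            raise ValidationError("StatePartition: no regions")
        ndims = {r.ndim for r in self.regions.values()}
        if len(ndims) != 1:
            raise ValidationError("StatePartition: regions of mixed dimensionality")
        self.ndim = ndims.pop()
        if self.periodic is None:
            self.periodic = (False,) * self.ndim
        self.periodic = tuple(bool(p) for p in np.atleast_1d(self.periodic))
        if len(self.periodic) != self.ndim:
            raise ValidationError("StatePartition: periodic flags length mismatch")
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self._overlap(self.regions[a], self.regions[b]):
                    raise ValidationError(
                        f"StatePartition: regions {a!r} and {b!r} overlap"
                    )

    def _overlap(self, ra: Region, rb: Region) -> bool:
        for d in range(self.ndim):
            arcs_a = ra._arcs(d, self.periodic)
            arcs_b = rb._arcs(d, self.periodic)
            if not any(
                _intervals_overlap(a, b) for a in arcs_a for b in arcs_b
            ):
                return False
        return True

    def assign_many(self, points) -> np.ndarray:
        """State label per point ('unassigned' where no region matches)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(pts), UNASSIGNED, dtype=object)
        for name, region in self.regions.items():
            hit = region.contains_many(pts, self.periodic)
            out[hit] = name
        return out


def assign_state(s, partition: StatePartition) -> str:
    """Deterministic box membership of a single CV point."""
    return str(partition.assign_many(np.atleast_2d(np.asarray(s, dtype=float)))[0])


def default_partition(name: str = "detachment_3d") -> StatePartition:
    """Package-constant basin boxes for the detachment_3d landscape."""
    if name == "detachment_3d":
        return StatePartition(
            {
                "crystalline": Region(((4.5, 7.5), (-0.5, 0.5), (2.4, -2.4))),
                "flipped": Region(((4.5, 7.5), (-0.5, 0.5), (-0.8, 0.8))),
                "disordered": Region(((-0.5, 4.5), (-0.5, 1.2), (-4.0, 4.0))),
                "detached": Region(((-0.5, 1.2), (1.6, 2.8), (-4.0, 4.0))),
            },
            periodic=(False, False, True),
        )
    if name == "double_well_1d":
        # the detached (product) boundary sits just past the barrier top so
        # thermal fluctuations around the product minimum (+-0.16 at 5 kT)
        # cannot break a commitment streak
        return StatePartition(
            {"reactant": Region(((-2.5, -0.5),)), "detached": Region(((0.5, 2.5),))}
        )
    raise ValidationError(f"no default partition for potential {name!r}")


def first_committed_entry(states, name: str, commitment: int):
    """Index of the first entry into ``name`` that persists >= commitment
    consecutive frames; None if never committed."""
    hit = np.asarray(states) == name
    run = 0
    for i, h in enumerate(hit):
        run = run + 1 if h else 0
        if run >= commitment:
            return i - commitment + 1
    return None


def _runs(states):
    """Run-length encode a state sequence into (state, length) pairs."""
    out = []
    for s in states:
        if out and out[-1][0] == s:
            out[-1][1] += 1
        else:
            out.append([s, 1])
    return [(s, n) for s, n in out]


@dataclass
class PathLabel:
    """Mechanism label plus the qualifying visited-state evidence."""

    label: str
    visited: list  # (state, dwell frames) runs with dwell >= min_dwell
    dwell_counts: dict  # total frames per state between leaving crystalline
    #                     and committing to detached
    replica_id: str = "0"

    def __post_init__(self):
        if self.label not in PATH_LABELS:
            raise ValidationError(f"PathLabel: unknown label {self.label!r}")


def classify_path(
    traj: CVTrajectory,
    partition: StatePartition,
    min_dwell: int = 5,
    commitment: int = 10,
    reactant_state: str = "crystalline",
    product_state: str = "detached",
) -> PathLabel:
    """Classify one detachment trajectory.

    The trajectory must commit to the product region (>= ``commitment``
    consecutive frames). The classification window runs from the first
    departure out of ``reactant_state`` to the commitment; intermediate
    states dwelling >= ``min_dwell`` consecutive frames anywhere in that
    window are recorded (re-entries into the reactant state are not counted
    as intermediates). Precedence: flipped > disordered > linear — any
    qualifying flipped dwell labels the path FLIPPED_INTERMEDIATE.
    """
    states = partition.assign_many(traj.points)
    k = first_committed_entry(states, product_state, commitment)
    if k is None:
        raise ValidationError(
            "classify_path: trajectory never commits to the product region; "
            "run detect_transition first to filter non-detaching replicas"
        )
    in_reactant = np.flatnonzero(states[:k] == reactant_state)
    if len(in_reactant):
        # end of the initial reactant dwell = first departure
        gaps = np.flatnonzero(np.diff(in_reactant) > 1)
        j = int(in_reactant[gaps[0]]) if len(gaps) else int(in_reactant[-1])
    else:
        j = -1
    segment = states[j + 1 : k]
    runs = _runs(segment)
    qualifying = [
        (s, n)
        for s, n in runs
        if n >= min_dwell and s not in (UNASSIGNED, reactant_state)
    ]
    dwell = {}
    for s, n in runs:
        dwell[s] = dwell.get(s, 0) + n
    if any(s == "flipped" for s, _ in qualifying):
        label = "FLIPPED_INTERMEDIATE"
    elif any(s == "disordered" for s, _ in qualifying):
        label = "VIA_DISORDERED"
    else:
        label = "LINEAR"
    return PathLabel(label, qualifying, dwell, replica_id=traj.replica_id)


def mechanism_fractions(labels) -> dict:
    """Fractions and counts of each mechanism over a set of path labels."""
    labels = list(labels)
    if not labels:
        raise ValidationError("mechanism_fractions: no labels")
    counts = {name: 0 for name in PATH_LABELS}
    for lab in labels:
        key = lab.label if isinstance(lab, PathLabel) else str(lab)
        if key not in counts:
            raise ValidationError(f"mechanism_fractions: unknown label {key!r}")
        counts[key] += 1
    n = len(labels)
    return {
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()},
        "n": n,
    }
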