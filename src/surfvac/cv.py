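"""Collective variables for surface detachment, computed from coordinate frames.

Three CVs describe the removal of a tagged ("biased") molecule from a crystal
slab:

* **coordination number** — a smooth count of solute neighbours of the tagged
  molecule within a cutoff, via the rational switching function
  ``s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m)`` (value ``n/m`` at the removable
  singularity ``r = r0``);
* **z distance** — signed height of the tagged molecule's centroid above a
  reference point in the crystal bulk (no periodic wrapping along z: the slab
  is periodic laterally only);
* **alignment angle** — signed angle in ``[-pi, pi)`` between the molecular
  axis (first -> last tagged particle) and the reference crystalline axis.
  The sign is taken from the projection of ``axis x reference_axis`` onto the
  ``plane_normal``; with the packaged fixtures the crystal-like configuration
  sits at +-pi and the flipped configuration at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .grids import wrap_angle
from .trajectory import CVTrajectory

CV_NAMES = ("cn", "dist", "angle")


@dataclass
class MolecularFrame:
    """One coordinate frame of the solute-in-slab fixture (lengths in nm)."""

    coordinates: np.ndarray
    biased_indices: tuple
    neighbor_indices: tuple
    reference_point: np.ndarray
    reference_axis: np.ndarray
    plane_normal: np.ndarray
    box: tuple

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.biased_indices = tuple(int(i) for i in self.biased_indices)
        self.neighbor_indices = tuple(int(i) for i in self.neighbor_indices)
        self.reference_point = np.asarray(self.reference_point, dtype=float).reshape(3)
        self.reference_axis = np.asarray(self.reference_axis, dtype=float).reshape(3)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float).reshape(3)
        self.box = tuple(float(b) for b in self.box)
        n = len(self.coordinates)
        allidx = self.biased_indices + self.neighbor_indices
        if len(self.biased_indices) < 1:
            raise ValidationError("MolecularFrame: no biased particles tagged")
        if set(self.biased_indices) & set(self.neighbor_indices):
            raise ValidationError("MolecularFrame: biased and neighbor indices overlap")
        if any(i < 0 or i >= n for i in allidx):
            raise ValidationError("MolecularFrame: particle index out of range")
        for name, v in (("reference_axis", self.reference_axis), ("plane_normal", self.plane_normal)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValidationError(f"MolecularFrame: {name} must have unit norm")
        if np.linalg.norm(np.cross(self.reference_axis, self.plane_normal)) < 1e-6:
            raise ValidationError("MolecularFrame: reference_axis parallel to plane_normal")
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValidationError("MolecularFrame: box must be three positive lengths")

    @property
    def biased_centroid(self) -> np.ndarray:
        return self.coordinates[list(self.biased_indices)].mean(axis=0)

    @property
    def molecular_axis(self) -> np.ndarray:
        a = (
            self.coordinates[self.biased_indices[-1]]
            - self.coordinates[self.biased_indices[0]]
        )
        nrm = np.linalg.norm(a)
        if nrm <= 1e-6:
            raise ValidationError(
                "MolecularFrame: degenerate molecular axis (norm <= 1e-6 nm)"
            )
        return a / nrm


@dataclass(frozen=True)
class SwitchingSpec:
    """Rational switching function parameters (cutoff r0 in nm, m > n > 0)."""

    r0: float = 0.7
    n: int = 6
    m: int = 12

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValidationError("SwitchingSpec: r0 must be positive")
        if not (self.m > self.n > 0):
            raise ValidationError("SwitchingSpec: require m > n > 0")

    def value(self, r):
        """s(r), vectorised; the removable singularity at r = r0 -> n/m."""
        r = np.asarray(r, dtype=float)
        x = r / self.r0
        xn = x**self.n
        xm = x**self.m
        den = 1.0 - xm
        out = np.where(
            np.abs(den) < 1e-12, self.n / self.m, (1.0 - xn) / np.where(den == 0, 1.0, den)
        )
        return out if out.ndim else float(out)


def minimum_image_xy(delta, box):
    """Minimum-image convention applied in x, y only (lateral slab periodicity)."""
    d = np.array(delta, dtype=float, copy=True)
    d = np.atleast_2d(d)
    for k in (0, 1):
        d[:, k] -= box[k] * np.round(d[:, k] / box[k])
    return d


def coordination_number(frame: MolecularFrame, spec: SwitchingSpec) -> float:
    """Smooth neighbour count of the biased molecule; in [0, n_neighbors]."""
    if not frame.neighbor_indices:
        return 0.0
    centroid = frame.biased_centroid
    delta = frame.coordinates[list(frame.neighbor_indices)] - centroid
    delta = minimum_image_xy(delta, frame.box)
    r = np.linalg.norm(delta, axis=1)
    if np.any(r < 1e-9):
        raise ValidationError("coordination_number: overlapping molecules (r ~ 0)")
    return float(np.sum(spec.value(r)))


def z_distance(frame: MolecularFrame) -> float:
    """Signed centroid height above the bulk reference point (no z wrapping)."""
    return float(frame.biased_centroid[2] - frame.reference_point[2])


def alignment_angle(frame: MolecularFrame) -> float:
    """Signed angle in [-pi, pi) between molecular axis and reference axis."""
    a = frame.molecular_axis
    e = frame.reference_axis
    nrm = frame.plane_normal
    ang = np.arctan2(np.dot(np.cross(a, e), nrm), np.dot(a, e))
    return float(wrap_angle(ang))


def compute_colvar_series(
    frames, spec: SwitchingSpec, dt: float = 1.0, replica_id: str = "0"
) -> CVTrajectory:
    """Apply the three CV calculators to a frame sequence.

    Frame times are ``i * dt``; errors are re-raised with the frame index.
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("compute_colvar_series: empty frame sequence")
    rows = []
    for i, frame in enumerate(frames):
        try:
            rows.append(
                (coordination_number(frame, spec), z_distance(frame), alignment_angle(frame))
            )
        except ValidationError as exc:
            raise ValidationError(f"frame {i}: {exc}") from exc
    times = dt * np.arange(len(rows))
    return CVTrajectory(times, np.array(rows), replica_id=replica_id, cv_names=CV_NAMES)
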