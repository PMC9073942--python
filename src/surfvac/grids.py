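"""Rectilinear grids over collective-variable space and free-energy surfaces.

Conventions
-----------
* Non-periodic dimensions use node-centred grids: ``n`` points including both
  endpoints, spacing ``(max - min)/(n - 1)``.
* Periodic (angle-like) dimensions tile ``[min, max)`` with ``n`` cells of
  width ``(max - min)/n``; the seam is identified, no endpoint duplication.
* Free energies are in units of k_B*T and referenced so that the minimum over
  the sampled mask is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

TWO_PI = 2.0 * np.pi


def wrap_angle(x):
    """Wrap angle(s) into [-pi, pi)."""
    return (np.asarray(x) + np.pi) % TWO_PI - np.pi


def wrap_delta(delta, period=TWO_PI):
    """Minimum-image displacement on a periodic axis of the given period."""
    return (np.asarray(delta) + 0.5 * period) % period - 0.5 * period


@dataclass(frozen=True)
class GridSpec:
    """A rectilinear grid over CV space.

    Parameters
    ----------
    mins, maxs : per-dimension lower/upper bounds.
    n_bins : per-dimension number of grid points (>= 8 each).
    periodic : per-dimension periodicity flags (default all False).
    """

    mins: tuple
    maxs: tuple
    n_bins: tuple
    periodic: tuple = None

    def __post_init__(self):
        mins = tuple(float(x) for x in np.atleast_1d(self.mins))
        maxs = tuple(float(x) for x in np.atleast_1d(self.maxs))
        nb = tuple(int(x) for x in np.atleast_1d(self.n_bins))
        per = self.periodic
        if per is None:
            per = (False,) * len(mins)
        per = tuple(bool(x) for x in np.atleast_1d(per))
        if not (len(mins) == len(maxs) == len(nb) == len(per)):
            raise ValidationError("GridSpec: mismatched per-dimension lengths")
        for lo, hi, n in zip(mins, maxs, nb):
            if not hi > lo:
                raise ValidationError(f"GridSpec: max ({hi}) must exceed min ({lo})")
            if n < 8:
                raise ValidationError(f"GridSpec: need >= 8 bins per dimension, got {n}")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        object.__setattr__(self, "n_bins", nb)
        object.__setattr__(self, "periodic", per)

    @property
    def ndim(self) -> int:
        return len(self.mins)

    @property
    def shape(self) -> tuple:
        return self.n_bins

    @property
    def size(self) -> int:
        return int(np.prod(self.n_bins))

    @property
    def spacing(self) -> tuple:
        out = []
        for lo, hi, n, per in zip(self.mins, self.maxs, self.n_bins, self.periodic):
            out.append((hi - lo) / n if per else (hi - lo) / (n - 1))
        return tuple(out)

    @property
    def periods(self) -> tuple:
        """Period length per dimension (None for non-periodic)."""
        return tuple(
            (hi - lo) if per else None
            for lo, hi, per in zip(self.mins, self.maxs, self.periodic)
        )

    def axis(self, d: int) -> np.ndarray:
        lo, hi, n = self.mins[d], self.maxs[d], self.n_bins[d]
        if self.periodic[d]:
            return lo + (hi - lo) * np.arange(n) / n
        return np.linspace(lo, hi, n)

    @property
    def axes(self) -> list:
        return [self.axis(d) for d in range(self.ndim)]

    def points(self) -> np.ndarray:
        """All grid points as an (N, ndim) array in C (row-major) order."""
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    @property
    def bin_volume(self) -> float:
        return float(np.prod(self.spacing))

    def contains(self, point) -> bool:
        p = np.atleast_1d(np.asarray(point, dtype=float))
        for d in range(self.ndim):
            if self.periodic[d]:
                continue
            if not (self.mins[d] - 1e-12 <= p[d] <= self.maxs[d] + 1e-12):
                return False
        return True

    def wrap(self, points) -> np.ndarray:
        """Wrap periodic coordinates into [min, max)."""
        p = np.array(points, dtype=float, copy=True)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        for d in range(self.ndim):
            if self.periodic[d]:
                lo, hi = self.mins[d], self.maxs[d]
                p[:, d] = (p[:, d] - lo) % (hi - lo) + lo
        return p[0] if single else p


@dataclass
class FreeEnergySurface:
    """Free energy on a grid, min-zero referenced on the sampled mask."""

    grid: GridSpec
    F: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float).reshape(self.grid.shape)
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool).reshape(self.grid.shape)
        if not self.mask.any():
            raise ValidationError("FreeEnergySurface: empty sampled mask")
        if not np.all(np.isfinite(self.F[self.mask])):
            raise ValidationError("FreeEnergySurface: non-finite free energy on mask")
        self.set_min_zero()

    def set_min_zero(self) -> None:
        self.F = self.F - self.F[self.mask].min()

    def copy(self) -> "FreeEnergySurface":
        return FreeEnergySurface(self.grid, self.F.copy(), self.mask.copy())

    def argmin(self) -> tuple:
        """Index of the masked minimum."""
        Fm = np.where(self.mask, self.F, np.inf)
        return np.unravel_index(int(np.argmin(Fm)), self.grid.shape)


def fes_rmsd(f1: FreeEnergySurface, f2: FreeEnergySurface, mask=None) -> float:
    """RMS deviation between two min-zero surfaces on a common mask."""
    if f1.grid != f2.grid:
        raise ValidationError("fes_rmsd: grids differ")
    m = f1.mask & f2.mask
    if mask is not None:
        m = m & mask
    if not m.any():
        raise ValidationError("fes_rmsd: empty mask intersection")
    a = f1.F - f1.F[m].min()
    b = f2.F - f2.F[m].min()
    d = a[m] - b[m]
    d = d - d.mean()
    return float(np.sqrt(np.mean(d**2)))
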