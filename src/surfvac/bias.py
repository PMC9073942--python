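"""Well-tempered metadynamics bias bookkeeping.

The bias potential is an ordered collection of Gaussian hills,

    V(s, t) = sum_{k : t_k <= t} h_k * exp( -sum_d  D_d(s, c_k)^2 / (2 sigma_d^2) ),

where ``D_d`` is the plain displacement on open dimensions and the
minimum-image (wrapped) displacement on periodic (angle-like) dimensions.
Hill heights are stored *post-tempering* (PLUMED "HEIGHT" convention), so
V(s, t) is a plain sum over deposited hills.

The well-tempered deposition rule for a hill dropped at CV position s and
time t is

    h = h0 * exp( -V(s, t) / ((gamma - 1) * kT) ),

with dimensionless bias factor gamma > 1; gamma -> infinity recovers
standard (untempered) metadynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grids import FreeEnergySurface, GridSpec, wrap_delta

#: named biasing-protocol presets; "table1" is the production protocol used
#: for the three detachment CVs (coordination number, distance, angle).
PROTOCOL_PRESETS = {
    "table1": dict(widths=(0.15, 0.1, 0.1), height0=2.5, bias_factor=15.0, pace=4000),
    "toy1d": dict(widths=(0.1,), height0=1.0, bias_factor=10.0, pace=200),
    "toy3d": dict(widths=(0.5, 0.15, 0.4), height0=1.5, bias_factor=12.0, pace=300),
}


@dataclass(frozen=True)
class BiasProtocol:
    """Deposition protocol: Gaussian widths, initial height, bias factor, pace.

    ``pace`` is in integrator steps between depositions; ``height0`` in kT.
    """

    widths: tuple
    height0: float
    bias_factor: float
    pace: int

    def __post_init__(self):
        widths = tuple(float(w) for w in np.atleast_1d(self.widths))
        object.__setattr__(self, "widths", widths)
        object.__setattr__(self, "height0", float(self.height0))
        object.__setattr__(self, "bias_factor", float(self.bias_factor))
        object.__setattr__(self, "pace", int(self.pace))
        if any(w <= 0 for w in self.widths):
            raise ValidationError("BiasProtocol: widths must be positive")
        if self.height0 <= 0:
            raise ValidationError("BiasProtocol: height0 must be positive")
        if self.bias_factor <= 1:
            raise ValidationError("BiasProtocol: bias factor must exceed 1")
        if self.pace < 1:
            raise ValidationError("BiasProtocol: pace must be >= 1")

    @property
    def ndim(self) -> int:
        return len(self.widths)

    @classmethod
    def preset(cls, name: str) -> "BiasProtocol":
        try:
            return cls(**PROTOCOL_PRESETS[name])
        except KeyError:
            raise ValidationError(
                f"unknown protocol preset {name!r}; valid presets: "
                f"{sorted(PROTOCOL_PRESETS)}"
            ) from None


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian."""

    time: float
    center: tuple
    widths: tuple
    height: float
    bias_factor: float

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in np.atleast_1d(self.center)))
        object.__setattr__(self, "widths", tuple(float(w) for w in np.atleast_1d(self.widths)))
        if self.height <= 0:
            raise ValidationError("Hill: height must be positive")
        if len(self.center) != len(self.widths):
            raise ValidationError("Hill: center/widths dimensionality mismatch")


class BiasPotential:
    """Ordered hills defining V(s, t) and its gradient.

    Evaluation strictly before the first hill (or with no hills) returns 0.
    """

    def __init__(self, ndim: int, periodic=None, domain=None, hills=None):
        self.ndim = int(ndim)
        if periodic is None:
            periodic = (False,) * self.ndim
        self.periodic = tuple(bool(p) for p in np.atleast_1d(periodic))
        if len(self.periodic) != self.ndim:
            raise ValidationError("BiasPotential: periodic flags length mismatch")
        if domain is None:
            domain = (tuple([-np.inf] * self.ndim), tuple([np.inf] * self.ndim))
        self.domain = (tuple(map(float, domain[0])), tuple(map(float, domain[1])))
        # per-dimension period used for minimum-image wrapping
        self._periods = np.array(
            [
                (self.domain[1][d] - self.domain[0][d]) if self.periodic[d] else np.inf
                for d in range(self.ndim)
            ]
        )
        for d in range(self.ndim):
            if self.periodic[d] and not np.isfinite(self._periods[d]):
                raise ValidationError(
                    "BiasPotential: periodic dimension requires a finite domain"
                )
        self._times = []
        self._centers = []
        self._widths = []
        self._heights = []
        self._biasf = []
        if hills:
            for h in hills:
                self.append(h)

    # -- container plumbing -------------------------------------------------
    def __len__(self) -> int:
        return len(self._times)

    @property
    def hills(self) -> list:
        return [
            Hill(t, c, w, h, b)
            for t, c, w, h, b in zip(
                self._times, self._centers, self._widths, self._heights, self._biasf
            )
        ]

    def append(self, hill: Hill) -> None:
        if len(hill.center) != self.ndim:
            raise ValidationError("BiasPotential: hill dimensionality mismatch")
        if self._times and hill.time < self._times[-1]:
            raise ValidationError("BiasPotential: hills must be appended in time order")
        self._times.append(float(hill.time))
        self._centers.append(np.asarray(hill.center, dtype=float))
        self._widths.append(np.asarray(hill.widths, dtype=float))
        self._heights.append(float(hill.height))
        self._biasf.append(float(hill.bias_factor))

    def arrays(self):
        """(times, centers, widths, heights, biasf) as stacked float arrays."""
        k = len(self)
        if k == 0:
            z = np.zeros((0, self.ndim))
            return np.zeros(0), z, z, np.zeros(0), np.zeros(0)
        cached = getattr(self, "_arrays_cache", None)
        if cached is None or len(cached[0]) != k:
            cached = (
                np.array(self._times),
                np.stack(self._centers),
                np.stack(self._widths),
                np.array(self._heights),
                np.array(self._biasf),
            )
            self._arrays_cache = cached
        return cached

    @property
    def bias_factor(self) -> float:
        """The common bias factor of the hills (error if inconsistent)."""
        if not self._biasf:
            raise ValidationError("BiasPotential: no hills, bias factor undefined")
        bf = np.array(self._biasf)
        if not np.allclose(bf, bf[0], rtol=0, atol=1e-12):
            raise ValidationError("BiasPotential: inconsistent bias factor across hills")
        return float(bf[0])

    def _n_active(self, t) -> int:
        if t is None:
            return len(self)
        return int(np.searchsorted(np.array(self._times), float(t), side="right"))

    def _wrap_deltas(self, deltas: np.ndarray) -> np.ndarray:
        for d in range(self.ndim):
            if self.periodic[d]:
                deltas[..., d] = wrap_delta(deltas[..., d], self._periods[d])
        return deltas

    # -- evaluation ---------------------------------------------------------
    def value_and_gradient(self, s, t=None):
        """Bias energy (kT) and gradient dV/ds at one point, hills with time <= t."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        V, G = self.value_and_gradient_on_points(s[None, :], t)
        return float(V[0]), G[0]

    def value_on_points(self, points, t=None) -> np.ndarray:
        return self.value_and_gradient_on_points(points, t)[0]

    def gradient_on_points(self, points, t=None) -> np.ndarray:
        return self.value_and_gradient_on_points(points, t)[1]

    def value_and_gradient_on_points(self, points, t=None, first=0, last=None):
        """Vectorised V and dV/ds over an (N, ndim) point set.

        ``first``/``last`` restrict the sum to hills with first <= index <
        last (used to accumulate the bias incrementally, window by window);
        ``t`` restricts to hills deposited at time <= t.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = self._n_active(t)
        if last is not None:
            n = min(n, int(last))
        V = np.zeros(len(pts))
        G = np.zeros((len(pts), self.ndim))
        if n <= first:
            return V, G
        _, centers, widths, heights, _ = self.arrays()
        centers, widths, heights = centers[first:n], widths[first:n], heights[first:n]
        # chunk over hills to bound memory at ~ (chunk x N x d) floats
        chunk = max(1, int(4e6 / max(len(pts), 1)))
        for a in range(0, len(heights), chunk):
            b = min(a + chunk, len(heights))
            delta = pts[None, :, :] - centers[a:b, None, :]
            delta = self._wrap_deltas(delta)
            z = delta / widths[a:b, None, :]
            g = heights[a:b, None] * np.exp(-0.5 * np.sum(z * z, axis=-1))
            V += g.sum(axis=0)
            G += np.einsum("kn,knd->nd", g, -delta / widths[a:b, None, :] ** 2)
        return V, G

    def in_domain(self, s) -> bool:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        lo, hi = self.domain
        for d in range(self.ndim):
            if self.periodic[d]:
                continue
            if not (lo[d] - 1e-12 <= s[d] <= hi[d] + 1e-12):
                return False
        return True


def deposit_hill(bias: BiasPotential, s, t: float, protocol: BiasProtocol, kT: float = 1.0) -> Hill:
    """Deposit one well-tempered hill at s, time t; returns the appended Hill."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if len(s) != bias.ndim:
        raise ValidationError("deposit_hill: point dimensionality mismatch")
    if not bias.in_domain(s):
        raise ValidationError(f"deposit_hill: point {s.tolist()} outside the bias domain")
    V, _ = bias.value_and_gradient(s, t)
    gamma = protocol.bias_factor
    height = protocol.height0 * np.exp(-V / ((gamma - 1.0) * kT))
    hill = Hill(t, tuple(s), protocol.widths, float(height), gamma)
    bias.append(hill)
    return hill


def bias_value_and_gradient(bias: BiasPotential, s, t=None):
    """Functional alias for :meth:`BiasPotential.value_and_gradient`."""
    return bias.value_and_gradient(s, t)


def fes_from_bias(bias: BiasPotential, grid: GridSpec, t=None, kT: float = 1.0) -> FreeEnergySurface:
    """Sum-of-hills free-energy estimate  F(s) = -(gamma/(gamma-1)) V(s, t) + const.

    This is the classic long-time well-tempered estimator, provided for
    cross-checks against the mean-force-integration reconstruction.
    """
    gamma = bias.bias_factor
    V = bias.value_on_points(grid.points(), t).reshape(grid.shape)
    F = -(gamma / (gamma - 1.0)) * V
    return FreeEnergySurface(grid, F)
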