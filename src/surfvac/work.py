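"""Bias-work estimation and transition-time extraction/validation.

In the well-tempered ensemble the instantaneous bias is related to the free
energy through the time-dependent offset

    c(t) = (1/beta) * ln [ sum_s exp( (gamma/(gamma-1)) beta V(s, t) )
                         / sum_s exp( (1/(gamma-1))   beta V(s, t) ) ],

evaluated on a grid covering the sampled reactant region. c(t) starts at 0,
is non-decreasing for non-negative accumulating hills, and its value at the
detachment (or terminal) time is the work W_i performed by the bias to drive
replica i over the barrier. The mean over replicas, W-bar +- sd, is the
reported work of defect formation.

Transition times harvested from biased runs are mapped back to unbiased
estimates with the acceleration factor

    alpha = < exp( V(s(t), t) / kT ) >   (time average up to the transition),

and the set of rescaled times is validated against the exponential
distribution expected of a rare-event first-passage process
(maximum-likelihood tau = mean; two-sided Kolmogorov-Smirnov p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .bias import BiasPotential
from .errors import ValidationError
from .grids import GridSpec
from .mechanism import StatePartition, first_committed_entry
from .trajectory import CVTrajectory

#: kJ/mol per kT at 300 K (k_B = 0.0083144626 kJ/mol/K)
KJ_PER_MOL_PER_KT_300K = 0.0083144626 * 300.0


@dataclass
class WorkTrace:
    """c(t) series for one replica plus the scalar work W_i (all in kT)."""

    times: np.ndarray
    c_t: np.ndarray
    W_i: float = None
    replica_id: str = "0"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.c_t = np.asarray(self.c_t, dtype=float)
        if self.times.shape != self.c_t.shape:
            raise ValidationError("WorkTrace: times/c_t length mismatch")
        if len(self.times) == 0 or self.times[0] != 0.0 or self.c_t[0] != 0.0:
            raise ValidationError("WorkTrace: series must start at c(0) = 0")
        if not np.all(np.isfinite(self.c_t)):
            raise ValidationError("WorkTrace: non-finite c(t)")


@dataclass
class WorkSummary:
    """Mean and spread of the per-replica work (kT)."""

    W_bar: float
    sd: float  # None for a single replica
    n_replicas: int

    def in_kj_per_mol(self, kj_per_kt: float = KJ_PER_MOL_PER_KT_300K):
        sd = None if self.sd is None else self.sd * kj_per_kt
        return self.W_bar * kj_per_kt, sd


@dataclass
class TransitionEvent:
    """A committed entry into the product region."""

    replica_id: str
    raw_time: float
    acceleration: float = 1.0
    frame_index: int = None

    @property
    def rescaled_time(self) -> float:
        return self.raw_time * self.acceleration


def c_of_t(
    bias: BiasPotential, grid: GridSpec, kT: float = 1.0, gamma: float = None
) -> WorkTrace:
    """Well-tempered ensemble offset c(t) at every deposition time.

    The grid must cover the sampled reactant region; uniform bin volumes
    cancel in the ratio of sums.
    """
    if gamma is None:
        gamma = bias.bias_factor if len(bias) else 2.0
    if gamma <= 1:
        raise ValidationError("c_of_t: bias factor must exceed 1")
    times, *_ = bias.arrays()
    pts = grid.points()
    out_t = [0.0]
    out_c = [0.0]
    a = gamma / (gamma - 1.0)
    b = 1.0 / (gamma - 1.0)
    V = np.zeros(len(pts))
    for k in range(len(times)):
        dV, _ = bias.value_and_gradient_on_points(pts, first=k, last=k + 1)
        V += dV
        beta_v = V / kT
        c = kT * (logsumexp(a * beta_v) - logsumexp(b * beta_v))
        out_t.append(times[k])
        out_c.append(float(c))
    return WorkTrace(np.array(out_t), np.array(out_c))


def work_of_replica(
    bias: BiasPotential,
    grid: GridSpec,
    detachment: TransitionEvent | None = None,
    kT: float = 1.0,
    gamma: float = None,
    mode: str = "detachment",
):
    """Work W_i = c(t_end) for one replica, from its own accumulated bias.

    ``t_end`` is the detachment time when a committed transition is supplied
    and ``mode == 'detachment'`` (the default), else the final deposition
    time. Returns (W_i, WorkTrace).
    """
    if mode not in ("detachment", "terminal"):
        raise ValidationError("work_of_replica: mode must be 'detachment' or 'terminal'")
    if len(bias) == 0:
        warn("work_of_replica: replica has no hills; W_i = 0", stacklevel=2)
        trace = WorkTrace(np.array([0.0]), np.array([0.0]), W_i=0.0)
        return 0.0, trace
    trace = c_of_t(bias, grid, kT=kT, gamma=gamma)
    if detachment is not None and mode == "detachment":
        t_end = min(detachment.raw_time, trace.times[-1])
    else:
        t_end = trace.times[-1]
    W = float(np.interp(t_end, trace.times, trace.c_t))
    trace.W_i = W
    return W, trace


def aggregate_work(works) -> WorkSummary:
    """Mean and standard deviation of per-replica works."""
    w = np.asarray(list(works), dtype=float)
    if len(w) == 0:
        raise ValidationError("aggregate_work: no work values")
    sd = float(np.std(w, ddof=1)) if len(w) >= 2 else None
    return WorkSummary(float(np.mean(w)), sd, len(w))


def detect_transition(
    traj: CVTrajectory,
    partition: StatePartition,
    commitment: int = 10,
    product_state: str = "detached",
) -> TransitionEvent | None:
    """First entry into the product region persisting >= ``commitment``
    consecutive frames; None if the trajectory never commits."""
    states = partition.assign_many(traj.points)
    k = first_committed_entry(states, product_state, commitment)
    if k is None:
        return None
    return TransitionEvent(
        replica_id=traj.replica_id,
        raw_time=float(traj.times[k]),
        frame_index=int(k),
    )


def rescale_transition_time(
    traj: CVTrajectory,
    bias: BiasPotential,
    event: TransitionEvent,
    kT: float = 1.0,
) -> TransitionEvent:
    """Attach the acceleration factor alpha = <exp(V(s(t), t)/kT)>.

    The average runs over the pre-transition trajectory, with V evaluated at
    each frame using only the hills deposited up to that frame's time.
    """
    sel = traj.times <= event.raw_time + 1e-12
    pts = traj.points[sel]
    times = traj.times[sel]
    if len(pts) == 0:
        raise ValidationError("rescale_transition_time: no pre-transition frames")
    hill_times, *_ = bias.arrays()
    V = np.zeros(len(pts))
    if len(hill_times):
        # frames are time-ordered, so the active-hill count is non-decreasing;
        # evaluate V block-wise with the hills active during each block
        n_active_per_frame = np.searchsorted(hill_times, times, side="right")
        boundaries = np.flatnonzero(np.diff(n_active_per_frame)) + 1
        for blk in np.split(np.arange(len(pts)), boundaries):
            k = int(n_active_per_frame[blk[0]])
            if k > 0:
                V[blk] = bias.value_and_gradient_on_points(pts[blk], last=k)[0]
    alpha = float(np.mean(np.exp(V / kT)))
    return TransitionEvent(
        replica_id=event.replica_id,
        raw_time=event.raw_time,
        acceleration=alpha,
        frame_index=event.frame_index,
    )


@dataclass
class TransitionTimeFit:
    """Exponential MLE fit and KS validation of transition times."""

    tau: float
    ks_stat: float
    p_value: float
    n: int


def validate_transition_times(times, tau: float = None) -> TransitionTimeFit:
    """Exponential fit (MLE tau = mean when ``tau`` is None) and two-sided
    Kolmogorov-Smirnov test of the sample against that exponential."""
    t = np.asarray(list(times), dtype=float)
    if len(t) < 5:
        raise ValidationError(
            f"validate_transition_times: need >= 5 events, got {len(t)}; "
            "run more replicas"
        )
    if np.any(t < 0):
        raise ValidationError("validate_transition_times: negative times")
    if tau is None:
        tau = float(np.mean(t))
    if tau <= 0:
        return TransitionTimeFit(tau, 1.0, 0.0, len(t))
    res = stats.kstest(t, stats.expon(scale=tau).cdf)
    return TransitionTimeFit(float(tau), float(res.statistic), float(res.pvalue), len(t))
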