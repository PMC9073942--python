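"""Mean Force Integration (MFI).

The time-independent free-energy surface is reconstructed from biased
sampling by estimating, for every inter-deposition window ``[t, t + tau]``,
the *mean thermodynamic force* on the grid,

    Phi(s) = kT * d/ds log p_b(s)  +  dV(s, t)/ds        ( = -dF/ds ),

where ``p_b`` is a Gaussian-kernel estimate of the biased probability density
of the window's samples and ``V(s, t)`` is the bias in effect during the
window (hills deposited before it). Because the instantaneous bias force is
subtracted exactly, each window yields an unbiased estimate of -dF/ds
wherever it has sampling; windows from the same or from *independent*
replicas are then fused by probability-weighted averaging and the result is
integrated (cumulative trapezoid in 1D, sparse least squares on the masked
gradient equations in >= 2D) to a surface referenced to zero at its sampled
minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .bias import BiasPotential
from .errors import ValidationError
from .grids import FreeEnergySurface, GridSpec, wrap_delta
from .trajectory import CVTrajectory

DEFAULT_BANDWIDTH = 0.03
DEFAULT_MASK_THRESHOLD = 1e-6


@dataclass
class WindowEstimate:
    """KDE density, its log-gradient and the bias force for one window."""

    index: int
    grid: GridSpec
    p_b: np.ndarray  # normalised density on the grid
    grad_log_p: np.ndarray  # shape grid.shape + (ndim,)
    bias_force: np.ndarray  # -dV/ds on the grid, same shape as grad_log_p
    n_frames: int

    def __post_init__(self):
        self.p_b = np.asarray(self.p_b, dtype=float).reshape(self.grid.shape)
        d = self.grid.ndim
        self.grad_log_p = np.asarray(self.grad_log_p, dtype=float).reshape(
            self.grid.shape + (d,)
        )
        self.bias_force = np.asarray(self.bias_force, dtype=float).reshape(
            self.grid.shape + (d,)
        )
        if np.any(self.p_b < 0):
            raise ValidationError("WindowEstimate: negative density")
        mass = self.p_b.sum() * self.grid.bin_volume
        if abs(mass - 1.0) > 1e-6:
            raise ValidationError(f"WindowEstimate: density mass {mass} != 1")


@dataclass
class MeanForceField:
    """Probability-weighted mean force accumulated over windows."""

    grid: GridSpec
    force: np.ndarray  # shape grid.shape + (ndim,)
    weight: np.ndarray  # accumulated probability mass per bin
    sampled_mask: np.ndarray

    def __post_init__(self):
        d = self.grid.ndim
        self.force = np.asarray(self.force, dtype=float).reshape(self.grid.shape + (d,))
        self.weight = np.asarray(self.weight, dtype=float).reshape(self.grid.shape)
        self.sampled_mask = np.asarray(self.sampled_mask, dtype=bool).reshape(
            self.grid.shape
        )
        if np.any(self.weight < 0):
            raise ValidationError("MeanForceField: negative weight")
        if not np.all(np.isfinite(self.force[self.sampled_mask])):
            raise ValidationError("MeanForceField: non-finite force on sampled mask")


def _bandwidth_vector(bandwidth, ndim: int) -> np.ndarray:
    h = np.atleast_1d(np.asarray(bandwidth, dtype=float))
    if len(h) == 1:
        h = np.repeat(h, ndim)
    if len(h) != ndim or np.any(h <= 0):
        raise ValidationError("bandwidth must be positive (scalar or per-CV)")
    return h


def _kde_log_density(samples, h, grid):
    """Log KDE and the analytic gradient of log density on the grid.

    Stable in the far tails: the gradient is a softmax-weighted average of
    per-kernel pulls, so it never forms 0/0.
    """
    pts = grid.points()  # (N, d)
    deltas = pts[None, :, :] - samples[:, None, :]  # (n, N, d)
    for dax in range(grid.ndim):
        per = grid.periods[dax]
        if per is not None:
            deltas[:, :, dax] = wrap_delta(deltas[:, :, dax], per)
    z = deltas / h
    expo = -0.5 * np.sum(z * z, axis=-1)  # (n, N)
    logp = logsumexp(expo, axis=0) - np.log(len(samples)) - np.sum(
        np.log(np.sqrt(2 * np.pi) * h)
    )
    w = np.exp(expo - logsumexp(expo, axis=0)[None, :])  # softmax over samples
    grad_log = np.einsum("nN,nNd->Nd", w, -deltas / (h * h))
    return logp, grad_log


def window_density(samples, bandwidth, grid: GridSpec, bias_force=None, index: int = 0):
    """Gaussian-kernel density estimate of one window on the grid.

    ``samples`` is (n, ndim); ``bias_force`` is the -dV/ds field in effect
    during the window (defaults to zero = unbiased window). The density is
    normalised on the grid.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 1:
        raise ValidationError("window_density: empty window")
    if samples.shape[1] != grid.ndim:
        raise ValidationError("window_density: sample dimensionality mismatch")
    h = _bandwidth_vector(bandwidth, grid.ndim)
    logp, grad_log = _kde_log_density(samples, h, grid)
    p = np.exp(logp - logp.max())
    p /= p.sum() * grid.bin_volume
    if bias_force is None:
        bias_force = np.zeros(grid.shape + (grid.ndim,))
    return WindowEstimate(
        index=index,
        grid=grid,
        p_b=p.reshape(grid.shape),
        grad_log_p=grad_log.reshape(grid.shape + (grid.ndim,)),
        bias_force=bias_force,
        n_frames=len(samples),
    )


def window_mean_force(w: WindowEstimate, kT: float = 1.0):
    """Per-bin mean thermodynamic force and probability weight of one window.

    Phi = kT * grad log p_b - f_bias with f_bias = -dV/ds, i.e. the
    instantaneous bias force is removed so Phi estimates -dF/ds.
    """
    force = kT * w.grad_log_p - w.bias_force
    weight = w.p_b * w.grid.bin_volume
    return force, weight


def aggregate_mean_force(
    windows, kT: float = 1.0, mask_threshold: float = DEFAULT_MASK_THRESHOLD
) -> MeanForceField:
    """Probability-weighted fusion of window mean forces (any replicas).

    The weighted mean is associative: splitting or duplicating windows leaves
    the aggregate unchanged.
    """
    windows = list(windows)
    if not windows:
        raise ValidationError("aggregate_mean_force: no windows")
    grid = windows[0].grid
    sum_w = np.zeros(grid.shape)
    sum_wf = np.zeros(grid.shape + (grid.ndim,))
    for w in windows:
        if w.grid != grid:
            raise ValidationError("aggregate_mean_force: window grids differ")
        f, wt = window_mean_force(w, kT)
        sum_w += wt
        sum_wf += wt[..., None] * f
    return _field_from_sums(grid, sum_w, sum_wf, mask_threshold)


def _field_from_sums(grid, sum_w, sum_wf, mask_threshold) -> MeanForceField:
    mask = sum_w >= mask_threshold * sum_w.sum()
    force = np.zeros_like(sum_wf)
    nz = sum_w > 0
    force[nz] = sum_wf[nz] / sum_w[nz][..., None]
    force[~nz] = 0.0
    return MeanForceField(grid, force, sum_w, mask)


# ---------------------------------------------------------------------------
# window slicing of biased replicas


def iter_windows(traj: CVTrajectory, hills: BiasPotential):
    """Yield (samples, n_active_hills) for every inter-deposition window.

    Window k spans times (t_{k-1}, t_k] between depositions; the bias in
    effect during it consists of the first k-1 hills (a hill deposited at the
    window's end acts only afterwards). The record at t = 0 and a trailing
    window after the last hill are included.
    """
    times = traj.times
    hill_times, *_ = hills.arrays()
    edges = np.concatenate([[0.0], hill_times, [np.inf]])
    idx = np.searchsorted(edges, times, side="left")  # window index per frame
    idx = np.clip(idx, 1, len(edges) - 1)
    for k in range(1, len(edges)):
        sel = idx == k
        if sel.any():
            yield traj.points[sel], k - 1


def mean_force_from_replicas(
    replicas,
    grid: GridSpec,
    bandwidth=DEFAULT_BANDWIDTH,
    kT: float = 1.0,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
) -> MeanForceField:
    """Window-wise MFI over (trajectory, hills) pairs from independent replicas.

    Equivalent to building every :class:`WindowEstimate` and calling
    :func:`aggregate_mean_force`, but accumulates the bias gradient
    incrementally per replica.
    """
    replicas = list(replicas)
    if not replicas:
        raise ValidationError("mean_force_from_replicas: no replicas")
    h = _bandwidth_vector(bandwidth, grid.ndim)
    pts = grid.points()
    sum_w = np.zeros(grid.size)
    sum_wf = np.zeros((grid.size, grid.ndim))
    for traj, hills in replicas:
        if traj.ndim != grid.ndim:
            raise ValidationError("mean_force_from_replicas: dimensionality mismatch")
        groups = list(iter_windows(traj, hills))
        # cumulative bias gradient at each window's start
        bias_grads = {}
        acc = np.zeros((grid.size, grid.ndim))
        n_active = 0
        for _, k in groups:
            if k > n_active:
                _, dG = hills.value_and_gradient_on_points(pts, first=n_active, last=k)
                acc = acc + dG
                n_active = k
            bias_grads[k] = acc
        # batch the KDE over windows with an equal number of frames
        by_count = {}
        for samples, k in groups:
            by_count.setdefault(len(samples), []).append((samples, k))
        for n, grp_all in by_count.items():
            # chunk windows to bound the (chunk, n, N, d) work array
            chunk = max(1, int(2e7 / max(n * grid.size * grid.ndim, 1)))
            for a in range(0, len(grp_all), chunk):
                grp = grp_all[a : a + chunk]
                S = np.stack([s for s, _ in grp])  # (n_w, n, d)
                deltas = pts[None, None, :, :] - S[:, :, None, :]  # (n_w, n, N, d)
                for dax in range(grid.ndim):
                    per = grid.periods[dax]
                    if per is not None:
                        deltas[..., dax] = wrap_delta(deltas[..., dax], per)
                z = deltas / h
                expo = -0.5 * np.sum(z * z, axis=-1)  # (n_w, n, N)
                lse = logsumexp(expo, axis=1)  # (n_w, N)
                w = np.exp(expo - lse[:, None, :])
                grad_log = np.einsum("wnN,wnNd->wNd", w, -deltas / (h * h))
                p = np.exp(lse - lse.max(axis=1, keepdims=True))
                p /= p.sum(axis=1, keepdims=True) * grid.bin_volume
                wt = p * grid.bin_volume  # (n_w, N)
                for i, (_, k) in enumerate(grp):
                    force = kT * grad_log[i] + bias_grads[k]
                    sum_w += wt[i]
                    sum_wf += wt[i][:, None] * force
    return _field_from_sums(
        grid, sum_w.reshape(grid.shape), sum_wf.reshape(grid.shape + (grid.ndim,)), mask_threshold
    )


# ---------------------------------------------------------------------------
# integration


def _edge_equations(grid: GridSpec, mask_flat):
    """Adjacent-bin gradient equations over the mask; returns (rows of
    (i, j, dim, spacing)) including periodic seam edges."""
    shape = grid.shape
    idx = np.arange(grid.size).reshape(shape)
    edges = []
    for d in range(grid.ndim):
        sp_d = grid.spacing[d]
        i = np.take(idx, np.arange(shape[d] - 1), axis=d).ravel()
        j = np.take(idx, np.arange(1, shape[d]), axis=d).ravel()
        edges.append((i, j, d, sp_d))
        if grid.periodic[d]:
            i = np.take(idx, [shape[d] - 1], axis=d).ravel()
            j = np.take(idx, [0], axis=d).ravel()
            edges.append((i, j, d, sp_d))
    out = []
    for i, j, d, sp_d in edges:
        keep = mask_flat[i] & mask_flat[j]
        out.append((i[keep], j[keep], d, sp_d))
    return out


def integrate_fes(mf: MeanForceField) -> FreeEnergySurface:
    """Integrate dF/ds = -Phi over the sampled mask, min-zero referenced.

    1D uses the cumulative trapezoid; >= 2D solves the masked gradient
    equations by sparse least squares (periodic seams included). If the mask
    is disconnected the largest connected component is integrated and a
    warning is issued.
    """
    grid = mf.grid
    mask = mf.sampled_mask.ravel()
    if not mask.any():
        raise ValidationError("integrate_fes: empty sampled mask")
    eqs = _edge_equations(grid, mask)
    n_edges = sum(len(i) for i, j, d, s in eqs)
    rows_i = np.concatenate([i for i, j, d, s in eqs]) if n_edges else np.zeros(0, int)
    rows_j = np.concatenate([j for i, j, d, s in eqs]) if n_edges else np.zeros(0, int)
    # connectivity over masked bins
    n_mask = int(mask.sum())
    remap = -np.ones(grid.size, dtype=int)
    remap[mask] = np.arange(n_mask)
    adj = sp.coo_matrix(
        (np.ones(n_edges), (remap[rows_i], remap[rows_j])), shape=(n_mask, n_mask)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        counts = np.bincount(labels)
        keep = labels == np.argmax(counts)
        warnings.warn(
            f"sampled mask has {n_comp} components; integrating the largest "
            f"({counts.max()} of {n_mask} bins)",
            stacklevel=2,
        )
        mask2 = mask.copy()
        mask2[np.flatnonzero(mask)[~keep]] = False
        mf2 = MeanForceField(grid, mf.force, mf.weight, mask2.reshape(grid.shape))
        return integrate_fes(mf2)

    force = mf.force.reshape(grid.size, grid.ndim)
    if grid.ndim == 1 and not grid.periodic[0]:
        sel = np.flatnonzero(mask)
        x = grid.axis(0)[sel]
        g = -force[sel, 0]  # dF/ds
        F = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(x))])
        full = np.full(grid.size, np.nan)
        full[sel] = F
        return FreeEnergySurface(grid, np.nan_to_num(full.reshape(grid.shape), nan=np.nanmax(F)), mask.reshape(grid.shape))

    # least squares on the edge equations
    data, ri, ci, rhs = [], [], [], []
    row = 0
    for i, j, d, sp_d in eqs:
        g_edge = -0.5 * (force[i, d] + force[j, d])  # target dF/ds on the edge
        for a, b, g in zip(remap[i], remap[j], g_edge * sp_d):
            ri.extend((row, row))
            ci.extend((a, b))
            data.extend((-1.0, 1.0))
            rhs.append(g)
            row += 1
    A = sp.csr_matrix((data, (ri, ci)), shape=(row, n_mask))
    sol = sp.linalg.lsqr(A, np.array(rhs), atol=1e-12, btol=1e-12, iter_lim=20000)[0]
    full = np.zeros(grid.size)
    full[mask] = sol
    full[~mask] = sol.max()
    return FreeEnergySurface(grid, full.reshape(grid.shape), mask.reshape(grid.shape))


def reconstruct_fes(
    replicas,
    grid: GridSpec,
    bandwidth=DEFAULT_BANDWIDTH,
    kT: float = 1.0,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
) -> FreeEnergySurface:
    """Full MFI pipeline: replicas -> mean force -> integrated FES."""
    return integrate_fes(
        mean_force_from_replicas(replicas, grid, bandwidth, kT, mask_threshold)
    )


# ---------------------------------------------------------------------------
# comparison statistics


def fes_difference(f1: FreeEnergySurface, f2: FreeEnergySurface):
    """Consistency statistic between two surfaces on the mask intersection.

    Both surfaces are aligned to min-zero (their own masks); returns
    (mean |dF|, standard deviation of dF) in kT.
    """
    if f1.grid != f2.grid:
        raise ValidationError("fes_difference: grids differ")
    m = f1.mask & f2.mask
    if not m.any():
        raise ValidationError("fes_difference: empty mask intersection")
    a = f1.F - f1.F[f1.mask].min()
    b = f2.F - f2.F[f2.mask].min()
    d = a[m] - b[m]
    return float(np.mean(np.abs(d))), float(np.std(d))


def basin_populations(fes: FreeEnergySurface, partition, kT: float = 1.0) -> dict:
    """Boltzmann populations of named CV-space regions within the basin.

    ``partition`` is a :class:`surfvac.mechanism.StatePartition` or a mapping
    of region names to Region boxes; regions must be disjoint. Fractions are
    normalised over the union of the regions (restricted to the sampled
    mask) and sum to one.
    """
    from .mechanism import StatePartition

    if not isinstance(partition, StatePartition):
        partition = StatePartition(dict(partition), periodic=fes.grid.periodic)
    pts = fes.grid.points()
    labels = partition.assign_many(pts)
    w = np.exp(-fes.F.ravel() / kT) * fes.mask.ravel()
    fractions = {}
    total = 0.0
    for name in partition.regions:
        mass = float(w[labels == name].sum())
        fractions[name] = mass
        total += mass
    if total <= 0:
        raise ValidationError("basin_populations: no sampled mass in any region")
    return {k: v / total for k, v in fractions.items()}
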