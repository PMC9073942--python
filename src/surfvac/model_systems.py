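"""Analytic model landscapes and an overdamped Langevin sampler.

These systems stand in for the all-atom crystal-slab molecular dynamics: the
downstream estimators (mean-force integration, bias-work, mechanism
classification) consume only CV time series and hill logs, so a Langevin
walker moving directly in CV space on a known landscape exercises every stage
against an exact analytic oracle.

Reduced units are used throughout: energies in k_B*T (kT = 1 by default),
lengths/angles in native CV units, time in units of the Langevin timestep
scale.

Presets
-------
``double_well_1d``
    U(x) = a (x^2 - 1)^2 — minima at x = +-1, barrier of height ``a`` at 0.
``three_basin_2d``
    Quartic confinement minus three Gaussian wells.
``detachment_3d``
    A (coordination, distance, angle) landscape emulating the topology of the
    surface-vacancy problem: a deep *crystalline* reactant basin at angle
    +-pi, a shallower *flipped* sub-basin at angle 0, a diffuse *disordered*
    intermediate at reduced coordination, and a *detached* product region at
    large distance and near-zero coordination. Coordination is slaved to
    distance through a harmonic coupling ``k_couple (c - mu(z))^2`` with a
    smooth sigmoidal profile ``mu(z)``, so pulling the molecule out of the
    surface necessarily sheds neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import root

from . import _kernels
from .bias import BiasPotential, BiasProtocol, Hill
from .cv import MolecularFrame, SwitchingSpec
from .errors import ConfigurationError, SimulationError, ValidationError
from .grids import FreeEnergySurface, GridSpec
from .trajectory import CVTrajectory

PRESET_NAMES = ("double_well_1d", "three_basin_2d", "detachment_3d")

#: fixed geometry of the detachment_3d landscape (see module docstring);
#: only the well depths and the coupling constant are user parameters.
DETACH3D_GEOMETRY = dict(
    cmax=6.0,  # crystalline coordination plateau
    zc=1.0,  # inflection of the coordination-distance coupling [distance units]
    wz=0.35,  # width of that sigmoid
    well_wc=0.8,  # (c, z, theta) widths of the crystalline/flipped wells
    well_wz=0.3,
    well_wth=0.7,
    well_c0=6.0,
    dis_c=3.5,  # disordered well centre and widths (theta-independent)
    dis_z=0.94,
    dis_wc=1.0,
    dis_wz=0.35,
    det_z=2.2,  # detached well centre (c = 0) and widths
    det_wc=0.8,
    det_wz=0.35,
    wall_k=50.0,  # quartic confining walls
    z_lo=-0.2,
    z_hi=2.6,
    c_lo=-0.3,
    c_hi=7.3,
)


@dataclass(frozen=True)
class PotentialModel:
    """An analytic potential over CV space (energies in kT)."""

    name: str
    ndim: int
    params: dict
    periodic: tuple
    lo: tuple
    hi: tuple
    cv_names: tuple
    minima: dict  # label -> np.ndarray stationary minimum
    _pid: int
    _pp: np.ndarray

    def energy(self, points):
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.ascontiguousarray(np.atleast_2d(pts))
        if pts.shape[1] != self.ndim:
            raise ValidationError(f"{self.name}: expected {self.ndim}-dimensional points")
        out = np.empty(len(pts))
        _kernels.pot_energy_many(self._pid, self._pp, pts, out)
        return float(out[0]) if single else out

    def gradient(self, points):
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.ascontiguousarray(np.atleast_2d(pts))
        if pts.shape[1] != self.ndim:
            raise ValidationError(f"{self.name}: expected {self.ndim}-dimensional points")
        out = np.empty_like(pts)
        _kernels.pot_grad_many(self._pid, self._pp, pts, out)
        return out[0] if single else out

    @property
    def reactant_minimum(self) -> np.ndarray:
        for label in ("crystalline", "reactant"):
            if label in self.minima:
                return self.minima[label].copy()
        return next(iter(self.minima.values())).copy()

    @property
    def domain(self):
        return np.array(self.lo), np.array(self.hi)


def _refine_minimum(pid, pp, guess) -> np.ndarray:
    """Polish a stationary point so the gradient norm is < 1e-9."""
    g = np.empty(len(guess))

    def grad(x):
        _kernels.pot_grad(pid, pp, np.asarray(x, dtype=float), g)
        return g.copy()

    sol = root(grad, np.asarray(guess, dtype=float), method="hybr", tol=1e-14)
    x = sol.x
    if np.linalg.norm(grad(x)) > 1e-9:
        raise SimulationError(f"minimum refinement failed near {guess}")
    return x


def _check_params(name, params, allowed):
    unknown = set(params) - set(allowed)
    if unknown:
        raise ValidationError(
            f"{name}: unknown parameter(s) {sorted(unknown)}; valid: {sorted(allowed)}"
        )
    for key, (lo, hi) in allowed.items():
        v = params[key]
        if not (lo < v <= hi):
            raise ValidationError(
                f"{name}: parameter {key}={v} outside documented range ({lo}, {hi}]"
            )


def make_potential(name: str, **params) -> PotentialModel:
    """Build a named analytic potential preset.

    double_well_1d:  a (barrier height, default 5)
    three_basin_2d:  depth1, depth2, depth3 (defaults 8, 6, 6)
    detachment_3d:   a_cryst (10), a_flip (7), a_dis (4), a_det (3),
                     k_couple (1)
    """
    if name == "double_well_1d":
        p = {"a": 5.0}
        p.update(params)
        _check_params(name, p, {"a": (0.0, 50.0)})
        pp = np.array([p["a"]])
        minima = {
            "reactant": np.array([-1.0]),
            "product": np.array([1.0]),
        }
        return PotentialModel(
            name, 1, p, (False,), (-2.5,), (2.5,), ("x",), minima, 0, pp
        )
    if name == "three_basin_2d":
        p = {"depth1": 8.0, "depth2": 6.0, "depth3": 6.0}
        p.update(params)
        _check_params(
            name, p, {"depth1": (0.0, 30.0), "depth2": (0.0, 30.0), "depth3": (0.0, 30.0)}
        )
        centers = [(-1.0, 0.0), (1.0, 0.9), (1.0, -0.9)]
        pp = np.array(
            [4.0, 1.8]
            + [v for d, (cx, cy) in zip((p["depth1"], p["depth2"], p["depth3"]), centers) for v in (d, cx, cy)]
            + [0.55]
        )
        minima = {
            f"basin{i + 1}": _refine_minimum(1, pp, np.array(c)) for i, c in enumerate(centers)
        }
        return PotentialModel(
            name,
            2,
            p,
            (False, False),
            (-2.5, -2.5),
            (2.5, 2.5),
            ("x", "y"),
            minima,
            1,
            pp,
        )
    if name == "detachment_3d":
        p = {"a_cryst": 10.0, "a_flip": 7.0, "a_dis": 4.0, "a_det": 3.0, "k_couple": 1.0}
        p.update(params)
        _check_params(
            name,
            p,
            {
                "a_cryst": (0.0, 30.0),
                "a_flip": (0.0, 30.0),
                "a_dis": (0.0, 30.0),
                "a_det": (0.0, 30.0),
                "k_couple": (0.0, 10.0),
            },
        )
        g = DETACH3D_GEOMETRY
        pp = np.array(
            [
                p["k_couple"],
                g["cmax"],
                g["zc"],
                g["wz"],
                p["a_cryst"],
                g["well_wc"],
                g["well_wz"],
                g["well_wth"],
                g["well_c0"],
                p["a_flip"],
                p["a_dis"],
                g["dis_c"],
                g["dis_z"],
                g["dis_wc"],
                g["dis_wz"],
                p["a_det"],
                g["det_z"],
                g["det_wc"],
                g["det_wz"],
                g["wall_k"],
                g["z_lo"],
                g["z_hi"],
                g["c_lo"],
                g["c_hi"],
            ]
        )
        # theta = pi and theta = 0 are exactly stationary by symmetry; only
        # (c, z) need polishing.
        minima = {
            "crystalline": _refine_minimum(2, pp, np.array([6.0, 0.0, math.pi - 1e-9])),
            "flipped": _refine_minimum(2, pp, np.array([6.0, 0.0, 0.0])),
            "disordered": _refine_minimum(2, pp, np.array([3.6, 0.9, math.pi - 1e-9])),
            "detached": _refine_minimum(2, pp, np.array([0.1, 2.2, math.pi - 1e-9])),
        }
        return PotentialModel(
            name,
            3,
            p,
            (False, False, True),
            (-0.5, -0.5, -math.pi),
            (7.5, 2.8, math.pi),
            ("cn", "dist", "angle"),
            minima,
            2,
            pp,
        )
    raise ConfigurationError(
        f"unknown potential {name!r}; valid presets: {list(PRESET_NAMES)}"
    )


def analytic_fes(potential: PotentialModel, grid: GridSpec) -> FreeEnergySurface:
    """Ground-truth free-energy surface F(s) = U(s) - min U over the grid."""
    lo, hi = potential.domain
    for d in range(grid.ndim):
        if grid.periodic[d]:
            continue
        if grid.mins[d] < lo[d] - 1e-9 or grid.maxs[d] > hi[d] + 1e-9:
            raise ValidationError(
                f"analytic_fes: grid dimension {d} exceeds the potential domain"
            )
    if grid.ndim != potential.ndim:
        raise ValidationError("analytic_fes: grid dimensionality mismatch")
    F = potential.energy(grid.points()).reshape(grid.shape)
    return FreeEnergySurface(grid, F)


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped Langevin (Euler-Maruyama) integration parameters.

    ``diffusion`` may be a scalar or per-CV sequence; ``temperature`` is the
    energy scale kT. Identical parameters + seed give bit-identical output.
    """

    timestep: float
    n_steps: int
    stride: int = 1
    temperature: float = 1.0
    diffusion: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValidationError("LangevinParams: timestep must be positive")
        if not (self.n_steps >= self.stride >= 1):
            raise ValidationError("LangevinParams: need n_steps >= stride >= 1")
        if self.temperature <= 0:
            raise ValidationError("LangevinParams: temperature must be positive")
        if np.any(np.asarray(self.diffusion, dtype=float) <= 0):
            raise ValidationError("LangevinParams: diffusion must be positive")

    def diffusion_vector(self, ndim: int) -> np.ndarray:
        D = np.atleast_1d(np.asarray(self.diffusion, dtype=float))
        if len(D) == 1:
            D = np.repeat(D, ndim)
        if len(D) != ndim:
            raise ValidationError("LangevinParams: diffusion length mismatch")
        return D


def run_langevin(
    potential: PotentialModel,
    bias: BiasPotential | None,
    params: LangevinParams,
    protocol: BiasProtocol | None = None,
    start=None,
    stop_region=None,
    stop_count: int = 0,
    replica_id: str = "0",
):
    """Propagate overdamped Langevin dynamics on U + V with optional WTmetaD.

    Returns ``(CVTrajectory, BiasPotential)`` where the second element holds
    only the *newly deposited* hills (empty when ``protocol`` is None). When
    ``stop_region=(lo, hi)`` and ``stop_count > 0`` the run halts once the
    walker stays inside the stop box for ``stop_count`` consecutive steps.
    """
    nd = potential.ndim
    if protocol is not None and protocol.ndim != nd:
        raise ValidationError("run_langevin: protocol dimensionality mismatch")
    if bias is not None and bias.ndim != nd:
        raise ValidationError("run_langevin: bias dimensionality mismatch")
    s0 = np.asarray(
        start if start is not None else potential.reactant_minimum, dtype=float
    ).copy()
    if s0.shape != (nd,):
        raise ValidationError("run_langevin: bad start point")
    lo, hi = potential.domain
    for d in range(nd):
        if potential.periodic[d]:
            s0[d] = (s0[d] - lo[d]) % (hi[d] - lo[d]) + lo[d]
            if s0[d] >= hi[d]:
                s0[d] = lo[d]
    periodic = np.array(potential.periodic, dtype=np.bool_)
    D = params.diffusion_vector(nd)
    kT = params.temperature

    n_hills0 = len(bias) if bias is not None else 0
    pace = protocol.pace if protocol is not None else 0
    max_hills = n_hills0 + (params.n_steps // pace + 1 if pace else 0) + 1
    hill_c = np.zeros((max_hills, nd))
    hill_w = np.ones((max_hills, nd))
    hill_h = np.zeros(max_hills)
    hill_t = np.zeros(max_hills)
    if bias is not None and n_hills0:
        bt, bc, bw, bh, _ = bias.arrays()
        hill_t[:n_hills0] = bt
        hill_c[:n_hills0] = bc
        hill_w[:n_hills0] = bw
        hill_h[:n_hills0] = bh

    if stop_region is not None and stop_count > 0:
        stop_lo = np.asarray(stop_region[0], dtype=float)
        stop_hi = np.asarray(stop_region[1], dtype=float)
    else:
        stop_lo = np.full(nd, np.inf)
        stop_hi = np.full(nd, -np.inf)
        stop_count = 0

    n_rec_max = params.n_steps // params.stride + 1
    rec_t = np.zeros(n_rec_max)
    rec_s = np.zeros((n_rec_max, nd))

    widths = (
        np.asarray(protocol.widths, dtype=float) if protocol is not None else np.ones(nd)
    )
    height0 = protocol.height0 if protocol is not None else 0.0
    gamma = protocol.bias_factor if protocol is not None else 2.0

    status, irec, n_hills = _kernels.simulate(
        potential._pid,
        potential._pp,
        periodic,
        np.array(lo),
        np.array(hi),
        s0,
        params.timestep,
        kT,
        D,
        params.n_steps,
        params.stride,
        int(params.seed) % (2**32),
        pace,
        widths,
        height0,
        gamma,
        hill_c,
        hill_w,
        hill_h,
        hill_t,
        n_hills0,
        stop_lo,
        stop_hi,
        stop_count,
        rec_t,
        rec_s,
    )
    if status < 0:
        raise SimulationError(
            f"trajectory diverged outside the domain guard at step {-status}; "
            "use a smaller timestep"
        )
    traj = CVTrajectory(
        rec_t[:irec],
        rec_s[:irec].copy(),
        replica_id=replica_id,
        cv_names=potential.cv_names,
    )
    hills_log = BiasPotential(
        nd, periodic=potential.periodic, domain=(potential.lo, potential.hi)
    )
    for k in range(n_hills0, n_hills):
        hills_log.append(
            Hill(hill_t[k], tuple(hill_c[k]), tuple(hill_w[k]), hill_h[k], gamma)
        )
    return traj, hills_log


def generate_replica_set(
    potential: PotentialModel,
    protocol: BiasProtocol | None,
    params: LangevinParams,
    n_replicas: int,
    base_seed: int,
    start=None,
    stop_region=None,
    stop_count: int = 0,
):
    """Independent replicas, seeds base_seed + i, all started at the reactant
    minimum (or at ``start``). Returns a list of (CVTrajectory, hills log)."""
    if n_replicas < 1:
        raise ValidationError("generate_replica_set: n_replicas must be >= 1")
    out = []
    for i in range(n_replicas):
        p = replace(params, seed=base_seed + i)
        out.append(
            run_langevin(
                potential,
                None,
                p,
                protocol,
                start=start,
                stop_region=stop_region,
                stop_count=stop_count,
                replica_id=str(i),
            )
        )
    return out


# ---------------------------------------------------------------------------
# molecular coordinate fixtures for the CV calculators

FIXTURE_LAYOUTS = ("lattice_slab", "uniform_gas", "scripted_detachment")

#: scripted_detachment schedule: the tagged molecule rises linearly to this
#: terminal +z displacement while its axis rotates by pi/2 about the x axis.
SCRIPTED_Z_TOTAL = 2.0
SCRIPTED_ROTATION = math.pi / 2


def _dumbbell(center, axis, half_length=0.15):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    c = np.asarray(center, dtype=float)
    return np.array([c - half_length * axis, c + half_length * axis])


def _slab_sites(box, spacing, z_top, n_sites):
    nx = max(1, int(box[0] / spacing))
    ny = max(1, int(box[1] / spacing))
    sites = []
    z = z_top
    while len(sites) < n_sites + 1 and z > 0:
        for ix in range(nx):
            for iy in range(ny):
                sites.append(((ix + 0.5) * spacing, (iy + 0.5) * spacing, z))
        z -= spacing
    return sites


def synth_molecular_fixture(
    n_neighbors: int,
    box,
    layout: str,
    seed: int = 0,
    n_frames: int | None = None,
):
    """Generate coordinate frames for the CV calculators.

    Layouts: ``lattice_slab`` (static crystalline slab, tagged dumbbell
    anti-parallel to the reference axis, hence angle +-pi), ``uniform_gas``
    (ideal-gas neighbours, re-drawn each frame), ``scripted_detachment``
    (the tagged molecule climbs along +z per the documented schedule while
    rotating its axis). Returns a list of MolecularFrame.
    """
    box = tuple(float(b) for b in np.atleast_1d(box)) if np.ndim(box) else (float(box),) * 3
    if len(box) == 1:
        box = box * 3
    if layout not in FIXTURE_LAYOUTS:
        raise ConfigurationError(
            f"unknown fixture layout {layout!r}; valid layouts: {list(FIXTURE_LAYOUTS)}"
        )
    rng = np.random.default_rng(seed)
    # lattice molecules point along +z; the crystalline reference axis is
    # defined as -z so the in-lattice tagged molecule reads an angle of +-pi.
    reference_axis = np.array([0.0, 0.0, -1.0])
    plane_normal = np.array([1.0, 0.0, 0.0])

    if layout == "uniform_gas":
        n_frames = 50 if n_frames is None else n_frames
        center = np.array(box) / 2.0
        frames = []
        for _ in range(n_frames):
            nb = rng.uniform(0.0, 1.0, size=(n_neighbors, 3)) * np.array(box)
            coords = np.vstack([_dumbbell(center, (0, 0, 1)), nb])
            frames.append(
                MolecularFrame(
                    coords,
                    (0, 1),
                    tuple(range(2, 2 + n_neighbors)),
                    center,
                    reference_axis,
                    plane_normal,
                    box,
                )
            )
        return frames

    spacing = 0.5
    z_top = box[2] / 2.0
    sites = _slab_sites(box, spacing, z_top, n_neighbors)
    tagged_site = np.array(sites[0])
    neighbor_sites = np.array(sites[1 : n_neighbors + 1])
    if len(neighbor_sites) < n_neighbors:
        raise ValidationError(
            "synth_molecular_fixture: box too small for the requested neighbor count"
        )

    def frame_at(center, axis):
        coords = np.vstack([_dumbbell(center, axis), neighbor_sites])
        return MolecularFrame(
            coords,
            (0, 1),
            tuple(range(2, 2 + n_neighbors)),
            tagged_site,
            reference_axis,
            plane_normal,
            box,
        )

    if layout == "lattice_slab":
        n_frames = 3 if n_frames is None else n_frames
        return [frame_at(tagged_site, (0, 0, 1)) for _ in range(n_frames)]

    # scripted_detachment
    n_frames = 60 if n_frames is None else n_frames
    frames = []
    for k in range(n_frames):
        f = k / (n_frames - 1) if n_frames > 1 else 1.0
        dz = SCRIPTED_Z_TOTAL * f
        phi = SCRIPTED_ROTATION * f
        axis = np.array([0.0, -math.sin(phi), math.cos(phi)])
        frames.append(frame_at(tagged_site + np.array([0.0, 0.0, dz]), axis))
    return frames


def scripted_mechanism_paths(dt: float = 1.0):
    """Three hand-scripted CV trajectories on the detachment_3d landscape,
    one per detachment mechanism (linear, flipped-intermediate,
    via-disordered). Used as classifier fixtures."""
    pot = make_potential("detachment_3d")
    cryst = pot.minima["crystalline"]
    flip = pot.minima["flipped"]
    dis = pot.minima["disordered"]
    det = pot.minima["detached"]

    def seg(a, b, n):
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        return a + (b - a) * np.linspace(0.0, 1.0, n)[:, None]

    def mk(points, rid):
        pts = np.vstack(points)
        return CVTrajectory(
            dt * np.arange(len(pts)), pts, replica_id=rid, cv_names=pot.cv_names
        )

    # transit segments are short (<= 3 frames inside any intermediate box)
    # so only the scripted stop-overs register as dwells
    linear = mk([np.tile(cryst, (20, 1)), seg(cryst, det, 10), np.tile(det, (30, 1))], "linear")
    flipped = mk(
        [
            np.tile(cryst, (20, 1)),
            seg(cryst, flip, 8),
            np.tile(flip, (20, 1)),
            seg(flip, det, 10),
            np.tile(det, (30, 1)),
        ],
        "flipped",
    )
    disordered = mk(
        [
            np.tile(cryst, (20, 1)),
            seg(cryst, dis, 8),
            np.tile(dis, (50, 1)),
            seg(dis, det, 20),
            np.tile(det, (30, 1)),
        ],
        "disordered",
    )
    return linear, flipped, disordered
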