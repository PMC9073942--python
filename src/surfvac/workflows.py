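"""End-to-end study workflows tying the modules together.

These functions freeze the desk-scale study conditions used throughout the
test-suite and the acceptance report: a 5 kT double-well landscape sampled by
30 well-tempered replicas for the free-energy reconstruction, a three-rung
barrier ladder (3/5/8 kT) for the bias-work estimator, and 30-replica panels
on the 3-D detachment landscape for the mechanism statistics. Problem sizes
are documented in docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .bias import BiasProtocol
from .grids import FreeEnergySurface, GridSpec, fes_rmsd
from .mechanism import classify_path, default_partition, mechanism_fractions
from .mfi import reconstruct_fes
from .model_systems import (
    LangevinParams,
    analytic_fes,
    generate_replica_set,
    make_potential,
)
from .bias import fes_from_bias
from .work import (
    aggregate_work,
    c_of_t,
    detect_transition,
    rescale_transition_time,
    validate_transition_times,
    work_of_replica,
)

# frozen study conditions -----------------------------------------------------

#: 1-D double-well reconstruction study (pace/stride = 8 frames per window)
DW_PROTOCOL = BiasProtocol(widths=(0.1,), height0=1.0, bias_factor=10.0, pace=200)
DW_LANGEVIN = LangevinParams(timestep=0.005, n_steps=200_000, stride=25, seed=0)
DW_GRID = GridSpec((-1.6,), (1.6,), (161,))
DW_BANDWIDTH = 0.03

#: reactant-side grid for the c(t)/work estimator on the double well
DW_WORK_GRID = GridSpec((-2.0,), (0.0,), (81,))
DW_STOP = ((0.5,), (2.5,))  # product-side stop box (past the barrier top)

#: work-study protocol: production-strength hills (2.5 kT); the deposition
#: lag (60 steps = 0.3 time units ~ 12 intra-well relaxation times) limits
#: bias deposition in the transition-state ensemble while keeping the
#: residual thermal-escape window small against the barrier
DW_WORK_PROTOCOL = BiasProtocol(widths=(0.1,), height0=2.5, bias_factor=10.0, pace=60)

#: 3-D detachment mechanism panel. Reorientation inside a crystal surface is
#: slow against translational shedding, so the angular diffusion coefficient
#: is five-fold smaller than the translational ones, and the angular hill
#: width is kept below the well width so the bias does not wash out the
#: rotational barrier.
MECH_PROTOCOL = BiasProtocol(
    widths=(0.5, 0.15, 0.15), height0=1.5, bias_factor=12.0, pace=300
)
MECH_LANGEVIN = LangevinParams(
    timestep=0.001, n_steps=600_000, stride=50, diffusion=(0.5, 0.5, 0.1), seed=0
)
MECH_STOP = ((-0.5, 1.6, -4.0), (1.2, 2.81, 4.0))


def double_well_fes_study(
    base_seed: int,
    n_replicas: int = 30,
    barrier: float = 5.0,
    protocol: BiasProtocol = DW_PROTOCOL,
    langevin: LangevinParams = DW_LANGEVIN,
    grid: GridSpec = DW_GRID,
    bandwidth=DW_BANDWIDTH,
):
    """WTmetaD replicas on the double well -> MFI FES vs the analytic oracle.

    Returns a dict with the replicas, the MFI surface, the analytic surface,
    and their RMSD (kT) on the sampled mask.
    """
    pot = make_potential("double_well_1d", a=barrier)
    replicas = generate_replica_set(pot, protocol, langevin, n_replicas, base_seed)
    fes = reconstruct_fes(replicas, grid, bandwidth=bandwidth)
    truth = analytic_fes(pot, grid)
    return {
        "potential": pot,
        "replicas": replicas,
        "fes": fes,
        "analytic": truth,
        "rmsd": fes_rmsd(fes, truth, mask=fes.mask),
    }


def sum_of_hills_fes(replicas, grid: GridSpec) -> FreeEnergySurface:
    """Replica-averaged -(gamma/(gamma-1)) V(s) estimate for cross-checks."""
    surfaces = []
    for _, hills in replicas:
        if len(hills):
            surfaces.append(fes_from_bias(hills, grid).F)
    if not surfaces:
        raise ValueError("sum_of_hills_fes: no hills in any replica")
    return FreeEnergySurface(grid, np.mean(surfaces, axis=0))


def barrier_work_study(
    base_seed: int,
    barriers=(3.0, 5.0, 8.0),
    n_seeds: int = 30,
    protocol: BiasProtocol = None,
    commitment: int = 10,
):
    """Bias-work ladder: W_i at the detachment time on the double well.

    For each barrier height, ``n_seeds`` independent biased escapes are run;
    c(t) is evaluated on the reactant-side grid and W_i read at each
    replica's own committed transition time. Returns per-barrier summaries
    plus the rescaled transition times of every committed event.
    """
    if protocol is None:
        protocol = DW_WORK_PROTOCOL
    langevin = replace(DW_LANGEVIN, n_steps=400_000)
    partition = default_partition("double_well_1d")
    out = {}
    for barrier in barriers:
        pot = make_potential("double_well_1d", a=barrier)
        works = []
        events = []
        n_committed = 0
        for i in range(n_seeds):
            params = replace(langevin, seed=base_seed + 1000 * int(barrier) + i)
            traj, hills = _run_single(pot, protocol, params)
            event = detect_transition(traj, partition, commitment=commitment)
            W, _ = work_of_replica(
                hills, DW_WORK_GRID, detachment=event, mode="detachment"
            )
            works.append(W)
            if event is not None:
                n_committed += 1
                events.append(rescale_transition_time(traj, hills, event))
        out[barrier] = {
            "works": np.array(works),
            "summary": aggregate_work(works),
            "median": float(np.median(works)),
            "events": events,
            "n_committed": n_committed,
        }
    return out


def _run_single(pot, protocol, params):
    from .model_systems import run_langevin

    return run_langevin(
        pot, None, params, protocol, stop_region=DW_STOP, stop_count=500
    )


def mechanism_study(
    base_seed: int,
    n_replicas: int = 30,
    a_flip: float = 7.0,
    min_dwell: int = 5,
    commitment: int = 10,
):
    """Detachment-mechanism panel on the 3-D landscape.

    Runs ``n_replicas`` biased detachments (seeds base_seed + i), classifies
    every committed path, and returns fractions, counts and the labels.
    """
    pot = make_potential("detachment_3d", a_flip=a_flip)
    partition = default_partition("detachment_3d")
    labels = []
    n_detached = 0
    for i in range(n_replicas):
        params = replace(MECH_LANGEVIN, seed=base_seed + i)
        from .model_systems import run_langevin

        traj, hills = run_langevin(
            pot,
            None,
            params,
            MECH_PROTOCOL,
            stop_region=MECH_STOP,
            stop_count=1000,
            replica_id=str(i),
        )
        event = detect_transition(traj, partition, commitment=commitment)
        if event is None:
            continue
        n_detached += 1
        labels.append(
            classify_path(traj, partition, min_dwell=min_dwell, commitment=commitment)
        )
    stats = mechanism_fractions(labels) if labels else {"counts": {}, "fractions": {}, "n": 0}
    stats["n_replicas"] = n_replicas
    stats["n_detached"] = n_detached
    stats["labels"] = labels
    return stats


def consistency_study(base_seed: int, n_replicas: int = 30):
    """Pairwise FES-consistency matrix across biasing protocols.

    Reconstructs the double-well FES under four protocol variants (differing
    bias factor and pace) from independent replica sets and reports the
    pairwise (mean |dF|, sd dF) matrix, mirroring how consistency across
    WTmetaD protocols is assessed.
    """
    from .mfi import fes_difference

    variants = {
        "g15_p200": BiasProtocol(widths=(0.1,), height0=1.0, bias_factor=15.0, pace=200),
        "g10_p200": DW_PROTOCOL,
        "g10_p250": BiasProtocol(widths=(0.1,), height0=1.0, bias_factor=10.0, pace=250),
    }
    pot = make_potential("double_well_1d", a=5.0)
    surfaces = {}
    for j, (name, proto) in enumerate(variants.items()):
        reps = generate_replica_set(
            pot, proto, DW_LANGEVIN, n_replicas, base_seed + 10_000 * j
        )
        surfaces[name] = reconstruct_fes(reps, DW_GRID, bandwidth=DW_BANDWIDTH)
    names = list(surfaces)
    matrix = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            matrix[(a, b)] = fes_difference(surfaces[a], surfaces[b])
    return {"surfaces": surfaces, "matrix": matrix}


def acceptance_report(seed: int, scale: float = 1.0) -> dict:
    """Recompute the package's headline quantities from scratch.

    Every value is produced by running the full pipeline at the frozen study
    conditions; ``scale`` < 1 shrinks replica counts proportionally for quick
    smoke runs. Returns {name: {"value": float, "n": int}}.
    """
    rep = {}

    def n_of(n):
        return max(2, int(round(n * scale)))

    # free-energy reconstruction quality
    study = double_well_fes_study(seed, n_replicas=n_of(30))
    rep["fes_rmsd_kT"] = {"value": round(study["rmsd"], 4), "n": n_of(30)}
    hills_est = sum_of_hills_fes(study["replicas"], DW_GRID)
    rep["sum_of_hills_rmsd_kT"] = {
        "value": round(fes_rmsd(hills_est, study["analytic"], mask=study["fes"].mask), 4),
        "n": n_of(30),
    }

    # work ladder
    ladder = barrier_work_study(seed, n_seeds=n_of(30))
    for barrier, res in ladder.items():
        rep[f"work_median_kT_barrier{int(barrier)}"] = {
            "value": round(res["median"], 3),
            "n": n_of(30),
        }
    rep["work_sd_kT_barrier5"] = {
        "value": round(float(ladder[5.0]["summary"].sd), 3),
        "n": n_of(30),
    }

    # transition-time statistics on the 5 kT rung
    events = ladder[5.0]["events"]
    if len(events) >= 5:
        fit = validate_transition_times([e.rescaled_time for e in events])
        rep["transition_tau_fit"] = {"value": round(fit.tau, 2), "n": fit.n}
        rep["transition_ks_p"] = {"value": round(fit.p_value, 4), "n": fit.n}

    # protocol consistency (pairwise mean |dF|)
    cons = consistency_study(seed, n_replicas=n_of(15))
    diffs = [d for d, _ in cons["matrix"].values()]
    sds = [s for _, s in cons["matrix"].values()]
    rep["protocol_consistency_max_mean_abs_dF_kT"] = {
        "value": round(max(diffs), 3),
        "n": n_of(15),
    }
    rep["protocol_consistency_max_sd_dF_kT"] = {
        "value": round(max(sds), 3),
        "n": n_of(15),
    }

    # reactant-basin decomposition of the 3-D landscape (Boltzmann fractions)
    from .mfi import basin_populations

    pot3 = make_potential("detachment_3d")
    grid3 = GridSpec(
        (-0.5, -0.5, -np.pi), (7.5, 2.8, np.pi), (46, 34, 40), (False, False, True)
    )
    part = default_partition("detachment_3d")
    sub = {k: part.regions[k] for k in ("crystalline", "flipped", "disordered")}
    from .mechanism import StatePartition

    fracs = basin_populations(
        analytic_fes(pot3, grid3), StatePartition(sub, periodic=part.periodic)
    )
    for k, v in fracs.items():
        rep[f"basin_percent_{k}"] = {"value": round(100 * v, 3), "n": grid3.size}

    # mechanism fractions
    mech = mechanism_study(seed, n_replicas=n_of(30))
    for k, v in mech["fractions"].items():
        rep[f"mechanism_percent_{k.lower()}"] = {
            "value": round(100 * v, 1),
            "n": mech["n_detached"],
        }
    rep["mechanism_detached_count"] = {
        "value": mech["n_detached"],
        "n": mech["n_replicas"],
    }
    return rep
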