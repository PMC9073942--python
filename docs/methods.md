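# Methods

This note records the models, estimators and numerical choices behind
`surfvac`, and what the packaged synthetic studies do and do not demonstrate.

## Problem setting

The toolkit quantifies the formation of a single surface vacancy on a crystal
facet: a tagged growth unit leaves an otherwise flat surface (state A → state
B). The process is described in a three-dimensional collective-variable (CV)
space — coordination number `cn` of the tagged molecule with other solute
molecules, signed distance `dist` of its centroid from a bulk reference point
along the surface normal, and a signed alignment angle `angle` relative to the
crystalline reference orientation. Enhanced sampling (well-tempered
metadynamics, WTmetaD) drives the rare detachment event; post-processing
recovers a time-independent free-energy surface (Mean Force Integration), the
work the bias performs to create the defect, and a mechanistic classification
of each detachment path.

All estimators consume only CV time series (COLVAR) and hill logs (HILLS).
The package therefore ships analytic model landscapes sampled by overdamped
Langevin dynamics directly in CV space: every downstream stage can be checked
against exact oracles at desk scale, and the same code applies unchanged to
logs produced by an external all-atom engine.

## Model systems

Reduced units throughout: energies in k_B·T (kT = 1), time in Langevin units;
kJ/mol appears only in I/O labels (conversion at 300 K, 1 kT = 2.494 kJ/mol).

* `double_well_1d` — U(x) = a(x² − 1)², minima at ±1, barrier `a`
  (default 5 kT). The workhorse for reconstruction and work studies.
* `three_basin_2d` — quartic confinement minus three Gaussian wells.
* `detachment_3d` — the vacancy-formation topology: a crystalline reactant
  basin (`cn`≈6, `dist`≈0, `angle`=±π, depth 10 kT), a flipped sub-basin at
  `angle`=0 (7 kT), a θ-independent disordered intermediate at reduced
  coordination (4 kT), and a detached product well at large distance and
  near-zero coordination (3 kT). Coordination is slaved to distance through a
  harmonic coupling k(c − μ(z))² with a sigmoidal μ(z), so withdrawal sheds
  neighbours. Angular localisation of the crystalline/flipped wells uses a von
  Mises factor exp(κ(cos Δθ − 1)), κ = 1/σθ²: it is exactly periodic and
  smooth at the antipode, where a single-minimum-image Gaussian would have a
  cusp. Well depths (`a_cryst`, `a_flip`, `a_dis`, `a_det`) and the coupling
  constant are user parameters; the geometry is a package constant
  (`DETACH3D_GEOMETRY`). Declared minima are polished at construction with a
  gradient root solve so their gradient norm is below 1e-9.

### Langevin sampler

Euler–Maruyama: s ← s − (D/kT)∇(U+V)dt + √(2D dt)η. The integrator's
stationary density deviates from Boltzmann at O(dt·U''); at the default
dt = 5e-3 and the stiffest well (U'' = 40) this is a ~10% variance inflation,
which matters for density-level validation but not for the barrier-scale
quantities studied here (the detailed-balance test uses dt = 5e-4).
Trajectories are bit-reproducible from (potential, parameters, protocol,
seed). A divergence guard aborts with advice to reduce the timestep.

Replica panels start exactly at the reactant minimum; no equilibration phase
is applied (the reactant basin equilibrates within the first few hundred
steps, far below the deposition lag).

## Well-tempered bias

Hills are anisotropic Gaussians with per-CV widths; the deposition rule is
h = h₀·exp(−V(s,t)/((γ−1)kT)) with dimensionless bias factor γ. Heights are
stored post-tempering, so V(s,t) is a plain sum over deposited hills. Angle
dimensions use minimum-image wrapping inside the Gaussian (error < 1e-8 for
σ = 0.1 on a 2π period). The production protocol ships as preset `table1`
(widths 0.15/0.1/0.1, h₀ = 2.5 kT, γ = 15, pace 4000 steps); the toy studies
use down-scaled presets recorded in `surfvac.workflows`.

## Mean Force Integration

For every inter-deposition window, the biased density p_b is estimated on the
grid with Gaussian kernels (default bandwidth h = 0.03 per CV, in native CV
units; configurable per dimension since one scalar serves three differently
scaled CVs). The window mean force

    Φ(s) = kT ∇log p_b(s) + ∇V(s, t_window)   ( = −∇F )

subtracts the instantaneous bias force exactly, so each window estimates the
same time-independent −∇F wherever it has sampling. Windows from all replicas
are fused by probability-weighted averaging — an associative operation, so
splitting or duplicating windows cannot change the result (this is tested
bit-for-bit). The log-gradient is computed as a softmax-weighted average of
kernel pulls, which is stable in density tails.

Integration: cumulative trapezoid of −Φ in 1D; in ≥2D a sparse least-squares
solve of the adjacent-bin gradient equations over the sampled mask, with
periodic seam edges on angle dimensions and connected components handled by
integrating the largest (with a warning). The surface is referenced to zero
at its sampled minimum. The sampled mask keeps bins holding at least 1e-6 of
the total accumulated probability mass (configurable); unsampled product
regions are deliberately not reported, mirroring how biased reconstructions
are converged only up to the barrier.

The number of frames per window is set by pace/stride; the default toy
protocol records 8 frames per window, matching the n_τ = 8 convention of the
production analysis.

Surface comparison: `fes_difference` aligns both surfaces to min-zero and
reports mean |δF| and σ_δF on the mask intersection (the consistency
statistic used to compare biasing protocols). `fes_rmsd`, used against
analytic oracles, removes the mean difference first, since a free energy is
defined up to an additive constant.

## Work of defect formation

The well-tempered offset

    c(t) = (1/β) ln [ Σ_s exp((γ/(γ−1)) βV(s,t)) / Σ_s exp((1/(γ−1)) βV(s,t)) ]

is evaluated over a grid covering the sampled reactant region at every
deposition time; c(0) = 0, and for a spatially constant bias c₀ the ratio
collapses to exp(βc₀) exactly. c(t) is non-decreasing when hills land at the
running bias maximum; hills dropped on the flanks produce sub-percent dips
(the softmax denominator momentarily grows faster), so monotonicity is
asserted at 1% of the final offset.

W_i is c(t) read at replica i's own detachment time (default) or at the final
deposition time (`mode="terminal"`); the reported work is W̄ ± sd over the
replica set. Detachment is the first entry into the product region that
persists a commitment window (default 10 recorded frames). The product
boundary sits just past the barrier top rather than at the product minimum,
so thermal fluctuations around the minimum cannot break a commitment streak.

The work-study protocol uses production-strength hills (2.5 kT) with a
deposition lag of 0.3 time units ≈ 12 intra-well relaxation times: long
enough that deposition within the transition-state ensemble is rare, short
enough that the residual thermal-escape window — by a Kramers estimate,
ln(ν·τ_dep/h_eff) kT below the barrier — stays small. Under these conditions
the 30-seed median work reproduces toy barriers of 3/5/8 kT to roughly ±1 kT
and is strictly ordered in the barrier.

### Transition times

Biased escape times are rescaled by the acceleration factor
α = ⟨exp(V(s(t), t)/kT)⟩ averaged over the pre-transition trajectory, with V
evaluated against the hills active at each frame. Under genuinely infrequent
biasing (small hills, long lag) the rescaled mean first-passage time agrees
with brute-force unbiased simulation within a factor of two (tested at a 4 kT
barrier). Under the aggressive work-study protocol the escape-time
distribution is *not* exponential — the KS p-value near zero in the
acceptance report is the expected signature of a perturbed transition-state
ensemble, not a defect. `validate_transition_times` fits τ by maximum
likelihood (the sample mean) and reports a two-sided Kolmogorov–Smirnov
p-value; the p = 0.05 threshold is reported, never enforced.

## Mechanism classification

CV points map to named half-open boxes (crystalline / flipped / disordered /
detached; angle intervals are wrap-aware). The packaged boxes for
`detachment_3d` are constants; for external data they are configuration. A
path is classified over the window from its first departure out of the
crystalline state to its committed entry into the detached state:
intermediate states dwelling at least `min_dwell` consecutive frames
(default 5) are recorded, and the label follows the precedence
flipped > disordered > linear, so every path gets exactly one label while the
full visited-state sequence is reported for re-binning. `min_dwell` = 5
frames (0.25 time units at the panel's stride) exceeds the diffusive transit
time through the intermediate boxes but is far below genuine basin trapping,
which is what separates a stop-over from a fly-through.

Mechanism-panel conditions: the angular diffusion coefficient is five-fold
smaller than the translational ones, and the angular hill width (0.15 rad) is
kept below the angular well width. Both reflect that reorientation of a
molecule embedded in a crystal surface is hindered; numerically they prevent
the bias from flattening the rotational barrier, which would otherwise let
free angular wandering carry nearly every walker through the flipped box and
saturate the flipped-path count. Under these conditions the flipped-path
count over a paired 30-seed panel responds strictly monotonically to the
flipped-basin depth (±4 kT), which is the designed sensitivity check of the
classifier. Direct (linear) detachments do not occur for a diffusive walker
on this landscape — some intermediate dwell always accumulates — so the
LINEAR label is exercised by scripted fixture paths.

## What the synthetic studies do and do not show

The Langevin panels validate the estimators: bias bookkeeping, window-wise
mean-force recovery, replica fusion, integration, c(t)/work, time rescaling
and path classification, each against analytic or brute-force oracles. They
do not emulate solvent structure, internal conformational dynamics,
finite-size slab effects, or CV imperfection (the toy bias acts on the exact
CVs; in molecular simulation the CVs are imperfect reaction coordinates).
Quantities such as the basin percentages and mechanism fractions in the
acceptance report are properties of the packaged toy landscape, not
predictions for any molecular system.

## Problem sizes used by tests and the acceptance script

30 replicas × 2·10⁵ steps for the reconstruction study (grid 161 bins,
h = 0.03); 30 seeds per rung for the 3/5/8 kT work ladder (runs stop shortly
after commitment); 3 × 15 replicas for the protocol-consistency matrix;
paired 30-seed panels (capped at 6·10⁵ steps, early-stopped on detachment)
for the mechanism statistics; 5·10⁶-step unbiased runs for the
detailed-balance and symmetry checks. The propagator is numba-compiled; a
full acceptance run takes ~2 minutes on one CPU.

## Known limitations

* Euler–Maruyama only; no higher-order SDE schemes (dt sensitivity above).
* No block-averaged error bars on the FES; no on-the-fly FES estimation.
* ≥2D integration assumes the masked force field is curl-free up to noise;
  strongly disconnected masks are reduced to their largest component.
* The kJ/mol conversion assumes 300 K unless configured otherwise.
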