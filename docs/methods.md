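# Methods

This package reconstructs the free-energy landscape of a two-basin
conformational transition with path collective variables (PCVs) and
well-tempered metadynamics (WT-MetaD), on synthetic systems small enough
that every stage runs in minutes on one core. This note documents the
models, the numerical choices, and what the synthetic systems do and do not
establish.

## Path collective variables

A transition path is discretized as a frame set: reference structures
i = 1..N. For a configuration x, per-frame displacements R_i(x) are mean
squared displacements (nm²) of a *measurement* atom subset after
least-squares rigid superposition on a separate *alignment* subset (the
rigid lobe). The PCVs are

    S(x) = Σ_i i·e^(−λ R_i) / Σ_i e^(−λ R_i)        (progress, in [1, N])
    Z(x) = −(1/λ)·ln Σ_i e^(−λ R_i)                 (distance from path, nm²)

Exponents are shifted by λ·min_i R_i before exponentiation, so S and Z stay
finite for λ up to at least 1e6 nm⁻² (tested). Z obeys the envelope
min R − ln(N)/λ ≤ Z ≤ min R; slightly negative Z is therefore expected for
on-path structures and is not an error.

**Superposition.** Kabsch least squares with reflection correction, via
`scipy.spatial.transform.Rotation.align_vectors`; batched evaluation
against all frames uses an SVD/quaternion implementation validated against
it. Superposition is unweighted and uses Cα-like beads only; mass
weighting is deliberately out of scope.

**Gradients.** Biasing S and Z requires ∂R_i/∂x including the response of
the optimal rotation to alignment-atom motion. We differentiate the Horn
quaternion eigenproblem to first order (the rotation is the top eigenvector
of the 4×4 correlation matrix; its perturbation uses the pseudo-inverse on
the orthogonal complement). The result matches central finite differences
to ~1e-9 relative error. A cheaper quasi-static approximation
(`rotation_response=False`) is retained for experimentation; it is exact
only when the align and measure subsets coincide and is *not* used in
dynamics.

**λ rule.** λ is adapted to the frame set as λ = ln(10)/⟨MSD⟩ where ⟨MSD⟩
is the mean squared adjacent-frame displacement in nm²: one decade of
weight decay per mean interframe MSD keeps adjacent frames distinguishable
while the mapping stays smooth. The conventional printed form of this rule
is notationally ambiguous (a literal reciprocal-of-log reading turns
negative for MSD < 1 nm²); the ln(10) convention is adopted because it
reproduces both standard calibration points — 312 nm⁻² at a 0.86 Å mean
interframe distance and 193 nm⁻² at 1.1 Å — within printed rounding.

## Synthetic systems

### Analytic potentials

`make_double_well_1d(barrier, separation)` builds U(u) = B((u/a)²−1)², flat
in the second coordinate, with the saddle exactly B kcal/mol above the two
minima. It is the validation tier for the metadynamics engine: every claim
about the engine (crossing enhancement, FES error, barrier recovery,
committor behavior) is first established where the answer is known in
closed form. The default particle mass (10 g/mol) was chosen so that at
300 K with a 5 kcal/mol barrier, spontaneous crossings are rare on the
nanosecond scale while biased runs cross freely — the regime the method is
for.

### The mini-VFT bead model

`make_mini_vft` builds a clamshell of two helical bead lobes (8 beads each
by default) joined at a hinge: a rigid lobe (alignment subset) and a mobile
lobe (measurement subset). The energy is a double-basin softmin mixture of
two elastic networks,

    E = −(1/β_mix)·ln( e^(−β_mix·E_closed) + e^(−β_mix·E_open) ),

each E_* harmonic in all pair distances about its own reference, so both
references are exact minima of their own term. Defaults: intra-lobe
springs 400 kcal/mol/nm² (rigid lobes), inter-lobe contact springs
6 kcal/mol/nm² within a 1.4 nm cutoff, β_mix = 2 (kcal/mol)⁻¹, hinge
opening 25°, bead mass 100 g/mol, 300 K. These give a minimum-energy-path
barrier of ≈ 4.3 kcal/mol (≈ 7 kT at 300 K): prohibitive for unbiased
desk-scale runs yet fillable by WT-MetaD in ~10⁵ steps. The barrier scales
with `barrier_scale` (multiplying the contact springs).

The model also defines a "wide-open" end state — the hinge opened 15°
beyond the open reference plus a 25° twist of the mobile lobe about its own
axis. It stands in for an over-opened conformation seen only in
simulation: it is used as the terminal frame of the path, and because of
the twist it does not lie on the closed→open hinge line, which is what
makes the endpoint-only guess path measurably worse than the
centroid-refined path.

The *engineered barrier* of a model is measured by a zero-temperature
string relaxation (gradient descent on 31–41 images with equal-arc-length
reparametrization, endpoints fixed) started from the rigid hinge
interpolation; it is deterministic and independent of the sampling
machinery it is used to check.

### The symmetric two-state rocker

Free energies of the clamshell's basins are *not* equal: the open basin is
floppier, and its extra entropy lowers its free energy by several
kcal/mol. That is a feature for the pipeline demo but useless for testing
whether the machinery recovers iso-energetic minima. `make_symmetric_mini_vft`
therefore builds a variant — collar and arm lobes end to end on the y
axis, each bead cluster exactly C2-symmetric about that axis, references
tilted ∓13° about the hinge — for which the C2 rotation (x→−x, z→−z, beads
permuted to partners) is an exact isometry exchanging the two basin
energies (verified to 1e-13). Its basins have *identical* free energies by
construction, so any reconstructed ΔF is pure estimator error. Default
contact springs (10 kcal/mol/nm²) put its string barrier at ≈ 4.0 kcal/mol
(6.7 kT).

### Langevin dynamics

BAOAB splitting; friction 5 ps⁻¹ (bead models) with dt = 0.005 ps, well
under the stability bound for the stiffest intra-lobe mode
(ω ≈ 13 rad/ps). Configurational sampling was validated against
equipartition (harmonic variance kT/k within 5%) and against analytic
Boltzmann well populations in a tilted double well. Velocities are drawn
fresh from Maxwell–Boltzmann at the start of every run; committor shooting
re-draws them per run from per-run seeds spawned off the master seed
(`numpy.random.SeedSequence`), which makes every stochastic stage exactly
reproducible from its logged seed.

## Path construction

**Morphing.** Between two structures we ramp a harmonic restraint on the
aligned RMSD-to-target linearly to zero over ≥ `min_intermediates` stages
(150 by default; scaled-down runs use 25–60), minimizing at each stage

    E(x) + k_r/2·(d(x, end) − d_target)² + k_step/2·MSD(x, x_prev)

with L-BFGS-B (gradient tolerance 1e-4 kcal/mol/nm). The proximal third
term (k_step = 300 kcal/mol/nm²) prevents the minimizer from teleporting
across a barrier at constant distance-to-target; any stage that still
moves more than twice the nominal spacing is subdivided into strongly
tethered sub-steps, and stages after the ramp tighten the restraint
(k_r ×5, up to 6 times) until the chain ends within 0.02 nm of the target.
This is restrained-energy morphing: the restraint is applied linearly in
the distance deviation and each step is followed by energy minimization,
rather than interpolating coordinates.

**Bridging and resampling.** Consecutive waypoints (the closed reference,
cluster centroids ordered by their S on the guess path, the wide-open end
point) are morphed pairwise and concatenated with each junction structure
appearing exactly once. Equispaced frame extraction places N frames at
uniform cumulative aligned-RMSD arc length (endpoints always included); a
spacing coefficient of variation above 0.15 warns that the chain is too
sparse. λ is re-adapted after every extraction, so λ·⟨MSD⟩ = ln 10 holds
by construction.

**Clustering.** GROMOS-style greedy neighbor-count clustering on the
aligned-RMSD metric (measure subset by default; an `all`-atom flag
exists because the convention is ambiguous in common usage), cutoff 1.5 Å.
Ties in neighbor count break toward the lowest frame index, making the
partition deterministic; it is tested against an independent O(n²)
reference implementation.

## Well-tempered metadynamics

Gaussian hills of base height w₀ = 0.1 kcal/mol are deposited every 1 ps
(the conventional schedule; the desk-scale demo deposits every 0.5 ps), with
the well-tempered damping w = w₀·e^(−V/((γ−1)kT)), γ = 8. Hill widths
default to σ_S = 0.2 and σ_Z = 0.2 nm²; whether the conventional "0.2" for
Z is nm² or Å² is ambiguous in the sources, so the choice is explicit in
config. The scaled-down bead-model runs use σ_S = 0.5 and σ_Z = 0.1 nm²:
with N = 12 frames instead of 40 and ~4×10³ hills instead of 2×10⁶, the
hill footprint must cover a proportionally larger fraction of the S range
for the surface to fill at all.

The engine keeps the bias and its analytic gradient on a grid (spacing
σ/6, bilinear interpolation, agreement with exact hill summation to ~1%);
sampling is never clipped at the grid edge — the interpolation just clamps
there. Bias forces reach bead coordinates through the chain rule with the
full analytic (S, Z) gradients.

FES reconstruction: F = −γ/(γ−1)·V with min-shift to zero (no absolute
reference). Because the instantaneous estimate oscillates as hills keep
arriving, quantitative estimates use the time-averaged variant (mean of
min-shifted snapshots over the last half of the run, 5 snapshots).
Recrossing detection (first completed A→B→A traversal of the S trace) is
available as a stopping rule to avoid overfilling the initial basin; on
desk-scale runs the first recrossing can arrive before the far basin is
filled, in which case the pipeline falls back to the full hills log with a
logged warning. Barriers are measured on the 1D profile
F(S) = −kT·ln ∫ e^(−F(S,Z)/kT) dZ between the window minima.

## Committor analysis

State windows follow the S ≤/≥ threshold, Z ≤ 0.05 nm² convention. Runs
start from the stored configuration nearest the requested (S, Z) in
normalized (S/N, Z/0.05 nm²) space — the stored pool comes from the
metadynamics trace — and integrate unbiased dynamics until entering A or B
(checked every 10 steps) or timing out (reported separately, excluded from
the p_B denominator, never dropped silently). The binomial CI is Wilson at
95%. The shooting estimator was validated against the exact overdamped 1D
splitting probability p_B(x₀) = ∫_A^{x₀} e^{βU} / ∫_A^B e^{βU} on a tilted
double well.

## Problem sizes

The demo configuration runs six 150 ps unbiased trajectories (30 000 steps
each), a 10-frame guess path, a 12-frame refined path, a 1.2 ns
metadynamics run (240 000 steps, 2 400 hills) and 40 shooting runs; the
whole study completes in a few minutes on one core. The acceptance suite
uses 200 000-step metadynamics runs (3 seeds on the double well, 5 on the
symmetric rocker). These sizes were chosen as the smallest at which the
qualitative claims stabilize across seeds.

## What the synthetic systems do and do not show

The bead models reproduce the *structure* of the real problem: two
metastable conformations of a bilobed architecture, a rigid lobe defining
the alignment frame, a barrier unreachable by direct sampling, an
over-opened state absent from the end-point pair, and basins whose
populations no single unbiased run can compare. They do not model
solvent, electrostatics, side-chain packing, or any chemistry: passing
tests here certify the *machinery* (CV mathematics, biasing, estimators,
bookkeeping), not force-field realism. Quantities tied to the real
all-atom system — a ~16 kcal/mol barrier, a committor of 0.31 at its
transition state, specific cluster populations — are not reproducible at
this scale and are covered only by their qualitative analogues (barrier
recovery within tolerance, p_B ∈ (0.2, 0.8) near the saddle, iso-energetic
recovery on the symmetric model).

## Known limitations

- The quasi-static gradient path is kept only as a baseline; it is wrong
  for deformed alignment subsets and must not be used for biasing.
- The grid-accumulated bias is exact only to bilinear-interpolation error
  (~1% at σ/6 spacing); `bias_value` performs exact summation for
  cross-checks.
- Equispaced extraction picks nearest chain indices; for very sparse
  chains the spacing CV bound (0.15) may be unattainable and is reported
  as a warning rather than silently accepted.
- `detect_recrossing` sees only the saved S trace; traversals faster than
  the save stride are invisible.
- The committor start-selection uses a fixed Z scale (0.05 nm²) for
  normalization; landscapes with much larger Z spreads would need it
  exposed.
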