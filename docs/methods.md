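# Methods

This note documents the models, conventions and numerical choices behind
abfekit, and what the synthetic toy system does and does not establish
about real protein–ligand calculations.

## Thermodynamic cycle and sign conventions

A per-pose binding free energy is assembled from letter-coded components
(m, a, l, t, e, f, v, w, n, b, c, r) that each measure one leg of the
restrain–decouple–release cycle. All components are tabulated in the
site→bulk (unbinding) direction: restraint-attachment legs are positive,
release legs negative, and ΔG°_bind = −Σ(components). This convention is
pinned by the bundled benchmark tables, where the merged components of two
poses sum to +2.4 and +3.7 kcal/mol and the published binding values are
−2.4 and −3.7 kcal/mol. Uncertainties combine as the root sum of squares.
Multiple non-interconverting poses combine through an overflow-safe
log-sum-exp; the model explicitly assumes no pose interconversion during
the per-pose calculations.

Scheme definitions: `split_ddm` requires all ten split letters;
`merged_sdr`/`mevn` require {m, e, v, n}, where **n** folds the analytic TR
release in internally (the benchmark shows merged n commensurate with the
split b+c+r sum), so merged schemes do not add **b** separately. The short
protocols `tevb` {t, e, v, b} and `m_star_evbc` {m*, e, v, b, c} add **b**
explicitly. The protein-restraint release **r** is pose-independent when
the apo reference state is shared, so a single Component can be reused
across pose ledgers.

## TR (Boresch) restraints

Six harmonic restraints tie the ligand's rigid-body pose to three protein
anchors: r = |P1−L1|, θ = ∠(P2,P1,L1), Θ = ∠(P1,L1,L2), φ = dih(P3,P2,P1,L1),
Φ = dih(P2,P1,L1,L2), Ψ = dih(P1,L1,L2,L3). This is the standard Boresch
construction; its correctness here is validated against the stiff-spring
closed form of the release integral, not against any diagram. Force
constants follow the AMBER convention (kcal·mol⁻¹·Å⁻² for r,
kcal·mol⁻¹·rad⁻² for angular terms; defaults 10 and 100). References are
measured from the input conformation so the restrained minimum is the pose
itself. Dihedral differences are wrapped to (−180°, 180°] before squaring;
angle math is in radians internally, degrees at the interface.

Conformational restraints cover every bonded heavy-atom quadruple of the
ligand — one entry per distinct quadruple, not one per rotatable bond,
which is the defensible reading of "all dihedrals" and is what the
enumeration tests pin down — plus protein φ/ψ dihedrals in user-declared
residue ranges. COM restraints only fix the reference frame and carry no
free-energy component.

## Anchor selection

P1–P3 are user-chosen backbone atoms, validated against qualitative rules
(backbone names N/CA/C/O, pairwise separation ≥ 5 Å, P1-P2-P3 angle at
least 25° from collinearity; both thresholds configurable since only the
qualitative rules are prescribed). L1 is the non-hydrogen ligand atom
nearest the search-zone centre, with the zone given in the reference frame
(hence the superposition step); an empty zone is the *unstable pose*
outcome — exit code 2, not an exception. L2 minimises |∠(P1,L1,L2) − 90°|
subject to a distance window on L1–L2 (default 2.5–5.0 Å, a reasonable
bonded-neighbour shell; the published workflow leaves the value to its
input file), and L3 repeats the rule one link down the chain. Candidates
are restricted to heavy atoms and ties break on the smallest serial so
selection is deterministic and frame-covariant. Re-selection after
equilibration is the same operation applied to the re-superposed structure.

## Estimators

**MBAR.** The dimensionless free energies solve
f_k = −ln Σ_n exp(−u_kn)/Σ_j N_j exp(f_j − u_jn) with f_1 ≡ 0. The solver
starts with self-consistent iteration and switches to Newton steps on the
convex MBAR objective (analytic gradient and Hessian) once the iterate is
within 1 in dimensionless units, falling back to self-consistent updates
whenever a Newton step misbehaves; convergence is max|Δf| < 1e-8 by
default. An overlap matrix O = (N_k W)Wᵀ is computed after convergence and
adjacent-window overlap below 0.01 warns but never fails, since poor
overlap degrades precision rather than invalidating the equations. BAR is
the two-window case of the same solver; their equivalence is asserted to
1e-8 in the tests. MBAR is cross-checked against brute-force quadrature of
one-dimensional configuration integrals (an independent oracle), not
against another MBAR implementation.

**TI-GQ.** `gq_schedule(n)` maps the n-point Gauss–Legendre nodes/weights
from [−1, 1] to [0, 1]; the node set is unique per n and integrates
polynomial integrands of degree ≤ 2n−1 exactly (asserted at 1e-10).
ΔG = Σ wᵢ⟨∂U/∂λ⟩ᵢ. Where an engine cannot expose ∂U/∂λ, `fd_dudl` brackets
λᵢ with two windows at λᵢ ± δλ/2 (δλ = 0.001 by default) and divides the
BAR free-energy difference by δλ.

**Uncertainties.** Block data analysis throughout: the series (or each
window's series) is cut into n contiguous equal blocks, the remainder
dropped from the front, the estimator recomputed per block, and the
uncertainty is std(blocks)/√n (sample standard deviation, ddof = 1). For
MBAR this recomputes the full solve per block rather than propagating
asymptotic covariances — simpler, and robust to correlated samples once
block lengths exceed the correlation time. Replica spreads use the
population standard deviation (divisor n), the only convention that
reproduces the bundled benchmark's printed spreads at one decimal. Display
rounding is half-away-from-zero to one decimal; stored values are never
rounded.

**Constants.** T = 298.15 K by default, R = 1.987204259×10⁻³
kcal·mol⁻¹·K⁻¹, V₀ = 1660.5392 Å³ at 1 M, orientational volume 8π².

## Standard-state correction

The release free energy is ΔG = −RT·ln(8π²V₀/Z_TR) with
Z_TR = ∫ r² sinθ sinΘ e^(−u/RT) over the six restrained coordinates.
Because u is a sum of independent harmonic terms and the Jacobian
factorises, Z_TR is evaluated exactly as a product of one-dimensional
adaptive quadratures (relative tolerance 1e-9; r over r₀ ± 10σ clipped at
zero, polar angles over (0, π), dihedrals over one full period — which
also makes ΔG provably independent of the dihedral reference values).
Dihedral wells narrower than 5° use the Gaussian integral directly to
avoid wasted nodes. The stiff-spring closed form
Z_TR ≈ r₀² sinθ₀ sinΘ₀ (2πRT)³ (Πk)^(−1/2) is provided as a fast
approximation and as the analytic oracle in the stiff limit; quadrature is
the default and the reference whenever the two disagree (e.g. θ₀ near the
sinθ boundary). Any nonpositive force constant raises a divergent-integral
error since the corresponding integral has no finite limit. Releasing
tight restraints into 1 M bulk yields ΔG < 0.

A Monte-Carlo oracle (`mc_release_oracle`) estimates the same quantity
independently: Metropolis chains sample the six coordinates with their
Jacobian along a λ ladder (0, 0.002, 0.01, 0.04, 0.12, 0.35, 1) scaling
the restraint, MBAR connects the restrained state to the flat
Jacobian-weighted reference whose volume is known in closed form, and
block analysis supplies the standard error. This is a staged, convergent
realisation of free-energy perturbation between the restrained Boltzmann
distribution and the uniform standard-state measure.

## Toy sampler and the synthetic study conditions

Metropolis sampling replaces MD: one chain per window, Gaussian proposals
with step sizes tuned in short pilot runs to an acceptance in [0.2, 0.65]
(error below 0.01), 10% burn-in, and a thinning stride (default 5 for the
1-D potentials, 10 for the six-coordinate field) so that kept samples are
approximately decorrelated and block uncertainties are honest. Identical
seed and parameters give bit-identical tables; every CLI entry point with
randomness takes an explicit seed.

Toy potentials carry their own closed forms: the geometric harmonic ladder
k(λ) = k₀(k₁/k₀)^λ (ΔG = (RT/2)Δλ·ln k₁/k₀, constant ⟨∂U/∂λ⟩), the
λ-coupled well U = ½k₀x² + λ^p·½cx² (Gaussian Z(λ), analytic ⟨∂U/∂λ⟩), and
the six-coordinate restraint field used for the end-to-end cycles. The toy
binding model places a harmonic "site well" of depth ε = 18 kcal/mol on
the six TR coordinates, split into an electrostatic-like part (ε = 5,
k = 6/60) and an LJ-like part (ε = 13, k = 14/140) so that decoupling
proceeds in two legs as in SDR; the restraint term uses the default
k = 10/100. These choices give a stiff, well-overlapping ladder and a
realistic binder of about −6.5 kcal/mol. The analytic truth is
ΔG°_bind = −(ΔG_release(site) + ε) with the combined site well evaluated
by the same quadrature as component b. Attach/decouple legs use the window
ladder (0, 0.05, 0.15, 0.3, 0.5, 0.75, 1) with 1500 samples per window by
default — sizes chosen so a full cycle runs in seconds on one CPU while
leaving the Monte-Carlo error near 0.02 kcal/mol. In the split toy cycle
the bulk ligand is structureless, so the recoupling components f and w are
identically zero, as are the conformational components a, l, c, r; the
split scheme accepts these as zero-strength restraints.

What the toy system emulates: window-based sampling with finite overlap,
correlated samples, block-analysis uncertainties, merged-vs-split closure,
and exact thermodynamic-cycle bookkeeping. What it does not: explicit
solvent, force-field error, slow conformational degrees of freedom,
hysteresis between attach and release, or finite-size electrostatics.
Passing toy cycles therefore validates the estimators and the cycle
arithmetic, not the physical accuracy of any particular MD protocol.

## Structure handling

PDB reading goes through gemmi (first model, first alternate-location
conformer; insertion codes ignored with a warning) with CONECT records
scanned directly since gemmi drops them; writing is fixed-column
formatting so CONECT output round-trips. Covalent radii come from gemmi's
element table; bond perception adds a bond when the distance is within the
radius sum + 0.4 Å (common heuristic), via a KD-tree that the tests verify
against the exhaustive O(N²) scan. Superposition maps alpha-carbons by
chain + residue number (a consistent numbering between mobile and
reference is required — the sequence-independent alignment of the original
workflow is out of scope) and solves the Kabsch problem through
scipy's `Rotation.align_vectors`; at least three non-collinear pairs are
required. HETATM residues that are not water default to the ligand role;
explicit role hints win.

## Known limitations

- The MBAR block uncertainty recomputes per block; it does not propagate
  the asymptotic MBAR covariance, and with very few blocks the SE itself
  is noisy.
- `RestraintSchedule` is a plan object; executing a gradual release is an
  engine concern.
- The DISANG writer covers the harmonic restraints used here; flat-bottom
  or distance-from-bound-configuration restraints are not implemented.
- The toy potentials live on internal coordinates, not Cartesian atoms; no
  replica exchange is performed, and the estimators accept samples
  regardless of how windows were coupled.
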