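# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.  It states no empirical result that the test suite or the
acceptance script does not itself compute.

## Units and conventions

The GROMOS/GROMACS unit system throughout: lengths nm, time ps, energies
kJ/mol, charges e, temperature K, pressure bar.  Dipoles are e·nm with
1 e·nm = 48.0321 D.  Derived outputs use the units liquid benchmarks print:
κ_T in 1/GPa (1 GPa = 10⁴ bar), C_P in J mol⁻¹ K⁻¹.  Atom indices are
1-based in files and public APIs, 0-based internally.  Only orthorhombic
boxes are supported; triclinic input raises.  XYZ files are Å and converted
to nm on read; GRO is nm natively.  Binary trajectory formats are
intentionally unsupported — conversion to multi-frame GRO is the user's job.

## Charge fitting (charges)

The model dipole is the point-charge sum μ(q) = Σ qᵢ(rᵢ − r₀) on a single
input geometry (the QM-optimized one); no conformational averaging.  For a
neutral molecule the origin cancels; for ions the declared origin is used.

The fit minimizes ‖μ(q) − μ_target‖² subject to equality constraints: one
row per charge group forcing its integer total, one row per frozen atom.
A "superimposed" charge group is expressed by listing its extra member
atoms; those atoms then appear in two group rows.  This single vector-space
objective penalizes direction and magnitude error simultaneously — an
iterative manual direction-first adjustment is not reproducible, a convex
least squares is.  Mechanics: shift variables d = q − q₀; the minimal-norm
particular solution of A d = c comes from the pseudoinverse, the remaining
freedom from an SVD nullspace basis; the nullspace least squares uses an
*absolute* singular-value cutoff (10⁻¹⁰ × the coordinate scale) so dipole
directions that are immovable under the constraints (e.g. out-of-plane for
a planar molecule) yield zero shift instead of exploding.  Among exact
minimizers the charge shift of minimal Euclidean norm is returned, making
underdetermined fits deterministic.  The |Δqᵢ| ≤ 0.5 e box (configurable) is
checked a posteriori: violation warns and flags, it does not alter the
solution.  Infeasible constraint systems (rank test on [A|b]) raise listing
the conflict.

Degeneracy worth knowing: a planar molecule with an in-plane target has a
one-dimensional manifold of exact dipole matches once ≥ 4 charges share one
group; only the minimal-shift representative is unique.  Tests compare
against a brute-force grid with the same tie-break, and against direct
charge equality on a non-planar variant where the minimizer is unique.

## Torsion fitting (torsions)

Basis restricted to the GROMOS-legal proper dihedral: multiplicities 1–6,
phases 0° or 180°, kₙ ≥ 0.  Because (1 + cos(nφ − 180°)) = 1 − cos(nφ), the
phase pair for one n is a sign choice on a single cos(nφ) coefficient, so
the fit is ordinary least squares on {1, cos(nφ)} of the min-shifted
(target − background) difference; a negative coefficient maps to the
opposite-phase positive-k term.  Constant offsets are unphysical: both
profiles are min-shifted before fitting and the residual constant is
reported, not fitted.  Default multiplicity set {1, 2, 3, 6}; no automatic
model selection, uniform weights on scan points (the scan protocol gives no
reason to weight).  The MM background (dihedral zeroed) is an input — this
toolkit does not evaluate full MM energies.  Rank of the design matrix is
checked; too few distinct angles raise.  Rotamer classification scans a 1°
grid: barrier < 2.5 kJ/mol (≈ kT at 298 K) ⇒ "spread".

## Liquid properties (liquids)

Block averaging uses 5 contiguous equal blocks; remainder frames are
dropped from the tail for determinism; the SD is the between-block ddof=1
scatter.  ΔH_vap takes the per-molecule gas mean and the total liquid mean.
The finite-difference estimators are written in density form:
α_P = −Δlnρ/ΔT, κ_T = +Δlnρ/ΔP.  The κ_T sign deserves a note: recasting
−(1/V)(∂V/∂P) in terms of ρ cancels the minus, so the physically positive
convention (density rising with pressure ⇒ κ_T > 0) is implemented.  With
three bracketing states (T ± 10 K, P ± 0.1 bar) the endpoint difference is
the central difference at the midpoint.  C_P is the classical estimator
ΔU/ΔT per molecule, no quantum corrections — known to overestimate
experimental heat capacities.  The dielectric constant uses the
conducting-boundary fluctuation formula; no reaction-field finite-size
correction is applied (a documented bias source).  Convergence is declared
when the running average moves < 2% over its final 20%.  Energy drift is
the |OLS slope| of total energy vs time normalized to J mol⁻¹ ns⁻¹ DoF⁻¹,
compared against the 0.5 quality threshold; < 10 samples raise.

## Thermodynamic integration (ti)

Each decoupling stage uses the 25-point schedule 0, 0.02, 0.04, 0.07, 0.1,
0.15, then uniform 0.05 steps through 0.8, then 0.85, 0.9, 0.93, 0.96,
0.98, 1 — the only reading of the published ellipsis that yields 25 per
stage and 50 total.  Trapezoid quadrature (the community default,
deterministic; no spline assumptions), with window SEMs propagated through
the trapezoid weights: err = √(Σwᵢ²semᵢ²); stages combine additively with
errors in quadrature.  λ = 0 is fully interacting, λ = 1 decoupled, so
ΔG_sim > 0 for a well-solvated solute and ΔG_hyd = −ΔG_sim.  Soft-core
power 1 and α_LJ = 0.5 are carried as provenance metadata only — the
soft-core potential itself is engine work.

## H-bonds and solvation (hbonds)

Geometric criterion r(D–A) ≤ 0.35 nm and ∠H–D–A ≤ 30°, the defaults of the
standard analysis tool; both configurable.  Counts never include a donor's
own atoms as acceptor.  Distances are minimum-image on orthorhombic boxes.

Residence time: completed (uncensored) bonded intervals feed an empirical
survival function S(t) on a uniform grid truncated where S reaches 5%, and
−1/slope of the log-linear OLS fit is τ.  This uninterrupted-interval
definition is the one consistent with lifetime ≡ 1/τ and with the Eyring
reproduction of tabulated free energies; an intermittent (Luzar–Chandler)
correlator is deliberately not the default.  Fewer than 20 completed events
flags insufficient sampling (rendered as dash cells); intervals all at or
below the frame spacing flag "short-lived" with τ ≤ dt.  Note the save
interval floors what a discretized indicator can resolve: sub-dt kinetics
are recoverable only from continuous interval data, which the synthetic
generator provides alongside the discretized series.

ΔG_HB = RT·ln(τ·k_BT/h) with τ in seconds — the transition-state inversion
of the first-order rate 1/τ; its fixed point ΔG = 0 sits at τ = h/k_BT.
This prefactor choice is an inference validated in the acceptance suite
against every checked (τ, ΔG) table pair.

RDF: shell-histogram estimator normalized by the ideal-gas count at the
bulk number density N_sel/V; bin width > box/4 raises.  OBD is the first
local maximum with g > 1 and height ≥ 1.05 × the following minimum (the
prominence filter rejects noise wiggles); failing that, the global maximum
is returned with a warning and a not-qualified flag.  CN integrates
ρ4πr²g(r) by trapezoid to the bounding minimum.  Orientation assumes rigid
3-site (SPC-geometry) waters: the dipole axis is the O→H-bisector, cosθ is
taken against the O→reference vector, and the mean over ≥ 100 in-shell
observations classifies with ±0.25 thresholds (H-oriented / O-oriented /
Undefined); all three thresholds configurable.

Report rows follow the canonical column order (Molecule, Atom, Aver_HB,
tau_HB, lifetime_HB, dG_HB, Percent, CN, OBD_HB, Orientation).  Aver_HB
carries the per-frame SD; kinetic/thermodynamic SDs come from splitting the
intervals into 5 consecutive chunks (the contiguous 50-ns blocks of a
250-ns run); CN/OBD SDs from per-block RDF scatter when per-block curves
are supplied.

## Benchmark statistics (stats)

AVED is the mean (and ddof=1 SD) of simulated − experimental within one
property; mixing properties raises.  The regression is OLS of simulated on
experimental with a single exclusion pass: points with |residual| > 2 ×
SD(residuals) of the all-points fit are dropped, then one refit; R is the
Pearson coefficient of the kept set.  Single-pass (not iterated) exclusion
and the residual-SD (not property-SD) threshold are the simplest
deterministic reading of a per-regression outlier rule.

## Synthetic generators (synth)

Generators draw directly in configuration/observable space — no dynamics
integrator — because every estimator under test consumes geometry or time
series only.  Each returns its ground truth alongside the data and is
byte-deterministic under a fixed seed.

* Two-state Markov H-bond indicator: alternating exponential dwells with
  means (τ_bound, τ_free), stationary occupancy τ_b/(τ_b+τ_f), discretized
  at the 2 ps save interval; continuous completed intervals returned too.
  Defaults (250 ns duration, 2 ps saves) mirror a production run in water.
* Liquid series: V(T,P) = V₀·exp(α(T−T₀))·exp(−κ(P−P₀)) and U linear in T,
  sampled at the five bracketing state points (T±10 K at 1 bar, 298.15 K at
  1±0.1 bar) with optional Gaussian frame noise — exactly the states the
  finite-difference estimators consume.
* TI curves: polynomial ⟨∂H/∂λ⟩ on the 25-window stage with closed-form
  integrals; hydration shells: a solute atom at the box center, n_shell
  rigid SPC-geometry waters at the target shell radius with inward/outward/
  random dipole orientation plus uniform bulk waters; torsion profiles:
  cosine-series energies on the 30° grid; toy molecules: diatomic, planar
  4-atom and hexagonal C₆H₆-like with six neutral CH charge groups.

What a green test does *not* establish: the generators have no force field,
no water structure beyond the constructed shell, no pressure/temperature
coupling artifacts, no conformational dynamics.  They validate estimator
correctness and statistical calibration, not force-field accuracy.
Ensemble-scale published results (force-field deviation tables, regression
equations across 42 liquids, hydration free energies, the ensemble dipole
angle) require QM plus multi-ns MD campaigns and are out of desk-scale
reach by design.

## Other numerical choices

* Charge-sum invariants on parsed topologies warn rather than raise —
  mid-fit inputs are legitimately non-integral; strict validation is
  opt-in.
* Parsers never silently drop rows; ragged rows, malformed lines (with
  line numbers) and empty data sections raise typed errors.
* Dipole-angle of a (near-)zero vector (< 10⁻¹² e·nm) is an error, not 0.
* The uniform-gas RDF flatness check uses 0.1 nm bins so the worst
  (smallest-shell) bin keeps ≥ ~500 counts at the stated sample size.
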