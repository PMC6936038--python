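# Methods

`homeostat` simulates the statistical mechanics of single adherent cells and
forecasts human mesenchymal stem cell (hMSC) lineage commitment from the
distribution of the cytoskeletal free energy. This note records the model,
its closures, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## The homeostatic ensemble

A cell exchanges nutrients with its medium and, over the interphase of the
cell cycle, holds the average copy number of each internal species fixed.
Over the resulting (non-thermal) fluctuations in morphology, the
ensemble-average Gibbs free energy of the cell–substrate system therefore
equals that of an isolated cell in suspension:

    ⟨Ĝ⟩ = G_S.

Maximizing morphological entropy subject to this constraint gives the
equilibrium distribution over morphological microstates j

    P_eq(j) = exp(−ζ Ĝ(j)) / Z,

with 1/ζ the *homeostatic temperature*, fixed by the constraint. The package
samples this distribution with Metropolis Monte Carlo and solves for ζ per
environment.

## Morphological microstates

A microstate is a smooth planar deformation x = χ(X) of the reference
circular cell (radius `R0`, default 20 µm) with a co-deforming circular
nucleus (`RN`, default 6 µm). χ is parametrized by 20 coefficients: a 2×2
affine block plus harmonic-polynomial enrichment Re/Im((z/R0)^m), m = 2…5,
in both displacement components. Harmonic polynomials are smooth, give
analytic deformation gradients, and reproduce circles, ellipses and lobed
spread shapes. Orders start at m = 2 because the m = 1 harmonics are linear
in X and would duplicate the affine block.

States with det F ≤ 0 anywhere on the quadrature grid, self-intersecting
boundaries, or (on patterned substrates) boundary points outside the
adhesive island are inadmissible; the sampler rejects such proposals rather
than penalizing them, so the energy model is evaluated only on physical
states.

## Free energy of a microstate

`Ĝ = F̂passive + F̂cyto + F̂sub`, all normalized by `energy_norm`
(default 1000 fJ; 1 fJ = 1 kPa·µm³).

**Passive elasticity.** Cytoplasm and nucleus are compressible 2D Ogden
bodies,

    Φ = (2µ/m²)(λ₁^m + λ₂^m − 2 − m ln J) + (κ/2)(J − 1)²,

with µ = `mu_cytoplasm` (6 kPa) or `mu_nucleus` (24 kPa), exponent
`ogden_m` = 3 and areal penalty `kappa` = 4.5 kPa, integrated over the
reference disc and scaled by the thickness `t0` = 1 µm. The −m ln J term
makes the undeformed circle both the zero and the stress-free state, which
the suspension calculation relies on. The moduli are effective 2D constants
chosen so that spread states at Â ≈ 1.2–1.5 cost an energy comparable to the
cytoskeletal gain that drives spreading.

**Stress-fibre cytoskeleton.** At every material point and fibre orientation
φ (16 bins on [0, π)), actomyosin exists as unbound proteins (uniform
normalized concentration N̂u = ν) in chemical equilibrium with bound
contractile fibres of angular concentration η̂(x, φ) and functional-unit
number n̂(x, φ) = max(1 + ε(x,φ), `n_min`), where ε is the nominal strain of
the material direction at φ. The binding closure is Langmuir-type:

    η̂ = η̂max · ν e^Ψ / (1 + ν e^Ψ),    Ψ = (σ(ε)·Ω̂ − µ̂b0)/kT̂,
    σ(ε) = σ_eff · max(0, 1 + β ε),

with σ_eff the attainable fibre tension (below). Protein conservation,
ν + ⟨η̂ n̂⟩ = 1 with ⟨·⟩ the area- and orientation-average over the disc,
closes the system; it is a scalar, strictly monotone root problem in ν
solved by damped Newton to |residual| < 1e-12 (warm-started along a chain).
The fibre system spans the whole disc — the nucleus differs only in its
passive modulus — which keeps every field smooth for the spectral traction
evaluation.

The cytoskeletal free energy combines mixing entropy of the unbound pool,
the standard free energy of bound fibres and the mechanical work of fibre
tension:

    F̂cyto = [ Ĉ·( ν(ln ν − 1) + ⟨ η̂ n̂ (ln(η̂ n̂/η̂max) − 1 − Ψ) ⟩ ) + F₀ ] / E_norm,

with entropic scale Ĉ = `c_cyto` = 700 fJ and offset F₀ = 7100 fJ. It
decreases strictly as the polymerization level N̂b = 1 − ν rises at fixed
strain (a tested property). The offset anchors the stiff-substrate
(70 kPa) ensemble mean near 2.4, inside the range of the literature lineage
bands (1.6–2.6); softer conditions extend above that range because this
model's F̂cyto span across stiffness is wider than in the original
formulation, whose absolute normalization is not reconstructible. Lineage
bands are therefore always recalibrated on this package's own ensembles
(below).

**Tension capacity and substrate coupling.** Steady-state fibre tension must
be reacted by the substrate through the adhesions, so the attainable tension
saturates with substrate stiffness:

    σ_eff = σmax · min(1, E(E_cap + E_half) / ((E + E_half) E_cap)),

with `E_half` = 4 kPa and the effective-stiffness cap `e_sub_cap` = 70 kPa
(glass and stiff gels are capped at 70 kPa; PDMS islands are treated as
rigid, σ_eff = σmax). The normalization makes stiff gels, glass and rigid
islands share one tension capacity, which is what lets large-island
ensembles converge to the unpatterned 70 kPa ensemble. In suspension there
are no mature adhesions; the capacity is `suspension_tension_factor` = 0.35
of σmax, reacted by the cell's own elasticity.

The default constants put the binding equilibrium near saturation in spread
states (ν e^Ψ ≫ 1). This is deliberate: a small cut in σmax (the ROCK-
inhibitor experiment, 240 → 231 kPa) then changes η̂ — and hence tractions
and morphology — only weakly, while F̂cyto still shifts through the explicit
−Ψ work term. That separation is the mechanism behind the "forecast changes,
morphometrics do not" behaviour of the inhibition experiment.

**Tractions and substrate energy.** The nominal (first Piola–Kirchhoff)
stress is the sum of the passive Ogden stress (via the spectral
decomposition of C = FᵀF) and the active fibre stress
(1/π)∫ η̂ σ(ε) (Fm ⊗ m)/|Fm| dφ. The traction transmitted to the substrate
is T = t0 · Div P, evaluated spectrally (barycentric differentiation in
radius, Fourier differentiation in angle), with the three rigid-body
force/torque modes projected out so the net force and torque vanish
identically. The substrate is a Winkler foundation u = T/k with
k = `winkler_c`·E_eff/R0, storing F̂sub = ∫|T|²/(2k) dA / E_norm (zero on
rigid islands). With `winkler_c` = 8000 the foundation is a weak, formally
correct coupling — the energy penalty per unit traction decreases with
stiffness — while the dominant stiffness response runs through σ_eff. The
free-edge boundary layer of the traction field is not resolved; T̂ maps are
interior-equilibrium estimates, adequate for the integrated observable
T̂T = ∫|T| dA/(σ_ref π R0²) (σ_ref fixed at 240 kPa so treated and untreated
runs share one scale).

**Suspension state.** The isolated circular cell contracts until fibre
tension balances passive compression; the equibiaxial balance is solved by
bisection for λ* (≈ 0.81 at defaults) and G_S = F̂passive(λ*) + F̂cyto(λ*)
(≈ 7.13). With σmax = 0 the suspended state is exactly the undeformed circle.

## Sampling and the ζ solve

Metropolis chains use independent Gaussian proposals on the 20 coefficients,
with a global scale adapted during burn-in (first 20% of steps) to a ~30%
acceptance target and frozen afterwards, preserving detailed balance in the
recorded portion. Samples are thinned ×10. Chains are bitwise reproducible
from their seed.

ζ is solved per environment by stochastic root finding: short pilot chains
estimate ⟨Ĝ⟩(ζ); since d⟨Ĝ⟩/dζ = −Var(Ĝ), Newton updates are used inside a
bracket, with geometric bisection as fallback; bracket sides are only
assigned when an estimate is clearly off target (beyond its own standard
error), so pilot noise cannot wedge the bracket. The production chain
re-verifies the constraint and applies up to five corrective Newton updates;
the verification tolerance is max(1% of |G_S|, 3 standard errors of the
estimated mean) — the constraint cannot be verified below the Monte-Carlo
resolution of the chain itself. For enumerable toy spaces the constraint is
solved exactly by bisection.

Two degenerate regimes are handled explicitly: if all states share one
energy, ζ = 1 is returned by convention; if the minimum reachable Ĝ exceeds
G_S (severe confinement — e.g. a 900 µm² island, where the cell must
compress), no root exists, ζ is capped at 1e4 and the cold, near-minimum
ensemble is returned flagged `no_root`/`constraint_ok=False`. Sweeps keep
running on flagged conditions; the flag is carried into the results table.

Diagnostics per ensemble: acceptance rate, integrated autocorrelation time
of Ĝ (Sokal window), split-chain R̂, constraint residual and tolerance.

## Observables and densities

Per sample: Â = area/(πR0²) (area via ∫J dA over the reference disc; the
boundary-integral route agrees to <1e-6 and is used as a cross-check), the
aspect ratio A_s of the moment-equivalent ellipse (second area moments),
T̂T, N̂b and F̂cyto. Marginal densities are Gaussian KDEs with Silverman
bandwidth; joint densities are 2D KDEs with Pearson/Spearman correlations
and bootstrap CIs. Comparative L1 distances between two sample densities use
one pooled bandwidth so that bandwidth differences cannot masquerade as
distribution shifts. Immunofluorescence-like renders splat per-point fibre
intensity ⟨η̂ n̂⟩ (green), |T̂| (pink) and the nucleus mask (blue) onto a
0.5 µm/px raster with a scale bar; they are deterministic per sample.

## Lineage forecasting

Over the 24–48 h commitment window the cell visits Nc (default 15)
decorrelated microstates, so the time-averaged F̄cyto is Gaussian with mean
µ and variance σ²/Nc, where (µ, σ) are the homeostatic moments of F̂cyto. A
cell commits to lineage x when F̄cyto ∈ F̄x ± ΔF̄x; the raw band probability
has the closed form Φ((F̄x+ΔF̄x−µ)√Nc/σ) − Φ((F̄x−ΔF̄x−µ)√Nc/σ), normalized
by Z_L = max(1, Σx Px), with 1 − ΣPx/Z_L undifferentiated. (The CLT density
is implemented in its standard form — negative exponent, variance σ²/Nc.)

Band parameters are media-specific and live on the model's energy scale, so
the default workflow *calibrates then predicts*: `calibrate_bands` fits
(F̄x, ΔF̄x) per lineage by bounded least squares (multi-start, since the
objective is multi-modal in the band parameters) to observed differentiation
fractions across conditions, then the fitted `MediaModel` is applied to new
conditions. The shipped calibration fractions are approximate digitizations
of the classical stiffness-directed (growth media: osteoblasts peak at
30 kPa at ~80%, myoblasts at 10 kPa) and island-directed (mixed media:
adipocytes on small islands, osteoblasts on large) differentiation data.
Undetected lineages are lumped into non-differentiation. On this package's
scale the fitted osteoblast band sits *below* the myoblast band, because
stiffer substrates (the osteogenic optimum) give lower F̂cyto.

## Experiments

* `run_stiffness_sweep` — ensembles at {1, 3, 10, 30, 70} kPa, in-sweep band
  calibration, forecasts, CSV + figures (figures regenerate from the CSV).
* `run_island_sweep` — square rigid islands (default areas 900–14 400 µm²)
  plus an unpatterned 70 kPa reference for the spreading-convergence check.
* `run_rock_inhibition` — paired ensembles at A_p = 2725 µm² with σmax = 240
  vs 231 kPa, sharing one seed (common random numbers) so the contrast is
  not polluted by independent ζ-solve noise; reports forecasts and the
  comparative L1 statistic.

## Problem sizes

Defaults are desk-scale. The library default is 2e5 production steps per
condition; the reproduction script uses 5e4 per condition (five conditions)
and the test suite 2e4–6e4, with ~2.5e3-step pilot chains for the ζ solve.
The quadrature grid is 16 radial × 24 angular Gauss/uniform points with 16
fibre orientations; doubling the grid changes the energy components of
representative spread states by <1%. At these budgets the Monte-Carlo
standard error of a forecast fraction is ~1–2 percentage points.

## Limitations

* The binding, tension-saturation and Winkler closures are this package's
  concrete defaults with the qualitative properties stated above; no
  equation-level fidelity to any particular published closure is claimed.
* 2D only; no focal-adhesion kinetics, no viscoelasticity, no cyclic
  loading, no gene-expression layer. The forecast output is a commitment
  probability, not a differentiation time-course.
* The shape basis (affine + 8 harmonics) reaches ellipses and lobed spread
  shapes but not filopodial or strongly branched morphologies; ensembles on
  very soft substrates are correspondingly conservative in shape variety.
* The traction field ignores the free-edge boundary layer; pointwise T̂ maps
  are qualitative, the integrated T̂T is the quantitative observable.
* Synthetic ensembles emulate morphology statistics, not real micrographs:
  passing tests show internal consistency of the model and pipeline, and
  agreement with the qualitative experimental trends encoded in the
  calibration fractions — not agreement with any particular measured cell
  population.
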