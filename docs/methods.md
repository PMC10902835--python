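# Methods

This note records the models implemented in `cavityfluc`, the numerical and
design choices that were genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Solvent models and units

The production solvent is mW water: a single-site Stillinger–Weber model
whose three-body term λε(cosθ − cosθ₀)² penalizes deviations from the
tetrahedral angle (cosθ₀ = −1/3), standing in for directional hydrogen
bonding. Parameters (ε = 25.89488 kJ/mol, σ = 2.3925 Å, a = 1.8, A, B,
p = 4, q = 0, λ = 23.15, γ = 1.2) live in the versioned file
`src/cavityfluc/data/mw.params`; both the pair and triplet terms vanish
with all derivatives at r = aσ through the exp(σ/(r − aσ)) switching
factor, so there are no cutoff discontinuities. Two reference solvents
serve as exact oracles: the ideal gas (U ≡ 0, occupancies exactly Poisson)
and hard spheres (U ∈ {0, ∞}).

Internal units are Å, kJ/mol, K. Pressures enter in atm and surface
tensions in dyn/cm; each is converted exactly once, in a named constant in
`constants.py` (1 atm = 6.1019×10⁻⁵ kJ mol⁻¹ Å⁻³;
1 dyn/cm = 6.0221×10⁻³ kJ mol⁻¹ Å⁻²). Minimum-image periodic boundaries in
an orthorhombic (in practice cubic) box; energies refuse boxes smaller than
twice the interaction range. The O(N³) brute-force energy sum is retained
as the oracle for the neighbor-filtered production kernel.

## Monte Carlo sampling

Isothermal–isobaric Metropolis MC. One pass = one attempted displacement
per particle (numba-compiled sweep), plus a configurable number of
cavity-translation moves (default one per pass) and an isotropic volume
move every fifth pass, following the simulation protocol the model system
is normally run with. The cavity is force-free; only the umbrella
W(n) = k₀(n − n₀)²/2 couples it to the solvent, so cavity moves accept on
ΔW alone. Volume moves use linear-V proposals with the standard
exp(−β(ΔU + ΔW + PΔV) + N ln(V′/V)) acceptance; the umbrella is re-evaluated
because rescaling can move particles across the boundary. Occupancy uses
the half-open convention (a center exactly at distance R is outside) —
measure-zero in practice, fixed for determinism.

Move sizes are tuned multiplicatively (×1.1 or ÷1.1 every 50 passes)
toward 30 % acceptance **during equilibration only** and frozen for
production, since tuning during production breaks detailed balance. All
randomness flows from one `numpy` PCG64 generator per window, so identical
seed + configuration reproduces the trajectory bit for bit.

Umbrella ladders follow the protocol n₀ = 0, 2, 4, … with the spring
constant interpolated in [2.5, 9] kJ/mol, stiffer as the cavity empties
(each window is meant to sample ±3 occupancies around its center);
per-window overrides are accepted.

Verified ensemble properties: the NPT ideal gas reproduces ⟨N/V⟩ = βP
(exact); the NVT ideal gas gives Poisson cavity occupancies (χ², α = 0.01,
on samples thinned by ~3 integrated autocorrelation times — the raw
occupancy series has τ_int ≈ 18 passes at the test conditions and a naive
χ² on correlated samples is invalid); a biased run samples
Poisson × exp(−βW) exactly.

At ambient conditions (25 °C, 1 atm) the mW model equilibrates here to
ρ = 0.997 g/cm³ and a potential energy of −42.1 kJ/mol per particle with
N = 128, consistent with published values for this model; the package
default bulk density is ρ = 0.033326 Å⁻³ (= 0.997 g/cm³), which also
reproduces the reference mean occupancies ⟨n⟩ = 34.9 (6.3 Å) and 7.1
(3.7 Å).

## WHAM

Standard self-consistent iteration, in log space, of
p_n ∝ Σ_w c_w(n) / Σ_w N_w exp(f_w − βW_w(n)) with
exp(−f_w) = Σ_n p_n exp(−βW_w(n)). Convergence when max|Δf_w| < 10⁻⁸
(up to 10⁵ iterations); warm starts are supported when windows are added.
The union of sampled occupancies must be contiguous — a gap leaves the
relative free energies of the two sides undetermined, and is a hard error
naming the first missing n. Error bars, when requested, come from a block
bootstrap over production blocks (default 20 blocks), which respects the
temporal correlation of the occupancy series. `pymbar` is not used; the
estimator is ~40 lines and having it in-package keeps the log-space
conventions uniform with the knitting route.

## RDF knitting

For frames conditioned on occupancy n, the cavity–solvent RDF g_n(r) is
accumulated as a distance histogram normalized by ideal shell volumes and
the bulk density. Because the umbrella depends only on n, the biased
conditional ensemble at fixed n equals the unbiased one, so same-n frames
pool across windows without reweighting; per-frame weights are nevertheless
accepted and honored. Interior normalization (the volume average of g_n
inside the cavity equals n/ρv) is asserted as an invariant.

The continuity constant comes from a simultaneous weighted least-squares
fit of

    −ln g_{n+1}(r<R) = α₂(r−R)² + α₁(r−R) + α₀ + ln K_n
    −ln g_n(r≥R)     = α₂(r−R)² + α₁(r−R) + α₀

over R ± 1 Å (beyond which the quadratic model of the potential of mean
force degrades). Default bin width 0.05 Å; per-bin weights are the raw pair
counts (inverse-variance weighting of −ln g under Poisson counting), with
an unweighted mode retained since the weighting convention is an open
choice. Bins with empty or non-positive RDF values are excluded with a
warning; fewer than six usable bins is an error. Occupancy states with
fewer than 100 frames (configurable) are excluded from knitting and
reported — never interpolated across. p_n is assembled as
p_n ∝ exp(Σ_{i<n} ln K_i) and the passivity identity Σ_n p_n g_n(r) = 1 is
available as a diagnostic; its statistical test uses a Bonferroni-corrected
per-bin z bound, since a fixed 3σ cut on ~100 simultaneous bins would have
a substantial false-alarm rate.

## IGFT

p_n is the normalized Gaussian with mean ⟨n⟩ = ρ·4πR³/3 and variance
σ² = χ(R)⟨n⟩. The normalized variance interpolates two rigorous limits:

- **Sub-diameter cavities (2R ≤ d_ww):** at most one solvent center fits,
  the occupancy is Bernoulli, and χ = 1 − ρv exactly.
- **Macroscopic cavities:** χ → χ∞ = ρ k_B T κ_T.

Between them the deficit χ − χ∞ is expanded in surface powers of
u = d_ww/2R (the leading 1/R term is the interfacial correction to the
variance, the u² term the next curvature correction), with both
coefficients fixed by demanding value and slope continuity at u = 1:
χ = χ∞ + [2(1−η−χ∞) − 3η]u + [3η − (1−η−χ∞)]u², η = πρd_ww³/6. This
closed form uses only ρ, κ_T and the effective water diameter
d_ww = 2.65 Å. At the package defaults it gives χ(6.3 Å) = 0.131 and an
IGFT empty-cavity free energy 64.5 k_BT above (1.92× the size of) the AFT
value at 6.3 Å, and places the 6.3 Å nucleation occupancy at n* = 21.8 —
all consistent with the reference results for this system, which is the
evidence behind adopting this interpolation. Note the approach to χ∞ is
first order in d_ww/2R, so "macroscopic" convergence is slow (10⁻³ relative
at R = 10⁴ Å).

## AFT

Emptying a large cavity proceeds by bubble nucleation. The bubble is a
spherical void of volume V_b = (⟨n⟩−n)/ρ; surface tension acts not at
R_b = (3V_b/4π)^{1/3} but at an effective radius R_b + ΔR with
ΔR = (3/4πρ)^{1/3}δ, a Tolman-like offset with δ a single dimensionless
fit parameter. The bubble-branch free energy is

    βμ_n = Z(⟨n⟩ − n) + βγ·4π(R_b + ΔR)² + ε,   Z = βP/ρ,

and the nucleation occupancy n* equates the per-molecule removal work
along the Gaussian path, (⟨n⟩−n)/σ², with that along the bubble path,
Z + 2βγ(R_b+ΔR)/(ρR_b²). Clearing denominators makes this a quintic in
R_b; it is solved by a 256-point sign scan on n ∈ (0, ⟨n⟩) followed by
Brent bisection, returning the root closest to ⟨n⟩ (the first transition
met on emptying) with a warning if several exist, and `None` when the
balance never crosses (no bubble; fluctuations stay Gaussian — the
generic outcome for small R or large γ). A second-order perturbation
series in (Z, δ) about the closed-form Z = δ = 0 solution
R₀ = [3βγσ²/2πρ²]^{1/4} is provided; its error contracts at third order
(≥4× on halving both parameters, the documented convergence check). The
piecewise AFT free energy uses the Gaussian branch for n ≥ n* and the
bubble branch below, with ε fixed by value continuity at n* (derivative
continuity holds by the definition of n*). Because n* sits ≳2σ below ⟨n⟩,
the distribution remains normalized through the Gaussian branch (verified
to 5 %). n is treated as continuous throughout; discrete evaluation is a
caller-side grid.

Default interface parameters: γ = 66.3 dyn/cm (the model's 66.0 dyn/cm at
300 K shifted to 25 °C with the experimental slope −0.1514 dyn cm⁻¹ K⁻¹)
and δ = 0.83, giving ΔR = 1.60 Å at the ambient density. δ can be re-fit
to (R, βμ₀ᵉˣ) data by weighted least squares; the fit raises when every
data point lies in the Gaussian regime (flat objective — δ enters only
through the bubble branch). The volume-accessibility correction of earlier
bubble descriptions is deliberately excluded: it forces p₀ → 0 and a
divergent empty-cavity free energy.

## Structure metrics

R_g(n) is the density-weighted second moment of the interior g_n(r)
profile about the cavity center, √(∫g r⁴ dr / ∫g r² dr); a uniform
interior gives √(3/5)·R, and that value normalizes cross-size comparisons.
The two simulation estimators of n* are the location of the R_g(n) minimum
(3-point discrete test, ties toward larger n, optional boxcar smoothing —
no smoothing by default) and the location of the ln K_n peak shifted up by
½ (ln K_n approximates −dβμ/dn at n + ½). Monotone profiles return `None`.

## Synthetic data: what it shows and what it does not

The ideal gas is the backbone oracle: i.i.d. uniform placements (particle
count Poisson(ρV)) make every stage exactly solvable — Poisson p_n,
interior g levels (n+1)/⟨n⟩, ln K_n = ln(⟨n⟩/(n+1)). The biased ideal-gas
generator samples n from Poisson × exp(−βW) and places interior/exterior
particles uniformly, which is the exact biased ensemble, so WHAM and
knitting can be validated against closed forms and against each other on
shared data. Hard-sphere frames add packing structure at negligible cost.
None of these reproduce the attractive, hydrogen-bond-network correlations
of water — passing them demonstrates estimator correctness, not water
physics. The one direct physical check runs mW water itself at reduced
scale: N = 128, R = 2.5 Å, 1.5×10³ equilibration and 1.2×10⁴ production
passes with vacancy-probability (hard-probe Widom) estimation of p₀, sizes
chosen so the full suite stays desk-scale; reference-scale studies of this
system use ~10⁶/2.5×10⁷ passes per window and ladders of dozens of
windows, and the configuration object accepts those values unchanged. At
reduced scale the check can only resolve the ~1 k_BT level of agreement
between −ln p₀ and IGFT at small R, plus three standard errors of the
estimate.

## Known limitations

- The χ interpolation is a closed-form surrogate for the exact
  pair-correlation integral; its accuracy degrades in regimes where the
  structure of the solvent deviates strongly from ambient water packing
  (e.g., near criticality).
- AFT below n* is semiquantitative: capillary fluctuations of the bubble
  interface (which make the last waters harder to remove) and
  Gaussian-curvature corrections for nonspherical volumes are not modeled.
- WHAM assumes contiguous occupancy coverage; there is no MBAR
  generalization or 2-D umbrella support.
- The MC engine is serial and single-cavity; no grand-canonical moves,
  molecular dynamics, or parallel tempering.
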