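# Methods

## Equilibrium model

The core object is the binding polynomial of a DNA molecule with three
protein binding sites, Z(L) = 1 + K1·L + K2·L² + K3·L³, evaluated at the free
protein concentration L (μM). The fraction of DNA with exactly i proteins
bound is θi = Ki·Lⁱ/Z. The macroscopic constants are sums over ligation
configurations of microscopic per-site constants (k1, k2, k3; μM⁻¹) and
pairwise coupling factors (k12, k13, k23; dimensionless):

    K1 = k1 + k2 + k3
    K2 = k1k2k12 + k1k3k13 + k2k3k23
    K3 = k1k2k3(k12 + k13 + k23)

Two conventions exist for the triply-liganded weight. The default (`sum`,
above) treats the three pairwise couplings additively; under it the
identical-independent-site limit (ki = Ka, couplings 1) gives
Z = 1 + 3KaL + 3Ka²L² + 3Ka³L³ rather than the binomial (1 + KaL)³. The
`product` convention (K3 = k1k2k3·k12k13k23) recovers the binomial limit and
is available through the `triple_term` argument of `macro_from_micro` and
`microstate_oracle` for comparison. The default follows the additive pairwise
convention; the discrepancy only affects the cubic coefficient and hence θ3
at high occupancy. An enumeration oracle (`microstate_oracle`) computes the
same fractions by explicitly summing the 8 ligation configurations and is
tested to agree with the polynomial route to 1e-12 under both conventions.

Cooperativity of the second and third binding events is quantified by
r2 = K2/(K1²/3) = 3K2/K1² and r3 = K3/(K1K2/3) = 3K3/(K1K2); both equal 1
exactly under identical independent sites and exceed 1 when the
corresponding event is cooperative. Under independence the reduction
K1 = 3Ka, K2 = 3Ka², K3 = 3Ka³ is inverted order by order,
(K1/3, √(K2/3), ∛(K3/3)), and the per-site Ka is reported as the arithmetic
mean of the three estimates (they agree exactly for data generated by the
model; averaging damps fit noise symmetrically). Kd = 1/Ka. The reduction is
refused whenever a cooperative verdict stands, because its premise fails.

Units are fixed package-wide: concentrations in μM, so K1, K2, K3 carry
μM⁻¹, μM⁻², μM⁻³; times in s; SPR responses in RU. Nothing auto-converts.

## Fitting the macroscopic constants

`MultisiteBindingModel` minimises the unweighted (optionally
inverse-variance-weighted) squared error between observed complex fractions
(f1, f2, f3) and model (θ1, θ2, θ3) over the concentration grid; θ0 is
excluded as it is fixed by normalisation. Positivity is enforced by
optimising log10 Ki with a trust-region reflective least-squares solver boxed
at ±12 (K within 10⁻¹²–10¹², far beyond any resolvable affinity, and safe
against overflow). Eight multistart initialisations are used: seven spanning
per-site Ka from 10⁻² to 10² in the identical-site shape (3a, 3a², 3a³) plus
one data-driven start at Ka ≈ 1/median(concentration). Best residual sum of
squares wins; ties below 1e-9 go to the smallest ‖log10 K‖. Standard errors
come from the Jacobian at the optimum via the delta method
(SE_K = K·ln10·SE_log10K). Datasets whose complex fractions never exceed 2%
raise an identifiability error instead of returning a meaningless fit.

Free vs total ligand: by default the total protein concentration is used as
L. In the emulated experiment (20 nM DNA, ≥ 100 nM protein) ligand depletion
is at most 3 × 20 nM = 60 nM, ≤ 6% at the lowest grid point, and the
simulator uses the same convention, so the approximation is internally
consistent. `ligand="exact"` solves the scalar mass balance
L + D_tot·(θ1 + 2θ2 + 3θ3) = P_tot by Brent bracketing on [0, P_tot] at every
grid point, in both the fitter and the generator.

## Bootstrap and cooperativity verdict

Replicate gels are fitted separately; r2, r3 and Ka are reported as mean ± SD
across replicates (SD = 0 for a single replicate). Uncertainty additionally
comes from a case-resampling bootstrap: each iteration resamples
concentration points with replacement within every replicate, refits each
replicate (warm-started at its full-data optimum), and records the
across-replicate mean of K1, K2, K3, r2, r3 and Ka — the same statistics the
report quotes. Iterations with any non-converging replicate are dropped and
counted. Default 1000 resamples; a seed is mandatory.

A binding event is called cooperative only when the bootstrap 2.5% quantile
of its ratio exceeds 1 (with a 1e-9 tolerance so that a degenerate noiseless
bootstrap, which sits at exactly 1 plus float jitter, does not trigger). This
is deliberately conservative relative to comparing the ratio mean to 1, and
the rule is recorded in the report.

Known limitation: the ratio estimators carry a small upward noise-induced
bias (~+0.02 in r2 at the default noise level), which case resampling cannot
estimate because it reuses the observed noise. At the per-assay
(single-replicate) unit the measured false-cooperative rate is ≈ 4% (event 2)
and ≈ 2% (event 3) over 50 seeded independent datasets, within nominal. When
several replicates are pooled the bootstrap interval of the mean tightens
around the still-biased point estimate, and the rule's effective size grows
(measured ≈ 20–30% at 5 replicates under the default noise). Verdicts from
many pooled replicates of low-noise data should therefore be read together
with the ratio means and SDs, not mechanically.

## Single-site fits, kinetics, groups

The hyperbola y = Bmax·x/(Kd + x) is fitted by Levenberg–Marquardt
(`scipy.optimize.curve_fit`) with moment-based initial guesses (plateau from
the curve top, Kd from the concentration nearest half-plateau). EMSA curves
and steady-state SPR series share this core verbatim (Bmax ≡ Rmax in RU).
Bmax is free by default and can be fixed (`fix_bmax`). A fitted Kd outside
(min x/100, 100·max x) is flagged poorly constrained rather than rejected.

Dissociation chases follow f(t) = (f0 − bg)·exp(−koff·t) + bg with the
background bg measured in a full-competition control lane and held fixed
(not fitted). The censoring rule dominates: if the complexed fraction is at
or below background at the first sampling time t1, no fit is attempted and
the result is the upper bound t½ ≤ t1 with koff absent. A more than 2-fold
rise between consecutive points (beyond a 0.05 absolute guard against
near-zero noise) is a data-quality error. t½ = ln 2/koff.

Group comparisons of replicate Kd values use a one-way fixed-effects ANOVA
(≥ 2 groups) or a two-sample equal-variance t test (exactly 2 groups;
Welch's variant by flag). p-values are reported raw; no multiple-testing
correction is applied and the report says so.

The active fraction of a protein preparation is bound-complex/total-protein
from a stoichiometric-binding EMSA (DNA in molar excess, 1:1 stoichiometry
assumed); ratios above 1 are clipped to 1 with a warning flag.

## Footprint quantification

Inputs are already-integrated per-base lane intensities (one profile per
strand; strands never merged). The complexed lane is rescaled so its summed
intensity over a reference base set matches the free lane; the reference
defaults to all bases (adequate when most of the lane is unaffected) and can
be restricted to known-unreactive bases. Per base,
percent_change = 100·(I_complex − I_free)/I_free; classification uses a
symmetric threshold, default 20%, recorded in the report. Bases with zero
free-lane intensity are flagged unquantifiable, never silently dropped.
Replicate gels (≥ 2 required) are combined by averaging percent changes per
base and re-classifying the mean. Reports are invariant to rescaling either
input lane by any positive constant.

## Synthetic data

The generators emulate the experimental designs at desk scale and define the
default study conditions:

- Titration: 12 protein concentrations from 0.1 to 1.3 μM, 20 nM DNA,
  ligation-state fractions from the binding polynomial, Dirichlet noise with
  concentration α (default in the CLI: 300, giving per-fraction SDs of
  ~0.01–0.03, the scale of careful gel densitometry; α = 0 is noiseless).
  Dirichlet noise respects the simplex constraint that independent Gaussians
  would violate; its mean is the true fraction vector.
- Single-site curves: grid 0.5–50 μM, additive Gaussian noise on y clipped
  to [0, 1] (default σ 0.03).
- SPR: injection series 0.1, 0.25, 0.5, 0.75, 1 μM, Gaussian noise on Req
  (default σ 1 RU on Rmax 100).
- Chase: exponential decay over a configurable time grid with a 5%
  background floor.
- Footprint: free-lane intensities log-normal (σ_log 0.25) around a baseline,
  complexed = free × per-base protection factor × (1 + Gaussian noise).

Every generator is seeded and bit-reproducible; noiseless mode reproduces the
forward model exactly. What the generators do not emulate: gel smearing and
band overlap, lane-to-lane loading drift, SPR drift/bulk effects, sequencing
gel compression. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated noise models, not robustness to those
instrument artefacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the experimental scale
(12–15-point grids, 1–5 replicates, 100–500 bootstrap resamples, 20–50
seeded repetitions for calibration studies), which keeps a full run in the
low minutes on one CPU while leaving Monte Carlo margins comfortably wider
than the tested tolerances. Bootstrap refits warm-start at the full-data
optimum (single start), standard practice that leaves the full-data estimator
untouched. All tolerances asserted in tests are stated inline; exact
identities are checked to 1e-12, noiseless fits to 1e-6 relative, stochastic
recoveries at the simulation-appropriate 5–10%.
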