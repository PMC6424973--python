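# Methods

## Kinetic model

Both schemes are networks of elementary mass-action steps over enzyme-
and substrate-derived species; halide, FAD, NADPH and the flavin
reductase/glucose-dehydrogenase regeneration system are in large excess
or continuously recycled in the assay and are not state variables.

**Sequential** (symmetric substrates, one mono intermediate; 6 species,
6 reactions):

    E + S  ⇌(ka1, kd1)  ES   →(kcat1)  E + P1
    E + P1 ⇌(ka2, kd2)  EP1  →(kcat2)  E + P2

The mono-halogenated product is released and rebinds as a free species.
A literal reading of some published scheme notations would have the
second substrate-binding event occur on an enzyme–product complex
("EP1 + S ⇌ EP1·S"), but that variant cannot produce the free mono
intermediate that HPLC observes and quantifies, and it is inconsistent
with defining a second-cycle K_m as (k_d,2 + k_cat,2)/k_a,2; the
free-intermediate form is therefore the implemented mechanism.

**Branched** (asymmetric substrates, two distinguishable mono products;
8 species, 10 reactions): a single ES complex partitions between two
catalytic channels,

    E + S   ⇌(ka1, kd1)   ES    →(kcat1a)  E + P1a
                          ES    →(kcat1b)  E + P1b
    E + P1x ⇌(ka2x, kd2x) EP1x  →(kcat2x)  E + P2      (x = a, b)

with both branches converging on the same di-halogenated product. The
shared complex makes the early-time partition of mono products exactly
kcat1a : kcat1b and implies a single first-cycle Michaelis constant,

    K_m,1 = (kd1 + kcat1a + kcat1b) / ka1,

consistent with identical reported per-branch K_m values for branched
reactions. An alternative topology with two separate first-cycle
complexes would allow distinct per-branch K_m but breaks the exact
partition ratio and doubles the binding flux; it is not implemented.

K_m for a single-channel cycle is (k_d + k_cat)/k_a. Units are fixed
package-wide: time in min, concentrations in µM, so k_a is µM⁻¹ min⁻¹
and catalytic efficiency k_cat/K_m is min⁻¹ µM⁻¹.

### The association rate is an assumption

Species fractions sampled on a minutes-scale grid contain no information
about the sub-second binding transient, so k_a is not identifiable and
is fixed (default 100 µM⁻¹ min⁻¹, configurable); schemes are
instantiated from macroscopic (k_cat, K_m) via k_d = k_a·K_m − k_cat.
The fixed k_a must exceed every step's k_cat/K_m or the implied k_d
would be negative; the conversion raises a clear error in that case.

## Simulation and the fraction observable

The mass-action ODE system is integrated with LSODA (rtol 1e-8, atol
1e-9 µM); reported K_m values span 0.076–1300 µM, so implied k_d values
span five orders of magnitude and the system is stiff. Enzyme totals
and substrate-moiety totals are conserved to better than 1e-6 relative
along every trajectory (tested), and an independent fixed-step RK4
integration at 1e-3 min agrees to < 1e-4 µM on non-stiff test schemes.

The observable is the percent of substrate-derived material per class
(S, P1 or P1a/P1b, P2). Enzyme-bound cargo counts toward its class —
the quench/extraction step of the assay releases bound material before
quantification — and at the assay's enzyme/substrate ratio (6/500 µM)
the distinction is at most 1.2 percentage points anyway. Conversion at
time t is 100 minus the substrate fraction, interpolated linearly
between computed grid points and never extrapolated.

## Synthetic data generator

The generator reproduces the optimized assay design: substrate 500 µM
(250 µM for iodination), enzyme 6 µM, quench grid 0, 5, 15, 30, 60,
120, 240, 360 min (with 720 min added for slow reactions; the
iodination grid is 0–480 min), duplicate reactions. Noise is additive
Gaussian on the percent fractions — the measured quantity — with
default sd 2 percentage points, clipped to [0, 100] and renormalized to
sum 100. The true replicate variance of chromatographic fractions is
rarely reported; 2 points is a stand-in chosen to yield the ~4–25%
relative standard errors typical of such fits, and it is configurable.
Draws use one counter-based generator per (seed, replicate, time,
class), so extending the design never perturbs earlier draws and every
dataset is bit-reproducible from its seed.

What the generator does *not* emulate: chromatographic peak shapes,
substrate/product degradation (some phloroglucinol-like substrates are
unstable under assay conditions), enzyme inactivation (iodide causes
gradual precipitation, which is why iodination kinetics are not a
recovery target), and correlated integration errors between co-eluting
peaks. Recovery tests passing on this generator demonstrate that the
estimator recovers parameters from data of the stated design and noise
level — not that real chromatograms are this well behaved.

## Global fit

All classes, time points and replicates enter one unweighted
least-squares objective in percent units (all species are on the same
scale; weighting is configurable in principle but defaults to none).
Free parameters are log10(k_cat) and log10(K_m) per step — positive by
construction — optimized with a trust-region reflective least-squares
solver under box bounds (k_cat ∈ [1e-4, 1e3] min⁻¹, K_m ∈ [1e-3, 1e4]
µM). The finite-difference step for the Jacobian is 1e-4 in log10
space; smaller steps fall below the ODE integrator's noise floor.
Infeasible trial points (implied k_d < 0) are clipped to k_d = 0 and
penalized through a constant-length penalty residual.

Initial guesses are data-driven: k_cat from the steepest observed
formation slope of the corresponding product class divided by E₀
(zero-order regime), K_m from a 1-D log-spaced grid scan (1e-2–1e3 µM)
at the k_cat guess with ties broken toward the smaller K_m. Five
seeded multi-starts (log-normal perturbations, sd 0.3 decades) guard
against local minima; the best objective wins.

Standard errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹ at the
optimum in log10 space, mapped to linear units by the delta method
(se(x) = x·ln10·se(log10 x)); efficiencies k_cat/K_m use the full
covariance (var(log10 eff) = var_kcat + var_Km − 2 cov). A JᵀJ
condition number above 1e12 is treated as singular: standard errors are
reported as undefined together with an identifiability warning, never
silently. Non-convergence is flagged in the result, not raised.

### Identifiability

Two regimes deserve explicit caution, and the fitter reports rather
than masks both:

* **K_m ≪ E₀** (e.g. first-cycle K_m 0.076 µM against 6 µM enzyme): the
  reaction is saturated over essentially the whole course and K_m is
  only weakly constrained; its standard error is large relative to
  k_cat's, which remains tightly determined by the zero-order slopes.
* **Tight-binding intermediate** (mono-product K_m well below substrate
  K_m, as for 3,5-dihydroxybenzyl alcohol: 0.44 vs 8.4 µM): the
  intermediate outcompetes substrate for the enzyme, placing k_cat,1
  and K_m,1 on a ridge. At the default noise level the asymptotic
  relative uncertainty of k_cat,1 in that regime is ~55%, so recovery
  of that one parameter to tight tolerances is not information-
  theoretically guaranteed by the duplicate design; k_cat,2 stays well
  determined (~9%). For branched fits at this noise the second-cycle
  (k_cat, K_m) pairs are likewise only jointly identified (their ratio,
  the efficiency scale, is what the data constrain); the first-cycle
  branch turnovers recover to a few percent.

## Product identification

Atomic monoisotopic masses and isotope abundances are pinned constants
from the IUPAC/CIAAW 2021 tables (Prohaska et al., Pure Appl. Chem. 94
(2022) 573). Adducts are [M−H]⁻ and [M+H]⁺ with the electron-corrected
proton mass 1.007276 Da.

Enumeration generates every multiset of 1–2 halides from the pool (the
enzyme's C-terminal region sterically excludes a third halogen;
trihalogenation is never observed). Fluoride is accepted in pools but
never productive. Substrate-specific dead ends — e.g. bromination that
stops at the mono product, or hetero-pairs never observed — are
supplied as data (per-halide caps and forbidden combinations), not
derived: no mechanism for them is known.

Isotope envelopes convolve the ³⁵Cl/³⁷Cl (75.76/24.24) and ⁷⁹Br/⁸¹Br
(50.69/49.31) binomials on their exact ~1.997 Da spacings; iodine is
monoisotopic. The optional full mode folds in ¹³C. Peaks within 0.01 Da
merge with abundance-weighted mean shift; the result is normalized to
base peak 100. The binomial route is verified in tests against a
brute-force enumeration of isotopologues.

XIC matching uses a **closed** interval [m − tol, m + tol] (the
instrument software writes "±"), robust to floating-point rounding at
exactly the boundary, and never assigns candidates whose adduct falls
outside the 80–600 m/z instrument window. Ambiguous matches are all
reported, unresolved.

The regiochemistry engine works on an abstract six-position substituent
map — sufficient for every single-ring case with assigned structures;
fused or second rings are out of scope. Rules: nitro-substituted rings
are never halogenated; candidate positions are ring hydrogens ortho to
at least one activating group (OH/NH₂), scored by the number of such
neighbours; positions *between* two activating groups are excluded
whenever a non-between candidate exists (phloroglucinol-like rings have
only between positions, so the exclusion cannot apply and dichlorination
proceeds); a methyl or styrenyl group meta to two hydroxyls re-admits
the between position with top priority. The best-scoring n positions
are returned with ties broken toward lower locants, and
symmetry-equivalent position sets are collapsed to their lowest-locant
representative via the ring's substituent-preserving automorphisms.

## Degenerate inputs and numerical conventions

* Rate constants must be finite and non-negative; k_a must be positive
  for any active cycle; violations name the offending parameter.
* Trajectories clip sub-atol negative solver noise to zero; the first
  row is the initial condition exactly.
* CSV fraction sums within 100 ± 5 are renormalized with a warning
  (chromatographic integration rarely closes exactly); anything further
  off is rejected with the offending replicate/time named. Duplicate
  (replicate, time, class) rows and non-numeric fields are rejected
  with line numbers.
* All randomness (noise, multi-start) flows from explicit integer
  seeds; there is no hidden global state.

## Problem sizes

Default test and acceptance runs fit 2 replicates × 8–9 quench times ×
3–4 classes (48–72 observations) per reaction — the size of the real
assay design. The bootstrap comparison of standard errors uses 30
parametric draws warm-started at the truth, and the Monte-Carlo check
of delta-method propagation uses 1e5 covariance draws; both are
oracle-scale choices, adequate for the factor-2 and 5% tolerances they
support.

## Known limitations

* Topology (sequential vs branched) is an input, chosen as an
  experimentalist would from the observed number of mono-product peaks;
  no information-criterion model selection is provided.
* Iodination kinetics are generated but never fitted as a recovery
  target (enzyme precipitates in iodide; no reference constants exist).
* The noise model is uncorrelated across classes before
  renormalization; real peak-area errors of co-eluting species are not.
* The rule engine predicts position *sets*, not reaction order between
  the two halogenation events.
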