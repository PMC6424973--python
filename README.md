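# halokin

Kinetics and product identification for two-cycle enzymatic halogenation.

FAD-dependent halogenases such as PltM install up to two halogens (Cl, Br
or I) on phenolic substrates in two successive catalytic cycles: the free
enzyme binds the substrate, halogenates it once and releases the
mono-halogenated intermediate, then rebinds that intermediate and
halogenates it a second time. `halokin` provides the computations that
turn HPLC/LC-MS time-course measurements of such reactions into kinetic
constants and product assignments:

* **Mass-action models** of the sequential scheme

  E + S ⇌(k_a,1, k_d,1) ES →(k_cat,1) E + P₁,  E + P₁ ⇌(k_a,2, k_d,2) EP₁ →(k_cat,2) E + P₂

  and of the branched scheme for asymmetric substrates, where a single ES
  complex partitions between two catalytic channels producing two
  distinguishable mono products (P₁a, P₁b) that both converge on the same
  di-halogenated product. K_m per step is defined microscopically as
  (k_d + k_cat)/k_a. Units package-wide: min, µM.
* **Stiff ODE simulation** of species-fraction progress curves — the
  percent of substrate-derived material in each class (S, P₁, P₂) at each
  quench time, the observable an HPLC assay reports.
* **Global nonlinear regression** of all species, time points and
  replicates at once, in log₁₀(k_cat, K_m) space with the association
  rate fixed (progress-curve fractions do not determine it), returning
  asymptotic standard errors and delta-method catalytic efficiencies
  k_cat/K_m.
* **Synthetic time-course generation** at the optimized assay design
  (substrate 0.5 mM, enzyme 6 µM, quench points 0–360/720 min, duplicate
  reactions) with additive noise on the measured fractions.
* **Product identification**: combinatorial enumeration of mono/di
  halogenation states under a halide pool, exact monoisotopic masses and
  [M−H]⁻/[M+H]⁺ adduct m/z, chlorine/bromine isotope envelopes, XIC
  tolerance-window matching, and a regiochemistry rule engine
  (halogenation ortho to OH/NH₂ but not between two of them, with the
  methyl/styrenyl meta exception).

## Worked example

```python
import halokin as hk

# sequential scheme at the published resorcinol-chlorination constants
scheme = hk.reference.reference_scheme("3", "Cl")
traj = hk.integrate(scheme, hk.initial_state(scheme, 500.0, 6.0),
                    [0, 30, 120, 360, 720])
print(hk.species_fractions(traj).round(2).to_string(index=False))
```

```
 time_min      S    P1     P2
      0.0 100.00  0.00   0.00
     30.0  39.07 57.13   3.80
    120.0   0.48 59.25  40.28
    360.0   0.00  0.00 100.00
    720.0   0.00  0.00 100.00
```

Substrate is half-consumed by ~25 min, the mono-chloro intermediate
peaks near one hour, and conversion to the dichloro product is complete
well before 720 min (overnight). Refitting noisy duplicates of this
experiment recovers the constants that generated them:

```python
data = hk.generate_timecourses(scheme, hk.default_design("chlorination"),
                               hk.NoiseModel(sd=2.0, seed=0))
result = hk.fit_global(data, hk.FitSpec(seed=1))
print(result.report().round(4).to_string(index=False))
```

```
step  kcat_per_min  kcat_se  km_uM  km_se  efficiency_per_min_per_uM  efficiency_se
   1        2.3532   0.0667 3.3916  4.102                     0.6938         0.8425
   2        0.4034   0.0165 4.8112  6.056                     0.0838         0.1022
```

Both turnover numbers come back within a few percent of the generating
values (2.3 and 0.40 min⁻¹) with ~3–4% standard errors. The K_m
estimates carry standard errors larger than the estimates themselves:
with K_m far below the 6 µM enzyme concentration the reaction is
substrate-saturated over nearly the whole course, so the fractions
barely constrain K_m — the fit reports that honestly instead of hiding
it.

Product identification for the same reaction:

```python
sub = hk.reference.SUBSTRATES["3"]              # resorcinol
hk.predict_positions(sub, 2)                    # {frozenset({4, 6})}
p = hk.HalogenationProduct(sub, (("Cl", 2),))
hk.adduct_mz(p, "negative").mz                  # 176.9516
hk.isotope_pattern(p).peaks                     # 100 : 64.0 : 10.2 at M, M+2, M+4
```

The rules place both chlorines ortho to the hydroxyls (positions 4 and
6, matching the NMR-assigned 4,6-dichlororesorcinol), and the two-Cl
isotope triplet identifies the halogen count in the mass spectrum.

A `halokin` command-line tool wraps the same functionality
(`simulate`, `make-fixtures`, `fit`, `enumerate`, `predict-sites`,
`isotopes`); see `halokin --help`.

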