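# tyrspec

Analysis toolkit for following peptide self-assembly with intrinsic tyrosine
fluorescence and minimalist conformational models, built around the 33-mer
gliadin peptide system (a proline/glutamine-rich, PPII-structured amphiphile
that assembles from nanomolar surfactant-like aggregates up to micromolar
thin-plate superstructures).  It is aimed at spectroscopists and biophysicists
who want the complete measurement-to-parameter chain — including the synthetic
data needed to validate it — as tested, scriptable Python.

Four measurement channels are covered:

* **Steady-state anisotropy** — `r = (Ivv − G·Ivh) / (Ivv + 2·G·Ivh)` with
  `G = Ihv/Ihh`, and a one-to-one binding isotherm
  `r(C) = r_free + (r_bound − r_free)·C/(K_D + C)` fitted by multi-start
  least squares to estimate the apparent dissociation constant K_D.
* **TCSPC lifetime analysis** — decays modelled as
  `I(t) = IRF(t) ⊛ Σ_i A_i exp(−t/τ_i)` and fitted by iterative-reconvolution
  NLLS (lifetimes τ_i, fractional intensities `f_i = A_iτ_i/Σ_jA_jτ_j`,
  reduced χ²), plus a maximum-entropy inversion recovering a lifetime
  distribution g(log τ) by maximizing `Q = S − λC` (Shannon–Jaynes entropy S
  against a flat prior, Poisson χ² C, discrepancy-principle λ), with band
  extraction and the normalized "fuzzy" entropy
  `H = −(1/log N) Σ w'_i log w'_i ∈ [0, 1]` as a micro-heterogeneity index.
* **Surface tension** — two-segment breakpoint regression of γ versus
  log10(concentration) to locate the critical aggregation concentration (CAC).
* **Rotamer/SASA analysis** — χ1 dihedral classification into g+/t/g− states
  (thirds of the 0–360° circle), pooled occupancy percentages, and
  kernel-density mode analysis of solvent-accessible surface area samples.

Because no raw data are deposited for this system, `tyrspec.simulate`
generates every input class (photon-count decays with Poisson noise,
titrations, dihedral and SASA ensembles) from explicit parameter sets and
seeds; all fitting code is validated by parameter recovery against the
published values collected in `tyrspec.reference`.

## Worked example

Simulate a three-lifetime decay at the published 100 μM MEM band parameters
(τ = 3.38/0.90/0.02 ns), then fit it both ways:

```
$ tyrspec simulate --lifetimes 3.38,0.90,0.02 --fractions 0.129,0.845,0.026 \
      --noise poisson --seed 7 --out demo
$ tyrspec memfit demo/decay.csv demo/irf.csv --out demo/mem.json
bands: 0.94 ns (98.5%), 3.71 ns (1.3%); H = 0.859; chi2 = 1.006
```

The dominant lifetime band sits within one grid point of the generating
0.90 ns lifetime; band percentages are shares of the distribution's amplitude
mass, so the short-lifetime components dominate even though the 0.90 ns
component carries most of the emitted intensity.  H near 1 reflects how much
the entropy-regularized solution spreads at the χ² ≈ 1 stopping point.  The
NLLS route on the published 100 μM NLLS parameters (τ = 4.80/1.08/0.02 ns):

```
$ tyrspec simulate --lifetimes 4.80,1.08,0.02 --fractions 0.21,0.27,0.52 \
      --noise poisson --seed 7 --out demo2
$ tyrspec decayfit demo2/decay.csv demo2/irf.csv --components 3
lifetimes (ns): 4.895, 1.060, 0.022; reduced chi2 = 1.024
```

Titration fits work the same way from CSV (`tyrspec anisofit`,
`tyrspec cacfit`), `tyrspec rotamers` / `tyrspec sasamodes` analyze dihedral
and SASA tables, and `tyrspec run-series` drives a whole
simulate → NLLS → MEM concentration series from one YAML config.

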