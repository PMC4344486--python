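# sgdyn — stress-granule dynamics and stress-phase mRNA decay

`sgdyn` is a Python toolkit for the quantitative assays used to ask whether
cytoplasmic stress granules (SGs) are required for mRNA stabilization during
cellular stress:

* **SG quantification in microscopy images** — spot detection inside labelled
  cells, per-cell SG-area fraction and SG-positive calls, and population
  summaries over stress time courses (e.g. control vs TIA1/TIAR/G3BP1 triple
  knockdown).
* **Protein exchange kinetics at SGs** — normalization and mono-exponential
  fitting of FRAP and photo-conversion traces, half-lives and mobile/immobile
  fractions, and classification of proteins into *transient movers* (assembly
  factors such as G3BP1 and TIA proteins, half-life of a few seconds, no
  appreciable immobile pool) vs *stable cargo* (RBPs such as IGF2BP1/YB1/HUR,
  half-life 15–20 s, immobile fraction 60–70%).
* **mRNA decay under transcription blockade (actinomycin D)** — ΔCt/ΔΔCt
  relative quantification from qPCR Ct tables with reference-gene
  cross-normalization, and array-style bulk analysis: detection-p filtering,
  background correction, quantile normalization, per-transcript linear decay
  slopes, between-condition slope correlation, and 2-fold log2-ratio scatter
  classification.
* **Synthetic data with known ground truth** for all of the above, so every
  stage is testable end to end without any external data.

## Models

**Exchange kinetics.** Molecule traffic in and out of a granule follows
first-order kinetics, `dM_in/dt = k1·M_in` and `dM_out/dt = k2·M_out`. At
steady state the fluxes balance, `k1 = k2 = k`, so inbound and outbound
half-lives coincide (`t_in = t_out = ln2/k`) and the region's fluorescence
relaxes mono-exponentially. FRAP recovery is fitted as
`F(t) = F_inf − (F_inf − F_bleach)·e^{−kt}` with mobile fraction
`(F_inf − F_bleach)/(F_pre − F_bleach)`; photo-converted (red) signal as
`R(t) = R_plat + (R0 − R_plat)·e^{−kt}` with immobile fraction `R_plat/R0`
and the 30-s retained fraction `R(30)/R0`.

**mRNA decay.** Each transcript decays exponentially, so qPCR cycle values
rise linearly, `Ct(t) = Ct(0) + log2(e)·λ·t`, and `2^−ΔCt` recovers the decay
curve; ΔΔCt divides by a non-decaying reference gene (e.g. RPLP0) and is
exactly invariant to per-sample Ct offsets. Array intensities are regressed
on time (non-log, ordinary least squares) to give a per-transcript decay
slope; Pearson correlation of the slope vectors of two conditions measures
how similar bulk decay is.

## Worked example

```python
from sgdyn.synthetic import preset_truth, gen_frap_trace
from sgdyn.kinetics import fit_recovery, normalize_trace, classify_dynamics

trace = gen_frap_trace(preset_truth("stable", noise_sd=0.02, seed=7))
fit = fit_recovery(normalize_trace(trace))
print(f"t_half = {fit.t_half:.2f} s, immobile = {fit.immobile_fraction:.2f}, "
      f"class = {classify_dynamics(fit).label}")
```

prints

```
t_half = 14.48 s, immobile = 0.67, class = stable
```

a single noisy simulated FRAP trace of the stable-cargo preset (true half-life
17 s, immobile fraction 0.65): the fitted half-life and immobile fraction are
within the scatter expected for one 30-s recovery, and the protein is
classified as stable cargo.

The full demo pipeline runs from the command line:

```bash
sgdyn run --seed 11 --out demo_run
sgdyn report demo_run        # writes demo_run/report.md
```

which simulates and analyses all four data kinds (fits table, SG time-course
summary, qPCR abundances and contrasts, decay slopes with correlation, and
fold-change class counts), reproducibly: the same seed gives byte-identical
outputs. `sgdyn quantify`, `fit-frap`, `fit-conversion`, `qpcr` and `array`
run the individual stages on user-supplied TIFF/CSV files.

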