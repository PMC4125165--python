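# eelvision

Visual-pigment spectroscopy and opsin analysis for anguillid eel
retinas: template-based λ_max estimation from microspectrophotometry
(MSP) absorbance traces, efficiency-corrected qPCR opsin expression,
and spectral-tuning-site annotation in bovine rhodopsin numbering —
plus seeded synthetic-data generators with known ground truth for
validating every stage.

Freshwater eels retune their rod vision as they migrate from turbid
estuaries (glass-eel stage) into clear upstream rivers (yellow-eel
stage).  Three mechanisms are in play and each maps to a module here:

1. **Photoreceptor spectral sensitivity** (`eelvision.templates`,
   `eelvision.msp`).  A visual pigment's absorbance spectrum is
   described by a chromophore-specific template parameterised only by
   its absorbance peak λ_max.  The α-band is

   S(x) = 1 / (e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D),  x = λ_max/λ,

   with a Gaussian β-band added at short wavelengths; A1
   (11-cis-retinal) and A2 (3,4-didehydroretinal) pigments use
   different constants, A2 being broader and red-shifted.  Each
   measured cell's λ_max is estimated by inverting every usable point
   on the long-wavelength limb to its implied λ_max; the mean of these
   per-point estimates is the cell's λ_max, their standard deviation
   is the fit quality in nm, and fits with SD ≥ 7.5 nm are discarded.
   The family (A1 vs A2) with the lower SD classifies the chromophore.
2. **Opsin gene expression** (`eelvision.qpcr`).  With amplification
   efficiency E and threshold cycle Ct, initial template abundance is
   ∝ (1+E)^(−Ct); expression is reported relative to housekeeping
   genes, T_i/T_h = (1+E_h)^{Ct_h}/(1+E_i)^{Ct_i}, and as a fraction
   of total opsin expression, T_i/T_all.
3. **Protein-level spectral tuning** (`eelvision.tuning`).  Opsin
   sequences are aligned to bovine rhodopsin to read off residues at
   registered tuning sites (Rh1: 83, 122, 207, 211, 265, 292, 295),
   call substitutions against the class consensus, and annotate known
   shifts (e.g. S292A → 7–16 nm red shift, D83N → blue shift).

## Worked example

The default configuration simulates the canonical five populations
(glass-eel rods at 493 nm n=60; cultured yellow-eel rods 489 nm n=40
and green cones 508 nm n=9; wild yellow-eel rods 489 nm n=44 and cones
517 nm n=7; all A1, peak-relative noise SD 0.02) and runs the full
pipeline:

```sh
$ eelvision run-all --seed 7 --out demo/
glass/rod: 492.7±0.3 nm (n=60, N=3)
cultured_yellow/rod: 488.8±0.3 nm (n=40, N=4)
cultured_yellow/cone: 507.8±0.2 nm (n=9, N=4)
wild_yellow/rod: 488.7±0.3 nm (n=44, N=2)
wild_yellow/cone: 516.8±0.3 nm (n=7, N=2)
```

Every stage mean lands within 0.4 nm of its generating λ_max, and the
glass-vs-yellow rod difference reproduces the ~4 nm blue shift the
pipeline is designed to resolve.  (The ±SD here reflects measurement
noise only — the generator draws every cell of a population from one
true λ_max, so these SDs are much smaller than the cell-to-cell spread
of a real retina.)  `demo/` then contains `fits.tsv` (per-cell λ_max,
chromophore, quality SD, accept flag), `stage_summary.tsv`,
`stage_comparisons.tsv` (pairwise t-tests; glass vs cultured rods:
t = 62.0, p ≈ 2e−80 at these noise-only SDs), `chromophore_ratios.tsv`,
`lambda_max_histogram.tsv` and `opsin_expression.tsv` (Rh1f proportion
0.936 recovered exactly from the noise-free default Ct table).

The same steps are available piecewise (`simulate`, `fit-spectra`,
`summarize`, `compare-stages`, `chromophore-ratio`, `histogram`,
`qpcr`, `tuning-sites`) over documented CSV/TSV/FASTA dialects, and as
library calls:

```python
import eelvision as ev

spectra = ev.simulate_spectra(ev.SpectrumSimConfig(true_lambda_max=493, seed=1))
fit = ev.fit_spectrum(spectra[0])        # λ_max ≈ 493, chromophore "A1"

seq, _ = ev.synthesize_opsin("Rh1", {292: "A"})
nmap = ev.build_numbering_map(seq)
report = ev.annotate_shifts(ev.extract_sites(nmap, seq, "Rh1"))
report.substitutions                     # ("S292A",) → red, 7–16 nm
```

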