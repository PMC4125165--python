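# Methods

## Visual-pigment templates

The absorbance templates are the standard A1/A2 forms: an α-band
S(x) = 1/(exp[A(a−x)] + exp[B(b−x)] + exp[C(c−x)] + D) with
x = λ_max/λ, plus a Gaussian β-band
S_β(λ) = A_β·exp[−((λ−λ_mβ)/b_β)²] whose position and width scale
linearly with λ_max.  All constants live in
`src/eelvision/data/govardovskii_constants.txt` (one key/value file,
no literals scattered in code):

* A1 α-band: A=69.7, B=28, C=−14.9, D=0.674, b=0.922, c=1.104,
  a = 0.8795 + 0.0459·exp[−(λ_max−300)²/11940];
  β-band A_β=0.26, λ_mβ = 189 + 0.315·λ_max, b_β = −40.5 + 0.195·λ_max.
* A2 α-band: A = 62.7 + 1.834·exp[(λ_max−625)/54.2], B=20.85,
  C=−10.37, D=0.5343, b=0.9101, c=1.1157,
  a = 0.875 + 0.0268·exp[(λ_max−665)/40.7];
  β-band A_β=0.37, λ_mβ = 216.7 + 0.287·λ_max, b_β = 150.5 + 0.0064·λ_max.

Internal-consistency checks are part of the test suite: the α-band
evaluates to ≈1 at λ = λ_max across the supported range for both
families, and the A2 FWHM exceeds the A1 FWHM at equal λ_max.

Curves are peak-normalised against a dense 0.1 nm internal grid, so
`max(evaluate_template) = 1` holds by construction.  One consequence
worth knowing: the A2 β-band is large (amplitude 0.37) and very broad
(b_β ≈ 150 nm), so for A2 pigments the argmax of the *summed* α+β
curve sits up to ~5 nm blue of the nominal λ_max at the short end of
the supported range.  For A1 the β-band is too small to move the peak
(argmax stays within 2 nm of λ_max).  Long-limb fitting is unaffected
because the limb lies far from the β-band.  A config switch
(`include_beta=False`) fits the α-band alone; the default includes the
β-band since measured outer-segment spectra contain it.

Supported λ_max range is 400–650 nm — brackets every rod/cone value
the pipeline is meant for with margin.  Long-limb inversion uses
Brent's method on λ_max with tolerance 0.05 nm; the template value at
a fixed limb wavelength is monotone in λ_max there, so the root is
unique.  Points whose absorbance no λ_max in range can reproduce raise
a typed inversion error (and are silently skipped during whole-limb
fitting).

## MSP pipeline

**Preprocessing.**  Baseline = mean absorbance over the
long-wavelength tail (top 5 % of the wavelength span, where the
pigment no longer absorbs); subtracted, optionally smoothed
(moving average, default 5 points), then scaled so the trace maximum
is 1.  Degenerate traces (no positive peak, span < 100 nm) raise.
Processed spectra carry a flag and pass through unchanged, which makes
`preprocess` idempotent by construction — a second moving-average pass
would otherwise narrow the curve slightly.

**Fitting.**  The per-cell λ_max estimate operationalises whole-limb
template fitting: each long-limb point with normalised absorbance in
the fitting window (default 0.2–0.9; below 0.2 the tail is
noise-dominated, above 0.9 the peak is flat and uninformative) is
inverted to a λ_max estimate; the mean is the cell's λ_max and the
SD, in nm, is the quality score the validity filter applies
(accept when SD < 7.5 nm).  Both template families are fitted and the
lower-SD family classifies the chromophore; exact ties resolve to A1,
the commoner chromophore in the stages this pipeline models.  Fewer
than 8 usable limb points yields a rejected fit carrying a reason
string rather than an exception, so a batch run never dies on one bad
cell.  An exhaustive grid-search least-squares fitter over a 0.1 nm
λ_max grid (`grid_search_fit`) is kept as an internal oracle; on
noiseless spectra the two estimators agree to 0.5 nm.

**Aggregation.**  Only accepted fits aggregate.  Cell-level estimates
are pooled across specimens within a stage (stage n counts cells, with
the specimen count reported alongside); stage × cell-type groups with
zero accepted cells are flagged "not detectable" rather than dropped.
Stage comparisons use the two-sample t-test computed from summary
statistics — Student's equal-variance form by default, Welch by flag.
Two degenerate groups with zero SD and equal means return p = 1 by
convention.  Histograms are left-closed/right-open, anchored at
400 nm, bin width 5 nm by default.

## qPCR quantification

Efficiency E ∈ (0, 1] is the per-cycle fractional gain, so one cycle
multiplies product by 1+E and initial abundance is ∝ (1+E)^(−Ct).
Relative expression: (1+E_h)^{Ct_h}/(1+E_i)^{Ct_i}.  Proportional
expression: (1+E_i)^{−Ct_i} normalised over the non-housekeeping genes
of the sample.  The efficiency-correction convention is isolated in
one helper so the alternative reading — E itself as the amplification
factor, E^Ct — is a single `amplification_base="e"` switch.
Replicate Ct values are averaged per gene × sample before any
computation.  Two housekeeping genes (cytochrome b, ARP) are supported;
their Ct values (and efficiencies) are averaged for normalisation,
which for equal efficiencies equals geometric-mean normalisation of
abundances.  Undetected genes (no Ct) report proportion 0 with a
`detected=False` flag.  Proportions sum to 1 to 1e−9 and are invariant
under a constant Ct shift at equal efficiencies.

## Tuning-site annotation

Residue coordinates follow the full-length bovine rhodopsin precursor
(348 aa, 1-based including the initiator Met), the convention of the
site-directed-mutagenesis literature; the reference sequence ships as
a FASTA fixture.  Queries are aligned globally (Biopython
`PairwiseAligner`, BLOSUM62, gap open −11 / extend −1, free terminal
gaps because opsin C-termini vary in length); aligned columns become a
strictly monotone query↔reference position map.  Opsins are highly
conserved, so results are insensitive to these parameters; an
alignment identity below 30 % sets a warning flag to catch
pathological inputs.

Site registries: Rh1 known sites 83, 122, 207, 211, 265, 292, 295
(consensus D, E, M, H, W, S, A); Rh2 97, 122, 207, 292 (T, E, M, S);
SWS2 94, 116, 118, 265, 292 (A, M, T, W, S).  Rh1 additionally carries
putative sites — the four retinal-pocket candidates 124, 189, 286, 290
and the eight interaction-divergent sites 112, 137, 189, 191, 193,
219, 255, 313 — which are reported but, having no consensus entry,
never generate substitution calls.  Consensus residues are registry
data, not computed from the input set: this keeps reporting
independent of input composition.  Shift rules: S292A red 7–16 nm,
A292S blue 7–15 nm, D83N blue (magnitude unspecified); substitutions
without a rule are annotated "no rule".

## Synthetic data

Generators are deterministic functions of (config, seed) and attach
their ground truth to every output.

* **Spectra**: trace = scale × template(λ_max) + linear baseline +
  i.i.d. Gaussian noise on the peak-normalised scale.  Defaults: grid
  350–750 nm at 1 nm, noise SD 0.02 — the simplest model that
  reproduces realistic per-cell quality SDs of a few nm under the
  validity filter.  Default population sizes and λ_max values follow
  the study conditions the pipeline models (glass rods 493 nm n=60,
  cultured rods 489 nm n=40, cones 508/517 nm n=9/7, wild rods 489 nm
  n=44).  What the generator does **not** emulate: cell-to-cell
  variation of true λ_max within a stage (every cell of a population
  shares one true value, so recovered stage SDs are measurement-only,
  ~0.3 nm, versus ~5 nm in real retinas), photobleaching, instrument
  drift, wavelength-dependent noise.  Passing recovery tests therefore
  demonstrates estimator correctness and calibration of the QC filter,
  not robustness to biological heterogeneity.
* **Mixtures**: exact counts from an A1 and an A2 population, order
  shuffled by seed; labels travel with each spectrum.
* **qPCR**: Ct values are derived by inverting the
  proportional-expression formula at the true proportions
  (Ct_i = C0 − log_{1+E} relative abundance, anchored at Ct 20 for the
  most abundant gene), plus optional replicate noise; at zero noise the
  pipeline inverts them exactly.  Zero-proportion genes are emitted as
  undetected.
* **Opsins**: sequences grow from a consensus scaffold (the bovine
  reference with class-consensus residues substituted at known sites),
  with residue assignments, deletions and insertions applied and the
  ground-truth position map returned, so extraction can be verified
  round-trip under indels.

## Problem sizes and numerics

Tests and the acceptance script run the pipeline at the study's own
sizes (60/40/9 spectra per population, 200-cell mixtures, 100-cell
recovery checks); a full run is tens of seconds on one CPU.  Stream
seeds are derived from one user seed by fixed offsets and kept below
2³¹.  Bisection tolerance 0.05 nm, template normalisation grid 0.1 nm,
fits reported to full double precision in TSV (`%.17g`).

## Known limitations

* Whole-limb inversion estimates carry a small (~0.3 nm at noise
  SD 0.02) blue bias because the noisy peak maximum used for
  normalisation is upward-biased, shrinking limb values; this is well
  inside the tolerances the pipeline targets.
* Chromophore classification relies on template-shape differences
  alone; heavily smoothed or truncated limbs reduce the A1/A2
  contrast.
* The t-test operates on summary statistics, matching how stage tables
  are published, and therefore inherits their pooled-cell (rather than
  per-specimen) error structure.
* No cone-class inference beyond a single green cone class;
  no bleaching-difference spectra; no instrument-artifact correction
  beyond baseline subtraction.
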