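# Methods

## The enrichment statistic

The central quantity is per-taxon **percentage enrichment** between a
paired unlabeled (¹²C) and labeled (¹³C) CsCl gradient. For gradient g and
heavy window W (a closed density interval), each taxon's 16S copy number
is the window sum of read proportion × fraction qPCR copies,

    N_g(t) = Σ_{f ∈ W} p_{t,f,g} · C_{f,g},

normalized to relative copy numbers r_g(t) = N_g(t) / Σ_u N_g(u) (this
cancels total-DNA differences between the two gradients), and

    enrichment(t) = 100 · (r₁₃(t) − r₁₂(t)) / r₁₂(t).

Assumptions worth stating explicitly:

* Because r sums to one within each gradient, enrichment is a *relative*
  statistic: one taxon's gain is other taxa's loss. In a two-taxon system
  enrichments cannot both be positive (tested as a property). Unlabeled
  taxa in a community with strong incorporators therefore show mildly
  negative enrichment even with no change in their biology.
* enrichment is invariant to any common rescaling of raw copies in either
  gradient; qPCR calibration offsets between runs cancel.
* r₁₂ = 0 makes the statistic undefined; such taxa carry a NaN marker and
  are excluded from threshold estimation rather than dropped or mapped to
  infinity.
* Class-level values are computed by summing genus read counts within each
  class *before* proportions, so the class statistic is the statistic of
  the pooled reads, not an average of genus statistics.

**Noise threshold.** From all strictly positive enrichment values the
package reports either the upper limit of the two-sided 95 % t-interval of
their mean (`ci_mean`) or their 97.5th percentile (`percentile`), together
with all intermediates (mean, half-width, n). Both are offered because the
mapping from a "noise" half-width to a flagging threshold is not uniquely
determined; neither is privileged. With few positive values (small
communities) the t-interval is extremely wide and flags nothing — the
honest small-sample behaviour; ranking by enrichment is then the
informative output. Flagging uses a strict `>` and an abundance floor
(default 0.1 % community-wide mean relative abundance).

**Heavy window.** The window is a required analysis choice. When not given
explicitly, the default rule normalizes both gradients ("ratio of
quantities", max = 1), interpolates the ¹²C ratios onto the ¹³C densities,
and takes the contiguous run of fractions where the ¹³C ratio exceeds the
¹²C ratio with the largest cumulative excess, ties toward the dense end.
Labeling shifts DNA denser, so the dominant excess run is the dense-side
bulge a practitioner would shade on the ratio-vs-density plot; scoring by
cumulative excess (rather than taking the densest run outright) keeps
single near-empty tail fractions, whose ratios flicker by noise, from
hijacking the window. Densities compare at 4-decimal precision with closed
endpoints, so boundary fractions are included deterministically.

## Gradient and chemistry conversions

* Refractive index → density: ρ = 10.8601 · RI − 13.4974 (linear CsCl
  calibration at 20 °C); slope and intercept are parameters, inputs outside
  RI ∈ [1.34, 1.42] are rejected.
* Density shift → incorporation: 100 · Δρ / Δρ_full with Δρ_full = 0.036
  g mL⁻¹, the buoyant-density increase of fully ¹³C-labeled DNA
  (configurable). Linear in Δρ; a 0.01 g mL⁻¹ shift ≈ 28 %.
* Peptide formulas are the residue-table sum minus one water per bond.
  SIM m/z uses nominal integer masses (C=12, H=1, N=14, O=16, S=32) plus 1
  for the proton plus 1 per ¹³C, because quadrupole SIM channels are
  integer m/z (monoisotopic mass is exposed separately). AVFA: C₂₀H₃₀N₄O₅,
  [M+H]⁺ 407/424 at 0/17 labels.

## Kinetics

Zero-order decay: k = −(OLS slope) of concentration vs. time. The fit uses
points up to and including the *first* observation below the quantitation
floor — that point anchors depletion; later bottomed-out points carry no
kinetic information and would bias k low. The floor defaults to 0.01 μM
but must be chosen **above the measurement noise** of the data at hand:
near-zero concentrations read as half-normal noise, and a floor below the
noise level lets depleted samples into the fit (the generator-recovery
test fits at 0.03 μM for its 0.01 μM noise for exactly this reason). With
sparse sampling the anchor can postdate the true zero-crossing, biasing k
slightly low; at the study's sampling times this bias is within ~8 %.
Replicates are fit separately and summarized. Rate groups are compared
with a Welch two-sample t-test (ratio of means reported); zero-variance
groups are reported as degenerate, not fatal.

## Nitrogen mass balance

Four pools of consumed peptide N at a reference time (default 24 h):

* hydrolysis = (Σ phenylalanine-bearing products, μM) / peptide consumed —
  each product molecule carries one F, and F uptake is slow on this
  timescale, so F-bearing species trace extracellular hydrolysis;
* remineralization = (ΔNH₄ treatment − ΔNH₄ control) / (consumed × 4 N),
  assuming negligible nitrification;
* biomass = Δcells × 20 fg C cell⁻¹ ÷ C/N ÷ 14 g mol⁻¹, as a fraction of
  consumed peptide N. **C/N = 4 is applied as a mass ratio** (carbon mass ÷
  4 → nitrogen mass): with the default constants this gives 0.118 μM N per
  3.3 × 10⁵ cells mL⁻¹ and reproduces the few-percent-to-~11 % biomass
  fractions typical at ~1 μM peptide N;
* residual DON = 1 − (sum of the above), always the closure term, never
  measured.

Fractions are reported unclipped: measurement noise legitimately produces
small negatives, which are flagged (as is over-closure beyond 1.05), not
truncated. Nominal atomic masses (N = 14, P = 31) match the constants'
precision. Phosphorus demand: Δcells × 0.2 pg dry mass × 1.3 % P ÷ 31,
in μM — 8.1 × 10⁴ and 9.0 × 10⁵ cells mL⁻¹ give 0.0068 and 0.0755 μM.

## Synthetic data generator

The generator emulates the study design so the pipeline is testable
without sequencing data. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_fractions | 30 | fractions per gradient |
| density range | 1.66–1.77 g mL⁻¹ | collected gradient span |
| GC → density | ρ = 1.660 + 0.098·GC | unlabeled band center |
| full_label_shift | 0.036 g mL⁻¹ | shift of 100 atom % ¹³C DNA |
| band_sigma | 0.006 g mL⁻¹ | Gaussian band spread |
| band_baseline | 0.05 | mass fraction smeared uniformly |
| qpcr_sigma | 0.15 | lognormal copy-number noise |
| reads_per_fraction | 5000 | multinomial sequencing depth |
| initial peptide | 0.35 μM | amendment (mid-range) |
| decay k | 0.014 / 0.0265 μM h⁻¹ | surface / bottom (range midpoints) |
| atom-fraction cap | 0.85 | 17/20 labeled substrate carbons |

Per taxon, DNA mass follows a Gaussian band at the GC-dependent center
plus atom_fraction × full_label_shift, renormalized over the gradient
(mass conservation), with `band_baseline` of its mass spread uniformly —
this emulates the diffusion, partial labeling and time-point pooling that
spread real SIP signal across the whole density range, and without it
taxa far from the window would have exactly zero heavy-window DNA, which
real gradients do not show. qPCR copies are column totals × lognormal
noise; reads are one multinomial draw per fraction. The ¹²C scenario is
the same community with atom fractions zeroed.

Incubation series: peptide declines linearly at the depth's k (clipped at
zero, *then* measurement noise is added and re-clipped — so depleted
samples read half-normal noise, as real instruments do); the killed
control stays flat; free amino acids and fragments follow a
produce-then-consume hump peaking near depletion (surface > bottom, F
dominant); ammonium rises sigmoidally after depletion; cells bloom
30–60 % and decline; duplicates share structure with independent noise.

Randomness: one integer seed; every draw comes from a named substream
(seed + CRC32 of a tag like `13C:surface/qpcr`), so identical seeds give
bit-identical outputs and the draw order is documented by the tags. The
per-fraction read draw is a single joint multinomial over taxa, so adding
a taxon necessarily changes that draw (per-taxon substreams cannot apply
there).

What the generator does **not** emulate: per-genome 16S copy-number
variation, PCR/primer bias, chimeras, gradient compression or
ethidium-bromide effects, within-taxon GC variance beyond the fixed band
spread. Passing tests therefore demonstrate the arithmetic and its
statistical behaviour under the assumed noise structure, not robustness
to those instrument- and biology-level artifacts.

## Numerical and design choices

* Tables are TSV with documented headers; floats are written at 17
  significant digits and parsed with round-trip precision, so
  write→read→write is byte-stable.
* All-zero read columns and all-zero gradients are flagged or rejected,
  never silently zero-filled.
* Analysis problem sizes (10 taxa × 30 fractions, 500-replicate recovery
  experiments, 50-seed end-to-end sweeps) were chosen so the whole suite
  and analysis run in seconds on one core while keeping Monte-Carlo
  standard errors well inside the asserted tolerances.

## Known limitations

* The heavy-window default is a reconstruction of a visual rule; analyses
  of real data should fix explicit bounds in config for comparability.
* The noise-threshold methods disagree when positive enrichments are few
  or skewed; report the intermediates, not just the flag.
* The floor-truncation kinetics rule is biased low when sampling is sparse
  relative to depletion; sample near the expected zero-crossing or raise
  the floor above noise.
* Percentage enrichment is compositional; it identifies *relative* label
  gain, not absolute growth, and taxa absent from the unlabeled heavy
  window are undefined rather than "infinitely enriched".
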