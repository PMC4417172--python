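# Methods

This note documents the models behind `pausekit`, the defaults and why
they hold, what the synthetic-data generators do and do not emulate, and
the numerical choices made where several designs were defensible.

## Coordinates and the scRNA length convention

Genomic intervals are 0-based half-open. TSS-relative offsets put the TSS
base at offset 0, positive downstream in the direction of transcription;
minus-strand genes are mirrored before any offset arithmetic, so "+34"
always means 34 nt downstream of the start site. A short capped RNA is
represented by its 5′- and 3′-end genomic coordinates, and its *length*
is defined as the absolute 5′→3′ end distance: a read initiating at the
TSS with its 3′ end at offset +34 has length 34 nt. This matches the
field convention that equates scRNA length with the pause position
downstream of the TSS (rather than an inclusive base count, which would
differ by one).

## scRNA model

Sense reads: 5′ end = true TSS + jitter (default pmf: 60% at 0, 15% at
±1, 5% at ±2 nt — an initiator-like, nearly single-nucleotide start),
3′ end = true TSS + pause offset (default: mass ⅓ each on +33/+34/+35
nt). A configurable fraction of reads is antisense (divergent
transcription): opposite strand, 3′ ends Gaussian around 150 nt upstream
(sd 40 nt, rounded to integers, ≥1 nt upstream enforced), lengths drawn
from the same pause distribution because divergent polymerases pause
too. Reads whose length falls outside the gel size-selection window of
18–120 nt are redrawn (at most 1,000 rounds, then an error); the window
itself is a modeling choice — gel selection bounds are rarely reported —
and is wide enough that the default distributions never reject.

TSS calling scans ±500 nt (the conventional search interval) around the
annotated TSS for the position with the most sense 5′-end hits. Ties are
broken by smallest |offset from annotation|, then upstream-most — an
arbitrary but deterministic rule. Pause profiling admits only reads whose
5′ end lies within ±2 nt of the called TSS, so pause offsets are measured
from the start the data support rather than the annotation; the gate
width is configurable. Zero-support genes return `None` (a no-call),
never a fabricated call.

Re-centering builds 1-bp-bin 5′-end metagenes around (a) annotated and
(b) called TSSs and reports *sharpness*: the fraction of in-window 5′
signal within ±2 nt of the center. When annotations are offset from the
true starts and jitter is symmetric, re-centering can only concentrate
the profile, so re-centered sharpness ≥ annotated sharpness; the
synthetic suite asserts this.

Sequence windows around start sites are summarized as a 4×L base
frequency matrix (N bases excluded from column counts) with per-column
information content 2 + Σ f·log₂f bits — 0 for a uniform column, 2 for a
fixed base.

## Paired-end ChIP model

Fragment centers are `floor((start+end)/2)`. Two generator modes:

* **Empirical** (default): centers drawn from a two-component Gaussian
  location mixture, default centers 0 and +110 nt (equal weights, sd
  20 nt) — the observed twin-peak promoter geometry. Fragment lengths
  default to Gaussian mean 200 bp, sd 50, truncated at 50 bp (typical
  sonication; no published value to match).
* **Mechanistic**: a hypothesis probe for the idea that sonication
  breakage is disfavored in the DNA protected by the paused complex
  (footprint default +34 ± 14 nt). Shear ends pile up at the footprint
  edges, and immunoprecipitation recovers the pieces crosslinked to the
  complex: the fragment abutting the upstream edge, the fragment abutting
  the downstream edge (together 80% of draws, split evenly), or a piece
  spanning the footprint (20%; its length is redrawn until it covers the
  footprint, its overhang uniform). No fragment endpoint ever falls
  strictly inside the footprint, and the center profile is necessarily
  bimodal, straddling the footprint — with the scRNA pause offset strictly
  between the two peaks. Note that a pure "reject fragments with an
  endpoint inside the footprint" scheme cannot produce this signature:
  footprint-overlapping survivors of such a filter must span the
  footprint, and their centers distribute unimodally around it. Edge
  pile-up plus complex-adjacent retention is the minimal shear mechanism
  that does produce flanking peaks, which is why the mode is built this
  way. It remains a speculative mechanism, not a validated model.

Promoter enrichment is the fragment-center density (per kb) in the ±500
nt promoter window over the genome-wide center density, so uniform
coverage scores 1. The top-fraction filter retains ⌈fraction·n⌉ genes
(default 30%), ties at the cut broken lexicographically by gene id —
`ceil` and the tie rule are conventions chosen for determinism and
order-invariance, both property-tested.

Metagenes bin item offsets into contiguous bins over [−window, +window)
(default 25-bp bins for ChIP, mirroring minus-strand genes first) and
average per-gene counts across genes; total signal is conserved exactly
(Σ values × n_genes = in-window items). Peak detection smooths with a
centered moving average (default 3 bins), reports interior local maxima
exceeding the median of the smoothed profile (plateaus report their
center bin), tallest first. Smoothing width and the median threshold are
exposed parameters; the defaults resolve two peaks 110 nt apart at 25-bp
bins while suppressing single-bin noise.

## Permanganate quantitation

Lane profiles carry per-offset intensities and a thymine mask; only T
positions can react. The generator gives in-bubble thymines expected
intensity `background + gain × bubble_fraction` (defaults 2 and 10
arbitrary densitometry units; both are configuration, not constants) and
everything else `background`, with additive (default) or multiplicative
Gaussian noise truncated at 0 — densitometry noise has no published
model, and additive truncation is the simplest stable choice.

`quantify_region` sums `max(0, intensity − mean(background))` over
in-region thymines; a sum, not a mean, so longer bubbles score higher,
matching gel-band intuition. `call_reactive_region` returns the longest
run of thymines exceeding background mean + z·sd (z = 2 by default;
needs ≥5 background thymines). When no explicit background set is given,
background thymines are those at or below the median thymine intensity —
robust as long as the reactive run covers a minority of thymines.
Calibration is ordinary least squares of aggregate signal on bubble
fraction, with R² defined as 0 for constant signals.

The fold-change test is a two-sided pooled-variance Student's *t* on the
replicate aggregates (Welch behind a flag; with no variance named in the
source convention, pooled is the default reading of "independent samples
t-test"). The fold is the ratio of group means — not the mean of
per-replicate ratios — with its sd from first-order propagation of the
group means' standard errors; identical zero-variance groups report
p = 1, differing ones p = 0 with a `zero_variance` flag. The occupancy
bound assumes strict signal–occupancy proportionality (justified by the
measured linearity of the calibration) and activated occupancy ≤ 100%,
giving max pre-activation occupancy = min(100, 100/fold) percent; it is
an upper bound, never an estimate.

## Decay kinetics

The generator produces 2^(−t/t½) with multiplicative (default) or
additive truncated Gaussian noise; noiseless output satisfies the
memorylessness identity v(t₁+t₂) = v(t₁)·v(t₂) exactly. Normalization
divides by the replicate-mean t = 0 value. Fitting is log-linear OLS of
ln(value) on time with a free intercept, replicates entering as separate
points (times with more replicates weigh more); t½ = ln2/(−slope). The
log-linear route was chosen over nonlinear least squares because it is
closed-form, deterministic, and exact (to 1e-9) on any noiseless
exponential; there is no plateau/baseline term because region
quantitation already removes background. Values ≤ 0 are floored at a
configurable ε = 1e-6 with a warning; a non-negative slope raises rather
than returning a meaningless half-life.

The two-state occupancy model treats each gene copy as vacant ⇄ paused
with initiation rate k_init and exit rate k_off = ln2/t½; stationary
occupancy k_init/(k_init+k_off). The Monte-Carlo companion
(`simulate_two_state_occupancy`) runs per-copy Gillespie dynamics from
vacant starts for 10 relaxation times 1/(k_init+k_off) — within ~5×10⁻⁵
of stationarity — and is the independent check of the closed form.

## What the synthetic data do and do not show

The generators reproduce the *location* structure of the assays
(positions, mixtures, linear response, exponential decay) with
independent draws per read/fragment/position. They do not emulate
mappability, PCR duplication, sequence-dependent shear or oxidation
preferences, gene-to-gene expression dispersion beyond the lognormal
score table, or correlated densitometry noise along a gel lane. Passing
tests therefore demonstrate that the *operations* recover what the
models put in at realistic sizes and noise — not that real libraries are
free of the artifacts above. Problem sizes in the test suite and
reproduction script (30,000 sense reads, 20,000 antisense reads, 100,000
fragments per run, 100-seed sweeps) were chosen so each distributional
check sits several standard errors away from its threshold while the
whole suite runs in minutes on one CPU.

## Known limitations

* TSS calling reports a single modal position; promoters with genuinely
  multimodal initiation get the tallest mode only.
* The mechanistic shear mode is a deliberately minimal hypothesis probe
  (see above); its peak spacing scales with fragment length, not with a
  fitted geometry.
* The occupancy bound inherits any background mismatch between in-cell
  and purified-template lanes; it is reported as a bound for exactly
  that reason.
* The half-life fit assumes a single exponential; mixed populations of
  stable and unstable paused complexes would bias t½ toward the slower
  component at late times.
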