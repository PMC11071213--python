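# Methods

`hmumap` re-derives, on fully synthetic data, the computational analysis of
genome-wide 5-hydroxymethyluracil (5-hmU) and chromatin accessibility in a
dinoflagellate-like genome. Everything is verifiable against planted truth:
the synthetic genome defines where the modification and the protected
footprints are, the simulators generate reads under explicit generative
models, and the analysis modules must recover the planted landscape.

## The synthetic genome

Dinoflagellate genomes organize genes into very long unidirectional arrays;
where a '+'-oriented array meets a '-'-oriented one (a convergent
junction), a topological domain boundary forms. The generator emulates this
by tiling each contig with gene arrays of alternating orientation
(length ~ Normal(mean, mean/4), clipped to [mean/2, 2·mean]) and emitting
every convergent junction as a 1-bp boundary interval. Defaults: 2 contigs
of 400 kbp, mean array length 40 kbp, yielding ~10 boundaries — large
enough that 5-kbp bins more than 30 kbp from any boundary exist (the
"interior" class of the correlation analysis), small enough that every
analysis runs in seconds.

Background sequence is i.i.d. at GC 0.44 (Symbiodiniaceae-like); i.i.d.
background guarantees near-unit mappability outside planted repeats, so
mappability structure is attributable to the repeats alone.

Five repeat families are planted as diverged copies (1–2% substitutions) of
a family consensus: a large DNA-transposon stand-in (`MaverickSim`, 2 kbp,
70% of copies placed within 2·w_b of a boundary), LTR-like, LINE-like and
satellite-like families placed mostly uniformly, and a `CollapsedSim`
family whose instances carry true copy number 2. Collapsed repeats are
represented by keeping all annotations in assembly coordinates and placing
each surplus copy (an *exact* duplicate of its diverged instance) on a
truth-only contig. Reads simulated from the surplus copies can only align
to the single assembly copy, which reproduces the artificial coverage
pileups of a collapsed assembly without perturbing any other coordinate.

**Modification map.** Each T (on either strand; the two strands are stored
separately because the chemistry acts per strand) receives a deposition
probability that is the *maximum* of three tiers: baseline `p0 = 0.03`,
`p_boundary = 0.35` within `w_b = 2 kbp` of a boundary, and a per-family
repeat tier (default `MaverickSim` 0.45, LTR 0.15, satellite 0.10,
collapsed 0.10; the LINE-like family deliberately stays at baseline so the
repeat-space analysis has a near-neutral family). Maximum rather than sum
keeps probabilities bounded without renormalization. The paper-scale
literature gives no absolute 5-hmU stoichiometry for this genus, so these
are free parameters chosen to give a clear planted contrast; all tests use
*recovery* (ranks, signs, monotonicity), never absolute levels.

**Occupancy map.** Protection footprints (width 140 bp — the center of the
nucleosomal 120–160 bp V-plot band — strength 0.9, density 0.6 per kbp) are
placed by rejection sampling with placement odds proportional to
`1 + γ·(local modification density in a ±500 bp window)`, γ = 30 by
default. This couples protection to 5-hmU, which is what makes ATAC and
MeDIP anti-correlated around boundaries. An optional per-family odds
multiplier supports the uncoupled "2× on Maverick" scenario used by the
footprint-enrichment analysis. Footprints never overlap; if the requested
density cannot be placed, the error reports the achieved density.

## Read simulators

Fragment lengths follow a gamma distribution parameterized by its mode
(60 bp for transposase libraries — the short-fragment peak expected when
chromatin is not nucleosomal — 300 bp for sheared MeDIP input), truncated
to [30, 400] bp by resampling so no mass piles at the bounds. Reads are
emitted in molecule orientation; paired 2×75 FASTQ and true-origin SAM are
available for every library.

* **gDNA**: uniform starts over the *truth* genome — the collapsed surplus
  copies therefore contribute ~2× pileups in assembly space.
* **ATAC**: fragment starts drawn from the per-base insertion weight
  `1 − occupancy`; the other end accepted with the same weight. A small
  fraction (2%) of the library is emitted as footprint-spanning fragments
  (length ~ Normal(footprint width, 12), center jitter σ = 8 bp),
  apportioned by footprint strength. The 2% default is an explicit
  calibration: cut-based coverage inside a footprint is ~0.08× its flanks,
  and each spanning fragment adds back ~1/17 of flank coverage at the
  default 200k-fragment depth, so 2% (≈8 spanning fragments per footprint)
  keeps footprints clearly depleted (~0.5× flanks) while still giving the
  V-plot its nucleosome-length band and the caller enough support.
* **MeDIP**: candidates from a 50/50 target/spike mixture (the spike genome
  is a 300-kbp modification-free contig). Each candidate's modified-T count
  K is drawn Binomial(n sites, mean site probability) over the fragment;
  pulldown accepts with probability `sigmoid(β0 + β·K)`. β can be given
  directly or calibrated so that the mean odds multiplier E[exp(βK)] over
  target candidates equals a requested value (the "double the target odds"
  setting used for spike-in quantification); β0 is always solved so the
  overall yield is 10%. The closed-form prediction for the ip spike
  fraction is Σ_spike σ / Σ_all σ over the realized candidate pool.
  "Input" is the unselected candidate pool, "depleted" its rejected
  complement, and "IgG" a modification-blind selection at the same yield.
* **Conversion**: per fragment, each origin-strand T is modified with the
  map probability; modified Ts read as C with efficiency 0.8 (harsh
  oxidation) or 0.3 (mild), unmodified Ts at the sequencing-error rate
  (0.001, applied to the T→C channel only — substitution errors at other
  bases do not enter conversion counting and are omitted). Events are
  recorded in reference space: T→C for plus-origin, A→G for minus-origin
  fragments.

What the simulators do **not** model: PCR duplicates, GC bias, indels,
quality-score structure, chimeras, or base-composition-dependent Tn5
insertion bias. Passing tests therefore demonstrate the correctness of the
analysis logic under the stated generative model, not robustness to every
real-data artifact.

## Alignment and multimapper-weighted signal

The aligner is an exact seed-and-verify search over a k-mer index (k = 12)
of the assembly, reporting *all* locations in the minimal-mismatch stratum
within a ≤2-mismatch budget on both strands. Splitting a read into
`max_mismatches + 1` equal segments guarantees by pigeonhole that some
segment is mismatch-free at every admissible location, so the search is
provably complete for reads carrying that many disjoint k-mers (≥36 bp at
the defaults); shorter reads degrade gracefully to a smaller guaranteed
budget. NH is the stratum size. Conversion-aware mode indexes T→C- and
A→G-collapsed copies of the genome and ignores those substitutions during
verification (three-letter alignment), so heavily converted fragments are
not lost — exactly the bias a naive mismatch budget would introduce.

Signal tracks implement multimapper weighting: each alignment contributes
1/NH, and per-position sums are normalized to reads per million mapped
fragments, `S[c,i] = (Σ_{R∈R_{c,i}} 1/NH_R) / (|R|/10⁶)`. `|R|` counts each
fragment once (it equals the sum of weights, since one fragment's weights
sum to 1); whether multimappers should instead count once per alignment is
ambiguous in common usage, and counting fragments once is the convention
adopted here. A "unique" mode drops NH > 1 fragments entirely. The
weighted-coverage conservation identity Σ S·|R|/10⁶ = Σ aligned lengths
holds exactly and is asserted in tests.

Mappability tiles a read at every position, remaps, and scores each
position RC/RL — the fraction of its covering tiling reads that map to
their origin *and nowhere else within the mismatch budget* (all strata, not
just the best: a read whose origin is its unique best hit but which has a
2-mismatch alternative is not unique by this definition). The test suite
holds this to exact agreement with an exhaustive all-lags remapping oracle.

## Conversion analysis

Site evidence is strand-aware: plus-strand T sites count T→C mismatches
from plus-origin unique fragments, minus-strand sites A→G from minus-origin
fragments; multimappers are excluded because mismatch attribution across
equally good loci is ambiguous. Rates aggregate in 500-bp bins stepped
100 bp (bins below 10× summed coverage are masked). Modified sites are
called by a one-sided binomial test against a background conversion rate
(sequencing error, estimable from the spike or an unmodified library) with
Benjamini–Hochberg control; the paper-scale protocols do not specify an
error model, so this caller is a declared, transparent stand-in. Sequence
context around called sites uses reverse-complemented context for
minus-strand sites and reports per-offset information content
`2 + Σ f·log2 f` against a uniform background; with the genome's GC of
0.44, a perfectly uniform deposition still scores ~0.012 bits per offset,
comfortably below the 0.05-bit null threshold used in tests.

Because conversion efficiency is below 1 and unknown in practice, all
conversion statements are *relative*: binned rates are monotone in planted
density (Spearman ρ > 0.9 across 20 tiers in the acceptance run), harsh
exceeds mild genome-wide, but absolute modification levels are not
estimable from conversion data alone and are never asserted.

## Figure-level statistics

* **Metaprofiles** average a track in ±W windows around oriented anchors
  (minus anchors mirrored, clipped windows dropped). Boundary profiles use
  W = 10 kbp with 2-kbp bins — the bin matches the planted boundary
  halfwidth, so the depletion/enrichment plateau falls in the central bins.
* **Enrichment domains** are the control-based replacement for an external
  peak caller: 500-bp windows, fragment-equivalent counts (window coverage
  divided by mean fragment length), and the *conditional* two-sample
  Poisson ratio test (binomial given the window total, evaluated by
  regularized incomplete beta so fractional counts are valid), BH across
  windows, same-sign windows within 200 bp merged, both signs reported.
  The conditional test is exact for any shared local rate, which is what
  makes collapsed-repeat pileups — present in treatment *and* control —
  cancel instead of appearing as peaks. An earlier one-sample variant that
  treated the scaled control as exact was visibly anticonservative at the
  2× pileup loci and was replaced.
* **Binned correlation** (5-kbp bins) reports Pearson and Spearman (the
  coefficient choice is left to the reader; both are computed) for three
  classes: all bins, boundary-proximal (center within D = 10 kbp of a
  boundary), and interior (farther than 3D; the intermediate band belongs
  to neither, so the two named classes are disjoint but deliberately not
  exhaustive). Bins below 0.5 mean mappability are excluded when a
  mappability track is supplied.
* **Repeat space** aligns reads directly to family consensus sequences with
  a relaxed budget (5 mismatches) and unlimited multimapping, weights by
  1/NH, and normalizes by the *library* size rather than the
  consensus-mapped subset — normalizing within repeat space would make the
  family shares compositional and a single strongly enriched family would
  depress all others. Enrichment is log2((T+ψ)/(C+ψ)), ψ = 0.5 RPM.
* **Overlap sets** count boundaries falling (within a slop) in each
  combination of low-accessibility domains, high-5-hmU regions and
  Maverick instances; assignment is by simple membership, and a boundary
  overlapping several classes counts in their intersection key.

## Nucleosome calling and V-plots

The caller is a transparent density-and-occupancy procedure with the
standard window geometry (sliding 1 kbp, step 500 bp): midpoints of
nucleosome-range (100–200 bp) fragments are smoothed with a Gaussian
(σ = 20 bp); local maxima become candidates; a candidate's occupancy is the
nucleosome-range fraction among all fragment midpoints within ±73 bp; calls
require occupancy ≥ 0.4 and ≥ 5 supporting fragments, are deduplicated
across overlapping windows keeping the higher occupancy, and respect a
120-bp minimum spacing. The high-resolution subset applies the 0.8
occupancy cutoff and is by construction a subset of all calls. The support
and occupancy floors are set by a null analysis: at the default depth a
spurious candidate sees ~36 midpoints of which ~13% are nucleosome-range,
so occupancy 0.4 sits ~8 standard deviations above the null and the
occupancy-free simulation yields zero calls; the floor of 5 fragments keeps
footprints receiving a below-average share of spanning fragments callable.
Fragment centers are floor((start+end)/2), resolving even-length ties
toward the start for determinism.

V-plots histogram (fragment length, center offset) pairs around anchors
(default ±100 bp, lengths 1–300, unique-mode fragments; a multimapper mode
is available since usage varies). With anchors spaced more than 2W apart
the matrix total equals the number of usable fragments.

Footprint-over-feature enrichment is the call density inside a family
divided by the genome-wide density, with a Clopper–Pearson interval on the
in-family proportion scaled by the family's bp share.

## Determinism and problem sizes

Every stochastic step takes a seed and uses `numpy.random.default_rng`;
the demonstration pipeline writes only text formats with fixed float
formatting and hashes its outputs, and two runs under the same seed are
byte-identical. Default problem sizes (800-kbp genome, 40k–200k fragments
per library) were chosen so that the full test suite and the acceptance
script each complete in a few minutes on one CPU while leaving every
planted effect many standard errors above its detection threshold.

## Known limitations

* The aligner is exact-match/substitution-only (no gaps, no quality
  awareness) and is intended for synthetic data and small references;
  real-data mode is expected to ingest externally produced SAM.
* The MeDIP dose-response (logistic in modified-T count) is a modeling
  choice; the real pulldown chemistry is unspecified at this resolution.
* The site caller's binomial background model ignores overdispersion from
  mapping artifacts that real data would show.
* Absolute 5-hmU stoichiometry is out of reach by design (conversion
  efficiency < 1); only relative statements are made anywhere.
* With ~10 planted boundaries, boundary-class correlations rest on ~40
  bins; signs and orderings are stable under the fixed seeds but the
  coefficients themselves carry sampling noise.
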