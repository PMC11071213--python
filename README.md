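# hmumap

Mapping **5-hydroxymethyluracil (5-hmU)** and **chromatin accessibility** in
dinoflagellate-like genomes — as a fully synthetic, fully verifiable
pipeline.

Dinoflagellate nuclei break most eukaryotic rules: chromatin is largely
histone-free, genes sit in very long unidirectional arrays whose convergent
junctions form topological domain ("dinoTAD") boundaries, and a large
fraction of thymines is replaced by the otherwise rare base 5-hmU. Mapping
that modification and the accessibility landscape requires a specific
analysis stack: multimapper-aware signal tracks (5-hmU lives on repeats),
spike-in-controlled immunoprecipitation (MeDIP) quantification,
basepair-resolution T→C chemical-conversion counting, boundary
metaprofiles and anti-correlation statistics, repeat-consensus-space
enrichment, and positioned-nucleosome/V-plot analysis — all of it robust to
collapsed-repeat assembly artifacts.

`hmumap` implements that stack end-to-end and, because real dinoflagellate
data is ~1 Gbp and hundreds of millions of reads, ships a first-class
**synthetic genome and read simulator** so every stage is exercised against
planted ground truth in seconds. The package is for genomicists who want
the analysis logic itself — reusable, tested, and oracle-verified — plus a
sandbox in which methods for unusual genomes can be validated before
touching real data.

## The core quantities

* **Multimapper-weighted signal** (reads per million mapped fragments):
  `S[c,i] = (Σ_{R ∈ R_{c,i}} 1/NH_R) / (|R|/10⁶)`, where `NH_R` is the
  number of equally best alignment locations of fragment R and |R| counts
  each mapped fragment once. Weighted coverage is conserved exactly:
  `Σ S·|R|/10⁶ = Σ aligned lengths`.
* **Mappability**: tile a read of length RL at every position, remap, and
  score each position `RC/RL` — the fraction of covering tiling reads that
  map to their origin and nowhere else within the mismatch budget.
* **Conversion rate**: strand-aware `conversions / coverage` per thymine
  (T→C for plus-strand, A→G in reference space for minus-strand sites),
  aggregated in 500-bp bins stepped 100 bp. Relative, not absolute:
  chemical conversion efficiency is below 1.
* **Occupancy** (nucleosome calling): the fraction of fragments with
  midpoints within ±73 bp of a candidate center whose lengths fall in the
  nucleosomal 100–200 bp range; calls at occupancy ≥ 0.8 form the
  high-resolution subset.

See `docs/methods.md` for the full model descriptions, parameter defaults
and their rationale, and known limitations.

## Worked example

```python
from hmumap import *
from hmumap.genome import GenomeConfig

# a 2 x 400 kbp toy genome: gene arrays, boundaries, repeat families,
# collapsed repeats, plus ground-truth 5-hmU and protection landscapes
genome = generate_genome(GenomeConfig(seed=7))
mod = build_modification_map(genome, p_repeat={"MaverickSim": 0.45})
occ = build_occupancy_map(genome, mod, seed=7)

# simulate an ATAC library and align it (exact multimapper, NH-aware)
cfg = LibraryConfig(n_fragments=200_000, seed=21)
frags = simulate_atac_fragments(genome, occ, cfg)
aligner = MultimapAligner(genome.assembly_view)
alns = aligner.align_fragments(fragment_sequences(genome, frags))
track = weighted_signal_track(alns, genome.contig_lengths(assembly_only=True))

prof = metaprofile(track, genome.boundaries, W=10_000, binwidth=2_000)
print(prof.offsets[prof.values.argmin()])   # -1000
print(round(prof.values.min() / prof.values.max(), 3))   # 0.729
```

The boundary metaprofile bottoms out in the bin adjacent to offset 0 —
accessibility is depleted exactly where the modification (and hence
protection) was planted — dropping to about 73% of the flanking signal,
a depleted-but-not-silenced boundary, not a hard domain border.

A complete scaled-down run (genome bundle, four libraries, tracks,
conversion bins, domains, correlations, repeat space, footprint calls,
V-plot) is one call:

```python
from hmumap.pipeline import run_pipeline
manifest = run_pipeline("out/", seed=12)   # {file: sha256}, byte-stable
```

A thin CLI wraps the same functions:

```bash
hmu synth genome --seed 7 --out bundle/
hmu synth reads --bundle bundle/ --library atac --n 50000 --out reads/
hmu align --sam reads/atac.sam --assembly bundle/assembly.fa --out aligned.sam
hmu track --sam aligned.sam --assembly bundle/assembly.fa --out atac.bedgraph
```

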