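"""Sequencing-fragment simulators for the synthetic genome.

Four library types are emulated:

* **gDNA control** — uniform fragmentation of naked DNA (optionally a
  two-genome target/spike mixture), blind to occupancy and modification.
* **ATAC** — transposase insertion weighted by per-base accessibility
  ``1 - occupancy`` at both fragment ends, plus "protected" fragments
  spanning planted footprints (length ~ footprint width) so that
  positioned-footprint V-plots are reproducible.
* **MeDIP** (ip / input / depleted / IgG) — pulldown of candidate fragments
  from a target+spike mixture with per-fragment acceptance probability
  ``sigmoid(beta0 + beta * modified_T_count)``; the spike genome carries no
  modification, so its fragments are selected at the baseline rate.
* **chemical conversion** (mild / harsh) — each origin-strand thymine that
  carries the modification converts T->C with the condition's efficiency;
  unmodified thymines convert at the sequencing-error rate.  Conversions are
  recorded in reference space (T->C for plus-origin fragments, A->G for
  minus-origin ones).

Fragment lengths follow a gamma model parameterized by its mode
(default 60 bp for transposase libraries, matching the short-fragment peak
of histone-poor chromatin; ~300 bp for sheared MeDIP input).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .genome import A, C, G, T, ModificationMap, OccupancyMap, ToyGenome, decode, _random_sequence

__all__ = [
    "SimFragment",
    "LibraryConfig",
    "make_spike_genome",
    "simulate_gdna_fragments",
    "simulate_atac_fragments",
    "simulate_medip_libraries",
    "simulate_conversion_reads",
    "fragment_sequences",
    "calibrate_beta",
    "calibrate_beta0",
]


@dataclass
class SimFragment:
    """One simulated sequenced fragment (0-based half-open coordinates)."""

    source: str  # "target" | "spike"
    contig: str
    start: int
    end: int
    strand: str = "+"
    converted: np.ndarray | None = None  # absolute ref positions (conversion libs)
    modified_t: int = 0  # modified-T count (MeDIP selection input)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LibraryConfig:
    n_fragments: int = 200_000
    frag_mode: int = 60  # gamma mode, bp
    frag_dispersion: float = 10.0  # gamma scale, bp
    min_length: int = 30
    max_length: int = 400
    read_length: int = 75
    spike_fraction: float = 0.0
    pulldown_yield: float = 0.10
    conversion_mild: float = 0.3
    conversion_harsh: float = 0.8
    sequencing_error: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be > 0")
        if not self.conversion_harsh > self.conversion_mild:
            raise ValueError("conversion_harsh must exceed conversion_mild")
        for name in ("spike_fraction", "pulldown_yield", "conversion_mild",
                     "conversion_harsh", "sequencing_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_length < 20 or self.max_length <= self.min_length:
            raise ValueError("fragment length bounds invalid")


def make_spike_genome(length: int = 300_000, gc: float = 0.41, seed: int = 99) -> ToyGenome:
    """A modification-free second genome used as spike-in (one contig)."""
    rng = np.random.default_rng(seed)
    seq = decode(_random_sequence(rng, length, gc))
    return ToyGenome(
        contigs={"spike_1": seq},
        assembly_contigs=("spike_1",),
        gene_starts=[],
        boundaries=[],
        repeat_instances=[],
        consensus={},
    )


def _sample_lengths(rng: np.random.Generator, cfg: LibraryConfig, n: int,
                    mode: int | None = None) -> np.ndarray:
    """Gamma fragment lengths (mode m), truncated to the configured range
    by resampling so no probability mass piles up at the bounds."""
    m = cfg.frag_mode if mode is None else mode
    shape = m / cfg.frag_dispersion + 1.0
    lengths = rng.gamma(shape, cfg.frag_dispersion, size=n)
    bad = (lengths < cfg.min_length) | (lengths > cfg.max_length)
    while bad.any():
        lengths[bad] = rng.gamma(shape, cfg.frag_dispersion, size=int(bad.sum()))
        bad = (lengths < cfg.min_length) | (lengths > cfg.max_length)
    return np.round(lengths).astype(np.int64)


def _uniform_fragments(
    rng: np.random.Generator,
    contigs: Mapping[str, str],
    n: int,
    cfg: LibraryConfig,
    source: str,
    mode: int | None = None,
) -> list[SimFragment]:
    names = list(contigs)
    sizes = np.array([len(contigs[c]) for c in names], dtype=np.float64)
    c_idx = rng.choice(len(names), size=n, p=sizes / sizes.sum())
    lengths = _sample_lengths(rng, cfg, n, mode=mode)
    starts = np.floor(rng.random(n) * (sizes[c_idx] - lengths)).astype(np.int64)
    starts = np.maximum(starts, 0)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    return [
        SimFragment(source, names[ci], int(s), int(s + ln), str(st))
        for ci, s, ln, st in zip(c_idx, starts, lengths, strands)
    ]


def simulate_gdna_fragments(
    genome: ToyGenome,
    cfg: LibraryConfig,
    spike_genome: ToyGenome | None = None,
) -> list[SimFragment]:
    """Uniform naked-DNA fragmentation over the truth genome.

    Fragment starts are uniform over the truth view (so collapsed-repeat
    surplus copies contribute reads that pile onto the single assembly
    copy); there is no dependence on occupancy or modification.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_spike = int(rng.binomial(cfg.n_fragments, cfg.spike_fraction)) if cfg.spike_fraction else 0
    if n_spike and spike_genome is None:
        raise ValueError("spike_fraction > 0 requires a spike_genome")
    frags = _uniform_fragments(rng, genome.truth_view, cfg.n_fragments - n_spike, cfg, "target")
    if n_spike:
        frags += _uniform_fragments(rng, spike_genome.truth_view, n_spike, cfg, "spike")
        frags = [frags[i] for i in rng.permutation(len(frags))]
    return frags


def simulate_atac_fragments(
    genome: ToyGenome,
    occ_map: OccupancyMap,
    cfg: LibraryConfig,
    protected_fraction: float = 0.02,
    center_jitter: float = 8.0,
    length_jitter: float = 12.0,
) -> list[SimFragment]:
    """Transposition fragments weighted by accessibility at both ends.

    Cut-based fragments draw their start from the per-position insertion
    weight ``1 - occupancy`` and are accepted with probability equal to the
    insertion weight at their other end.  A ``protected_fraction`` of the
    library is emitted as footprint-spanning fragments (length centred on
    the footprint width), apportioned across footprints in proportion to
    footprint strength.  The default fraction is set so that a planted
    footprint stays strongly coverage-depleted relative to its flanks
    (spanning fragments add back roughly half the removed coverage at the
    default library depth) while each footprint still receives a handful
    of nucleosome-sized spanning fragments for V-plots and calling.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = list(genome.contigs)
    weights = {c: 1.0 - np.asarray(occ_map.occupancy[c], dtype=np.float64) for c in names}
    totals = np.array([weights[c].sum() for c in names])
    if totals.sum() <= 0:
        raise ValueError("occupancy is 1 everywhere: no accessible DNA to transpose")
    cum = {c: np.cumsum(weights[c]) for c in names}
    contig_p = totals / totals.sum()
    sizes = {c: len(genome.contigs[c]) for c in names}

    n_protected = int(round(protected_fraction * cfg.n_fragments)) if occ_map.footprints else 0
    n_cut = cfg.n_fragments - n_protected

    frags: list[SimFragment] = []
    while len(frags) < n_cut:
        n_draw = max(1024, int((n_cut - len(frags)) * 1.6))
        c_idx = rng.choice(len(names), size=n_draw, p=contig_p)
        u = rng.random(n_draw)
        lengths = _sample_lengths(rng, cfg, n_draw)
        accept_u = rng.random(n_draw)
        strands = rng.random(n_draw) < 0.5
        for ci, ui, ln, au, st in zip(c_idx, u, lengths, accept_u, strands):
            cname = names[ci]
            start = int(np.searchsorted(cum[cname], ui * cum[cname][-1]))
            end = start + int(ln)
            if end > sizes[cname]:
                continue
            if au >= weights[cname][end - 1]:
                continue
            frags.append(SimFragment("target", cname, start, end, "+" if st else "-"))
            if len(frags) >= n_cut:
                break

    if n_protected:
        strengths = np.array([fp.strength for fp in occ_map.footprints])
        alloc = rng.multinomial(n_protected, strengths / strengths.sum())
        for fp, k in zip(occ_map.footprints, alloc):
            if k == 0:
                continue
            centers = fp.center + np.round(rng.normal(0.0, center_jitter, k)).astype(int)
            lens = np.clip(
                np.round(rng.normal(fp.width, length_jitter, k)),
                fp.width - 40,
                fp.width + 60,
            ).astype(int)
            strands = rng.random(k) < 0.5
            for ctr, ln, st in zip(centers, lens, strands):
                s = int(ctr - ln // 2)
                e = s + int(ln)
                if s < 0 or e > sizes[fp.contig]:
                    continue
                frags.append(SimFragment("target", fp.contig, s, e, "+" if st else "-"))
    return frags


# ---------------------------------------------------------------------------
# MeDIP
# ---------------------------------------------------------------------------


def _modified_t_counts(
    rng: np.random.Generator, mod_map: ModificationMap, frags: Sequence[SimFragment]
) -> np.ndarray:
    """Per-fragment modified-T draw (both strands).

    The count is drawn as Binomial(n_sites, mean site probability) over the
    fragment, which matches the Poisson-binomial mean exactly and its
    variance closely for the tiered maps used here.
    """
    cums: dict[str, np.ndarray] = {}
    ns: dict[str, np.ndarray] = {}
    counts = np.zeros(len(frags), dtype=np.int64)
    for i, fr in enumerate(frags):
        if fr.source != "target":
            continue
        if fr.contig not in cums:
            p = mod_map.combined(fr.contig).astype(np.float64)
            cums[fr.contig] = np.concatenate([[0.0], np.cumsum(p)])
            ns[fr.contig] = np.concatenate([[0], np.cumsum(p > 0)])
        cs, nn = cums[fr.contig], ns[fr.contig]
        s_p = cs[fr.end] - cs[fr.start]
        n_sites = int(nn[fr.end] - nn[fr.start])
        if n_sites > 0:
            counts[i] = rng.binomial(n_sites, min(1.0, s_p / n_sites))
    return counts


def calibrate_beta(counts: np.ndarray, target_odds: float = 2.0) -> float:
    """beta such that the mean pulldown-odds multiplier E[exp(beta*K)] over
    the given modified-T counts equals ``target_odds``."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.max() <= 0:
        raise ValueError("cannot calibrate beta: all modified-T counts are zero")

    def f(beta: float) -> float:
        return logsumexp(beta * counts) - np.log(len(counts)) - np.log(target_odds)

    return float(brentq(f, 0.0, 5.0, xtol=1e-12))


def calibrate_beta0(counts: np.ndarray, beta: float, yield_fraction: float) -> float:
    """beta0 such that mean sigmoid(beta0 + beta*K) equals the library yield."""

    def f(b0: float) -> float:
        return float(expit(b0 + beta * counts).mean() - yield_fraction)

    return float(brentq(f, -40.0, 40.0, xtol=1e-12))


def simulate_medip_libraries(
    genome: ToyGenome,
    spike_genome: ToyGenome,
    mod_map: ModificationMap,
    cfg: LibraryConfig,
    beta: float | None = None,
    target_odds: float | None = None,
    frag_mode: int = 300,
) -> dict[str, list[SimFragment]]:
    """Simulate the pulldown experiment with its three controls.

    Candidate fragments are drawn uniformly from the target/spike mixture
    (the spike genome is modification-free by construction).  Selection uses
    a logistic link on the per-fragment modified-T count, with the intercept
    calibrated so the overall ip yield matches ``cfg.pulldown_yield``.
    Returns ``{"ip", "input", "depleted", "igg"}``; ip and depleted
    partition the candidate set, input is the unselected candidate pool, and
    IgG is a modification-blind selection at the same yield.
    """
    cfg.validate()
    if beta is not None and beta < 0:
        raise ValueError("beta must be non-negative (enrichment model)")
    for cname in spike_genome.contigs:
        if mod_map.p_plus.get(cname) is not None and mod_map.p_plus[cname].any():
            raise ValueError("spike genome must carry zero modification")
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_fragments
    n_spike = int(rng.binomial(n, cfg.spike_fraction))
    candidates = _uniform_fragments(
        rng, genome.truth_view, n - n_spike, cfg, "target", mode=frag_mode
    ) + _uniform_fragments(
        rng, spike_genome.truth_view, n_spike, cfg, "spike", mode=frag_mode
    )
    candidates = [candidates[i] for i in rng.permutation(len(candidates))]

    counts = _modified_t_counts(rng, mod_map, candidates)
    for fr, k in zip(candidates, counts):
        fr.modified_t = int(k)

    if beta is None:
        target_counts = counts[[fr.source == "target" for fr in candidates]]
        beta = calibrate_beta(target_counts, target_odds if target_odds else 2.0)
    beta0 = calibrate_beta0(counts, beta, cfg.pulldown_yield)

    p_accept = expit(beta0 + beta * counts)
    u = rng.random(len(candidates))
    accepted = u < p_accept
    igg_mask = rng.random(len(candidates)) < cfg.pulldown_yield

    ip = [fr for fr, a in zip(candidates, accepted) if a]
    depleted = [fr for fr, a in zip(candidates, accepted) if not a]
    igg = [fr for fr, m in zip(candidates, igg_mask) if m]
    return {
        "ip": ip,
        "input": candidates,
        "depleted": depleted,
        "igg": igg,
        "beta": beta,
        "beta0": beta0,
        "p_accept": p_accept,
    }


# ---------------------------------------------------------------------------
# Chemical conversion
# ---------------------------------------------------------------------------


def simulate_conversion_reads(
    genome: ToyGenome,
    mod_map: ModificationMap,
    cfg: LibraryConfig,
    condition: str = "harsh",
) -> list[SimFragment]:
    """Oxidation/conversion fragments: modified origin-strand Ts read as C.

    Per fragment, each thymine of the origin strand is modified with the
    map's per-site probability; modified Ts convert with the condition's
    efficiency, unmodified Ts at the sequencing-error rate.  Converted
    positions are stored as absolute reference coordinates (reference T for
    plus-origin, reference A for minus-origin fragments).
    """
    cfg.validate()
    if condition not in ("mild", "harsh"):
        raise ValueError("condition must be 'mild' or 'harsh'")
    e = cfg.conversion_mild if condition == "mild" else cfg.conversion_harsh
    if not 0.0 <= e <= 1.0:
        raise ValueError("conversion efficiency must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)

    frags = _uniform_fragments(rng, genome.truth_view, cfg.n_fragments, cfg, "target")

    # per-contig origin-strand site tables
    sites: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for cname in genome.contigs:
        seq = genome.encoded(cname)
        pos_t = np.flatnonzero(seq == T)
        pos_a = np.flatnonzero(seq == A)
        sites[(cname, "+")] = (pos_t, mod_map.p_plus[cname][pos_t].astype(np.float64))
        sites[(cname, "-")] = (pos_a, mod_map.p_minus[cname][pos_a].astype(np.float64))

    by_key: dict[tuple[str, str], list[int]] = {}
    for i, fr in enumerate(frags):
        by_key.setdefault((fr.contig, fr.strand), []).append(i)

    for key, idxs in by_key.items():
        pos, probs = sites[key]
        starts = np.array([frags[i].start for i in idxs])
        ends = np.array([frags[i].end for i in idxs])
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        frag_of = np.repeat(np.arange(len(idxs)), counts)
        flat = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts) + np.repeat(lo, counts)
        site_pos = pos[flat]
        site_p = probs[flat]
        modified = rng.random(total) < site_p
        conv = np.where(modified, rng.random(total) < e, rng.random(total) < cfg.sequencing_error)
        conv_pos = site_pos[conv]
        conv_frag = frag_of[conv]
        split_at = np.searchsorted(conv_frag, np.arange(1, len(idxs)))
        n_mod = np.bincount(frag_of, weights=modified, minlength=len(idxs))
        for j, positions in enumerate(np.split(conv_pos, split_at)):
            fr = frags[idxs[j]]
            fr.converted = positions.astype(np.int64)
            fr.modified_t = int(n_mod[j])
    for fr in frags:
        if fr.converted is None:
            fr.converted = np.empty(0, dtype=np.int64)
    return frags


def fragment_sequences(
    genomes: Mapping[str, ToyGenome] | ToyGenome,
    frags: Sequence[SimFragment],
    apply_conversions: bool = True,
) -> list[str]:
    """Molecule-orientation fragment sequences, conversions applied.

    Minus-origin fragments are reverse-complemented (the sequenced molecule
    is the minus strand), so conversion events always read as T->C in
    molecule space and an aligner recovers the origin strand from the
    mapping orientation.  ``genomes`` may be a single genome or a mapping
    from source label ("target"/"spike") to genome.
    """
    from .genome import revcomp_codes

    if isinstance(genomes, ToyGenome):
        genomes = {"target": genomes, "spike": genomes}
    out: list[str] = []
    for fr in frags:
        g = genomes[fr.source]
        seq = g.encoded(fr.contig)[fr.start : fr.end].copy()
        if apply_conversions and fr.converted is not None and len(fr.converted):
            rel = np.asarray(fr.converted) - fr.start
            is_t = seq[rel] == T
            seq[rel[is_t]] = C
            seq[rel[~is_t]] = G
        if fr.strand == "-":
            seq = revcomp_codes(seq)
        out.append(decode(seq))
    return out
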