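"""Exact-search multimapping alignment and multimapper-weighted signal.

The aligner reports, for each fragment sequence, *all* alignment locations
in the minimal-mismatch stratum within a small mismatch budget (default 2),
on both strands — the multiplicity of that set is the fragment's NH.  It is
an exact seed-and-verify search over a k-mer index: a read is split into
``max_mismatches + 1`` equal segments, so by pigeonhole at least one
segment is mismatch-free at every admissible location and its leading
k-mer lookup recovers the candidate.  The search is therefore provably
complete whenever the read is long enough to carry ``max_mismatches + 1``
disjoint k-mers (for shorter reads the budget degrades gracefully to
``len(read) // k - 1`` guaranteed mismatches).

Conversion-aware mode additionally indexes T->C- and A->G-collapsed copies
of the genome and treats those substitutions as matches, so chemically
converted fragments seed and verify at their origin regardless of how many
converted bases they carry (three-letter alignment in the bisulfite
tradition).

Signal tracks weight every alignment by 1/NH and normalize to reads per
million mapped fragments (RPM):

    S[c, i] = (sum over alignments covering (c, i) of 1/NH) / (|R| / 1e6)

where |R| counts each mapped fragment once (the sum of weights, since the
weights of one fragment's alignments sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import A, C, G, T, ToyGenome, decode, encode, revcomp_codes

__all__ = [
    "AlignedFragment",
    "MultimapAligner",
    "SignalTrack",
    "MappabilityTrack",
    "weighted_signal_track",
    "mappability_track",
    "composition_stats",
    "fragment_length_histogram",
    "truth_alignments",
    "unique_alignments",
]

_SEP = np.uint8(4)


@dataclass(frozen=True)
class AlignedFragment:
    """One alignment location of one fragment.

    ``nh`` is the total number of equally-best locations of the fragment,
    so its weight is 1/nh and the weights of all its records sum to 1.
    ``mismatches`` holds (absolute position, ref base, read base) triples.
    """

    fragment_id: int
    contig: str
    start: int
    end: int
    strand: str
    nh: int
    mismatches: tuple = ()
    source: str | None = None

    @property
    def weight(self) -> float:
        return 1.0 / self.nh

    @property
    def length(self) -> int:
        return self.end - self.start


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted k-mer codes and their start positions (separators excluded)."""
    n = arr.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    codes = np.zeros(m, dtype=np.uint64)
    safe = np.where(arr > 3, 0, arr).astype(np.uint64)
    for j in range(k):
        codes = codes * 4 + safe[j : m + j]
    bad = np.convolve((arr > 3).astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
    pos = np.flatnonzero(~bad).astype(np.int64)
    codes = codes[pos]
    order = np.argsort(codes, kind="stable")
    return codes[order], pos[order]


class _CodeIndex:
    def __init__(self, arr: np.ndarray, k: int):
        self.k = k
        self.codes, self.pos = _kmer_codes(arr, k)

    def lookup(self, code) -> np.ndarray:
        # query with a dtype-matched array: a Python-int needle forces a
        # slow casting path inside searchsorted
        q = np.asarray([code, code + 1], dtype=np.uint64)
        lo, hi = np.searchsorted(self.codes, q)
        return self.pos[lo:hi]


def _collapse(arr: np.ndarray, src: int, dst: int) -> np.ndarray:
    out = arr.copy()
    out[out == src] = dst
    return out


class MultimapAligner:
    """Best-stratum exact multimapper over a small reference."""

    def __init__(
        self,
        contigs: Mapping[str, str] | ToyGenome,
        k: int = 12,
        max_mismatches: int = 2,
        conversion_aware: bool = False,
    ):
        if isinstance(contigs, ToyGenome):
            contigs = contigs.assembly_view
        if not contigs:
            raise ValueError("reference has no contigs")
        self.k = k
        self.max_mismatches = max_mismatches
        self.conversion_aware = conversion_aware
        self.contig_names = list(contigs)
        parts, offsets = [], []
        cursor = 0
        for name in self.contig_names:
            if len(contigs[name]) == 0:
                raise ValueError(f"contig {name!r} has zero length")
            offsets.append(cursor)
            arr = encode(contigs[name])
            parts.append(arr)
            parts.append(np.array([_SEP]))
            cursor += arr.size + 1
        self.concat = np.concatenate(parts)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.array([len(contigs[n]) for n in self.contig_names], dtype=np.int64)
        self.index = _CodeIndex(self.concat, k)
        if conversion_aware:
            self.index_tc = _CodeIndex(_collapse(self.concat, T, C), k)
            self.index_ag = _CodeIndex(_collapse(self.concat, A, G), k)
        self._pow = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)

    # -- helpers ----------------------------------------------------------

    def locate(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.offsets, gpos, side="right") - 1)
        return self.contig_names[ci], int(gpos - self.offsets[ci])

    def _seed_codes(self, q: np.ndarray, starts: np.ndarray) -> np.ndarray:
        k = self.k
        mat = np.stack([q[s : s + k] for s in starts]).astype(np.uint64)
        return (mat * self._pow).sum(axis=1)

    def _candidates(self, q: np.ndarray) -> np.ndarray:
        L = q.size
        n_seg = min(self.max_mismatches + 1, L // self.k)
        if n_seg < 1:
            return np.empty(0, dtype=np.int64)
        seg_starts = (np.arange(n_seg) * L) // n_seg
        cands: list[np.ndarray] = []
        if self.conversion_aware:
            # the collapsed indexes subsume exact matches, so the primary
            # index is redundant here
            queries = [
                (self.index_tc, _collapse(q, T, C)),
                (self.index_ag, _collapse(q, A, G)),
            ]
        else:
            queries = [(self.index, q)]
        for index, qq in queries:
            codes = self._seed_codes(qq, seg_starts)
            for code, s in zip(codes, seg_starts):
                hits = index.lookup(code)
                if hits.size:
                    cands.append(hits - s)
        if not cands:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(cands))

    def _verify(self, q: np.ndarray, g: int) -> int:
        """Mismatch count of q placed at global position g, or -1."""
        L = q.size
        if g < 0 or g + L > self.concat.size:
            return -1
        a = self.concat[g : g + L]
        if (a == _SEP).any():
            return -1
        diff = a != q
        if self.conversion_aware:
            diff &= ~(((a == T) & (q == C)) | ((a == A) & (q == G)))
        mm = int(diff.sum())
        return mm if mm <= self.max_mismatches else -1

    # -- public API -------------------------------------------------------

    def align_sequence(
        self, seq: str | np.ndarray, best_only: bool = True
    ) -> list[tuple[str, int, str, int, tuple]]:
        """Placements of one sequence on both strands.

        With ``best_only`` (the default) only the minimal-mismatch stratum
        is reported (bowtie ``--best --strata`` semantics); otherwise every
        placement within the mismatch budget is returned, which is the
        notion of uniqueness the mappability track uses.  Returns (contig,
        start, strand, n_mismatches, mismatch triples) tuples; the empty
        list means unaligned.
        """
        q_fwd = encode(seq) if isinstance(seq, str) else seq
        q_rev = revcomp_codes(q_fwd)
        placements: list[tuple[int, str, int]] = []
        for q, strand in ((q_fwd, "+"), (q_rev, "-")):
            for g in self._candidates(q):
                mm = self._verify(q, int(g))
                if mm >= 0:
                    placements.append((int(g), strand, mm))
        if not placements:
            return []
        best = min(mm for _g, _s, mm in placements)
        out = []
        for g, strand, mm in placements:
            if best_only and mm != best:
                continue
            q = q_fwd if strand == "+" else q_rev
            a = self.concat[g : g + q.size]
            diff = a != q
            if self.conversion_aware:
                # report conversion-type substitutions as mismatches too:
                # downstream conversion counting consumes them
                diff = a != q
            idx = np.flatnonzero(diff)
            contig, local = self.locate(g)
            mism = tuple(
                (int(local + i), decode(a[i : i + 1]), decode(q[i : i + 1]))
                for i in idx
            )
            out.append((contig, local, strand, mm, mism))
        return out

    def align_fragments(
        self,
        sequences: Sequence[str | np.ndarray],
        sources: Sequence[str] | None = None,
    ) -> list[AlignedFragment]:
        """Align many fragment sequences; unaligned fragments are dropped.

        Raises on an empty input set.  Records are grouped by fragment in
        input order; NH is the placement count of the fragment.
        """
        if len(sequences) == 0:
            raise ValueError("empty read set")
        out: list[AlignedFragment] = []
        for i, seq in enumerate(sequences):
            placements = self.align_sequence(seq)
            if not placements:
                continue
            nh = len(placements)
            src = sources[i] if sources is not None else None
            for contig, start, strand, _mm, mism in placements:
                out.append(
                    AlignedFragment(
                        fragment_id=i,
                        contig=contig,
                        start=start,
                        end=start + (len(seq) if isinstance(seq, str) else seq.size),
                        strand=strand,
                        nh=nh,
                        mismatches=mism,
                        source=src,
                    )
                )
        return out


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------


@dataclass
class SignalTrack:
    """Per-contig multimapper-weighted RPM vectors for one library."""

    values: dict[str, np.ndarray]  # RPM units
    library_size: float  # |R|: mapped fragments, each counted once

    def coverage(self) -> dict[str, np.ndarray]:
        """Weighted coverage in fragment units (RPM * |R| / 1e6)."""
        f = self.library_size / 1e6
        return {c: v * f for c, v in self.values.items()}

    def total_weighted_bp(self) -> float:
        return float(sum(v.sum() for v in self.coverage().values()))


@dataclass
class MappabilityTrack:
    values: dict[str, np.ndarray]  # RC/RL in [0, 1]
    read_length: int


def weighted_signal_track(
    alignments: Sequence[AlignedFragment],
    contig_lengths: Mapping[str, int],
    mode: str = "all",
) -> SignalTrack:
    """Multimapper-weighted RPM track.

    ``mode="all"`` spreads each fragment over its locations with weight
    1/NH; ``mode="unique"`` drops NH > 1 fragments entirely.  |R| counts
    each retained fragment once.
    """
    if mode not in ("all", "unique"):
        raise ValueError("mode must be 'all' or 'unique'")
    if mode == "unique":
        alignments = [a for a in alignments if a.nh == 1]
    if not alignments:
        raise ValueError("no mapped fragments: |R| = 0")
    diffs = {c: np.zeros(n + 1, dtype=np.float64) for c, n in contig_lengths.items()}
    lib = 0.0
    for a in alignments:
        w = a.weight
        diffs[a.contig][a.start] += w
        diffs[a.contig][a.end] -= w
        lib += w
    values = {c: np.cumsum(d[:-1]) / (lib / 1e6) for c, d in diffs.items()}
    return SignalTrack(values=values, library_size=lib)


def mappability_track(
    contigs: Mapping[str, str] | ToyGenome,
    read_length: int = 75,
    max_mismatches: int = 2,
    k: int = 12,
) -> MappabilityTrack:
    """Tile a read at every start, remap, and score positions by RC/RL.

    A tiling read is "unique" when it maps to its origin and nowhere else
    within the mismatch budget.  A position's value is the fraction of the
    ``read_length`` tiling reads covering it that are unique, so interior
    positions of repeat-free sequence score 1.0 and the final RL - 1
    positions of each contig are reduced by the edge effect.
    """
    if isinstance(contigs, ToyGenome):
        contigs = contigs.assembly_view
    min_len = min(len(s) for s in contigs.values())
    if read_length > min_len:
        raise ValueError("read_length exceeds the shortest contig")
    aligner = MultimapAligner(contigs, k=k, max_mismatches=max_mismatches)
    values: dict[str, np.ndarray] = {}
    for ci, (cname, seq) in enumerate(contigs.items()):
        arr = encode(seq)
        n_reads = arr.size - read_length + 1
        unique = np.zeros(n_reads, dtype=np.float64)
        for p in range(n_reads):
            placements = aligner.align_sequence(
                arr[p : p + read_length], best_only=False
            )
            if len(placements) == 1:
                c0, s0, _strand, _mm, _m = placements[0]
                if c0 == cname and s0 == p:
                    unique[p] = 1.0
        rc = np.convolve(unique, np.ones(read_length), mode="full")
        values[cname] = rc / read_length
    return MappabilityTrack(values=values, read_length=read_length)


def composition_stats(
    alignments: Sequence[AlignedFragment],
    genome_of: Mapping[str, str],
) -> dict:
    """Library composition over a joint multi-genome index.

    Genome fractions are computed over fragments whose best alignments are
    confined to a single genome; fragments with equally-best hits in more
    than one genome are counted separately as ambiguous.  The multimapper
    fraction is NH > 1 fragments over all mapped fragments.
    """
    if not alignments:
        raise ValueError("zero mapped fragments")
    genomes_by_frag: dict[int, set] = {}
    nh_by_frag: dict[int, int] = {}
    for a in alignments:
        genomes_by_frag.setdefault(a.fragment_id, set()).add(genome_of[a.contig])
        nh_by_frag[a.fragment_id] = a.nh
    counts: dict[str, int] = {}
    ambiguous = 0
    for fid, gset in genomes_by_frag.items():
        if len(gset) == 1:
            g = next(iter(gset))
            counts[g] = counts.get(g, 0) + 1
        else:
            ambiguous += 1
    n_mapped = len(genomes_by_frag)
    n_confined = n_mapped - ambiguous
    multi = sum(1 for nh in nh_by_frag.values() if nh > 1)
    return {
        "genome_fractions": {g: c / n_confined for g, c in sorted(counts.items())},
        "ambiguous_fraction": ambiguous / n_mapped,
        "multimapper_fraction": multi / n_mapped,
        "n_fragments": n_mapped,
    }


def fragment_length_histogram(
    alignments: Sequence[AlignedFragment],
    mode: str = "all",
) -> pd.Series:
    """Integer fragment-length counts (one entry per fragment).

    ``mode="unique"`` restricts to NH = 1 fragments; ``"multi"`` to NH > 1.
    """
    if mode not in ("all", "unique", "multi"):
        raise ValueError("mode must be 'all', 'unique' or 'multi'")
    seen: dict[int, int] = {}
    for a in alignments:
        if mode == "unique" and a.nh != 1:
            continue
        if mode == "multi" and a.nh == 1:
            continue
        seen.setdefault(a.fragment_id, a.length)
    if not seen:
        return pd.Series(dtype=np.int64)
    lengths = np.fromiter(seen.values(), dtype=np.int64)
    counts = np.bincount(lengths)
    return pd.Series(counts, index=np.arange(counts.size), name="count")


def truth_alignments(
    frags: Sequence,
    genomes: Mapping[str, ToyGenome] | ToyGenome,
) -> list[AlignedFragment]:
    """Lift simulated fragments to unique truth alignments (NH = 1).

    Conversion events become reference-space mismatch triples so that
    downstream conversion counting can run on simulator truth without the
    alignment step.
    """
    if isinstance(genomes, ToyGenome):
        genomes = {"target": genomes, "spike": genomes}
    out = []
    for i, fr in enumerate(frags):
        mism: tuple = ()
        if fr.converted is not None and len(fr.converted):
            g = genomes[fr.source]
            seq = g.encoded(fr.contig)
            triples = []
            for pos in fr.converted:
                ref = decode(seq[pos : pos + 1])
                triples.append((int(pos), ref, "C" if ref == "T" else "G"))
            mism = tuple(triples)
        out.append(
            AlignedFragment(
                fragment_id=i,
                contig=fr.contig,
                start=fr.start,
                end=fr.end,
                strand=fr.strand,
                nh=1,
                mismatches=mism,
                source=fr.source,
            )
        )
    return out


def unique_alignments(alignments: Iterable[AlignedFragment]) -> list[AlignedFragment]:
    return [a for a in alignments if a.nh == 1]
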