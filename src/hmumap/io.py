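"""File formats: FASTA, BED6, bedGraph, FASTQ, SAM, bundle manifests.

All interval output is 0-based half-open (BED convention).  bedGraph values
are written with fixed 6-decimal formatting and zero runs are omitted, so a
round trip reconstructs the dense per-base array exactly at that precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    Footprint,
    GenomeConfig,
    ModificationMap,
    OccupancyMap,
    RepeatInstance,
    ToyGenome,
)

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_genome_bundle",
    "read_genome_bundle",
    "write_fragments_fastq",
    "write_fragments_sam",
    "read_sam_alignments",
    "write_sam_alignments",
]


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(
    intervals: Iterable[tuple], path: str | Path, with_strand: bool = True
) -> None:
    """Write (contig, start, end, name[, score[, strand]]) tuples as BED6."""
    with open(path, "w") as fh:
        for iv in intervals:
            contig, start, end, name = iv[0], iv[1], iv[2], iv[3]
            score = iv[4] if len(iv) > 4 else 0
            strand = iv[5] if len(iv) > 5 else "."
            if with_strand:
                fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
            else:
                fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            rest = parts[3:]
            if len(rest) >= 2:
                rest[1] = float(rest[1]) if "." in rest[1] else int(rest[1])
            out.append((contig, start, end, *rest))
    return out


def write_bedgraph(values: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encode dense per-base arrays; zero runs are omitted."""
    with open(path, "w") as fh:
        for contig, arr in values.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0.0:
                    continue
                fh.write(f"{contig}\t{s}\t{e}\t{v:.6f}\n")


def read_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    out = {c: np.zeros(n, dtype=np.float32) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, s, e, v = line.split("\t")
            out[contig][int(s) : int(e)] = np.float32(v)
    return out


# ---------------------------------------------------------------------------
# Genome bundle
# ---------------------------------------------------------------------------


def write_genome_bundle(
    genome: ToyGenome,
    mod_map: ModificationMap | None,
    occ_map: OccupancyMap | None,
    outdir: str | Path,
) -> dict:
    """Emit the toy genome plus truth maps to ``outdir``; returns the manifest.

    Files: truth and assembly FASTA, BED6 annotations (gene starts with
    strand, boundaries as 1-bp intervals, repeats with ``family;cn=k`` in the
    name field), strand-split modification bedGraphs, occupancy bedGraph,
    footprint BED, repeat consensus FASTA and a JSON manifest recording the
    seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def reg(key: str, fname: str) -> Path:
        files[key] = fname
        return outdir / fname

    write_fasta(genome.truth_view, reg("truth_fasta", "truth.fa"))
    write_fasta(genome.assembly_view, reg("assembly_fasta", "assembly.fa"))
    write_fasta(genome.consensus, reg("consensus_fasta", "repeat_consensus.fa"))

    write_bed(
        [(c, p, p + 1, f"gene_{i}", 0, s) for i, (c, p, s) in enumerate(genome.gene_starts)],
        reg("gene_starts_bed", "gene_starts.bed"),
    )
    write_bed(
        [(c, p, p + 1, f"boundary_{i}", 0, ".") for i, (c, p) in enumerate(genome.boundaries)],
        reg("boundaries_bed", "boundaries.bed"),
    )
    write_bed(
        [
            (ri.contig, ri.start, ri.end, f"{ri.family};cn={ri.copy_number}", 0, "+")
            for ri in genome.repeat_instances
        ],
        reg("repeats_bed", "repeats.bed"),
    )

    if mod_map is not None:
        write_bedgraph(mod_map.p_plus, reg("modification_plus", "modification_plus.bedgraph"))
        write_bedgraph(mod_map.p_minus, reg("modification_minus", "modification_minus.bedgraph"))
    if occ_map is not None:
        write_bedgraph(occ_map.occupancy, reg("occupancy", "occupancy.bedgraph"))
        write_bed(
            [
                (fp.contig, fp.start, fp.end, f"fp_{i}", int(round(fp.strength * 1000)), ".")
                for i, fp in enumerate(occ_map.footprints)
            ],
            reg("footprints_bed", "footprints.bed"),
        )

    manifest = {
        "files": files,
        "assembly_contigs": list(genome.assembly_contigs),
        "seed": genome.config.seed if genome.config else None,
        "mod_params": None
        if mod_map is None
        else {
            "p0": mod_map.p0,
            "p_boundary": mod_map.p_boundary,
            "p_repeat": mod_map.p_repeat,
            "w_b": mod_map.w_b,
        },
        "occ_params": None
        if occ_map is None
        else {"gamma": occ_map.gamma, "fp_w": occ_map.fp_w},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_genome_bundle(
    outdir: str | Path,
) -> tuple[ToyGenome, ModificationMap | None, OccupancyMap | None]:
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    files = manifest["files"]

    contigs = read_fasta(outdir / files["truth_fasta"])
    consensus = read_fasta(outdir / files["consensus_fasta"])
    gene_starts = [
        (c, s, strand)
        for c, s, _e, _name, _score, strand in read_bed(outdir / files["gene_starts_bed"])
    ]
    boundaries = [
        (c, s) for c, s, _e, *_rest in read_bed(outdir / files["boundaries_bed"])
    ]
    repeats = []
    for c, s, e, name, *_rest in read_bed(outdir / files["repeats_bed"]):
        fam, cn = name.split(";cn=")
        repeats.append(RepeatInstance(c, s, e, fam, int(cn)))

    genome = ToyGenome(
        contigs=contigs,
        assembly_contigs=tuple(manifest["assembly_contigs"]),
        gene_starts=gene_starts,
        boundaries=boundaries,
        repeat_instances=repeats,
        consensus=consensus,
    )

    lengths = genome.contig_lengths()
    mod_map = None
    if manifest["mod_params"] is not None:
        mp = manifest["mod_params"]
        mod_map = ModificationMap(
            p_plus=read_bedgraph(outdir / files["modification_plus"], lengths),
            p_minus=read_bedgraph(outdir / files["modification_minus"], lengths),
            p0=mp["p0"],
            p_boundary=mp["p_boundary"],
            p_repeat=mp["p_repeat"],
            w_b=mp["w_b"],
        )
    occ_map = None
    if manifest["occ_params"] is not None:
        op = manifest["occ_params"]
        fps = [
            Footprint(c, (s + e) // 2, e - s, score / 1000.0)
            for c, s, e, _name, score, _strand in read_bed(outdir / files["footprints_bed"])
        ]
        occ_map = OccupancyMap(
            occupancy=read_bedgraph(outdir / files["occupancy"], lengths),
            footprints=fps,
            gamma=op["gamma"],
            fp_w=op["fp_w"],
        )
    return genome, mod_map, occ_map


# ---------------------------------------------------------------------------
# Reads: FASTQ / SAM
# ---------------------------------------------------------------------------


def _fragment_read_pair(seq: str, read_length: int) -> tuple[str, str]:
    r1 = seq[:read_length]
    r2 = str(Seq(seq[-read_length:]).reverse_complement())
    return r1, r2


def write_fragments_fastq(
    sequences: Sequence[str],
    path_r1: str | Path,
    path_r2: str | Path,
    read_length: int = 75,
    name_prefix: str = "frag",
) -> None:
    """Paired 2 x ``read_length`` reads truncated from fragment sequences;
    fragments shorter than the read length are sequenced fully."""
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for i, seq in enumerate(sequences):
            r1, r2 = _fragment_read_pair(seq, read_length)
            f1.write(f"@{name_prefix}_{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name_prefix}_{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def _sam_header(contig_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
        }
    )


def write_fragments_sam(
    fragments: Sequence,
    sequences: Sequence[str],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """True-origin SAM for simulated fragments (tags: XS source genome,
    XO origin strand).  NH is deliberately left unset here; it is an
    alignment-time quantity."""
    header = _sam_header(contig_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, (frag, seq) in enumerate(zip(fragments, sequences)):
            a = pysam.AlignedSegment(header)
            a.query_name = f"frag_{i}"
            # SAM stores SEQ in reference orientation; sequences arrive in
            # molecule orientation
            if frag.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            a.query_sequence = seq
            a.reference_name = frag.contig
            a.reference_start = frag.start
            a.cigarstring = f"{frag.end - frag.start}M"
            a.mapping_quality = 255
            a.flag = 16 if frag.strand == "-" else 0
            a.set_tag("XS", frag.source)
            a.set_tag("XO", frag.strand)
            out.write(a)


def write_sam_alignments(
    alignments: Sequence,
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write AlignedFragment records with NH tags (sequence omitted)."""
    header = _sam_header(contig_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            a = pysam.AlignedSegment(header)
            a.query_name = f"frag_{aln.fragment_id}"
            a.reference_name = aln.contig
            a.reference_start = aln.start
            a.cigarstring = f"{aln.end - aln.start}M"
            a.mapping_quality = 255
            a.flag = 16 if aln.strand == "-" else 0
            a.set_tag("NH", aln.nh)
            if aln.source is not None:
                a.set_tag("XS", aln.source)
            out.write(a)


def read_sam_alignments(path: str | Path) -> list:
    """Read a SAM written by :func:`write_sam_alignments` back into
    AlignedFragment records (mismatch lists are not round-tripped)."""
    from .align import AlignedFragment

    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            frag_id = int(rec.query_name.rsplit("_", 1)[1])
            out.append(
                AlignedFragment(
                    fragment_id=frag_id,
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    nh=rec.get_tag("NH") if rec.has_tag("NH") else 1,
                    mismatches=(),
                    source=rec.get_tag("XS") if rec.has_tag("XS") else None,
                )
            )
    return out
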