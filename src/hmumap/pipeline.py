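"""End-to-end demonstration pipeline on a scaled-down synthetic genome.

Generates a genome bundle, simulates the four library types, aligns them to
the assembly, and emits the derived products (weighted signal tracks,
conversion-rate bins, boundary metaprofiles, bin correlations, repeat-space
enrichment, footprint calls, V-plot matrix, overlap report).  Every output
is a text file; the returned manifest maps file names to SHA-256 digests so
reproducibility is a single dictionary comparison.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .align import (
    MultimapAligner,
    truth_alignments,
    weighted_signal_track,
)
from .conversion import binned_conversion_rate, count_site_conversions
from .genome import (
    GenomeConfig,
    build_modification_map,
    build_occupancy_map,
    generate_genome,
)
from .meta import (
    binned_correlation,
    enrichment_domains,
    feature_overlap_sets,
    metaprofile,
    repeat_space_profile,
)
from .nucleosomes import call_positioned_nucleosomes, vplot
from .simulate import (
    LibraryConfig,
    fragment_sequences,
    make_spike_genome,
    simulate_atac_fragments,
    simulate_conversion_reads,
    simulate_gdna_fragments,
    simulate_medip_libraries,
)

DEFAULT_P_REPEAT = {
    "MaverickSim": 0.45,
    "CopiaSimLTR": 0.15,
    "SatSim": 0.10,
    "CollapsedSim": 0.10,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    n_atac: int = 30_000,
    n_gdna: int = 30_000,
    n_medip: int = 20_000,
    n_conv: int = 15_000,
    genome_config: GenomeConfig | None = None,
) -> dict[str, str]:
    """Run the whole analysis on a small simulated data set.

    Returns {relative file name: sha256}; identical seeds produce
    byte-identical output directories.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    cfg = genome_config or GenomeConfig(
        n_contigs=2, contig_length=150_000, array_length_mean=15_000, seed=seed
    )
    genome = generate_genome(cfg)
    mod = build_modification_map(genome, p_repeat=DEFAULT_P_REPEAT)
    occ = build_occupancy_map(genome, mod, seed=seed)
    hio.write_genome_bundle(genome, mod, occ, out / "bundle")

    lengths = genome.contig_lengths(assembly_only=True)
    spike = make_spike_genome()
    genomes = {"target": genome, "spike": spike}

    gdna = simulate_gdna_fragments(genome, LibraryConfig(n_fragments=n_gdna, seed=seed + 1))
    atac = simulate_atac_fragments(genome, occ, LibraryConfig(n_fragments=n_atac, seed=seed + 2))
    medip = simulate_medip_libraries(
        genome, spike, mod,
        LibraryConfig(n_fragments=n_medip, seed=seed + 3, spike_fraction=0.5),
        beta=0.08,
    )
    conv = simulate_conversion_reads(
        genome, mod, LibraryConfig(n_fragments=n_conv, seed=seed + 4), "harsh"
    )

    aligner = MultimapAligner(genome.assembly_view)
    gdna_aln = aligner.align_fragments(fragment_sequences(genomes, gdna))
    atac_aln = aligner.align_fragments(fragment_sequences(genomes, atac))
    ip_aln = aligner.align_fragments(fragment_sequences(genomes, medip["ip"]))
    conv_aln = truth_alignments(conv, genome)

    hio.write_fragments_sam(
        atac, fragment_sequences(genomes, atac), genome.contig_lengths(), out / "atac_truth.sam"
    )
    hio.write_sam_alignments(atac_aln, lengths, out / "atac_aligned.sam")

    gdna_tr = weighted_signal_track(gdna_aln, lengths)
    atac_tr = weighted_signal_track(atac_aln, lengths)
    ip_tr = weighted_signal_track(ip_aln, lengths)
    hio.write_bedgraph(atac_tr.values, out / "atac_rpm.bedgraph")
    hio.write_bedgraph(gdna_tr.values, out / "gdna_rpm.bedgraph")
    hio.write_bedgraph(ip_tr.values, out / "medip_ip_rpm.bedgraph")

    # boundary metaprofiles
    prof_rows = []
    for name, tr in (("atac", atac_tr), ("medip_ip", ip_tr), ("gdna", gdna_tr)):
        prof = metaprofile(tr, genome.boundaries, W=10_000, binwidth=2_000)
        for off, val in zip(prof.offsets, prof.values):
            prof_rows.append((name, int(off), float(val)))
    pd.DataFrame(prof_rows, columns=["track", "offset", "rpm"]).to_csv(
        out / "boundary_metaprofiles.tsv", sep="\t", index=False, float_format="%.6f"
    )

    corr = binned_correlation(atac_tr, ip_tr, boundaries=genome.boundaries)
    with open(out / "bin_correlation.json", "w") as fh:
        json.dump(
            {
                k: {"pearson_r": v.pearson_r, "spearman_rho": v.spearman_rho, "n": v.n_bins}
                for k, v in corr.items()
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    domains = enrichment_domains(atac_tr, gdna_tr)
    domains.drop(columns=["t", "lam"]).to_csv(
        out / "atac_domains.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # conversion bins
    table = count_site_conversions(conv_aln, genome.assembly_view)
    bins = binned_conversion_rate(table)
    bins.to_csv(out / "conversion_bins.tsv", sep="\t", index=False, float_format="%.6f")

    # repeat space (subsampled for speed)
    rs = repeat_space_profile(
        fragment_sequences(genomes, medip["ip"][: min(len(medip["ip"]), 5_000)]),
        genome.consensus,
        fragment_sequences(genomes, medip["input"][:5_000]),
    )
    rs.to_csv(out / "medip_repeat_space.tsv", sep="\t", index=False, float_format="%.6f")

    # footprint calls + V-plot
    calls = call_positioned_nucleosomes(atac_aln, lengths)
    hio.write_bed(
        [
            (r.contig, int(r.center), int(r.center) + 1, r.resolution,
             int(round(r.occupancy * 1000)), ".")
            for r in calls.itertuples()
        ],
        out / "nucleosome_calls.bed",
    )
    if len(calls):
        vp = vplot(atac_aln, [(r.contig, int(r.center)) for r in calls.itertuples()], W=100)
        np.savetxt(out / "vplot_matrix.tsv", vp.matrix, fmt="%d", delimiter="\t")

    # overlap report
    dep = domains[domains["sign"] == -1][["contig", "start", "end"]].itertuples(index=False)
    mav = [
        (ri.contig, ri.start, ri.end)
        for ri in genome.repeat_instances
        if ri.family == "MaverickSim" and ri.contig in genome.assembly_contigs
    ]
    high_bins = bins[bins["rate"] > bins["rate"].quantile(0.95)]
    overlap = feature_overlap_sets(
        genome.boundaries,
        [tuple(r) for r in dep],
        [(r.contig, int(r.start), int(r.end)) for r in high_bins.itertuples()],
        mav,
        slop=2_000,
    )
    with open(out / "overlap_report.json", "w") as fh:
        json.dump(overlap, fh, indent=2, sort_keys=True)

    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "checksums.json"
    }
    with open(out / "checksums.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
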