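"""Aligner, weighted signal, mappability, composition, length histograms."""

import numpy as np
import pandas as pd
import pytest

from hmumap.align import (
    AlignedFragment,
    MultimapAligner,
    composition_stats,
    fragment_length_histogram,
    mappability_track,
    weighted_signal_track,
)
from hmumap.genome import decode, encode, revcomp_codes, _random_sequence
from hmumap.simulate import (
    LibraryConfig,
    fragment_sequences,
    simulate_gdna_fragments,
)


@pytest.fixture(scope="module")
def dup_contig():
    """6-kbp random contig with one exact 400-bp internal duplication."""
    rng = np.random.default_rng(42)
    arr = _random_sequence(rng, 6_000, 0.44)
    arr[4_000:4_400] = arr[1_000:1_400]
    return arr


def test_unique_read_single_alignment(dup_contig):
    al = MultimapAligner({"c": decode(dup_contig)}, k=8)
    read = decode(dup_contig[2_000:2_075])
    placements = al.align_sequence(read)
    assert len(placements) == 1
    contig, start, strand, mm, _ = placements[0]
    assert (contig, start, strand, mm) == ("c", 2_000, "+", 0)


def test_repeat_read_reports_both_loci(dup_contig):
    al = MultimapAligner({"c": decode(dup_contig)}, k=8)
    read = decode(dup_contig[1_100:1_175])  # wholly inside the duplication
    placements = al.align_sequence(read)
    starts = sorted(p[1] for p in placements)
    assert starts == [1_100, 4_100]
    alns = al.align_fragments([read])
    assert all(a.nh == 2 for a in alns)


def test_reverse_strand_alignment(dup_contig):
    al = MultimapAligner({"c": decode(dup_contig)}, k=8)
    read = decode(revcomp_codes(dup_contig[3_000:3_075].copy()))
    ((contig, start, strand, mm, _),) = al.align_sequence(read)
    assert (start, strand, mm) == (3_000, "-", 0)


def test_mismatches_reported_in_reference_space(dup_contig):
    al = MultimapAligner({"c": decode(dup_contig)}, k=8)
    arr = dup_contig[2_500:2_575].copy()
    ref_base = decode(arr[40 : 41])
    arr[40] = (arr[40] + 1) % 4
    ((contig, start, strand, mm, mism),) = al.align_sequence(decode(arr))
    assert mm == 1 and len(mism) == 1
    pos, ref, read = mism[0]
    assert pos == 2_540 and ref == ref_base


def test_empty_read_set_rejected(dup_contig):
    al = MultimapAligner({"c": decode(dup_contig)}, k=8)
    with pytest.raises(ValueError, match="empty"):
        al.align_fragments([])


def test_weight_normalization_per_fragment(genome7, aligner7):
    frags = simulate_gdna_fragments(genome7, LibraryConfig(n_fragments=2_000, seed=13))
    alns = aligner7.align_fragments(fragment_sequences(genome7, frags))
    weights: dict[int, float] = {}
    for a in alns:
        weights[a.fragment_id] = weights.get(a.fragment_id, 0.0) + a.weight
    assert all(abs(w - 1.0) < 1e-9 for w in weights.values())


def test_signal_track_unit_case():
    aln = AlignedFragment(0, "c", 5, 15, "+", nh=1)
    track = weighted_signal_track([aln], {"c": 30})
    expected = np.zeros(30)
    expected[5:15] = 1e6
    np.testing.assert_allclose(track.values["c"], expected)


def test_signal_track_matches_per_position_oracle(dup_contig):
    """Multimapper-weighted track equals an exhaustive per-position sum."""
    rng = np.random.default_rng(5)
    al = MultimapAligner({"c": decode(dup_contig)}, k=8)
    starts = rng.integers(0, 5_900, size=80)
    seqs = [decode(dup_contig[s : s + rng.integers(40, 100)]) for s in starts]
    alns = al.align_fragments(seqs)
    track = weighted_signal_track(alns, {"c": 6_000})
    # |R| counts each fragment once = the sum of all alignment weights
    assert track.library_size == pytest.approx(len({a.fragment_id for a in alns}))
    # brute force: loop alignments per position
    oracle = np.zeros(6_000)
    for a in alns:
        for i in range(a.start, a.end):
            oracle[i] += a.weight
    np.testing.assert_allclose(
        track.values["c"] * track.library_size / 1e6, oracle, atol=1e-9
    )


def test_signal_track_conservation(atac200k_aligned, genome7):
    track = weighted_signal_track(
        atac200k_aligned, genome7.contig_lengths(assembly_only=True)
    )
    total_bp = track.total_weighted_bp()
    frag_lengths = {a.fragment_id: a.length for a in atac200k_aligned}
    assert total_bp == pytest.approx(sum(frag_lengths.values()), rel=1e-9)


def test_signal_track_rpm_invariant_under_duplication(dup_contig):
    al = MultimapAligner({"c": decode(dup_contig)}, k=8)
    seqs = [decode(dup_contig[s : s + 60]) for s in (100, 900, 1_150, 2_700)]
    alns = al.align_fragments(seqs)
    doubled = alns + [
        AlignedFragment(a.fragment_id + 10, a.contig, a.start, a.end, a.strand, a.nh)
        for a in alns
    ]
    t1 = weighted_signal_track(alns, {"c": 6_000})
    t2 = weighted_signal_track(doubled, {"c": 6_000})
    np.testing.assert_allclose(t1.values["c"], t2.values["c"], atol=1e-9)


def test_collapsed_family_coverage_doubles(genome7, aligner7):
    """Reads from a 2-copy family align onto the single assembly copy."""
    frags = simulate_gdna_fragments(genome7, LibraryConfig(n_fragments=60_000, seed=14))
    alns = aligner7.align_fragments(fragment_sequences(genome7, frags))
    track = weighted_signal_track(alns, genome7.contig_lengths(assembly_only=True))
    ratios = []
    for ri in genome7.repeat_instances:
        if ri.family != "CollapsedSim" or ri.contig not in genome7.assembly_contigs:
            continue
        local = track.values[ri.contig][ri.start : ri.end].mean()
        flank = track.values[ri.contig][ri.start - 3_000 : ri.start].mean()
        ratios.append(local / flank)
    assert 1.5 < np.mean(ratios) < 2.5


def test_mappability_repeat_free_interior_is_one():
    rng = np.random.default_rng(6)
    contig = decode(_random_sequence(rng, 3_000, 0.5))
    track = mappability_track({"c": contig}, read_length=25, max_mismatches=0, k=8)
    vals = track.values["c"]
    assert (vals[24:-24] == 1.0).all()
    # edge effect: the last RL-1 positions are covered by < RL tiling reads
    assert (vals[-24:] < 1.0).all() and vals[-1] == pytest.approx(1 / 25)


def test_mappability_zero_inside_duplication(dup_contig):
    track = mappability_track({"c": decode(dup_contig)}, read_length=25, max_mismatches=0, k=8)
    vals = track.values["c"]
    # positions covered only by reads fully inside a duplicated copy get 0
    assert (vals[1_050:1_350] == 0.0).all()
    assert vals[2_000] == 1.0


def test_mappability_reverse_complement_symmetry():
    rng = np.random.default_rng(8)
    arr = _random_sequence(rng, 2_000, 0.44)
    arr[1_500:1_600] = arr[200:300]
    fwd = mappability_track({"c": decode(arr)}, 25, 0, k=8).values["c"]
    rev = mappability_track({"c": decode(revcomp_codes(arr))}, 25, 0, k=8).values["c"]
    np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)


def test_composition_even_mixture(genome7, spike_genome, aligner7):
    from hmumap.align import truth_alignments

    frags = simulate_gdna_fragments(
        genome7, LibraryConfig(n_fragments=20_000, seed=15, spike_fraction=0.5), spike_genome
    )
    alns = truth_alignments(frags, {"target": genome7, "spike": spike_genome})
    genome_of = {c: "target" for c in genome7.contigs}
    genome_of["spike_1"] = "spike"
    stats = composition_stats(alns, genome_of)
    assert stats["genome_fractions"]["spike"] == pytest.approx(0.5, abs=0.015)
    assert stats["multimapper_fraction"] == 0.0
    with pytest.raises(ValueError, match="zero"):
        composition_stats([], genome_of)


def test_length_histogram_partition(atac200k_truth):
    h_all = fragment_length_histogram(atac200k_truth, "all")
    h_uni = fragment_length_histogram(atac200k_truth, "unique")
    h_mul = fragment_length_histogram(atac200k_truth, "multi")
    combined = h_uni.reindex(h_all.index, fill_value=0) + h_mul.reindex(
        h_all.index, fill_value=0
    )
    pd.testing.assert_series_equal(h_all, combined, check_names=False, check_dtype=False)
    assert h_all.reindex([5]).fillna(0).iloc[0] == 0  # absent length -> 0


def test_conversion_aware_alignment_recovers_truth_rate(small_flat_genome):
    from hmumap.align import truth_alignments
    from hmumap.conversion import count_site_conversions, genome_wide_rate
    from hmumap.genome import build_modification_map
    from hmumap.simulate import simulate_conversion_reads

    g = small_flat_genome
    mod = build_modification_map(g, p0=0.2, p_boundary=0.2)
    frags = simulate_conversion_reads(g, mod, LibraryConfig(n_fragments=8_000, seed=16), "harsh")
    truth_rate = genome_wide_rate(
        count_site_conversions(truth_alignments(frags, g), g.assembly_view)
    )
    al = MultimapAligner(g.assembly_view, conversion_aware=True)
    alns = al.align_fragments(fragment_sequences(g, frags))
    mapped = len({a.fragment_id for a in alns})
    assert mapped / len(frags) > 0.99
    aligned_rate = genome_wide_rate(count_site_conversions(alns, g.assembly_view))
    assert aligned_rate == pytest.approx(truth_rate, rel=0.02)
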