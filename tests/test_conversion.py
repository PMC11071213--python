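"""Strand-aware conversion counting, binning, site calling, context."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from hmumap.align import AlignedFragment, truth_alignments
from hmumap.conversion import (
    binned_conversion_rate,
    call_modified_sites,
    context_consensus,
    count_site_conversions,
    genome_wide_rate,
)
from hmumap.genome import ModificationMap, build_modification_map, decode, _random_sequence
from hmumap.simulate import LibraryConfig, simulate_conversion_reads


def test_zero_conversion_library_all_rates_zero(small_flat_genome):
    g = small_flat_genome
    mod = build_modification_map(g, p0=0.0, p_boundary=0.0)
    cfg = LibraryConfig(n_fragments=3_000, seed=20, sequencing_error=0.0)
    frags = simulate_conversion_reads(g, mod, cfg, "harsh")
    table = count_site_conversions(truth_alignments(frags, g), g.assembly_view)
    assert genome_wide_rate(table) == 0.0


def test_fully_modified_site_rate_matches_efficiency(small_flat_genome):
    """A site with modification probability 1 converts at the oxidation
    efficiency (binomial sampling around e = 0.8 at ~100x coverage)."""
    g = small_flat_genome
    seq = g.encoded("contig_1")
    site = int(np.flatnonzero(seq == 3)[5_000])  # an arbitrary interior T
    mod = build_modification_map(g, p0=0.0, p_boundary=0.0)
    mod.p_plus["contig_1"][site] = 1.0
    cfg = LibraryConfig(n_fragments=400_000, seed=21, sequencing_error=0.0)
    frags = simulate_conversion_reads(g, mod, cfg, "harsh")
    table = count_site_conversions(truth_alignments(frags, g), g.assembly_view)
    cov = table.cov_plus["contig_1"][site]
    rate = table.conv_plus["contig_1"][site] / cov
    assert cov > 50
    assert abs(rate - 0.8) < 3 * np.sqrt(0.8 * 0.2 / cov)


def test_opposite_strand_coverage_masked():
    contig = {"c": "AAATTTAAATTTAAATTTAA"}
    # one minus-strand fragment: plus-strand T sites get zero coverage
    aln = AlignedFragment(0, "c", 0, 20, "-", nh=1)
    table = count_site_conversions([aln], contig)
    assert table.cov_plus["c"].sum() == 0
    assert table.cov_minus["c"].sum() > 0
    frame = table.frame(min_cov=1)
    assert set(frame["strand"]) == {"-"}


def test_mismatch_outside_fragment_is_integrity_error():
    aln = AlignedFragment(0, "c", 0, 10, "+", nh=1, mismatches=((15, "T", "C"),))
    with pytest.raises(ValueError, match="outside"):
        count_site_conversions([aln], {"c": "ACGT" * 10})


def test_bin_geometry_and_errors():
    rng = np.random.default_rng(0)
    contig = {"c": decode(_random_sequence(rng, 1_000, 0.5))}
    alns = [AlignedFragment(i, "c", 0, 1_000, "+", nh=1) for i in range(20)]
    table = count_site_conversions(alns, contig)
    bins = binned_conversion_rate(table, width=500, step=100)
    assert list(bins["start"]) == [0, 100, 200, 300, 400, 500]
    with pytest.raises(ValueError, match="step"):
        binned_conversion_rate(table, width=100, step=500)


def test_uniform_rate_recovered_in_bins(small_flat_genome):
    g = small_flat_genome
    mod = build_modification_map(g, p0=0.25, p_boundary=0.25)
    frags = simulate_conversion_reads(
        g, mod, LibraryConfig(n_fragments=40_000, seed=22), "harsh"
    )
    table = count_site_conversions(truth_alignments(frags, g), g.assembly_view)
    bins = binned_conversion_rate(table)
    rates = bins["rate"].dropna()
    assert rates.mean() == pytest.approx(0.25 * 0.8, rel=0.05)
    # aggregation equals direct recomputation from per-site counts
    b0 = bins.iloc[0]
    cov = (table.cov_plus["contig_1"] + table.cov_minus["contig_1"])[0:500].sum()
    conv = (table.conv_plus["contig_1"] + table.conv_minus["contig_1"])[0:500].sum()
    assert b0["rate"] == pytest.approx(conv / cov)


def test_boundary_elevated_bins_rank_higher(small_flat_genome):
    g = small_flat_genome
    mod = build_modification_map(g, p0=0.03, p_boundary=0.35, w_b=2_000)
    frags = simulate_conversion_reads(
        g, mod, LibraryConfig(n_fragments=60_000, seed=23), "harsh"
    )
    table = count_site_conversions(truth_alignments(frags, g), g.assembly_view)
    bins = binned_conversion_rate(table).dropna(subset=["rate"])
    bpos = np.array([p for _c, p in g.boundaries])
    centers = (bins["start"] + bins["end"]) // 2
    dist = np.abs(centers.to_numpy()[:, None] - bpos[None, :]).min(axis=1)
    near = bins["rate"][dist < 1_500]
    far = bins["rate"][dist > 5_000]
    assert mannwhitneyu(near, far, alternative="greater").pvalue < 0.01


def _site_frame(rng, n, cov, rate):
    conv = rng.binomial(cov, rate, size=n)
    return pd.DataFrame(
        {
            "contig": "c",
            "pos": np.arange(n),
            "strand": "+",
            "cov": cov,
            "conv": conv,
            "rate": conv / cov,
        }
    )


def test_caller_extreme_site_called():
    df = _site_frame(np.random.default_rng(1), 10, 50, 0.001)
    df.loc[0, "conv"] = 40
    called = call_modified_sites(df, background_rate=0.001, alpha=0.05)
    assert 0 in set(called["pos"])
    with pytest.raises(ValueError, match="background"):
        call_modified_sites(df, background_rate=1.0)


def test_caller_type_I_error_controlled():
    """On 10,000 pure-background sites the called fraction stays at or
    below the nominal FDR."""
    df = _site_frame(np.random.default_rng(2), 10_000, 50, 0.001)
    called = call_modified_sites(df, background_rate=0.001, alpha=0.05)
    assert len(called) / len(df) <= 0.05


def test_caller_power_on_planted_sites():
    rng = np.random.default_rng(3)
    null = _site_frame(rng, 8_000, 50, 0.001)
    alt = _site_frame(rng, 2_000, 50, 0.8)
    alt["pos"] += 10_000
    df = pd.concat([null, alt], ignore_index=True)
    called = call_modified_sites(df, background_rate=0.001, alpha=0.05)
    recall = len(set(called["pos"]) & set(alt["pos"])) / len(alt)
    assert recall >= 0.9


def test_context_single_site_one_hot():
    contig = {"c": "ACGTACGTACGTACGTACGT"}
    df = pd.DataFrame({"contig": ["c"], "pos": [7], "strand": ["+"]})
    ctx = context_consensus(df, contig, k=2)
    assert ctx.n_sites == 1
    assert (ctx.freq.max(axis=1) == 1.0).all()
    np.testing.assert_allclose(ctx.info.to_numpy(), 2.0)
    assert ctx.freq.loc[0, "T"] == 1.0
    with pytest.raises(ValueError, match="empty"):
        context_consensus(df.iloc[0:0], contig, k=2)


def test_context_planted_ta_preference(small_flat_genome):
    """Modified Ts chosen only before A: offset +1 is (almost) pure A."""
    g = small_flat_genome
    seq = g.encoded("contig_1")
    t_before_a = np.flatnonzero((seq[:-1] == 3) & (seq[1:] == 0))
    a_after_t = np.flatnonzero(seq == 0)
    a_after_t = a_after_t[(a_after_t > 0)]
    a_after_t = a_after_t[seq[a_after_t - 1] == 3]  # minus-strand T with next base A
    plus = pd.DataFrame({"contig": "contig_1", "pos": t_before_a[:3000], "strand": "+"})
    minus = pd.DataFrame({"contig": "contig_1", "pos": a_after_t[:3000], "strand": "-"})
    ctx = context_consensus(pd.concat([plus, minus]), g.assembly_view, k=3)
    assert ctx.freq.loc[1, "A"] > 0.999
    assert ctx.info.loc[1] > 1.9
    assert ctx.freq.loc[0, "T"] == 1.0


def test_site_conversion_conservation(small_flat_genome):
    """Counted conversions equal the simulator's emitted events."""
    g = small_flat_genome
    mod = build_modification_map(g, p0=0.2, p_boundary=0.2)
    frags = simulate_conversion_reads(
        g, mod, LibraryConfig(n_fragments=5_000, seed=24), "harsh"
    )
    table = count_site_conversions(truth_alignments(frags, g), g.assembly_view)
    emitted = sum(len(f.converted) for f in frags)
    counted = table.conv_plus["contig_1"].sum() + table.conv_minus["contig_1"].sum()
    assert counted == emitted
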