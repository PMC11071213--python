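"""Metaprofiles, domain calling, binned correlation, overlaps, repeat space."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmumap.align import SignalTrack
from hmumap.meta import (
    binned_correlation,
    boundary_repeat_density,
    enrichment_domains,
    feature_overlap_sets,
    metaprofile,
    repeat_space_profile,
)


def _track(values: dict[str, np.ndarray], lib: float = 1e6) -> SignalTrack:
    return SignalTrack(values={c: np.asarray(v, float) for c, v in values.items()}, library_size=lib)


def test_metaprofile_constant_track_is_flat():
    prof = metaprofile({"c": np.full(20_000, 3.5)}, [("c", 10_000)], W=2_000, binwidth=500)
    np.testing.assert_allclose(prof.values, 3.5)
    assert prof.n_anchors == 1


def test_metaprofile_drops_clipped_windows_and_errors_when_none():
    track = {"c": np.ones(5_000)}
    prof = metaprofile(track, [("c", 100), ("c", 2_500)], W=2_000, binwidth=500)
    assert prof.n_anchors == 1
    with pytest.raises(ValueError, match="anchors"):
        metaprofile(track, [("c", 100)], W=2_000, binwidth=500)


def test_metaprofile_mirrors_minus_anchors():
    arr = np.zeros(10_000)
    arr[6_000:6_500] = 1.0  # feature downstream of position 5000
    plus = metaprofile({"c": arr}, [("c", 5_000, "+")], W=2_000, binwidth=500)
    minus = metaprofile({"c": arr}, [("c", 5_000, "-")], W=2_000, binwidth=500)
    np.testing.assert_allclose(plus.values, minus.values[::-1])
    assert plus.values[np.searchsorted(plus.offsets, 1_250)] > 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a=st.floats(-5, 5, allow_nan=False),
    b=st.floats(-5, 5, allow_nan=False),
    seed=st.integers(0, 100),
)
def test_metaprofile_linearity(a, b, seed):
    rng = np.random.default_rng(seed)
    t1 = rng.random(8_000)
    t2 = rng.random(8_000)
    anchors = [("c", int(p)) for p in rng.integers(2_000, 6_000, size=5)]
    p1 = metaprofile({"c": t1}, anchors, W=1_000, binwidth=250).values
    p2 = metaprofile({"c": t2}, anchors, W=1_000, binwidth=250).values
    p12 = metaprofile({"c": a * t1 + b * t2}, anchors, W=1_000, binwidth=250).values
    np.testing.assert_allclose(p12, a * p1 + b * p2, atol=1e-9)


def _poisson_cov_track(rng, n, rate, lib):
    """Synthetic fragment coverage: lib fragments of length 50, uniform."""
    starts = rng.integers(0, n - 50, size=lib)
    d = np.zeros(n + 1)
    np.add.at(d, starts, 1.0)
    np.add.at(d, starts + 50, -1.0)
    cov = np.cumsum(d[:-1]) * rate
    return SignalTrack({"c": cov / (lib / 1e6)}, library_size=lib)


def test_enrichment_domains_null_type_I():
    rng = np.random.default_rng(9)
    t = _poisson_cov_track(rng, 1_000_000, 1.0, 120_000)
    c = _poisson_cov_track(rng, 1_000_000, 1.0, 120_000)
    _doms, windows = enrichment_domains(t, c, alpha=0.05, return_windows=True)
    assert len(windows) == 2_000
    assert windows["sig"].mean() <= 0.05


def test_enrichment_domains_recovers_planted_depletion():
    rng = np.random.default_rng(10)
    n = 400_000
    starts = rng.integers(0, n - 50, size=80_000)
    # thin fragments inside the depleted block to 1/3
    block = (starts >= 100_000) & (starts < 105_000)
    keep = ~block | (rng.random(starts.size) < 1 / 3)
    starts = starts[keep]
    d = np.zeros(n + 1)
    np.add.at(d, starts, 1.0)
    np.add.at(d, starts + 50, -1.0)
    treat = SignalTrack({"c": np.cumsum(d[:-1]) / (starts.size / 1e6)}, library_size=starts.size)
    ctrl = _poisson_cov_track(rng, n, 1.0, 80_000)
    doms = enrichment_domains(treat, ctrl)
    dep = doms[doms["sign"] == -1]
    assert not dep.empty
    best = max(
        (min(r.end, 105_000) - max(r.start, 100_000))
        / (max(r.end, 105_000) - min(r.start, 100_000))
        for r in dep.itertuples()
    )
    assert best >= 0.5


def test_enrichment_domains_require_control():
    t = _track({"c": np.ones(10_000)})
    c = _track({"c": np.zeros(10_000)})
    with pytest.raises(ValueError, match="control"):
        enrichment_domains(t, c)


def test_binned_correlation_identity_and_inverse():
    rng = np.random.default_rng(11)
    a = rng.random(200_000)
    same = binned_correlation({"c": a}, {"c": a.copy()})
    assert same["all"].pearson_r == pytest.approx(1.0)
    assert same["all"].spearman_rho == pytest.approx(1.0)
    inv = binned_correlation({"c": a}, {"c": -a + 7.0})
    assert inv["all"].pearson_r == pytest.approx(-1.0)


def test_binned_correlation_classes_and_min_bins():
    rng = np.random.default_rng(12)
    a = rng.random(300_000)
    b = rng.random(300_000)
    res = binned_correlation(
        {"c": a}, {"c": b}, boundaries=[("c", 50_000), ("c", 250_000)]
    )
    n_all = res["all"].n_bins
    assert res["boundary"].n_bins + res["interior"].n_bins <= n_all
    assert res["boundary"].n_bins > 0 and res["interior"].n_bins > 0
    with pytest.raises(ValueError, match="bins"):
        binned_correlation({"c": a[:20_000]}, {"c": b[:20_000]})


def test_binned_correlation_mappability_mask():
    rng = np.random.default_rng(13)
    a = rng.random(100_000)
    b = rng.random(100_000)
    mapp = {"c": np.ones(100_000)}
    mapp["c"][:50_000] = 0.0
    res = binned_correlation({"c": a}, {"c": b}, mappability=mapp)
    assert res["all"].n_bins == 10  # half the bins masked away


def test_boundary_repeat_density_flat_and_empty(genome7):
    lengths = {"c": 200_000}
    rng = np.random.default_rng(14)
    uniform = [("c", int(s), int(s) + 500, "fam") for s in rng.integers(0, 199_000, 400)]
    bounds = [("c", int(p)) for p in rng.integers(20_000, 180_000, 30)]
    prof = boundary_repeat_density(uniform, bounds, lengths, W=10_000, binwidth=2_000)["fam"]
    assert prof.values.std() / prof.values.mean() < 0.25
    empty = boundary_repeat_density([], bounds, lengths, W=10_000, binwidth=2_000)
    np.testing.assert_allclose(empty["all"].values, 0.0)
    with pytest.raises(KeyError, match="unknown"):
        boundary_repeat_density(uniform, bounds, lengths, families=["nope"])


def test_maverick_density_peaks_at_boundaries(genome7):
    prof = boundary_repeat_density(
        genome7.repeat_instances,
        genome7.boundaries,
        genome7.contig_lengths(),
        W=10_000,
        binwidth=2_000,
    )["MaverickSim"]
    center = prof.values[len(prof.values) // 2 - 1 : len(prof.values) // 2 + 1].max()
    flanks = (prof.values[0] + prof.values[-1]) / 2
    assert center >= 2 * max(flanks, 1e-9)


def test_feature_overlap_disjoint_sets_and_oracle():
    rng = np.random.default_rng(15)
    # far-apart disjoint sets, slop 0 -> no intersections
    res = feature_overlap_sets(
        [("c", 10)], [("c", 100, 110)], [("c", 200, 210)], [("c", 300, 310)], slop=0
    )
    assert res["combo_counts"] == {"none": 1}

    # oracle equivalence on a random 200-interval instance
    def rand_ivs(n):
        s = rng.integers(0, 100_000, n)
        return [("c", int(x), int(x + rng.integers(50, 500))) for x in s]

    bounds = [("c", int(p)) for p in rng.integers(0, 100_000, 100)]
    sets = [rand_ivs(70), rand_ivs(70), rand_ivs(60)]
    slop = 250
    res = feature_overlap_sets(bounds, *sets, slop=slop)
    names = ("low_access", "high_hmu", "maverick")
    oracle: dict[str, int] = {}
    for _c, p in bounds:
        hits = [
            nm
            for nm, ivs in zip(names, sets)
            if any(s - slop <= p < e + slop for _cc, s, e in ivs)
        ]
        key = "+".join(hits) if hits else "none"
        oracle[key] = oracle.get(key, 0) + 1
    assert res["combo_counts"] == oracle


def test_repeat_space_null_is_flat(genome7):
    rng = np.random.default_rng(16)
    seqs = []
    for fam, cons in genome7.consensus.items():
        for _ in range(60):
            s = int(rng.integers(0, len(cons) - 75))
            seqs.append(cons[s : s + 75])
    df = repeat_space_profile(seqs, genome7.consensus, list(seqs))
    assert np.abs(df["log2_ratio"]).max() < 1e-9
    with pytest.raises(ValueError, match="zero length"):
        repeat_space_profile(seqs, {"bad": ""}, seqs)


def test_repeat_space_weighted_reads_bounded(genome7):
    rng = np.random.default_rng(17)
    cons = genome7.consensus["MaverickSim"]
    seqs = [cons[i : i + 75] for i in rng.integers(0, len(cons) - 75, 200)]
    df = repeat_space_profile(seqs, genome7.consensus, seqs[:50])
    total_weighted = df.attrs["treatment_mapped"]
    assert total_weighted <= len(seqs) + 1e-9
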