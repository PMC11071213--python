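"""Aggregate statistics: metaprofiles, enrichment domains, correlations,
boundary repeat density, overlap sets, and repeat-consensus-space
enrichment.

Enrichment/depletion domains are called with an internal Poisson window
test of treatment counts against the library-size-scaled control
expectation.  Working against a matched control is essential here: a
collapsed repeat produces the same artificial coverage pileup in treatment
and control, so the ratio test leaves it uncalled, whereas a control-free
caller would report it as a spurious peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .align import AlignedFragment, MappabilityTrack, MultimapAligner, SignalTrack

__all__ = [
    "MetaProfile",
    "metaprofile",
    "enrichment_domains",
    "BinCorrelation",
    "binned_correlation",
    "boundary_repeat_density",
    "feature_overlap_sets",
    "repeat_space_profile",
]


def _as_arrays(track) -> Mapping[str, np.ndarray]:
    if isinstance(track, (SignalTrack, MappabilityTrack)):
        return track.values
    return track


@dataclass
class MetaProfile:
    """Mean signal per offset bin across a set of (optionally oriented)
    anchor points; minus-strand anchors are mirrored before aggregation."""

    offsets: np.ndarray  # bin centers relative to the anchor
    values: np.ndarray
    n_anchors: int
    binwidth: int


def metaprofile(
    track,
    anchors: Sequence[tuple],
    W: int = 10_000,
    binwidth: int = 500,
) -> MetaProfile:
    """Average a per-base track in ``[-W, W)`` windows around anchors.

    ``anchors`` are (contig, pos) or (contig, pos, strand) tuples; windows
    that would extend past a contig end are dropped.
    """
    if W % binwidth != 0:
        raise ValueError("W must be a multiple of binwidth")
    arrays = _as_arrays(track)
    n_bins = 2 * W // binwidth
    acc = np.zeros(n_bins, dtype=np.float64)
    used = 0
    for anchor in anchors:
        contig, pos = anchor[0], int(anchor[1])
        strand = anchor[2] if len(anchor) > 2 else "+"
        if contig not in arrays:
            continue
        arr = arrays[contig]
        if pos - W < 0 or pos + W > arr.size:
            continue
        window = np.asarray(arr[pos - W : pos + W], dtype=np.float64)
        if strand == "-":
            window = window[::-1]
        acc += window.reshape(n_bins, binwidth).mean(axis=1)
        used += 1
    if used == 0:
        raise ValueError("zero usable anchors (all windows clipped)")
    offsets = -W + binwidth * np.arange(n_bins) + binwidth // 2
    return MetaProfile(offsets=offsets, values=acc / used, n_anchors=used, binwidth=binwidth)


def enrichment_domains(
    treatment: SignalTrack,
    control: SignalTrack,
    window: int = 500,
    alpha: float = 0.05,
    merge_gap: int = 200,
    pseudocount: float = 1.0,
    return_windows: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Signed enrichment/depletion domains of treatment vs control.

    Per tiling window, treatment and control weighted coverages are
    converted to fragment equivalents and compared with the conditional
    form of the two-sample Poisson ratio test: given the window total
    ``t + c``, the treatment count is binomial with success probability
    equal to the treatment's share of the combined library sizes.
    Conditioning makes the test exact under any shared local rate, so a
    collapsed-repeat pileup present in both tracks cancels instead of
    being called.  Benjamini-Hochberg runs across windows; adjacent
    significant windows of the same sign within ``merge_gap`` are merged.
    Returns a frame of signed domains (+1 enriched, -1 depleted) with log2
    ratios and q-values, plus the per-window table when
    ``return_windows``.
    """
    t_cov = treatment.coverage()
    c_cov = control.coverage()
    if sum(v.sum() for v in c_cov.values()) == 0:
        raise ValueError("control track is degenerate (all zero)")
    lbar_t = sum(v.sum() for v in t_cov.values()) / treatment.library_size
    lbar_c = sum(v.sum() for v in c_cov.values()) / control.library_size
    scale = treatment.library_size / control.library_size
    p0 = treatment.library_size / (treatment.library_size + control.library_size)

    recs = []
    for contig in t_cov:
        n = t_cov[contig].size
        starts = np.arange(0, n - window + 1, window)
        cs_t = np.concatenate([[0.0], np.cumsum(t_cov[contig])])
        cs_c = np.concatenate([[0.0], np.cumsum(c_cov[contig])])
        t = (cs_t[starts + window] - cs_t[starts]) / lbar_t
        c = (cs_c[starts + window] - cs_c[starts]) / lbar_c
        lam = (c + pseudocount) * scale
        # regularized incomplete beta gives the binomial tails and stays
        # valid for the fractional fragment-equivalent counts used here
        p_enr = np.where(t > 0, betainc(np.maximum(t, 1e-9), c + 1.0, p0), 1.0)
        p_dep = np.where(c > 0, betainc(np.maximum(c, 1e-9), t + 1.0, 1.0 - p0), 1.0)
        p = np.minimum(1.0, 2.0 * np.minimum(p_enr, p_dep))
        sign = np.where(t >= lam, 1, -1)
        for s, ti, ci, li, pi, sg in zip(starts, t, c, lam, p, sign):
            recs.append((contig, int(s), int(s + window), ti, li, pi, int(sg)))
    df = pd.DataFrame(
        recs, columns=["contig", "start", "end", "t", "lam", "pval", "sign"]
    )
    rej, qval, _a, _b = multipletests(df["pval"], alpha=alpha, method="fdr_bh")
    df["qval"] = qval
    df["sig"] = rej

    domains = []
    for (contig, sign), grp in df[df["sig"]].groupby(["contig", "sign"]):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples():
            if cur is not None and row.start - cur["end"] <= merge_gap:
                cur["end"] = row.end
                cur["t"] += row.t
                cur["lam"] += row.lam
                cur["qval"] = min(cur["qval"], row.qval)
                cur["pval"] = min(cur["pval"], row.pval)
            else:
                if cur is not None:
                    domains.append(cur)
                cur = {
                    "contig": contig,
                    "start": row.start,
                    "end": row.end,
                    "sign": sign,
                    "t": row.t,
                    "lam": row.lam,
                    "pval": row.pval,
                    "qval": row.qval,
                }
        if cur is not None:
            domains.append(cur)
    out = pd.DataFrame(
        domains,
        columns=["contig", "start", "end", "sign", "t", "lam", "pval", "qval"],
    )
    if not out.empty:
        out["log2_ratio"] = np.log2(
            (out["t"] + pseudocount) / (out["lam"] + pseudocount)
        )
        out = out.sort_values(["contig", "start"]).reset_index(drop=True)
    else:
        out["log2_ratio"] = pd.Series(dtype=float)
    return (out, df) if return_windows else out


@dataclass
class BinCorrelation:
    pearson_r: float
    spearman_rho: float
    n_bins: int


def binned_correlation(
    track_a,
    track_b,
    binwidth: int = 5_000,
    boundaries: Sequence[tuple] | None = None,
    D: int = 10_000,
    interior_min_dist: int | None = None,
    mappability: MappabilityTrack | Mapping[str, np.ndarray] | None = None,
    mappability_threshold: float = 0.5,
    min_bins: int = 10,
) -> dict[str, BinCorrelation]:
    """Pearson and Spearman correlation of two tracks in fixed-width bins.

    Reported per region class: ``all``, ``boundary`` (bin center within
    ``D`` of a domain boundary) and ``interior`` (farther than
    ``interior_min_dist``, default 3 * D; the intermediate band belongs to
    neither class).  Bins with mean mappability below the threshold are
    excluded when a mappability track is provided.
    """
    arrays_a = _as_arrays(track_a)
    arrays_b = _as_arrays(track_b)
    if interior_min_dist is None:
        interior_min_dist = 3 * D
    vals_a, vals_b, dists = [], [], []
    for contig in arrays_a:
        a = np.asarray(arrays_a[contig], dtype=np.float64)
        b = np.asarray(arrays_b[contig], dtype=np.float64)
        n_bins = a.size // binwidth
        if n_bins == 0:
            continue
        am = a[: n_bins * binwidth].reshape(n_bins, binwidth).mean(axis=1)
        bm = b[: n_bins * binwidth].reshape(n_bins, binwidth).mean(axis=1)
        centers = binwidth * np.arange(n_bins) + binwidth // 2
        keep = np.ones(n_bins, dtype=bool)
        if mappability is not None:
            marr = _as_arrays(mappability)[contig]
            mm = np.asarray(marr[: n_bins * binwidth], dtype=np.float64)
            keep &= mm.reshape(n_bins, binwidth).mean(axis=1) >= mappability_threshold
        bpos = np.array(
            [p for bc, p in (boundaries or []) if bc == contig], dtype=np.float64
        )
        if bpos.size:
            dist = np.abs(centers[:, None] - bpos[None, :]).min(axis=1)
        else:
            dist = np.full(n_bins, np.inf)
        vals_a.append(am[keep])
        vals_b.append(bm[keep])
        dists.append(dist[keep])
    a = np.concatenate(vals_a)
    b = np.concatenate(vals_b)
    dist = np.concatenate(dists)
    if a.size < min_bins:
        raise ValueError(f"only {a.size} usable bins (< {min_bins})")

    def corr(mask: np.ndarray) -> BinCorrelation:
        if mask.sum() < 3:
            return BinCorrelation(np.nan, np.nan, int(mask.sum()))
        r = pearsonr(a[mask], b[mask]).statistic
        rho = spearmanr(a[mask], b[mask]).statistic
        return BinCorrelation(float(r), float(rho), int(mask.sum()))

    return {
        "all": corr(np.ones(a.size, dtype=bool)),
        "boundary": corr(dist <= D),
        "interior": corr(dist > interior_min_dist),
    }


def boundary_repeat_density(
    repeats: Iterable,
    boundaries: Sequence[tuple],
    contig_lengths: Mapping[str, int],
    W: int = 10_000,
    binwidth: int = 500,
    families: Sequence[str] | None = None,
) -> dict[str, MetaProfile]:
    """Per-family repeat-bp coverage fraction around domain boundaries.

    ``repeats`` yields (contig, start, end, family) tuples or objects with
    those attributes.  The profile value in a bin is the fraction of its
    positions covered by the family.  An ``all`` profile pools families.
    """
    tuples = []
    for r in repeats:
        if hasattr(r, "family"):
            tuples.append((r.contig, r.start, r.end, r.family))
        else:
            tuples.append(tuple(r[:4]))
    present = {fam for _c, _s, _e, fam in tuples}
    if families is not None:
        unknown = set(families) - present
        if unknown:
            raise KeyError(f"unknown repeat families: {sorted(unknown)}")
        wanted = list(families)
    else:
        wanted = sorted(present)

    out: dict[str, MetaProfile] = {}
    for fam in wanted + ["all"]:
        cov = {c: np.zeros(n, dtype=np.float64) for c, n in contig_lengths.items()}
        for c, s, e, f in tuples:
            if (fam == "all" or f == fam) and c in cov:
                cov[c][s:e] = 1.0
        out[fam] = metaprofile(cov, boundaries, W=W, binwidth=binwidth)
    return out


def feature_overlap_sets(
    boundaries: Sequence[tuple],
    low_access_domains: Sequence[tuple],
    high_hmu_domains: Sequence[tuple],
    maverick_instances: Sequence[tuple],
    slop: int = 0,
) -> dict:
    """Overlap of domain boundaries with three interval sets.

    A boundary belongs to a set when its 1-bp interval overlaps a member
    interval padded by ``slop`` on each side.  Returns per-combination
    counts (keys like ``"low_access+maverick"``; ``"none"`` for boundaries
    hitting no set) plus per-set totals and fractions.
    """
    names = ("low_access", "high_hmu", "maverick")
    sets = (low_access_domains, high_hmu_domains, maverick_instances)

    def member(contig: str, pos: int, intervals: Sequence[tuple]) -> bool:
        for iv in intervals:
            c, s, e = iv[0], iv[1], iv[2]
            if c == contig and s - slop <= pos < e + slop:
                return True
        return False

    combo_counts: dict[str, int] = {}
    set_counts = dict.fromkeys(names, 0)
    for b in boundaries:
        contig, pos = b[0], int(b[1])
        hits = [name for name, ivs in zip(names, sets) if member(contig, pos, ivs)]
        for h in hits:
            set_counts[h] += 1
        key = "+".join(hits) if hits else "none"
        combo_counts[key] = combo_counts.get(key, 0) + 1
    n = len(boundaries)
    return {
        "n_boundaries": n,
        "combo_counts": combo_counts,
        "set_counts": set_counts,
        "set_fractions": {k: v / n for k, v in set_counts.items()} if n else {},
    }


def repeat_space_profile(
    sequences: Sequence[str],
    consensus_library: Mapping[str, str],
    control_sequences: Sequence[str],
    max_mismatches: int = 5,
    k: int = 12,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-family enrichment of a library over a control in repeat space.

    Reads are aligned directly to the family consensus sequences with a
    relaxed mismatch budget and unlimited multimapping; alignments get the
    usual 1/NH weights and are summed per family in RPM units.  The RPM
    denominator is the library size (all submitted fragments), not the
    consensus-mapped subset: normalizing to the latter would make family
    shares compositional, so a single strongly enriched family would
    depress every other family's apparent signal.  The result holds
    log2((T + psi) / (C + psi)) per family.
    """
    if not consensus_library:
        raise ValueError("consensus library is empty")
    for fam, seq in consensus_library.items():
        if len(seq) == 0:
            raise ValueError(f"consensus family {fam!r} has zero length")
    aligner = MultimapAligner(
        dict(consensus_library), k=k, max_mismatches=max_mismatches
    )

    def family_rpm(seqs: Sequence[str]) -> tuple[dict[str, float], float]:
        weights = dict.fromkeys(consensus_library, 0.0)
        lib = 0.0
        for aln in aligner.align_fragments(seqs):
            weights[aln.contig] += aln.weight
            lib += aln.weight
        denom = len(seqs) / 1e6
        return {f: w / denom for f, w in weights.items()}, lib

    t_rpm, t_lib = family_rpm(sequences)
    c_rpm, c_lib = family_rpm(control_sequences)
    rows = []
    for fam in consensus_library:
        rows.append(
            {
                "family": fam,
                "treatment_rpm": t_rpm[fam],
                "control_rpm": c_rpm[fam],
                "log2_ratio": np.log2(
                    (t_rpm[fam] + pseudocount) / (c_rpm[fam] + pseudocount)
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["treatment_mapped"] = t_lib
    df.attrs["control_mapped"] = c_lib
    return df
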