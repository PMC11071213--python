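"""Positioned-footprint calling from transposition fragments, V-plots, and
footprint enrichment over repeat families.

The caller is a transparent density-and-occupancy procedure: sliding 1-kbp
windows (step 500 bp) scan a Gaussian-smoothed (sigma 20 bp) midpoint
density of nucleosome-range fragments (100-200 bp); local maxima become
candidate centers; a candidate's occupancy is the nucleosome-range fraction
among all fragments whose midpoints fall within +/-73 bp of it (73 bp being
half the canonical nucleosomal footprint).  Redundant candidates from
overlapping windows are deduplicated keeping the higher occupancy, with a
minimum spacing between retained calls.  The high-resolution subset applies
an occupancy cutoff (default 0.8) on top of the low-resolution call set, so
high-resolution calls are always a subset of low-resolution ones.

Fragment centers are floor((start + end) / 2); even-length ties resolve
toward the fragment start, keeping every derived statistic deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.proportion import proportion_confint

from .align import AlignedFragment, MappabilityTrack
from .meta import MetaProfile, metaprofile

__all__ = [
    "call_positioned_nucleosomes",
    "VPlotMatrix",
    "vplot",
    "footprint_feature_enrichment",
    "mappability_at_calls",
]


def _fragment_mid_len(
    alignments: Sequence[AlignedFragment], unique_only: bool
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-contig (midpoint, length) arrays, one entry per fragment record."""
    mids: dict[str, list[int]] = {}
    lens: dict[str, list[int]] = {}
    for a in alignments:
        if unique_only and a.nh != 1:
            continue
        mids.setdefault(a.contig, []).append((a.start + a.end) // 2)
        lens.setdefault(a.contig, []).append(a.end - a.start)
    return {
        c: (np.asarray(mids[c], dtype=np.int64), np.asarray(lens[c], dtype=np.int64))
        for c in mids
    }


def call_positioned_nucleosomes(
    alignments: Sequence[AlignedFragment],
    contig_lengths: Mapping[str, int],
    window: int = 1_000,
    step: int = 500,
    nuc_range: tuple[int, int] = (100, 200),
    occ_cutoff: float = 0.8,
    min_occupancy: float = 0.4,
    min_fragments: int = 5,
    sigma: float = 20.0,
    flank: int = 73,
    min_spacing: int = 120,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Call putative positioned protective footprints.

    Returns a frame (contig, center, occupancy, n_fragments, resolution)
    sorted by contig and center.  ``resolution`` is "high" when occupancy
    reaches ``occ_cutoff``, else "low"; the high set is a subset of all
    calls.  An empty frame (no nucleosome-range fragments) is a valid
    result, not an error.
    """
    if step <= 0 or window <= 0 or step > window:
        raise ValueError("malformed window geometry: need 0 < step <= window")
    lo, hi = nuc_range
    if not 0 < lo < hi:
        raise ValueError("nuc_range must be an increasing positive interval")

    per_contig = _fragment_mid_len(alignments, unique_only)
    calls = []
    for contig, (mids, lens) in per_contig.items():
        L = contig_lengths[contig]
        nuc_mask = (lens >= lo) & (lens <= hi)
        nuc_mids = mids[nuc_mask]
        if nuc_mids.size == 0:
            continue
        density = gaussian_filter1d(
            np.bincount(nuc_mids, minlength=L).astype(np.float64), sigma
        )
        all_sorted = np.sort(mids)
        nuc_sorted = np.sort(nuc_mids)

        candidates: dict[int, tuple[float, int]] = {}
        interior = np.zeros(L, dtype=bool)
        interior[1:-1] = (density[1:-1] >= density[:-2]) & (density[1:-1] > density[2:])
        maxima = np.flatnonzero(interior)
        for ws in range(0, max(L - window, 0) + 1, step):
            in_win = maxima[(maxima >= ws) & (maxima < ws + window)]
            for c in in_win:
                if c in candidates:
                    continue
                n_all = int(
                    np.searchsorted(all_sorted, c + flank, side="right")
                    - np.searchsorted(all_sorted, c - flank, side="left")
                )
                if n_all < min_fragments:
                    continue
                n_nuc = int(
                    np.searchsorted(nuc_sorted, c + flank, side="right")
                    - np.searchsorted(nuc_sorted, c - flank, side="left")
                )
                occ = n_nuc / n_all
                if occ >= min_occupancy:
                    candidates[int(c)] = (occ, n_all)

        # dedup: highest occupancy wins, min_spacing between retained calls
        order = sorted(candidates.items(), key=lambda kv: (-kv[1][0], kv[0]))
        kept: list[int] = []
        for center, (occ, n_all) in order:
            if all(abs(center - kc) >= min_spacing for kc in kept):
                kept.append(center)
                calls.append((contig, center, occ, n_all))

    df = pd.DataFrame(calls, columns=["contig", "center", "occupancy", "n_fragments"])
    if df.empty:
        df["resolution"] = pd.Series(dtype=object)
        return df
    df["resolution"] = np.where(df["occupancy"] >= occ_cutoff, "high", "low")
    return df.sort_values(["contig", "center"]).reset_index(drop=True)


@dataclass
class VPlotMatrix:
    """2-D histogram of fragment length vs fragment-center offset."""

    matrix: np.ndarray  # shape (length_max, 2W+1)
    lengths: np.ndarray  # 1..length_max
    offsets: np.ndarray  # -W..W
    n_fragments: int

    def length_marginal(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def modal_length(self) -> int:
        return int(self.lengths[int(np.argmax(self.length_marginal()))])


def vplot(
    alignments: Sequence[AlignedFragment],
    anchors: Sequence[tuple],
    W: int = 100,
    length_max: int = 300,
    unique_only: bool = True,
) -> VPlotMatrix:
    """Aggregate (fragment length, center offset) counts around anchors.

    Every (anchor, fragment) pair with |center - anchor| <= W and
    1 <= length <= length_max contributes one count; when anchors are
    spaced more than 2 W apart each fragment is counted at most once and
    the matrix total equals the number of usable fragments.
    """
    if W <= 0:
        raise ValueError("W must be positive")
    if not anchors:
        raise ValueError("anchor set is empty")
    per_contig = _fragment_mid_len(alignments, unique_only)
    matrix = np.zeros((length_max, 2 * W + 1), dtype=np.int64)
    for contig, group in _group_anchors(anchors).items():
        if contig not in per_contig:
            continue
        mids, lens = per_contig[contig]
        order = np.argsort(mids, kind="stable")
        mids_s, lens_s = mids[order], lens[order]
        for pos in group:
            lo = np.searchsorted(mids_s, pos - W, side="left")
            hi = np.searchsorted(mids_s, pos + W, side="right")
            if hi <= lo:
                continue
            ls = lens_s[lo:hi]
            offs = mids_s[lo:hi] - pos + W
            ok = (ls >= 1) & (ls <= length_max)
            np.add.at(matrix, (ls[ok] - 1, offs[ok]), 1)
    return VPlotMatrix(
        matrix=matrix,
        lengths=np.arange(1, length_max + 1),
        offsets=np.arange(-W, W + 1),
        n_fragments=int(matrix.sum()),
    )


def _group_anchors(anchors: Sequence[tuple]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for a in anchors:
        out.setdefault(a[0], []).append(int(a[1]))
    return out


def footprint_feature_enrichment(
    calls: pd.DataFrame,
    features: Mapping[str, Sequence[tuple]],
    contig_lengths: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Density ratio of calls inside each feature family vs genome-wide.

    The ratio is (calls per bp in the family) / (calls per bp overall);
    its confidence interval is the exact (Clopper-Pearson) binomial CI of
    the in-family call proportion, scaled by the family's bp share.
    Families covering zero bp are excluded with a warning.
    """
    n_calls = len(calls)
    if n_calls == 0:
        raise ValueError("zero calls")
    total_bp = sum(contig_lengths.values())
    rows = []
    for fam, intervals in features.items():
        fam_bp = sum(iv[2] - iv[1] for iv in intervals)
        if fam_bp == 0:
            warnings.warn(f"feature family {fam!r} covers 0 bp; excluded")
            continue
        inside = 0
        for row in calls.itertuples():
            for iv in intervals:
                if iv[0] == row.contig and iv[1] <= row.center < iv[2]:
                    inside += 1
                    break
        p0 = fam_bp / total_bp
        phat = inside / n_calls
        lo, hi = proportion_confint(inside, n_calls, alpha=alpha, method="beta")
        rows.append(
            {
                "family": fam,
                "n_calls": inside,
                "family_bp": fam_bp,
                "density_ratio": phat / p0,
                "ci_low": lo / p0,
                "ci_high": hi / p0,
            }
        )
    return pd.DataFrame(rows)


def mappability_at_calls(
    calls: pd.DataFrame,
    mappability: MappabilityTrack,
    W: int = 1_000,
    binwidth: int = 50,
) -> MetaProfile:
    """Mean mappability per offset bin around call centers."""
    if len(calls) == 0:
        raise ValueError("empty call set")
    anchors = [(row.contig, int(row.center)) for row in calls.itertuples()]
    return metaprofile(mappability, anchors, W=W, binwidth=binwidth)
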