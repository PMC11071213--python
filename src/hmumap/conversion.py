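"""Basepair-resolution 5-hmU analysis from T->C conversion mismatches.

A site's evidence is strand-aware: a plus-strand thymine is only informed
by fragments that originate on the plus strand (T->C mismatches in
reference space), a minus-strand thymine (reference A) only by minus-origin
fragments (A->G in reference space).  Multimapping fragments are excluded
from conversion counting because mismatch attribution across equally good
loci is ambiguous.

Because the chemistry converts only a fraction of modified bases, the
estimated rates are relative, not absolute: per-region rates are monotone
in the underlying modification density, but their level scales with the
oxidation efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .align import AlignedFragment
from .genome import A, T, ToyGenome, encode

__all__ = [
    "SiteConversionTable",
    "count_site_conversions",
    "binned_conversion_rate",
    "genome_wide_rate",
    "call_modified_sites",
    "ContextMatrix",
    "context_consensus",
]


@dataclass
class SiteConversionTable:
    """Dense per-contig, per-strand coverage and conversion counts."""

    cov_plus: dict[str, np.ndarray]
    conv_plus: dict[str, np.ndarray]
    cov_minus: dict[str, np.ndarray]
    conv_minus: dict[str, np.ndarray]
    is_t: dict[str, np.ndarray]  # reference T mask (plus-strand sites)
    is_a: dict[str, np.ndarray]  # reference A mask (minus-strand sites)

    def frame(self, min_cov: int = 1) -> pd.DataFrame:
        """Long-format site table (contig, pos, strand, cov, conv, rate).

        Sites with coverage below ``min_cov`` (e.g. covered only by
        opposite-strand reads) are masked out.
        """
        rows = []
        for contig in self.cov_plus:
            for strand, cov, conv, mask in (
                ("+", self.cov_plus[contig], self.conv_plus[contig], self.is_t[contig]),
                ("-", self.cov_minus[contig], self.conv_minus[contig], self.is_a[contig]),
            ):
                keep = mask & (cov >= min_cov)
                pos = np.flatnonzero(keep)
                if pos.size == 0:
                    continue
                rows.append(
                    pd.DataFrame(
                        {
                            "contig": contig,
                            "pos": pos,
                            "strand": strand,
                            "cov": cov[pos],
                            "conv": conv[pos],
                        }
                    )
                )
        if not rows:
            return pd.DataFrame(columns=["contig", "pos", "strand", "cov", "conv", "rate"])
        df = pd.concat(rows, ignore_index=True)
        df["rate"] = df["conv"] / df["cov"]
        return df


def count_site_conversions(
    alignments: Sequence[AlignedFragment],
    contigs: Mapping[str, str] | ToyGenome,
) -> SiteConversionTable:
    """Tally strand-aware coverage and T->C / A->G conversion counts.

    Only unique alignments contribute.  Sequencing-error mismatches are
    included (they are deconvolved downstream against a background rate).
    Raises if any recorded mismatch lies outside its fragment.
    """
    if isinstance(contigs, ToyGenome):
        contigs = contigs.assembly_view
    enc = {c: encode(s) for c, s in contigs.items()}
    sizes = {c: a.size for c, a in enc.items()}

    starts: dict[tuple[str, str], list[int]] = {}
    ends: dict[tuple[str, str], list[int]] = {}
    conv_pos: dict[tuple[str, str], list[int]] = {}
    for aln in alignments:
        if aln.nh != 1 or aln.contig not in enc:
            continue
        key = (aln.contig, aln.strand)
        starts.setdefault(key, []).append(aln.start)
        ends.setdefault(key, []).append(aln.end)
        for pos, ref, read in aln.mismatches:
            if not aln.start <= pos < aln.end:
                raise ValueError(
                    f"mismatch at {aln.contig}:{pos} outside fragment "
                    f"[{aln.start}, {aln.end})"
                )
            if aln.strand == "+" and ref == "T" and read == "C":
                conv_pos.setdefault(key, []).append(pos)
            elif aln.strand == "-" and ref == "A" and read == "G":
                conv_pos.setdefault(key, []).append(pos)

    def _cov(key: tuple[str, str], n: int) -> np.ndarray:
        d = np.zeros(n + 1, dtype=np.int64)
        if key in starts:
            np.add.at(d, np.asarray(starts[key]), 1)
            np.add.at(d, np.asarray(ends[key]), -1)
        return np.cumsum(d[:-1])

    def _conv(key: tuple[str, str], n: int) -> np.ndarray:
        out = np.zeros(n, dtype=np.int64)
        if key in conv_pos:
            np.add.at(out, np.asarray(conv_pos[key]), 1)
        return out

    table = SiteConversionTable(
        cov_plus={}, conv_plus={}, cov_minus={}, conv_minus={}, is_t={}, is_a={}
    )
    for c, n in sizes.items():
        t_mask = enc[c] == T
        a_mask = enc[c] == A
        table.cov_plus[c] = np.where(t_mask, _cov((c, "+"), n), 0)
        table.conv_plus[c] = _conv((c, "+"), n)
        table.cov_minus[c] = np.where(a_mask, _cov((c, "-"), n), 0)
        table.conv_minus[c] = _conv((c, "-"), n)
        table.is_t[c] = t_mask
        table.is_a[c] = a_mask
    return table


def binned_conversion_rate(
    table: SiteConversionTable,
    width: int = 500,
    step: int = 100,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Aggregate conversion rate in sliding bins (width 500, step 100).

    Bins tile each contig with fully contained windows; a bin's rate is
    sum(conversions) / sum(coverage) over both strands, masked (NaN) when
    the summed coverage falls below ``min_cov``.
    """
    if step > width:
        raise ValueError("step must not exceed width (bins would leave gaps)")
    rows = []
    for contig in table.cov_plus:
        n = table.cov_plus[contig].size
        if n < width:
            continue
        cov = (table.cov_plus[contig] + table.cov_minus[contig]).astype(np.float64)
        conv = (table.conv_plus[contig] + table.conv_minus[contig]).astype(np.float64)
        n_sites = (table.is_t[contig] | table.is_a[contig]).astype(np.float64)
        cs_cov = np.concatenate([[0.0], np.cumsum(cov)])
        cs_conv = np.concatenate([[0.0], np.cumsum(conv)])
        cs_n = np.concatenate([[0.0], np.cumsum(n_sites)])
        bin_starts = np.arange(0, n - width + 1, step)
        be = bin_starts + width
        bcov = cs_cov[be] - cs_cov[bin_starts]
        bconv = cs_conv[be] - cs_conv[bin_starts]
        bn = cs_n[be] - cs_n[bin_starts]
        rate = np.where(bcov >= min_cov, bconv / np.maximum(bcov, 1.0), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "start": bin_starts,
                    "end": be,
                    "n_T_sites": bn.astype(np.int64),
                    "coverage": bcov,
                    "conversions": bconv,
                    "rate": rate,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def genome_wide_rate(table: SiteConversionTable) -> float:
    cov = sum(
        table.cov_plus[c].sum() + table.cov_minus[c].sum() for c in table.cov_plus
    )
    conv = sum(
        table.conv_plus[c].sum() + table.conv_minus[c].sum() for c in table.cov_plus
    )
    if cov == 0:
        raise ValueError("no covered T sites")
    return float(conv / cov)


def call_modified_sites(
    sites: pd.DataFrame | SiteConversionTable,
    background_rate: float,
    alpha: float = 0.05,
    min_cov: int = 5,
    return_all: bool = False,
) -> pd.DataFrame:
    """One-sided binomial test per site against the background conversion
    rate, Benjamini-Hochberg corrected at ``alpha``.

    ``background_rate`` is the conversion level expected from sequencing
    error alone (estimated from the spike or an unmodified control).
    Returns the surviving sites (or the full tested table when
    ``return_all``) with p- and q-values.
    """
    if background_rate >= 1.0:
        raise ValueError("background_rate must be < 1")
    if isinstance(sites, SiteConversionTable):
        sites = sites.frame(min_cov=min_cov)
    else:
        sites = sites[sites["cov"] >= min_cov]
    df = sites.reset_index(drop=True).copy()
    if df.empty:
        raise ValueError("no sites with sufficient coverage")
    df["pval"] = binom.sf(df["conv"] - 1, df["cov"], background_rate)
    called, qval, _a, _b = multipletests(df["pval"], alpha=alpha, method="fdr_bh")
    df["qval"] = qval
    df["called"] = called
    return df if return_all else df[df["called"]].reset_index(drop=True)


@dataclass
class ContextMatrix:
    """Base composition around called modified Ts, in origin-strand sense."""

    freq: pd.DataFrame  # index: offsets -k..k, columns: A, C, G, T
    info: pd.Series  # bits per offset, uniform background
    n_sites: int


def context_consensus(
    called_sites: pd.DataFrame,
    contigs: Mapping[str, str] | ToyGenome,
    k: int = 5,
) -> ContextMatrix:
    """Sequence context consensus over called modified T positions.

    Minus-strand sites contribute their reverse-complemented context, so
    the center base is T by construction.  Information content per offset
    is ``2 + sum(f * log2 f)`` against a uniform background.
    """
    if called_sites.empty:
        raise ValueError("empty site set")
    if isinstance(contigs, ToyGenome):
        contigs = contigs.assembly_view
    enc = {c: encode(s) for c, s in contigs.items()}
    offsets = np.arange(-k, k + 1)
    counts = np.zeros((2 * k + 1, 4), dtype=np.int64)
    n_used = 0
    for (contig, strand), grp in called_sites.groupby(["contig", "strand"]):
        seq = enc[contig]
        pos = grp["pos"].to_numpy()
        ok = (pos >= k) & (pos < seq.size - k)
        pos = pos[ok]
        if pos.size == 0:
            continue
        mat = seq[pos[:, None] + offsets[None, :]]
        if strand == "-":
            mat = (3 - mat)[:, ::-1]
        for j in range(2 * k + 1):
            counts[j] += np.bincount(mat[:, j], minlength=4)
        n_used += pos.size
    if n_used == 0:
        raise ValueError("no sites with full flanking context")
    freq = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    freq_df = pd.DataFrame(freq, index=offsets, columns=list("ACGT"))
    return ContextMatrix(
        freq=freq_df, info=pd.Series(info, index=offsets, name="bits"), n_sites=n_used
    )
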