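"""Synthetic dinoflagellate-like genome generation.

Builds a small toy genome with the structural features the downstream
analyses assume: long unidirectional gene arrays whose convergent junctions
define domain ("dinoTAD") boundaries, planted repeat families (a large DNA
transposon stand-in, LTR-like, LINE-like and satellite-like elements),
collapsed-repeat assembly artifacts, plus ground-truth per-base landscapes
of 5-hydroxymethyluracil (5-hmU) deposition and physical protection
(occupancy).

Coordinates are 0-based, half-open throughout (BED convention); a domain
boundary is a 1-bp point interval at the junction where a '+'-oriented gene
array is followed by a '-'-oriented one.

Collapsed repeats are modelled by keeping all annotations in assembly
coordinates and placing the surplus copies of each collapsed instance on a
truth-only contig (``*_collapsed_extra``).  Reads simulated from that extra
contig can only align to the single assembly copy, producing the
characteristic artificial coverage pileups of a collapsed assembly while
assembly coordinates of every other feature stay identical between truth
and assembly views.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeConfigError",
    "RepeatFamilySpec",
    "GenomeConfig",
    "RepeatInstance",
    "ToyGenome",
    "ModificationMap",
    "OccupancyMap",
    "generate_genome",
    "build_modification_map",
    "build_occupancy_map",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in 0..3 coding

# base codes
A, C, G, T = 0, 1, 2, 3


class GenomeConfigError(ValueError):
    """Invalid genome configuration; the message names the offending field."""


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 array with A,C,G,T -> 0,1,2,3."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(raw.size, dtype=np.uint8)
    # vectorized lookup table over ASCII
    table = np.full(256, 255, dtype=np.uint8)
    table[ord("A")] = A
    table[ord("C")] = C
    table[ord("G")] = G
    table[ord("T")] = T
    out = table[raw]
    if (out == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return out


def decode(arr: np.ndarray) -> str:
    return _BASE_BYTES[arr].tobytes().decode("ascii")


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One planted repeat family.

    near_boundary_fraction is the fraction of instances placed within
    2 * w_b of a randomly chosen domain boundary; the rest are uniform.
    divergence is the per-base substitution rate of each instance relative
    to the family consensus.
    """

    name: str
    consensus_length: int
    n_copies: int
    near_boundary_fraction: float = 0.0
    divergence: float = 0.01


def default_repeat_families() -> tuple[RepeatFamilySpec, ...]:
    return (
        RepeatFamilySpec("MaverickSim", 2000, 12, 0.7),
        RepeatFamilySpec("CopiaSimLTR", 1500, 14, 0.1),
        RepeatFamilySpec("LINESim", 1200, 14, 0.1),
        RepeatFamilySpec("SatSim", 600, 18, 0.1),
        RepeatFamilySpec("CollapsedSim", 1000, 3, 0.0, divergence=0.02),
    )


@dataclass
class GenomeConfig:
    n_contigs: int = 2
    contig_length: int = 400_000
    array_length_mean: int = 40_000
    boundary_halfwidth: int = 2_000
    repeat_families: tuple[RepeatFamilySpec, ...] = field(
        default_factory=default_repeat_families
    )
    collapsed_families: Mapping[str, int] = field(
        default_factory=lambda: {"CollapsedSim": 2}
    )
    gc_fraction: float = 0.44
    gene_spacing: int = 3_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise GenomeConfigError("n_contigs must be >= 1")
        if self.contig_length < 10 * self.array_length_mean:
            raise GenomeConfigError(
                "contig_length must be >= 10 * array_length_mean"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise GenomeConfigError("gc_fraction must lie in [0, 1]")
        if self.boundary_halfwidth <= 0:
            raise GenomeConfigError("boundary_halfwidth must be positive")
        if self.gene_spacing <= 0:
            raise GenomeConfigError("gene_spacing must be positive")
        names = [f.name for f in self.repeat_families]
        if len(set(names)) != len(names):
            raise GenomeConfigError("repeat_families names must be unique")
        for fam in self.repeat_families:
            if not 0.0 <= fam.near_boundary_fraction <= 1.0:
                raise GenomeConfigError(
                    f"near_boundary_fraction of {fam.name} must lie in [0, 1]"
                )
            if fam.consensus_length <= 0 or fam.n_copies < 0:
                raise GenomeConfigError(
                    f"repeat_families entry {fam.name} has invalid dimensions"
                )
        for fam_name, k in self.collapsed_families.items():
            if fam_name not in names:
                raise GenomeConfigError(
                    f"collapsed_families references unknown family {fam_name!r}"
                )
            if k < 1:
                raise GenomeConfigError("collapsed_copy_number must be >= 1")


@dataclass
class RepeatInstance:
    contig: str
    start: int
    end: int
    family: str
    copy_number: int = 1  # true genomic copy number of this assembly instance

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ToyGenome:
    """Toy genome: sequences plus ground-truth annotations.

    ``contigs`` holds the truth view (including any ``*_collapsed_extra``
    contig); ``assembly_contigs`` names the subset that forms the assembly.
    All annotation coordinates refer to assembly contigs except repeat
    instances on the extra contig (surplus collapsed copies).
    """

    contigs: dict[str, str]
    assembly_contigs: tuple[str, ...]
    gene_starts: list[tuple[str, int, str]]
    boundaries: list[tuple[str, int]]
    repeat_instances: list[RepeatInstance]
    consensus: dict[str, str]
    config: GenomeConfig | None = None
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def assembly_view(self) -> dict[str, str]:
        return {name: self.contigs[name] for name in self.assembly_contigs}

    @property
    def truth_view(self) -> dict[str, str]:
        return dict(self.contigs)

    def encoded(self, contig: str) -> np.ndarray:
        if contig not in self._encoded:
            self._encoded[contig] = encode(self.contigs[contig])
        return self._encoded[contig]

    def contig_lengths(self, assembly_only: bool = False) -> dict[str, int]:
        names = self.assembly_contigs if assembly_only else self.contigs
        return {name: len(self.contigs[name]) for name in names}

    def total_length(self, assembly_only: bool = False) -> int:
        return sum(self.contig_lengths(assembly_only).values())

    def family_instances(self, family: str) -> list[RepeatInstance]:
        return [ri for ri in self.repeat_instances if ri.family == family]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _draw_array_lengths(
    rng: np.random.Generator, total: int, mean: int
) -> list[int]:
    """Array lengths filling ``total`` bp, each within [mean/2, 2*mean]."""
    lengths: list[int] = []
    remaining = total
    while remaining > 0:
        ln = int(np.clip(rng.normal(mean, mean / 4), mean / 2, 2 * mean))
        ln = min(ln, remaining)
        if remaining - ln < mean // 2:
            ln = remaining  # absorb the tail into the last array
        lengths.append(ln)
        remaining -= ln
    return lengths


def generate_genome(config: GenomeConfig) -> ToyGenome:
    """Generate a toy genome with annotations; deterministic under seed.

    Gene arrays alternate orientation along each contig so that every other
    junction is convergent ('+' followed by '-'); those junctions are the
    emitted domain boundaries.  Repeat instances are copied from a family
    consensus with per-instance divergence and never overlap each other.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    contigs: dict[str, str] = {}
    encoded: dict[str, np.ndarray] = {}
    gene_starts: list[tuple[str, int, str]] = []
    boundaries: list[tuple[str, int]] = []
    repeat_instances: list[RepeatInstance] = []

    # family consensus sequences (shared across contigs)
    consensus: dict[str, np.ndarray] = {}
    for fam in config.repeat_families:
        consensus[fam.name] = _random_sequence(
            rng, fam.consensus_length, config.gc_fraction
        )

    contig_names = [f"contig_{i + 1}" for i in range(config.n_contigs)]
    for name in contig_names:
        seq = _random_sequence(rng, config.contig_length, config.gc_fraction)

        lengths = _draw_array_lengths(
            rng, config.contig_length, config.array_length_mean
        )
        first = rng.choice(["+", "-"])
        orientations = [
            ("+" if i % 2 == 0 else "-") if first == "+" else
            ("-" if i % 2 == 0 else "+")
            for i in range(len(lengths))
        ]
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(int)
        for i in range(len(lengths) - 1):
            if orientations[i] == "+" and orientations[i + 1] == "-":
                boundaries.append((name, int(starts[i + 1])))
        for ln, start, ori in zip(lengths, starts, orientations):
            offsets = np.arange(config.gene_spacing // 2, ln, config.gene_spacing)
            if ori == "-":
                # TSSs of a '-' array sit at the high-coordinate ends
                positions = start + ln - 1 - offsets
            else:
                positions = start + offsets
            for pos in positions:
                gene_starts.append((name, int(pos), ori))

        encoded[name] = seq
        contigs[name] = ""  # filled after repeat placement

    boundary_by_contig: dict[str, list[int]] = {}
    for cname, pos in boundaries:
        boundary_by_contig.setdefault(cname, []).append(pos)

    # --- repeat placement (non-overlapping, partially boundary-biased) ---
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in contig_names}

    def overlaps(cname: str, s: int, e: int) -> bool:
        return any(s < oe and os_ < e for os_, oe in occupied[cname])

    for fam in config.repeat_families:
        fam_len = fam.consensus_length
        for _ in range(fam.n_copies):
            placed = False
            for _attempt in range(400):
                near = rng.random() < fam.near_boundary_fraction
                cname = contig_names[int(rng.integers(len(contig_names)))]
                if near and boundary_by_contig.get(cname):
                    b = int(
                        rng.choice(np.asarray(boundary_by_contig[cname]))
                    )
                    lo = b - 2 * config.boundary_halfwidth
                    hi = b + 2 * config.boundary_halfwidth - fam_len
                    if hi <= lo:
                        continue
                    start = int(rng.integers(lo, hi))
                else:
                    start = int(
                        rng.integers(0, config.contig_length - fam_len)
                    )
                if start < 0 or start + fam_len > config.contig_length:
                    continue
                if overlaps(cname, start, start + fam_len):
                    continue
                inst_seq = consensus[fam.name].copy()
                n_sub = rng.binomial(fam_len, fam.divergence)
                if n_sub:
                    idx = rng.choice(fam_len, size=n_sub, replace=False)
                    inst_seq[idx] = (
                        inst_seq[idx] + rng.integers(1, 4, size=n_sub)
                    ) % 4
                encoded[cname][start : start + fam_len] = inst_seq
                occupied[cname].append((start, start + fam_len))
                k = int(config.collapsed_families.get(fam.name, 1))
                repeat_instances.append(
                    RepeatInstance(cname, start, start + fam_len, fam.name, k)
                )
                placed = True
                break
            if not placed:
                raise GenomeConfigError(
                    f"could not place repeat family {fam.name}: "
                    "repeat_families too dense for contig_length"
                )

    # --- collapsed repeats: surplus copies on a truth-only contig ---
    extra_parts: list[np.ndarray] = []
    extra_instances: list[tuple[int, int, str, int]] = []
    cursor = 0
    spacer_len = 3000
    for inst in list(repeat_instances):
        if inst.copy_number <= 1:
            continue
        copy_seq = encoded[inst.contig][inst.start : inst.end]
        for _ in range(inst.copy_number - 1):
            spacer = _random_sequence(rng, spacer_len, config.gc_fraction)
            extra_parts.append(spacer)
            cursor += spacer_len
            extra_parts.append(copy_seq.copy())
            extra_instances.append(
                (cursor, cursor + inst.length, inst.family, inst.copy_number)
            )
            cursor += inst.length
    if extra_parts:
        extra_parts.append(_random_sequence(rng, spacer_len, config.gc_fraction))
        extra_name = "contig_collapsed_extra"
        encoded[extra_name] = np.concatenate(extra_parts)
        contig_names_truth = contig_names + [extra_name]
        for s, e, fam_name, k in extra_instances:
            repeat_instances.append(
                RepeatInstance(extra_name, s, e, fam_name, k)
            )
    else:
        contig_names_truth = contig_names

    for name in contig_names_truth:
        contigs[name] = decode(encoded[name])

    genome = ToyGenome(
        contigs=contigs,
        assembly_contigs=tuple(contig_names),
        gene_starts=gene_starts,
        boundaries=boundaries,
        repeat_instances=repeat_instances,
        consensus={n: decode(s) for n, s in consensus.items()},
        config=config,
    )
    genome._encoded = encoded
    return genome


# ---------------------------------------------------------------------------
# Modification (5-hmU) map
# ---------------------------------------------------------------------------


@dataclass
class ModificationMap:
    """Per-position 5-hmU deposition probabilities, one tier per strand.

    ``p_plus`` is nonzero only at reference T positions (plus-strand
    thymines), ``p_minus`` only at reference A positions (thymines of the
    minus strand).  Tiers (baseline / boundary window / repeat family)
    combine by maximum, keeping probabilities bounded.
    """

    p_plus: dict[str, np.ndarray]
    p_minus: dict[str, np.ndarray]
    p0: float
    p_boundary: float
    p_repeat: dict[str, float]
    w_b: int

    def combined(self, contig: str) -> np.ndarray:
        """Per-position probability on either strand (T and A sites are
        disjoint so the sum equals the per-site values)."""
        return self.p_plus[contig] + self.p_minus[contig]

    def local_density(self, contig: str, halfwidth: int = 500) -> np.ndarray:
        """Mean modification probability in a +/- halfwidth window."""
        p = self.combined(contig).astype(np.float64)
        width = 2 * halfwidth + 1
        cs = np.concatenate([[0.0], np.cumsum(p)])
        n = p.size
        lo = np.clip(np.arange(n) - halfwidth, 0, n)
        hi = np.clip(np.arange(n) + halfwidth + 1, 0, n)
        return (cs[hi] - cs[lo]) / (hi - lo)


def build_modification_map(
    genome: ToyGenome,
    p0: float = 0.03,
    p_boundary: float = 0.35,
    p_repeat: Mapping[str, float] | None = None,
    w_b: int = 2_000,
) -> ModificationMap:
    """Assign 5-hmU deposition probabilities to every T/A site.

    The per-site probability is the maximum of the applicable tiers:
    baseline ``p0`` everywhere, ``p_boundary`` within ``w_b`` of a domain
    boundary, and ``p_repeat[family]`` inside instances of that family
    (including surplus collapsed copies on the truth-only contig).
    """
    p_repeat = dict(p_repeat or {})
    for prob, label in [(p0, "p0"), (p_boundary, "p_boundary")]:
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"{label} must lie in [0, 1]")
    known = {fam.name for fam in (genome.config.repeat_families if genome.config else [])}
    known.update(ri.family for ri in genome.repeat_instances)
    for fam_name, prob in p_repeat.items():
        if fam_name not in known:
            raise KeyError(f"unknown repeat family {fam_name!r}")
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"p_repeat[{fam_name!r}] must lie in [0, 1]")

    p_plus: dict[str, np.ndarray] = {}
    p_minus: dict[str, np.ndarray] = {}
    for cname in genome.contigs:
        seq = genome.encoded(cname)
        tier = np.full(seq.size, p0, dtype=np.float32)
        for bc, pos in genome.boundaries:
            if bc != cname:
                continue
            lo, hi = max(0, pos - w_b), min(seq.size, pos + w_b)
            tier[lo:hi] = np.maximum(tier[lo:hi], p_boundary)
        for ri in genome.repeat_instances:
            if ri.contig != cname or ri.family not in p_repeat:
                continue
            tier[ri.start : ri.end] = np.maximum(
                tier[ri.start : ri.end], p_repeat[ri.family]
            )
        p_plus[cname] = np.where(seq == T, tier, 0.0).astype(np.float32)
        p_minus[cname] = np.where(seq == A, tier, 0.0).astype(np.float32)

    return ModificationMap(
        p_plus=p_plus,
        p_minus=p_minus,
        p0=p0,
        p_boundary=p_boundary,
        p_repeat=p_repeat,
        w_b=w_b,
    )


# ---------------------------------------------------------------------------
# Occupancy (protection) map
# ---------------------------------------------------------------------------


@dataclass
class Footprint:
    contig: str
    center: int
    width: int
    strength: float

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass
class OccupancyMap:
    """Per-position protection probability plus the planted footprint list."""

    occupancy: dict[str, np.ndarray]
    footprints: list[Footprint]
    gamma: float
    fp_w: int

    def footprint_intervals(self, contig: str | None = None) -> list[tuple[str, int, int]]:
        out = []
        for fp in self.footprints:
            if contig is None or fp.contig == contig:
                out.append((fp.contig, fp.start, fp.end))
        return out


class OccupancyPlacementError(RuntimeError):
    pass


def build_occupancy_map(
    genome: ToyGenome,
    mod_map: ModificationMap,
    density: float = 0.6,
    gamma: float = 30.0,
    fp_w: int = 140,
    strength: float = 0.9,
    family_multiplier: Mapping[str, float] | None = None,
    seed: int = 0,
    max_batches: int = 200,
) -> OccupancyMap:
    """Place non-overlapping protection footprints along the truth genome.

    Placement odds per candidate center are proportional to
    ``(1 + gamma * local modification density)`` times an optional per-repeat
    family multiplier, so protection couples to 5-hmU when gamma > 0.
    ``density`` is expressed in footprints per kbp; rejection sampling keeps
    footprints disjoint and raises (reporting the achieved density) if the
    requested density cannot be realized.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    if fp_w < 20:
        raise ValueError("fp_w must be >= 20 bp")
    rng = np.random.default_rng(seed)
    family_multiplier = dict(family_multiplier or {})

    cnames = list(genome.contigs)
    weights: dict[str, np.ndarray] = {}
    half = fp_w // 2
    for cname in cnames:
        w = 1.0 + gamma * mod_map.local_density(cname, halfwidth=500)
        for ri in genome.repeat_instances:
            if ri.contig == cname and ri.family in family_multiplier:
                w[ri.start : ri.end] *= family_multiplier[ri.family]
        # a footprint must fit inside the contig
        w[:half] = 0.0
        w[len(w) - (fp_w - half) :] = 0.0
        weights[cname] = w

    total_bp = genome.total_length()
    n_target = int(round(density * total_bp / 1000.0))
    contig_w = np.array([weights[c].sum() for c in cnames])
    contig_p = contig_w / contig_w.sum()

    cum = {c: np.cumsum(weights[c]) for c in cnames}
    occupied = {c: np.zeros(len(genome.contigs[c]), dtype=bool) for c in cnames}
    footprints: list[Footprint] = []

    placed = 0
    for _batch in range(max_batches):
        if placed >= n_target:
            break
        n_draw = max(64, 2 * (n_target - placed))
        c_idx = rng.choice(len(cnames), size=n_draw, p=contig_p)
        u = rng.random(n_draw)
        for ci, ui in zip(c_idx, u):
            if placed >= n_target:
                break
            cname = cnames[ci]
            center = int(np.searchsorted(cum[cname], ui * cum[cname][-1]))
            s, e = center - half, center - half + fp_w
            if s < 0 or e > occupied[cname].size:
                continue
            if occupied[cname][s:e].any():
                continue
            occupied[cname][s:e] = True
            footprints.append(Footprint(cname, center, fp_w, strength))
            placed += 1
    if placed < n_target:
        achieved = placed * 1000.0 / total_bp
        raise OccupancyPlacementError(
            f"requested footprint density {density}/kbp but only "
            f"{achieved:.3f}/kbp could be placed without overlap"
        )

    occ = {
        c: np.where(occupied[c], np.float32(strength), np.float32(0.0))
        for c in cnames
    }
    return OccupancyMap(occupancy=occ, footprints=footprints, gamma=gamma, fp_w=fp_w)
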