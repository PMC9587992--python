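"""In-silico Targeted Locus Amplification (TLA) read simulator.

Emulates the TLA library structure end to end: NlaIII digestion of each
haplotype, haplotype-pure proximity-ligation circles whose fragment content
decays with genomic distance from a viewpoint fragment, inverse-PCR amplicons
anchored at the viewpoint primers, and platform reads — 150 bp paired-end
short reads or full-amplicon long reads — with simple per-base error models.
Every read carries ground-truth provenance (circle, haplotype, constituent
fragment intervals) so downstream mapping, calling and phasing can be
benchmarked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import Read
from .locus_model import (
    NLAIII,
    DiploidLocus,
    Fragment,
    Reference,
    RestrictionEnzyme,
    ValidationError,
    Variant,
    digest,
    inverse_coord_map,
    left_normalize,
    revcomp,
)

__all__ = [
    "Viewpoint",
    "ContactModel",
    "Circle",
    "Amplicon",
    "ReadProfile",
    "SHORT_PROFILE",
    "LONG_PROFILE",
    "SimulationError",
    "HaplotypeFragments",
    "digest_haplotypes",
    "simulate_circle",
    "amplify",
    "generate_reads",
    "simulate_dataset",
    "synthesize_locus",
]

PROVENANCE_COLUMNS = [
    "read_id", "circle_id", "hap",
    "fragment_ref_start", "fragment_ref_end", "read_offset", "strand",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Viewpoint:
    """The restriction fragment carrying the inverse-PCR primer pair.

    ``fragment_interval`` is the reference-coordinate interval of the NlaIII
    fragment; primer offsets are relative to the fragment start.
    """

    name: str
    fragment_interval: tuple[int, int]
    primer_fwd: int
    primer_rev: int

    @classmethod
    def at_position(cls, reference: Reference, pos: int,
                    enzyme: RestrictionEnzyme = NLAIII, name: str = "vp") -> "Viewpoint":
        """Build the viewpoint around the fragment containing ``pos``."""
        for frag in digest(reference.seq, enzyme):
            if frag.start <= pos < frag.end:
                flen = len(frag)
                return cls(name=name, fragment_interval=(frag.start, frag.end),
                           primer_fwd=min(flen - 1, max(1, flen // 3)),
                           primer_rev=max(0, flen - max(1, flen // 3)))
        raise ValidationError(f"position {pos} outside reference")


@dataclass(frozen=True)
class ContactModel:
    """Distance-decay contact model for circle composition.

    The probability of ligating the fragment at inter-fragment ordinal
    distance ``d`` from the viewpoint is proportional to ``(1+d)**-alpha``.
    Circle size is drawn as a geometric number of non-viewpoint fragments but
    is dominated in practice by the amplicon length bounds: fragments keep
    being added until the minimum amplicon length is reached, and circles
    exceeding the maximum are rejected.
    """

    decay_exponent: float = 1.0
    mean_extra_fragments: float = 3.0
    min_amplicon_len: int = 4000
    max_amplicon_len: int = 10000

    def __post_init__(self):
        if self.decay_exponent <= 0:
            raise ValidationError("decay_exponent must be positive")
        if not 0 < self.min_amplicon_len < self.max_amplicon_len:
            raise ValidationError("require 0 < min_amplicon_len < max_amplicon_len")


@dataclass(frozen=True)
class Circle:
    """A haplotype-pure ligation circle: ordered fragments of one haplotype,
    always including the viewpoint fragment."""

    circle_id: int
    hap: int
    fragments: tuple[Fragment, ...]
    viewpoint_index: int  # position of the viewpoint fragment in ``fragments``

    @property
    def seq(self) -> str:
        return "".join(f.seq for f in self.fragments)

    def __len__(self) -> int:
        return sum(len(f) for f in self.fragments)


@dataclass(frozen=True)
class ProvSegment:
    """One contiguous stretch of an amplicon attributed to a fragment."""

    offset: int
    length: int
    hap: int
    ref_start: int
    ref_end: int


@dataclass(frozen=True)
class Amplicon:
    """Linearized TLA-PCR product: the circle rotated to the forward primer."""

    circle_id: int
    seq: str
    provenance: tuple[ProvSegment, ...]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadProfile:
    """Platform read model: ``short`` = paired-end, substitution errors only;
    ``long`` = whole-amplicon reads with substitution and indel errors and a
    length bias favouring shorter amplicons (weight ∝ length**-beta)."""

    platform: str
    read_length: int = 150
    insert_range: tuple[int, int] = (300, 600)
    sub_error_rate: float = 0.0
    indel_error_rate: float = 0.0
    length_bias_exponent: float = 1.0
    quality_q: int = 30

    def __post_init__(self):
        if self.platform not in ("short", "long"):
            raise ValidationError("platform must be 'short' or 'long'")
        if not 0 <= self.sub_error_rate < 1 or not 0 <= self.indel_error_rate < 1:
            raise ValidationError("error rates must lie in [0, 1)")
        if self.read_length < 20:
            raise ValidationError("read_length must be >= 20")


#: Illumina-like preset: 150 bp pairs, low substitution error.
SHORT_PROFILE = ReadProfile(platform="short", read_length=150,
                            sub_error_rate=0.001, quality_q=35)
#: Nanopore-like preset: whole-amplicon reads, mixed error, shorter-read bias.
LONG_PROFILE = ReadProfile(platform="long", sub_error_rate=0.02,
                           indel_error_rate=0.01, length_bias_exponent=1.0,
                           quality_q=12)


# ---------------------------------------------------------------------------
# fragment bookkeeping

@dataclass(frozen=True)
class HaplotypeFragments:
    """Digested fragments of one haplotype with their reference intervals."""

    fragments: tuple[Fragment, ...]
    ref_intervals: tuple[tuple[int, int], ...]
    viewpoint_index: int


def digest_haplotypes(locus: DiploidLocus, viewpoint: Viewpoint,
                      enzyme: RestrictionEnzyme = NLAIII) -> tuple[HaplotypeFragments, HaplotypeFragments]:
    """Digest both haplotypes and locate the viewpoint fragment on each."""
    out = []
    anchor_ref = viewpoint.fragment_interval[0] + viewpoint.primer_fwd
    for hap in (0, 1):
        hap_seq = locus.hap_seqs[hap]
        frags = tuple(digest(hap_seq, enzyme, hap=hap))
        inv = inverse_coord_map(locus.coord_maps[hap], len(hap_seq))
        intervals = tuple((int(inv[f.start]), int(inv[f.end])) for f in frags)
        anchor_hap = locus.hap_position(hap, anchor_ref)
        vp_idx = next(i for i, f in enumerate(frags) if f.start <= anchor_hap < f.end)
        out.append(HaplotypeFragments(frags, intervals, vp_idx))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# circle simulation

def simulate_circle(haps: tuple[HaplotypeFragments, HaplotypeFragments],
                    contact_model: ContactModel,
                    rng: np.random.Generator,
                    circle_id: int = 0,
                    max_attempts: int = 200) -> Circle:
    """Simulate one haplotype-pure ligation circle.

    One haplotype is chosen uniformly; the viewpoint fragment of that
    haplotype is always included and further fragments of the *same*
    haplotype are added without replacement with probability proportional to
    ``(1+d)**-alpha`` (d = ordinal fragment distance) until both the drawn
    fragment count and the minimum amplicon length are satisfied.  Circles
    longer than the maximum amplicon length are rejected and resampled.
    """
    m = contact_model
    for _ in range(max_attempts):
        hap = int(rng.integers(2))
        hf = haps[hap]
        n = len(hf.fragments)
        lengths = np.array([len(f) for f in hf.fragments])
        d = np.abs(np.arange(n) - hf.viewpoint_index).astype(float)
        w = (1.0 + d) ** (-m.decay_exponent)
        w[hf.viewpoint_index] = 0.0
        # window-edge fragments are not true restriction fragments (their
        # outer boundary is the locus edge, not a cut site) and would create
        # motif-free ligation junctions; they never circularize
        w[0] = w[n - 1] = 0.0
        n_target = int(rng.geometric(1.0 / max(1.0, m.mean_extra_fragments)))
        # weighted sampling without replacement (Efraimidis–Spirakis keys)
        u = rng.random(n)
        with np.errstate(divide="ignore"):
            keys = np.where(w > 0, u ** (1.0 / np.where(w > 0, w, 1.0)), -1.0)
        order = np.argsort(-keys)
        chosen = [hf.viewpoint_index]
        total = int(lengths[hf.viewpoint_index])
        ok = False
        for i in order:
            if keys[i] < 0:
                break
            chosen.append(int(i))
            total += int(lengths[i])
            if len(chosen) - 1 >= n_target and total >= m.min_amplicon_len:
                ok = total <= m.max_amplicon_len
                break
        if not ok:
            continue
        # ligation order around the circle is random; orientation stays
        # forward (no inversions)
        order_perm = rng.permutation(len(chosen))
        chosen = [chosen[int(j)] for j in order_perm]
        frags = tuple(hf.fragments[i] for i in chosen)
        return Circle(circle_id=circle_id, hap=hap, fragments=frags,
                      viewpoint_index=chosen.index(hf.viewpoint_index))
    raise SimulationError(
        "no admissible circle within amplicon length bounds "
        f"[{m.min_amplicon_len}, {m.max_amplicon_len}]; adjust the bounds or enlarge the locus"
    )


def amplify(circles: list[Circle], viewpoint: Viewpoint,
            haps: tuple[HaplotypeFragments, HaplotypeFragments]) -> list[Amplicon]:
    """Linearize circles into viewpoint-anchored amplicons.

    The amplicon is the circle sequence rotated so position 0 is the forward
    primer start inside the viewpoint fragment; circles lacking a viewpoint
    fragment are dropped.  Per-base provenance is carried over (the viewpoint
    fragment is split into a leading and a trailing piece by the rotation).
    """
    out = []
    for c in circles:
        hf = haps[c.hap]
        vp_pos_in_circle = None
        segs: list[ProvSegment] = []
        off = 0
        for f in c.fragments:
            idx = f.index
            rs, re_ = hf.ref_intervals[idx]
            segs.append(ProvSegment(off, len(f), c.hap, rs, re_))
            if idx == hf.viewpoint_index:
                vp_pos_in_circle = off
            off += len(f)
        if vp_pos_in_circle is None:
            continue
        vp_frag = c.fragments[c.viewpoint_index]
        rot = vp_pos_in_circle + min(viewpoint.primer_fwd, len(vp_frag) - 1)
        seq = c.seq
        total = len(seq)
        rotated = seq[rot:] + seq[:rot]
        # rotate provenance segments, splitting the one containing ``rot``
        new_segs: list[ProvSegment] = []
        for s in segs:
            pieces = []
            if s.offset < rot < s.offset + s.length:
                cut = rot - s.offset
                frac = cut * (s.ref_end - s.ref_start) // s.length
                pieces = [
                    ProvSegment(s.offset, cut, s.hap, s.ref_start, s.ref_start + frac),
                    ProvSegment(s.offset + cut, s.length - cut, s.hap, s.ref_start + frac, s.ref_end),
                ]
            else:
                pieces = [s]
            for p in pieces:
                new_off = (p.offset - rot) % total
                new_segs.append(replace(p, offset=new_off))
        new_segs.sort(key=lambda s: s.offset)
        out.append(Amplicon(circle_id=c.circle_id, seq=rotated, provenance=tuple(new_segs)))
    return out


# ---------------------------------------------------------------------------
# read generation

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_substitutions(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return arr


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    draws = rng.random(len(seq))
    out = []
    for i, ch in enumerate(seq):
        r = draws[i]
        if r < rate / 2:          # deletion
            continue
        if r < rate:              # insertion after the base
            out.append(ch)
            out.append(chr(_BASES[rng.integers(4)]))
            continue
        out.append(ch)
    return "".join(out)


def _mutate(seq: str, profile: ReadProfile, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr = _apply_substitutions(arr, profile.sub_error_rate, rng)
    seq = arr.tobytes().decode()
    return _apply_indels(seq, profile.indel_error_rate, rng)


def _clip_segments(provenance: tuple[ProvSegment, ...], lo: int, hi: int) -> list[ProvSegment]:
    """Restrict amplicon provenance to window [lo, hi); offsets become window-relative."""
    out = []
    for s in provenance:
        a, b = max(s.offset, lo), min(s.offset + s.length, hi)
        if a >= b:
            continue
        span = s.ref_end - s.ref_start
        rs = s.ref_start + (a - s.offset) * span // s.length
        re_ = s.ref_start + (b - s.offset) * span // s.length
        out.append(ProvSegment(a - lo, b - a, s.hap, rs, re_))
    return out


def generate_reads(amplicons: list[Amplicon], profile: ReadProfile,
                   rng: np.random.Generator, n_reads: int
                   ) -> tuple[list[Read], pd.DataFrame]:
    """Sample reads from amplicons with ground-truth provenance.

    Short mode: ``n_reads`` read pairs; an amplicon is chosen with probability
    proportional to its length, the insert uniformly within it, and the two
    150 bp mates carry substitution errors only.  Long mode: ``n_reads``
    whole-amplicon reads, amplicons chosen with weight ∝ length**-beta,
    substitution and indel errors applied.  Provenance offsets refer to the
    error-free read coordinates (exact when error rates are zero).
    """
    if not amplicons:
        raise ValidationError("no amplicons to sequence")
    lengths = np.array([len(a) for a in amplicons], dtype=float)
    reads: list[Read] = []
    rows: list[tuple] = []
    if profile.platform == "long":
        w = lengths ** (-profile.length_bias_exponent)
        w /= w.sum()
        picks = rng.choice(len(amplicons), size=n_reads, p=w)
        for i, ai in enumerate(picks):
            amp = amplicons[ai]
            rid = f"L{i:06d}"
            seq = _mutate(amp.seq, profile, rng)
            reads.append(Read(read_id=rid, seq=seq, qual=chr(profile.quality_q + 33) * len(seq)))
            for s in amp.provenance:
                rows.append((rid, amp.circle_id, s.hap, s.ref_start, s.ref_end, s.offset, "+"))
    else:
        w = lengths / lengths.sum()
        rl = profile.read_length
        lo_ins, hi_ins = profile.insert_range
        picks = rng.choice(len(amplicons), size=n_reads, p=w)
        for i, ai in enumerate(picks):
            amp = amplicons[ai]
            alen = len(amp)
            insert = int(rng.integers(max(rl, lo_ins), max(rl, hi_ins) + 1))
            insert = min(insert, alen)
            start = int(rng.integers(0, alen - insert + 1))
            end = start + insert
            rid = f"S{i:06d}"
            m1 = amp.seq[start:start + rl]
            m2 = revcomp(amp.seq[end - rl:end])
            for mate, seq_ in ((1, m1), (2, m2)):
                arr = np.frombuffer(seq_.encode(), dtype=np.uint8).copy()
                arr = _apply_substitutions(arr, profile.sub_error_rate, rng)
                reads.append(Read(read_id=rid, seq=arr.tobytes().decode(),
                                  qual=chr(profile.quality_q + 33) * len(seq_), mate=mate))
            for s in _clip_segments(amp.provenance, start, start + rl):
                rows.append((rid, amp.circle_id, s.hap, s.ref_start, s.ref_end, s.offset, "+"))
            for s in _clip_segments(amp.provenance, end - rl, end):
                rows.append((rid, amp.circle_id, s.hap, s.ref_start, s.ref_end, s.offset, "-"))
    prov = pd.DataFrame(rows, columns=PROVENANCE_COLUMNS)
    return reads, prov


# ---------------------------------------------------------------------------
# end-to-end dataset

@dataclass
class SimulatedRun:
    """In-memory product of one simulated TLA sequencing run."""

    locus: DiploidLocus
    viewpoint: Viewpoint
    profile: ReadProfile
    circles: list[Circle]
    amplicons: list[Amplicon]
    reads: list[Read]
    provenance: pd.DataFrame


def simulate_dataset(locus: DiploidLocus, viewpoint: Viewpoint,
                     profile: ReadProfile, contact_model: ContactModel,
                     n_circles: int, n_reads: int,
                     rng: np.random.Generator,
                     enzyme: RestrictionEnzyme = NLAIII) -> SimulatedRun:
    """Simulate circles, amplicons and reads for one viewpoint."""
    haps = digest_haplotypes(locus, viewpoint, enzyme)
    circles = [simulate_circle(haps, contact_model, rng, circle_id=i)
               for i in range(n_circles)]
    amplicons = amplify(circles, viewpoint, haps)
    if n_circles == 0 or n_reads == 0:
        reads, prov = [], pd.DataFrame(columns=PROVENANCE_COLUMNS)
    else:
        reads, prov = generate_reads(amplicons, profile, rng, n_reads)
    return SimulatedRun(locus=locus, viewpoint=viewpoint, profile=profile,
                        circles=circles, amplicons=amplicons, reads=reads,
                        provenance=prov)


# ---------------------------------------------------------------------------
# synthetic locus generator

def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _motif_safe(seq: str, pos: int, ref: str, alt: str, motif: str = "CATG") -> bool:
    """True when swapping ref→alt at pos neither creates nor destroys a motif
    occurrence in the surrounding window (keeps fragment boundaries shared
    between reference and haplotypes)."""
    k = len(motif)
    lo = max(0, pos - k)
    hi = min(len(seq), pos + len(ref) + k)
    before = seq[lo:hi]
    after = seq[lo:pos] + alt + seq[pos + len(ref):hi]
    return (motif in before) == (motif in after) and motif not in after


def synthesize_locus(length: int, rng: np.random.Generator,
                     gc: float = 0.45,
                     n_het_snvs: int = 12, n_het_indels: int = 3,
                     n_hom_alt: int = 2,
                     variant_region: tuple[int, int] | None = None,
                     min_spacing: int = 60,
                     name: str = "locus") -> DiploidLocus:
    """Generate a random diploid locus with planted phased variants.

    Variant sites are placed inside ``variant_region`` (default: the central
    two thirds), at least ``min_spacing`` bases apart, and only where the
    edit neither creates nor destroys an NlaIII site, so reference and
    haplotype fragment grids stay congruent.
    """
    seq = _random_sequence(length, gc, rng)
    ref = Reference(name=name, seq=seq)
    lo, hi = variant_region or (length // 6, length - length // 6)
    n_total = n_het_snvs + n_het_indels + n_hom_alt
    placed: list[Variant] = []
    used: list[int] = []
    attempts = 0
    kinds = (["snv"] * n_het_snvs + ["indel"] * n_het_indels + ["snv"] * n_hom_alt)
    genotypes = ([None] * (n_het_snvs + n_het_indels) + [(1, 1)] * n_hom_alt)
    order = rng.permutation(n_total)
    for idx in order:
        kind, gt = kinds[idx], genotypes[idx]
        while True:
            attempts += 1
            if attempts > 200 * n_total:
                raise SimulationError("could not place all variants; relax constraints")
            pos = int(rng.integers(lo, hi))
            if any(abs(pos - u) < min_spacing for u in used):
                continue
            if kind == "snv":
                r = seq[pos]
                a = str(rng.choice([b for b in "ACGT" if b != r]))
            else:
                if rng.random() < 0.5 and pos + 4 < hi:       # deletion of 1–3 bp
                    dlen = int(rng.integers(1, 4))
                    r = seq[pos:pos + 1 + dlen]
                    a = seq[pos]
                else:                                          # insertion of 1–3 bp
                    r = seq[pos]
                    a = r + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            if not _motif_safe(seq, pos, r, a):
                continue
            if (pos, r, a) != left_normalize(seq, pos, r, a):
                continue  # keep only canonical indel representations
            if gt is None:
                gt = (1, 0) if rng.random() < 0.5 else (0, 1)
            placed.append(Variant(pos=pos, ref_allele=r, alt_allele=a, genotype=gt))
            used.append(pos)
            break
    placed.sort(key=lambda v: v.pos)
    return DiploidLocus.from_reference(ref, placed)


# ---------------------------------------------------------------------------
# file-level simulation entry point

class ConfigError(ValueError):
    pass


_RUN_KEYS = {"reference_fasta", "truth_vcf", "viewpoint_bed", "platform",
             "n_circles", "n_reads", "seed"}
_OPTIONAL_KEYS = {"sub_error_rate", "indel_error_rate", "min_amplicon_len",
                  "max_amplicon_len", "decay_exponent"}


def simulate_run(config: dict, out_dir: str) -> dict[str, str]:
    """Run a full simulation from a config mapping and write its artifacts.

    Writes FASTQ read file(s), the phased truth VCF, a provenance TSV (one
    row per read/fragment attribution) and a truth phase table.  Reruns with
    the same config are byte-identical.  Returns the written paths.
    """
    import os

    from . import io as tio

    missing = sorted(_RUN_KEYS - set(config))
    unknown = sorted(set(config) - _RUN_KEYS - _OPTIONAL_KEYS)
    if missing or unknown:
        raise ConfigError(f"bad config keys: missing={missing}, unknown={unknown}")
    if config["platform"] not in ("short", "long"):
        raise ConfigError("bad config keys: platform must be 'short' or 'long'")
    reference = tio.read_fasta(config["reference_fasta"])[0]
    variants, _ = tio.read_vcf(config["truth_vcf"])
    locus = DiploidLocus.from_reference(reference, variants)
    bed = tio.read_bed(config["viewpoint_bed"])
    name, s, e, vp_name = bed[0]
    viewpoint = Viewpoint.at_position(reference, (s + e) // 2, name=vp_name or "vp")
    base = SHORT_PROFILE if config["platform"] == "short" else LONG_PROFILE
    profile = replace(base, **{k: config[k] for k in ("sub_error_rate", "indel_error_rate")
                               if k in config})
    contact = ContactModel(**{k: config[k] for k in
                              ("decay_exponent", "min_amplicon_len", "max_amplicon_len")
                              if k in config})
    rng = np.random.default_rng(int(config["seed"]))
    run = simulate_dataset(locus, viewpoint, profile, contact,
                           int(config["n_circles"]), int(config["n_reads"]), rng)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    if profile.platform == "short":
        for mate in (1, 2):
            p = os.path.join(out_dir, f"reads_R{mate}.fastq")
            tio.write_fastq(p, [r for r in run.reads if r.mate == mate])
            paths[f"reads_R{mate}"] = p
    else:
        p = os.path.join(out_dir, "reads.fastq")
        tio.write_fastq(p, run.reads)
        paths["reads"] = p
    paths["truth_vcf"] = os.path.join(out_dir, "truth.vcf")
    tio.write_vcf(paths["truth_vcf"], reference, list(locus.variants), phased=True)
    paths["provenance"] = os.path.join(out_dir, "provenance.tsv")
    run.provenance.to_csv(paths["provenance"], sep="\t", index=False)
    paths["phase_table"] = os.path.join(out_dir, "phase_table.tsv")
    with open(paths["phase_table"], "w") as fh:
        fh.write("pos\tref\talt\thap0_allele\thap1_allele\n")
        for v in locus.variants:
            fh.write(f"{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{v.genotype[0]}\t{v.genotype[1]}\n")
    return paths
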