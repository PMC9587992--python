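"""End-to-end pipeline: simulate → split-map → call → phase → benchmark.

One :class:`PipelineConfig` drives everything from a single seed: the
synthetic diploid locus (optionally with a diverged homolog acting as a
mapping decoy), one or more viewpoints, platform-specific read simulation,
split-mapping against the reference (decoy included when present), depth-
filtered calling, link phasing and benchmarking against the planted truth.

Scenario presets encode the qualitative contrasts of interest at desk scale:
a small gene with one viewpoint, a large gene with four combined viewpoints,
a locus shadowed by a 94 %-identity homolog (short vs long reads), and
viewpoints with/without a heterozygous site in the viewpoint fragment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as tio
from .benchmark import (GenotypeComparison, PhasingComparison,
                        compare_genotypes, compare_phasing)
from .link_phaser import PhaseBlock, extract_links, phase
from .locus_model import (NLAIII, DiploidLocus, Reference, Variant, digest,
                          make_homolog)
from .pileup_caller import (LONG_CALLER, SHORT_CALLER, CallerConfig, Pileup,
                            build_pileup, call_variants, coverage_at_depth,
                            on_target_stats)
from .split_mapper import (LONG_MAPPER, SHORT_MAPPER, MapperParams,
                           alignments_to_df, build_index, map_reads)
from .tla_simulator import (LONG_PROFILE, SHORT_PROFILE, ContactModel,
                            ReadProfile, Viewpoint, simulate_dataset,
                            synthesize_locus)

__all__ = ["PipelineConfig", "RunResult", "run_pipeline", "make_scenarios"]


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one pipeline run."""

    name: str = "run"
    seed: int = 0
    # locus generation
    length: int = 12000
    gc: float = 0.45
    n_het_snvs: int = 10
    n_het_indels: int = 3
    n_hom_alt: int = 2
    # homolog decoy
    homolog: bool = False
    homolog_identity: float = 0.94
    # viewpoints
    viewpoint_mode: str = "het"           # het | no_het | fractions
    viewpoint_fractions: tuple[float, ...] = (0.5,)
    # sequencing
    platform: str = "long"
    n_circles: int = 300
    n_reads: int = 1500
    sub_error_rate: float | None = None   # None = platform default
    indel_error_rate: float | None = None
    min_amplicon_len: int = 4000
    max_amplicon_len: int = 10000
    decay_exponent: float = 1.0
    # analysis
    ambiguity_policy: str = "keep"
    min_depth: int | None = None          # None = platform default (25 / 100)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["viewpoint_fractions"] = list(self.viewpoint_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(d) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        if "viewpoint_fractions" in d:
            d = dict(d, viewpoint_fractions=tuple(d["viewpoint_fractions"]))
        return cls(**d)

    @property
    def profile(self) -> ReadProfile:
        base = SHORT_PROFILE if self.platform == "short" else LONG_PROFILE
        kw = {}
        if self.sub_error_rate is not None:
            kw["sub_error_rate"] = self.sub_error_rate
        if self.indel_error_rate is not None:
            kw["indel_error_rate"] = self.indel_error_rate
        return replace(base, **kw) if kw else base

    @property
    def mapper(self) -> MapperParams:
        base = SHORT_MAPPER if self.platform == "short" else LONG_MAPPER
        return replace(base, ambiguity_policy=self.ambiguity_policy)

    @property
    def caller(self) -> CallerConfig:
        base = SHORT_CALLER if self.platform == "short" else LONG_CALLER
        if self.min_depth is not None:
            base = replace(base, min_depth=self.min_depth)
        return base

    @property
    def contact(self) -> ContactModel:
        return ContactModel(decay_exponent=self.decay_exponent,
                            min_amplicon_len=self.min_amplicon_len,
                            max_amplicon_len=self.max_amplicon_len)

    @property
    def roi(self) -> tuple[int, int]:
        """Region of interest: where variants are planted (the 'gene')."""
        return self.length * 22 // 100, self.length * 78 // 100


@dataclass
class RunResult:
    config: PipelineConfig
    locus: DiploidLocus
    viewpoints: list[Viewpoint]
    reads: list
    provenance: pd.DataFrame
    alignments: list
    remnants: list
    pileup: Pileup
    calls: list
    blocks: list[PhaseBlock]
    links: list
    on_target: dict
    coverage: dict
    genotype_cmp: GenotypeComparison
    phasing_cmp: PhasingComparison
    manifest: dict[str, str] = field(default_factory=dict)

    @property
    def het_calls(self) -> list:
        return [c for c in self.calls if c.is_het]

    def report(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "on_target": {k: v for k, v in self.on_target.items()},
            "coverage": {k: v for k, v in self.coverage.items()
                         if k != "zero_depth_intervals"},
            "genotypes": self.genotype_cmp.as_dict(),
            "phasing": self.phasing_cmp.as_dict(),
        }


def _place_viewpoints(cfg: PipelineConfig, locus: DiploidLocus) -> list[Viewpoint]:
    ref = locus.reference
    frags = digest(ref.seq, NLAIII)
    center = cfg.length // 2
    if cfg.viewpoint_mode == "fractions":
        return [Viewpoint.at_position(ref, int(f * cfg.length), name=f"vp{i}")
                for i, f in enumerate(cfg.viewpoint_fractions)]
    het_snv_pos = [v.pos for v in locus.het_variants if v.kind == "SNV"]
    if cfg.viewpoint_mode == "het":
        pos = min(het_snv_pos, key=lambda p: abs(p - center))
        return [Viewpoint.at_position(ref, pos, name="vp_het")]
    if cfg.viewpoint_mode == "no_het":
        # viewpoint with no het site nearby: the variant-free fragment (in
        # the central 60% of the locus) farthest from any heterozygous site,
        # so enrichment concentrates away from the variants
        occupied = [(v.pos, v.end) for v in locus.variants]
        het_pos = [v.pos for v in locus.het_variants]

        def clean(f):
            return all(e <= f.start or s >= f.end for s, e in occupied)

        lo, hi = cfg.length * 20 // 100, cfg.length * 80 // 100
        cand = [f for f in frags[1:-1]
                if clean(f) and len(f) >= 60 and lo <= f.start and f.end <= hi]
        best = max(cand, key=lambda f: min(abs((f.start + f.end) // 2 - p)
                                           for p in het_pos))
        return [Viewpoint.at_position(ref, (best.start + best.end) // 2, name="vp_nohet")]
    raise ValueError(f"unknown viewpoint_mode {cfg.viewpoint_mode!r}")


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> RunResult:
    """Execute all stages for one configuration; optionally write artifacts."""
    ss = np.random.SeedSequence(config.seed)
    ss_locus, ss_hom, ss_sim, ss_map = ss.spawn(4)

    # --- locus & viewpoints -------------------------------------------------
    locus = synthesize_locus(config.length, np.random.default_rng(ss_locus),
                             gc=config.gc, n_het_snvs=config.n_het_snvs,
                             n_het_indels=config.n_het_indels,
                             n_hom_alt=config.n_hom_alt,
                             variant_region=config.roi, name=config.name)
    viewpoints = _place_viewpoints(config, locus)
    references = {locus.reference.name: locus.reference.seq}
    hom_locus = None
    if config.homolog:
        hseed = int(ss_hom.generate_state(1)[0]) & 0x7FFFFFFF
        hom_seq = make_homolog(locus.reference.seq, config.homolog_identity, hseed)
        hom_ref = Reference(name=f"{config.name}_hom", seq=hom_seq)
        hom_locus = DiploidLocus.from_reference(hom_ref, [])
        references[hom_ref.name] = hom_seq

    # --- simulate -----------------------------------------------------------
    sim_children = ss_sim.spawn(2 * len(viewpoints))
    reads, prov_frames = [], []
    for i, vp in enumerate(viewpoints):
        rng = np.random.default_rng(sim_children[2 * i])
        run = simulate_dataset(locus, vp, config.profile, config.contact,
                               config.n_circles, config.n_reads, rng)
        for r in run.reads:
            reads.append(replace(r, read_id=f"V{i}_{r.read_id}"))
        p = run.provenance.copy()
        p["read_id"] = f"V{i}_" + p["read_id"]
        prov_frames.append(p)
        if hom_locus is not None:
            # the homolog is enriched by the same primers: a matched run from
            # the homologous viewpoint, carrying no variants
            hvp = Viewpoint.at_position(hom_locus.reference,
                                        vp.fragment_interval[0] + vp.primer_fwd,
                                        name=f"{vp.name}_hom")
            rng_h = np.random.default_rng(sim_children[2 * i + 1])
            hrun = simulate_dataset(hom_locus, hvp, config.profile, config.contact,
                                    config.n_circles, config.n_reads, rng_h)
            for r in hrun.reads:
                reads.append(replace(r, read_id=f"H{i}_{r.read_id}"))
            hp = hrun.provenance.copy()
            hp["read_id"] = f"H{i}_" + hp["read_id"]
            hp["hap"] = -1  # homolog provenance: not a locus haplotype
            prov_frames.append(hp)
    provenance = pd.concat(prov_frames, ignore_index=True) if prov_frames \
        else pd.DataFrame()

    # --- map ----------------------------------------------------------------
    index = build_index(references, k=config.mapper.k)
    rng_map = np.random.default_rng(ss_map)
    alignments, remnants = map_reads(reads, index, NLAIII, config.mapper, rng_map)

    # --- pileup & call ------------------------------------------------------
    pileup = build_pileup(alignments, locus.reference, reads)
    calls = call_variants(pileup, config.caller)
    roi = [config.roi]
    on_target = on_target_stats(alignments, [(locus.reference.name, *config.roi)])
    coverage = coverage_at_depth(pileup, config.caller.min_depth, roi)

    # --- phase --------------------------------------------------------------
    het_calls = sorted((c for c in calls if c.is_het), key=lambda c: c.pos)
    _, links = extract_links(alignments, reads, het_calls, locus.reference)
    blocks = phase(links, het_calls)

    # --- benchmark ----------------------------------------------------------
    genotype_cmp = compare_genotypes(calls, list(locus.variants), pileup, config.caller)
    phasing_cmp = compare_phasing(blocks, het_calls, list(locus.variants))

    result = RunResult(config=config, locus=locus, viewpoints=viewpoints,
                       reads=reads, provenance=provenance,
                       alignments=alignments, remnants=remnants,
                       pileup=pileup, calls=calls, blocks=blocks, links=links,
                       on_target=on_target, coverage=coverage,
                       genotype_cmp=genotype_cmp, phasing_cmp=phasing_cmp)
    if out_dir is not None:
        _write_outputs(result, references, out_dir)
    return result


def _write_outputs(result: RunResult, references: dict[str, str], out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    cfg = result.config
    locus = result.locus

    def path(name: str) -> str:
        return os.path.join(out_dir, name)

    tio.write_fasta(path("reference.fasta"),
                    [Reference(name=n, seq=s) for n, s in sorted(references.items())])
    tio.write_vcf(path("truth.vcf"), locus.reference, list(locus.variants), phased=True)
    tio.write_bed(path("viewpoints.bed"),
                  [(locus.reference.name, *vp.fragment_interval, vp.name)
                   for vp in result.viewpoints])
    if cfg.platform == "short":
        tio.write_fastq(path("reads_R1.fastq"), [r for r in result.reads if r.mate == 1])
        tio.write_fastq(path("reads_R2.fastq"), [r for r in result.reads if r.mate == 2])
    else:
        tio.write_fastq(path("reads.fastq"), result.reads)
    result.provenance.to_csv(path("provenance.tsv"), sep="\t", index=False)
    alignments_to_df(result.alignments).to_csv(path("alignments.tsv"), sep="\t", index=False)
    pd.DataFrame([r.__dict__ for r in result.remnants]).to_csv(
        path("remnants.tsv"), sep="\t", index=False)
    # calls as an unphased VCF with DP/AF, then the phased VCF with PS tags
    call_variants_list = [Variant(pos=c.pos, ref_allele=c.ref_allele,
                                  alt_allele=c.alt_allele,
                                  genotype=(0, 1) if c.is_het else (1, 1))
                          for c in result.calls]
    info = {c.pos: {"DP": c.depth, "AF": round(c.alt_fraction, 4)} for c in result.calls}
    tio.write_vcf(path("calls.vcf"), locus.reference, call_variants_list,
                  phased=False, info=info)
    het_calls = result.het_calls
    phase_sets: dict[int, int] = {}
    phased_variants: list[Variant] = []
    side_of: dict[int, int] = {}
    for b in result.blocks:
        if b.phased:
            for vid, side in b.assignment.items():
                side_of[vid] = side
                phase_sets[het_calls[vid].pos] = b.block_id
    for vid, c in enumerate(het_calls):
        side = side_of.get(vid)
        gt = (1, 0) if side == 0 else (0, 1)
        phased_variants.append(Variant(pos=c.pos, ref_allele=c.ref_allele,
                                       alt_allele=c.alt_allele, genotype=gt))
    tio.write_vcf(path("phased.vcf"), locus.reference, phased_variants,
                  phased=True, phase_sets=phase_sets)
    pd.DataFrame([(het_calls[l.var_a].pos, het_calls[l.var_b].pos, l.n_cis, l.n_trans)
                  for l in result.links],
                 columns=["pos_a", "pos_b", "n_cis", "n_trans"]
                 ).to_csv(path("links.tsv"), sep="\t", index=False)
    pd.DataFrame([(b.block_id, len(b.variant_ids), int(b.phased), b.agreement_score)
                  for b in result.blocks],
                 columns=["block_id", "n_variants", "phased", "agreement_score"]
                 ).to_csv(path("blocks.tsv"), sep="\t", index=False)
    zero_bed = [(locus.reference.name, s, e, "zero_depth")
                for s, e in result.coverage["zero_depth_intervals"]]
    tio.write_bed(path("zero_depth.bed"), zero_bed)
    with open(path("report.json"), "w") as fh:
        json.dump(result.report(), fh, indent=2, sort_keys=True)
    # manifest: checksums of every artifact written above
    manifest = {}
    for name in sorted(os.listdir(out_dir)):
        if name in ("manifest.json", "run.log"):
            continue
        with open(os.path.join(out_dir, name), "rb") as fh:
            manifest[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(path("run.log"), "w") as fh:
        fh.write(f"pipeline {cfg.name}\n")
        for k, v in sorted(cfg.to_dict().items()):
            fh.write(f"{k} = {v}\n")
        fh.write(f"reads = {len(result.reads)}\n")
        fh.write(f"alignments = {len(result.alignments)}\n")
        fh.write(f"calls = {len(result.calls)}\n")
    result.manifest = manifest


def make_scenarios(seed: int = 1) -> dict[str, PipelineConfig]:
    """Named presets encoding the study's qualitative contrasts at desk scale.

    Matched pairs (homolog short/long; viewpoint with/without het) share a
    seed, hence the same locus, and differ only in the contrasted setting.
    """
    return {
        # error-free long-read run: the clean end-to-end recovery scenario
        "noise_free_long": PipelineConfig(
            name="noise_free_long", seed=seed, length=12000,
            n_het_snvs=10, n_het_indels=3, n_hom_alt=2,
            platform="long", sub_error_rate=0.0, indel_error_rate=0.0,
            viewpoint_mode="het", n_circles=300, n_reads=1800),
        # small gene, one viewpoint, short reads
        "small_gene_short": PipelineConfig(
            name="small_gene_short", seed=seed + 1, length=10000,
            n_het_snvs=10, n_het_indels=2, n_hom_alt=2,
            platform="short", viewpoint_mode="het",
            n_circles=300, n_reads=5000),
        # large gene, four viewpoints combined before pileup
        "four_viewpoints_short": PipelineConfig(
            name="four_viewpoints_short", seed=seed + 2, length=20000,
            n_het_snvs=12, n_het_indels=3, n_hom_alt=2,
            platform="short", viewpoint_mode="fractions",
            viewpoint_fractions=(0.3, 0.45, 0.6, 0.7),
            n_circles=150, n_reads=1800),
        # pseudogene-shadowed locus, short vs long reads (matched seed)
        "homolog_short": PipelineConfig(
            name="homolog_short", seed=seed + 3, length=9000,
            n_het_snvs=10, n_het_indels=2, n_hom_alt=2,
            homolog=True, platform="short", viewpoint_mode="het",
            n_circles=250, n_reads=3000),
        "homolog_long": PipelineConfig(
            name="homolog_long", seed=seed + 3, length=9000,
            n_het_snvs=10, n_het_indels=2, n_hom_alt=2,
            homolog=True, platform="long", viewpoint_mode="het",
            n_circles=250, n_reads=1000),
        # sparse short-read linking with/without a het in the viewpoint
        # fragment (matched seed): a larger locus keeps pairwise fragment
        # co-occurrence rare, so links hinge on the always-present viewpoint
        "viewpoint_with_het_short": PipelineConfig(
            name="viewpoint_with_het_short", seed=seed + 4, length=24000,
            n_het_snvs=10, n_het_indels=0, n_hom_alt=0,
            platform="short", viewpoint_mode="het", decay_exponent=1.3,
            n_circles=400, n_reads=5000),
        "viewpoint_no_het_short": PipelineConfig(
            name="viewpoint_no_het_short", seed=seed + 4, length=24000,
            n_het_snvs=10, n_het_indels=0, n_hom_alt=0,
            platform="short", viewpoint_mode="no_het", decay_exponent=1.3,
            n_circles=400, n_reads=5000),
    }
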