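"""File input/output: FASTA, FASTQ, VCF, BED and the pipeline's TSV tables.

FASTA/FASTQ go through Biopython, VCF through pysam, BED and TSV through
pandas.  All writers are deterministic (no timestamps or unordered dicts) so
pipeline manifests are reproducible byte-for-byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus_model import Reference, Variant

__all__ = [
    "read_fasta", "write_fasta", "write_fastq", "read_fastq",
    "read_vcf", "write_vcf", "read_bed", "write_bed",
]


def read_fasta(path: str | os.PathLike) -> list[Reference]:
    return [Reference(name=r.id, seq=str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | os.PathLike, references: list[Reference]) -> None:
    records = [SeqRecord(Seq(r.seq), id=r.name, description="") for r in references]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class Read:
    """One sequencing read.  ``mate`` is 0 for single-end, 1/2 for pairs;
    ``molecule`` groups the two mates of a pair (and equals ``read_id`` for
    single-end reads)."""

    read_id: str
    seq: str
    qual: str
    mate: int = 0

    @property
    def molecule(self) -> str:
        return self.read_id


def write_fastq(path: str | os.PathLike, reads: list[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            name = r.read_id if r.mate == 0 else f"{r.read_id}/{r.mate}"
            fh.write(f"@{name}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str | os.PathLike) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        name = rec.id
        mate = 0
        if name.endswith("/1") or name.endswith("/2"):
            mate = int(name[-1])
            name = name[:-2]
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(read_id=name, seq=str(rec.seq).upper(), qual=qual, mate=mate))
    return reads


def _vcf_header(reference: Reference, phased: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={reference.name},length={len(reference)}>")
    header.info.add("DP", 1, "Integer", "Raw position depth")
    header.info.add("AF", "A", "Float", "ALT allele fraction")
    header.formats.add("GT", 1, "String", "Genotype")
    if phased:
        header.formats.add("PS", 1, "Integer", "Phase set (block id)")
    header.add_sample("SAMPLE")
    return header


def write_vcf(
    path: str | os.PathLike,
    reference: Reference,
    variants: list[Variant],
    phased: bool = True,
    phase_sets: dict[int, int] | None = None,
    info: dict[int, dict] | None = None,
) -> None:
    """Write a single-sample VCF.

    ``phase_sets`` maps variant pos → PS block id; variants without an entry
    are written unphased ("/").  ``info`` maps pos → {"DP": ..., "AF": ...}.
    """
    header = _vcf_header(reference, phased)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in variants:
            rec = vf.new_record(
                contig=reference.name,
                start=v.pos,
                alleles=(v.ref_allele, v.alt_allele),
            )
            extra = (info or {}).get(v.pos)
            if extra:
                for k, val in extra.items():
                    rec.info[k] = val
            rec.samples["SAMPLE"]["GT"] = tuple(v.genotype)
            in_block = phase_sets is not None and v.pos in phase_sets
            rec.samples["SAMPLE"].phased = bool(phased and (phase_sets is None or in_block))
            if phased and in_block:
                rec.samples["SAMPLE"]["PS"] = phase_sets[v.pos]
            vf.write(rec)


def read_vcf(path: str | os.PathLike) -> tuple[list[Variant], dict[int, int]]:
    """Read a single-sample VCF into variants plus a pos→PS map.

    Unphased genotypes are normalized so the lower allele index comes first;
    phased ones keep their order.
    """
    variants: list[Variant] = []
    phase_sets: dict[int, int] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sample = rec.samples[0]
            gt = sample["GT"]
            if gt is None or any(g is None for g in gt):
                continue
            g = tuple(int(x) for x in gt)
            if not sample.phased:
                g = tuple(sorted(g))
            variants.append(
                Variant(pos=rec.start, ref_allele=rec.ref, alt_allele=rec.alts[0], genotype=g)
            )
            ps = sample.get("PS") if "PS" in rec.format else None
            if sample.phased and ps is not None:
                phase_sets[rec.start] = int(ps)
    return variants, phase_sets


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else ""
        out.append((str(row[0]), int(row[1]), int(row[2]), name))
    return out


def write_bed(path: str | os.PathLike, intervals: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
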