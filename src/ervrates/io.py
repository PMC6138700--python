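"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions follow the named standards bit-exactly: VCF positions are
1-based, BED / bedGraph intervals 0-based half-open.  Singleton VCFs carry
the carrier sample in the ``SAMPLE`` INFO field (plus ``AC``) instead of
genotype columns.
"""

from __future__ import annotations

import pandas as pd

from .kmers import GenomeSequence, VariantRecord


def read_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """BED intervals (0-based half-open) grouped by chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    for ivs in out.values():
        ivs.sort()
    return out


def write_bed(intervals: dict[str, list[tuple[int, int]]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for start, end in intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bedgraph(path: str) -> dict[str, list[tuple[int, int, float]]]:
    out: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            out.setdefault(chrom, []).append((int(start), int(end), float(value)))
    for ivs in out.values():
        ivs.sort()
    return out


def write_bedgraph(track: dict[str, list[tuple[int, int, float]]], path: str,
                   name: str | None = None) -> None:
    with open(path, "w") as fh:
        if name:
            fh.write(f"track type=bedGraph name={name}\n")
        for chrom in track:
            for start, end, value in track[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def vcf_header(genome: GenomeSequence, extra_info: list[str] | None = None) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for chrom in genome.chrom_names:
        lines.append(f"##contig=<ID={chrom},length={genome.length(chrom)}>")
    lines.append('##INFO=<ID=AC,Number=1,Type=Integer,Description="Allele count">')
    lines.append('##INFO=<ID=SAMPLE,Number=1,Type=String,Description='
                 '"Carrier sample of a singleton">')
    for line in extra_info or []:
        lines.append(line)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


def write_vcf(variants: list[VariantRecord], genome: GenomeSequence,
              path: str) -> None:
    """Sites-only VCF; sample and allele count go into INFO."""
    with open(path, "w") as fh:
        fh.write(vcf_header(genome))
        for v in variants:
            info = f"AC={v.allele_count}"
            if v.sample:
                info += f";SAMPLE={v.sample}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str) -> list[VariantRecord]:
    """Biallelic SNVs from a VCF; non-SNV records are skipped."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                continue
            ac = rec.info.get("AC", 1)
            if isinstance(ac, tuple):
                ac = ac[0]
            out.append(VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                sample=str(rec.info.get("SAMPLE", "")),
                allele_count=int(ac)))
    return out


def read_denovo_tsv(path: str) -> list[VariantRecord]:
    """De novo mutations as 4-column TSV: chrom, pos (1-based), ref, alt."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "ref", "alt"],
                     dtype={"chrom": str})
    return [VariantRecord(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
            for r in df.itertuples()]


def write_denovo_tsv(variants: list[VariantRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")
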