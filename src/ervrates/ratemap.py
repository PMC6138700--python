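"""Genome-wide per-site predicted mutation probabilities and VCF annotation.

Every predictable site gets three independent probabilities, one per
possible alternative allele, from the inverse-logit of its subtype's
feature-effect model evaluated at the local predictor values.  Sites whose
subtype has no fitted model, or that fall inside the configured telomeric
exclusion (where feature data are typically unavailable), fall back to the
marginal 7-mer relative rate; provenance is recorded per site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureTrack, SubtypeEffectModel, annotate_features
from .kmers import (
    ContextError,
    GenomeSequence,
    MutationSubtype,
    canonical_subtype,
    extract_context,
    subtype_index,
)
from .rates import RateTable


@dataclass
class SiteRatePrediction:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, str, str]          # genome-strand alternative alleles
    probabilities: tuple[float, float, float]
    provenance: str                     # "feature-model" | "marginal-7mer-fallback"


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _site_subtypes(genome: GenomeSequence, chrom: str, pos: int
                   ) -> tuple[str, list[tuple[str, MutationSubtype]]]:
    """Genome-strand ref and the 3 (genome-strand alt, canonical subtype)."""
    ctx = extract_context(genome, chrom, pos, 7)
    ref = ctx[3]
    out = []
    for alt in "ACGT":
        if alt == ref:
            continue
        out.append((alt, canonical_subtype(ref, alt, ctx)))
    return ref, out


def predict_site_rate(genome: GenomeSequence, chrom: str, pos: int,
                      models: dict[MutationSubtype, SubtypeEffectModel],
                      marginal: RateTable,
                      tracks: list[FeatureTrack] | None = None,
                      depth: FeatureTrack | None = None,
                      telomere_bp: int = 0,
                      window_bp: int = 10_000) -> SiteRatePrediction:
    """Three per-alt mutation probabilities for one site.

    Uses all estimated effects of the subtype's model (significant or not).
    Sites within ``telomere_bp`` of a contig end, or whose subtype has no
    fitted model, receive the marginal 7-mer rate with fallback provenance.
    N-contexts raise :class:`ContextError`.
    """
    ref, subs = _site_subtypes(genome, chrom, pos)
    in_telomere = (pos <= telomere_bp
                   or pos > genome.length(chrom) - telomere_bp)
    idx = subtype_index(7)
    probs, prov = [], []
    x = None
    for alt, sub in subs:
        model = models.get(sub)
        if in_telomere or model is None or not model.fitted:
            probs.append(float(marginal.rates[idx[sub]]))
            prov.append("marginal-7mer-fallback")
            continue
        if x is None:
            x, keep, _ = annotate_features([(chrom, pos)], genome,
                                           tracks or [], depth, window_bp)
            if not keep[0]:
                x = np.nan_to_num(x)  # missing predictors contribute nothing
        probs.append(float(model.predict_probability(x[0])[0]))
        prov.append("feature-model")
    provenance = ("feature-model" if all(p == "feature-model" for p in prov)
                  else "marginal-7mer-fallback" if all(
                      p == "marginal-7mer-fallback" for p in prov)
                  else "mixed")
    alts = tuple(a for a, _ in subs)
    return SiteRatePrediction(chrom, pos, ref, alts, tuple(probs), provenance)


def predict_map(genome: GenomeSequence,
                models: dict[MutationSubtype, SubtypeEffectModel],
                marginal: RateTable,
                tracks: list[FeatureTrack] | None = None,
                depth: FeatureTrack | None = None,
                telomere_bp: int = 0,
                chroms: list[str] | None = None):
    """Yield :class:`SiteRatePrediction` in coordinate order, skipping
    N-context sites."""
    for chrom in chroms or genome.chrom_names:
        for pos in range(4, genome.length(chrom) - 2):
            try:
                yield predict_site_rate(genome, chrom, pos, models, marginal,
                                        tracks, depth, telomere_bp)
            except ContextError:
                continue


def write_map(predictions, path: str, fmt: str = "tsv") -> None:
    """Stream predictions to a 6-column TSV or per-alt bedGraph tracks.

    Floats are written with 6 significant digits; out-of-order input is an
    error so downstream consumers can rely on sorted coordinates.
    """
    if fmt not in ("tsv", "bedgraph"):
        raise ValueError(f"unsupported format {fmt!r}")
    last: dict[str, int] = {}
    seen_order: list[str] = []
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("#chrom\tpos\tref\talt1_p\talt2_p\talt3_p\n")
        else:
            fh.write("track type=bedGraph name=mutation_rate\n")
        for p in predictions:
            if p.chrom in last:
                if p.pos <= last[p.chrom] or seen_order[-1] != p.chrom:
                    raise ValueError(
                        f"predictions out of coordinate order at {p.chrom}:{p.pos}")
            else:
                seen_order.append(p.chrom)
            last[p.chrom] = p.pos
            vals = "\t".join(f"{v:.6g}" for v in p.probabilities)
            if fmt == "tsv":
                fh.write(f"{p.chrom}\t{p.pos}\t{p.ref}\t{vals}\n")
            else:
                total = sum(p.probabilities)
                fh.write(f"{p.chrom}\t{p.pos - 1}\t{p.pos}\t{total:.6g}\n")


def merge_equal_runs(intervals: list[tuple[int, int, float]]
                     ) -> list[tuple[int, int, float]]:
    """Run-length merge of adjacent equal-valued half-open intervals."""
    out: list[tuple[int, int, float]] = []
    for start, end, value in intervals:
        if out and out[-1][1] == start and out[-1][2] == value:
            out[-1] = (out[-1][0], end, value)
        else:
            out.append((start, end, value))
    return out


def annotate_vcf(vcf_in: str, vcf_out: str, genome: GenomeSequence,
                 table: RateTable,
                 models: dict[MutationSubtype, SubtypeEffectModel] | None = None,
                 tracks: list[FeatureTrack] | None = None,
                 depth: FeatureTrack | None = None) -> dict:
    """Annotate SNV records with subtype, K-mer rate and model probability.

    Adds INFO fields ``SUBTYPE``, ``KRATE`` and (when models are given)
    ``PRED``.  Non-SNV records pass through with a ``NOANN`` flag; records
    whose REF disagrees with the genome are flagged ``REFMISMATCH`` rather
    than silently annotated.  Returns annotation counts.
    """
    import pysam

    stats = {"annotated": 0, "passthrough": 0, "ref_mismatch": 0, "no_context": 0}
    idx = subtype_index(table.k)
    with pysam.VariantFile(vcf_in) as vf:
        header = vf.header.copy()
        header.add_line('##INFO=<ID=SUBTYPE,Number=1,Type=String,'
                        'Description="Canonical mutation subtype">')
        header.add_line(f'##INFO=<ID=KRATE,Number=1,Type=Float,'
                        f'Description="Relative {table.k}-mer mutation rate">')
        header.add_line('##INFO=<ID=PRED,Number=1,Type=Float,'
                        'Description="Feature-model predicted probability">')
        header.add_line('##INFO=<ID=NOANN,Number=0,Type=Flag,'
                        'Description="Record not annotated (non-SNV)">')
        header.add_line('##INFO=<ID=REFMISMATCH,Number=0,Type=Flag,'
                        'Description="VCF REF disagrees with genome">')
        with pysam.VariantFile(vcf_out, "w", header=header) as out:
            for rec in vf:
                nrec = rec.copy()
                nrec.translate(header)
                is_snv = (rec.alts is not None and len(rec.alts) == 1
                          and len(rec.ref) == 1 and len(rec.alts[0]) == 1)
                if not is_snv:
                    nrec.info["NOANN"] = True
                    stats["passthrough"] += 1
                    out.write(nrec)
                    continue
                if genome.base(rec.chrom, rec.pos) != rec.ref:
                    nrec.info["REFMISMATCH"] = True
                    stats["ref_mismatch"] += 1
                    out.write(nrec)
                    continue
                try:
                    ctx = extract_context(genome, rec.chrom, rec.pos, table.k)
                except ContextError:
                    nrec.info["NOANN"] = True
                    stats["no_context"] += 1
                    out.write(nrec)
                    continue
                sub = canonical_subtype(rec.ref, rec.alts[0], ctx)
                nrec.info["SUBTYPE"] = str(sub)
                nrec.info["KRATE"] = float(table.rates[idx[sub]])
                if models is not None:
                    m = models.get(sub)
                    if m is not None and m.fitted:
                        x, keep, _ = annotate_features(
                            [(rec.chrom, rec.pos)], genome, tracks or [], depth)
                        if not keep[0]:
                            x = np.nan_to_num(x)
                        nrec.info["PRED"] = float(m.predict_probability(x[0])[0])
                stats["annotated"] += 1
                out.write(nrec)
    return stats
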