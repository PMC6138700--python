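"""Synthetic genomes, feature tracks, singleton cohorts and de novo sets.

The forward model mirrors the analysis model exactly: every eligible site
and alternative allele carries an independent Bernoulli singleton
indicator whose log-odds are the subtype's baseline log-odds plus the
site's feature effects — the same linear predictor the feature-effect
regressions estimate.  De novo sets are drawn with probability
proportional to the same (optionally perturbed) rates.  Every generator is
deterministic given its seed, and the :class:`GroundTruth` object records
enough to recompute any estimator's expectation.

Default baseline rates are calibrated to the observed singleton spectrum
of large human cohorts: transitions more common than transversions, CpG
C>T hypermutable (~0.12), with per-7-mer lognormal spread around the
type-level mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .kmers import (
    BASES,
    GenomeSequence,
    VariantRecord,
    decode,
    enumerate_subtypes,
    genome_motif_ranks,
    n_subtypes,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: baseline mean relative rate per basic type (proportion of motif sites
#: carrying a singleton); CpG C>T handled separately
DEFAULT_TYPE_RATES = {
    "A>C": 0.004, "A>G": 0.018, "A>T": 0.004,
    "C>A": 0.007, "C>G": 0.007, "C>T": 0.022,
}
DEFAULT_CPG_CT_RATE = 0.12
DEFAULT_LOG_SD = 0.5


@dataclass
class GroundTruth:
    """Everything needed to recompute expectations for any estimator."""

    rates7: np.ndarray                       # true rate per 7-mer subtype
    feature_betas: dict = field(default_factory=dict)
    # {subtype_index: {feature_name: log-odds}}
    feature_names: list[str] = field(default_factory=list)
    signatures: np.ndarray | None = None     # 3 x 96, for QC spike-ins
    contributions: np.ndarray | None = None
    seeds: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "rates7": self.rates7.tolist(),
            "feature_betas": {str(k): v for k, v in self.feature_betas.items()},
            "feature_names": self.feature_names,
            "signatures": None if self.signatures is None
            else self.signatures.tolist(),
            "contributions": None if self.contributions is None
            else self.contributions.tolist(),
            "seeds": self.seeds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(rates7=np.array(d["rates7"]),
                   feature_betas={int(k): v
                                  for k, v in d["feature_betas"].items()},
                   feature_names=d["feature_names"],
                   signatures=None if d["signatures"] is None
                   else np.array(d["signatures"]),
                   contributions=None if d["contributions"] is None
                   else np.array(d["contributions"]),
                   seeds=d["seeds"])


def gen_genome(length_bp: int, gc_fraction: float = 0.4, n_contigs: int = 1,
               seed: int = 0, mask_fraction: float = 0.0) -> GenomeSequence:
    """I.i.d.-base reference with the requested GC content.

    Contigs split the total length as evenly as possible.  When
    ``mask_fraction`` > 0, random intervals totalling roughly that share
    of each contig are marked accessible=False... masked; the rest is
    accessible.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if length_bp < 7 * n_contigs:
        raise ValueError("need at least 7 bp per contig")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    base_len = length_bp // n_contigs
    seqs, mask_intervals = {}, {}
    for i in range(n_contigs):
        ln = base_len + (length_bp % n_contigs if i == n_contigs - 1 else 0)
        codes = rng.choice(4, size=ln, p=p)
        name = f"chr{i + 1}"
        seqs[name] = decode(codes)
        ivs = []
        if mask_fraction > 0:
            n_iv = max(1, int(mask_fraction * ln / 200))
            for _ in range(n_iv):
                start = int(rng.integers(0, max(1, ln - 200)))
                ivs.append((start, min(ln, start + 200)))
        mask_intervals[name] = _complement_intervals(ivs, ln) \
            if mask_fraction > 0 else [(0, ln)]
    return GenomeSequence.from_strings(seqs, mask_intervals)


def _complement_intervals(ivs: list[tuple[int, int]], length: int
                          ) -> list[tuple[int, int]]:
    """Accessible regions = contig minus the masked-out intervals."""
    covered = np.zeros(length, dtype=bool)
    for s, e in ivs:
        covered[s:e] = True
    out, start = [], None
    for i, c in enumerate(~covered):
        if c and start is None:
            start = i
        elif not c and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, length))
    return out


def make_truth(seed: int = 0,
               type_rates: dict[str, float] | None = None,
               cpg_ct_rate: float = DEFAULT_CPG_CT_RATE,
               log_sd: float = DEFAULT_LOG_SD,
               feature_betas: dict | None = None,
               feature_names: list[str] | None = None) -> GroundTruth:
    """True per-7-mer rates: lognormal spread around type-level means.

    CpG C>T subtypes (central C followed by G) get the hypermutable mean.
    """
    type_rates = type_rates or DEFAULT_TYPE_RATES
    rng = np.random.default_rng(seed)
    subs = enumerate_subtypes(7)
    rates = np.empty(len(subs))
    for i, s in enumerate(subs):
        mean = type_rates[s.basic_type]
        if s.basic_type == "C>T" and s.motif[4] == "G":
            mean = cpg_ct_rate
        rates[i] = mean * rng.lognormal(0.0, log_sd)
    rates = np.clip(rates, 1e-6, 0.5)
    return GroundTruth(rates7=rates,
                       feature_betas=feature_betas or {},
                       feature_names=feature_names or [],
                       seeds={"truth": seed})


DEFAULT_BINARY_FEATURES = (
    "H3K4me1", "H3K4me3", "H3K9me3", "H3K27ac", "H3K27me3", "H3K36me3",
    "H3K9ac", "LAD", "CpG_island", "DHS", "exon")
DEFAULT_CONTINUOUS_FEATURES = ("recomb_rate", "repl_timing", "gc_content")


def gen_feature_tracks(genome: GenomeSequence, seed: int = 0,
                       coverage: float = 0.2,
                       binary_names: tuple[str, ...] = DEFAULT_BINARY_FEATURES,
                       continuous_names: tuple[str, ...] =
                       DEFAULT_CONTINUOUS_FEATURES,
                       mean_depth: float = 10.0):
    """11 binary interval tracks, 3 smooth continuous tracks, and depth.

    Binary tracks are random interval unions at the requested coverage;
    continuous tracks are random walks binned at 100 bp; depth is
    overdispersed (negative-binomial-like) per 100-bp bin.
    """
    from .features import FeatureTrack

    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tracks = []
    for name in binary_names:
        intervals = {}
        for chrom in genome.chrom_names:
            ln = genome.length(chrom)
            ivs = []
            if coverage > 0:
                # non-overlapping 500-bp bins keep realized coverage honest
                iv_len = 500
                n_bins = max(1, ln // iv_len)
                k_bins = int(round(coverage * n_bins))
                chosen = np.sort(rng.choice(n_bins, size=k_bins,
                                            replace=False))
                for b in chosen:
                    s = int(b) * iv_len
                    e = min(ln, s + iv_len)
                    if ivs and ivs[-1][1] == s:
                        ivs[-1] = (ivs[-1][0], e)
                    else:
                        ivs.append((s, e))
            intervals[chrom] = ivs
        tracks.append(FeatureTrack(name=name, kind="binary",
                                   intervals=intervals))
    bin_bp = 100
    for name in continuous_names:
        values = {}
        for chrom in genome.chrom_names:
            ln = genome.length(chrom)
            n_bins = max(1, ln // bin_bp)
            walk = np.cumsum(rng.normal(0, 1, size=n_bins))
            walk = (walk - walk.min()) / max(float(np.ptp(walk)), 1e-9)
            runs = []
            for b in range(n_bins):
                end = ln if b == n_bins - 1 else (b + 1) * bin_bp
                runs.append((b * bin_bp, end, float(walk[b])))
            values[chrom] = runs
        tracks.append(FeatureTrack(name=name, kind="continuous", values=values))
    depth_values = {}
    for chrom in genome.chrom_names:
        ln = genome.length(chrom)
        n_bins = max(1, ln // bin_bp)
        lam = rng.gamma(shape=4.0, scale=mean_depth / 4.0, size=n_bins)
        depth = rng.poisson(lam).astype(float)
        runs = []
        for b in range(n_bins):
            end = ln if b == n_bins - 1 else (b + 1) * bin_bp
            runs.append((b * bin_bp, end, float(depth[b])))
        depth_values[chrom] = runs
    depth_track = FeatureTrack(name="depth", kind="continuous",
                               values=depth_values)
    return tracks, depth_track


def _site_alt_rates(genome: GenomeSequence, truth: GroundTruth,
                    tracks=None, depth=None, rate_scale: float = 1.0):
    """Per (chrom): positions, 3 x n alt-allele chars, 3 x n probabilities.

    Probabilities follow the forward model: logit(p) = logit(base rate) +
    sum of feature betas at the site (when the truth carries any).
    """
    ranks_flips = genome_motif_ranks(genome, 7)
    out = {}
    beta_subtypes = set(truth.feature_betas)
    for chrom, (ranks, flips) in ranks_flips.items():
        valid = np.flatnonzero(ranks >= 0)
        positions = valid + 1
        arr = genome.chroms[chrom]
        sub_idx = np.empty((3, len(valid)), dtype=np.int64)
        alt_chars = np.empty((3, len(valid)), dtype="U1")
        for a in range(3):
            sub_idx[a] = ranks[valid] * 3 + a
        # canonical alt order per central base: A-> (C,G,T); C-> (A,G,T)
        canon_central_c = np.isin(arr[valid], (1, 2))  # C, or G folding to C
        for a in range(3):
            canon_alt = np.where(canon_central_c,
                                 np.array(["A", "G", "T"])[a],
                                 np.array(["C", "G", "T"])[a])
            flipped = flips[valid]
            alt_chars[a] = np.where(flipped,
                                    [_COMP[c] for c in canon_alt],
                                    canon_alt)
        probs = truth.rates7[sub_idx] * rate_scale
        if beta_subtypes and tracks is not None:
            from .features import annotate_features

            hot = np.isin(sub_idx, list(beta_subtypes))
            if hot.any():
                sites = [(chrom, int(p)) for p in positions]
                x, keep, names = annotate_features(sites, genome, tracks, depth)
                x = np.nan_to_num(x)
                for a in range(3):
                    for j in np.flatnonzero(hot[a]):
                        betas = truth.feature_betas[int(sub_idx[a, j])]
                        base = probs[a, j]
                        lin = np.log(base / (1 - base))
                        for fname, beta in betas.items():
                            lin += beta * x[j, names.index(fname)]
                        probs[a, j] = 1 / (1 + np.exp(-lin))
        out[chrom] = (positions, alt_chars, np.clip(probs, 0, 0.999))
    return out


def gen_singletons(genome: GenomeSequence, truth: GroundTruth,
                   n_samples: int = 100, seed: int = 0,
                   tracks=None, depth=None, rate_scale: float = 1.0,
                   sample_probs: np.ndarray | None = None
                   ) -> list[VariantRecord]:
    """Bernoulli singletons per (site, alt) from the forward model.

    Each emitted variant is assigned to one of ``n_samples`` samples,
    uniformly by default or per ``sample_probs`` (e.g. signature-driven
    for QC spike tests).  Variants are allele-count-1 SNVs.
    """
    rng = np.random.default_rng(seed)
    site_rates = _site_alt_rates(genome, truth, tracks, depth, rate_scale)
    expected = sum(p.sum() for _, _, p in site_rates.values())
    n_sites = sum(len(pos) for pos, _, _ in site_rates.values())
    if expected > n_sites:
        raise ValueError("expected singleton count exceeds site count: "
                         "rates too high for this genome")
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    out = []
    for chrom in genome.chrom_names:
        positions, alt_chars, probs = site_rates[chrom]
        hits = rng.random(probs.shape) < probs
        for a in range(3):
            for j in np.flatnonzero(hits[a]):
                pos = int(positions[j])
                ref = genome.base(chrom, pos)
                who = rng.choice(n_samples, p=sample_probs) \
                    if sample_probs is not None else rng.integers(n_samples)
                out.append(VariantRecord(
                    chrom=chrom, pos=pos, ref=ref,
                    alt=str(alt_chars[a, j]), sample=sample_ids[int(who)],
                    allele_count=1))
    out.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return out


def gen_denovo(genome: GenomeSequence, truth: GroundTruth, n: int,
               seed: int = 0, perturbation: str | None = None,
               exclude: set[tuple[str, int]] | None = None
               ) -> list[VariantRecord]:
    """n de novo mutations drawn with probability proportional to the rates.

    ``perturbation="uniform"`` draws sites uniformly instead (to test that
    the validation framework prefers the matching covariate).  Positions in
    ``exclude`` (e.g. singleton sites) are never drawn, and each (site,
    alt) pair is drawn at most once.
    """
    rng = np.random.default_rng(seed)
    site_rates = _site_alt_rates(genome, truth)
    recs = []
    weights = []
    exclude = exclude or set()
    for chrom in genome.chrom_names:
        positions, alt_chars, probs = site_rates[chrom]
        for a in range(3):
            for j in range(len(positions)):
                pos = int(positions[j])
                if (chrom, pos) in exclude:
                    continue
                recs.append((chrom, pos, str(alt_chars[a, j])))
                weights.append(probs[a, j])
    if n > len(recs):
        raise ValueError(f"requested {n} de novos but only {len(recs)} "
                         f"eligible (site, alt) pairs")
    if n == 0:
        return []
    w = np.asarray(weights)
    if perturbation == "uniform":
        w = np.ones_like(w)
    elif perturbation is not None:
        raise ValueError(f"unknown perturbation {perturbation!r}")
    # weighted sampling without replacement via exponential race
    keys = rng.exponential(size=len(w)) / w
    picks = np.argpartition(keys, n)[:n]
    out = []
    for i in picks:
        chrom, pos, alt = recs[i]
        out.append(VariantRecord(chrom=chrom, pos=pos,
                                 ref=genome.base(chrom, pos), alt=alt))
    out.sort(key=lambda v: (v.chrom, v.pos, v.alt))
    return out


def aberrant_spectrum(seed: int = 0, concentration: float = 0.05
                      ) -> np.ndarray:
    """A spiky random 96-dim spectrum, far from any smooth cohort spectrum."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(n_subtypes(3), concentration))


def spike_outliers(variants: list[VariantRecord], genome: GenomeSequence,
                   n_outliers: int, seed: int = 0,
                   spectrum: np.ndarray | None = None
                   ) -> tuple[list[VariantRecord], list[str]]:
    """Resample selected samples' variants from an aberrant 3-mer spectrum.

    Each spiked sample keeps its variant count but every variant is
    replaced by one drawn at a random position whose 3-mer context matches
    a subtype drawn from the aberrant spectrum.  Returns the modified
    variant list and the spiked sample IDs (the truth labels).
    """
    samples = sorted({v.sample for v in variants})
    if n_outliers >= len(samples):
        raise ValueError("n_outliers must be < number of samples")
    if n_outliers == 0:
        return list(variants), []
    rng = np.random.default_rng(seed)
    if spectrum is None:
        spectrum = aberrant_spectrum(seed)
    spiked = [samples[i] for i in
              rng.choice(len(samples), size=n_outliers, replace=False)]
    spiked_set = set(spiked)
    # index genome positions by canonical 3-mer rank
    ranks_flips = genome_motif_ranks(genome, 3)
    pos_by_rank: dict[int, list] = {}
    for chrom, (ranks, flips) in ranks_flips.items():
        for r in np.unique(ranks[ranks >= 0]):
            sel = np.flatnonzero(ranks == r)
            pos_by_rank.setdefault(int(r), []).append(
                (chrom, sel + 1, flips[sel]))
    subs3 = enumerate_subtypes(3)
    out = []
    for v in variants:
        if v.sample not in spiked_set:
            out.append(v)
            continue
        for _ in range(100):
            s_idx = int(rng.choice(len(spectrum), p=spectrum))
            rank = s_idx // 3
            if rank in pos_by_rank:
                break
        else:
            raise RuntimeError("aberrant spectrum hits no motif in genome")
        chrom, positions, flips = pos_by_rank[rank][
            int(rng.integers(len(pos_by_rank[rank])))]
        j = int(rng.integers(len(positions)))
        pos = int(positions[j])
        sub = subs3[s_idx]
        alt = _COMP[sub.alt] if flips[j] else sub.alt
        out.append(VariantRecord(chrom=chrom, pos=pos,
                                 ref=genome.base(chrom, pos), alt=alt,
                                 sample=v.sample, allele_count=1))
    out.sort(key=lambda v: (v.chrom, v.pos, v.alt, v.sample))
    return out, spiked
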