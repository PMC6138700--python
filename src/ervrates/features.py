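"""Per-subtype logistic regression of mutability on local genomic features.

For every 7-mer subtype with enough observed singletons, each genome site
centred on the subtype's motif is labelled Z = 1 if it carries a singleton
of that subtype, and the log-odds of Z are regressed on 11 binary features
(histone marks, lamin-associated domains, CpG islands, DNase
hypersensitive sites, exons), 3 continuous features averaged over a 10-kb
window (recombination rate, replication timing, GC content) and per-site
read depth.  The intercept is the feature-adjusted relative mutation rate.
Benjamini-Hochberg FDR is applied per feature across all subtype models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import (
    GenomeSequence,
    MutationSubtype,
    VariantRecord,
    canonical_subtype,
    extract_context,
    genome_motif_ranks,
    subtype_index,
)

DEFAULT_WINDOW_BP = 10_000
MIN_ERVS = 20


@dataclass
class FeatureTrack:
    """A genomic feature, either interval membership or a positional signal.

    Binary tracks hold sorted 0-based half-open intervals per chromosome.
    Continuous tracks hold bedGraph-style (start, end, value) runs and are
    queried as the mean over a window; read depth is queried at a point.
    """

    name: str
    kind: str  # "binary" | "continuous"
    intervals: dict[str, list[tuple[int, int]]] | None = None
    values: dict[str, list[tuple[int, int, float]]] | None = None
    _starts: dict = field(default_factory=dict, repr=False)
    _pos_values: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_bed(cls, name: str, path: str) -> "FeatureTrack":
        from .io import read_bed
        return cls(name=name, kind="binary", intervals=read_bed(path))

    @classmethod
    def from_bedgraph(cls, name: str, path: str) -> "FeatureTrack":
        from .io import read_bedgraph
        return cls(name=name, kind="continuous", values=read_bedgraph(path))

    # -- binary ---------------------------------------------------------
    def contains(self, chrom: str, pos: int) -> bool:
        """Is 1-based ``pos`` inside any interval (half-open semantics)?"""
        if self.kind != "binary":
            raise ValueError(f"{self.name} is not a binary track")
        ivs = (self.intervals or {}).get(chrom, [])
        if chrom not in self._starts:
            self._starts[chrom] = (np.array([s for s, _ in ivs]),
                                   np.array([e for _, e in ivs]))
        starts, ends = self._starts[chrom]
        if len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos - 1, side="right")) - 1
        return i >= 0 and pos - 1 < ends[i]

    # -- continuous -----------------------------------------------------
    def _dense(self, chrom: str, length: int) -> np.ndarray:
        """Per-position values with NaN where the track has no data."""
        if chrom not in self._pos_values:
            arr = np.full(length, np.nan)
            for start, end, value in (self.values or {}).get(chrom, []):
                arr[start:min(end, length)] = value
            self._pos_values[chrom] = arr
        return self._pos_values[chrom]

    def window_mean(self, genome: GenomeSequence, chrom: str, pos: int,
                    window_bp: int = DEFAULT_WINDOW_BP) -> float:
        """Mean value over a centred window, truncated at contig edges.

        NaN when the track has no data anywhere in the window.
        """
        if self.kind != "continuous":
            raise ValueError(f"{self.name} is not a continuous track")
        length = genome.length(chrom)
        arr = self._dense(chrom, length)
        half = window_bp // 2
        lo = max(0, pos - 1 - half)
        hi = min(length, pos - 1 + half + 1)
        window = arr[lo:hi]
        if np.isnan(window).all():
            return float("nan")
        return float(np.nanmean(window))

    def value_at(self, genome: GenomeSequence, chrom: str, pos: int) -> float:
        if self.kind != "continuous":
            raise ValueError(f"{self.name} is not a continuous track")
        return float(self._dense(chrom, genome.length(chrom))[pos - 1])


def annotate_features(sites: list[tuple[str, int]], genome: GenomeSequence,
                      tracks: list[FeatureTrack],
                      depth: FeatureTrack | None = None,
                      window_bp: int = DEFAULT_WINDOW_BP
                      ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Predictor matrix for a list of (chrom, 1-based pos) sites.

    Binary features are central-site membership indicators; continuous
    features are means over the centred window; depth is the value at the
    central site.  Returns (matrix, keep_mask, column_names): rows with any
    missing predictor are masked out rather than silently dropped.
    """
    names = [t.name for t in tracks] + ([depth.name] if depth else [])
    x = np.zeros((len(sites), len(names)))
    for j, t in enumerate(tracks):
        if t.kind == "binary":
            x[:, j] = [1.0 if t.contains(c, p) else 0.0 for c, p in sites]
        else:
            x[:, j] = [t.window_mean(genome, c, p, window_bp) for c, p in sites]
    if depth is not None:
        x[:, len(tracks)] = [depth.value_at(genome, c, p) for c, p in sites]
    keep = np.isfinite(x).all(axis=1)
    return x, keep, names


def collect_subtype_sites(genome: GenomeSequence, subtype: MutationSubtype,
                          variants: list[VariantRecord],
                          ranks_cache: dict | None = None
                          ) -> list[tuple[str, int, int]]:
    """All (chrom, pos, Z) sites whose canonical centred 7-mer is the motif.

    Z = 1 iff a singleton of exactly this subtype (same canonical alt)
    occurs at the position.
    """
    if subtype.k != 7:
        raise ValueError("feature models are defined on 7-mer subtypes")
    if ranks_cache is None:
        ranks_cache = genome_motif_ranks(genome, 7)
    target_rank = subtype_index(7)[subtype] // 3
    carriers = set()
    for v in variants:
        try:
            ctx = extract_context(genome, v.chrom, v.pos, 7)
        except Exception:
            continue
        if canonical_subtype(v.ref, v.alt, ctx) == subtype:
            carriers.add((v.chrom, v.pos))
    out = []
    for chrom, (ranks, _) in ranks_cache.items():
        for p0 in np.flatnonzero(ranks == target_rank):
            pos = int(p0) + 1
            out.append((chrom, pos, 1 if (chrom, pos) in carriers else 0))
    return out


@dataclass
class SubtypeEffectModel:
    """Fitted per-subtype coefficient vector with SEs and Wald p-values."""

    subtype: MutationSubtype
    coef_names: list[str]          # "intercept" + feature names
    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    n_sites: int
    n_ervs: int
    scale: np.ndarray              # divisor applied to each predictor column
    fitted: bool = True
    note: str = ""
    fdr_flags: dict[str, int] = field(default_factory=dict)  # name -> +1/-1

    def linear_predictor(self, x_raw: np.ndarray) -> np.ndarray:
        """beta0 + sum_g beta_g * F_g on unscaled predictor rows."""
        xs = np.atleast_2d(x_raw) / self.scale
        return self.coef[0] + xs @ self.coef[1:]

    def predict_probability(self, x_raw: np.ndarray) -> np.ndarray:
        lin = self.linear_predictor(x_raw)
        return 1.0 / (1.0 + np.exp(-lin))


def fit_subtype_model(subtype: MutationSubtype, z: np.ndarray,
                      x: np.ndarray, names: list[str],
                      continuous: list[str] | None = None,
                      min_ervs: int = MIN_ERVS) -> SubtypeEffectModel:
    """ML logistic fit of Z on intercept + features (+ depth) for one subtype.

    Continuous predictors are divided by one-tenth of their observed range
    so each coefficient is the log-odds change per 10% increase across the
    feature's range.  Subtypes with fewer than ``min_ervs`` singletons are
    skipped; separation or collinearity withholds coefficients with a note.
    """
    import statsmodels.api as sm

    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    n_sites, n_feat = x.shape
    n_ervs = int(z.sum())
    scale = np.ones(n_feat)
    continuous = continuous or []
    for j, name in enumerate(names):
        if name in continuous:
            rng_j = x[:, j].max() - x[:, j].min()
            if rng_j > 0:
                scale[j] = rng_j / 10.0
    empty = SubtypeEffectModel(
        subtype=subtype, coef_names=["intercept"] + list(names),
        coef=np.full(n_feat + 1, np.nan), se=np.full(n_feat + 1, np.nan),
        p_values=np.full(n_feat + 1, np.nan), n_sites=n_sites,
        n_ervs=n_ervs, scale=scale, fitted=False)
    if n_ervs < min_ervs:
        empty.note = f"skipped: {n_ervs} ERVs < {min_ervs}"
        return empty
    xs = x / scale
    design = np.column_stack([np.ones(n_sites), xs])
    # constant columns (beyond the intercept) are unidentifiable: pin to 0
    varying = np.concatenate([[True],
                              design[:, 1:].std(axis=0) > 0])
    try:
        res = sm.GLM(z, design[:, varying],
                     family=sm.families.Binomial()).fit(maxiter=100)
    except Exception as exc:
        empty.note = f"fit failed: {exc}"
        return empty
    if not res.converged or not np.isfinite(res.bse).all() \
            or np.abs(res.params).max() > 50:
        empty.note = "separation or collinearity; coefficients withheld"
        return empty
    coef = np.zeros(n_feat + 1)
    se = np.full(n_feat + 1, np.nan)
    pvals = np.full(n_feat + 1, np.nan)
    coef[varying] = res.params
    se[varying] = res.bse
    pvals[varying] = res.pvalues
    return SubtypeEffectModel(
        subtype=subtype, coef_names=["intercept"] + list(names),
        coef=coef, se=se, p_values=pvals, n_sites=n_sites, n_ervs=n_ervs,
        scale=scale)


def models_to_frame(models: list[SubtypeEffectModel]) -> pd.DataFrame:
    """Long-format table: one row per fitted subtype x coefficient."""
    rows = []
    for m in models:
        if not m.fitted:
            continue
        for name, b, s, p in zip(m.coef_names, m.coef, m.se, m.p_values):
            rows.append({"motif": m.subtype.motif, "alt": m.subtype.alt,
                         "coef": name, "estimate": b, "se": s, "p": p,
                         "n_sites": m.n_sites, "n_ervs": m.n_ervs})
    return pd.DataFrame(rows)


def fdr_select(models: list[SubtypeEffectModel], q: float = 0.05
               ) -> pd.DataFrame:
    """Benjamini-Hochberg per feature across all fitted subtype models.

    Flags carry the effect direction (+1 for OR > 1, -1 for OR < 1) and are
    written back onto each model's ``fdr_flags``.
    """
    from statsmodels.stats.multitest import multipletests

    fitted = [m for m in models if m.fitted]
    rows = []
    if not fitted:
        return pd.DataFrame(
            columns=["motif", "alt", "feature", "estimate", "p", "significant",
                     "direction"])
    feature_names = fitted[0].coef_names[1:]
    for feat in feature_names:
        entries = []
        for m in fitted:
            j = m.coef_names.index(feat)
            if np.isfinite(m.p_values[j]):
                entries.append((m, j))
        if not entries:
            continue
        pvals = np.array([m.p_values[j] for m, j in entries])
        rej, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
        for (m, j), sig in zip(entries, rej):
            direction = 1 if m.coef[j] > 0 else -1
            if sig:
                m.fdr_flags[feat] = direction
            rows.append({"motif": m.subtype.motif, "alt": m.subtype.alt,
                         "feature": feat, "estimate": m.coef[j],
                         "p": m.p_values[j], "significant": bool(sig),
                         "direction": direction})
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    category: str
    k: int
    n: int
    null_p: float
    p_upper: float
    p_two_sided: float
    testable: bool = True


def signature_enrichment(flagged: list[MutationSubtype],
                         in_category, null_p: float,
                         category: str = "") -> EnrichmentResult:
    """Exact binomial test: are flagged subtypes concentrated in a category?

    ``in_category`` is a predicate over subtypes; ``null_p`` is the
    proportion of the full enumeration the category occupies (e.g. 1/6 for
    one basic type, 1/4 for W[A>G]W flank membership).
    """
    n = len(flagged)
    if n == 0:
        return EnrichmentResult(category, 0, 0, null_p, float("nan"),
                                float("nan"), testable=False)
    k = sum(1 for s in flagged if in_category(s))
    p_upper = float(stats.binom.sf(k - 1, n, null_p))
    p_two = float(stats.binomtest(k, n, null_p).pvalue)
    return EnrichmentResult(category, k, n, null_p, p_upper, p_two)


@dataclass
class DeNovoFeatureResult:
    statistic: float
    df: int
    p_value: float
    table: np.ndarray          # 2x2: rows (de novo, background), cols (in, out)
    rate_ratio: float          # (dn in / bg in) / (dn out / bg out)
    direction: int             # +1 enrichment inside, -1 depletion
    method: str = "pearson-chi2"


def denovo_feature_test(denovo_sites: list[tuple[str, int]],
                        background_sites: list[tuple[str, int]],
                        track: FeatureTrack) -> DeNovoFeatureResult:
    """2x2 chi-squared: de novo vs background, inside vs outside a feature.

    Falls back to Fisher's exact test (labelled) when an expected cell is
    zero.
    """
    dn_in = sum(track.contains(c, p) for c, p in denovo_sites)
    bg_in = sum(track.contains(c, p) for c, p in background_sites)
    table = np.array([[dn_in, len(denovo_sites) - dn_in],
                      [bg_in, len(background_sites) - bg_in]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row @ col / total
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = (table[0, 0] / row[0, 0]) / (table[1, 0] / row[1, 0])
    direction = 1 if rr > 1 else -1
    if (expected == 0).any():
        _, p = stats.fisher_exact(table.astype(int))
        return DeNovoFeatureResult(float("nan"), 1, float(p), table,
                                   float(rr), direction, method="fisher-exact")
    stat = float(((table - expected) ** 2 / expected).sum())
    return DeNovoFeatureResult(stat, 1, float(stats.chi2.sf(stat, 1)), table,
                               float(rr), direction)
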