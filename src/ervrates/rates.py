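"""Relative mutation-rate estimation per K-mer subtype.

The relative mutation rate of a subtype is the number of singletons (ERVs)
observed at the central position of its motif divided by the number of
occurrences of that motif in the reference genome — a unitless proportion,
not a per-generation rate.  Rates nest exactly: each K-mer subtype's rate
is the motif-count-weighted mean of its 16 (K+2)-mer constituents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import (
    BASIC_TYPES,
    ContextError,
    GenomeSequence,
    MutationSubtype,
    RefMismatchError,
    VariantRecord,
    canonical_subtype,
    count_motifs,
    enumerate_subtypes,
    extract_context,
    subtype_index,
)


@dataclass
class RateTable:
    """Per-subtype ERV counts, genome motif counts and relative rates.

    Arrays are indexed by the fixed subtype enumeration order for ``k``.
    ``skipped`` counts input variants that could not be classified
    (N-adjacent or chromosome-edge contexts).
    """

    k: int
    erv_counts: np.ndarray
    motif_counts: np.ndarray
    skipped: int = 0
    skipped_records: list = field(default_factory=list)

    def __post_init__(self):
        if (self.motif_counts == 0).any() and \
                (self.erv_counts[self.motif_counts == 0] > 0).any():
            raise ValueError(
                "ERVs observed at a motif absent from the genome: "
                "genome and variants are inconsistent")

    @property
    def subtypes(self) -> tuple[MutationSubtype, ...]:
        return enumerate_subtypes(self.k)

    @property
    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.erv_counts / self.motif_counts
        return np.where(self.motif_counts > 0, r, 0.0)

    def rate_of(self, subtype: MutationSubtype) -> float:
        return float(self.rates[subtype_index(self.k)[subtype]])

    def to_frame(self) -> pd.DataFrame:
        subs = self.subtypes
        return pd.DataFrame({
            "motif": [s.motif for s in subs],
            "alt": [s.alt for s in subs],
            "K": self.k,
            "erv_count": self.erv_counts,
            "motif_count": self.motif_counts,
            "rate": self.rates,
        })

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateTable":
        k = int(df["K"].iloc[0])
        idx = subtype_index(k)
        erv = np.zeros(len(idx), dtype=np.int64)
        motif = np.zeros(len(idx), dtype=np.int64)
        for row in df.itertuples():
            i = idx[MutationSubtype(row.motif, row.alt)]
            erv[i] = row.erv_count
            motif[i] = row.motif_count
        return cls(k=k, erv_counts=erv, motif_counts=motif)


def classify_variants(variants: list[VariantRecord], genome: GenomeSequence,
                      k: int) -> tuple[np.ndarray, int, list]:
    """Count variants per canonical subtype; returns (counts, n_skipped, skips)."""
    idx = subtype_index(k)
    counts = np.zeros(len(idx), dtype=np.int64)
    skipped = []
    for v in variants:
        try:
            context = extract_context(genome, v.chrom, v.pos, k)
        except ContextError as exc:
            skipped.append((v, str(exc)))
            continue
        if context[k // 2] != v.ref:
            raise RefMismatchError(
                f"{v.chrom}:{v.pos} VCF ref {v.ref} != genome {context[k // 2]}")
        counts[idx[canonical_subtype(v.ref, v.alt, context)]] += 1
    return counts, len(skipped), skipped


def estimate_rates(variants: list[VariantRecord], genome: GenomeSequence,
                   k: int, use_mask: bool = False,
                   min_ac: int | None = 1, max_ac: int | None = 1) -> RateTable:
    """Estimate per-subtype relative mutation rates from a variant set.

    The allele-count filter defaults to singletons (min = max = 1); passing
    ``min_ac=10, max_ac=None`` reproduces a common-variant (MAC10+) style
    table.  Variants whose context cannot be extracted are skipped and
    reported on the returned table.
    """
    kept = [v for v in variants
            if (min_ac is None or v.allele_count >= min_ac)
            and (max_ac is None or v.allele_count <= max_ac)]
    masked_out = []
    if use_mask and genome.mask is not None:
        masked_out = [(v, "central base outside accessibility mask")
                      for v in kept if not genome.accessible(v.chrom, v.pos)]
        kept = [v for v in kept if genome.accessible(v.chrom, v.pos)]
    erv, n_skip, skips = classify_variants(kept, genome, k)
    skips = masked_out + skips
    n_skip += len(masked_out)
    expanded = np.repeat(count_motifs(genome, k, use_mask=use_mask), 3)
    return RateTable(k=k, erv_counts=erv, motif_counts=expanded,
                     skipped=n_skip, skipped_records=skips)


def _parent_child_map(k_child: int) -> np.ndarray:
    """Index of each child (K)-subtype's parent (K-2)-subtype."""
    k_parent = k_child - 2
    parent_idx = subtype_index(k_parent)
    children = enumerate_subtypes(k_child)
    return np.array([parent_idx[MutationSubtype(s.motif[1:-1], s.alt)]
                     for s in children])


def aggregate_rates(child: RateTable) -> RateTable:
    """Fold a (K+2)-mer table onto its K-mer parents by summing counts.

    The parent rate is then automatically the motif-count-weighted mean of
    its 16 constituents, and agrees exactly with direct estimation at K.
    """
    if child.k - 2 < 1:
        raise ValueError("cannot aggregate below K=1")
    mapping = _parent_child_map(child.k)
    n_parent = len(enumerate_subtypes(child.k - 2))
    erv = np.bincount(mapping, weights=child.erv_counts, minlength=n_parent)
    motif = np.bincount(mapping, weights=child.motif_counts, minlength=n_parent)
    return RateTable(k=child.k - 2, erv_counts=erv.astype(np.int64),
                     motif_counts=motif.astype(np.int64), skipped=child.skipped)


@dataclass
class HeterogeneityResult:
    """Chi-squared test of rate uniformity across a subtype's 16 constituents."""

    parent: MutationSubtype
    statistic: float
    df: int
    p_value: float
    testable: bool = True


def heterogeneity_test(parent: MutationSubtype,
                       children: list[tuple[int, int]]) -> HeterogeneityResult:
    """Pearson chi-squared on the 16 x 2 table (ERV, non-ERV occurrences).

    Always reported at 15 degrees of freedom.  Children with zero motif
    count contribute nothing to the statistic.  A parent with zero ERVs is
    untestable and returned flagged as such.
    """
    if len(children) != 16:
        raise ValueError(f"expected 16 constituent subtypes, got {len(children)}")
    erv = np.asarray([c[0] for c in children], dtype=float)
    motif = np.asarray([c[1] for c in children], dtype=float)
    if (erv > motif).any() or (erv < 0).any():
        raise ValueError("invalid counts: need 0 <= erv_count <= motif_count")
    df = 15
    if erv.sum() == 0 or motif.sum() == 0:
        return HeterogeneityResult(parent, float("nan"), df, float("nan"),
                                   testable=False)
    p_hat = erv.sum() / motif.sum()
    expected = np.stack([motif * p_hat, motif * (1 - p_hat)])
    observed = np.stack([erv, motif - erv])
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (observed - expected) ** 2 / expected
    stat = float(np.nansum(np.where(expected > 0, cells, 0.0)))
    return HeterogeneityResult(parent, stat, df, float(stats.chi2.sf(stat, df)))


def heterogeneity_tests(parent_table: RateTable, child_table: RateTable
                        ) -> list[HeterogeneityResult]:
    """Run the 15-df uniformity test for every parent subtype."""
    if child_table.k != parent_table.k + 2:
        raise ValueError("child table must be at K+2")
    mapping = _parent_child_map(child_table.k)
    results = []
    for i, parent in enumerate(parent_table.subtypes):
        sel = np.flatnonzero(mapping == i)
        children = [(int(child_table.erv_counts[j]),
                     int(child_table.motif_counts[j])) for j in sel]
        results.append(heterogeneity_test(parent, children))
    return results


@dataclass
class RateComparison:
    """Comparison of two same-K rate tables after within-table normalization."""

    k: int
    spearman_overall: float
    spearman_by_type: dict[str, float]
    ratio: np.ndarray            # normalized b / normalized a, NaN if undefined
    frac_diff_ge_50pct: float    # share of comparable subtypes with >=50% change
    n_excluded: int              # subtypes unusable in one table (zero motif/rate)

    def summary(self) -> dict:
        return {
            "K": self.k,
            "spearman_overall": self.spearman_overall,
            "spearman_by_type": self.spearman_by_type,
            "frac_diff_ge_50pct": self.frac_diff_ge_50pct,
            "n_excluded": self.n_excluded,
            "normalization": "rate / sum(rates) within each table",
        }


def compare_rate_tables(a: RateTable, b: RateTable) -> RateComparison:
    """Spearman correlations and normalized per-subtype ratios between tables.

    Rates are divided by their table-wide sum before ratios are taken, so
    tables built from cohorts of different sizes are comparable.  Subtypes
    with no motif occurrences in either table are excluded and counted.
    """
    if a.k != b.k:
        raise ValueError("rate tables must share K")
    ra, rb = a.rates, b.rates
    usable = (a.motif_counts > 0) & (b.motif_counts > 0)
    na = ra / ra.sum()
    nb = rb / rb.sum()
    rho = float(stats.spearmanr(na[usable], nb[usable]).statistic)
    by_type = {}
    types = np.array([s.basic_type for s in a.subtypes])
    for t in BASIC_TYPES:
        sel = usable & (types == t)
        by_type[t] = float(stats.spearmanr(na[sel], nb[sel]).statistic) \
            if sel.sum() >= 2 else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(usable & (na > 0), nb / na, np.nan)
    comparable = np.isfinite(ratio)
    frac = float(np.mean(np.abs(ratio[comparable] - 1.0) >= 0.5)) \
        if comparable.any() else float("nan")
    return RateComparison(
        k=a.k, spearman_overall=rho, spearman_by_type=by_type, ratio=ratio,
        frac_diff_ge_50pct=frac, n_excluded=int((~usable).sum()))


@dataclass
class GCStrataResult:
    basic_type: str
    t_statistic: float
    p_value: float
    n_high_gc: int
    n_low_gc: int
    testable: bool = True


def gc_strata_test(a: RateTable, b: RateTable,
                   types: tuple[str, ...] = ("A>C", "A>G")
                   ) -> dict[str, GCStrataResult]:
    """Do table-b/table-a rate ratios differ between GC-rich and GC-poor motifs?

    Each 7-mer motif is classified by the number of G/C bases among its six
    flanking positions: high-GC (4-6) vs low-GC (0-3).  A two-sample t-test
    compares log(normalized b / normalized a) between strata, per basic type.
    """
    if a.k != 7 or b.k != 7:
        raise ValueError("GC strata test is defined for K=7 tables")
    ra = a.rates / a.rates.sum()
    rb = b.rates / b.rates.sum()
    subs = a.subtypes
    out = {}
    for t in types:
        logratio_hi, logratio_lo = [], []
        for i, s in enumerate(subs):
            if s.basic_type != t or ra[i] <= 0 or rb[i] <= 0:
                continue
            flanks = s.motif[:3] + s.motif[4:]
            gc = sum(base in "GC" for base in flanks)
            (logratio_hi if gc >= 4 else logratio_lo).append(
                np.log(rb[i] / ra[i]))
        if len(logratio_hi) < 2 or len(logratio_lo) < 2:
            out[t] = GCStrataResult(t, float("nan"), float("nan"),
                                    len(logratio_hi), len(logratio_lo),
                                    testable=False)
            continue
        hi, lo = np.asarray(logratio_hi), np.asarray(logratio_lo)
        if hi.std() == 0 and lo.std() == 0 and hi.mean() == lo.mean():
            # degenerate identical-ratio case: no signal by construction
            out[t] = GCStrataResult(t, 0.0, 1.0, len(hi), len(lo))
            continue
        res = stats.ttest_ind(hi, lo)
        out[t] = GCStrataResult(t, float(res.statistic), float(res.pvalue),
                                len(hi), len(lo))
    return out
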