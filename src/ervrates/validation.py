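"""Likelihood framework validating rate estimates against de novo mutations.

De novo mutations from family sequencing are the gold standard of recent
germline mutation.  Each rate-estimation strategy M supplies a covariate
r_iM per testing site; a single-covariate logistic regression

    ln( Pr(d_i = 1) / Pr(d_i = 0) ) = alpha_0 + alpha_1 * r_iM

is fit over the union of de novo sites (d=1) and a random nonmutated
background (d=0), and strategies are ranked by AIC = 2 - 2 ln L (one
covariate parameter) and Nagelkerke's pseudo-R^2.  Background sites are
partitioned into three sets so each site serves as the nonmutated
background of exactly one mutation type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kmers import (
    ContextError,
    GenomeSequence,
    VariantRecord,
    canonical_subtype,
    extract_context,
    subtype_index,
)
from .rates import RateTable

#: the 9 basic types: CpG status splits the three C types
BASIC_TYPES_9 = ("A>C", "A>G", "A>T",
                 "CpG>A", "CpG>G", "CpG>T",
                 "C>A", "C>G", "C>T")

# partition set -> alt assigned to (A-like ref, C-like ref) background sites
_PARTITION_ALTS = {0: ("G", "T"), 1: ("C", "G"), 2: ("T", "A")}


@dataclass(frozen=True)
class TestingSite:
    """One unit of the validation likelihood: a site with one possible event."""

    chrom: str
    pos: int
    d: int                 # 1 = de novo mutation, 0 = nonmutated background
    ref: str               # canonical-strand ref (A or C)
    alt: str               # canonical-strand alt
    basic_type: str        # one of BASIC_TYPES_9


def mappable_positions(genome: GenomeSequence, use_mask: bool = False
                       ) -> list[tuple[str, np.ndarray]]:
    """Per-chromosome 1-based positions with non-N (and unmasked) bases."""
    out = []
    for chrom, arr in genome.chroms.items():
        ok = arr < 4
        if use_mask and genome.mask is not None:
            ok = ok & genome.mask[chrom]
        out.append((chrom, np.flatnonzero(ok) + 1))
    return out


def sample_background(genome: GenomeSequence, n: int,
                      exclude: set[tuple[str, int]] | None = None,
                      seed: int = 0, use_mask: bool = False
                      ) -> list[tuple[str, int]]:
    """Draw n distinct non-N positions uniformly, excluding given sites."""
    if n < 0:
        raise ValueError("n must be >= 0")
    exclude = exclude or set()
    pool = []
    for chrom, positions in mappable_positions(genome, use_mask=use_mask):
        for p in positions:
            if (chrom, int(p)) not in exclude:
                pool.append((chrom, int(p)))
    if n > len(pool):
        raise ValueError(f"requested {n} background sites but only "
                         f"{len(pool)} eligible positions exist")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in picks]


def partition_background(sites: list, seed: int = 0) -> list[list]:
    """Random 3-way partition; largest set first.

    Sizes are ceil(n/3) then an even split of the remainder, so 1,000,000
    sites partition into 333,334 / 333,333 / 333,333.
    """
    n = len(sites)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    s1 = math.ceil(n / 3)
    s2 = math.ceil((n - s1) / 2)
    cuts = [s1, s1 + s2]
    shuffled = [sites[i] for i in order]
    return [shuffled[:cuts[0]], shuffled[cuts[0]:cuts[1]], shuffled[cuts[1]:]]


def _cpg_status(genome: GenomeSequence, chrom: str, pos: int, ref: str) -> bool:
    """Is the canonical-strand C of this site part of a CpG dinucleotide?

    For a reference C, CpG means the next base is G; for a reference G (a C
    on the minus strand) it means the previous base is C.
    """
    arr = genome.chroms[chrom]
    if ref == "C":
        return pos < len(arr) and "ACGTN"[arr[pos]] == "G"
    if ref == "G":
        return pos >= 2 and "ACGTN"[arr[pos - 2]] == "C"
    raise ValueError(f"CpG status undefined for ref {ref!r}")


def assign_basic_type(genome: GenomeSequence, chrom: str, pos: int,
                      ref: str, alt: str) -> str:
    """9-way basic type for a mutation event (canonical strand, CpG split)."""
    sub = canonical_subtype(ref, alt, extract_context(genome, chrom, pos, 3))
    if sub.ref == "A":
        return sub.basic_type
    cpg = _cpg_status(genome, chrom, pos, ref)
    return f"CpG>{sub.alt}" if cpg else f"C>{sub.alt}"


def build_testing_sites(genome: GenomeSequence, denovo: list[VariantRecord],
                        background: list[tuple[str, int]], seed: int = 0
                        ) -> tuple[list[TestingSite], int]:
    """Assemble the testing-site set from de novos plus partitioned background.

    Background partition set 1 provides nonmutated A>G / C>T sites, set 2
    A>C / C>G, set 3 A>T / C>A, according to each site's (canonicalized)
    reference base.  Sites whose 3-mer context is unavailable (edge or N)
    are dropped and counted.
    """
    sites: list[TestingSite] = []
    dropped = 0
    for v in denovo:
        try:
            t = assign_basic_type(genome, v.chrom, v.pos, v.ref, v.alt)
        except ContextError:
            dropped += 1
            continue
        sub = canonical_subtype(v.ref, v.alt,
                                extract_context(genome, v.chrom, v.pos, 3))
        sites.append(TestingSite(v.chrom, v.pos, 1, sub.ref, sub.alt, t))
    for set_i, part in enumerate(partition_background(background, seed=seed)):
        alt_a, alt_c = _PARTITION_ALTS[set_i]
        for chrom, pos in part:
            ref = genome.base(chrom, pos)
            alt = alt_a if ref in "AT" else alt_c
            if ref in "TG":  # express the event on the strand of the record
                alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[alt]
            try:
                t = assign_basic_type(genome, chrom, pos, ref, alt)
            except ContextError:
                dropped += 1
                continue
            sub = canonical_subtype(ref, alt,
                                    extract_context(genome, chrom, pos, 3))
            sites.append(TestingSite(chrom, pos, 0, sub.ref, sub.alt, t))
    return sites, dropped


def annotate_covariate(sites: list[TestingSite], genome: GenomeSequence,
                       table: RateTable) -> np.ndarray:
    """Per-site relative rate r_iM under a rate table's K; NaN if unavailable."""
    idx = subtype_index(table.k)
    r = np.full(len(sites), np.nan)
    rates = table.rates
    for i, s in enumerate(sites):
        try:
            ctx = extract_context(genome, s.chrom, s.pos, table.k)
        except ContextError:
            continue
        r[i] = rates[idx[canonical_subtype(ctx[table.k // 2],
                                           s.alt if ctx[table.k // 2] == s.ref
                                           else {"A": "T", "C": "G",
                                                 "G": "C", "T": "A"}[s.alt],
                                           ctx)]]
    return r


@dataclass
class FitResult:
    """A fitted single-covariate validation model and its fit statistics."""

    strategy: str
    alpha0: float
    alpha1: float
    loglik: float
    loglik_null: float
    aic: float
    nagelkerke_r2: float
    n: int
    converged: bool = True
    note: str = ""
    delta_aic: float = float("nan")


def _nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    """Rescaled likelihood-ratio pseudo-R^2, computed on the log scale."""
    cox_snell = 1.0 - math.exp((2.0 / n) * (ll_null - ll_model))
    max_r2 = 1.0 - math.exp((2.0 / n) * ll_null)
    if max_r2 <= 0:
        return 0.0
    return max(0.0, cox_snell / max_r2)


def fit_validation_model(d: np.ndarray, r: np.ndarray, strategy: str = "",
                         max_iter: int = 100, tol: float = 1e-8) -> FitResult:
    """ML logistic fit of the de novo indicator on a single rate covariate.

    Fit by IRLS (statsmodels GLM, binomial family).  AIC counts the single
    covariate parameter: AIC = 2 - 2 ln L.  Nagelkerke R^2 compares against
    the intercept-only null.  A constant covariate reduces the fit to the
    null model (R^2 = 0); non-convergence or separation is flagged rather
    than silently reported.
    """
    import statsmodels.api as sm

    d = np.asarray(d, dtype=float)
    r = np.asarray(r, dtype=float)
    if d.shape != r.shape:
        raise ValueError("d and r must align")
    keep = np.isfinite(r)
    d, r = d[keep], r[keep]
    n = len(d)
    if n == 0 or d.min() == d.max():
        raise ValueError("need at least one de novo and one background site")

    p0 = d.mean()
    ll_null = float(n * (p0 * math.log(p0) + (1 - p0) * math.log(1 - p0)))

    if r.min() == r.max():
        return FitResult(strategy=strategy, alpha0=math.log(p0 / (1 - p0)),
                         alpha1=0.0, loglik=ll_null, loglik_null=ll_null,
                         aic=2.0 - 2.0 * ll_null, nagelkerke_r2=0.0, n=n,
                         converged=True, note="constant covariate; null fit")

    x = sm.add_constant(r)
    try:
        res = sm.GLM(d, x, family=sm.families.Binomial()).fit(
            maxiter=max_iter, tol=tol)
        converged = bool(res.converged)
    except Exception as exc:  # separation / singular design
        return FitResult(strategy=strategy, alpha0=float("nan"),
                         alpha1=float("nan"), loglik=float("nan"),
                         loglik_null=ll_null, aic=float("nan"),
                         nagelkerke_r2=float("nan"), n=n, converged=False,
                         note=f"fit failed: {exc}")
    ll = float(res.llf)
    fitted = np.clip(res.fittedvalues, 1e-12, 1 - 1e-12)
    if not converged or np.any((fitted < 1e-10) & (d == 1)):
        note = "non-convergence or separation suspected"
    else:
        note = ""
    return FitResult(strategy=strategy, alpha0=float(res.params[0]),
                     alpha1=float(res.params[1]), loglik=ll,
                     loglik_null=ll_null, aic=2.0 - 2.0 * ll,
                     nagelkerke_r2=_nagelkerke(ll, ll_null, n), n=n,
                     converged=converged, note=note)


def compare_models(fits: list[FitResult]) -> list[FitResult]:
    """Rank fits by AIC; requires identical site counts across fits.

    Returns the fits sorted best-first with ``delta_aic`` filled in.
    Models with delta AIC < 10 are conventionally considered comparable to
    the optimum.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"AIC is not comparable across differing site "
                         f"counts: {sorted(ns)}")
    best = min(f.aic for f in fits if math.isfinite(f.aic))
    ranked = sorted(fits, key=lambda f: (not math.isfinite(f.aic), f.aic))
    for f in ranked:
        f.delta_aic = f.aic - best
    return ranked


def comparable_to_best(fit: FitResult, threshold: float = 10.0) -> bool:
    return math.isfinite(fit.delta_aic) and fit.delta_aic < threshold
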