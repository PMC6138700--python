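"""Per-sample 3-mer mutation spectra and NMF-based outlier screening.

Samples whose singletons arise from systematic sequencing errors or batch
effects show aberrant 3-mer spectra.  The screen factorizes the cohort's
n_samples x 96 rate matrix into three non-negative "signatures" and flags
samples whose signature contribution deviates more than ``k_sd`` standard
deviations from the cohort mean for any signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmers import GenomeSequence, VariantRecord, count_motifs, enumerate_subtypes
from .rates import classify_variants


@dataclass
class SampleSpectrum:
    """n_samples x 96 matrix of per-individual 3-mer relative rates."""

    samples: list[str]
    matrix: np.ndarray  # rows ordered as ``samples``, columns in subtype order
    zero_samples: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [str(s) for s in enumerate_subtypes(3)]
        return pd.DataFrame(self.matrix, index=self.samples, columns=cols)


def per_sample_spectra(variants: list[VariantRecord], genome: GenomeSequence,
                       samples: list[str] | None = None) -> SampleSpectrum:
    """3-mer rate vector per sample, using only that sample's singletons.

    Column j of row s is (sample s's ERVs of subtype j) / (genome count of
    subtype j's motif).  Samples contributing no singletons get all-zero
    rows and are reported.  Variants carrying a sample ID not in
    ``samples`` (when given) are an error.
    """
    if samples is None:
        samples = sorted({v.sample for v in variants})
    known = set(samples)
    by_sample: dict[str, list[VariantRecord]] = {s: [] for s in samples}
    for v in variants:
        if v.sample not in known:
            raise ValueError(f"variant at {v.chrom}:{v.pos} has unknown "
                             f"sample ID {v.sample!r}")
        by_sample[v.sample].append(v)
    motif_counts = np.repeat(count_motifs(genome, 3), 3).astype(float)
    matrix = np.zeros((len(samples), len(motif_counts)))
    zero_samples = []
    for i, s in enumerate(samples):
        if not by_sample[s]:
            zero_samples.append(s)
            continue
        counts, _, _ = classify_variants(by_sample[s], genome, 3)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = counts / motif_counts
        matrix[i] = np.where(motif_counts > 0, row, 0.0)
    return SampleSpectrum(samples=list(samples), matrix=matrix,
                          zero_samples=zero_samples)


@dataclass
class SignatureDecomposition:
    """Rank-r NMF of a sample spectrum matrix plus contribution statistics."""

    samples: list[str]
    contributions: np.ndarray     # n_samples x rank, row-normalized if requested
    signatures: np.ndarray        # rank x 96
    reconstruction_error: float   # relative Frobenius error
    objective_trace: list[float]
    contribution_mean: np.ndarray = None
    contribution_sd: np.ndarray = None
    flagged: list[str] = field(default_factory=list)


def _mu_nmf(x: np.ndarray, rank: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lee-Seung multiplicative updates for the Frobenius objective.

    The objective is non-increasing per update; this is asserted each
    iteration (up to roundoff) as a guard against implementation drift.
    """
    n, m = x.shape
    eps = 1e-12
    scale = np.sqrt(x.mean() / rank)
    w = rng.uniform(0.0, 1.0, size=(n, rank)) * scale + eps
    h = rng.uniform(0.0, 1.0, size=(rank, m)) * scale + eps
    obj = [float(np.linalg.norm(x - w @ h))]
    for _ in range(max_iter):
        h *= (w.T @ x) / (w.T @ w @ h + eps)
        w *= (x @ h.T) / (w @ (h @ h.T) + eps)
        obj.append(float(np.linalg.norm(x - w @ h)))
        # non-increasing up to float roundoff near stationary points
        assert obj[-1] <= obj[-2] + max(1e-10 * obj[0], 1e-12), \
            "NMF objective increased"
        if obj[-2] - obj[-1] <= tol * max(obj[-2], eps):
            break
    return w, h, obj


def nmf_decompose(spectra: SampleSpectrum, rank: int = 3, seed: int = 0,
                  n_restarts: int = 5, max_iter: int = 500,
                  tol: float = 1e-6,
                  normalize_contributions: bool = True) -> SignatureDecomposition:
    """Best-of-restarts non-negative factorization of the spectrum matrix.

    Contributions are row-normalized to proportions by default before any
    downstream statistics, since a "relative contribution" is compositional;
    set ``normalize_contributions=False`` for raw loadings.
    """
    x = np.asarray(spectra.matrix, dtype=float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if (x < 0).any():
        raise ValueError("spectrum matrix must be non-negative")
    if not x.any():
        raise ValueError("all-zero spectrum matrix cannot be factorized")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        w, h, obj = _mu_nmf(x, rank, rng, max_iter, tol)
        if best is None or obj[-1] < best[2][-1]:
            best = (w, h, obj)
    w, h, obj = best
    rel_err = obj[-1] / max(float(np.linalg.norm(x)), 1e-300)
    contrib = w.copy()
    if normalize_contributions:
        row_sums = contrib.sum(axis=1, keepdims=True)
        contrib = np.divide(contrib, row_sums,
                            out=np.zeros_like(contrib), where=row_sums > 0)
    return SignatureDecomposition(
        samples=list(spectra.samples), contributions=contrib, signatures=h,
        reconstruction_error=rel_err, objective_trace=obj)


def flag_outliers(decomp: SignatureDecomposition, k_sd: float = 2.0
                  ) -> list[str]:
    """Samples whose contribution is > k_sd SDs from the mean, any signature.

    Mean and SD are computed per signature over all samples.  A signature
    with zero SD flags nobody (degenerate identical-contribution case).
    The decomposition is updated in place with the statistics and flags.
    """
    c = decomp.contributions
    mean = c.mean(axis=0)
    sd = c.std(axis=0)
    dev = np.abs(c - mean)
    # an SD at float-noise level means identical contributions: no signal
    effective = sd > 1e-9 * np.maximum(np.abs(mean), 1e-30)
    with np.errstate(invalid="ignore", divide="ignore"):
        outlying = (dev > k_sd * sd) & effective
    flags = [s for s, row in zip(decomp.samples, outlying) if row.any()]
    decomp.contribution_mean = mean
    decomp.contribution_sd = sd
    decomp.flagged = flags
    return flags


def qc_report(decomp: SignatureDecomposition, k_sd: float = 2.0) -> dict:
    flags = decomp.flagged or flag_outliers(decomp, k_sd)
    return {
        "n_samples": len(decomp.samples),
        "rank": decomp.signatures.shape[0],
        "reconstruction_error": decomp.reconstruction_error,
        "objective": "frobenius, multiplicative updates",
        "k_sd": k_sd,
        "n_flagged": len(flags),
        "flagged": flags,
        "contribution_mean": decomp.contribution_mean.tolist(),
        "contribution_sd": decomp.contribution_sd.tolist(),
    }
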