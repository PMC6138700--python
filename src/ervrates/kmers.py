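"""Reference-sequence handling and the canonical mutation-subtype taxonomy.

A mutation subtype is a K-mer sequence motif (K odd) together with a
substitution of its central base.  Subtypes are strand-collapsed so the
central reference base is always A or C: a T>G change inside motif ``m`` is
the same subtype as the A>C change inside the reverse complement of ``m``.
With 6 basic types (A>C, A>G, A>T, C>A, C>G, C>T) and free flanking bases
there are ``6 * 4**(K-1)`` subtypes: 6, 96, 1536 and 24,576 for
K = 1, 3, 5, 7.

Bases are encoded A=0, C=1, G=2, T=3, N=4; complementation is ``3 - code``.
Motif codes are base-4 integers in string order, so numeric order equals
lexicographic order and canonical motifs (central digit 0 or 1) have the
closed-form rank used throughout for vectorised lookups.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(BASES)}
_CODE["N"] = 4
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUPPORTED_K = (1, 3, 5, 7)

#: the six basic mutation types in canonical (A/C-centred) notation
BASIC_TYPES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")


class ContextError(ValueError):
    """Raised when a K-mer context cannot be extracted or is ambiguous."""


class RefMismatchError(ValueError):
    """Raised when a variant's REF allele disagrees with the genome."""


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 code array (A=0,C=1,G=2,T=3,N=4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


@dataclass(frozen=True, order=True)
class MutationSubtype:
    """A canonical (motif, alt) pair; central base of ``motif`` is A or C."""

    motif: str
    alt: str

    def __post_init__(self):
        k = len(self.motif)
        if k % 2 != 1 or k not in SUPPORTED_K:
            raise ValueError(f"unsupported motif length {k}")
        if self.ref not in "AC":
            raise ValueError("central base of a canonical motif must be A or C")
        if self.alt == self.ref or self.alt not in BASES:
            raise ValueError(f"invalid alt {self.alt!r} for ref {self.ref!r}")

    @property
    def k(self) -> int:
        return len(self.motif)

    @property
    def ref(self) -> str:
        return self.motif[len(self.motif) // 2]

    @property
    def basic_type(self) -> str:
        return f"{self.ref}>{self.alt}"

    def __str__(self) -> str:  # e.g. ATA[C>T]GCA
        h = self.k // 2
        return f"{self.motif[:h]}[{self.ref}>{self.alt}]{self.motif[h + 1:]}"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV with its carrier sample and cohort allele count."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample: str = ""
    allele_count: int = 1


@dataclass
class GenomeSequence:
    """Per-chromosome sequences plus an optional accessibility mask.

    ``chroms`` maps name -> uint8 code array.  ``mask`` maps name -> boolean
    accessibility array (True = accessible); sites outside the mask are
    skipped wherever masking is requested.  Mask intervals given to the
    constructors are 0-based half-open, matching BED.
    """

    chroms: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] | None = None
    _seq_cache: dict[str, str] = field(default_factory=dict, repr=False)

    @classmethod
    def from_strings(cls, seqs: dict[str, str],
                     mask_intervals: dict[str, list[tuple[int, int]]] | None = None
                     ) -> "GenomeSequence":
        chroms = {name: encode(s) for name, s in seqs.items()}
        mask = None
        if mask_intervals is not None:
            mask = {}
            for name, arr in chroms.items():
                acc = np.zeros(len(arr), dtype=bool)
                for start, end in mask_intervals.get(name, []):
                    acc[start:end] = True
                mask[name] = acc
        return cls(chroms=chroms, mask=mask)

    @classmethod
    def from_fasta(cls, fasta_path: str, mask_bed: str | None = None
                   ) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        mask_intervals = None
        if mask_bed is not None:
            from .io import read_bed

            mask_intervals = read_bed(mask_bed)
        return cls.from_strings(seqs, mask_intervals)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def sequence(self, chrom: str) -> str:
        if chrom not in self._seq_cache:
            self._seq_cache[chrom] = decode(self.chroms[chrom])
        return self._seq_cache[chrom]

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return "ACGTN"[self.chroms[chrom][pos - 1]]

    def accessible(self, chrom: str, pos: int) -> bool:
        if self.mask is None:
            return True
        return bool(self.mask[chrom][pos - 1])

    def reverse_complemented(self) -> "GenomeSequence":
        """Strand-flipped copy (sequence reversed and complemented)."""
        chroms = {}
        for name, arr in self.chroms.items():
            out = arr[::-1].copy()
            acgt = out < 4
            out[acgt] = 3 - out[acgt]
            chroms[name] = out
        mask = None
        if self.mask is not None:
            mask = {name: m[::-1].copy() for name, m in self.mask.items()}
        return GenomeSequence(chroms=chroms, mask=mask)


# ---------------------------------------------------------------------------
# subtype enumeration and code arithmetic


@functools.lru_cache(maxsize=None)
def _revcomp_codes(k: int) -> np.ndarray:
    """Lookup table: motif code -> code of its reverse complement."""
    n = 4 ** k
    codes = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    for i in range(k):
        digit = (codes // 4 ** i) % 4
        rc += (3 - digit) * 4 ** (k - 1 - i)
    return rc


@functools.lru_cache(maxsize=None)
def _fold_codes(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per motif code: (canonical motif code, was-flipped flag).

    A motif is canonical iff its central base is A or C; others fold onto
    their reverse complement.
    """
    c = k // 2
    codes = np.arange(4 ** k)
    central = (codes // 4 ** c) % 4
    flip = central >= 2
    folded = np.where(flip, _revcomp_codes(k)[codes], codes)
    return folded, flip


def canonical_rank(code: int | np.ndarray, k: int):
    """Rank of a canonical motif code among all canonical K-mers.

    Canonical codes sorted ascending enumerate (hi flank, central in {A,C},
    lo flank) lexicographically, giving rank = (hi*2 + central)*4**c + lo
    with c = (K-1)/2 flanking bases per side.
    """
    c = k // 2
    p = 4 ** c
    hi = code // (4 * p)
    central = (code // p) % 4
    lo = code % p
    return (hi * 2 + central) * p + lo


def n_canonical_motifs(k: int) -> int:
    return 2 * 4 ** (k - 1)


def n_subtypes(k: int) -> int:
    return 6 * 4 ** (k - 1)


@functools.lru_cache(maxsize=None)
def enumerate_subtypes(k: int) -> tuple[MutationSubtype, ...]:
    """All canonical subtypes at motif length ``k``, in (motif, alt) order."""
    if k not in SUPPORTED_K:
        raise ValueError(f"K must be one of {SUPPORTED_K}, got {k}")
    c = k // 2
    out = []
    for code in range(4 ** k):
        central = (code // 4 ** c) % 4
        if central >= 2:
            continue
        motif = decode([(code // 4 ** (k - 1 - i)) % 4 for i in range(k)])
        ref = motif[c]
        for alt in BASES:
            if alt != ref:
                out.append(MutationSubtype(motif, alt))
    return tuple(out)


@functools.lru_cache(maxsize=None)
def subtype_index(k: int) -> dict[MutationSubtype, int]:
    return {s: i for i, s in enumerate(enumerate_subtypes(k))}


def _alt_rank(central_code: int, alt_code: int) -> int:
    """Position of an alt among the 3 alphabetical alts for a central base."""
    return alt_code - 1 if alt_code > central_code else alt_code


def subtype_rank(motif_code: int, alt_code: int, k: int) -> int:
    """Flat subtype index from a canonical motif code and alt base code."""
    c = k // 2
    central = (motif_code // 4 ** c) % 4
    return 3 * canonical_rank(motif_code, k) + _alt_rank(central, alt_code)


# ---------------------------------------------------------------------------
# operations


def canonical_subtype(ref: str, alt: str, context: str) -> MutationSubtype:
    """Fold a substitution and its K-mer context onto the canonical strand.

    If the central reference base is G or T the motif is reverse
    complemented and ref/alt complemented, so the result's central base is
    A or C.  ``canonical_subtype`` of a mutation and of its strand mirror
    are identical.
    """
    k = len(context)
    if k % 2 != 1:
        raise ContextError(f"context length must be odd, got {k}")
    context = context.upper()
    if any(b not in BASES for b in context):
        raise ContextError(f"ambiguous context {context!r}")
    if ref not in BASES or alt not in BASES:
        raise ContextError(f"invalid alleles {ref!r}>{alt!r}")
    if context[k // 2] != ref:
        raise ContextError(
            f"central base {context[k // 2]!r} of context does not match ref {ref!r}")
    if alt == ref:
        raise ContextError("alt equals ref")
    if ref in "GT":
        context = revcomp(context)
        alt = _COMP[alt]
    return MutationSubtype(context, alt)


def extract_context(genome: GenomeSequence, chrom: str, pos: int, k: int) -> str:
    """Reference K-mer centred on a 1-based position.

    Raises :class:`ContextError` when the window runs off the chromosome or
    contains an N, so callers can skip the site.
    """
    h = k // 2
    arr = genome.chroms[chrom]
    if pos - 1 - h < 0 or pos - 1 + h >= len(arr):
        raise ContextError(f"{chrom}:{pos} K={k} window off chromosome end")
    window = arr[pos - 1 - h: pos + h]
    if (window >= 4).any():
        raise ContextError(f"{chrom}:{pos} K={k} window contains N")
    return decode(window)


def genome_motif_ranks(genome: GenomeSequence, k: int, use_mask: bool = False
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome canonical-motif ranks for every position.

    Returns ``{chrom: (ranks, flipped)}`` where ``ranks[i]`` is the
    canonical motif rank of the K-window centred at 0-based position ``i``
    (-1 if the window is invalid: off-end, contains N, or central base
    masked out) and ``flipped[i]`` marks positions whose motif was folded
    onto the reverse complement (central base G/T).
    """
    folded, flip = _fold_codes(k)
    h = k // 2
    out = {}
    for chrom, arr in genome.chroms.items():
        n = len(arr)
        ranks = np.full(n, -1, dtype=np.int64)
        flipped = np.zeros(n, dtype=bool)
        if n >= k:
            win = np.lib.stride_tricks.sliding_window_view(arr, k)
            valid = (win < 4).all(axis=1)
            codes = win.astype(np.int64) @ (4 ** np.arange(k - 1, -1, -1))
            codes = np.where(valid, codes, 0)
            centre = slice(h, n - h) if h else slice(None)
            if use_mask and genome.mask is not None:
                valid &= genome.mask[chrom][centre]
            ranks[centre] = np.where(valid, canonical_rank(folded[codes], k), -1)
            flipped[centre] = np.where(valid, flip[codes], False)
        out[chrom] = (ranks, flipped)
    return out


def count_motifs(genome: GenomeSequence, k: int, use_mask: bool = False
                 ) -> np.ndarray:
    """Sliding-window canonical K-mer counts over the genome.

    Every position whose centred K-window lies inside one chromosome and
    contains no N contributes 1 to its canonical motif; when ``use_mask``
    is set the central base must additionally be accessible.  Returns an
    array of length ``2*4**(K-1)`` in canonical motif order.
    """
    if k not in SUPPORTED_K:
        raise ValueError(f"K must be one of {SUPPORTED_K}, got {k}")
    counts = np.zeros(n_canonical_motifs(k), dtype=np.int64)
    for ranks, _ in genome_motif_ranks(genome, k, use_mask=use_mask).values():
        good = ranks[ranks >= 0]
        counts += np.bincount(good, minlength=len(counts))
    return counts


def motif_count_map(genome: GenomeSequence, k: int, use_mask: bool = False
                    ) -> dict[str, int]:
    """``count_motifs`` keyed by canonical motif string."""
    counts = count_motifs(genome, k, use_mask=use_mask)
    motifs = [s.motif for s in enumerate_subtypes(k)[::3]]
    return dict(zip(motifs, counts.tolist()))
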