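"""Constant-weight error-robust barcode codebooks.

Each gene is assigned a fixed-weight binary word; a minimum pairwise Hamming
distance of 4 allows correction of any single bit error while guaranteeing
that two errors never silently convert one codeword into another.  A small
set of valid codewords is left unassigned ("blanks"): because blanks share
the gene codewords' error statistics, their call rate estimates the
false-positive (misidentification) rate of decoding.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "build_codebook",
    "decode_word",
    "sum_residue_codewords",
    "greedy_codewords",
    "write_codebook_csv",
    "read_codebook_csv",
]


class CodebookCapacityError(ValueError):
    """Raised when a construction cannot supply the requested number of codewords."""


@dataclass
class Codebook:
    """A gene/blank <-> binary barcode map.

    Parameters
    ----------
    n_bits
        Number of imaging rounds / bits per barcode.
    weight
        Number of on-bits in every barcode (constant-weight code).
    min_distance
        Guaranteed minimum pairwise Hamming distance.
    entries
        Ordered mapping name -> bit vector (uint8 array of length ``n_bits``).
        Blank entries are named ``Blank-1`` ... and carry no gene.
    n_blanks
        Number of blank entries at the end of ``entries``.
    """

    n_bits: int
    weight: int
    min_distance: int
    entries: Dict[str, np.ndarray] = field(default_factory=dict)
    n_blanks: int = 0

    @property
    def names(self) -> List[str]:
        return list(self.entries)

    @property
    def gene_names(self) -> List[str]:
        return [n for n in self.entries if not self.is_blank(n)]

    @property
    def blank_names(self) -> List[str]:
        return [n for n in self.entries if self.is_blank(n)]

    @staticmethod
    def is_blank(name: str) -> bool:
        return name.startswith("Blank-")

    def matrix(self) -> np.ndarray:
        """Entries stacked as a (n_entries, n_bits) uint8 matrix."""
        return np.vstack([self.entries[n] for n in self.entries]).astype(np.uint8)

    def barcode_of(self, name: str) -> np.ndarray:
        return self.entries[name]

    def validate(self) -> None:
        """Check all invariants by brute force; raise ``ValueError`` on violation."""
        mat = self.matrix()
        if mat.shape[1] != self.n_bits:
            raise ValueError("barcode length does not match n_bits")
        if not np.all(mat.sum(axis=1) == self.weight):
            raise ValueError("not all barcodes have the declared Hamming weight")
        # pairwise distances, exhaustively
        d = pairwise_hamming(mat)
        n = len(mat)
        if n > 1:
            off = d[np.triu_indices(n, k=1)]
            if off.min() < self.min_distance:
                raise ValueError(
                    f"pairwise Hamming distance {off.min()} < declared minimum {self.min_distance}"
                )
        blanks = self.blank_names
        if len(blanks) != self.n_blanks:
            raise ValueError("blank count inconsistent with entry names")


def pairwise_hamming(mat: np.ndarray) -> np.ndarray:
    """All pairwise Hamming distances of a 0/1 matrix (rows are words)."""
    m = mat.astype(np.int16)
    # d(a,b) = |a| + |b| - 2 a.b
    dots = m @ m.T
    w = m.sum(axis=1)
    return w[:, None] + w[None, :] - 2 * dots


def sum_residue_codewords(n_bits: int, weight: int) -> np.ndarray:
    """All weight-``weight`` words over ``n_bits`` whose on-bit positions sum to 0 mod ``n_bits``.

    For weight 4 this forces any two distinct words to share at most 2 on-bit
    positions (equal 3-subsets would force equal 4th elements mod n_bits),
    hence pairwise Hamming distance >= 4.  The enumeration is deterministic
    (lexicographic in the on-bit positions).
    """
    words = []
    for comb in itertools.combinations(range(n_bits), weight):
        if sum(comb) % n_bits == 0:
            w = np.zeros(n_bits, dtype=np.uint8)
            w[list(comb)] = 1
            words.append(w)
    if not words:
        return np.zeros((0, n_bits), dtype=np.uint8)
    return np.vstack(words)


def greedy_codewords(n_bits: int, weight: int, min_distance: int,
                     n_needed: Optional[int] = None) -> np.ndarray:
    """Lexicographic greedy constant-weight code (fallback construction).

    Scans weight-``weight`` words in lexicographic order of on-bit positions
    and keeps a word iff it is at distance >= ``min_distance`` from every
    kept word.  Stops early once ``n_needed`` words are collected.
    """
    kept: List[np.ndarray] = []
    kept_mat = np.zeros((0, n_bits), dtype=np.int16)
    for comb in itertools.combinations(range(n_bits), weight):
        w = np.zeros(n_bits, dtype=np.int16)
        w[list(comb)] = 1
        if len(kept):
            d = weight + kept_mat.sum(axis=1) - 2 * (kept_mat @ w)
            if d.min() < min_distance:
                continue
        kept.append(w.astype(np.uint8))
        kept_mat = np.vstack([kept_mat, w])
        if n_needed is not None and len(kept) >= n_needed:
            break
    if not kept:
        return np.zeros((0, n_bits), dtype=np.uint8)
    return np.vstack(kept)


def build_codebook(n_bits: int, weight: int, min_distance: int,
                   n_genes: int, n_blanks: int, seed: int = 0,
                   gene_names: Optional[Sequence[str]] = None) -> Codebook:
    """Build a constant-weight codebook and assign genes and blanks.

    The primary generator is the sum-residue construction; when it yields too
    few codewords, the lexicographic greedy construction is used instead.
    Codewords are kept in lexicographic order and mapped onto the gene list
    in input order; blank codewords are sampled uniformly (seeded) from the
    remaining pool.

    Raises
    ------
    ValueError
        If ``weight > n_bits`` or ``min_distance`` is odd / < 2.
    CodebookCapacityError
        If fewer than ``n_genes + n_blanks`` codewords are available.
    """
    if weight > n_bits:
        raise ValueError(f"weight {weight} exceeds n_bits {n_bits}")
    if min_distance < 2 or min_distance % 2 != 0:
        raise ValueError("min_distance must be an even integer >= 2")
    n_total = n_genes + n_blanks
    if n_total < 1:
        raise ValueError("need at least one entry")

    words = np.zeros((0, n_bits), dtype=np.uint8)
    if weight == 4 and min_distance <= 4:
        words = sum_residue_codewords(n_bits, weight)
    if len(words) < n_total:
        words = greedy_codewords(n_bits, weight, min_distance)
    if len(words) < n_total:
        raise CodebookCapacityError(
            f"construction yields {len(words)} codewords; {n_total} requested"
        )

    if gene_names is None:
        gene_names = [f"gene_{i + 1:03d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")

    rng = random.Random(seed)
    blank_pool = list(range(n_genes, len(words)))
    blank_idx = sorted(rng.sample(blank_pool, n_blanks)) if n_blanks else []

    entries: Dict[str, np.ndarray] = {}
    for i, name in enumerate(gene_names):
        entries[str(name)] = words[i].copy()
    for j, idx in enumerate(blank_idx):
        entries[f"Blank-{j + 1}"] = words[idx].copy()

    cb = Codebook(n_bits=n_bits, weight=weight, min_distance=min_distance,
                  entries=entries, n_blanks=n_blanks)
    cb.validate()
    return cb


def decode_word(bits: np.ndarray, codebook: Codebook,
                max_errors: int = 1) -> Optional[Tuple[str, int]]:
    """Decode a bit vector against a codebook with bounded error correction.

    Returns ``(entry_name, n_corrected)`` for the unique entry within Hamming
    distance <= ``max_errors``; ``None`` (no-call) when no entry is in range
    or two entries tie at the minimal distance.  Ties are never guessed.
    """
    bits = np.asarray(bits, dtype=np.int16).ravel()
    if bits.size != codebook.n_bits:
        raise ValueError(f"bit vector length {bits.size} != n_bits {codebook.n_bits}")
    if max_errors not in (0, 1):
        raise ValueError("max_errors must be 0 or 1")
    mat = codebook.matrix().astype(np.int16)
    d = np.abs(mat - bits[None, :]).sum(axis=1)
    dmin = int(d.min())
    if dmin > max_errors:
        return None
    hits = np.flatnonzero(d == dmin)
    if len(hits) > 1:
        return None
    name = codebook.names[int(hits[0])]
    return name, dmin


# ---------------------------------------------------------------------------
# CSV serialization: header `name,is_blank,barcode`, bit string MSB = round 1.

def write_codebook_csv(codebook: Codebook, path) -> None:
    rows = [
        {"name": n,
         "is_blank": int(Codebook.is_blank(n)),
         "barcode": "".join(str(int(b)) for b in codebook.entries[n])}
        for n in codebook.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codebook_csv(path, weight: Optional[int] = None,
                      min_distance: int = 4) -> Codebook:
    df = pd.read_csv(path, dtype={"barcode": str})
    entries: Dict[str, np.ndarray] = {}
    for _, row in df.iterrows():
        entries[str(row["name"])] = np.array([int(c) for c in row["barcode"]], dtype=np.uint8)
    n_bits = len(next(iter(entries.values())))
    if weight is None:
        weight = int(next(iter(entries.values())).sum())
    n_blanks = int(df["is_blank"].sum())
    return Codebook(n_bits=n_bits, weight=weight, min_distance=min_distance,
                    entries=entries, n_blanks=n_blanks)
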