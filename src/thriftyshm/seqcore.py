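"""Nucleotide alphabet handling, k-mer indexing, and codon-degeneracy logic.

All indexing uses the alphabetical base order A=0, C=1, G=2, T=3. The
ambiguity symbol N (and, implicitly, sequence ends) maps to a wildcard.
Coordinates are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

BASES = "ACGT"
ALPHABET = "ACGTN"
BASE_TO_CODE = {b: i for i, b in enumerate(ALPHABET)}
N_CODE = 4  # integer code for the ambiguous base
WILDCARD_3MER = 64  # token for any 3-mer window containing N or an end


@dataclass(frozen=True)
class NucSequence:
    """A validated nucleotide sequence over A, C, G, T, N.

    Lowercase input is normalized to uppercase on construction; any other
    character is rejected with the offending 0-based position.
    """

    bases: str

    def __post_init__(self) -> None:
        seq = self.bases.upper()
        if len(seq) < 1:
            raise ValueError("sequence must have length >= 1")
        for i, ch in enumerate(seq):
            if ch not in BASE_TO_CODE:
                raise ValueError(
                    f"invalid character {ch!r} at position {i}; "
                    f"alphabet is {ALPHABET}"
                )
        object.__setattr__(self, "bases", seq)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def codes(self) -> np.ndarray:
        """Integer codes A=0,C=1,G=2,T=3,N=4 as an int8 array."""
        return np.frombuffer(
            self.bases.encode().translate(_CODE_TABLE), dtype=np.int8
        ).copy()


_CODE_TABLE = bytes.maketrans(b"ACGTN", bytes(range(5)))


def seq_codes(seq: "NucSequence | str") -> np.ndarray:
    """Integer codes for a sequence or raw string (validated on the fly)."""
    if isinstance(seq, NucSequence):
        return seq.codes()
    return NucSequence(seq).codes()


def encode_3mers(seq: "NucSequence | str") -> np.ndarray:
    """Per-site 3-mer token indices.

    The token at site i encodes the 3-mer centered at i (bases i-1, i, i+1)
    as a base-4 integer, most-significant digit first. Windows containing N
    or overhanging a sequence end map to the wildcard token 64.
    """
    codes = seq_codes(seq)
    n = len(codes)
    tokens = np.full(n, WILDCARD_3MER, dtype=np.int64)
    if n >= 3:
        left, mid, right = codes[:-2], codes[1:-1], codes[2:]
        valid = (left != N_CODE) & (mid != N_CODE) & (right != N_CODE)
        interior = 16 * left.astype(np.int64) + 4 * mid + right
        tokens[1:-1] = np.where(valid, interior, WILDCARD_3MER)
    return tokens


def decode_3mer(token: int) -> str:
    """Inverse of the 3-mer indexing for the 64 canonical tokens."""
    if not 0 <= token < 64:
        raise ValueError(f"token {token} is not a canonical 3-mer token")
    return BASES[token // 16] + BASES[(token // 4) % 4] + BASES[token % 4]


def kmer_index(seq: "NucSequence | str", site: int, k: int) -> int:
    """Base-4 index of the k-mer centered at ``site``.

    Returns the wildcard sentinel 4**k when the window contains N or
    overhangs a sequence end. k must be odd.
    """
    codes = seq_codes(seq)
    if k % 2 == 0 or k < 1:
        raise ValueError(f"k must be odd and >= 1, got {k}")
    if not 0 <= site < len(codes):
        raise ValueError(f"site {site} outside sequence of length {len(codes)}")
    return int(kmer_indices_from_codes(codes, k)[site])


def kmer_indices(seq: "NucSequence | str", k: int) -> np.ndarray:
    """Vectorized k-mer index at every site (wildcard sentinel = 4**k)."""
    if k % 2 == 0 or k < 1:
        raise ValueError(f"k must be odd and >= 1, got {k}")
    return kmer_indices_from_codes(seq_codes(seq), k)


def kmer_indices_from_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """k-mer indices from precomputed integer codes (no validation)."""
    n = len(codes)
    wildcard = 4**k
    out = np.full(n, wildcard, dtype=np.int64)
    if n < k:
        return out
    half = k // 2
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = np.all(windows != N_CODE, axis=1)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows.astype(np.int64) @ weights
    if half > 0:
        out[half:-half] = np.where(valid, idx, wildcard)
    else:
        out[:] = np.where(valid, idx, wildcard)
    return out


_FOURFOLD_PREFIXES: dict[str, bool] | None = None


def _codon_table() -> dict[str, bool]:
    global _FOURFOLD_PREFIXES
    if _FOURFOLD_PREFIXES is None:
        table = {}
        for a in BASES:
            for b in BASES:
                aas = {str(Seq(a + b + c).translate()) for c in BASES}
                table[a + b] = len(aas) == 1
        _FOURFOLD_PREFIXES = table
    return _FOURFOLD_PREFIXES


def is_fourfold_degenerate(codon_prefix: str) -> bool:
    """True iff all four codons with this two-base prefix encode one amino acid.

    A prefix containing N returns False: degeneracy cannot be certified for
    an ambiguous codon context. Uses the standard nuclear genetic code.
    """
    prefix = codon_prefix.upper()
    if len(prefix) != 2:
        raise ValueError(f"codon prefix must have 2 bases, got {prefix!r}")
    if "N" in prefix:
        return False
    if any(ch not in BASES for ch in prefix):
        raise ValueError(f"invalid base in codon prefix {prefix!r}")
    return _codon_table()[prefix]


def read_fasta(path) -> Iterator[tuple[str, NucSequence]]:
    """Yield (record id, sequence) pairs from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, NucSequence(str(rec.seq))


def write_fasta(path, records) -> None:
    """Write (id, NucSequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
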