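"""Low-level DNA sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Set of canonical k-mers of ``seq``.

    A canonical k-mer is the lexicographic minimum of the k-mer and its
    reverse complement, so the result is strand-independent. K-mers
    containing any base other than A/C/G/T are skipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    out: set[str] = set()
    n = len(seq)
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. random DNA of the given length and expected GC fraction."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    idx = rng.choice(4, size=length, p=p)
    return _BASE_ARR[idx].tobytes().decode("ascii")


def mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Apply i.i.d. substitutions at the given per-base rate.

    Each selected position is replaced by one of the three other bases,
    chosen uniformly. Returns the mutated sequence and the realized
    substitution count.
    """
    if rate < 0:
        raise ValueError(f"substitution rate must be >= 0, got {rate}")
    if rate == 0 or not seq:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n == 0:
        return seq, 0
    # map current base to an index, shift by 1..3 mod 4 to guarantee a change
    base_idx = np.searchsorted(_BASE_ARR, arr[hit])
    shift = rng.integers(1, 4, size=n)
    arr[hit] = _BASE_ARR[(base_idx + shift) % 4]
    return arr.tobytes().decode("ascii"), n


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a DNA string for vectorized comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
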