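"""Read mapping to a repeat consensus and coverage-based estimates.

Maps reads to a single repeat consensus by exact k-mer seeding and
per-diagonal extension, keeps each read's best hit when its identity
reaches the mapping threshold (default 95%), accumulates per-position
depth per sex pool, and derives the downstream arithmetic: genome
fold-coverage, copy numbers (element depth / genome depth), sex
fold-differences, and internal-deletion calls from localized coverage
drops.

Since the read model is substitution-only, extension is gapless: every
candidate alignment lies on one diagonal, identity is matches over the
overlapping columns (end overhangs are free), and the computation is exact
rather than heuristic. Reads spanning a deletion junction of a variant
copy do not fit the full consensus on any single diagonal and fall below
the identity threshold — exactly the behavior that makes the deleted
region's coverage drop informative about carrier copies.

Integer copy numbers use round-half-down (17.5 -> 17, 325.46 -> 325),
and carrier copies are a difference of rounded copy numbers, not a
rounded difference — the only conventions consistent with all of the
printed worked examples this module is validated against.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqs import revcomp, seq_to_array

DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_K_SEED = 13
#: minimum aligned reference columns as a fraction of read length; the
#: deterministic stand-in for manual curation of marginal hits
DEFAULT_MIN_ALIGNED_FRAC = 0.5


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    ref_start: int  # 0-based, half-open
    ref_end: int
    strand: str
    identity: float
    matches: int
    aligned_columns: int


@dataclass
class CoverageProfile:
    """Per-position mapped depth over a reference for one read pool."""

    reference_name: str
    length_bp: int
    depth: np.ndarray
    n_mapped: int = 0

    def mean_depth(self, start: int = 0, end: Optional[int] = None) -> float:
        end = self.length_bp if end is None else end
        if not 0 <= start < end <= self.length_bp:
            raise ValueError(f"region [{start}, {end}) outside reference")
        return float(self.depth[start:end].mean())

    def mean_depth_excluding(self, start: int, end: int) -> float:
        mask = np.ones(self.length_bp, dtype=bool)
        mask[start:end] = False
        if not mask.any():
            raise ValueError("excluded region covers the whole reference")
        return float(self.depth[mask].mean())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tdepth\n")
            for i, d in enumerate(self.depth):
                fh.write(f"{i}\t{int(d)}\n")


class ReferenceIndex:
    """Exact k-mer seed index over a single reference sequence."""

    def __init__(self, reference: str, k: int = DEFAULT_K_SEED, name: str = "ref"):
        if not reference:
            raise ValueError("reference sequence is empty")
        if k >= len(reference):
            raise ValueError(f"k_seed ({k}) must be smaller than the reference")
        self.name = name
        self.seq = reference.upper()
        self.k = k
        self.arr = seq_to_array(self.seq)
        self.index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(self.seq) - k + 1):
            kmer = self.seq[i : i + k]
            if "N" not in kmer:
                self.index[kmer].append(i)


def _best_hit(
    ref: ReferenceIndex,
    read_id: str,
    seq: str,
    min_aligned: int,
) -> Optional[AlignmentHit]:
    """Best gapless hit of a read over all seeded diagonals, both strands.

    Ties are broken by leftmost reference start, then forward strand.
    """
    ref_len = len(ref.seq)
    best: Optional[AlignmentHit] = None
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        L = len(oriented)
        read_arr = seq_to_array(oriented)
        diagonals: set[int] = set()
        for p in range(L - ref.k + 1):
            kmer = oriented[p : p + ref.k]
            for rp in ref.index.get(kmer, ()):
                diagonals.add(rp - p)
        for d in sorted(diagonals):
            a = max(0, d)
            b = min(ref_len, d + L)
            cols = b - a
            if cols < min_aligned:
                continue
            matches = int(
                np.count_nonzero(ref.arr[a:b] == read_arr[a - d : b - d])
            )
            identity = matches / cols
            hit = AlignmentHit(read_id, a, b, strand, identity, matches, cols)
            if (
                best is None
                or hit.identity > best.identity
                or (
                    hit.identity == best.identity
                    and (hit.ref_start, hit.strand != "+")
                    < (best.ref_start, best.strand != "+")
                )
            ):
                best = hit
    return best


def map_reads(
    reads: Iterable[tuple[str, str]],
    reference: str | ReferenceIndex,
    reference_name: str = "ref",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k_seed: int = DEFAULT_K_SEED,
    min_aligned_frac: float = DEFAULT_MIN_ALIGNED_FRAC,
) -> tuple[list[AlignmentHit], CoverageProfile]:
    """Map a read pool to one consensus; return retained hits and depth.

    Each read contributes at most once, at its best hit, and only if that
    hit's identity is >= ``min_identity`` and it spans at least
    ``min_aligned_frac`` of the read. Depth is incremented over the
    aligned reference columns only.
    """
    if not 0.5 < min_identity <= 1.0:
        raise ValueError(f"min_identity must be in (0.5, 1], got {min_identity}")
    ref = (
        reference
        if isinstance(reference, ReferenceIndex)
        else ReferenceIndex(reference, k=k_seed, name=reference_name)
    )
    depth = np.zeros(len(ref.seq), dtype=np.int64)
    hits: list[AlignmentHit] = []
    for read_id, seq in reads:
        min_aligned = max(ref.k, int(math.ceil(min_aligned_frac * len(seq))))
        hit = _best_hit(ref, read_id, seq.upper(), min_aligned)
        if hit is not None and hit.identity >= min_identity:
            hits.append(hit)
            depth[hit.ref_start : hit.ref_end] += 1
    profile = CoverageProfile(ref.name, len(ref.seq), depth, n_mapped=len(hits))
    return hits, profile


def map_to_reference(
    pools: dict[str, list[tuple[str, str]]],
    reference: str,
    reference_name: str = "ref",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k_seed: int = DEFAULT_K_SEED,
    min_aligned_frac: float = DEFAULT_MIN_ALIGNED_FRAC,
) -> dict[str, tuple[list[AlignmentHit], CoverageProfile]]:
    """Map per-sex read pools (e.g. {'F': reads, 'M': reads}) to a consensus."""
    ref = ReferenceIndex(reference, k=k_seed, name=reference_name)
    return {
        sex: map_reads(
            reads,
            ref,
            min_identity=min_identity,
            min_aligned_frac=min_aligned_frac,
        )
        for sex, reads in pools.items()
    }


def hits_to_tsv(hits: Sequence[AlignmentHit], path) -> None:
    """Hit table: read_id, ref start/end (0-based half-open), strand, identity."""
    with open(path, "w") as fh:
        fh.write("read_id\tref_start\tref_end\tstrand\tidentity\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.ref_start}\t{h.ref_end}\t{h.strand}\t{h.identity:.4f}\n"
            )


# ---------------------------------------------------------------------------
# coverage arithmetic


def round_half_down(x: float) -> int:
    """Nearest integer with exact halves rounded down (17.5 -> 17)."""
    if x < 0:
        raise ValueError(f"round_half_down expects a non-negative value, got {x}")
    return int(math.ceil(x - 0.5))


def estimate_genome_coverage(total_read_bases: float, genome_size_bp: float) -> float:
    """Genome fold-coverage = total read bases / genome size."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if total_read_bases < 0:
        raise ValueError("total read bases must be non-negative")
    return total_read_bases / genome_size_bp


@dataclass(frozen=True)
class CopyNumberEstimate:
    element_coverage: float
    genome_coverage: float
    copies_raw: float
    copies: int


def estimate_copies(element_coverage: float, genome_coverage: float) -> CopyNumberEstimate:
    """Copy number = element fold-coverage / genome fold-coverage.

    The integer copy count uses round-half-down. For a W-limited element
    this is a haploid-genome equivalent: reads come from diploid cells, so
    a single-W female contributes half the per-copy depth of a diploid
    locus (see the simulator's dosage note).
    """
    if genome_coverage <= 0:
        raise ValueError("genome coverage must be positive")
    if element_coverage < 0:
        raise ValueError("element coverage must be non-negative")
    raw = element_coverage / genome_coverage
    return CopyNumberEstimate(element_coverage, genome_coverage, raw, round_half_down(raw))


def fold_difference(copies_a: int, copies_b: int) -> float:
    """Integer fold-difference round(a/b), halves down; b = 0 -> inf."""
    if copies_b == 0:
        return math.inf
    return round_half_down(copies_a / copies_b)


@dataclass(frozen=True)
class DeletionCall:
    region: tuple[int, int]
    coverage_inside: float
    coverage_outside: float
    drop_percent: int
    carrier_copies: int


def call_deletion(
    coverage_inside: float,
    coverage_outside: float,
    genome_coverage: float,
    region: tuple[int, int] = (0, 0),
) -> DeletionCall:
    """Deletion-variant arithmetic from inside/outside fold-coverages.

    drop_percent = round((C_out - C_in) / C_out * 100); carrier copies are
    the difference of the *rounded* copy numbers outside and inside — the
    convention that keeps carrier counts consistent with the reported
    per-element copy numbers.
    """
    if coverage_outside <= 0:
        raise ValueError("coverage outside the region is zero; deletion call undefined")
    if coverage_inside < 0:
        raise ValueError("coverage inside the region must be non-negative")
    drop = round_half_down((coverage_outside - coverage_inside) / coverage_outside * 100.0)
    drop = max(0, min(100, drop))
    copies_out = estimate_copies(coverage_outside, genome_coverage).copies
    copies_in = estimate_copies(coverage_inside, genome_coverage).copies
    return DeletionCall(
        region=region,
        coverage_inside=coverage_inside,
        coverage_outside=coverage_outside,
        drop_percent=drop,
        carrier_copies=max(0, copies_out - copies_in),
    )


def analyze_deletion(
    profile: CoverageProfile,
    region: tuple[int, int],
    genome_coverage: float,
    coverage_outside: Optional[float] = None,
) -> DeletionCall:
    """Call an internal deletion from a coverage profile.

    ``coverage_outside`` defaults to the mean depth over the element
    excluding the region; pass a full-element mean explicitly to reproduce
    summaries quoted against whole-element coverage.
    """
    start, end = region
    c_in = profile.mean_depth(start, end)
    c_out = (
        profile.mean_depth_excluding(start, end)
        if coverage_outside is None
        else coverage_outside
    )
    return call_deletion(c_in, c_out, genome_coverage, region=(start, end))


def scan_deletion_regions(
    profile: CoverageProfile,
    window_bp: int = 100,
    drop_threshold: float = 0.9,
    edge_trim_bp: Optional[int] = None,
) -> list[tuple[int, int]]:
    """Candidate internal-deletion regions from sliding-window coverage drops.

    A centered sliding-window mean is compared with ``drop_threshold``
    times the mean depth of the scanned interior; maximal runs of
    below-threshold positions are merged and reported as 0-based half-open
    regions, ordered by ascending windowed depth (strongest drop first).

    Coverage always falls off near the reference ends (reads overhang and
    shorter overlaps are rejected), so ``edge_trim_bp`` positions at each
    end — one window width by default, ideally the read length — are
    excluded from both the baseline and the scan. With
    ``drop_threshold = 1.0`` every below-average window is flagged — a
    degenerate setting kept only for completeness.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if edge_trim_bp is None:
        edge_trim_bp = window_bp
    depth = profile.depth.astype(float)
    n = depth.size
    lo, hi = edge_trim_bp, n - edge_trim_bp
    if n == 0 or hi - lo < window_bp:
        return []
    interior = depth[lo:hi]
    interior_mean = interior.mean()
    if interior_mean == 0:
        return []
    w = min(window_bp, interior.size)
    kernel = np.ones(w) / w
    # mean of every fully-contained window; window i spans [i, i + w)
    window_means = np.convolve(interior, kernel, mode="valid")
    below = window_means < drop_threshold * interior_mean

    regions: list[tuple[int, int]] = []
    depths: list[float] = []
    i = 0
    m = below.size
    while i < m:
        if below[i]:
            j = i
            while j < m and below[j]:
                j += 1
            regions.append((i + lo, j - 1 + lo + w))
            depths.append(float(window_means[i:j].min()))
            i = j
        else:
            i += 1
    order = sorted(range(len(regions)), key=lambda idx: (depths[idx], regions[idx][0]))
    return [regions[idx] for idx in order]
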