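"""Deterministic read preparation: crop, equal-depth subsampling, tagging, pooling.

Comparative read clustering is only meaningful when every individual
contributes the same number of reads of the same length. This module crops
reads to a fixed length, draws a fixed-size uniform subsample per
individual, tags read names with a per-individual prefix, and concatenates
the tagged sets into a single pool whose per-individual origin can always
be recovered from the prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simgenome import ReadSet


@dataclass(frozen=True)
class TagInfo:
    sex: str
    prefix: str
    n_reads: int


@dataclass
class PooledReads:
    """Concatenated tagged reads from several individuals.

    ``tag_map`` maps individual id to (sex, prefix, read count); every read
    id in ``reads`` begins with exactly one known prefix.
    """

    reads: list[tuple[str, str]] = field(default_factory=list)
    tag_map: dict[str, TagInfo] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def individual_of(self, read_id: str) -> str:
        for ind, tag in self.tag_map.items():
            if read_id.startswith(tag.prefix):
                return ind
        raise ValueError(f"read id {read_id!r} matches no known individual prefix")


def prefix_for(individual_id: str) -> str:
    """Tag prefix convention: ``<individual_id>_``."""
    return f"{individual_id}_"


def prepare_reads(readset: ReadSet, crop_length_bp: int) -> ReadSet:
    """Crop reads to a fixed length, discarding those that are too short.

    Longer reads are truncated from the 3' end (the low-quality end of the
    sequencing platform); input order is preserved.
    """
    if crop_length_bp <= 0:
        raise ValueError(f"crop_length_bp must be positive, got {crop_length_bp}")
    kept = [
        (rid, seq[:crop_length_bp], qual[:crop_length_bp] if qual else qual)
        for rid, seq, qual in readset.reads
        if len(seq) >= crop_length_bp
    ]
    return ReadSet(readset.individual_id, readset.sex, kept, crop_length_bp)


def sample_and_tag(
    readset: ReadSet, n: int, prefix: str | None = None, seed: int = 0
) -> ReadSet:
    """Uniform subsample of exactly ``n`` reads, ids prefixed for pooling.

    Sampling is without replacement; the sampled reads keep their input
    order. The default prefix is ``<individual_id>_``.
    """
    available = len(readset.reads)
    if n > available:
        raise ValueError(
            f"requested {n} reads from individual {readset.individual_id!r} "
            f"but only {available} are available"
        )
    if prefix is None:
        prefix = prefix_for(readset.individual_id)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(available, size=n, replace=False))
    sampled = [
        (prefix + readset.reads[i][0], readset.reads[i][1], readset.reads[i][2])
        for i in idx
    ]
    return ReadSet(readset.individual_id, readset.sex, sampled, readset.read_length_bp)


def pool_reads(readsets: list[ReadSet]) -> PooledReads:
    """Concatenate tagged read sets into one pool, preserving order.

    Every read set must already be tagged (its ids start with its
    individual's prefix) and prefixes must be unique.
    """
    pool = PooledReads()
    for rs in readsets:
        prefix = prefix_for(rs.individual_id)
        if rs.individual_id in pool.tag_map:
            raise ValueError(f"duplicate individual prefix {prefix!r} in pool")
        for rid, _, _ in rs.reads:
            if not rid.startswith(prefix):
                raise ValueError(
                    f"read {rid!r} of individual {rs.individual_id!r} lacks "
                    f"its tag prefix {prefix!r}; run sample_and_tag first"
                )
        pool.tag_map[rs.individual_id] = TagInfo(rs.sex, prefix, len(rs.reads))
        pool.reads.extend((rid, seq) for rid, seq, _ in rs.reads)
    return pool


def split_pool(pool: PooledReads) -> dict[str, list[tuple[str, str]]]:
    """Invert pooling: reads per individual with tag prefixes stripped."""
    out: dict[str, list[tuple[str, str]]] = {ind: [] for ind in pool.tag_map}
    for rid, seq in pool.reads:
        ind = pool.individual_of(rid)
        prefix = pool.tag_map[ind].prefix
        out[ind].append((rid[len(prefix) :], seq))
    return out


def write_pool_fasta(pool: PooledReads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in pool.reads:
            fh.write(f">{rid}\n{seq}\n")
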