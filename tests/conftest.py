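"""Shared fixtures: a reference synthetic run used by several test modules.

The two-family fixture emulates the comparative study design at desk
scale: a 2 Mb WZ/ZZ genome, a LINE-like family (540-bp monomer, 150 W
copies, 2 autosomal copies, 2% divergence) and a Bel-Pao-like family
(800-bp monomer, 90 W copies, 1 autosomal copy, 1% divergence, 213-bp
internal deletion in 17% of W copies), three individuals per sex at
0.77x simulated depth, 150-bp reads cropped to 140 bp, and 800 sampled
reads per individual (about 0.06x pooled sampling, preserving the
low-coverage regime in which single-copy reads rarely overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from wrepscan import enrichstat, readprep, repclust, simgenome


@dataclass
class TwoFamilyRun:
    spec: simgenome.GenomeSpec
    families: list[simgenome.RepeatFamily]
    female: dict[str, str]
    male: dict[str, str]
    manifest: simgenome.TruthManifest
    readsets: list[simgenome.ReadSet]
    pool: readprep.PooledReads
    clusters: list[list[int]]
    table: repclust.ClusterTable
    records: list[enrichstat.EnrichmentRecord]
    selected: list[enrichstat.EnrichmentRecord]
    summary: enrichstat.WSummary


def family_label(
    manifest: simgenome.TruthManifest,
    read_id: str,
    read_length: int = 140,
    min_overlap: int = 32,
) -> str | None:
    """Family of origin of a simulated read, from its provenance fields.

    A read is attributed to the planted family whose insert it overlaps
    most, provided the overlap reaches ``min_overlap`` bases (the exact
    overlap needed to share 20 13-mers, i.e. enough repeat sequence to
    have joined a cluster on merit). Reads of purely background origin
    return None.
    """
    comp, start, _ = simgenome.read_origin(read_id)
    best, best_ov = None, 0
    for ins in manifest.inserts:
        if ins.compartment != comp:
            continue
        ov = min(start + read_length, ins.end) - max(start, ins.start)
        if ov > best_ov:
            best, best_ov = ins.family, ov
    return best if best_ov >= min_overlap else None


def simulate_individuals(
    female: dict[str, str],
    male: dict[str, str],
    depth: float = 0.77,
    read_length: int = 150,
    error_rate: float = 0.005,
    per_sex: int = 3,
    seed: int = 0,
) -> list[simgenome.ReadSet]:
    readsets = []
    for sex, genomes in (("F", female), ("M", male)):
        for i in range(per_sex):
            readsets.append(
                simgenome.simulate_reads(
                    genomes,
                    sex,
                    depth,
                    read_length,
                    error_rate=error_rate,
                    seed=seed * 100 + len(readsets),
                    individual_id=f"{sex}{i + 1}",
                )
            )
    return readsets


def make_two_family_genome(seed: int = 7):
    spec = simgenome.GenomeSpec(
        genome_size_bp=2_000_000, w_fraction=0.2, z_fraction=0.1, gc=0.38, seed=seed
    )
    families = [
        simgenome.RepeatFamily(
            "line_like",
            simgenome.random_monomer(540, seed=11),
            copies_w=150,
            copies_autosome=2,
            divergence=0.02,
        ),
        simgenome.RepeatFamily(
            "belpao_like",
            simgenome.random_monomer(800, seed=12),
            copies_w=90,
            copies_autosome=1,
            divergence=0.01,
            deletion=simgenome.Deletion(300, 213, 0.17),
        ),
    ]
    return spec, families


@pytest.fixture(scope="session")
def two_family_run() -> TwoFamilyRun:
    spec, families = make_two_family_genome(seed=7)
    female, male, manifest = simgenome.build_genomes(spec, families)
    readsets = simulate_individuals(female, male, seed=1)
    tagged = [
        readprep.sample_and_tag(readprep.prepare_reads(rs, 140), 800, seed=i)
        for i, rs in enumerate(readsets)
    ]
    pool = readprep.pool_reads(tagged)
    graph = repclust.build_read_graph(pool)
    clusters = repclust.cluster_reads(graph)
    table = repclust.tabulate_clusters(clusters, pool)
    records = enrichstat.score_cluster_table(table)
    selected, summary = enrichstat.select_w_enriched(records)
    return TwoFamilyRun(
        spec=spec,
        families=families,
        female=female,
        male=male,
        manifest=manifest,
        readsets=readsets,
        pool=pool,
        clusters=clusters,
        table=table,
        records=records,
        selected=selected,
        summary=summary,
    )
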