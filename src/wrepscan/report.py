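"""Run configuration, unit conversions, and human-readable summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional

#: standard C-value conversion factor, megabases per picogram
MB_PER_PG = 978


def pg_to_mb(c_value_pg: float) -> int:
    """Convert a C-value in picograms to integer megabases.

    Uses the standard 978 Mb/pg factor with floor rounding
    (0.646 pg -> 631 Mb, 0.53 pg -> 518 Mb).
    """
    if c_value_pg <= 0:
        raise ValueError(f"C-value must be positive, got {c_value_pg}")
    return int(math.floor(c_value_pg * MB_PER_PG))


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    Defaults are the reference analysis conditions: 140-bp cropped reads,
    100,000 sampled reads per individual, a 0.01% cluster-abundance floor,
    raw P < 0.05, a 95% mapping identity threshold, and a 631 Mb genome.
    """

    crop_length_bp: int = 140
    n_per_individual: int = 100_000
    k: int = 13
    min_shared_kmers: int = 20
    min_cluster_reads: int = 2
    min_fraction: float = 0.0001
    alpha: float = 0.05
    min_identity: float = 0.95
    k_seed: int = 13
    min_aligned_frac: float = 0.5
    genome_size_bp: int = 631_000_000
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.crop_length_bp <= 0:
            raise ValueError("crop_length_bp must be positive")
        if self.n_per_individual <= 0:
            raise ValueError("n_per_individual must be positive")
        if self.k < 1 or self.k >= self.crop_length_bp:
            raise ValueError("k must satisfy 1 <= k < crop_length_bp")
        if self.min_shared_kmers < 1:
            raise ValueError("min_shared_kmers must be >= 1")
        if self.min_cluster_reads < 2:
            raise ValueError("min_cluster_reads must be >= 2")
        if not 0.0 <= self.min_fraction < 1.0:
            raise ValueError("min_fraction must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.5 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0.5, 1]")
        if not 0.0 < self.min_aligned_frac <= 1.0:
            raise ValueError("min_aligned_frac must be in (0, 1]")
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")
        return self

    def to_file(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("# wrepscan run configuration\n")
            for f in fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise ValueError(f"unknown configuration key {key!r}")
                kwargs[key] = (float if types[key] == "float" else int)(value.strip())
        return cls(**kwargs).validate()


def write_summary(
    out_dir: str | Path,
    cluster_table=None,
    records=None,
    w_summary=None,
    copy_estimates: Optional[dict] = None,
    deletion_calls: Optional[dict] = None,
    manifest=None,
) -> dict[str, Path]:
    """Write deterministic report files for whichever stages ran.

    Produces ``clusters.tsv`` (cluster counts), ``enrichment.tsv`` (one row
    per scored cluster: enrichment, per-sex genome percents, Welch
    statistics, filter flags), and ``summary.txt`` with the W-selection
    block, copy-number and deletion blocks, and — when a truth manifest is
    supplied — a recovery section comparing estimates with the planted
    (dosage-adjusted) expectations. Identical inputs give byte-identical
    files.
    """
    if all(
        x is None
        for x in (cluster_table, records, w_summary, copy_estimates, deletion_calls)
    ):
        raise ValueError("write_summary needs at least one stage output")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    lines: list[str] = ["wrepscan run summary", "===================="]

    if cluster_table is not None:
        paths["clusters"] = out / "clusters.tsv"
        cluster_table.to_tsv(paths["clusters"])
        lines.append("")
        lines.append(
            f"clusters: {len(cluster_table.table)} retained, "
            f"clustered fraction of pool {cluster_table.clustered_fraction:.4f}"
        )

    if records is not None:
        paths["enrichment"] = out / "enrichment.tsv"
        with paths["enrichment"].open("w") as fh:
            fh.write(
                "cluster_id\tenrichment\tfemale_percent\tmale_percent\t"
                "t\tdf\tp\tabundant\tsignificant\tselected\tzero_adjusted\n"
            )
            for r in sorted(records, key=lambda r: r.cluster_id):
                sel = "" if r.passes_empirical is None else int(r.passes_empirical)
                fh.write(
                    f"{r.cluster_id}\t{r.ratio:.2f}\t{r.mean_f:.4f}\t{r.mean_m:.4f}\t"
                    f"{r.t_stat:.4f}\t{r.df:.3f}\t{r.p_value:.4g}\t"
                    f"{int(r.passes_abundance)}\t{int(r.passes_significance)}\t"
                    f"{sel}\t{int(r.zero_adjusted)}\n"
                )

    if w_summary is not None:
        lines.append("")
        lines.append("putative W-enriched repeats")
        lines.append(f"  selected clusters: {w_summary.n_selected}")
        lines.append(f"  empirical cutoff r_max: {w_summary.r_max_cutoff:.2f}")
        if w_summary.n_selected:
            lines.append(
                f"  enrichment: geometric mean {w_summary.geometric_mean_enrichment:.2f}, "
                f"maximum {w_summary.max_enrichment:.2f}"
            )
        else:
            lines.append("  zero putative W repeats passed the filters")

    if copy_estimates:
        lines.append("")
        lines.append("copy-number estimates (element coverage / genome coverage)")
        for name in sorted(copy_estimates):
            for sex in sorted(copy_estimates[name]):
                est = copy_estimates[name][sex]
                lines.append(
                    f"  {name} [{sex}]: {est.element_coverage:.1f}x / "
                    f"{est.genome_coverage:.2f}x = {est.copies_raw:.2f} -> {est.copies} copies"
                )

    if deletion_calls:
        lines.append("")
        lines.append("internal-deletion calls")
        for name in sorted(deletion_calls):
            call = deletion_calls[name]
            lines.append(
                f"  {name}: region [{call.region[0]}, {call.region[1]}), coverage "
                f"{call.coverage_inside:.1f}x inside vs {call.coverage_outside:.1f}x outside, "
                f"drop {call.drop_percent}%, carrier copies {call.carrier_copies}"
            )

    if manifest is not None and copy_estimates:
        lines.append("")
        lines.append("recovery vs planted truth (haploid-equivalent copies)")
        for name in sorted(copy_estimates):
            if name not in manifest.families():
                continue
            for sex in sorted(copy_estimates[name]):
                expected = manifest.expected_copy_equivalent(name, sex)
                est = copy_estimates[name][sex]
                lines.append(
                    f"  {name} [{sex}]: planted equivalent {expected:.1f}, "
                    f"estimated {est.copies_raw:.1f}"
                )

    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
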