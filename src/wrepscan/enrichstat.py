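"""Sex-differential cluster abundance: Welch tests, filters, W-repeat selection.

Each cluster's per-individual genome percentages (cluster reads / sampled
reads x 100) are compared between females and males with Welch's unequal-
variance two-sample t-test. Three filters mirror the study design of a
comparative repeat scan:

1. abundance — the cluster holds at least ``min_fraction`` of the pooled
   reads (default 0.01%);
2. significance — two-sided Welch P < alpha (default 0.05, uncorrected);
3. empirical false-positive cutoff — the maximum male-over-female
   enrichment among *male*-significant clusters defines the noise ceiling
   r_max; only female-enriched clusters whose female-to-male ratio exceeds
   r_max are accepted as putative W repeats.

Enrichment ratios are always computed from raw counts (equivalently,
unrounded percentages) — never from display-rounded table values, which
can shift a ratio by several percent. The summary "average enrichment" is
the geometric mean of the selected ratios, the natural average for
fold-changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_FRACTION = 0.0001

#: pseudo-reads added to an all-zero sex pool so a ratio stays finite
ZERO_RULE_PSEUDOCOUNT = 0.5


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Returns (t, df, p) with t = (mean x - mean y) / sqrt(s2x/nx + s2y/ny),
    Welch-Satterthwaite degrees of freedom, and sample variances with
    divisor n - 1. Two samples that are both constant and equal give
    (0, nx + ny - 2, 1) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"each sample needs at least 2 values, got {x.size} and {y.size}"
        )
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        t = math.inf if x.mean() > y.mean() else -math.inf
        return t, float(nx + ny - 2), 0.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One cluster's sex-differential abundance scoring."""

    cluster_id: int
    mean_f: float  # mean female genome percent (raw, possibly 0)
    mean_m: float
    ratio: float  # female-over-male, zero-rule applied when mean_m == 0
    direction: str  # 'female', 'male', or 'none'
    t_stat: float
    df: float
    p_value: float
    passes_abundance: bool
    passes_significance: bool
    passes_empirical: Optional[bool] = None  # set during selection
    zero_adjusted: bool = False
    total_f: int = 0
    total_m: int = 0
    n_sampled_f: int = 0
    n_sampled_m: int = 0

    def male_over_female(self) -> float:
        """Reciprocal enrichment with the same zero guard on the female side."""
        if self.mean_f > 0:
            return self.mean_m / self.mean_f
        if self.n_sampled_f <= 0:
            return math.inf
        guarded = ZERO_RULE_PSEUDOCOUNT / self.n_sampled_f * 100.0
        return self.mean_m / guarded


@dataclass(frozen=True)
class WSummary:
    """Selection summary: count, geometric-mean and maximum enrichment, cutoff."""

    n_selected: int
    geometric_mean_enrichment: float
    max_enrichment: float
    r_max_cutoff: float


def score_cluster(
    cluster_id: int,
    counts_f: Sequence[int],
    counts_m: Sequence[int],
    n_sampled_f: Sequence[int],
    n_sampled_m: Sequence[int],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    alpha: float = DEFAULT_ALPHA,
) -> EnrichmentRecord:
    """Score one cluster for sex-differential abundance.

    ``counts_*`` are per-individual cluster read counts; ``n_sampled_*``
    the per-individual sampled totals (equal across individuals in the
    standard design). Genome percentages, the Welch test, and the raw-count
    enrichment ratio are derived here. When one sex has zero reads in the
    cluster, 0.5 pseudo-reads are added to that sex's *pooled* count before
    its mean enters the ratio, and the record is flagged; the test itself
    uses the unadjusted values.
    """
    cf = np.asarray(counts_f, dtype=float)
    cm = np.asarray(counts_m, dtype=float)
    nf = np.asarray(n_sampled_f, dtype=float)
    nm = np.asarray(n_sampled_m, dtype=float)
    if (cf < 0).any() or (cm < 0).any():
        raise ValueError("cluster counts must be non-negative")
    if cf.size < 2 or cm.size < 2:
        raise ValueError("need at least 2 individuals per sex")

    pct_f = cf / nf * 100.0
    pct_m = cm / nm * 100.0
    mean_f = float(pct_f.mean())
    mean_m = float(pct_m.mean())

    pool_fraction = float((cf.sum() + cm.sum()) / (nf.sum() + nm.sum()))
    passes_abundance = pool_fraction >= min_fraction

    t, df, p = welch_t_test(pct_f, pct_m)
    passes_significance = p < alpha

    zero_adjusted = False
    ratio_mean_m = mean_m
    ratio_mean_f = mean_f
    if mean_m == 0.0:
        ratio_mean_m = ZERO_RULE_PSEUDOCOUNT / nm.sum() * 100.0
        zero_adjusted = True
    if mean_f == 0.0:
        ratio_mean_f = ZERO_RULE_PSEUDOCOUNT / nf.sum() * 100.0
        zero_adjusted = True
    ratio = ratio_mean_f / ratio_mean_m

    if passes_significance and mean_f > mean_m:
        direction = "female"
    elif passes_significance and mean_m > mean_f:
        direction = "male"
    else:
        direction = "none"

    return EnrichmentRecord(
        cluster_id=cluster_id,
        mean_f=mean_f,
        mean_m=mean_m,
        ratio=float(ratio),
        direction=direction,
        t_stat=t,
        df=df,
        p_value=p,
        passes_abundance=passes_abundance,
        passes_significance=passes_significance,
        zero_adjusted=zero_adjusted,
        total_f=int(cf.sum()),
        total_m=int(cm.sum()),
        n_sampled_f=int(nf.sum()),
        n_sampled_m=int(nm.sum()),
    )


def score_cluster_table(cluster_table, min_fraction: float = DEFAULT_MIN_FRACTION,
                        alpha: float = DEFAULT_ALPHA) -> list[EnrichmentRecord]:
    """Score every retained cluster of a :class:`~wrepscan.repclust.ClusterTable`."""
    records = []
    nf = cluster_table.n_sampled("F")
    nm = cluster_table.n_sampled("M")
    for cid in cluster_table.table["cluster_id"]:
        records.append(
            score_cluster(
                int(cid),
                cluster_table.counts(int(cid), "F"),
                cluster_table.counts(int(cid), "M"),
                nf,
                nm,
                min_fraction=min_fraction,
                alpha=alpha,
            )
        )
    return records


def benjamini_hochberg(records: list[EnrichmentRecord], alpha: float = DEFAULT_ALPHA
                       ) -> list[EnrichmentRecord]:
    """Optional FDR variant: re-flag significance by Benjamini-Hochberg.

    Off the default path — the reference procedure uses raw P < alpha.
    Direction labels are refreshed to match the adjusted significance.
    """
    if not records:
        return []
    ps = np.array([r.p_value for r in records])
    order = np.argsort(ps)
    m = len(ps)
    passed = np.zeros(m, dtype=bool)
    max_k = 0
    for rank, idx in enumerate(order, start=1):
        if ps[idx] <= alpha * rank / m:
            max_k = rank
    passed[order[:max_k]] = True
    out = []
    for r, ok in zip(records, passed):
        direction = "none"
        if ok and r.mean_f > r.mean_m:
            direction = "female"
        elif ok and r.mean_m > r.mean_f:
            direction = "male"
        out.append(replace(r, passes_significance=bool(ok), direction=direction))
    return out


def select_w_enriched(
    records: list[EnrichmentRecord],
    r_max_floor: float = 1.0,
) -> tuple[list[EnrichmentRecord], WSummary]:
    """Apply the empirical false-positive cutoff and summarize W candidates.

    The cutoff r_max is the maximum male-over-female enrichment among
    abundant, significant, male-direction clusters — the observed ceiling
    of spurious enrichment — or ``r_max_floor`` when no such cluster
    exists. Selected clusters are the abundant, significant,
    female-direction records whose female-to-male ratio exceeds r_max.
    """
    candidates = [r for r in records if r.passes_abundance and r.passes_significance]
    male_ratios = [r.male_over_female() for r in candidates if r.direction == "male"]
    r_max = max(male_ratios) if male_ratios else r_max_floor

    selected = [
        replace(r, passes_empirical=True)
        for r in candidates
        if r.direction == "female" and r.ratio > r_max
    ]
    selected.sort(key=lambda r: r.cluster_id)

    if selected:
        ratios = [r.ratio for r in selected]
        summary = WSummary(
            n_selected=len(selected),
            geometric_mean_enrichment=float(stats.gmean(ratios)),
            max_enrichment=float(max(ratios)),
            r_max_cutoff=float(r_max),
        )
    else:
        summary = WSummary(0, float("nan"), float("nan"), float(r_max))
    return selected, summary
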