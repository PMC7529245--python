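"""TE spatial association statistics.

Windowed TE-bp association curves with resampled ANOVA nulls, nearest-TE
distance comparisons, superfamily size proportions, and randomized Fisher
compartment enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    ChromosomePartition,
    GeneRecord,
    TERecord,
    classify_compartment,
    nearest_te_distance,
    te_bp_in_window,
)

__all__ = [
    "association_curve",
    "resampled_anova",
    "nearest_distance_ttest",
    "superfamily_size_proportions",
    "randomized_fisher_enrichment",
    "te_bp_profile",
]


class TeAssocError(ValueError):
    pass


def te_bp_profile(
    genes: Sequence[GeneRecord],
    tes_by_chrom: Mapping[str, Sequence[TERecord]],
    distances: Sequence[int],
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> np.ndarray:
    """TE bp per gene (rows) per flank distance (columns)."""
    out = np.zeros((len(genes), len(distances)))
    for i, g in enumerate(genes):
        chrom_tes = tes_by_chrom.get(g.interval.chrom, ())
        L = chrom_lengths.get(g.interval.chrom) if chrom_lengths else None
        for j, d in enumerate(distances):
            out[i, j] = te_bp_in_window(g, chrom_tes, d, chrom_length=L)
    return out


def resampled_anova(
    focal_values: Sequence[float],
    background_values: Sequence[float],
    n_resample: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Average one-way-ANOVA p over resampled background subsets.

    Each iteration draws |focal| background values without replacement and
    runs a one-way ANOVA of focal vs the drawn subset (identical to the
    pooled-variance two-sample t-test for two groups); the mean of the
    ``n_resample`` p-values is returned.  Deterministic under a fixed seed.
    """
    focal = np.asarray(focal_values, dtype=float)
    background = np.asarray(background_values, dtype=float)
    if focal.size < 2:
        raise TeAssocError("need at least 2 focal values")
    if background.size < focal.size:
        raise TeAssocError("background must be at least as large as focal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ps = np.empty(n_resample)
    for i in range(n_resample):
        draw = rng.choice(background, size=focal.size, replace=False)
        res = stats.f_oneway(focal, draw)
        ps[i] = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return float(ps.mean())


def association_curve(
    focal_genes: Sequence[GeneRecord],
    background_genes: Sequence[GeneRecord],
    tes: Sequence[TERecord],
    chrom_lengths: Optional[Mapping[str, int]] = None,
    max_d: int = 1000,
    step: int = 100,
    n_resample: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean TE bp around focal vs background genes per flank distance.

    One row per distance d in {0, step, ..., max_d}: group means, 95%
    t-based confidence half-widths, and the average resampled-ANOVA p.
    """
    if not focal_genes or not background_genes:
        raise TeAssocError("focal and background gene sets must be non-empty")
    focal_ids = {g.id for g in focal_genes}
    if focal_ids & {g.id for g in background_genes}:
        raise TeAssocError("focal and background sets must be disjoint")
    if step <= 0 or max_d % step != 0:
        raise TeAssocError("step must divide max_d")
    distances = list(range(0, max_d + 1, step))

    by_chrom: Dict[str, List[TERecord]] = {}
    for t in tes:
        by_chrom.setdefault(t.interval.chrom, []).append(t)

    focal_bp = te_bp_profile(focal_genes, by_chrom, distances, chrom_lengths)
    back_bp = te_bp_profile(background_genes, by_chrom, distances, chrom_lengths)

    rng = np.random.default_rng(seed)
    rows = []
    for j, d in enumerate(distances):
        f = focal_bp[:, j]
        b = back_bp[:, j]
        rows.append(
            {
                "distance": d,
                "mean_focal": f.mean(),
                "mean_background": b.mean(),
                "ci_focal": _ci_halfwidth(f),
                "ci_background": _ci_halfwidth(b),
                "avg_resampled_p": resampled_anova(f, b, n_resample=n_resample, seed=rng),
            }
        )
    return pd.DataFrame(rows)


def _ci_halfwidth(values: np.ndarray, level: float = 0.95) -> float:
    n = values.size
    if n < 2:
        return float("nan")
    sem = values.std(ddof=1) / np.sqrt(n)
    return float(stats.t.ppf(0.5 + level / 2, df=n - 1) * sem)


def nearest_distance_ttest(
    group_a_genes: Sequence[GeneRecord],
    group_b_genes: Sequence[GeneRecord],
    tes: Sequence[TERecord],
):
    """Welch t-test of mean nearest-TE distance between two gene groups.

    Genes with no TE on their chromosome are excluded rather than assigned
    an infinite distance.
    """
    by_chrom: Dict[str, List[TERecord]] = {}
    for t in tes:
        by_chrom.setdefault(t.interval.chrom, []).append(t)

    def dists(genes):
        vals = []
        for g in genes:
            d = nearest_te_distance(g, by_chrom.get(g.interval.chrom, ()))
            if d is not None:
                vals.append(d)
        return np.asarray(vals, dtype=float)

    a = dists(group_a_genes)
    b = dists(group_b_genes)
    if a.size == 0 or b.size == 0:
        raise TeAssocError("a group has no genes with a defined nearest-TE distance")
    if np.array_equal(a, b):
        return float(a.mean()), float(b.mean()), 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return float(a.mean()), float(b.mean()), p


def superfamily_size_proportions(te_set: Sequence[TERecord]) -> Dict[str, float]:
    """Summed TE length per superfamily divided by the total summed length."""
    if not te_set:
        raise TeAssocError("te_set must be non-empty")
    sums: Dict[str, float] = {}
    for t in te_set:
        sums[t.superfamily] = sums.get(t.superfamily, 0.0) + t.interval.length
    total = sum(sums.values())
    return {fam: bp / total for fam, bp in sorted(sums.items())}


@dataclass
class EnrichmentRow:
    compartment: str
    superfamily: str
    n_focal: int
    n_pool: int
    focal_in_family: int
    pool_in_family: int
    focal_size_proportion: Optional[float]
    pool_size_proportion: Optional[float]
    p_observed: Optional[float]
    mean_randomized_p: Optional[float]
    rank_observed: Optional[float]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def randomized_fisher_enrichment(
    focal_tes: Sequence[TERecord],
    all_tes: Sequence[TERecord],
    partition: ChromosomePartition,
    superfamily: str,
    compartment: str,
    n_random: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentRow:
    """Fisher enrichment of one superfamily among focal TEs in a compartment.

    The observed 2x2 table is [focal in family, focal not; non-focal in
    family, non-focal not] over TEs whose midpoint falls in ``compartment``.
    ``n_random`` pseudo-focal sets of the same size are drawn uniformly
    without replacement from the compartment pool; the function reports the
    observed two-sided Fisher p, the mean randomized p, and the empirical
    rank of the observed p among the randomized ones (fraction of randomized
    p <= observed).  Seeded and deterministic.
    """
    focal_ids = {t.id for t in focal_tes}
    all_ids = {t.id for t in all_tes}
    if not focal_ids <= all_ids:
        raise TeAssocError("focal TEs must be a subset of all TEs")
    if compartment not in ("arm", "pericentromere"):
        raise TeAssocError(f"unknown compartment {compartment!r}")

    pool = [t for t in all_tes if classify_compartment(t.interval, partition) == compartment]
    pool_focal = [t for t in pool if t.id in focal_ids]
    n_focal = len(pool_focal)
    if n_focal == 0:
        return EnrichmentRow(
            compartment, superfamily, 0, len(pool), 0, 0,
            None, None, None, None, None,
        )

    in_family = np.array([t.superfamily == superfamily for t in pool])
    is_focal = np.array([t.id in focal_ids for t in pool])

    def fisher_p(focal_mask: np.ndarray) -> float:
        a = int((focal_mask & in_family).sum())
        b = int((focal_mask & ~in_family).sum())
        c = int((~focal_mask & in_family).sum())
        d = int((~focal_mask & ~in_family).sum())
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])

    p_obs = fisher_p(is_focal)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pool = len(pool)
    rand_ps = np.empty(n_random)
    for i in range(n_random):
        idx = rng.choice(n_pool, size=n_focal, replace=False)
        mask = np.zeros(n_pool, dtype=bool)
        mask[idx] = True
        rand_ps[i] = fisher_p(mask)
    rank = float((rand_ps <= p_obs).mean())

    def size_prop(tes_sub):
        total = sum(t.interval.length for t in tes_sub)
        if total == 0:
            return None
        fam = sum(t.interval.length for t in tes_sub if t.superfamily == superfamily)
        return fam / total

    return EnrichmentRow(
        compartment=compartment,
        superfamily=superfamily,
        n_focal=n_focal,
        n_pool=n_pool,
        focal_in_family=int((is_focal & in_family).sum()),
        pool_in_family=int(in_family.sum()),
        focal_size_proportion=size_prop(pool_focal),
        pool_size_proportion=size_prop(pool),
        p_observed=p_obs,
        mean_randomized_p=float(rand_ps.mean()),
        rank_observed=rank,
    )
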