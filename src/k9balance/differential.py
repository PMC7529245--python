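"""Per-feature differential abundance between two genotypes.

Filtering, median-of-ratios normalization, a deliberately simple
negative-binomial Wald test (method-of-moments dispersion, no shrinkage),
Benjamini-Hochberg correction, threshold calling, replicate QC, and the
paired K9/H3 log-ratio summary.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_expressed",
    "estimate_size_factors",
    "nb_wald_test",
    "bh_adjust",
    "call_differential",
    "replicate_spearman",
    "k9_relative_summary",
    "group_columns",
]

PSEUDOCOUNT = 0.5
MIN_DISPERSION = 1e-8


class DifferentialError(ValueError):
    pass


def group_columns(samples: pd.DataFrame, genotype: str) -> list:
    """Sample ids of one genotype, in sample-sheet order."""
    return list(samples.index[samples["genotype"] == genotype])


def filter_expressed(counts: pd.DataFrame, min_value: float = 1) -> pd.DataFrame:
    """Drop features whose value is below ``min_value`` in ALL libraries.

    A feature is retained as soon as any single library reaches the
    threshold; row order is preserved.
    """
    keep = (counts >= min_value).any(axis=1)
    return counts.loc[keep]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over all-positive rows of count_ij / geometric mean_i,
    rescaled to geometric mean 1 so that re-estimating factors on a
    factor-normalized matrix returns all ones (fixed-point property).
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise DifferentialError(
            "no feature has positive counts in every sample; prefilter the matrix"
        )
    sub = arr[positive]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geo[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_stats(norm: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    return norm.mean(axis=1), norm.var(axis=1, ddof=1)


def nb_wald_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    size_factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Two-group NB Wald test on a feature x sample count matrix.

    Counts are divided by size factors; per-feature dispersion comes from a
    method-of-moments fit on normalized counts pooled across both groups
    (floored at 1e-8).  log2fc uses group means with pseudocount 0.5; the
    Wald statistic is log2fc / SE under the NB variance model with a
    two-sided p-value from a t reference with n1+n2 degrees of freedom.
    A normal reference is anti-conservative at typical replicate numbers
    because the moment dispersion estimate is noisy, while a pooled-variance
    t (n1+n2-2 df) over-corrects since the model-based SE is partially
    stabilized by the well-estimated means; n1+n2 df calibrates the type-I
    error on simulated null NB counts.  Deliberately simpler than
    shrinkage-based tools: no dispersion shrinkage, no outlier handling.
    """
    wt_cols = group_columns(samples, "WT")
    mut_cols = group_columns(samples, "mutant")
    if not wt_cols or not mut_cols:
        raise DifferentialError("both genotypes WT and mutant must be present")
    if len(wt_cols) < 2 or len(mut_cols) < 2:
        raise DifferentialError("need >= 2 samples per genotype")
    if size_factors is None:
        size_factors = estimate_size_factors(counts[wt_cols + mut_cols])
    norm = counts[wt_cols + mut_cols].to_numpy(dtype=float) / size_factors[
        wt_cols + mut_cols
    ].to_numpy()
    n_wt = len(wt_cols)
    wt = norm[:, :n_wt]
    mut = norm[:, n_wt:]

    mu_wt, var_wt = _group_stats(wt)
    mu_mut, var_mut = _group_stats(mut)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion pooled across groups:
    # within-group residual variance vs the pooled mean level
    df_wt, df_mut = wt.shape[1] - 1, mut.shape[1] - 1
    pooled_var = (df_wt * var_wt + df_mut * var_mut) / (df_wt + df_mut)
    pooled_mean = 0.5 * (mu_wt + mu_mut)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (pooled_var - pooled_mean) / np.square(pooled_mean)
    disp = np.where(np.isfinite(disp), disp, MIN_DISPERSION)
    disp = np.maximum(disp, MIN_DISPERSION)

    m_wt = mu_wt + PSEUDOCOUNT
    m_mut = mu_mut + PSEUDOCOUNT
    log2fc = np.log2(m_mut / m_wt)

    # Var(mean_g) = (mu + disp*mu^2)/n ; delta method onto log2 scale
    var_mean_wt = (m_wt + disp * m_wt**2) / wt.shape[1]
    var_mean_mut = (m_mut + disp * m_mut**2) / mut.shape[1]
    se = np.sqrt(var_mean_wt / m_wt**2 + var_mean_mut / m_mut**2) / math.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    dof = wt.shape[1] + mut.shape[1]
    p = 2.0 * stats.t.sf(np.abs(z), df=dof)
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {"baseMean": base_mean, "log2fc": log2fc, "p": p},
        index=counts.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DifferentialError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_differential(
    results: pd.DataFrame, padj_max: float = 0.05, fc_min: float = 1.2
) -> pd.DataFrame:
    """Attach padj and the up/down/ns call at the stated thresholds."""
    if fc_min <= 1:
        raise DifferentialError("fc_min must exceed 1")
    out = results.copy()
    out["padj"] = bh_adjust(out["p"].to_numpy())
    lfc_min = math.log2(fc_min)
    call = np.full(len(out), "ns", dtype=object)
    sig = out["padj"].to_numpy() <= padj_max
    lfc = out["log2fc"].to_numpy()
    call[sig & (lfc >= lfc_min)] = "up"
    call[sig & (lfc <= -lfc_min)] = "down"
    out["call"] = call
    return out


def replicate_spearman(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Spearman R for every within-condition replicate pair.

    Conditions are (genotype, assay) groups; ties get average ranks.  A
    constant vector yields NaN for that pair.
    """
    rows = []
    for (genotype, assay), grp in samples.groupby(["genotype", "assay"], sort=True):
        cols = list(grp.index)
        for a, b in itertools.combinations(cols, 2):
            x = counts[a].to_numpy(dtype=float)
            y = counts[b].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho = float("nan")
            else:
                rho = float(stats.spearmanr(x, y).statistic)
            rows.append(
                {
                    "genotype": genotype,
                    "assay": assay,
                    "sample_a": a,
                    "sample_b": b,
                    "spearman_r": rho,
                }
            )
    if not rows:
        raise DifferentialError("no condition has >= 2 replicates")
    return pd.DataFrame(rows)


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise DifferentialError("zero-total library cannot be depth-normalized")
    return counts * 1e6 / totals


def k9_relative_summary(
    k9_counts: pd.DataFrame,
    k9_samples: pd.DataFrame,
    h3_counts: pd.DataFrame,
    h3_samples: pd.DataFrame,
) -> Tuple[pd.DataFrame, float]:
    """Per-feature K9-relative-to-H3 log ratios per genotype + paired test.

    Each library is depth-normalized (per million); replicate values are
    summed per genotype before the ratio log2((K9+0.5)/(H3+0.5)).  The
    returned p-value is a two-sided Wilcoxon signed-rank test comparing the
    genotypes across features (zero differences dropped).
    """
    if not k9_counts.index.equals(h3_counts.index):
        raise DifferentialError("K9 and H3 matrices must share the feature set")
    k9n = _cpm(k9_counts)
    h3n = _cpm(h3_counts)
    ratios = {}
    for genotype in ("WT", "mutant"):
        k9_cols = group_columns(k9_samples, genotype)
        h3_cols = group_columns(h3_samples, genotype)
        if not k9_cols or not h3_cols:
            raise DifferentialError(f"genotype {genotype} missing from a matrix")
        k9_sum = k9n[k9_cols].sum(axis=1)
        h3_sum = h3n[h3_cols].sum(axis=1)
        ratios[genotype] = np.log2((k9_sum + PSEUDOCOUNT) / (h3_sum + PSEUDOCOUNT))
    table = pd.DataFrame(
        {"log2_k9_h3_WT": ratios["WT"], "log2_k9_h3_mutant": ratios["mutant"]}
    )
    diff = table["log2_k9_h3_mutant"] - table["log2_k9_h3_WT"]
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        return table, 1.0
    res = stats.wilcoxon(nonzero.to_numpy(), alternative="two-sided")
    return table, float(res.pvalue)
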