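"""Imaging-feature / pathway association analysis and cohort summaries.

Qualitative associations: for each radiomic feature, patients are split into
high and low groups at the median (ties to low), genes are ranked by the
two-group statistic, and GSEA flags pathways enriched in either group.
Quantitative associations: Pearson correlation between each feature and each
pathway's per-sample GSVA score, with two-sided t-distribution p-values
(df = n - 2, no multiplicity correction).

Summaries count significant pairs, unique pathways/features and per-category
breakdowns; two cohorts' category profiles are compared with a two-sided
Pearson chi-squared test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from radigen._utils import derive_seed, round_half_up
from radigen.enrichment import (
    gsea_phenotype_significance,
    gsea_significance,
    gsva_scores,
    rank_genes,
    size_factors,
)
from radigen.features import FeatureCatalog


def median_split(values) -> np.ndarray:
    """Binary high/low labels at the median cutoff (ties go to low).

    Returns a boolean array, True = high (value strictly above the median).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 6:
        raise ValueError("median_split needs a 1-D vector of >= 6 values")
    med = np.median(v)
    high = v > med
    if high.all() or not high.any():
        raise ValueError("degenerate split: all values on one side of the median")
    return high


@dataclass
class AssociationTable:
    """Per (feature, pathway) association results.

    ``qualitative`` columns: es, nes, pval, qval, direction, significant.
    ``quantitative`` columns: r, pval, significant, reason.
    Either side may be absent (None) if only one analysis was run.
    """

    qualitative: pd.DataFrame | None = None
    quantitative: pd.DataFrame | None = None
    threshold: float = 0.05
    regime: str = "pval"  # 'pval' (raw p) or 'qval' (BH-corrected)

    def significant_pairs(self, side: str = "qualitative") -> pd.DataFrame:
        table = getattr(self, side)
        if table is None:
            raise ValueError(f"{side} side was not computed")
        return table[table["significant"]]


def qualitative_associations(
    features: pd.DataFrame,
    counts: pd.DataFrame,
    sets: dict[str, list[str]],
    n_perm: int = 200,
    seed: int = 0,
    threshold: float = 0.05,
    regime: str = "pval",
    null: str = "phenotype",
) -> AssociationTable:
    """Median-split GSEA of every feature against every pathway.

    ``features`` is patients x features; ``counts`` genes x samples with
    matching sample IDs.  Features with a degenerate median split are skipped
    with a warning (their rows are absent from the table).

    ``null`` selects the permutation scheme: ``"phenotype"`` (default)
    reshuffles sample labels and stays calibrated when member genes are
    co-expressed; ``"gene"`` permutes gene labels (cheaper, but assumes gene
    exchangeability).
    """
    if regime not in ("pval", "qval"):
        raise ValueError("regime must be 'pval' or 'qval'")
    if null not in ("phenotype", "gene"):
        raise ValueError("null must be 'phenotype' or 'gene'")
    missing = [s for s in features.index if s not in set(counts.columns)]
    if missing:
        raise ValueError(f"sample IDs in features but not in counts: {missing[:5]}")
    # canonical sample order: results do not depend on input row order
    order = sorted(features.index)
    features = features.loc[order]
    counts = counts[order]
    factors = size_factors(counts)
    blocks = []
    for fi, feature in enumerate(features.columns):
        try:
            high = median_split(features[feature].to_numpy())
        except ValueError:
            warnings.warn(f"feature '{feature}' skipped: degenerate median split")
            continue
        feature_seed = derive_seed(seed, f"gsea:{feature}")
        if null == "phenotype":
            res = gsea_phenotype_significance(
                counts, high, sets, n_perm=n_perm, seed=feature_seed, factors=factors
            )
        else:
            ranked = rank_genes(counts, high, factors)
            res = gsea_significance(ranked, sets, n_perm=n_perm, seed=feature_seed)
        block = res.table.copy()
        block["feature"] = feature
        blocks.append(block.reset_index())
    table = pd.concat(blocks, ignore_index=True)
    table["significant"] = table[regime] < threshold
    table = table.set_index(["feature", "pathway"])
    return AssociationTable(qualitative=table, threshold=threshold, regime=regime)


def quantitative_associations(
    features: pd.DataFrame,
    es: pd.DataFrame,
    threshold: float = 0.05,
) -> AssociationTable:
    """Pearson correlation of each feature with each pathway's GSVA score.

    ``features`` is patients x features; ``es`` pathways x samples.  Pairs
    with a zero-variance member get r = NaN, significant = False and a
    reason code.
    """
    common = [s for s in features.index if s in set(es.columns)]
    if len(common) != len(features.index) or len(common) != es.shape[1]:
        raise ValueError("features and enrichment scores must cover the same samples")
    n = len(common)
    F = np.asarray(features.loc[common], dtype=float)  # n x f
    E = np.asarray(es[common], dtype=float).T  # n x p
    Fc = F - F.mean(axis=0)
    Ec = E - E.mean(axis=0)
    fs = np.sqrt((Fc**2).sum(axis=0))
    es_sd = np.sqrt((Ec**2).sum(axis=0))
    denom = np.outer(fs, es_sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Fc.T @ Ec) / denom
    r[denom == 0] = np.nan
    r_clip = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
    pval = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pval = np.where(np.isclose(np.abs(r_clip), 1.0), 0.0, pval)
    idx = pd.MultiIndex.from_product(
        [features.columns, es.index], names=["feature", "pathway"]
    )
    table = pd.DataFrame(
        {
            "r": r.ravel(),
            "pval": pval.ravel(),
        },
        index=idx,
    )
    table["significant"] = (table["pval"] < threshold) & table["r"].notna()
    table["reason"] = np.where(table["r"].isna(), "zero_variance", "")
    return AssociationTable(quantitative=table, threshold=threshold)


@dataclass
class CategorySummary:
    """Counts/percentages of significant feature–pathway associations."""

    n_features: int
    n_pathways: int
    total_pairs: int
    significant_pairs: int
    pct_pairs: float
    unique_pathways: int
    pct_pathways: float
    unique_features: int
    pct_features: float
    mean_features_per_pathway: float
    mean_pathways_per_feature: float
    by_category: dict[str, pd.DataFrame]

    def as_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "n_features",
                "n_pathways",
                "total_pairs",
                "significant_pairs",
                "pct_pairs",
                "unique_pathways",
                "pct_pathways",
                "unique_features",
                "pct_features",
                "mean_features_per_pathway",
                "mean_pathways_per_feature",
            )
        }
        out["by_category"] = {k: v.to_dict("index") for k, v in self.by_category.items()}
        return out


def summarize(
    flags: pd.DataFrame,
    catalog: FeatureCatalog | None = None,
) -> CategorySummary:
    """Cohort-level and per-category association summary.

    ``flags`` is a features x pathways boolean matrix of significant pairs.
    Percentages are rounded half-up to one decimal; means of an empty
    denominator are reported as 0.0.
    """
    flags = flags.astype(bool)
    n_features, n_pathways = flags.shape
    total = n_features * n_pathways
    sig = int(flags.to_numpy().sum())
    pathways_hit = flags.any(axis=0)
    features_hit = flags.any(axis=1)
    uniq_p, uniq_f = int(pathways_hit.sum()), int(features_hit.sum())

    by_category: dict[str, pd.DataFrame] = {}
    if catalog is not None:
        cats = catalog.categories()
        cats = cats.loc[[f for f in flags.index if f in cats.index]]
        for level in ("category_I", "category_II", "category_III"):
            rows = []
            for cat, members in cats.groupby(level, sort=False):
                sub = flags.loc[members.index]
                n_sub = len(members)
                rows.append(
                    {
                        "category": cat,
                        "n_features": n_sub,
                        "significant_pairs": int(sub.to_numpy().sum()),
                        "unique_pathways": int(sub.any(axis=0).sum()),
                        "unique_features": int(sub.any(axis=1).sum()),
                        "pct_features": round_half_up(
                            100.0 * sub.any(axis=1).sum() / n_sub
                        ),
                    }
                )
            by_category[level] = pd.DataFrame(rows).set_index("category")

    return CategorySummary(
        n_features=n_features,
        n_pathways=n_pathways,
        total_pairs=total,
        significant_pairs=sig,
        pct_pairs=round_half_up(100.0 * sig / total) if total else 0.0,
        unique_pathways=uniq_p,
        pct_pathways=round_half_up(100.0 * uniq_p / n_pathways) if n_pathways else 0.0,
        unique_features=uniq_f,
        pct_features=round_half_up(100.0 * uniq_f / n_features) if n_features else 0.0,
        mean_features_per_pathway=round_half_up(sig / uniq_p) if uniq_p else 0.0,
        mean_pathways_per_feature=round_half_up(sig / uniq_f) if uniq_f else 0.0,
        by_category=by_category,
    )


def compare_cohorts(counts_a, counts_b) -> tuple[float, float]:
    """Two-sided Pearson chi-squared homogeneity test on two count vectors.

    ``counts_a`` / ``counts_b`` are per-category counts (e.g. unique
    associated pathways per feature category) from two cohorts.  Warns when
    an expected cell is below 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and equal length")
    contingency = np.vstack([a, b])
    if np.array_equal(a, b):
        return 0.0, 1.0
    res = stats.chi2_contingency(contingency, correction=False)
    expected = res.expected_freq
    if np.any(expected < 1):
        warnings.warn("expected cell count < 1; consider an exact test")
    return float(res.statistic), float(res.pvalue)
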