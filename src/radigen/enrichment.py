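"""Transcriptomic enrichment scoring: normalization, GSEA, and GSVA.

Implements the expression side of the radiogenomic analysis from scratch:

* median-of-ratios size factors for count normalization;
* a two-group gene-ranking statistic (Welch t on log2 normalized counts —
  a deliberately simple, monotone substitute for a full negative-binomial
  GLM, which GSEA's rank-based statistic does not require);
* GSEA: the weighted Kolmogorov–Smirnov running-sum enrichment score with a
  gene-permutation null, nominal p, NES and Benjamini–Hochberg q-values;
* GSVA: per-sample enrichment scores via kernel-estimated expression CDFs,
  symmetric rank statistics and a weighted KS random walk (max-diff scoring).

Conventions: 0*log0 := 0; entropies use base-2 logs; every stochastic
operation takes an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special


# ---------------------------------------------------------------------------
# normalization and ranking
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    For genes with an all-positive geometric mean across samples, the factor
    of sample j is the median over those genes of count_gj / geomean_g.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("counts must be a genes x samples matrix with >= 2 samples")
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    all_positive = (X > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene is expressed in all samples; median-of-ratios undefined "
            "(consider a pseudo-reference fallback)"
        )
    ref = X[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(count / size_factor + 1) expression matrix."""
    if factors is None:
        factors = size_factors(counts)
    return np.log2(counts.div(factors, axis=1) + 1.0)


def rank_genes(
    counts: pd.DataFrame,
    group_labels,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene Welch t statistic on log2 normalized counts (high vs low).

    Positive values mean higher expression in the ``True``/1 group.  The
    returned Series is ordered descending (ties broken by gene ID), so the
    head of the Series is the most up-regulated gene in the high group.
    """
    labels = np.asarray(group_labels).astype(bool)
    if labels.size != counts.shape[1]:
        raise ValueError("group_labels length must equal the number of samples")
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 < 3 or n0 < 3:
        raise ValueError(f"both groups need >= 3 samples, got {n1}/{n0}")
    log_expr = normalize_log(counts, factors)
    X = np.asarray(log_expr, dtype=float)
    x1, x0 = X[:, labels], X[:, ~labels]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1, v0 = x1.var(axis=1, ddof=1), x0.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / n1 + v0 / n0)
    diff = m1 - m0
    if np.all(denom == 0):
        raise ValueError("degenerate input: zero variance in every gene")
    t = np.zeros_like(diff)
    ok = denom > 0
    t[ok] = diff[ok] / denom[ok]
    # zero-variance genes with a mean shift: place beyond the finite range
    stuck = (~ok) & (diff != 0)
    if stuck.any():
        cap = np.abs(t[ok]).max() if ok.any() else 1.0
        t[stuck] = np.sign(diff[stuck]) * (cap + 1.0)
    out = pd.Series(t, index=counts.index, name="stat")
    order = sorted(out.index, key=lambda g: (-out[g], g))
    return out.loc[order]


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def _es_from_positions(
    positions: np.ndarray,
    weights: np.ndarray,
    n_genes: int,
) -> np.ndarray:
    """Signed extremal running-sum deviation for each row of hit positions.

    ``positions`` (n_walks x m) holds 0-based, ascending in-ranking positions
    of the member genes; ``weights`` the matching non-negative hit weights.
    Misses decrement by 1/(N - m).  Returns the running-sum value of maximal
    absolute deviation (positive on ties).
    """
    n_walks, m = positions.shape
    if m >= n_genes:
        raise ValueError("set must be smaller than the gene universe")
    W = weights.sum(axis=1, keepdims=True)
    flat = (W == 0).ravel()
    if flat.any():  # all member stats zero: fall back to unweighted hits
        weights = weights.copy()
        weights[flat] = 1.0
        W = weights.sum(axis=1, keepdims=True)
    H = np.cumsum(weights, axis=1) / W
    d = 1.0 / (n_genes - m)
    misses = (positions - np.arange(m)) * d
    after = H - misses  # value just after each hit
    before = np.concatenate([np.zeros((n_walks, 1)), H[:, :-1]], axis=1) - misses
    es_max = after.max(axis=1)
    es_min = np.minimum(before.min(axis=1), 0.0)
    return np.where(es_max >= -es_min, es_max, es_min)


def gsea_es(ranked_stats, member_flags, p: float = 1.0) -> float:
    """Weighted KS enrichment score of one gene set on a ranked list.

    ``ranked_stats`` is the ranking statistic in descending order;
    ``member_flags`` marks set members in the same order.  Hits increment by
    |stat|^p normalized over members, misses decrement by 1/(N - m); the ES
    is the running-sum value of maximal absolute deviation (signed).
    """
    s = np.asarray(ranked_stats, dtype=float)
    flags = np.asarray(member_flags).astype(bool)
    if s.shape != flags.shape or s.ndim != 1:
        raise ValueError("ranked_stats and member_flags must be equal-length 1-D")
    m = int(flags.sum())
    if m < 1 or m >= s.size:
        raise ValueError("need >= 1 member and >= 1 non-member")
    positions = np.flatnonzero(flags)[None, :]
    weights = np.abs(s[positions]) ** p
    if weights.sum() == 0 and p > 0:
        warnings.warn("all member stats zero; falling back to unweighted (p=0) ES")
    return float(_es_from_positions(positions, weights, s.size)[0])


@dataclass
class GseaResult:
    """GSEA outcome table: one row per pathway."""

    table: pd.DataFrame  # columns: es, nes, pval, qval, direction, size

    def __getitem__(self, pathway: str) -> pd.Series:
        return self.table.loc[pathway]


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def gsea_significance(
    ranked_stats: pd.Series,
    sets: dict[str, list[str]],
    n_perm: int = 200,
    seed: int = 0,
    weight_p: float = 1.0,
) -> GseaResult:
    """GSEA over a collection of gene sets with a gene-permutation null.

    For each set the null ES distribution comes from ``n_perm`` random draws
    of equally sized gene subsets.  Nominal p = fraction of same-sign null ES
    with |ES| >= |observed|; NES = ES / mean same-sign null |ES|; q-values by
    Benjamini–Hochberg across the supplied pathways.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    s = np.asarray(ranked_stats, dtype=float)
    gene_pos = {g: i for i, g in enumerate(ranked_stats.index)}
    N = s.size
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in sets.items():
        idx = sorted(gene_pos[g] for g in members if g in gene_pos)
        m = len(idx)
        if m < 1:
            raise ValueError(f"gene set '{name}' has no genes in the ranked universe")
        if m >= N:
            raise ValueError(f"gene set '{name}' covers the whole gene universe")
        positions = np.array(idx)[None, :]
        es = float(_es_from_positions(positions, np.abs(s[positions]) ** weight_p, N)[0])
        # null: random same-size subsets == permuted gene labels
        null_pos = np.sort(
            rng.permuted(np.broadcast_to(np.arange(N), (n_perm, N)), axis=1)[:, :m],
            axis=1,
        )
        null_es = _es_from_positions(null_pos, np.abs(s[null_pos]) ** weight_p, N)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        if n_same:
            pval = float((np.abs(null_es[same_sign]) >= abs(es)).mean())
            mean_abs = float(np.abs(null_es[same_sign]).mean())
            nes = es / mean_abs if mean_abs > 0 else 0.0
        else:
            pval, nes = 1.0 / n_perm, 0.0
        rows.append((name, es, nes, pval, "high" if es > 0 else "low", m))
    table = pd.DataFrame(
        rows, columns=["pathway", "es", "nes", "pval", "direction", "size"]
    ).set_index("pathway")
    table["qval"] = benjamini_hochberg(table["pval"].to_numpy())
    return GseaResult(table=table[["es", "nes", "pval", "qval", "direction", "size"]])


def _welch_t_matrix(X: np.ndarray, labels_matrix: np.ndarray) -> np.ndarray:
    """Welch t per gene for many label vectors at once.

    ``X`` is genes x samples (log expression); ``labels_matrix`` samples x k
    boolean, each column one high/low assignment with identical group sizes.
    Returns genes x k statistics.
    """
    L = labels_matrix.astype(float)
    n1 = L[:, 0].sum()
    n0 = L.shape[0] - n1
    X2 = X**2
    M1 = (X @ L) / n1
    M0 = (X @ (1.0 - L)) / n0
    V1 = ((X2 @ L) / n1 - M1**2) * (n1 / (n1 - 1))
    V0 = ((X2 @ (1.0 - L)) / n0 - M0**2) * (n0 / (n0 - 1))
    V1 = np.clip(V1, 0.0, None)
    V0 = np.clip(V0, 0.0, None)
    denom = np.sqrt(V1 / n1 + V0 / n0)
    diff = M1 - M0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def gsea_phenotype_significance(
    counts: pd.DataFrame,
    group_labels,
    sets: dict[str, list[str]],
    n_perm: int = 200,
    seed: int = 0,
    weight_p: float = 1.0,
    factors: pd.Series | None = None,
) -> GseaResult:
    """GSEA with a phenotype-permutation null (labels reshuffled).

    Unlike the gene-permutation null, reshuffling sample labels preserves
    gene–gene correlation, so coherently co-expressed modules stay calibrated
    under the null.  Rankings for every permutation are recomputed with the
    same Welch-t statistic as the observed ranking.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(group_labels).astype(bool)
    n = labels.size
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise ValueError("both groups need >= 3 samples")
    log_expr = normalize_log(counts, factors)
    X = np.asarray(log_expr, dtype=float)
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm), dtype=bool)
    for k in range(n_perm):
        perms[:, k] = labels[rng.permutation(n)]
    all_labels = np.concatenate([labels[:, None], perms], axis=1)
    T = _welch_t_matrix(X, all_labels)  # genes x (1 + n_perm)

    # per-column ranking (descending stat, stable)
    order = np.argsort(-T, axis=0, kind="stable")
    rank_of = np.empty_like(order)
    np.put_along_axis(rank_of, order, np.arange(X.shape[0])[:, None], axis=0)
    # |stat|^p arranged by ranking position (not by gene row)
    sorted_abs = np.take_along_axis(np.abs(T) ** weight_p, order, axis=0)

    gene_row = {g: i for i, g in enumerate(counts.index)}
    N = X.shape[0]
    rows = []
    for name, members in sets.items():
        rows_idx = [gene_row[g] for g in members if g in gene_row]
        m = len(rows_idx)
        if m < 1 or m >= N:
            raise ValueError(f"gene set '{name}' is empty or covers the universe")
        pos = np.sort(rank_of[rows_idx, :], axis=0).T  # (1+n_perm) x m
        w = np.take_along_axis(sorted_abs.T, pos, axis=1)
        es_all = _es_from_positions(pos, w, N)
        es, null_es = float(es_all[0]), es_all[1:]
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        if n_same:
            pval = float((np.abs(null_es[same_sign]) >= abs(es)).mean())
            mean_abs = float(np.abs(null_es[same_sign]).mean())
            nes = es / mean_abs if mean_abs > 0 else 0.0
        else:
            pval, nes = 1.0 / n_perm, 0.0
        rows.append((name, es, nes, pval, "high" if es > 0 else "low", m))
    table = pd.DataFrame(
        rows, columns=["pathway", "es", "nes", "pval", "direction", "size"]
    ).set_index("pathway")
    table["qval"] = benjamini_hochberg(table["pval"].to_numpy())
    return GseaResult(table=table[["es", "nes", "pval", "qval", "direction", "size"]])


# ---------------------------------------------------------------------------
# GSVA
# ---------------------------------------------------------------------------

def _kernel_cdf(X: np.ndarray, kernel: str) -> np.ndarray:
    """Per-gene kernel-estimated CDF of each sample's expression level.

    Poisson kernel (counts): z_gj = mean_k P(Pois(x_gk + 0.5) <= x_gj).
    Gaussian kernel: z_gj = mean_k Phi((x_gj - x_gk) / (sd_g / 4)).
    """
    G, n = X.shape
    Z = np.empty_like(X, dtype=float)
    if kernel == "poisson":
        for g in range(G):
            lam = X[g] + 0.5
            Z[g] = special.pdtr(X[g][:, None], lam[None, :]).mean(axis=1)
    elif kernel == "gaussian":
        sd = X.std(axis=1, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        h = sd / 4.0
        for g in range(G):
            Z[g] = special.ndtr((X[g][:, None] - X[g][None, :]) / h[g]).mean(axis=1)
    else:
        raise ValueError(f"unknown kernel '{kernel}'")
    return Z


def gsva_scores(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    tau: float = 1.0,
    kernel: str = "auto",
) -> pd.DataFrame:
    """Per-sample pathway enrichment scores (pathways x samples, in [-1, 1]).

    Pipeline: kernel CDF per gene across samples -> per-sample gene ranking
    by decreasing level statistic -> symmetric rank weights |N/2 - rank|^tau
    -> weighted KS random walk per sample; the score is the signed sum of the
    maximal positive and maximal negative walk deviations (max-diff
    convention).  Needs >= 4 samples; constant gene rows are dropped.
    """
    if expr.shape[1] < 4:
        raise ValueError("GSVA needs >= 4 samples for kernel density estimation")
    X = np.asarray(expr, dtype=float)
    constant = X.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant gene rows")
        expr = expr.loc[~constant]
        X = X[~constant]
    if kernel == "auto":
        is_counts = np.all(X >= 0) and np.allclose(X, np.round(X))
        kernel = "poisson" if is_counts else "gaussian"
    Z = _kernel_cdf(X, kernel)

    G, n = Z.shape
    genes = list(expr.index)
    gene_row = {g: i for i, g in enumerate(genes)}
    # per sample: rank genes by decreasing z (stable tie-break by row order)
    order = np.argsort(-Z, axis=0, kind="stable")  # order[r, j] = gene at rank r
    rank_of = np.empty_like(order)
    np.put_along_axis(rank_of, order, np.arange(G)[:, None], axis=0)

    scores = np.empty((len(sets), n))
    for si, (name, members) in enumerate(sets.items()):
        rows = [gene_row[g] for g in members if g in gene_row]
        if len(rows) < 2:
            raise ValueError(f"gene set '{name}' has < 2 genes in the expression matrix")
        pos = np.sort(rank_of[rows, :], axis=0).T  # sample x m, ascending positions
        # symmetric rank weight depends only on the walk position: |G/2 - rank|
        w = np.abs(G / 2.0 - (pos + 1.0)) ** tau
        m = pos.shape[1]
        W = w.sum(axis=1, keepdims=True)
        W = np.where(W > 0, W, 1.0)
        H = np.cumsum(w, axis=1) / W
        d = 1.0 / (G - m)
        misses = (pos - np.arange(m)) * d
        after = H - misses
        before = np.concatenate([np.zeros((n, 1)), H[:, :-1]], axis=1) - misses
        max_pos = np.maximum(after.max(axis=1), 0.0)
        max_neg = np.minimum(before.min(axis=1), 0.0)
        scores[si] = max_pos + max_neg
    return pd.DataFrame(scores, index=list(sets.keys()), columns=expr.columns)
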