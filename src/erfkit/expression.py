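"""Expression analysis: FPKM, differential calls, clustering, GO enrichment.

Differential expression uses the published thresholds (|log2FC| > 1 and
BH-adjusted p < 0.05) with a Welch test on log2(FPKM+1) across replicates
as the underlying statistic.  Time-course profiles of the resulting DEGs
are grouped with fuzzy c-means (four clusters by default), GO enrichment
uses a one-sided Fisher exact test with BH FDR <= 0.01, and cross-species
expression similarity is summarized as a Pearson correlation over ortholog
pairs with the time-course side averaged over its five time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Counts plus design metadata for one species.

    ``counts`` is genes x samples (non-negative integers), ``lengths`` the
    transcript lengths in bp, and ``design`` one row per sample with
    condition, time and replicate.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame

    def __post_init__(self):
        missing = self.counts.index.difference(self.lengths.index)
        if len(missing):
            raise ValueError(f"missing gene length for {list(missing)[:3]}...")
        if (self.lengths.reindex(self.counts.index) <= 0).any():
            raise ValueError("gene lengths must be positive")
        if set(self.counts.columns) != set(self.design["sample"]):
            raise ValueError("design does not match count columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_for(self, condition: str) -> list[str]:
        rows = self.design[self.design["condition"] == condition]
        return list(rows["sample"])


def fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """FPKM[g, s] = counts * 1e9 / (library_size * length)."""
    lib = matrix.library_sizes
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for samples {zero[:3]}")
    lengths = matrix.lengths.reindex(matrix.counts.index)
    return (matrix.counts * 1e9).div(lib, axis=1).div(lengths, axis=0)


def call_degs(matrix: ExpressionMatrix, condition: str,
              control: str = "control", lfc_threshold: float = 1.0,
              alpha: float = 0.05) -> pd.DataFrame:
    """Differential-expression calls for one condition against control.

    log2FC uses mean FPKM with a pseudocount of 1 for zero-count stability;
    the p-value is a two-sided Welch test on log2(FPKM+1) across the
    condition's samples vs the control's, BH-adjusted across genes.  A gene
    is called up/down only when |log2FC| exceeds the threshold AND the
    adjusted p-value is below ``alpha``.
    """
    cond_samples = matrix.samples_for(condition)
    ctrl_samples = matrix.samples_for(control)
    if len(ctrl_samples) < 2:
        raise ValueError(f"missing or insufficient control samples "
                         f"({control!r}: {len(ctrl_samples)})")
    if len(cond_samples) < 2:
        raise ValueError(f"need >= 2 replicates for {condition!r}")
    values = fpkm(matrix)
    log_cond = np.log2(values[cond_samples] + 1.0)
    log_ctrl = np.log2(values[ctrl_samples] + 1.0)
    log2fc = np.log2((values[cond_samples].mean(axis=1) + 1.0)
                     / (values[ctrl_samples].mean(axis=1) + 1.0))
    t_res = stats.ttest_ind(log_cond, log_ctrl, axis=1, equal_var=False)
    pvalues = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
    padj = multipletests(pvalues, method="fdr_bh")[1]
    call = np.where((log2fc > lfc_threshold) & (padj < alpha), "up",
                    np.where((log2fc < -lfc_threshold) & (padj < alpha),
                             "down", "none"))
    return pd.DataFrame({
        "gene": values.index,
        "condition": condition,
        "log2fc": log2fc.to_numpy(),
        "pvalue": pvalues,
        "padj": padj,
        "call": call,
    }).set_index("gene")


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means clustering (Bezdek membership/centroid updates).

    Parameters
    ----------
    n_clusters : number of clusters.
    m : fuzzifier (> 1); 2.0 is the conventional default.
    n_init : random restarts; the run with the lowest objective wins.
    max_iter, tol : iteration control on the objective decrease.
    random_state : seed for the membership initializations.

    Attributes (after fit)
    ----------------------
    cluster_centers_ : (n_clusters, n_features) centroids.
    membership_ : (n_samples, n_clusters) fuzzy memberships (rows sum to 1).
    labels_ : hard assignment by maximal membership.
    objective_ : sum of membership^m * squared distance at convergence.
    """

    def __init__(self, n_clusters: int = 4, m: float = 2.0,
                 n_init: int = 20, max_iter: int = 300, tol: float = 1e-6,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.m = m
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (self.m - 1.0))
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            u[rows_zero] = 0.0
            first = np.argmax(zero[rows_zero], axis=1)
            u[np.flatnonzero(rows_zero), first] = 1.0
        return u

    def fit(self, X, y=None):
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        X = check_array(X, dtype=float)
        n, _ = X.shape
        if n < self.n_clusters:
            raise ValueError("need at least n_clusters samples")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            u = rng.random((n, self.n_clusters))
            u /= u.sum(axis=1, keepdims=True)
            prev = np.inf
            for _ in range(self.max_iter):
                um = u ** self.m
                centers = (um.T @ X) / um.sum(axis=0)[:, None]
                u = self._memberships(X, centers)
                d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
                objective = float(((u ** self.m) * d2).sum())
                if prev - objective < self.tol:
                    break
                prev = objective
            if best is None or objective < best[0]:
                best = (objective, u, centers)
        self.objective_, self.membership_, self.cluster_centers_ = best
        self.labels_ = self.membership_.argmax(axis=1)
        return self

    def predict(self, X):
        X = check_array(X, dtype=float)
        return self._memberships(X, self.cluster_centers_).argmax(axis=1)


def standardize_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene zero-mean, unit-variance scaling over the time course.

    Genes with zero variance cannot be standardized and are excluded; their
    ids are returned alongside the scaled matrix.
    """
    values = profiles.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, keepdims=True)
    constant = sds[:, 0] <= 1e-12
    scaled = (values - means) / np.where(sds == 0, 1.0, sds)
    kept = profiles.index[~constant]
    dropped = list(profiles.index[constant])
    return pd.DataFrame(scaled[~constant], index=kept,
                        columns=profiles.columns), dropped


def cluster_profiles(profiles: pd.DataFrame, k: int = 4, m: float = 2.0,
                     seed: int | None = 0,
                     n_init: int = 20) -> tuple[pd.DataFrame, float, list[str]]:
    """Cluster standardized expression profiles with fuzzy c-means.

    Returns per-gene memberships with a hard ``cluster`` column, the final
    objective value, and the list of constant-profile genes excluded.
    """
    scaled, dropped = standardize_profiles(profiles)
    if len(scaled) < k:
        raise ValueError("fewer usable genes than clusters")
    model = FuzzyCMeans(n_clusters=k, m=m, n_init=n_init, random_state=seed)
    model.fit(scaled.to_numpy())
    out = pd.DataFrame(model.membership_, index=scaled.index,
                       columns=[f"C{i + 1}" for i in range(k)])
    out["cluster"] = [f"C{i + 1}" for i in model.labels_]
    return out, model.objective_, dropped


def go_enrichment(gene_set, background, annotations: pd.DataFrame,
                  fdr: float = 0.01) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric tail) enrichment per GO term.

    ``annotations`` maps genes to GO ids (columns ``gene``, ``go_id``).
    p-values are BH-adjusted across terms; a term is significant at
    FDR <= ``fdr``.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set:
        return pd.DataFrame(columns=["go_id", "k", "K", "n", "N",
                                     "pvalue", "fdr", "significant"])
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    ann = annotations[annotations["gene"].isin(background)]
    if ann.empty:
        raise ValueError("no annotations overlap the background")
    N = len(background)
    n = len(gene_set)
    rows = []
    for term, genes in ann.groupby("go_id")["gene"]:
        annotated = set(genes)
        K = len(annotated)
        k = len(annotated & gene_set)
        # hypergeometric upper tail: P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"go_id": term, "k": k, "K": K, "n": n, "N": N,
                     "pvalue": min(p, 1.0)})
    result = pd.DataFrame(rows)
    result["fdr"] = multipletests(result["pvalue"], method="fdr_bh")[1]
    result["significant"] = result["fdr"] <= fdr
    return result.sort_values(["fdr", "pvalue", "go_id"]).reset_index(drop=True)


def top_terms(enrichment: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    return enrichment.head(n)


def ortholog_expression_correlation(fpkm_a: pd.DataFrame,
                                    design_a: pd.DataFrame,
                                    fpkm_b: pd.DataFrame,
                                    design_b: pd.DataFrame,
                                    pairs, conditions) -> pd.Series:
    """Pearson r of ortholog expression per condition.

    The first species' FPKM values are averaged over its time points (and
    replicates) per condition; the second species' over its replicates.
    Conditions are matched by name.  With fewer than 3 usable pairs the
    correlation is undefined (NaN).
    """
    out = {}
    for cond in conditions:
        samples_a = design_a.loc[design_a["condition"] == cond, "sample"]
        samples_b = design_b.loc[design_b["condition"] == cond, "sample"]
        if samples_a.empty or samples_b.empty:
            out[cond] = float("nan")
            continue
        mean_a = fpkm_a[list(samples_a)].mean(axis=1)
        mean_b = fpkm_b[list(samples_b)].mean(axis=1)
        xs, ys = [], []
        for ga, gb in pairs:
            if ga in mean_a.index and gb in mean_b.index:
                xs.append(mean_a[ga])
                ys.append(mean_b[gb])
        if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            out[cond] = float("nan")
        else:
            out[cond] = float(stats.pearsonr(xs, ys).statistic)
    return pd.Series(out, name="pearson_r")
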