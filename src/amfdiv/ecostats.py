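"""Community-level statistics and survey summary computations.

Covers total-sum scaling, Pearson/Spearman correlation matrices with
significance stars, rank-based ANOSIM with permutation p-values, classical
MDS and PCA ordinations, Ward hierarchical clustering on arbitrary
distances, per-taxon group tests, and the headline averages/ratios of the
nine-plot field survey tables bundled with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "CorrelationMatrix",
    "AnosimResult",
    "tss_normalize",
    "pearson_r",
    "r_significant",
    "correlation_matrix",
    "spearman_distance_matrix",
    "anosim",
    "classical_mds",
    "pca",
    "ward_clustering",
    "dendrogram_newick",
    "group_difference_tests",
    "load_survey_tables",
    "summary_tables",
]


# ---------------------------------------------------------------------------
# normalization and correlation


def tss_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: divide each sample row by its total.

    Zero-sum samples are dropped (with no row a fraction could be defined
    for, they carry no compositional information).
    """
    sums = counts.sum(axis=1)
    kept = counts.loc[sums > 0]
    return kept.div(kept.sum(axis=1), axis=0)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def r_significant(r: float, n: int, alpha: float = 0.05) -> bool:
    """Two-sided t-test on a correlation coefficient with df = n - 2."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return True
    t = abs(r) * np.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(t, n - 2)
    return p < alpha


@dataclass
class CorrelationMatrix:
    labels: list[str]
    r: pd.DataFrame
    significant: pd.DataFrame
    method: str = "pearson"

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        return self.r.round(decimals)


def correlation_matrix(
    table: pd.DataFrame, method: str = "pearson", alpha: float = 0.05
) -> CorrelationMatrix:
    """All-pairs correlation of the columns of ``table`` with alpha stars."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    n = len(table)
    cols = list(table.columns)
    r = table.corr(method=method)
    sig = pd.DataFrame(False, index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            flag = r_significant(float(r.loc[a, b]), n, alpha)
            sig.loc[a, b] = sig.loc[b, a] = flag
    np.fill_diagonal(sig.values, True)
    return CorrelationMatrix(cols, r, sig, method)


def spearman_distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Between-sample distances 1 - rho over feature profiles (rows = samples)."""
    if table.shape[1] < 2:
        raise ValueError("need at least two features")
    if (table.std(axis=1) == 0).any():
        raise ValueError("constant feature profile: Spearman rho undefined")
    rho = np.corrcoef(stats.rankdata(table.values, axis=1))
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return pd.DataFrame(d, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int


def _anosim_r(rank_d: np.ndarray, same_group: np.ndarray) -> float:
    m = rank_d.size
    rb = rank_d[~same_group].mean()
    rw = rank_d[same_group].mean()
    n = (1 + np.sqrt(1 + 8 * m)) / 2  # invert m = n(n-1)/2
    return float((rb - rw) / (m / 2))


def anosim(
    distances: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) over the
    M = n(n-1)/2 ranked pairwise distances; p is the permutation fraction
    with the +1 correction, so p >= 1/(n_perm+1).
    """
    d = np.asarray(distances, dtype=float)
    groups = np.asarray(groups)
    if d.shape[0] != d.shape[1] or d.shape[0] != groups.size:
        raise ValueError("distance matrix and group labels disagree")
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")
    iu = np.triu_indices(d.shape[0], k=1)
    vec = d[iu]
    rank_d = stats.rankdata(vec)
    same = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(rank_d, same)
    rng = np.random.default_rng(seed)
    count_ge = 0
    idx = np.arange(groups.size)
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        g = groups[perm]
        same_p = g[iu[0]] == g[iu[1]]
        if _anosim_r(rank_d, same_p) >= r_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (n_perm + 1)
    return AnosimResult(r_obs, p, n_perm, seed)


# ---------------------------------------------------------------------------
# ordination


def classical_mds(distances: pd.DataFrame | np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (metric) MDS by double centering + eigendecomposition.

    Coordinates are ordered by eigenvalue; for Euclidean-realizable inputs
    the embedding reproduces the distances exactly (up to rotation).
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = max(int(np.sum(w > 1e-10)), 1)
    k_eff = min(k, pos)
    coords = v[:, :k_eff] * np.sqrt(np.clip(w[:k_eff], 0, None))
    # deterministic sign: largest-magnitude coordinate positive per axis
    for a in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, a])))
        if coords[i, a] < 0:
            coords[:, a] *= -1
    return coords


def pca(table: pd.DataFrame, k: int = 2, scale: bool = False):
    """PCA on centered (optionally unit-scaled) data via SVD.

    Returns (scores, loadings, variance_fractions); per component the
    largest-magnitude loading is made positive.
    """
    x = np.asarray(table, dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k_eff = min(k, s.size)
    var = s**2 / max(len(x) - 1, 1)
    frac = var / var.sum() if var.sum() > 0 else var
    scores = u[:, :k_eff] * s[:k_eff]
    loadings = vt[:k_eff].T
    for a in range(k_eff):
        i = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[i, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return scores, loadings, frac[:k_eff]


def ward_clustering(distances: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ward agglomeration (Lance-Williams update) on a precomputed distance matrix."""
    d = np.asarray(distances, dtype=float)
    if d.shape[0] < 2:
        raise ValueError("need at least two items")
    return linkage(squareform(d, checks=False), method="ward")


def dendrogram_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as Newick with merge heights."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: str(labels[i]) for i in range(n)}
    for step, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        new = n + step
        node[new] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[new] = h
    return node[n + len(z) - 1] + ";"


# ---------------------------------------------------------------------------
# group tests


def group_difference_tests(
    rel_abund: pd.DataFrame,
    groups: Sequence[str],
    welch: bool = False,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-taxon one-way ANOVA (two-sample t for two groups) across groups.

    Raw p-values with alpha flags by default; pass ``fdr=True`` for optional
    Benjamini-Hochberg adjusted flags.
    """
    groups = np.asarray(groups)
    uniq = sorted(set(groups))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for taxon in rel_abund.columns:
        vals = [rel_abund.loc[groups == g, taxon].to_numpy(dtype=float) for g in uniq]
        if any(v.size < 2 for v in vals):
            continue
        if len(uniq) == 2:
            res = stats.ttest_ind(vals[0], vals[1], equal_var=not welch)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            if welch:
                res = stats.alexandergovern(*vals)
                stat, p = float(res.statistic), float(res.pvalue)
            else:
                res = stats.f_oneway(*vals)
                stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):
            p = 1.0
        rows.append((taxon, stat, p))
    out = pd.DataFrame(rows, columns=["taxon", "statistic", "p_value"]).set_index("taxon")
    out["significant"] = out["p_value"] < alpha
    if fdr and len(out):
        m = len(out)
        order = np.argsort(out["p_value"].values)
        adj = np.empty(m)
        prev = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            i = m - rank_i
            prev = min(prev, out["p_value"].values[idx] * m / i)
            adj[idx] = prev
        out["p_adjusted"] = adj
        out["significant_fdr"] = out["p_adjusted"] < alpha
    return out


# ---------------------------------------------------------------------------
# survey summary (bundled nine-plot field tables)


def load_survey_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bundled field-survey tables for the nine North Caucasus trial plots.

    Returns (survey, read_counts, biotope_otus): plot locations/altitudes by
    biotope; per-plot sequencing and AMF read/OTU counts for both spacers;
    and biotope-pooled AMF OTU counts per marker.
    """
    pkg = resources.files("amfdiv.data")
    survey = pd.read_csv(pkg / "stp_survey.tsv", sep="\t")
    reads = pd.read_csv(pkg / "read_counts.tsv", sep="\t")
    biotope = pd.read_csv(pkg / "biotope_otus.tsv", sep="\t")
    return survey, reads, biotope


def summary_tables(
    read_counts: pd.DataFrame,
    biotope_otus: pd.DataFrame,
) -> dict[str, float]:
    """Headline per-plot averages and biotope/marker ratios.

    Means are rounded to the nearest integer, ratios to one decimal, matching
    how a survey report prints them.
    """

    def _biotope(marker: str, biotope: str) -> int:
        m = biotope_otus[(biotope_otus.marker == marker) & (biotope_otus.biotope == biotope)]
        return int(m.amf_otus.iloc[0])

    its1 = read_counts["amf_reads_its1"].to_numpy(dtype=float)
    its2 = read_counts["amf_reads_its2"].to_numpy(dtype=float)
    out = {
        "mean_amf_reads_its1": round(float(its1.mean())),
        "mean_amf_reads_its2": round(float(its2.mean())),
        "total_amf_reads_its1": int(its1.sum()),
        "total_amf_reads_its2": int(its2.sum()),
        "marker_read_ratio": round(float(its1.sum() / its2.sum()), 1),
        "otu_ratio_valley_forest_its1": round(_biotope("ITS1", "river_valley") / _biotope("ITS1", "forest"), 1),
        "otu_ratio_valley_meadow_its1": round(_biotope("ITS1", "river_valley") / _biotope("ITS1", "subalpine_meadow"), 1),
        "otu_ratio_meadow_forest_its1": round(_biotope("ITS1", "subalpine_meadow") / _biotope("ITS1", "forest"), 1),
        "otu_ratio_valley_forest_its2": round(_biotope("ITS2", "river_valley") / _biotope("ITS2", "forest"), 1),
        "otu_ratio_meadow_forest_its2": round(_biotope("ITS2", "subalpine_meadow") / _biotope("ITS2", "forest"), 1),
    }
    return out
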