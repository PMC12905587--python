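"""Cellular-module detection from cluster co-occurrence.

Cell clusters whose per-sample frequencies rise and fall together across a
cohort form cellular modules — each module a tumor-immune-microenvironment
(TIME) subtype. The substrate is the samples x clusters frequency matrix over
non-epithelial cells: raw per-sample proportions, and per-cluster z-scores
across samples so that rare and abundant clusters contribute comparably.
Modules are found by Ward.D2 agglomerative clustering on the correlation
distance (1 - Pearson r) between cluster frequency profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterFrequencyMatrix",
    "CellularModuleResult",
    "filter_low_cell_samples",
    "compute_cluster_frequencies",
    "detect_modules",
    "assign_dominant_module",
    "module_raw_shares",
    "derive_module_signature",
    "classify_time_heterogeneity",
    "CellularModuleAnalysis",
    "CellularModuleResults",
]


@dataclass
class ClusterFrequencyMatrix:
    """Per-sample cluster frequencies: raw proportions and per-cluster z-scores."""

    raw: pd.DataFrame         # samples x clusters, rows sum to 1
    normalized: pd.DataFrame  # per-cluster z-score across samples (sd=0 -> 0)


@dataclass
class CellularModuleResult:
    correlation: pd.DataFrame
    linkage: np.ndarray
    module_of: dict[str, str]
    k: int
    silhouette: float
    weak_structure: bool
    zero_variance_clusters: list[str] = field(default_factory=list)
    signatures: dict[str, list[str]] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.module_of.values()), key=lambda m: int(m[1:]))

    def members(self, module: str) -> list[str]:
        return [c for c, m in self.module_of.items() if m == module]


def filter_low_cell_samples(table: pd.DataFrame, min_cells: int = 1000) -> pd.DataFrame:
    """Drop samples with fewer than ``min_cells`` non-epithelial cells (strict)."""
    if "is_epithelial" not in table.columns:
        raise ValueError("cell table must carry an is_epithelial flag")
    counts = table.loc[~table["is_epithelial"]].groupby("sample_id").size()
    counts = counts.reindex(table["sample_id"].unique(), fill_value=0)
    keep = counts[counts >= min_cells].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("excluding %d samples with < %d non-epithelial cells: %s",
                    len(dropped), min_cells, dropped[:10])
    if len(keep) == 0:
        raise ValueError(f"all samples have fewer than {min_cells} non-epithelial cells")
    return table.loc[table["sample_id"].isin(keep)].copy()


def compute_cluster_frequencies(table: pd.DataFrame) -> ClusterFrequencyMatrix:
    """Per-sample proportions over non-epithelial clusters plus per-cluster z-scores.

    The z-score uses the sample standard deviation (ddof=1) across samples;
    clusters with zero variance get an all-zero normalized column.
    """
    sub = table.loc[~table["is_epithelial"]] if "is_epithelial" in table.columns else table
    counts = pd.crosstab(sub["sample_id"], sub["cluster_id"])
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples to normalize cluster frequencies")
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 clusters")
    raw = counts.div(counts.sum(axis=1), axis=0)
    sd = raw.std(axis=0, ddof=1)
    normalized = (raw - raw.mean(axis=0)).div(sd.replace(0.0, np.inf), axis=1)
    return ClusterFrequencyMatrix(raw=raw, normalized=normalized)


def _auto_k(D: np.ndarray, Z: np.ndarray, k_range: range) -> tuple[int, float]:
    best_k, best_s = None, -np.inf
    for k in k_range:
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(D, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("could not select k: degenerate distance structure")
    return best_k, float(best_s)


def detect_modules(freq: ClusterFrequencyMatrix, k: int | str = "auto",
                   max_k: int = 8, weak_threshold: float = 0.25) -> CellularModuleResult:
    """Cluster cluster-frequency profiles into cellular modules.

    Pearson correlation between normalized frequency profiles, Ward.D2 linkage
    on d = 1 - r, tree cut at ``k`` (or the k in 2..max_k maximizing the mean
    silhouette). Zero-variance clusters are set aside and assigned afterwards
    to the module with the nearest raw-frequency centroid.
    """
    norm = freq.normalized
    if norm.shape[1] < 3:
        raise ValueError("need at least 3 clusters to detect modules")
    variances = norm.std(axis=0)
    zero_var = list(norm.columns[variances == 0])
    active = [c for c in norm.columns if c not in zero_var]
    if len(active) < 3:
        raise ValueError("fewer than 3 clusters with nonzero variance")

    corr = pd.DataFrame(np.corrcoef(norm[active].to_numpy().T),
                        index=active, columns=active)
    D = np.clip(1.0 - corr.to_numpy(), 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="ward")
    if k == "auto":
        kk, sil = _auto_k(D, Z, range(2, min(max_k, len(active) - 1) + 1))
    else:
        kk = int(k)
        labels0 = fcluster(Z, t=kk, criterion="maxclust")
        sil = (silhouette_score(D, labels0, metric="precomputed")
               if len(set(labels0)) > 1 else float("nan"))
    labels = fcluster(Z, t=kk, criterion="maxclust")
    module_of = {c: f"M{lab}" for c, lab in zip(active, labels)}

    if zero_var:
        logger.warning("zero-variance clusters assigned by nearest centroid: %s", zero_var)
        raw = freq.raw
        centroids = {m: raw[[c for c in active if module_of[c] == m]].mean(axis=1)
                     for m in set(module_of.values())}
        for c in zero_var:
            dists = {m: float(((raw[c] - cen) ** 2).sum()) for m, cen in centroids.items()}
            module_of[c] = min(dists, key=lambda m: (dists[m], m))

    weak = sil < weak_threshold
    if weak:
        logger.warning("weak module structure: mean silhouette %.3f < %.2f", sil, weak_threshold)
    return CellularModuleResult(correlation=corr, linkage=Z, module_of=module_of,
                                k=kk, silhouette=sil, weak_structure=weak,
                                zero_variance_clusters=zero_var)


def assign_dominant_module(freq: ClusterFrequencyMatrix,
                           result: CellularModuleResult) -> dict[str, str]:
    """Per sample, sum normalized frequencies within each module; argmax wins.

    Exact ties resolve to the lowest module id, with a logged warning.
    """
    sums = pd.DataFrame({
        m: freq.normalized[result.members(m)].sum(axis=1) for m in result.modules
    })
    assignment: dict[str, str] = {}
    for sample, row in sums.iterrows():
        top = row.max()
        winners = sorted(row.index[row == top], key=lambda m: int(m[1:]))
        if len(winners) > 1:
            logger.warning("sample %s: dominant-module tie among %s; choosing %s",
                           sample, winners, winners[0])
        assignment[sample] = winners[0]
    return assignment


def module_raw_shares(freq: ClusterFrequencyMatrix,
                      result: CellularModuleResult) -> pd.DataFrame:
    """Samples x modules matrix of raw-frequency shares (rows sum to 1)."""
    return pd.DataFrame({
        m: freq.raw[result.members(m)].sum(axis=1) for m in result.modules
    })


def derive_module_signature(table: pd.DataFrame, expr: pd.DataFrame,
                            result: CellularModuleResult,
                            n_types: int = 5, n_markers: int = 10,
                            min_detection: float = 0.1) -> dict[str, list[str]]:
    """Molecular signature per module: top markers of its most prevalent cell types.

    Within each module's cells, the ``n_types`` most abundant cell types are
    ranked by cell count; each contributes its top ``n_markers`` genes by
    one-vs-rest log fold change of mean expression (genes detected in at least
    ``min_detection`` of the type's cells). The signature is the deduplicated
    union (at most ``n_types * n_markers`` genes).
    """
    sub = table.loc[~table["is_epithelial"]] if "is_epithelial" in table.columns else table
    sub = sub.loc[sub["cell_id"].isin(expr.columns)]
    signatures: dict[str, list[str]] = {}
    eps = 1e-9
    for module in result.modules:
        cells = sub.loc[sub["cluster_id"].isin(result.members(module))]
        type_counts = cells["cell_type"].value_counts()
        if len(type_counts) < n_types:
            logger.info("module %s has only %d cell types; using all",
                        module, len(type_counts))
        top_types = list(type_counts.index[:n_types])
        module_expr = expr[cells["cell_id"]]
        sig: list[str] = []
        for ct in top_types:
            in_cells = cells.loc[cells["cell_type"] == ct, "cell_id"]
            out_cells = cells.loc[cells["cell_type"] != ct, "cell_id"]
            mean_in = module_expr[in_cells].mean(axis=1)
            mean_out = (module_expr[out_cells].mean(axis=1)
                        if len(out_cells) else pd.Series(0.0, index=expr.index))
            detect = (module_expr[in_cells] > 0).mean(axis=1)
            lfc = np.log2((mean_in + eps) / (mean_out + eps))
            lfc = lfc.where(detect >= min_detection, -np.inf)
            for g in lfc.sort_values(ascending=False).index[:n_markers]:
                if np.isfinite(lfc[g]) and g not in sig:
                    sig.append(g)
        signatures[module] = sig
    result.signatures = signatures
    return signatures


def classify_time_heterogeneity(dominant_fractions: dict[str, float],
                                threshold: float = 0.65) -> dict[str, str]:
    """Monotypic iff the largest single-module raw-frequency share is >= 65%."""
    out = {}
    for sample, frac in dominant_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction for {sample} outside [0, 1]: {frac}")
        out[sample] = "monotypic" if frac >= threshold else "heterotypic"
    return out


class CellularModuleAnalysis:
    """Cellular-module model over a cell annotation table.

    Parameters
    ----------
    table:
        Cell annotation table (cell_id, sample_id, cluster_id, cell_type,
        is_epithelial).
    min_cells:
        Minimum non-epithelial cells per sample; samples below are excluded.
    """

    def __init__(self, table: pd.DataFrame, min_cells: int = 1000):
        self.table = filter_low_cell_samples(table, min_cells=min_cells)
        self.freq = compute_cluster_frequencies(self.table)

    def fit(self, k: int | str = "auto") -> "CellularModuleResults":
        detection = detect_modules(self.freq, k=k)
        dominant = assign_dominant_module(self.freq, detection)
        shares = module_raw_shares(self.freq, detection)
        return CellularModuleResults(self, detection, dominant, shares)


class CellularModuleResults:
    """Fitted cellular modules: partition, dominance, and TIME heterogeneity."""

    def __init__(self, model: CellularModuleAnalysis, detection: CellularModuleResult,
                 dominant: dict[str, str], shares: pd.DataFrame):
        self.model = model
        self.detection = detection
        self.dominant_module = dominant
        self.module_shares = shares
        self.max_share = shares.max(axis=1).to_dict()
        self.heterogeneity = classify_time_heterogeneity(self.max_share)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dominant_module": pd.Series(self.dominant_module),
            "max_module_share": pd.Series(self.max_share),
            "time_class": pd.Series(self.heterogeneity),
        })

    def plot_dendrogram(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        dendrogram(self.detection.linkage,
                   labels=list(self.detection.correlation.columns), ax=ax)
        ax.set_ylabel("Ward.D2 height (1 - r)")
        return ax
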