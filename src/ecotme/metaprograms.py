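"""Consolidation of per-sample gene-expression programs into meta-programs.

Per-sample NMF decomposes each tumor's malignant cells into gene expression
programs (GEPs): a row-stochastic usage matrix (cells x programs) and a
nonnegative loading matrix (genes x programs). Programs recur across tumors;
clustering the loading vectors of all retained programs (correlation distance,
average linkage) and aggregating each cluster's top-100 gene loadings yields
meta-programs (MPs), each summarized by its 30 highest-loading marker genes.

The consensus NMF here is a light in-package implementation: multiple
multiplicative-update NMF restarts, component clustering across restarts with
outlier dropping, median consensus loadings, and a nonnegative-least-squares
usage refit. Externally produced GEP matrices are accepted on equal terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

from .synthetic import GEPMatrices

logger = logging.getLogger(__name__)

__all__ = [
    "MetaProgram",
    "filter_cells_genes",
    "filter_low_tumor_samples",
    "select_overdispersed_genes",
    "consensus_nmf",
    "choose_k",
    "filter_geps_by_usage",
    "cluster_geps",
    "aggregate_meta_program",
    "consolidate_meta_programs",
    "assign_programmed_cells",
]


@dataclass
class MetaProgram:
    """A consolidated meta-program: member GEPs, aggregated loadings, markers."""

    mp_id: str
    member_programs: list[tuple[str, str]]
    gene_loadings: pd.Series
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.member_programs:
            raise ValueError("a meta-program needs at least one member program")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_cells_genes(expr: pd.DataFrame, min_genes_per_cell: int = 300,
                       min_cells_per_gene: int = 5) -> pd.DataFrame:
    """Drop cells with < ``min_genes_per_cell`` detected genes, then genes
    detected in < ``min_cells_per_gene`` cells (both thresholds strict)."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression counts must be nonnegative")
    detected = expr > 0
    cells = expr.columns[detected.sum(axis=0) >= min_genes_per_cell]
    expr = expr[cells]
    genes = expr.index[(expr > 0).sum(axis=1) >= min_cells_per_gene]
    expr = expr.loc[genes]
    if expr.empty:
        raise ValueError("no cells/genes survive filtering")
    return expr


def filter_low_tumor_samples(tumor_cell_counts: dict[str, int] | pd.Series,
                             min_tumor_cells: int = 100) -> list[str]:
    """Keep samples with at least ``min_tumor_cells`` tumor cells."""
    counts = pd.Series(tumor_cell_counts)
    keep = sorted(counts.index[counts >= min_tumor_cells])
    if not keep:
        raise ValueError(f"no samples with >= {min_tumor_cells} tumor cells")
    return keep


def select_overdispersed_genes(expr: pd.DataFrame, n: int = 2000) -> list[str]:
    """Rank genes by over-dispersion and return the top ``n``.

    The score is the residual of log CV^2 from a log-log linear fit of CV^2
    against mean expression — a variance-mean trend residual standing in for a
    v-score-style statistic. Constant input is rejected.
    """
    mat = expr.to_numpy(dtype=float)
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    if np.all(var == 0):
        raise ValueError("constant expression matrix: over-dispersion undefined")
    ok = (mean > 0) & (var > 0)
    eps = 1e-12
    cv2 = var[ok] / (mean[ok] ** 2 + eps)
    x = np.log(mean[ok] + eps)
    y = np.log(cv2 + eps)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    score = pd.Series(-np.inf, index=expr.index)
    score.iloc[np.flatnonzero(ok)] = resid
    if n >= len(expr.index):
        logger.warning("requested %d over-dispersed genes but only %d available",
                       n, len(expr.index))
        return list(expr.index)
    return list(score.sort_values(ascending=False).index[:n])


# ---------------------------------------------------------------------------
# consensus NMF
# ---------------------------------------------------------------------------

def _unit_scale_genes(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=0).replace(0.0, 1.0)
    return expr.div(sd, axis=0)


def _nmf_restarts(V: np.ndarray, k: int, restarts: int, max_iter: int,
                  seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for r in range(restarts):
        model = NMF(n_components=k, init="random", solver="mu",
                    beta_loss="frobenius", max_iter=max_iter,
                    random_state=seed + r, tol=1e-5)
        W = model.fit_transform(V)      # genes x k
        H = model.components_           # k x cells
        out.append((W, H))
    return out


def consensus_nmf(expr: pd.DataFrame, k: int, restarts: int = 10,
                  max_iter: int = 200, seed: int = 0,
                  outlier_quantile: float = 0.9,
                  sample_id: str = "sample") -> GEPMatrices:
    """Consensus NMF of a genes x cells matrix into ``k`` programs.

    Genes are scaled to unit variance; ``restarts`` multiplicative-update NMF
    runs (``max_iter`` iterations each) produce pooled components that are
    k-means clustered; components farther from their cluster median than the
    ``outlier_quantile`` of all such distances are dropped; the consensus
    loading of each cluster is the elementwise median; cell usages are refit
    against the consensus loadings by nonnegative least squares and
    row-normalized. Deterministic in ``seed``.
    """
    V = _unit_scale_genes(expr).to_numpy(dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be nonnegative")
    runs = _nmf_restarts(V, k, restarts, max_iter, seed)
    comps = np.vstack([(W / (np.linalg.norm(W, axis=0, keepdims=True) + 1e-12)).T
                       for W, _ in runs])  # (restarts*k) x genes
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(comps)
    consensus_cols = []
    for c in range(k):
        members = comps[km.labels_ == c]
        if members.size == 0:
            raise ValueError("consensus clustering produced an empty component cluster")
        median = np.median(members, axis=0)
        dists = np.linalg.norm(members - median, axis=1)
        cut = np.quantile(dists, outlier_quantile)
        kept = members[dists <= cut]
        consensus_cols.append(np.median(kept, axis=0))
    W_cons = np.clip(np.asarray(consensus_cols).T, 0.0, None)  # genes x k

    usage = np.zeros((expr.shape[1], k))
    for j in range(expr.shape[1]):
        usage[j], _ = nnls(W_cons, V[:, j])
    row_sums = usage.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    usage /= row_sums
    programs = [f"p{i}" for i in range(k)]
    return GEPMatrices(
        sample_id=sample_id,
        usage=pd.DataFrame(usage, index=expr.columns, columns=programs),
        loadings=pd.DataFrame(W_cons, index=expr.index, columns=programs),
    )


def choose_k(expr: pd.DataFrame, k_range, restarts: int = 5,
             max_iter: int = 200, seed: int = 0,
             stability_weight: float = 0.5) -> tuple[int, pd.DataFrame]:
    """Pick the NMF rank trading off restart stability against reconstruction error.

    For each k: stability = mean silhouette of pooled restart components under
    k-means with k clusters (cosine-normalized); error = relative Frobenius
    reconstruction error of the consensus factorization, min-max normalized
    across the k range. The selected k maximizes
    ``stability - stability_weight * normalized_error``. Returns the chosen k
    and the per-k diagnostics; a best stability < 0.3 is flagged as weak.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k range")
    V = _unit_scale_genes(expr).to_numpy(dtype=float)
    rows = []
    for k in ks:
        if k == 1:
            rows.append({"k": 1, "stability": 1.0, "error": np.nan})
            continue
        runs = _nmf_restarts(V, k, restarts, max_iter, seed)
        comps = np.vstack([(W / (np.linalg.norm(W, axis=0, keepdims=True) + 1e-12)).T
                           for W, _ in runs])
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(comps)
        stab = (silhouette_score(comps, km.labels_)
                if len(set(km.labels_)) > 1 else 0.0)
        geps = consensus_nmf(expr, k, restarts=restarts, max_iter=max_iter, seed=seed)
        recon = geps.loadings.to_numpy() @ _refit_scale(geps, V)
        err = np.linalg.norm(V - recon) / np.linalg.norm(V)
        rows.append({"k": k, "stability": float(stab), "error": float(err)})
    diag = pd.DataFrame(rows).set_index("k")
    err = diag["error"]
    if err.notna().sum() > 1 and err.max() > err.min():
        norm_err = (err - err.min()) / (err.max() - err.min())
    else:
        norm_err = err.fillna(0.0) * 0.0
    diag["score"] = diag["stability"].fillna(1.0) - stability_weight * norm_err.fillna(0.0)
    best = int(diag["score"].idxmax())
    if diag["stability"].max() < 0.3:
        logger.warning("all ranks unstable (max stability %.2f): likely pure noise",
                       diag["stability"].max())
    return best, diag


def _refit_scale(geps: GEPMatrices, V: np.ndarray) -> np.ndarray:
    """Scaled usage (k x cells) minimizing ||V - W U|| given row-stochastic usage."""
    W = geps.loadings.to_numpy()
    U = geps.usage.to_numpy().T  # k x cells
    WU = W @ U
    denom = (WU * WU).sum(axis=0)
    denom[denom == 0] = 1.0
    scale = (WU * V).sum(axis=0) / denom
    return U * np.clip(scale, 0.0, None)


# ---------------------------------------------------------------------------
# program retention, clustering, aggregation
# ---------------------------------------------------------------------------

def filter_geps_by_usage(geps: list[GEPMatrices],
                         min_mean_usage: float = 0.01) -> list[tuple[str, str]]:
    """Retain programs whose mean cell usage is strictly above the threshold."""
    kept = []
    for g in geps:
        means = g.usage.mean(axis=0)
        for program, mu in means.items():
            if mu > min_mean_usage:
                kept.append((g.sample_id, str(program)))
    if not kept:
        raise ValueError("no programs exceed the mean-usage threshold")
    return kept


def _loading_matrix(geps: list[GEPMatrices],
                    programs: list[tuple[str, str]]) -> pd.DataFrame:
    """Programs x genes matrix over the union gene universe (missing -> 0)."""
    by_sample = {g.sample_id: g for g in geps}
    universe: pd.Index = pd.Index([])
    for sample, _ in programs:
        universe = universe.union(by_sample[sample].loadings.index)
    cols = {}
    for sample, program in programs:
        vec = by_sample[sample].loadings[program].reindex(universe, fill_value=0.0)
        cols[(sample, program)] = vec
    return pd.DataFrame(cols).T


def cluster_geps(geps: list[GEPMatrices],
                 programs: list[tuple[str, str]] | None = None,
                 k: int | str = "auto", max_k: int = 10,
                 ) -> tuple[dict[tuple[str, str], int], pd.DataFrame]:
    """Cluster GEP loading vectors by 1 - Pearson r with average linkage.

    ``programs`` defaults to all programs of all samples. Returns the partition
    (program -> cluster label, 1-based) and the loading matrix used.
    """
    if programs is None:
        programs = [(g.sample_id, str(p)) for g in geps for p in g.loadings.columns]
    if len(programs) < 2:
        raise ValueError("need at least 2 programs to cluster")
    L = _loading_matrix(geps, programs)
    corr = np.corrcoef(L.to_numpy())
    D = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="average")
    if k == "auto":
        best_k, best_s = None, -np.inf
        for kk in range(2, min(max_k, len(programs) - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            s = silhouette_score(D, labels, metric="precomputed")
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k
    labels = fcluster(Z, t=int(k), criterion="maxclust")
    return dict(zip(L.index, labels)), L


def aggregate_meta_program(loadings: list[pd.Series], mp_id: str = "MP1",
                           member_programs: list[tuple[str, str]] | None = None,
                           top_genes: int = 100, n_markers: int = 30) -> MetaProgram:
    """Aggregate a cluster of GEP loading vectors into one meta-program.

    The gene universe is the union of each program's top-``top_genes`` gene
    set. Per gene, loadings are summed over the programs whose top set contains
    it (exclusive genes keep their single loading), then every total is divided
    by the number of programs in the cluster. Markers are the ``n_markers``
    genes with the highest aggregated loading; a tie at the marker boundary is
    resolved by lexicographic gene id and logged.
    """
    if not loadings:
        raise ValueError("empty program cluster")
    n_prog = len(loadings)
    totals: dict[str, float] = {}
    for vec in loadings:
        top = vec.sort_values(ascending=False).index[:top_genes]
        for g in top:
            totals[g] = totals.get(g, 0.0) + float(vec[g])
    agg = pd.Series(totals).sort_index() / n_prog
    ranked = agg.sort_values(ascending=False, kind="stable")
    if len(ranked) > n_markers and ranked.iloc[n_markers - 1] == ranked.iloc[n_markers]:
        tied_value = ranked.iloc[n_markers - 1]
        tied = sorted(ranked.index[ranked == tied_value])
        logger.info("marker-rank tie at %.6g resolved lexicographically: %s",
                    tied_value, tied[:6])
        above = list(ranked.index[ranked > tied_value])
        markers = above + tied[: n_markers - len(above)]
    else:
        markers = list(ranked.index[:n_markers])
    members = member_programs or [("unknown", f"p{i}") for i in range(n_prog)]
    return MetaProgram(mp_id=mp_id, member_programs=members,
                       gene_loadings=agg, markers=markers)


def consolidate_meta_programs(geps: list[GEPMatrices],
                              min_mean_usage: float = 0.01,
                              k: int | str = "auto") -> list[MetaProgram]:
    """Full chain: usage filter, GEP clustering, per-cluster aggregation."""
    kept = filter_geps_by_usage(geps, min_mean_usage=min_mean_usage)
    partition, L = cluster_geps(geps, programs=kept, k=k)
    mps = []
    for label in sorted(set(partition.values())):
        members = [p for p, lab in partition.items() if lab == label]
        vecs = [L.loc[m] for m in members]
        mps.append(aggregate_meta_program(vecs, mp_id=f"MP{label}",
                                          member_programs=members))
    return mps


def assign_programmed_cells(expr: pd.DataFrame, mps: list[MetaProgram],
                            threshold: float = 0.70) -> pd.DataFrame:
    """Call programmed cells: a cell is programmed for an MP iff it expresses
    (count > 0) at least ``threshold`` of the MP's marker genes.

    Returns a DataFrame indexed by cell with one coverage column per MP, a
    boolean ``programmed_<mp>`` column each, and a ``primary_mp`` column
    (highest coverage among programmed MPs; ties or none -> None).
    """
    if not mps:
        raise ValueError("no meta-programs given")
    out = pd.DataFrame(index=expr.columns)
    for mp in mps:
        if not mp.markers:
            raise ValueError(f"{mp.mp_id} has no markers")
        present = [g for g in mp.markers if g in expr.index]
        detected = (expr.loc[present] > 0).sum(axis=0) if present else 0
        coverage = detected / len(mp.markers)
        out[mp.mp_id] = coverage
        out[f"programmed_{mp.mp_id}"] = coverage >= threshold
    cov = out[[mp.mp_id for mp in mps]]
    prog = out[[f"programmed_{mp.mp_id}" for mp in mps]].to_numpy()
    primary = []
    for i, (_, row) in enumerate(cov.iterrows()):
        eligible = row[prog[i]]
        if eligible.empty:
            primary.append(None)
            continue
        top = eligible.max()
        winners = eligible.index[eligible == top]
        primary.append(winners[0] if len(winners) == 1 else None)
    out["primary_mp"] = primary
    return out
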