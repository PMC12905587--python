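"""Tumor-ecosystem assembly: clustering CM/MP abundance profiles, building
ecosystem gene signatures, and scoring them on bulk expression with ssGSEA.

An ecosystem is a cluster of co-varying components — TIME cellular modules
(CMs) and malignant meta-programs (MPs) — found by Ward.D2 clustering of the
correlation distance between component abundance vectors across samples. Each
ecosystem's signature unions its member CM signatures, member MP markers, and
the genes of its ten highest-Ro/e ligand-receptor pairs. Bulk samples are
scored per signature with a single-sample GSEA (weighted rank running sum,
alpha = 0.25, global max-min normalization) and assigned to the argmax
ecosystem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .interactions import RoeResult, top_k_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "EcosystemPartition",
    "SignatureSet",
    "cluster_ecosystems",
    "assemble_ecosystem_signature",
    "ssgsea_score",
    "assign_samples_to_ecosystem",
]


@dataclass
class EcosystemPartition:
    """Partition of CM/MP components into ecosystems."""

    ecosystem_of: dict[str, str]
    k: int
    silhouette: float
    flagged: list[str] = field(default_factory=list)  # ecosystems missing a CM or MP
    excluded: list[str] = field(default_factory=list)  # constant components

    def members(self, ecosystem: str) -> list[str]:
        return [c for c, e in self.ecosystem_of.items() if e == ecosystem]

    @property
    def ecosystems(self) -> list[str]:
        return sorted(set(self.ecosystem_of.values()), key=lambda e: int(e[1:]))


@dataclass
class SignatureSet:
    """An ecosystem signature: ordered deduplicated genes with provenance."""

    ecosystem_id: str
    genes: list[str]
    provenance: dict[str, set[str]]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty ecosystem signature")
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("signature genes must be unique")


def cluster_ecosystems(profiles: pd.DataFrame, k: int | str = "auto",
                       max_k: int = 6) -> EcosystemPartition:
    """Cluster component abundance profiles (samples x components) into ecosystems.

    Pearson correlation of component columns across samples, Ward.D2 linkage on
    1 - r, cut at ``k`` (auto: max mean silhouette over 2..max_k). Component
    labels must start with "CM" or "MP"; ecosystems lacking either kind are
    flagged. Constant columns are excluded with a warning.
    """
    if profiles.shape[1] < 4:
        raise ValueError("need at least 4 components")
    if profiles.shape[0] < 5:
        raise ValueError("need at least 5 samples")
    sd = profiles.std(axis=0)
    excluded = list(profiles.columns[sd == 0])
    if excluded:
        logger.warning("excluding constant components: %s", excluded)
    active = [c for c in profiles.columns if c not in excluded]
    X = profiles[active].to_numpy(dtype=float).T
    corr = np.corrcoef(X)
    D = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="ward")
    if k == "auto":
        best_k, best_s = None, -np.inf
        for kk in range(2, min(max_k, len(active) - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            s = silhouette_score(D, labels, metric="precomputed")
            if s > best_s:
                best_k, best_s = kk, s
        k, sil = best_k, best_s
    else:
        k = int(k)
        labels0 = fcluster(Z, t=k, criterion="maxclust")
        sil = (silhouette_score(D, labels0, metric="precomputed")
               if len(set(labels0)) > 1 else float("nan"))
    labels = fcluster(Z, t=int(k), criterion="maxclust")
    ecosystem_of = {c: f"E{lab}" for c, lab in zip(active, labels)}
    flagged = []
    for eco in sorted(set(ecosystem_of.values())):
        members = [c for c, e in ecosystem_of.items() if e == eco]
        if not any(c.startswith("CM") for c in members) or \
           not any(c.startswith("MP") for c in members):
            flagged.append(eco)
    if flagged:
        logger.warning("ecosystems without both a CM and an MP: %s", flagged)
    return EcosystemPartition(ecosystem_of=ecosystem_of, k=int(k),
                              silhouette=float(sil), flagged=flagged,
                              excluded=excluded)


def _pair_genes(pair_id: str) -> list[str]:
    """Expand a ligand-receptor pair id into its component gene symbols.

    Pair ids join participants with "_"; complex participants expand to all
    their gene symbols, so every "_"-separated token is one gene.
    """
    return [tok for tok in str(pair_id).split("_") if tok]


def assemble_ecosystem_signature(cm_signatures: dict[str, list[str]],
                                 mp_markers: dict[str, list[str]],
                                 roe_result: RoeResult | None,
                                 partition: EcosystemPartition,
                                 ecosystem: str,
                                 n_pairs: int = 10) -> SignatureSet:
    """Union of member CM signatures, member MP markers, and top-Ro/e pair genes.

    Order-independent: sources are visited CMs, then MPs, then ligand-receptor
    pairs, each in sorted member order; duplicates keep multi-source provenance.
    """
    members = partition.members(ecosystem)
    cms = sorted(c for c in members if c.startswith("CM"))
    mps = sorted(c for c in members if c.startswith("MP"))
    genes: list[str] = []
    provenance: dict[str, set[str]] = {}

    def add(gene: str, source: str) -> None:
        if gene not in provenance:
            provenance[gene] = set()
            genes.append(gene)
        provenance[gene].add(source)

    for cm in cms:
        for g in cm_signatures.get(cm, []):
            add(g, "CM signature")
    for mp in mps:
        for g in mp_markers.get(mp, []):
            add(g, "MP markers")
    if roe_result is not None and ecosystem in roe_result.roe.columns:
        for pair in top_k_pairs(roe_result, ecosystem, k=n_pairs):
            for g in _pair_genes(pair):
                add(g, "LR pair")
    if not genes:
        raise ValueError(f"signature for {ecosystem} is empty")
    return SignatureSet(ecosystem_id=ecosystem, genes=genes, provenance=provenance)


def _ssgsea_sample(expr: pd.Series, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment of one sample (Barbie-style single-sample GSEA)."""
    # rank: highest expression -> largest rank; average ranks on ties
    ranks = expr.rank(method="average", ascending=True).to_numpy()
    order = np.lexsort((np.arange(len(ranks)), -ranks))  # descending, stable
    in_ord = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(in_ord, w, 0.0)
    denom_in = w_in.sum()
    if denom_in == 0:
        return 0.0
    p_in = np.cumsum(w_in) / denom_in
    n_out = (~in_ord).sum()
    if n_out == 0:
        p_out = np.zeros_like(p_in)  # degenerate: signature covers all genes
    else:
        p_out = np.cumsum(np.where(in_ord, 0.0, 1.0)) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(expr: pd.DataFrame, signatures: dict[str, SignatureSet | list[str]],
                 alpha: float = 0.25, normalize: bool = True) -> pd.DataFrame:
    """ssGSEA scores of each signature in each bulk sample.

    ``expr`` is genes x samples (any monotone scale; scores are rank-based).
    Per sample the enrichment is the sum over all ranked positions of the
    weighted (rank^alpha) in-set ECDF minus the unweighted out-set ECDF. With
    ``normalize`` the whole score matrix is divided by its max - min range.
    Raises if fewer than two signature genes are present in ``expr``.
    """
    scores = {}
    gene_index = expr.index
    for name, sig in signatures.items():
        genes = sig.genes if isinstance(sig, SignatureSet) else list(sig)
        present = [g for g in genes if g in gene_index]
        if len(present) < 2:
            missing = sorted(set(genes) - set(gene_index))
            raise ValueError(
                f"signature {name!r} has {len(present)} gene(s) in the matrix; "
                f"missing: {missing[:10]}{'...' if len(missing) > 10 else ''}")
        in_set = gene_index.isin(present)
        scores[name] = [
            _ssgsea_sample(expr[col], in_set, alpha) for col in expr.columns
        ]
    out = pd.DataFrame(scores, index=expr.columns)
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng > 0:
            out = out / rng
    return out


def assign_samples_to_ecosystem(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each sample to its argmax-score ecosystem.

    Returns a DataFrame with ``ecosystem`` (None on exact ties, logged) and the
    ``margin`` between the top two scores.
    """
    records = []
    for sample, row in scores.iterrows():
        ordered = row.sort_values(ascending=False)
        top = ordered.iloc[0]
        winners = list(ordered.index[ordered == top])
        margin = float(top - ordered.iloc[1]) if len(ordered) > 1 else np.inf
        if len(winners) > 1:
            logger.warning("sample %s: tied ecosystem scores %s; unassigned",
                           sample, winners)
            records.append({"ecosystem": None, "margin": 0.0})
        else:
            records.append({"ecosystem": winners[0], "margin": margin})
    return pd.DataFrame(records, index=scores.index)
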