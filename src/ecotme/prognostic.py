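"""Machine-learning prognostic framework: 126 selector/modeler combinations.

Eleven survival algorithms — LASSO, Elastic Net over nine mixing values, ridge,
Random Survival Forest (RSF), CoxBoost-style componentwise boosting, stepwise
Cox in three directions, SuperPC, PLS-Cox, survival SVM, gradient-boosted Cox
trees (GBM), and a bootstrap-stability Kang-style score — give 21 modeling
variants. The five screening-capable algorithms (LASSO, Kang score, RSF,
StepCox, CoxBoost) are each paired with every modeling variant, and every
variant also runs standalone: 5 x 21 + 21 = 126 combinations. Each combination
is fitted on a training cohort, scored on validation cohorts with Harrell's
C-index, and the leaderboard's best model with at most 15 genes is selected.

Gene expression enters z-scored per cohort; "model size" is the number of
genes with nonzero contribution (nonzero coefficients for linear models,
features actually used in splits for forest/boosted-tree models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import (
    ComponentwiseGradientBoostingSurvivalAnalysis,
    GradientBoostingSurvivalAnalysis,
    RandomSurvivalForest,
)
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.svm import FastSurvivalSVM
from sksurv.util import Surv

from .survival import bh_fdr, fit_cox, harrell_c, univariate_cox_scan

logger = logging.getLogger(__name__)

__all__ = [
    "AlgorithmSpec",
    "CombinationTemplate",
    "FittedCombination",
    "default_registry",
    "enumerate_combinations",
    "screen_degs",
    "split_train_validation",
    "fit_combination",
    "build_leaderboard",
    "select_optimal",
    "compute_risk_score",
    "cross_validate",
    "PrognosticModelSearch",
    "ModelSearchResults",
]

SCREEN_CAPABLE = {"LASSO", "KangScore", "RSF", "StepCox", "CoxBoost"}
ENET_ALPHAS = tuple(round(0.1 * i, 1) for i in range(1, 10))
STEPCOX_DIRECTIONS = ("forward", "backward", "both")


@dataclass(frozen=True)
class AlgorithmSpec:
    name: str
    role: str  # "screen", "model", or "both"
    hyperparams: dict = field(default_factory=dict, hash=False)


def default_registry() -> list[AlgorithmSpec]:
    names = ["LASSO", "Enet", "ridge", "RSF", "CoxBoost", "StepCox",
             "SuperPC", "plsRcox", "survivalSVM", "GBM", "KangScore"]
    return [AlgorithmSpec(n, "both" if n in SCREEN_CAPABLE else "model")
            for n in names]


@dataclass(frozen=True)
class CombinationTemplate:
    selector: str | None
    modeler: str
    modeler_params: tuple = ()

    @property
    def name(self) -> str:
        mod = self.modeler
        if self.modeler_params:
            mod += "(" + ",".join(str(v) for _, v in self.modeler_params) + ")"
        return f"{self.selector or 'none'}+{mod}"


def _modeling_variants(names: set[str]) -> list[tuple[str, tuple]]:
    variants: list[tuple[str, tuple]] = []
    for name in sorted(names):
        if name == "Enet":
            variants += [("Enet", (("alpha", a),)) for a in ENET_ALPHAS]
        elif name == "StepCox":
            variants += [("StepCox", (("direction", d),)) for d in STEPCOX_DIRECTIONS]
        else:
            variants.append((name, ()))
    return variants


def enumerate_combinations(registry: list[AlgorithmSpec]) -> list[CombinationTemplate]:
    """Expand a registry into selector x modeler combination templates.

    Enet expands to nine mixing values, StepCox to three directions; every
    screening-capable algorithm pairs with every modeling variant, and every
    variant also stands alone. The full 11-algorithm registry yields 126.
    """
    names = [s.name for s in registry]
    if len(names) != len(set(names)):
        raise ValueError("duplicate algorithm names in registry")
    variants = _modeling_variants(set(names))
    screeners = sorted(n for n in names if n in SCREEN_CAPABLE)
    templates = [CombinationTemplate(None, m, p) for m, p in variants]
    for s in screeners:
        templates += [CombinationTemplate(s, m, p) for m, p in variants]
    return templates


# ---------------------------------------------------------------------------
# DEG screening and data splitting
# ---------------------------------------------------------------------------

def screen_degs(expr: pd.DataFrame, groups: pd.Series, surv: pd.DataFrame,
                high_risk_label: str, fc_threshold: float = 1.5,
                fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Screen prognostic DEGs between the high-risk group and the rest.

    Fold change is computed on log-scale expression as the difference of group
    means, reported as a linear ratio; genes need |FC| > ``fc_threshold``, a
    Wilcoxon rank-sum BH-FDR < ``fdr_threshold``, and a direction-consistent
    univariate Cox fit (up in the high-risk group => HR > 1, up elsewhere =>
    HR < 1). Returns the per-gene screening table restricted to survivors; an
    empty result raises with per-filter attrition counts.
    """
    samples = expr.columns.intersection(surv.index)
    groups = pd.Series(groups).reindex(samples)
    high = groups == high_risk_label
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("both the high-risk group and the rest must be non-empty")
    X = expr[samples]
    mean_high = X.loc[:, high.to_numpy()].mean(axis=1)
    mean_rest = X.loc[:, (~high).to_numpy()].mean(axis=1)
    ratio = np.power(2.0, mean_high - mean_rest)
    pvals = np.array([
        ranksums(row[high.to_numpy()], row[(~high).to_numpy()]).pvalue
        for row in X.to_numpy()
    ])
    fdr = bh_fdr(pvals)
    scan = univariate_cox_scan(surv.loc[samples, "time"].to_numpy(),
                               surv.loc[samples, "event"].to_numpy(), X.T)
    hr = np.exp(scan["beta"])

    fc_pass = (ratio > fc_threshold) | (ratio < 1.0 / fc_threshold)
    fdr_pass = fdr < fdr_threshold
    direction = np.where(ratio > 1.0, hr > 1.0, hr < 1.0)
    keep = fc_pass.to_numpy() & fdr_pass & direction
    table = pd.DataFrame({
        "fold_change": ratio, "p": pvals, "fdr": fdr,
        "hr": hr, "beta": scan["beta"], "selected": keep,
    }, index=expr.index)
    if not keep.any():
        raise ValueError(
            "no genes survive screening "
            f"(FC pass: {int(fc_pass.sum())}, FDR pass: {int(fdr_pass.sum())}, "
            f"direction pass: {int(direction.sum())})")
    return table.loc[keep]


def split_train_validation(surv: pd.DataFrame, frac: float = 0.7,
                           seed: int = 0) -> tuple[pd.Index, pd.Index]:
    """Event-stratified random split of samples into train/internal-validation."""
    rng = np.random.default_rng(seed)
    n_train_total = int(round(frac * len(surv)))
    for attempt in range(10):
        # largest-remainder allocation across event strata
        strata = [grp.index.to_numpy().copy()
                  for _, grp in surv.groupby(surv["event"])]
        quotas = [frac * len(ids) for ids in strata]
        base = [int(np.floor(q)) for q in quotas]
        for i in sorted(range(len(strata)), key=lambda i: quotas[i] - base[i],
                        reverse=True):
            if sum(base) >= n_train_total:
                break
            base[i] += 1
        train_idx: list = []
        for ids, n_train in zip(strata, base):
            rng.shuffle(ids)
            train_idx.extend(ids[:n_train])
        train = pd.Index(train_idx)
        valid = surv.index.difference(train)
        if surv.loc[train, "event"].sum() > 0 and surv.loc[valid, "event"].sum() > 0:
            return surv.index.intersection(train), valid
    raise ValueError("could not produce a split with events on both sides")


# ---------------------------------------------------------------------------
# fitted combinations
# ---------------------------------------------------------------------------

@dataclass
class FittedCombination:
    template: CombinationTemplate
    genes: list[str]
    coefficients: pd.Series | None
    predict: Callable[[pd.DataFrame], np.ndarray] | None
    model_size: int
    status: str = "ok"
    reason: str = ""

    @property
    def name(self) -> str:
        return self.template.name


def _zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene (row) within a cohort; constant genes stay 0."""
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=0).replace(0.0, 1.0)
    return expr.sub(mu, axis=0).div(sd, axis=0)


def _surv_y(surv: pd.DataFrame):
    return Surv.from_arrays(event=surv["event"].astype(bool).to_numpy(),
                            time=surv["time"].to_numpy())


def _linear_predictor(coef: pd.Series) -> Callable[[pd.DataFrame], np.ndarray]:
    def predict(X: pd.DataFrame) -> np.ndarray:
        return X[list(coef.index)].to_numpy() @ coef.to_numpy()
    return predict


def _cindex_of(risk: np.ndarray, surv: pd.DataFrame) -> float:
    return harrell_c(surv, np.asarray(risk, dtype=float))


def _cv_folds(surv: pd.DataFrame, n_splits: int, seed: int):
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    idx = np.arange(len(surv))
    return list(skf.split(idx, surv["event"].to_numpy()))


def _fit_coxnet(X: pd.DataFrame, surv: pd.DataFrame, l1_ratio: float,
                seed: int) -> pd.Series:
    """Coxnet fit with the penalty weight chosen by 3-fold C-index CV."""
    y = _surv_y(surv)
    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alpha_min_ratio=0.01,
                                  n_alphas=25, max_iter=20000)
    path.fit(X.to_numpy(), y)
    alphas = path.alphas_
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for tr, te in _cv_folds(surv, 3, seed):
        fold = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas,
                                      max_iter=20000)
        fold.fit(X.iloc[tr].to_numpy(), _surv_y(surv.iloc[tr]))
        for j, a in enumerate(fold.alphas_):
            risk = fold.predict(X.iloc[te].to_numpy(), alpha=a)
            try:
                scores[j] += _cindex_of(risk, surv.iloc[te])
                counts[j] += 1
            except ValueError:
                continue
    with np.errstate(invalid="ignore"):
        mean_scores = np.where(counts > 0, scores / np.maximum(counts, 1), -np.inf)
    best = alphas[int(np.argmax(mean_scores))]
    final = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=[best], max_iter=20000)
    final.fit(X.to_numpy(), y)
    return pd.Series(final.coef_[:, 0], index=X.columns)


def _stepwise_cox(X: pd.DataFrame, surv: pd.DataFrame, direction: str,
                  alpha_enter: float = 0.05, alpha_remove: float = 0.05,
                  max_start: int = 25) -> pd.Series:
    """P-value-driven stepwise Cox selection; returns coefficients of the final fit."""
    data = pd.concat([surv[["time", "event"]], X], axis=1)
    genes = list(X.columns)
    if direction in ("backward",) and len(genes) > max_start:
        scan = univariate_cox_scan(surv["time"].to_numpy(),
                                   surv["event"].to_numpy(), X)
        genes = list(scan["p"].sort_values().index[:max_start])

    def wald_p(model_genes: list[str]) -> pd.Series:
        return fit_cox(data, model_genes).p

    if direction == "backward":
        current = list(genes)
        while len(current) > 1:
            p = wald_p(current)
            worst = p.idxmax()
            if p[worst] <= alpha_remove:
                break
            current.remove(worst)
        selected = current
    else:  # forward or both
        current: list[str] = []
        remaining = list(genes)
        while remaining:
            best_gene, best_p = None, 1.0
            for g in remaining:
                try:
                    p = wald_p(current + [g])[g]
                except (ValueError, np.linalg.LinAlgError):
                    continue
                if p < best_p:
                    best_gene, best_p = g, p
            if best_gene is None or best_p >= alpha_enter:
                break
            current.append(best_gene)
            remaining.remove(best_gene)
            if direction == "both" and len(current) > 1:
                while len(current) > 1:
                    p = wald_p(current)
                    worst = p.idxmax()
                    if p[worst] <= alpha_remove:
                        break
                    current.remove(worst)
                    if worst in genes and worst not in remaining:
                        remaining.append(worst)
        selected = current
    if not selected:
        return pd.Series(dtype=float)
    fit = fit_cox(data, selected)
    return fit.beta


def _kang_stability(X: pd.DataFrame, surv: pd.DataFrame, seed: int,
                    n_boot: int = 100, p_cut: float = 0.05,
                    stability: float = 0.8) -> tuple[list[str], pd.Series]:
    """Bootstrap-stability univariate-Cox screening (Kang-style).

    Genes significant (p < ``p_cut``) in at least ``stability`` of ``n_boot``
    bootstrap resamples are kept; the score direction is the sign of the
    full-data univariate coefficient.
    """
    rng = np.random.default_rng(seed)
    t = surv["time"].to_numpy()
    d = surv["event"].to_numpy()
    hits = np.zeros(X.shape[1])
    done = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(t), size=len(t))
        if d[idx].sum() < 2:
            continue
        scan = univariate_cox_scan(t[idx], d[idx], X.iloc[idx])
        hits += (scan["p"] < p_cut).to_numpy()
        done += 1
    frac = hits / max(done, 1)
    keep = list(X.columns[frac >= stability])
    full = univariate_cox_scan(t, d, X)
    signs = np.sign(full["beta"]).replace(0.0, 1.0)
    return keep, signs


def _null_deviance_residuals(surv: pd.DataFrame) -> np.ndarray:
    """Deviance residuals of the null Cox model (Nelson-Aalen baseline)."""
    t = surv["time"].to_numpy(dtype=float)
    d = surv["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    n = len(t)
    at_risk = n - np.arange(n)
    increments = d[order] / at_risk
    cumhaz_sorted = np.cumsum(increments)
    cumhaz = np.empty(n)
    cumhaz[order] = cumhaz_sorted
    martingale = d - cumhaz
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(d > 0, d * np.log(np.clip(d - martingale, 1e-12, None)), 0.0)
    dev = np.sign(martingale) * np.sqrt(np.clip(-2 * (martingale + logterm), 0, None))
    return dev


def _tree_features_used(estimators, columns) -> list[str]:
    used: set[int] = set()
    for est in estimators:
        tree = est.tree_ if hasattr(est, "tree_") else est
        feats = tree.feature[tree.feature >= 0]
        used.update(int(f) for f in feats)
    return [columns[i] for i in sorted(used)]


def _fit_modeler(name: str, params: dict, X: pd.DataFrame, surv: pd.DataFrame,
                 seed: int) -> tuple[pd.Series | None, Callable, list[str]]:
    """Fit one modeling variant; returns (coefficients, predictor, genes_used)."""
    y = _surv_y(surv)
    if name == "LASSO":
        coef = _fit_coxnet(X, surv, l1_ratio=1.0, seed=seed)
    elif name == "Enet":
        coef = _fit_coxnet(X, surv, l1_ratio=float(params["alpha"]), seed=seed)
    elif name == "ridge":
        coef = _fit_coxnet(X, surv, l1_ratio=0.01, seed=seed)
        coef[coef == 0] = 1e-12  # ridge keeps every gene in the model
    elif name == "StepCox":
        coef = _stepwise_cox(X, surv, params["direction"])
        if coef.empty:
            return None, None, []
    elif name == "KangScore":
        keep, signs = _kang_stability(X, surv, seed)
        if not keep:
            return None, None, []
        coef = pd.Series({g: float(signs[g]) for g in keep})
    elif name == "CoxBoost":
        best_n, best_c = 100, -np.inf
        for n_est in (50, 100, 200):
            cs = []
            for tr, te in _cv_folds(surv, 3, seed):
                m = ComponentwiseGradientBoostingSurvivalAnalysis(
                    loss="coxph", n_estimators=n_est, learning_rate=0.1,
                    random_state=seed)
                m.fit(X.iloc[tr].to_numpy(), _surv_y(surv.iloc[tr]))
                try:
                    cs.append(_cindex_of(m.predict(X.iloc[te].to_numpy()),
                                         surv.iloc[te]))
                except ValueError:
                    continue
            if cs and np.mean(cs) > best_c:
                best_n, best_c = n_est, float(np.mean(cs))
        model = ComponentwiseGradientBoostingSurvivalAnalysis(
            loss="coxph", n_estimators=best_n, learning_rate=0.1, random_state=seed)
        model.fit(X.to_numpy(), y)
        coef_arr = np.asarray(model.coef_).ravel()
        if len(coef_arr) == X.shape[1] + 1:  # leading intercept term
            coef_arr = coef_arr[1:]
        coef = pd.Series(coef_arr, index=X.columns)
    elif name == "RSF":
        model = RandomSurvivalForest(n_estimators=500, min_samples_leaf=20,
                                     max_features="sqrt", max_samples=0.5,
                                     random_state=seed, n_jobs=1)
        model.fit(X.to_numpy(), y)
        genes = _tree_features_used(model.estimators_, list(X.columns))
        order = list(X.columns)

        def predict_rsf(Xn: pd.DataFrame) -> np.ndarray:
            return model.predict(Xn[order].to_numpy())
        predict_rsf.input_genes = order
        return None, predict_rsf, genes
    elif name == "GBM":
        model = GradientBoostingSurvivalAnalysis(
            loss="coxph", max_depth=2, learning_rate=0.01, n_estimators=500,
            n_iter_no_change=10, validation_fraction=0.2, random_state=seed)
        model.fit(X.to_numpy(), y)
        importances = model.feature_importances_
        genes = [g for g, imp in zip(X.columns, importances) if imp > 0]
        order = list(X.columns)

        def predict_gbm(Xn: pd.DataFrame) -> np.ndarray:
            return model.predict(Xn[order].to_numpy())
        predict_gbm.input_genes = order
        return None, predict_gbm, genes
    elif name == "SuperPC":
        best = None
        for thr in (1.5, 2.0, 2.5):
            for n_comp in (1, 2, 3):
                cs = []
                for tr, te in _cv_folds(surv, 3, seed):
                    try:
                        pred = _superpc_fit(X.iloc[tr], surv.iloc[tr], thr,
                                            n_comp)
                        cs.append(_cindex_of(pred(X.iloc[te]), surv.iloc[te]))
                    except ValueError:
                        continue
                if cs and (best is None or np.mean(cs) > best[0]):
                    best = (float(np.mean(cs)), thr, n_comp)
        if best is None:
            return None, None, []
        _, thr, n_comp = best
        pred = _superpc_fit(X, surv, thr, n_comp)
        return None, pred, pred.genes
    elif name == "plsRcox":
        resid = _null_deviance_residuals(surv)
        n_comp = min(2, X.shape[1])
        pls = PLSRegression(n_components=n_comp)
        pls.fit(X.to_numpy(), resid)
        w = pls.coef_.ravel()
        coef = pd.Series(w, index=X.columns)
    elif name == "survivalSVM":
        model = FastSurvivalSVM(rank_ratio=1.0, max_iter=100, random_state=seed)
        model.fit(X.to_numpy(), y)
        coef = pd.Series(model.coef_, index=X.columns)
    else:
        raise ValueError(f"unknown modeler {name!r}")
    nz = coef[coef != 0]
    if nz.empty:
        return None, None, []
    return nz, _linear_predictor(nz), list(nz.index)


def _superpc_fit(X: pd.DataFrame, surv: pd.DataFrame, z_threshold: float,
                 n_components: int):
    """Supervised PCA: univariate-z screen, PCA, Cox on the leading components."""
    scan = univariate_cox_scan(surv["time"].to_numpy(),
                               surv["event"].to_numpy(), X)
    genes = list(scan.index[np.abs(scan["z"]) > z_threshold])
    if len(genes) < max(2, n_components):
        raise ValueError("SuperPC screen left too few genes")
    pca = PCA(n_components=min(n_components, len(genes)))
    comps = pca.fit_transform(X[genes].to_numpy())
    comp_cols = [f"pc{i + 1}" for i in range(comps.shape[1])]
    data = pd.concat([surv[["time", "event"]].reset_index(drop=True),
                      pd.DataFrame(comps, columns=comp_cols)], axis=1)
    fit = fit_cox(data, comp_cols)

    def predict(Xn: pd.DataFrame) -> np.ndarray:
        proj = pca.transform(Xn[genes].to_numpy())
        return proj @ fit.beta.to_numpy()
    predict.genes = genes
    predict.input_genes = genes
    return predict


def _select_genes(selector: str, X: pd.DataFrame, surv: pd.DataFrame,
                  seed: int) -> list[str]:
    """Run a screening-capable algorithm in its variable-selection role."""
    if selector == "LASSO":
        coef = _fit_coxnet(X, surv, l1_ratio=1.0, seed=seed)
        return list(coef[coef != 0].index)
    if selector == "KangScore":
        keep, _ = _kang_stability(X, surv, seed)
        return keep
    if selector == "StepCox":
        coef = _stepwise_cox(X, surv, "both")
        return list(coef.index)
    if selector == "CoxBoost":
        coef, _, genes = _fit_modeler("CoxBoost", {}, X, surv, seed)
        return [] if coef is None else list(coef.index)
    if selector == "RSF":
        model = RandomSurvivalForest(n_estimators=300, min_samples_leaf=20,
                                     max_features="sqrt", max_samples=0.5,
                                     random_state=seed, n_jobs=1)
        y = _surv_y(surv)
        sub = np.random.default_rng(seed).choice(
            len(X), size=min(len(X), 300), replace=False)
        model.fit(X.to_numpy(), y)
        imp = permutation_importance(model, X.iloc[sub].to_numpy(),
                                     y[sub], n_repeats=3, random_state=seed)
        return [g for g, m in zip(X.columns, imp.importances_mean) if m > 0]
    raise ValueError(f"{selector!r} is not screening-capable")


def fit_combination(template: CombinationTemplate, train_expr: pd.DataFrame,
                    train_surv: pd.DataFrame, seed: int = 0,
                    selector_cache: dict | None = None) -> FittedCombination:
    """Fit one selector+modeler combination on the training cohort.

    ``train_expr`` is genes x samples; genes are z-scored within the cohort.
    A selector that leaves fewer than 2 genes marks the combination failed.
    ``selector_cache`` lets callers reuse each selector's gene set across the
    21 modelers it pairs with.
    """
    X = _zscore_genes(train_expr).T  # samples x genes
    X = X.loc[train_surv.index]
    if template.selector is not None:
        cache = selector_cache if selector_cache is not None else {}
        if template.selector not in cache:
            cache[template.selector] = _select_genes(template.selector, X,
                                                     train_surv, seed)
        genes = cache[template.selector]
        if len(genes) < 2:
            return FittedCombination(template, [], None, None, 0,
                                     status="failed",
                                     reason=f"selector left {len(genes)} genes")
        X = X[genes]
    coef, predictor, genes_used = _fit_modeler(template.modeler,
                                               dict(template.modeler_params),
                                               X, train_surv, seed)
    if predictor is None:
        return FittedCombination(template, [], None, None, 0,
                                 status="failed", reason="modeler kept no genes")
    return FittedCombination(template, genes_used, coef, predictor,
                             model_size=len(genes_used))


def compute_risk_score(model: FittedCombination, expr: pd.DataFrame,
                       missing_warn: bool = True) -> pd.Series:
    """Per-sample risk score of a fitted combination on a cohort (genes x samples).

    Genes are z-scored within the cohort; genes absent from the cohort are
    imputed at the cohort mean (zero after z-scoring) with a warning. More than
    50% missing raises.
    """
    if model.predict is None:
        raise ValueError(f"{model.name} is not fitted")
    needed = (list(model.coefficients.index) if model.coefficients is not None
              else list(getattr(model.predict, "input_genes", model.genes)))
    missing = [g for g in needed if g not in expr.index]
    if len(needed) > 0 and len(missing) > 0.5 * len(needed):
        raise ValueError(f"{model.name}: {len(missing)}/{len(needed)} genes missing")
    if missing and missing_warn:
        logger.warning("%s: imputing %d missing genes at cohort mean",
                       model.name, len(missing))
    Z = _zscore_genes(expr).T
    for g in missing:
        Z[g] = 0.0  # cohort mean after z-scoring
    risk = model.predict(Z)
    return pd.Series(np.asarray(risk, dtype=float), index=Z.index)


def build_leaderboard(models: list[FittedCombination],
                      cohorts: list[tuple[str, pd.DataFrame, pd.DataFrame]],
                      ) -> pd.DataFrame:
    """C-index of every fitted combination on every validation cohort.

    Returns one row per combination with per-cohort C, the arithmetic mean over
    validation cohorts, model size and status; failed combinations appear with
    NaN scores and their failure reason.
    """
    rows = []
    for model in models:
        row = {"combination": model.name, "model_size": model.model_size,
               "status": model.status, "reason": model.reason}
        cs = []
        for name, expr, surv in cohorts:
            c = np.nan
            if model.status == "ok":
                try:
                    risk = compute_risk_score(model, expr, missing_warn=False)
                    c = harrell_c(surv, risk.loc[surv.index])
                except ValueError as exc:
                    logger.warning("%s on %s skipped: %s", model.name, name, exc)
            row[f"C_{name}"] = c
            if not np.isnan(c):
                cs.append(c)
        row["mean_C"] = float(np.mean(cs)) if cs else np.nan
        rows.append(row)
    board = pd.DataFrame(rows).set_index("combination")
    return board.sort_values("mean_C", ascending=False)


def select_optimal(board: pd.DataFrame, models: list[FittedCombination] | None = None,
                   max_size: int = 15) -> tuple[str, bool]:
    """Pick the highest mean-C combination with at most ``max_size`` genes.

    Ties resolve to the smaller model, then lexicographic name. If no model
    satisfies the bound, the best overall is returned with the
    constraint-violated flag set. Returns ``(combination_name, size_ok)``.
    """
    if board.empty:
        raise ValueError("empty leaderboard")
    ok = board[(board["status"] == "ok") & board["mean_C"].notna()]
    if ok.empty:
        raise ValueError("no successfully fitted models on the leaderboard")
    within = ok[ok["model_size"] <= max_size]
    pool, size_ok = (within, True) if not within.empty else (ok, False)
    if not size_ok:
        logger.warning("CONSTRAINT VIOLATED: no model with <= %d genes; "
                       "returning best overall", max_size)
    ranked = pool.sort_values(["mean_C", "model_size"],
                              ascending=[False, True], kind="stable")
    top_c = ranked["mean_C"].iloc[0]
    tied = ranked[ranked["mean_C"] == top_c]
    min_size = tied["model_size"].min()
    finalists = sorted(tied[tied["model_size"] == min_size].index)
    return finalists[0], size_ok


def cross_validate(template: CombinationTemplate, expr: pd.DataFrame,
                   surv: pd.DataFrame, folds: int = 10, seed: int = 0
                   ) -> pd.DataFrame:
    """Event-stratified k-fold cross-validation of one combination template.

    Per fold: fit on the remaining folds, score the held-out fold (Harrell C),
    and record the R-squared between held-out risk scores and the full-data
    model's risk scores on those samples.
    """
    full = fit_combination(template, expr, surv, seed=seed)
    if full.status != "ok":
        raise ValueError(f"template failed on the full data: {full.reason}")
    full_risk = compute_risk_score(full, expr, missing_warn=False)
    rows = []
    for i, (tr, te) in enumerate(_cv_folds(surv, folds, seed)):
        tr_ids, te_ids = surv.index[tr], surv.index[te]
        if surv.loc[te_ids, "event"].sum() == 0:
            raise ValueError(f"fold {i} has no events")
        fit = fit_combination(template, expr[tr_ids], surv.loc[tr_ids], seed=seed)
        if fit.status != "ok":
            rows.append({"fold": i, "C": np.nan, "R2": np.nan})
            continue
        risk = compute_risk_score(fit, expr[te_ids], missing_warn=False)
        c = harrell_c(surv.loc[te_ids], risk)
        ref = full_risk.loc[te_ids].to_numpy()
        pred = risk.to_numpy()
        ss_res = float(((ref - pred) ** 2).sum())
        ss_tot = float(((ref - ref.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        rows.append({"fold": i, "C": c, "R2": r2})
    return pd.DataFrame(rows).set_index("fold")


# ---------------------------------------------------------------------------
# model-search front end
# ---------------------------------------------------------------------------

class PrognosticModelSearch:
    """Search over selector/modeler combinations for a prognostic gene model.

    Parameters
    ----------
    train_expr, train_surv:
        Training cohort: genes x samples log-scale expression and a survival
        table (time, event) indexed by sample.
    validation_cohorts:
        List of ``(name, expr, surv)`` validation cohorts for the leaderboard.
    registry:
        Algorithm registry; defaults to the full 11-algorithm set (126
        combinations).
    """

    def __init__(self, train_expr: pd.DataFrame, train_surv: pd.DataFrame,
                 validation_cohorts: list[tuple[str, pd.DataFrame, pd.DataFrame]],
                 registry: list[AlgorithmSpec] | None = None):
        self.train_expr = train_expr
        self.train_surv = train_surv.loc[train_expr.columns.intersection(train_surv.index)]
        self.validation_cohorts = validation_cohorts
        self.registry = registry or default_registry()
        self.templates = enumerate_combinations(self.registry)

    def fit(self, seed: int = 0, max_size: int = 15) -> "ModelSearchResults":
        cache: dict = {}
        fitted = []
        for template in self.templates:
            try:
                fitted.append(fit_combination(template, self.train_expr,
                                              self.train_surv, seed=seed,
                                              selector_cache=cache))
            except (ValueError, np.linalg.LinAlgError) as exc:
                fitted.append(FittedCombination(template, [], None, None, 0,
                                                status="failed", reason=str(exc)))
        board = build_leaderboard(fitted, self.validation_cohorts)
        return ModelSearchResults(self, fitted, board, max_size=max_size)


class ModelSearchResults:
    """Leaderboard of fitted combinations plus the size-constrained optimum."""

    def __init__(self, model: PrognosticModelSearch,
                 fitted: list[FittedCombination], board: pd.DataFrame,
                 max_size: int = 15):
        self.model = model
        self.fitted = {f.name: f for f in fitted}
        self.leaderboard = board
        self.max_size = max_size
        name, size_ok = select_optimal(board, max_size=max_size)
        self.optimal_name = name
        self.size_constraint_met = size_ok

    @property
    def optimal(self) -> FittedCombination:
        return self.fitted[self.optimal_name]

    def risk_scores(self, expr: pd.DataFrame) -> pd.Series:
        return compute_risk_score(self.optimal, expr)

    def summary(self, top: int = 10) -> pd.DataFrame:
        cols = [c for c in self.leaderboard.columns if c != "reason"]
        out = self.leaderboard[cols].head(top).copy()
        out.attrs["optimal"] = self.optimal_name
        return out
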