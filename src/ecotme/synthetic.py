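"""Seeded synthetic cohorts with planted ground truth.

Every downstream stage of the pipeline (cellular-module detection, meta-program
consolidation, Ro/e enrichment, ecosystem scoring, prognostic model selection)
can be exercised against cohorts in which the answer is planted:

* cell cohorts whose cluster abundances co-vary in blocks (cellular modules),
* per-sample gene-expression-program matrices containing noisy copies of shared
  archetype programs plus low-usage private noise programs (meta-programs),
* ligand-receptor count tables with multiplicative enrichment on chosen cells,
* bulk expression with ecosystem-specific gene blocks and survival times drawn
  from a proportional-hazards model over planted prognostic genes.

All generators are pure functions of ``(config, seed)``: the global seed is
expanded into per-generator substreams by fixed offsets, so each stage is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "GEPMatrices",
    "generate_cell_cohort",
    "generate_sample_geps",
    "generate_bulk_survival",
    "generate_lr_counts",
    "generate_abundance_profiles",
    "generate_type_marker_expression",
]

# Fixed substream offsets: one per generator stage.
_SUB_COHORT = 11
_SUB_GEPS = 23
_SUB_BULK = 37
_SUB_LR = 53
_SUB_PROFILES = 67
_SUB_MARKERS = 79


class InvalidConfigError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generators.

    Defaults are the study conditions the pipeline is validated under: 60
    samples x 40 immune clusters with 4 planted cellular modules; 20 tumor
    samples x 8 programs with 6 shared meta-program archetypes; 4 ecosystems;
    bulk cohorts with 5 planted prognostic genes (|log HR| = 0.7 per SD) and
    ~30% censoring.
    """

    seed: int = 0
    n_samples: int = 60
    n_clusters: int = 40
    n_planted_modules: int = 4
    n_cells_per_sample: tuple[int, int] = (1500, 3000)
    n_genes: int = 1000
    n_programs_per_sample: int = 8
    n_planted_mps: int = 6
    n_bulk_samples: int = 400
    n_prognostic_genes: int = 5
    effect_size: float = 0.7
    censoring_rate: float = 0.3
    noise_sd: float = 0.1
    # plumbing knobs beyond the core field list
    module_boost: float = 5.0
    epithelial_fraction: float = 0.4
    n_ecosystems: int = 4
    ecosystem_shift: float = 1.5
    n_lr_pairs: int = 40
    n_lr_groups: int = 4
    lr_boost: float = 3.0

    def __post_init__(self) -> None:
        if self.n_planted_modules > self.n_clusters:
            raise InvalidConfigError("n_planted_modules must be <= n_clusters")
        if self.n_planted_mps > self.n_programs_per_sample:
            raise InvalidConfigError("n_planted_mps must be <= n_programs_per_sample")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise InvalidConfigError("censoring_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        lo, hi = self.n_cells_per_sample
        if lo < 1 or hi < lo:
            raise InvalidConfigError("n_cells_per_sample must be a valid (lo, hi) range")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, the oracle for recovery tests."""

    cluster_to_module: dict[str, str] = field(default_factory=dict)
    gene_to_mp: dict[str, str] = field(default_factory=dict)
    prognostic_genes: list[tuple[str, int]] = field(default_factory=list)
    sample_ecosystem: dict[str, str] = field(default_factory=dict)
    enriched_pairs: list[tuple[str, str]] = field(default_factory=list)
    # auxiliary truth used by stage-specific checks
    sample_dominant_module: dict[str, str] = field(default_factory=dict)
    program_to_mp: dict[tuple[str, str], str | None] = field(default_factory=dict)
    component_to_ecosystem: dict[str, str] = field(default_factory=dict)
    ecosystem_genes: dict[str, list[str]] = field(default_factory=dict)
    high_risk_ecosystem: str | None = None
    type_markers: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class GEPMatrices:
    """Per-sample NMF output: row-stochastic usage and nonnegative loadings."""

    sample_id: str
    usage: pd.DataFrame      # cells x programs, rows sum to 1
    loadings: pd.DataFrame   # genes x programs, nonnegative


def _rng(config: SyntheticConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), offset])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# cell cohort with planted cellular modules
# ---------------------------------------------------------------------------

def generate_cell_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a cell annotation table whose cluster abundances co-vary in modules.

    Each sample draws a dominant planted module; the Dirichlet concentration of
    that module's clusters is multiplied by ``module_boost`` (default x5 over a
    base of 1.0), producing block-structured co-occurrence across samples.
    Epithelial cells are appended per sample so that the non-epithelial cell
    filter is exercised.
    """
    if config.n_planted_modules < 2:
        raise InvalidConfigError("need at least 2 planted modules")
    if config.n_clusters < 2 * config.n_planted_modules:
        raise InvalidConfigError("each planted module needs at least 2 clusters")
    rng = _rng(config, _SUB_COHORT)

    clusters = [f"c{i:02d}" for i in range(config.n_clusters)]
    modules = [f"M{i + 1}" for i in range(config.n_planted_modules)]
    cluster_to_module = {c: modules[i % len(modules)] for i, c in enumerate(clusters)}
    module_members = {
        m: np.array([i for i, c in enumerate(clusters) if cluster_to_module[c] == m])
        for m in modules
    }

    lo, hi = config.n_cells_per_sample
    frames = []
    truth = PlantedTruth(cluster_to_module=cluster_to_module)
    for s in range(config.n_samples):
        sample = f"s{s:03d}"
        dominant = modules[int(rng.integers(len(modules)))]
        truth.sample_dominant_module[sample] = dominant
        alpha = np.ones(config.n_clusters)
        alpha[module_members[dominant]] *= config.module_boost
        props = rng.dirichlet(alpha)
        n_cells = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(n_cells, props)
        n_epi = int(rng.poisson(config.epithelial_fraction * n_cells))
        cluster_col = np.repeat(clusters, counts).tolist() + ["epithelial"] * n_epi
        n_total = n_cells + n_epi
        frames.append(pd.DataFrame({
            "cell_id": [f"{sample}_cell{j:05d}" for j in range(n_total)],
            "sample_id": sample,
            "cluster_id": cluster_col,
            "cell_type": [f"ct{c[1:]}" if c != "epithelial" else "epithelial"
                          for c in cluster_col],
            "is_epithelial": [c == "epithelial" for c in cluster_col],
        }))
    table = pd.concat(frames, ignore_index=True)
    return table, truth


# ---------------------------------------------------------------------------
# per-sample GEP matrices with shared archetypes
# ---------------------------------------------------------------------------

def generate_sample_geps(config: SyntheticConfig) -> tuple[list[GEPMatrices], PlantedTruth]:
    """Generate per-sample usage/loading pairs containing shared MP archetypes.

    Each archetype owns a dedicated block of high-loading genes on top of a
    sparse background. Samples carry noisy copies of the archetypes (additive
    Gaussian noise of sd ``noise_sd``, clipped at zero) plus sample-private
    noise programs whose mean cell usage is kept below the 0.01 retention
    threshold.
    """
    if config.n_genes < 200:
        raise InvalidConfigError("n_genes must be >= 200 (top-100 aggregation headroom)")
    rng = _rng(config, _SUB_GEPS)
    genes = _gene_ids(config.n_genes)
    n_mp = config.n_planted_mps
    block = 50

    truth = PlantedTruth()
    archetypes = np.zeros((config.n_genes, n_mp))
    for m in range(n_mp):
        base = rng.exponential(0.03, size=config.n_genes)
        idx = np.arange(m * block, (m + 1) * block) % config.n_genes
        base[idx] += rng.uniform(1.0, 2.0, size=block)
        archetypes[:, m] = base
        for g in idx:
            truth.gene_to_mp[genes[g]] = f"MP{m + 1}"

    n_noise = config.n_programs_per_sample - n_mp
    lo, hi = config.n_cells_per_sample
    geps: list[GEPMatrices] = []
    for s in range(config.n_samples):
        sample = f"s{s:03d}"
        load_cols, alphas, labels = [], [], []
        order = rng.permutation(n_mp)[: min(n_mp, config.n_programs_per_sample)]
        for m in order:
            noisy = archetypes[:, m] + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            load_cols.append(np.clip(noisy, 0.0, None))
            alphas.append(1.0)
            labels.append(f"MP{m + 1}")
        for _ in range(n_noise):
            load_cols.append(rng.exponential(0.3, size=config.n_genes))
            alphas.append(0.005)
            labels.append(None)
        programs = [f"p{j}" for j in range(len(load_cols))]
        loadings = pd.DataFrame(np.column_stack(load_cols), index=genes, columns=programs)
        n_cells = int(rng.integers(lo, hi + 1))
        usage = rng.dirichlet(np.asarray(alphas), size=n_cells)
        usage /= usage.sum(axis=1, keepdims=True)
        usage_df = pd.DataFrame(
            usage, index=[f"{sample}_cell{j:05d}" for j in range(n_cells)], columns=programs)
        for p, lab in zip(programs, labels):
            truth.program_to_mp[(sample, p)] = lab
        geps.append(GEPMatrices(sample_id=sample, usage=usage_df, loadings=loadings))
    return geps, truth


# ---------------------------------------------------------------------------
# bulk expression + survival with planted prognostic genes
# ---------------------------------------------------------------------------

def _plant_ecosystem_genes(config: SyntheticConfig, rng: np.random.Generator,
                           truth: PlantedTruth) -> None:
    """Assign each ecosystem a dedicated block of signature genes and pick
    prognostic genes tied to the high-risk ecosystem."""
    genes = _gene_ids(config.n_genes)
    sig_size = 40
    ecosystems = [f"E{i + 1}" for i in range(config.n_ecosystems)]
    start = 0
    for e in ecosystems:
        truth.ecosystem_genes[e] = genes[start:start + sig_size]
        start += sig_size
    truth.high_risk_ecosystem = ecosystems[1] if len(ecosystems) > 1 else ecosystems[0]
    k = config.n_prognostic_genes
    n_pos = (k + 1) // 2
    risky = truth.ecosystem_genes[truth.high_risk_ecosystem]
    other = [g for e in ecosystems if e != truth.high_risk_ecosystem
             for g in truth.ecosystem_genes[e]]
    truth.prognostic_genes = (
        [(g, +1) for g in risky[:n_pos]]
        + [(g, -1) for g in rng.choice(other, size=k - n_pos, replace=False)]
    )


def generate_bulk_survival(
    config: SyntheticConfig, truth: PlantedTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate bulk expression (genes x samples, log scale) and survival.

    Expression is Gaussian on the log scale (log-normal on the natural scale);
    samples of an ecosystem get a mean shift of ``ecosystem_shift`` on their
    ecosystem's signature genes. Survival times follow an exponential
    proportional-hazards model with linear predictor
    ``sum(sign * effect_size * z(expr))`` over the planted prognostic genes;
    censoring is independent exponential with its rate tuned so the expected
    censored fraction matches ``censoring_rate``.

    Returns ``(expression, survival, truth)``; an existing ``truth`` (e.g. to
    share planted genes across cohorts) is reused, otherwise planted.
    """
    if config.effect_size < 0:
        raise InvalidConfigError("effect_size must be >= 0; direction is carried by the sign")
    rng = _rng(config, _SUB_BULK)
    genes = _gene_ids(config.n_genes)
    if truth is None or not truth.prognostic_genes:
        truth = truth or PlantedTruth()
        _plant_ecosystem_genes(config, rng, truth)

    samples = [f"b{config.seed}_{i:04d}" for i in range(config.n_bulk_samples)]
    ecosystems = sorted(truth.ecosystem_genes) or ["E1"]
    labels = [ecosystems[int(rng.integers(len(ecosystems)))] for _ in samples]
    for s, lab in zip(samples, labels):
        truth.sample_ecosystem[s] = lab

    expr = rng.normal(0.0, 1.0, size=(config.n_genes, config.n_bulk_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    for e in ecosystems:
        cols = [j for j, lab in enumerate(labels) if lab == e]
        rows = [gene_index[g] for g in truth.ecosystem_genes.get(e, [])]
        if cols and rows:
            expr[np.ix_(rows, cols)] += config.ecosystem_shift
    # protective prognostic genes are depleted in the high-risk ecosystem, so
    # they are genuine DEGs of the high-risk-vs-rest contrast
    hr_cols = [j for j, lab in enumerate(labels)
               if lab == truth.high_risk_ecosystem]
    neg_rows = [gene_index[g] for g, sign in truth.prognostic_genes
                if sign < 0 and g in gene_index]
    if hr_cols and neg_rows:
        expr[np.ix_(neg_rows, hr_cols)] -= config.ecosystem_shift
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)

    lp = np.zeros(config.n_bulk_samples)
    for g, sign in truth.prognostic_genes:
        x = expr_df.loc[g].to_numpy()
        z = (x - x.mean()) / x.std(ddof=0)
        lp += sign * config.effect_size * z

    base_hazard = 0.05  # per month; median ~14 months at lp = 0
    rate = base_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if config.censoring_rate <= 0:
        time, event = t_event, np.ones_like(t_event, dtype=int)
    else:
        def censored_frac(lam: float) -> float:
            return float(np.mean(lam / (lam + rate))) - config.censoring_rate
        lam_c = brentq(censored_frac, 1e-8, 1e6)
        t_cens = rng.exponential(1.0 / lam_c, size=t_event.shape)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    surv = pd.DataFrame({"time": time, "event": event}, index=samples)
    surv["ecosystem"] = labels
    return expr_df, surv, truth


# ---------------------------------------------------------------------------
# ligand-receptor counts with planted enrichment
# ---------------------------------------------------------------------------

def generate_lr_counts(config: SyntheticConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a ligand-receptor pair x group count table.

    Counts are Poisson around a product-of-margins baseline with a
    multiplicative ``lr_boost`` on planted (pair, group) cells (two pairs per
    group). ``lr_boost = 1`` gives a null table.
    """
    if config.n_lr_groups < 2:
        raise InvalidConfigError("need at least 2 groups for Ro/e")
    rng = _rng(config, _SUB_LR)
    pairs = [f"LIG{i:02d}_REC{i:02d}" for i in range(config.n_lr_pairs)]
    groups = [f"E{j + 1}" for j in range(config.n_lr_groups)]
    row_w = rng.uniform(4.0, 8.0, size=config.n_lr_pairs)
    col_w = rng.uniform(5.0, 9.0, size=config.n_lr_groups)
    mu = np.outer(row_w, col_w)

    truth = PlantedTruth()
    boost = np.ones_like(mu)
    if config.lr_boost != 1.0:
        for j, g in enumerate(groups):
            planted = rng.choice(config.n_lr_pairs, size=2, replace=False)
            for i in planted:
                boost[i, j] = config.lr_boost
                truth.enriched_pairs.append((pairs[i], g))
    counts = rng.poisson(mu * boost)
    return pd.DataFrame(counts, index=pairs, columns=groups), truth


# ---------------------------------------------------------------------------
# component abundance profiles with planted ecosystems
# ---------------------------------------------------------------------------

def generate_abundance_profiles(config: SyntheticConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate per-sample CM/MP abundance fractions with planted ecosystems.

    Components (4 CM columns + 6 MP columns by default) are partitioned into
    ``n_ecosystems`` groups, each containing at least one CM and one MP. Each
    sample draws one elevated ecosystem; the fractions of that ecosystem's
    components are boosted, so component abundance vectors correlate in blocks.
    """
    n_cm, n_mp = 4, 6
    if config.n_ecosystems < 2 or config.n_ecosystems > min(n_cm, n_mp):
        raise InvalidConfigError("n_ecosystems must lie in [2, 4] for 4 CMs and 6 MPs")
    rng = _rng(config, _SUB_PROFILES)
    cms = [f"CM{i + 1}" for i in range(n_cm)]
    mps = [f"MP{i + 1}" for i in range(n_mp)]
    ecosystems = [f"E{i + 1}" for i in range(config.n_ecosystems)]
    truth = PlantedTruth()
    for i, c in enumerate(cms):
        truth.component_to_ecosystem[c] = ecosystems[i % len(ecosystems)]
    for i, m in enumerate(mps):
        truth.component_to_ecosystem[m] = ecosystems[i % len(ecosystems)]

    rows = []
    samples = [f"s{config.seed}_{i:03d}" for i in range(config.n_samples)]
    for s in samples:
        eco = ecosystems[int(rng.integers(len(ecosystems)))]
        truth.sample_ecosystem[s] = eco
        row = {}
        for family in (cms, mps):
            alpha = np.array([config.module_boost
                              if truth.component_to_ecosystem[c] == eco else 1.0
                              for c in family])
            fracs = rng.dirichlet(alpha)
            row.update(dict(zip(family, fracs)))
        rows.append(row)
    return pd.DataFrame(rows, index=samples, columns=cms + mps), truth


# ---------------------------------------------------------------------------
# per-cell expression with planted cell-type markers
# ---------------------------------------------------------------------------

def generate_type_marker_expression(
    table: pd.DataFrame,
    markers_per_type: int = 12,
    n_background_genes: int = 100,
    seed: int = 0,
    max_cells_per_type: int = 200,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a gene x cell count matrix with planted cell-type markers.

    Each non-epithelial cell type gets ``markers_per_type`` dedicated marker
    genes drawn at Poisson(3) in its own cells and Poisson(0.1) elsewhere, on
    top of Poisson(0.5) background genes. Cells are subsampled per type to keep
    the matrix small; the planted marker map is returned as truth.
    """
    rng = np.random.default_rng([int(seed), _SUB_MARKERS])
    sub = table.loc[~table["is_epithelial"]]
    kept = sub.groupby("cell_type", sort=True).head(max_cells_per_type)
    cells = kept["cell_id"].tolist()
    types = sorted(kept["cell_type"].unique())
    truth = PlantedTruth()
    gene_rows, names = [], []
    type_of = kept.set_index("cell_id")["cell_type"].reindex(cells).to_numpy()
    for t in types:
        mask = type_of == t
        markers = [f"{t}_mk{j:02d}" for j in range(markers_per_type)]
        truth.type_markers[t] = markers
        for g in markers:
            lam = np.where(mask, 3.0, 0.1)
            gene_rows.append(rng.poisson(lam))
            names.append(g)
    for b in range(n_background_genes):
        gene_rows.append(rng.poisson(0.5, size=len(cells)))
        names.append(f"bg{b:03d}")
    expr = pd.DataFrame(np.asarray(gene_rows), index=names, columns=cells)
    return expr, truth
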