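"""Population-level analyses: conductance optimization, subtype
classification, IFC-conductance correlation, and the (p x n_synapses)
transmission maps.

The optimizer is an elitist genetic algorithm over maximal-conductance
densities.  Fitness is multi-objective in spirit — one |z|-distance per
electrophysiological feature against a target template — scalarized by the
summed z-distance for selection; the best individual is carried over
unchanged each generation, so the best summed distance is non-increasing.
The search space is read from the channel table's per-compartment bounds
(the channel table is the single source of truth).

Classification follows the experimental recipe: accelerating cells are
pre-separated by their unmistakable positive frequency change, k-means
(20 restarts) with silhouette model selection runs on the rest in the
(IFC, f_initial) plane in native units, normality is screened with a
Lilliefors test and cluster separation with a one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.diagnostic import lilliefors

from .cell import GrCModel, load_model, simulate_current_clamp, validate_model
from .features import EFeatureVector, extract_efeatures, spike_train_stats
from .protocols import SynapticTrainProtocol, run_synaptic_protocol
from .synapse import TMParameters

__all__ = [
    "OptimizationConfig",
    "ModelPopulation",
    "ClusterResult",
    "optimize_conductances",
    "make_template",
    "classify_subtypes",
    "correlate_ifc_gmax",
    "map_parameter_space",
    "ACCELERATING_IFC_CUTOFF",
]

#: operational cutoff (%) above which a cell counts as accelerating and is
#: pre-separated before k-means, mirroring the experimental treatment
ACCELERATING_IFC_CUTOFF = 20.0

#: default search space: the somatic conductances that differentiate firing
DEFAULT_GENES: tuple[tuple[str, str], ...] = (
    ("Nav1.6", "soma"),
    ("Nav1.6+FHF", "soma"),
    ("Kv1.1", "soma"),
    ("Kv1.5", "soma"),
    ("Kv2", "soma"),
    ("Kv3.4", "soma"),
    ("Kv4.3", "soma"),
    ("Kv7", "soma"),
    ("Cav2.2", "soma"),
    ("KCa1.1", "soma"),
)

#: feature dispersions used to normalize per-feature distances (template
#: units: mV, ms, Hz); roughly the between-cell SDs of the recordings
FEATURE_SCALES: dict[str, float] = {
    "resting_potential": 2.0,
    "spike_width": 0.1,
    "spike_height": 5.0,
    "fast_ahp_depth": 2.0,
    "slow_ahp_depth": 2.0,
    "mean_frequency": 5.0,
    "time_to_first_spike": 5.0,
    "adaptation_index": 0.02,
    "isi_cv": 0.05,
}


@dataclass(frozen=True)
class OptimizationConfig:
    population_size: int = 32
    n_generations: int = 8
    template: Mapping[float, EFeatureVector] | None = None  # current (pA) -> features
    template_currents: tuple[float, ...] = (10.0,)
    genes: tuple[tuple[str, str], ...] = DEFAULT_GENES
    seed: int = 0
    stim_duration: float = 500.0   # ms; the optimization window of the assay
    eval_dt: float = 0.02          # ms; coarse integration is fine for search
    crossover_rate: float = 0.7
    mutation_rate: float = 0.25
    mutation_sigma: float = 0.15   # fraction of each gene's bound range
    elite: int = 2

    def __post_init__(self):
        if self.population_size < 4 or self.n_generations < 1:
            raise ValueError("population_size >= 4 and n_generations >= 1 required")


@dataclass
class ModelPopulation:
    """Final GA population: one row per individual."""

    table: pd.DataFrame          # gene columns + fitness + valid
    genes: tuple[tuple[str, str], ...]
    seed: int
    history: list = field(default_factory=list)  # best summed z per generation

    def best(self) -> dict[tuple[str, str], float]:
        row = self.table.sort_values("fitness").iloc[0]
        return {g: float(row[f"{g[0]}@{g[1]}"]) for g in self.genes}

    def validated(self) -> pd.DataFrame:
        if "valid" in self.table:
            return self.table[self.table["valid"]]
        return self.table


def _feature_distance(
    feats: Mapping[float, EFeatureVector], template: Mapping[float, EFeatureVector]
) -> np.ndarray:
    """Per-feature |z| distances averaged over template currents."""
    names = EFeatureVector.names()
    scales = np.array([FEATURE_SCALES[n] for n in names])
    dists = []
    for amp, tmpl in template.items():
        a = feats[amp].as_array()
        b = tmpl.as_array()
        z = np.abs(a - b) / scales
        # an undefined feature on either side counts as a large miss unless
        # undefined on both (then it carries no information)
        both_nan = np.isnan(a) & np.isnan(b)
        z[np.isnan(z)] = 10.0
        z[both_nan] = 0.0
        dists.append(z)
    return np.mean(dists, axis=0)


def make_template(
    model: GrCModel,
    currents: Sequence[float] = (10.0,),
    stim_duration: float = 500.0,
    dt: float = 0.02,
) -> dict[float, EFeatureVector]:
    """Extract a feature template from a (reference) model — the in-silico
    analogue of building the experimental template from recordings."""
    return {
        amp: extract_efeatures(
            simulate_current_clamp(model, amp, stim_duration, dt=dt)
        )
        for amp in currents
    }


def optimize_conductances(
    cfg: OptimizationConfig,
    base_model: GrCModel | None = None,
    progress: Callable[[int, float], None] | None = None,
    validate: bool = False,
) -> ModelPopulation:
    """Elitist GA over maximal conductance densities.

    Raises ``RuntimeError`` with diagnostics when, with ``validate=True``,
    no individual of the final population passes the spike-generation/
    conduction screen.
    """
    if cfg.template is None:
        raise ValueError("OptimizationConfig.template is required")
    base = base_model or GrCModel.from_config()
    rng = np.random.default_rng(cfg.seed)
    bounds = np.array(
        [base.table.bounds(ch, comp) for ch, comp in cfg.genes], dtype=float
    )
    span = bounds[:, 1] - bounds[:, 0]
    npop, ngene = cfg.population_size, len(cfg.genes)

    pop = bounds[:, 0] + rng.random((npop, ngene)) * span

    def evaluate(genome: np.ndarray) -> float:
        overrides = {g: float(v) for g, v in zip(cfg.genes, genome)}
        model = base.with_gmax(overrides)
        feats = {
            amp: extract_efeatures(
                simulate_current_clamp(
                    model, amp, cfg.stim_duration, dt=cfg.eval_dt
                )
            )
            for amp in cfg.template_currents
        }
        return float(np.sum(_feature_distance(feats, cfg.template)))

    fitness = np.array([evaluate(g) for g in pop])
    history = [float(fitness.min())]

    for gen in range(cfg.n_generations):
        order = np.argsort(fitness)
        pop, fitness = pop[order], fitness[order]
        new_pop = [pop[i].copy() for i in range(cfg.elite)]  # elitism
        while len(new_pop) < npop:
            # binary tournament selection
            i, j = rng.integers(0, npop, 2)
            a = pop[i] if fitness[i] <= fitness[j] else pop[j]
            i, j = rng.integers(0, npop, 2)
            b = pop[i] if fitness[i] <= fitness[j] else pop[j]
            child = a.copy()
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(ngene) < 0.5
                child[mask] = b[mask]
            mut = rng.random(ngene) < cfg.mutation_rate
            child = child + mut * rng.normal(0.0, cfg.mutation_sigma, ngene) * span
            new_pop.append(np.clip(child, bounds[:, 0], bounds[:, 1]))
        pop = np.array(new_pop)
        keep = fitness[: cfg.elite]
        fitness = np.concatenate(
            [keep, [evaluate(g) for g in pop[cfg.elite :]]]
        )
        history.append(float(fitness.min()))
        if progress is not None:
            progress(gen, history[-1])

    cols = {f"{c}@{comp}": pop[:, k] for k, (c, comp) in enumerate(cfg.genes)}
    table = pd.DataFrame(cols)
    table["fitness"] = fitness
    if validate:
        valid = []
        for _, row in table.iterrows():
            overrides = {
                g: float(row[f"{g[0]}@{g[1]}"]) for g in cfg.genes
            }
            ok, _ = validate_model(base.with_gmax(overrides), dt=0.02)
            valid.append(ok)
        table["valid"] = valid
        if not any(valid):
            raise RuntimeError(
                "no individual passed validation; best fitness "
                f"{table['fitness'].min():.2f}, bounds may be inconsistent"
            )
    return ModelPopulation(table=table, genes=cfg.genes, seed=cfg.seed, history=history)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray          # -1 marks pre-separated accelerating cells
    centroids: np.ndarray            # (k, 2) in original (IFC, f_initial) units
    silhouettes: dict                 # k -> mean silhouette
    normality_p: float | None
    anova_p: float | None
    degenerate: bool = False


def classify_subtypes(
    features: pd.DataFrame,
    k_range: Sequence[int] = (2, 3, 4, 5),
    n_restarts: int = 20,
    seed: int = 0,
    accelerating_cutoff: float = ACCELERATING_IFC_CUTOFF,
) -> ClusterResult:
    """k-means subtype classification in the (IFC, f_initial) plane.

    ``features`` needs columns ``ifc`` (%) and ``f_initial`` (Hz).
    Accelerating cells (ifc > cutoff) are excluded from clustering and
    marked -1 in the assignment vector, as in the experimental analysis.
    """
    if not {"ifc", "f_initial"} <= set(features.columns):
        raise ValueError("features must have 'ifc' and 'f_initial' columns")
    ifc = features["ifc"].to_numpy(dtype=float)
    f0 = features["f_initial"].to_numpy(dtype=float)
    accel = ifc > accelerating_cutoff
    X = np.column_stack([ifc[~accel], f0[~accel]])
    n = len(X)
    assignments = np.full(len(features), -1, dtype=int)
    if n < max(k_range) + 1 or np.allclose(X.std(axis=0), 0.0):
        # degenerate: everything identical (or too few cells) -> one cluster
        assignments[~accel] = 0
        return ClusterResult(
            k=1,
            assignments=assignments,
            centroids=X.mean(axis=0, keepdims=True) if n else np.zeros((0, 2)),
            silhouettes={},
            normality_p=None,
            anova_p=None,
            degenerate=True,
        )
    # features in native units (%, Hz), as in the original analysis: IFC
    # spans ~100 units and dominates the metric, which is what separates
    # the adaptation groups
    Z = X
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(Z)
        labels_by_k[k] = lab
        sil[k] = float(silhouette_score(Z, lab)) if len(np.unique(lab)) > 1 else -1.0
    best_k = max(sil, key=sil.get)
    lab = labels_by_k[best_k]
    # order clusters by IFC centroid (most adapting first) for stable labels
    cent = np.array([X[lab == c].mean(axis=0) for c in range(best_k)])
    order = np.argsort(cent[:, 0])
    remap = {int(c): int(r) for r, c in enumerate(order)}
    lab = np.array([remap[int(c)] for c in lab])
    cent = cent[order]
    assignments[~accel] = lab
    try:
        norm_p = float(lilliefors(ifc[~accel])[1])
    except Exception:
        norm_p = None
    groups = [X[lab == c, 0] for c in range(best_k) if np.sum(lab == c) > 1]
    anova_p = float(stats.f_oneway(*groups)[1]) if len(groups) > 1 else None
    return ClusterResult(
        k=best_k,
        assignments=assignments,
        centroids=cent,
        silhouettes=sil,
        normality_p=norm_p,
        anova_p=anova_p,
    )


# ---------------------------------------------------------------------------
# structure-function correlation and transmission maps
# ---------------------------------------------------------------------------

def correlate_ifc_gmax(
    pop: pd.DataFrame, channel: str = "Cav2.2", compartment: str = "soma"
) -> tuple[float, float, float]:
    """OLS of IFC@10pA on a maximal conductance density.

    ``pop`` needs columns ``ifc`` and ``{channel}@{compartment}``.
    Returns (slope, R^2, p_value).
    """
    col = f"{channel}@{compartment}"
    if col not in pop.columns:
        raise ValueError(f"population table lacks column {col!r}")
    if len(pop) < 10:
        raise ValueError("need at least 10 models")
    x = pop[col].to_numpy(dtype=float)
    y = pop["ifc"].to_numpy(dtype=float)
    if np.allclose(x.std(), 0.0):
        raise ValueError("zero variance in gmax: slope undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def ifc_vs_gmax_sweep(
    channel: str = "Cav2.2",
    compartment: str = "soma",
    n_models: int = 30,
    gmax_range: tuple[float, float] | None = None,
    base_overrides: Mapping[tuple[str, str], float] | None = None,
    i_inj: float = 10.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Simulate a sweep of models along one conductance and collect IFC@10pA.

    The in-silico analogue of the model-population scatter relating firing
    adaptation to the Cav2.2 density.
    """
    base = GrCModel.from_config()
    if base_overrides:
        base = base.with_gmax(dict(base_overrides))
    lo, hi = gmax_range or base.table.bounds(channel, compartment)
    rows = []
    for g in np.linspace(lo, hi, n_models):
        m = base.with_gmax({(channel, compartment): float(g)})
        st = spike_train_stats(simulate_current_clamp(m, i_inj, 2000.0, dt=dt))
        ifc = st.delta_f_0_2000
        rows.append(
            {
                f"{channel}@{compartment}": float(g),
                "ifc": np.nan if ifc is None else ifc,
                "f_initial": st.f_initial,
            }
        )
    return pd.DataFrame(rows).dropna(subset=["ifc"])


def map_parameter_space(
    models: Mapping[str, GrCModel] | None = None,
    p_values: Sequence[float] = (0.1, 0.5, 0.9),
    n_synapses: Sequence[int] = (1, 2, 3, 4),
    proto: SynapticTrainProtocol | None = None,
    dt: float | None = None,
) -> pd.DataFrame:
    """SFC@20Hz and S/N grids over release probability x active synapses.

    Returns a tidy frame: subtype, p, n_syn, f_bkg, f_burst, sfc_20, s_n.
    ``n_syn = 0`` rows are included analytically (no transmission:
    SFC = -100%, S/N undefined).
    """
    from .features import signal_to_noise, synaptic_frequency_change

    if models is None:
        models = {tag: load_model(tag) for tag in
                  ("strong_adapting", "mild_adapting", "non_adapting", "accelerating")}
    proto = proto or SynapticTrainProtocol()
    rows = []
    for tag, model in models.items():
        for n_syn in n_synapses:
            if n_syn == 0:
                rows.append(
                    {"subtype": tag, "p": np.nan, "n_syn": 0, "f_bkg": 0.0,
                     "f_burst": 0.0, "sfc_20": -100.0, "s_n": np.nan}
                )
                continue
            for p in p_values:
                kwargs = {} if dt is None else {"dt": dt}
                r = run_synaptic_protocol(
                    model, TMParameters(p=p, n_synapses=n_syn), proto=proto, **kwargs
                )
                rows.append(
                    {
                        "subtype": tag,
                        "p": p,
                        "n_syn": n_syn,
                        "f_bkg": r.f_resp_background,
                        "f_burst": r.f_resp_burst,
                        "sfc_20": synaptic_frequency_change(
                            r.f_resp_background, proto.background_rate
                        ),
                        "s_n": signal_to_noise(r.f_resp_burst, r.f_resp_background),
                    }
                )
    return pd.DataFrame(rows)
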