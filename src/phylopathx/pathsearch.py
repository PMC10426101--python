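"""Score every candidate path model by phylogenetic d-separation, rank by
CICc, and conditionally average the best-fitting set.

For each model the d-separation basis set is tested with phylogenetic
regressions; the claim p-values combine into Fisher's C = -2 sum(ln p),
chi-square with 2k df under the model.  Models are compared with
CICc = C + 2 q n / (n - 1 - q), the small-sample information criterion for
path models, with q = |edges| + |nodes| by default.  Models within a CICc
threshold (default 2) of the best are retained with Akaike weights
exp(-delta/2) (normalised), and each directed path's coefficient is averaged
over only the retained models that contain it (conditional averaging), with
an unconditional standard error that includes the between-model variance
term.  Paths whose 95% CI crosses zero are flagged as excluded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dagspace import (
    ConstraintSpec,
    DagModel,
    IndependenceClaim,
    basis_set,
    count_dags,
    enumerate_dags,
    to_dot,
)
from .phyloreg import P_FLOOR, RegressionSpec, pgls_fit
from .treeio import Phylogeny

__all__ = [
    "PathConfig",
    "ModelScore",
    "AveragedModel",
    "PathEstimate",
    "ClaimCache",
    "fisher_c",
    "cicc",
    "akaike_weights",
    "score_models",
    "best_set",
    "average_models",
    "explore",
    "ExploreReport",
]


@dataclass
class PathConfig:
    """Knobs of the path search.

    ``q_definition`` counts estimated parameters as edges+nodes (the
    phylopath convention) or edges only.  ``averaging`` is conditional
    (average over models containing the path) or full (absent paths count
    as zero).  ``weighted`` toggles CICc-weighted vs unweighted averaging.
    """

    transform: str = "lambda"
    binary_method: str = "linear"
    q_definition: str = "edges_plus_nodes"  # or "edges"
    delta_threshold: float = 2.0
    averaging: str = "conditional"  # or "full"
    weighted: bool = True
    ci_multiplier: float = 1.96
    use_cache: bool = True
    standardize: bool = True

    def __post_init__(self):
        if self.q_definition not in ("edges_plus_nodes", "edges"):
            raise ValueError(f"unknown q definition {self.q_definition!r}")
        if self.averaging not in ("conditional", "full"):
            raise ValueError(f"unknown averaging mode {self.averaging!r}")


@dataclass
class ModelScore:
    model: DagModel
    C: float
    C_pvalue: float
    q: int
    n: int
    CICc: float
    delta: float = float("nan")
    weight: float = 0.0
    error: str | None = None

    @property
    def scored(self) -> bool:
        return self.error is None


@dataclass
class PathEstimate:
    source: str
    target: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    n_models: int
    total_weight: float

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass
class AveragedModel:
    paths: list[PathEstimate]
    bidirectional_pairs: list[tuple[str, str]]
    excluded_paths: list[tuple[str, str]]

    def path(self, source: str, target: str) -> PathEstimate | None:
        for p in self.paths:
            if p.source == source and p.target == target:
                return p
        return None

    def significant_edges(self) -> set[tuple[str, str]]:
        return {(p.source, p.target) for p in self.paths if p.excludes_zero}


def fisher_c(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's C = -2 sum(ln p) and its chi-square (2k df) model p-value.

    An empty basis (saturated model) gives C = 0, p = 1.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return 0.0, 1.0
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    C = float(-2.0 * np.sum(np.log(ps)))
    return C, float(stats.chi2.sf(C, 2 * ps.size))


def cicc(C: float, q: int, n: int) -> float:
    """CICc = C + 2 q n / (n - 1 - q); requires n > q + 1."""
    if n <= q + 1:
        raise ValueError(f"insufficient sample for correction: n={n} <= q+1={q + 1}")
    return float(C) + 2.0 * q * n / (n - 1.0 - q)


def akaike_weights(deltas: Sequence[float]) -> np.ndarray:
    d = np.asarray(deltas, dtype=float)
    w = np.exp(-d / 2.0)
    return w / w.sum()


class ClaimCache:
    """Process-wide cache of claim p-values keyed on canonicalised claims.

    Guarantees each independence claim is fitted at most once per search.
    """

    def __init__(self):
        self._p: dict[tuple, float] = {}
        self._logp: dict[tuple, float] = {}
        self.hits = 0
        self.misses = 0

    def log_p(self, claim: IndependenceClaim, fitter) -> float:
        key = claim.key()
        if key in self._logp:
            self.hits += 1
            return self._logp[key]
        self.misses += 1
        p = max(float(fitter(claim)), P_FLOOR)
        self._p[key] = p
        self._logp[key] = math.log(p)
        return self._logp[key]

    def p_value(self, claim: IndependenceClaim, fitter) -> float:
        self.log_p(claim, fitter)
        return self._p[claim.key()]

    @property
    def stats(self) -> dict:
        return {"hits": self.hits, "misses": self.misses, "size": len(self._p)}


def _prepare_path_data(traits: pd.DataFrame, tree: Phylogeny, nodes: Sequence[str],
                       standardize: bool) -> pd.DataFrame:
    missing = [v for v in nodes if v not in traits.columns]
    if missing:
        raise KeyError(f"model variables not in trait table: {missing}")
    offenders = sorted(set(traits.index) - set(tree.tips))
    if offenders:
        raise ValueError(f"taxa not on the tree: {offenders}")
    # global listwise deletion: all models are scored on the same n
    data = traits[list(nodes)].dropna().astype(float)
    if standardize:
        sd = data.std(ddof=1)
        if (sd == 0).any():
            bad = sorted(sd.index[sd == 0])
            raise ValueError(f"zero-variance variables: {bad}")
        data = (data - data.mean()) / sd
    return data


def _claim_fitter(data: pd.DataFrame, tree: Phylogeny, config: PathConfig):
    def fit(claim: IndependenceClaim) -> float:
        spec = RegressionSpec(
            response=claim.response,
            predictors=[claim.predictor],
            conditioning=sorted(claim.conditioning),
            transform=config.transform,
            binary_method=config.binary_method,
        )
        res = pgls_fit(data, tree, spec)
        return res.p_values[claim.predictor]

    return fit


def _model_q(model: DagModel, config: PathConfig) -> int:
    q = len(model.edges)
    if config.q_definition == "edges_plus_nodes":
        q += len(model.nodes)
    return q


def score_models(
    models: Iterable[DagModel],
    traits: pd.DataFrame,
    tree: Phylogeny,
    config: PathConfig | None = None,
    cache: ClaimCache | None = None,
) -> list[ModelScore]:
    """Score a stream of models; returns the list sorted ascending by CICc.

    Ties break by smaller C, then fewer edges, then the lexicographic edge
    list.  A claim-fit failure marks that model unscored (with the reason)
    rather than aborting the search.
    """
    config = config or PathConfig()
    models = iter(models)
    try:
        first = next(models)
    except StopIteration:
        return []
    nodes = first.nodes
    data = _prepare_path_data(traits, tree, nodes, config.standardize)
    n = len(data)
    fitter = _claim_fitter(data, tree, config)
    cache = cache if cache is not None else ClaimCache()

    scores: list[ModelScore] = []
    for model in itertools.chain([first], models):
        if model.nodes != nodes:
            raise ValueError("all models in one search must share the same variables")
        q = _model_q(model, config)
        try:
            if config.use_cache:
                logps = [cache.log_p(c, fitter) for c in basis_set(model)]
                C = -2.0 * sum(logps)
                k = len(logps)
            else:
                ps = [max(float(fitter(c)), P_FLOOR) for c in basis_set(model)]
                C, _ = fisher_c(ps) if ps else (0.0, 1.0)
                k = len(ps)
            C = max(C, 0.0)
            Cp = float(stats.chi2.sf(C, 2 * k)) if k else 1.0
            scores.append(ModelScore(
                model=model, C=C, C_pvalue=Cp, q=q, n=n, CICc=cicc(C, q, n),
            ))
        except Exception as exc:
            scores.append(ModelScore(
                model=model, C=float("nan"), C_pvalue=float("nan"), q=q, n=n,
                CICc=float("inf"), error=str(exc),
            ))

    scored = [s for s in scores if s.scored]
    if scored:
        best = min(s.CICc for s in scored)
        for s in scored:
            s.delta = s.CICc - best
    scores.sort(key=lambda s: (
        s.CICc, s.C if s.scored else float("inf"),
        len(s.model.edges), s.model.sorted_edges(),
    ))
    return scores


def best_set(scores: Sequence[ModelScore], threshold: float = 2.0) -> list[ModelScore]:
    """Models within ``threshold`` CICc of the best, with Akaike weights."""
    scored = [s for s in scores if s.scored]
    if not scored:
        raise ValueError("no scored models")
    best = min(s.CICc for s in scored)
    retained = [s for s in scored if s.CICc - best <= threshold]
    w = akaike_weights([s.CICc - best for s in retained])
    for s, wi in zip(retained, w):
        s.delta = s.CICc - best
        s.weight = float(wi)
    return retained


class CoefficientCache:
    """Caches per-node coefficient fits keyed on (child, parent set)."""

    def __init__(self, data: pd.DataFrame, tree: Phylogeny, config: PathConfig):
        self.data = data
        self.tree = tree
        self.config = config
        self._store: dict[tuple, dict] = {}

    def fits_for(self, model: DagModel) -> dict[tuple[str, str], tuple[float, float]]:
        out: dict[tuple[str, str], tuple[float, float]] = {}
        for child, parents in model.parents.items():
            if not parents:
                continue
            key = (child, tuple(sorted(parents)))
            if key not in self._store:
                spec = RegressionSpec(
                    response=child, predictors=sorted(parents),
                    transform=self.config.transform,
                    binary_method=self.config.binary_method,
                )
                res = pgls_fit(self.data, self.tree, spec)
                self._store[key] = {
                    p: (res.coefficients[p], res.standard_errors[p])
                    for p in sorted(parents)
                }
            for p, (b, se) in self._store[key].items():
                out[(p, child)] = (b, se)
        return out


def average_models(
    retained: Sequence[ModelScore],
    traits: pd.DataFrame,
    tree: Phylogeny,
    config: PathConfig | None = None,
    coefficient_fits: Mapping[int, Mapping[tuple[str, str], tuple[float, float]]] | None = None,
) -> AveragedModel:
    """Conditionally average path coefficients over the retained models.

    For each directed path present in at least one retained model the
    coefficient is the weighted mean over just those models (weights
    renormalised within the subset); the averaged SE uses Buckland's
    unconditional formula sum w_i sqrt(se_i^2 + (b_i - b_bar)^2).  With
    ``config.averaging == 'full'`` models lacking the path contribute a zero
    coefficient instead.  Pairs present in both orientations across the
    retained set are flagged bidirectional.
    """
    config = config or PathConfig()
    if not retained:
        raise ValueError("empty retained set")
    nodes = retained[0].model.nodes
    if coefficient_fits is None:
        data = _prepare_path_data(traits, tree, nodes, config.standardize)
        cc = CoefficientCache(data, tree, config)
        coefficient_fits = {i: cc.fits_for(s.model) for i, s in enumerate(retained)}

    weights = np.array([s.weight for s in retained], dtype=float)
    if not config.weighted or weights.sum() <= 0:
        weights = np.ones(len(retained))
    weights = weights / weights.sum()

    all_edges = sorted(
        {e for s in retained for e in s.model.edges},
        key=lambda e: (nodes.index(e[0]), nodes.index(e[1])),
    )
    paths: list[PathEstimate] = []
    for edge in all_edges:
        present = [i for i, s in enumerate(retained) if edge in s.model.edges]
        if config.averaging == "conditional":
            idx = present
        else:
            idx = list(range(len(retained)))
        w = weights[idx]
        total_w = float(weights[present].sum())
        w = w / w.sum()
        bs = np.array([
            coefficient_fits[i].get(edge, (0.0, 0.0))[0] for i in idx
        ])
        ses = np.array([
            coefficient_fits[i].get(edge, (0.0, 0.0))[1] for i in idx
        ])
        b_bar = float(w @ bs)
        se_bar = float(w @ np.sqrt(ses ** 2 + (bs - b_bar) ** 2))
        ci = config.ci_multiplier * se_bar
        paths.append(PathEstimate(
            source=edge[0], target=edge[1], coefficient=b_bar, se=se_bar,
            ci_low=b_bar - ci, ci_high=b_bar + ci,
            n_models=len(present), total_weight=total_w,
        ))

    edge_set = {(p.source, p.target) for p in paths}
    bidirectional = sorted({
        tuple(sorted((u, v))) for (u, v) in edge_set if (v, u) in edge_set
    })
    excluded = [(p.source, p.target) for p in paths if not p.excludes_zero]
    return AveragedModel(
        paths=paths,
        bidirectional_pairs=[tuple(p) for p in bidirectional],
        excluded_paths=excluded,
    )


@dataclass
class ExploreReport:
    nodes: tuple[str, ...]
    n_models: int
    n_unscored: int
    n_taxa: int
    best_cicc: float
    n_retained: int
    retained: list[ModelScore]
    averaged: AveragedModel
    dot: str
    cache_stats: dict
    config: PathConfig
    ranking_head: list[dict] = field(default_factory=list)
    seed: int | None = None

    def to_json_obj(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "n_models": self.n_models,
            "n_unscored": self.n_unscored,
            "n_taxa": self.n_taxa,
            "best_cicc": self.best_cicc,
            "n_retained": self.n_retained,
            "seed": self.seed,
            "config": {
                "transform": self.config.transform,
                "binary_method": self.config.binary_method,
                "q_definition": self.config.q_definition,
                "delta_threshold": self.config.delta_threshold,
                "averaging": self.config.averaging,
                "weighted": self.config.weighted,
                "ci_multiplier": self.config.ci_multiplier,
            },
            "cache_stats": self.cache_stats,
            "ranking_head": self.ranking_head,
            "retained": [
                {
                    "edges": [list(e) for e in s.model.sorted_edges()],
                    "C": s.C, "C_pvalue": s.C_pvalue, "q": s.q, "n": s.n,
                    "CICc": s.CICc, "delta": s.delta, "weight": s.weight,
                }
                for s in self.retained
            ],
            "averaged_paths": [
                {
                    "from": p.source, "to": p.target,
                    "coefficient": p.coefficient, "se": p.se,
                    "ci_low": p.ci_low, "ci_high": p.ci_high,
                    "n_models": p.n_models, "total_weight": p.total_weight,
                    "ci_excludes_zero": p.excludes_zero,
                }
                for p in self.averaged.paths
            ],
            "bidirectional_pairs": [list(p) for p in self.averaged.bidirectional_pairs],
            "excluded_paths": [list(p) for p in self.averaged.excluded_paths],
            "dot": self.dot,
        }


def explore(
    traits: pd.DataFrame,
    tree: Phylogeny,
    constraints: ConstraintSpec | None = None,
    config: PathConfig | None = None,
    variables: Sequence[str] | None = None,
    node_limit: int = 7,
    allow_large: bool = False,
    seed: int | None = None,
    ranking_head: int = 20,
) -> ExploreReport:
    """End-to-end exploratory path analysis: enumerate -> score -> best set
    -> conditional average -> DOT render.

    Deterministic: the same inputs and configuration produce a byte-identical
    report.
    """
    config = config or PathConfig()
    nodes = tuple(variables) if variables is not None else tuple(traits.columns)
    # validate before any fitting happens
    data = _prepare_path_data(traits, tree, nodes, config.standardize)
    if constraints is not None:
        constraints.validate(list(traits.columns))  # catch typos first
        constraints = constraints.restrict(nodes)

    cache = ClaimCache()
    stream = enumerate_dags(nodes, constraints, node_limit=node_limit,
                            allow_large=allow_large)
    scores = score_models(stream, traits, tree, config, cache=cache)
    retained = best_set(scores, threshold=config.delta_threshold)
    cc = CoefficientCache(data, tree, config)
    fits = {i: cc.fits_for(s.model) for i, s in enumerate(retained)}
    averaged = average_models(retained, traits, tree, config, coefficient_fits=fits)

    display = DagModel(
        nodes=nodes,
        edges=frozenset(
            (p.source, p.target) for p in averaged.paths if p.excludes_zero
        ),
    ) if _orientable(averaged) else None
    annotations = {
        (p.source, p.target): p.coefficient
        for p in averaged.paths if p.excludes_zero
    }
    if display is not None:
        dot = to_dot(display, annotations, name="averaged")
    else:  # bidirectional pairs make the significant-edge graph cyclic
        dot = _dot_with_cycles(nodes, annotations)

    best = retained[0].CICc
    head = [
        {
            "edges": [list(e) for e in s.model.sorted_edges()],
            "C": s.C, "CICc": s.CICc, "delta": s.delta,
        }
        for s in scores[:ranking_head] if s.scored
    ]
    n_unscored = sum(1 for s in scores if not s.scored)
    return ExploreReport(
        nodes=nodes, n_models=len(scores), n_unscored=n_unscored,
        n_taxa=len(data), best_cicc=best, n_retained=len(retained),
        retained=retained, averaged=averaged, dot=dot,
        cache_stats=cache.stats, config=config, ranking_head=head, seed=seed,
    )


def _orientable(averaged: AveragedModel) -> bool:
    sig = averaged.significant_edges()
    from .dagspace import is_acyclic
    return is_acyclic(sig)


def _dot_with_cycles(nodes, annotations) -> str:
    max_abs = max((abs(c) for c in annotations.values()), default=0.0)
    lines = ["digraph averaged {"]
    for v in nodes:
        lines.append(f'  "{v}";')
    order = {v: i for i, v in enumerate(nodes)}
    for (u, v), coef in sorted(annotations.items(),
                               key=lambda kv: (order[kv[0][0]], order[kv[0][1]])):
        width = 1.0 + (3.0 * abs(coef) / max_abs if max_abs > 0 else 0.0)
        color = "red3" if coef < 0 else "black"
        lines.append(
            f'  "{u}" -> "{v}" [label="{coef:.3f}", penwidth={width:.3f}, color={color}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def paper_pattern_constraints(
    environment: Sequence[str], shielded: str, socio_cultural: Sequence[str]
) -> ConstraintSpec:
    """Convenience constructor for the common restriction pattern: a group of
    mutually exogenous environmental variables, plus one variable (e.g. a
    pathogen measure) that socio-cultural variables may not cause."""
    return ConstraintSpec(
        mutually_exogenous=(frozenset(environment),),
        forbidden_parents={shielded: frozenset(socio_cultural)},
    )
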