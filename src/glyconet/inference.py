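"""Pathway-distance scoring of GGM edges and rule-based model selection.

The central idea: if a pathway model is close to the biological truth,
significant partial correlations should pile up between glycoform pairs
at pathway distance 1 (reactant/product of a single enzymatic step).
Each candidate model is scored with a Fisher exact test on the 2x2 table

    rows:    pathway distance == 1  vs  distance > 1
    columns: GGM edge significant   vs  not

over all classifiable glycoform pairs.  Pairs of the same structure in
different subclasses cannot be interpreted as reactions and are labeled
"X"; all other cross-subclass pairs are excluded.  Lower p-values are
read as variance-normalized effect sizes: the model with the strongest
distance-1 enrichment explains the network best.

Model uncertainty is quantified by a nonparametric bootstrap that
re-runs the whole pipeline (GGM estimation + classification + Fisher
test) on resampled cohorts; a model beats the known pathway when its
point p-value is lower and the 95% percentile confidence intervals do
not overlap.  Among all models that beat the known pathway, the one with
the fewest rules is selected (ties broken by lowest point p-value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .netinfer import CorrelationNetwork, build_ggm, pcor_significance, \
    partial_correlation, pearson_network
from .pathway import PathwayModel, Rule, enumerate_models, parse_glycoform

__all__ = [
    "PairClassification",
    "ModelFit",
    "classify_pairs",
    "fisher_overlap",
    "fisher_exact_2x2",
    "fit_models",
    "select_model",
    "replication_fisher",
]


@dataclass
class PairClassification:
    """Per glycoform pair: distance category, significance and sign."""

    table: pd.DataFrame  # node1, node2, category, distance, significant, sign

    def contingency(self, at_distance: int = 1) -> np.ndarray:
        """2x2 counts [[d==at, sig], [d==at, not sig], ...] over distance
        pairs only ("X" and excluded pairs are omitted)."""
        t = self.table[self.table["category"] == "distance"]
        close = t["distance"] == at_distance
        sig = t["significant"].astype(bool)
        return np.array(
            [
                [int((close & sig).sum()), int((close & ~sig).sum())],
                [int((~close & sig).sum()), int((~close & ~sig).sum())],
            ]
        )


def classify_pairs(
    network: CorrelationNetwork, model: PathwayModel
) -> PairClassification:
    """Classify every node pair of ``network`` against ``model``.

    Within-subclass pairs get the model's pathway distance; same
    structure across subclasses is "X"; different structure across
    subclasses is excluded.
    """
    glyco = [parse_glycoform(c) for c in network.labels]
    for g in glyco:
        if g.structure not in model.panel:
            raise ValueError(f"structure {g.structure.name} not in model panel")
    dist = model.distances()
    if network.mask is None:
        raise ValueError("network has no significance mask")
    iu, ju = network.triu()
    rows = []
    for i, j in zip(iu, ju):
        a, b = glyco[i], glyco[j]
        if a.subclass == b.subclass:
            d = dist.get(a.structure, {}).get(b.structure, float("inf"))
            cat = "distance"
        elif a.structure == b.structure:
            d, cat = float("nan"), "X"
        else:
            d, cat = float("nan"), "excluded"
        rows.append(
            (
                network.labels[i],
                network.labels[j],
                cat,
                float(d),
                bool(network.mask[i, j]),
                int(np.sign(network.coef[i, j])),
            )
        )
    return PairClassification(
        pd.DataFrame(
            rows,
            columns=["node1", "node2", "category", "distance", "significant", "sign"],
        )
    )


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def _fisher_two_sided_fast(a: int, row1: int, col1: int, n: int) -> float:
    """Two-sided Fisher p for the table with top-left cell ``a``, first
    row margin ``row1``, first column margin ``col1`` and total ``n``.

    Sums the hypergeometric probabilities of all tables (with the same
    margins) no more probable than the observed one.  Used inside the
    bootstrap loop; cross-checked against scipy in the test suite.
    """
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def fisher_overlap(
    classification: PairClassification, at_distance: int = 1
) -> tuple[np.ndarray, float]:
    """Fisher exact test: does GGM significance accumulate at the given
    pathway distance?  Returns (2x2 table, two-sided p)."""
    table = classification.contingency(at_distance)
    if table.sum(axis=1).min() == 0:
        raise ValueError("empty row margin in contingency table")
    return table, fisher_exact_2x2(table)


@dataclass
class ModelFit:
    """Fisher p-value of one pathway model with its bootstrap 95% CI."""

    rule_ids: frozenset[str]
    p: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_boot: int = 0
    better_than_known: bool = False
    model: PathwayModel | None = None

    def __post_init__(self) -> None:
        if (
            self.ci_lower is not None
            and self.ci_upper is not None
            and self.ci_lower > self.ci_upper
        ):
            raise ValueError("bootstrap CI bounds out of order")

    @property
    def label(self) -> str:
        return "+".join(sorted(self.rule_ids)) if self.rule_ids else "known"


def _pair_structure(labels: tuple[str, ...], models: list[PathwayModel]):
    """Precompute, per model, the distance==1 indicator over the upper
    triangle, plus the shared valid-pair (within-subclass) mask."""
    glyco = [parse_glycoform(c) for c in labels]
    p = len(labels)
    iu, ju = np.triu_indices(p, k=1)
    valid = np.array(
        [glyco[i].subclass == glyco[j].subclass for i, j in zip(iu, ju)]
    )
    d1_masks = []
    for model in models:
        dist = model.distances()
        d1 = np.array(
            [
                glyco[i].subclass == glyco[j].subclass
                and dist.get(glyco[i].structure, {}).get(glyco[j].structure, -1) == 1
                for i, j in zip(iu, ju)
            ]
        )
        d1_masks.append(d1)
    return iu, ju, valid, d1_masks


def _fisher_from_masks(sig: np.ndarray, d1: np.ndarray, valid: np.ndarray) -> float:
    a = int((sig & d1 & valid).sum())
    row1 = int((d1 & valid).sum())
    col1 = int((sig & valid).sum())
    n = int(valid.sum())
    return _fisher_two_sided_fast(a, row1, col1, n)


def _ggm_sig_vector(
    values: pd.DataFrame,
    confounders: pd.DataFrame | None,
    alpha: float,
    iu: np.ndarray,
    ju: np.ndarray,
    method: str,
) -> np.ndarray:
    pearson = pearson_network(values, alpha=alpha)
    partial = pcor_significance(
        partial_correlation(values, confounders), alpha=alpha, method=method
    )
    g = build_ggm(pearson, partial)
    return g.mask[iu, ju]


def fit_models(
    values: pd.DataFrame,
    models: list[PathwayModel],
    confounders: pd.DataFrame | None = None,
    alpha: float = 0.01,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
    method: str = "fisher_z",
) -> list[ModelFit]:
    """Fit every pathway model: full-data Fisher p + bootstrap 95% CI.

    Each bootstrap resample redraws samples with replacement and re-runs
    the entire pipeline (Pearson + shrinkage partial correlations, FDR
    masks, GGM masking, classification, Fisher test) before the
    percentile CI is formed.  Reproducible given ``seed``.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if n_boot < 2:
        raise ValueError("need at least two bootstrap resamples")
    rng = np.random.default_rng(seed)
    labels = tuple(values.columns)
    iu, ju, valid, d1_masks = _pair_structure(labels, models)
    sig = _ggm_sig_vector(values, confounders, alpha, iu, ju, method)
    point = [_fisher_from_masks(sig, d1, valid) for d1 in d1_masks]
    boot = np.empty((n_boot, len(models)))
    n = len(values)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        v = values.iloc[idx].reset_index(drop=True)
        c = (
            confounders.iloc[idx].reset_index(drop=True)
            if confounders is not None
            else None
        )
        try:
            sig_b = _ggm_sig_vector(v, c, alpha, iu, ju, method)
        except ValueError:  # degenerate resample (e.g. zero variance)
            boot[b] = np.nan
            continue
        boot[b] = [_fisher_from_masks(sig_b, d1, valid) for d1 in d1_masks]
    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)
    fits = [
        ModelFit(
            rule_ids=m.rule_ids,
            p=point[i],
            ci_lower=float(lo[i]),
            ci_upper=float(hi[i]),
            n_boot=n_boot,
            model=m,
        )
        for i, m in enumerate(models)
    ]
    known = next((f for f in fits if not f.rule_ids), None)
    if known is not None:
        for f in fits:
            f.better_than_known = (
                f is not known
                and f.p < known.p
                and f.ci_upper < known.ci_lower
            )
    return fits


def select_model(fits: list[ModelFit]) -> ModelFit:
    """Parsimony selection: among models flagged better than the known
    pathway, return the one with the fewest rules (ties by lowest point
    p-value); if none, return the known pathway."""
    known = next((f for f in fits if not f.rule_ids), None)
    if known is None:
        raise ValueError("fits must include the known pathway (empty rule set)")
    better = [f for f in fits if f.better_than_known]
    if not better:
        return known
    return min(better, key=lambda f: (len(f.rule_ids), f.p))


def fit_and_select(
    values: pd.DataFrame,
    base_model: PathwayModel,
    rules: list[Rule],
    confounders: pd.DataFrame | None = None,
    alpha: float = 0.01,
    n_boot: int = 10_000,
    seed=None,
    method: str = "fisher_z",
) -> tuple[list[ModelFit], ModelFit]:
    """Enumerate all rule-subset models, fit them, and select one."""
    models = enumerate_models(base_model, rules)
    fits = fit_models(
        values, models, confounders, alpha=alpha, n_boot=n_boot, seed=seed,
        method=method,
    )
    return fits, select_model(fits)


def replication_fisher(
    consensus_net: CorrelationNetwork, model: PathwayModel
) -> tuple[np.ndarray, float]:
    """Do edges replicated in all cohorts concentrate at distance 1?

    Only pairs significant in at least one cohort enter; the 2x2 table
    crosses replication status (significant in all cohorts) with pathway
    distance == 1.  "X" and excluded cross-subclass pairs are omitted.
    """
    if consensus_net.counts is None:
        raise ValueError("expected a consensus network with replication counts")
    cls = classify_pairs(consensus_net, model)
    iu, ju = consensus_net.triu()
    counts = consensus_net.counts[iu, ju]
    t = cls.table.assign(count=counts)
    t = t[(t["category"] == "distance") & (t["count"] >= 1)]
    if not len(t):
        raise ValueError("no within-subclass pairs significant in any cohort")
    replicated = t["significant"].astype(bool)  # mask = significant in all
    close = t["distance"] == 1
    table = np.array(
        [
            [int((replicated & close).sum()), int((replicated & ~close).sum())],
            [int((~replicated & close).sum()), int((~replicated & ~close).sum())],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        raise ValueError("degenerate replication contingency table")
    return table, fisher_exact_2x2(table)
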