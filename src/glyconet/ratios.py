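"""Product–substrate ratio traits and the p-gain statistic.

For every pathway reaction with both endpoints measured in a subclass,
the trait is ``log(product / substrate)``, residualized on age and sex
and then rank-based inverse-normal transformed.  Ratio traits sharpen
genetic association signals at the catalyzing enzyme's locus; the
*p-gain* — min(single-glycan association p-values) / ratio p-value —
quantifies that sharpening, with >= 10 read as a meaningful gain
(one order of magnitude).

Only the trait construction, the p-gain arithmetic and a simple additive
linear-model association (for synthetic genotype dosages) live here; no
genome-scale association machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pathway import PathwayModel, Reaction, SUBCLASSES

__all__ = [
    "PGAIN_THRESHOLD",
    "GENOMEWIDE_BASE",
    "SUGGESTIVE_THRESHOLD",
    "RatioTrait",
    "inverse_normal",
    "residualize",
    "ratio_traits",
    "p_gain",
    "additive_association",
    "genomewide_threshold",
]

PGAIN_THRESHOLD = 10.0
GENOMEWIDE_BASE = 5e-8
SUGGESTIVE_THRESHOLD = 1e-7


@dataclass
class RatioTrait:
    reaction: Reaction
    subclass: str
    values: pd.Series  # residualized + inverse-normal transformed

    @property
    def name(self) -> str:
        return (
            f"{self.subclass}_{self.reaction.product.name}"
            f"/{self.reaction.substrate.name}"
        )


def inverse_normal(x: pd.Series | np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offsets).

    Maps values to standard-normal quantiles of ``(rank - 3/8) /
    (n + 1/4)``; ties get average ranks.
    """
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def residualize(y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of ``y`` on the covariates (with intercept)."""
    X = np.column_stack(
        [np.ones(len(y))] + [covariates[c].to_numpy(dtype=float) for c in covariates]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def ratio_traits(
    values: pd.DataFrame,
    model: PathwayModel,
    covariates: pd.DataFrame | None = None,
) -> list[RatioTrait]:
    """One trait per (reaction, subclass) with both endpoints measured.

    ``values`` must hold strictly positive abundances with glycoform
    columns (``IgG1_G0F`` style).  Pipeline per trait: log ratio ->
    residualize on covariates -> rank-based inverse normal.
    """
    traits: list[RatioTrait] = []
    cols = set(values.columns)
    for reaction in sorted(model.reactions):
        for sub in SUBCLASSES:
            s_col = f"{sub}_{reaction.substrate.name}"
            p_col = f"{sub}_{reaction.product.name}"
            if s_col not in cols or p_col not in cols:
                continue  # endpoint not measured in this subclass
            s = values[s_col].to_numpy(dtype=float)
            p = values[p_col].to_numpy(dtype=float)
            if (s <= 0).any() or (p <= 0).any():
                raise ValueError(
                    f"non-positive abundance for ratio {p_col}/{s_col}"
                )
            y = np.log(p / s)
            if covariates is not None and len(covariates.columns):
                y = residualize(y, covariates.reindex(values.index))
            traits.append(
                RatioTrait(
                    reaction=reaction,
                    subclass=sub,
                    values=pd.Series(inverse_normal(y), index=values.index),
                )
            )
    return traits


def p_gain(p_ratio: float, p_substrate: float, p_product: float) -> float:
    """min(single-glycan p-values) / ratio p-value.

    Values >= 10 (one order of magnitude) flag a meaningful gain of the
    ratio over its parts.
    """
    for name, p in (
        ("p_ratio", p_ratio),
        ("p_substrate", p_substrate),
        ("p_product", p_product),
    ):
        if not 0 < p <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    return min(p_substrate, p_product) / p_ratio


def additive_association(trait: np.ndarray | pd.Series, dosage: np.ndarray) -> float:
    """Slope-test p-value of a linear regression of trait on dosage.

    Stand-in for an additive genetic model on allele dosages in [0, 2].
    """
    trait = np.asarray(trait, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if dosage.min() < 0 or dosage.max() > 2:
        raise ValueError("dosages must lie in [0, 2]")
    if len(trait) != len(dosage):
        raise ValueError("trait and dosage lengths differ")
    if np.ptp(dosage) == 0:
        raise ValueError("constant dosage vector")
    res = stats.linregress(dosage, trait)
    return float(res.pvalue)


def genomewide_threshold(
    n_ratios: int, base: float = GENOMEWIDE_BASE
) -> float:
    """Bonferroni-corrected genome-wide significance threshold:
    ``base / n_ratios`` for the number of ratio traits tested."""
    if n_ratios < 1:
        raise ValueError("n_ratios must be positive")
    return base / n_ratios
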