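"""Synthetic glycomics cohorts with a prescribed conditional-dependence
structure.

The generator plants a Gaussian graphical model whose edges are exactly
the reactions of a chosen pathway model: the latent precision matrix has
unit diagonal, ``-rho`` on within-subclass reaction edges and ``-rho_x``
on same-structure cross-subclass pairs, so the implied partial
correlation of every planted edge is ``+rho`` (``+rho_x``).  On top of
the latent multivariate-normal log-abundances it layers the nuisance
structure real cohorts show: age and sex effects, per-sample dilution
(log-normal factors, removable by PQN) and optional missingness.
Abundances are exponentiated, i.e. log-normal.

Every draw stores its ground truth (edges, dilution factors, precision
matrix), making the generator the test bed for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway import PathwayModel, Reaction, SUBCLASSES, known_pathway
from .preprocess import GlycomicsMatrix

__all__ = ["SimulationConfig", "build_precision", "simulate_cohort", "simulate_variant"]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the discovery-cohort setting: ~700 unrelated adult
    samples, planted edge partial correlations of 0.35, moderate
    same-structure cross-subclass coupling, small age/sex effects on the
    log scale and a log-normal dilution spread.
    """

    model: PathwayModel = field(default_factory=known_pathway)
    n_samples: int = 700
    rho: float = 0.35
    rho_x: float = 0.25
    age_effect: float = 0.01   # per year, on the log scale, sign by (gal+sia)
    sex_effect: float = 0.10   # log-scale shift for fucosylated glycoforms
    latent_sd: float = 0.30    # marginal SD of log-abundances
    dilution_sd: float = 0.30  # sigma of the log-normal dilution factors
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("rho", "rho_x"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ValueError(f"{name} must be in (-1, 1), got {v}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    def glycoform_labels(self) -> list[str]:
        return [g.label for g in self.model.glycoforms()]


def build_precision(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Precision matrix over the measured glycoforms.

    Unit diagonal; ``-rho`` on reaction edges within each subclass block
    and ``-rho_x`` on same-structure cross-subclass pairs, zero
    elsewhere — so the nonzero pattern equals the model adjacency and
    the planted partial correlations equal ``rho`` / ``rho_x``.  If the
    matrix is not positive definite the off-diagonals are scaled down
    just enough (spectrally) to restore a safe margin.

    Raises
    ------
    ValueError
        If positive definiteness cannot be achieved (advice: smaller rho).
    """
    glyco = config.model.glycoforms()
    labels = [g.label for g in glyco]
    p = len(labels)
    idx = {g: i for i, g in enumerate(glyco)}
    coupling = np.zeros((p, p))
    for r in config.model.reactions:
        for sub in SUBCLASSES:
            measured = config.model.measured.get(sub, frozenset())
            if r.substrate in measured and r.product in measured:
                i = idx[next(g for g in glyco if g.subclass == sub and g.structure == r.substrate)]
                j = idx[next(g for g in glyco if g.subclass == sub and g.structure == r.product)]
                coupling[i, j] = coupling[j, i] = config.rho
    for a in glyco:
        for b in glyco:
            if a.subclass < b.subclass and a.structure == b.structure:
                i, j = idx[a], idx[b]
                coupling[i, j] = coupling[j, i] = config.rho_x
    omega = np.eye(p) - coupling
    eig = np.linalg.eigvalsh(omega)
    if eig.min() <= 1e-8:
        lam_max = float(np.linalg.eigvalsh(coupling).max())
        omega = np.eye(p) - coupling * (0.99 / lam_max)
        if np.linalg.eigvalsh(omega).min() <= 0:
            raise ValueError(
                "precision matrix not positive definite; use a smaller rho"
            )
    return labels, omega


def _covariate_effects(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-glycoform age and sex coefficients on the log scale.

    Age shifts galactosylated/sialylated structures down (the well-known
    age-related loss of galactosylation) and agalactosylated ones up;
    sex shifts fucosylated structures.
    """
    glyco = [g.structure for g in config.model.glycoforms()]
    age = np.array(
        [-config.age_effect * (s.gal + s.sia - 1.5) / 1.5 for s in glyco]
    )
    sex = np.array([config.sex_effect * (0.5 - float(s.fuc)) for s in glyco])
    return age, sex


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GlycomicsMatrix, dict]:
    """Draw a synthetic cohort; returns (matrix, truth).

    ``truth`` records the planted edge list, the precision matrix, the
    per-sample dilution factors and the covariate coefficients.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels, omega = build_precision(config)
    p = len(labels)
    n = config.n_samples
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    sigma_corr = sigma / np.outer(d, d)  # unit-variance latent scale
    chol = np.linalg.cholesky(sigma_corr)
    z = rng.standard_normal((n, p)) @ chol.T * config.latent_sd
    age = rng.uniform(18, 88, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    beta_age, beta_sex = _covariate_effects(config)
    baseline = rng.uniform(-0.5, 1.5, size=p)  # log-scale abundance offsets
    log_abund = (
        z
        + baseline[None, :]
        + np.outer(age - age.mean(), beta_age)
        + np.outer(sex, beta_sex)
    )
    dilution = np.exp(rng.normal(0.0, config.dilution_sd, size=n))
    values = np.exp(log_abund) * dilution[:, None]
    if config.missing_rate > 0:
        miss = rng.random((n, p)) < config.missing_rate
        values = np.where(miss, np.nan, values)
    index = pd.RangeIndex(n, name="sample")
    matrix = GlycomicsMatrix(
        values=pd.DataFrame(values, index=index, columns=labels),
        covariates=pd.DataFrame({"age": age, "sex": sex}, index=index),
        cohort="synthetic",
    )
    truth = {
        "labels": labels,
        "precision": omega,
        "edges": {
            frozenset((labels[i], labels[j]))
            for i, j in zip(*np.nonzero(np.triu(omega, k=1)))
        },
        "dilution": pd.Series(dilution, index=index),
        "beta_age": beta_age,
        "beta_sex": beta_sex,
    }
    return matrix, truth


def simulate_variant(
    config: SimulationConfig,
    reaction: Reaction,
    beta: float,
    maf: float = 0.3,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GlycomicsMatrix, dict]:
    """Cohort plus a genetic variant acting on one reaction.

    Dosages are Binomial(2, maf); each allele shifts the reaction's
    product up and its substrate down by ``beta/2`` on the latent log
    scale (in every subclass where both endpoints are measured).
    """
    if reaction not in config.model.reactions:
        raise ValueError(f"reaction {reaction} not in the pathway model")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    matrix, truth = simulate_cohort(config, rng=rng)
    dosage = rng.binomial(2, maf, size=config.n_samples).astype(float)
    values = matrix.values.copy()
    for sub in SUBCLASSES:
        measured = config.model.measured.get(sub, frozenset())
        if reaction.substrate in measured and reaction.product in measured:
            s_col = f"{sub}_{reaction.substrate.name}"
            p_col = f"{sub}_{reaction.product.name}"
            values[p_col] = values[p_col] * np.exp(beta / 2 * dosage)
            values[s_col] = values[s_col] * np.exp(-beta / 2 * dosage)
    truth["dosage_beta"] = beta
    return dosage, GlycomicsMatrix(values, matrix.covariates, matrix.cohort), truth
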