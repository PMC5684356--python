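"""Normalization and sample filtering for glycomics abundance tables.

The pipeline mirrors standard glycomics/metabolomics preprocessing:

1. drop samples with missing values (:func:`drop_incomplete`),
2. probabilistic quotient normalization per IgG subclass
   (:func:`pqn_normalize`) to remove per-sample dilution,
3. natural-log transform (:func:`log_transform`) — glycan abundances are
   closer to log-normal than normal,
4. optional removal of related samples given a kinship matrix
   (:func:`select_unrelated`), keeping no pair above the kinship
   threshold 0.0312 (first-degree cousins or closer).

An optional per-batch location-scale adjuster (:func:`batch_adjust`) is
provided as a simple, transparent alternative to empirical-Bayes batch
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathway import SUBCLASSES, parse_glycoform

__all__ = [
    "GlycomicsMatrix",
    "KINSHIP_THRESHOLD",
    "pqn_normalize",
    "log_transform",
    "drop_incomplete",
    "select_unrelated",
    "batch_adjust",
    "preprocess_pipeline",
]

#: kinship above this implies first-degree cousins or closer
KINSHIP_THRESHOLD = 0.0312


@dataclass
class GlycomicsMatrix:
    """Samples x glycoforms abundances with per-sample covariates.

    Column labels must parse as glycoform labels (``IgG1_G0F`` style);
    ``covariates`` is indexed like ``values`` and carries at least
    ``age`` (years) and ``sex`` (0/1).
    """

    values: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    cohort: str | None = None

    def __post_init__(self) -> None:
        for col in self.values.columns:
            parse_glycoform(col)  # raises on malformed labels
        if len(self.covariates) and not self.covariates.index.equals(
            self.values.index
        ):
            self.covariates = self.covariates.reindex(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subclass_of(self) -> pd.Series:
        """Subclass label for each glycoform column."""
        return pd.Series(
            {c: parse_glycoform(c).subclass for c in self.values.columns}
        )

    def subset(self, index) -> "GlycomicsMatrix":
        cov = self.covariates.loc[index] if len(self.covariates) else self.covariates
        return GlycomicsMatrix(self.values.loc[index], cov, self.cohort)


def _subclass_groups(columns) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for c in columns:
        groups.setdefault(parse_glycoform(c).subclass, []).append(c)
    return groups


def pqn_normalize(
    values: pd.DataFrame, per_subclass: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probabilistic quotient normalization.

    The reference profile is the per-glycoform median over all samples.
    Each sample is divided by the median of its per-glycoform quotients
    against the reference (its dilution factor).  With
    ``per_subclass=True`` the procedure is applied independently within
    each IgG subclass block, yielding one dilution factor per sample per
    subclass.

    Returns
    -------
    normalized : DataFrame
        Same shape as ``values``.
    factors : DataFrame
        Samples x subclass (or single column ``all``) dilution factors.

    Raises
    ------
    ValueError
        If a reference entry is not strictly positive (names the
        offending glycoform).
    """
    groups = (
        _subclass_groups(values.columns)
        if per_subclass
        else {"all": list(values.columns)}
    )
    normalized = values.copy().astype(float)
    factors = pd.DataFrame(index=values.index, dtype=float)
    for name, cols in groups.items():
        block = values[cols].astype(float)
        reference = block.median(axis=0)
        bad = reference[~(reference > 0)]
        if len(bad):
            raise ValueError(
                f"non-positive PQN reference median for glycoform(s) "
                f"{list(bad.index)}"
            )
        quotients = block / reference
        f = quotients.median(axis=1)
        normalized[cols] = block.div(f, axis=0)
        factors[name] = f
    return normalized, factors


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise natural log; errors on non-positive entries with
    their coordinates."""
    arr = values.to_numpy(dtype=float)
    bad = np.argwhere(~(arr > 0) & ~np.isnan(arr))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-positive abundance at sample {values.index[i]!r}, "
            f"glycoform {values.columns[j]!r}"
        )
    return pd.DataFrame(np.log(arr), index=values.index, columns=values.columns)


def drop_incomplete(values: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Remove samples (rows) containing any missing value.

    Returns the retained matrix and the list of dropped sample ids.
    """
    mask = values.isna().any(axis=1)
    dropped = list(values.index[mask])
    return values.loc[~mask], dropped


def select_unrelated(
    kinship: pd.DataFrame, threshold: float = KINSHIP_THRESHOLD
) -> list:
    """Greedily select samples so no retained pair exceeds ``threshold``.

    Repeatedly drops the sample implicated in the most above-threshold
    pairs (ties broken by lowest sample id) until no violating pair
    remains — removing hubs of relatedness first keeps the most samples.

    Raises
    ------
    ValueError
        If the kinship matrix is not symmetric.
    """
    if list(kinship.index) != list(kinship.columns):
        raise ValueError("kinship matrix must have identical row/column ids")
    arr = kinship.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, equal_nan=True):
        raise ValueError("kinship matrix is not symmetric")
    ids = list(kinship.index)
    above = arr > threshold
    np.fill_diagonal(above, False)
    keep = np.ones(len(ids), dtype=bool)
    while True:
        degree = (above & keep[None, :] & keep[:, None]).sum(axis=1)
        degree[~keep] = 0
        if degree.max() == 0:
            break
        worst = int(np.flatnonzero(degree == degree.max())[0])  # lowest index
        keep[worst] = False
    return [ids[i] for i in np.flatnonzero(keep)]


def batch_adjust(values: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Per-batch median-centering and MAD-scaling on the log scale.

    A simple location-scale adjuster: within each batch, every glycoform
    column is centered to the global column median and scaled to the
    global column MAD.  Intended for log-transformed data.
    """
    batches = batches.reindex(values.index)
    global_med = values.median(axis=0)
    global_mad = (values - global_med).abs().median(axis=0).replace(0.0, 1.0)
    out = values.copy()
    for _, idx in values.groupby(batches).groups.items():
        block = values.loc[idx]
        med = block.median(axis=0)
        mad = (block - med).abs().median(axis=0).replace(0.0, 1.0)
        out.loc[idx] = (block - med) / mad * global_mad + global_med
    return out


def preprocess_pipeline(
    matrix: GlycomicsMatrix,
    kinship: pd.DataFrame | None = None,
    threshold: float = KINSHIP_THRESHOLD,
    log: bool = True,
) -> tuple[GlycomicsMatrix, dict]:
    """Complete preprocessing: drop incomplete -> unrelated filter -> PQN
    -> log.  Returns the analysis-ready matrix and a provenance dict.

    The PQN reference is computed after both sample filters, so every
    retained sample contributes to the reference profile.
    """
    info: dict = {"n_input": matrix.n_samples}
    values, dropped = drop_incomplete(matrix.values)
    info["dropped_incomplete"] = dropped
    if kinship is not None:
        common = [s for s in values.index if s in kinship.index]
        retained = select_unrelated(kinship.loc[common, common], threshold)
        info["dropped_related"] = sorted(set(common) - set(retained))
        values = values.loc[[s for s in values.index if s not in set(info["dropped_related"])]]
    values, factors = pqn_normalize(values, per_subclass=True)
    info["dilution_factors"] = factors
    if log:
        values = log_transform(values)
    info["n_retained"] = len(values)
    cov = (
        matrix.covariates.loc[values.index]
        if len(matrix.covariates)
        else matrix.covariates
    )
    return GlycomicsMatrix(values, cov, matrix.cohort), info
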