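"""Correlation-network estimation for glycomics data.

Two network estimators are provided:

* :func:`pearson_network` — pairwise product–moment correlations with
  t-distribution p-values;
* :func:`partial_correlation` — shrinkage partial correlations in the
  Schäfer–Strimmer style: the sample correlation matrix is shrunk toward
  the identity with the analytic intensity
  ``lambda* = sum Var(r_ij) / sum r_ij^2`` (clipped to [0, 1]), inverted,
  and rescaled to partial correlations.  Confounders (age, sex) are
  included as extra columns during estimation and dropped from the
  returned network, so every coefficient is conditioned on them.

Multiple testing is controlled by Benjamini–Hochberg FDR over all tested
pairs.  The final Gaussian graphical model (:func:`build_ggm`) keeps a
partial-correlation edge only if the corresponding Pearson correlation is
also significant, which suppresses spurious conditional dependencies
between marginally uncorrelated variables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationNetwork",
    "pearson_network",
    "shrinkage_intensity",
    "partial_correlation",
    "pcor_significance",
    "build_ggm",
    "ggm",
    "consensus",
]


@dataclass
class CorrelationNetwork:
    """Symmetric coefficient matrix with p/q-values and an FDR mask."""

    labels: tuple[str, ...]
    coef: np.ndarray
    kind: str  # "pearson" | "partial"
    n_samples: int
    pvalues: np.ndarray | None = None
    qvalues: np.ndarray | None = None
    mask: np.ndarray | None = None
    alpha: float | None = None
    shrinkage: float | None = None
    confounders: tuple[str, ...] = ()
    counts: np.ndarray | None = None  # per-edge replication counts (consensus)

    def __post_init__(self) -> None:
        p = len(self.labels)
        if self.coef.shape != (p, p):
            raise ValueError("coefficient matrix shape does not match labels")
        if not np.allclose(self.coef, self.coef.T, atol=1e-10):
            raise ValueError("coefficient matrix is not symmetric")

    @property
    def n_vars(self) -> int:
        return len(self.labels)

    def triu(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the upper triangle (i < j)."""
        return np.triu_indices(self.n_vars, k=1)

    def edges(self) -> pd.DataFrame:
        """Tidy per-pair table (node1, node2, coefficient, p, q, significant)."""
        iu, ju = self.triu()
        df = pd.DataFrame(
            {
                "node1": [self.labels[i] for i in iu],
                "node2": [self.labels[j] for j in ju],
                "coefficient": self.coef[iu, ju],
            }
        )
        if self.pvalues is not None:
            df["p"] = self.pvalues[iu, ju]
        if self.qvalues is not None:
            df["q"] = self.qvalues[iu, ju]
        if self.mask is not None:
            df["significant"] = self.mask[iu, ju]
        if self.counts is not None:
            df["count"] = self.counts[iu, ju]
        return df

    def significant_pairs(self) -> set[frozenset]:
        iu, ju = self.triu()
        sel = self.mask[iu, ju]
        return {
            frozenset((self.labels[i], self.labels[j]))
            for i, j in zip(iu[sel], ju[sel])
        }


def _bh_mask(pvalues: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up over the upper triangle; returns symmetric (q, mask)."""
    p = pvalues.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    rej, q, _, _ = multipletests(pvalues[iu, ju], alpha=alpha, method="fdr_bh")
    qmat = np.zeros_like(pvalues)
    mmat = np.zeros_like(pvalues, dtype=bool)
    qmat[iu, ju] = qmat[ju, iu] = q
    mmat[iu, ju] = mmat[ju, iu] = rej
    return qmat, mmat


def pearson_network(values: pd.DataFrame, alpha: float = 0.01) -> CorrelationNetwork:
    """Pairwise Pearson correlation network with BH FDR control.

    P-values come from the exact t-distribution transform
    ``t = r sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom.
    """
    n, p = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    zero = np.flatnonzero(sd <= 1e-12 * (np.abs(arr.mean(axis=0)) + 1.0))
    if len(zero):
        raise ValueError(
            f"zero-variance glycoform {values.columns[zero[0]]!r}"
        )
    r = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(r, 1.0)
    rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1 - rr**2))
    pv = 2 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pv, 0.0)
    q, mask = _bh_mask(pv, alpha)
    return CorrelationNetwork(
        labels=tuple(values.columns),
        coef=r,
        kind="pearson",
        n_samples=n,
        pvalues=pv,
        qvalues=q,
        mask=mask,
        alpha=alpha,
    )


def shrinkage_intensity(x: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    ``lambda* = sum_{i<j} Var-hat(r_ij) / sum_{i<j} r_ij^2`` with the
    variance of each correlation coefficient estimated from the centered
    cross-products of the standardized data; clipped to [0, 1].
    """
    n, p = x.shape
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = (xs.T @ xs) / (n - 1)
    iu, ju = np.triu_indices(p, k=1)
    # w_kij = xs_ki * xs_kj; Var(r_ij) = n/(n-1)^3 * sum_k (w_kij - wbar)^2
    w = xs[:, iu] * xs[:, ju]
    wbar = w.mean(axis=0)
    var_r = n / (n - 1) ** 3 * ((w - wbar) ** 2).sum(axis=0)
    denom = (r[iu, ju] ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(var_r.sum() / denom, 0.0, 1.0))


def partial_correlation(
    values: pd.DataFrame,
    confounders: pd.DataFrame | None = None,
    shrinkage: float | None = None,
) -> CorrelationNetwork:
    """Shrinkage-estimated partial correlations between all columns.

    Confounder columns are appended for estimation (so all coefficients
    are conditioned on them) but dropped from the returned network.
    ``shrinkage`` overrides the analytic intensity (0 = plain inversion
    of the sample correlation matrix).
    """
    if values.shape[0] <= 3:
        raise ValueError("need more than 3 samples")
    cols = list(values.columns)
    if confounders is not None and len(confounders.columns):
        conf_cols = tuple(confounders.columns)
        x = pd.concat([values, confounders.reindex(values.index)], axis=1)
    else:
        conf_cols = ()
        x = values
    arr = x.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values in input")
    sd = arr.std(axis=0)
    zero = sd <= 1e-12 * (np.abs(arr.mean(axis=0)) + 1.0)
    if zero.any():
        bad = x.columns[int(np.flatnonzero(zero)[0])]
        raise ValueError(f"zero-variance column {bad!r}")
    lam = shrinkage_intensity(arr) if shrinkage is None else float(shrinkage)
    r = np.corrcoef(arr, rowvar=False)
    p_all = r.shape[0]
    r_shrunk = (1.0 - lam) * r + lam * np.eye(p_all)
    try:
        omega = np.linalg.inv(r_shrunk)
    except np.linalg.LinAlgError as exc:  # lambda=0 on singular input
        raise ValueError(
            "shrunken correlation matrix is singular; use shrinkage > 0"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    keep = np.arange(len(cols))
    pcor = pcor[np.ix_(keep, keep)]
    return CorrelationNetwork(
        labels=tuple(cols),
        coef=pcor,
        kind="partial",
        n_samples=values.shape[0],
        shrinkage=lam,
        confounders=conf_cols,
    )


def _empirical_null_pvalues(coef: np.ndarray) -> np.ndarray:
    """P-values from a fitted empirical null for partial correlations.

    Under the null, a partial correlation r follows the density
    ``f0(r; kappa) ~ (1 - r^2)^((kappa-3)/2)``, i.e. ``r^2 ~
    Beta(1/2, (kappa-1)/2)``.  ``kappa`` (the effective degrees of
    freedom) is fitted by maximum likelihood to all observed
    coefficients, treating the edge population as predominantly null —
    the GeneNet-style mixture approach.
    """
    iu, ju = np.triu_indices(coef.shape[0], k=1)
    r2 = np.clip(coef[iu, ju] ** 2, 1e-300, 1 - 1e-12)

    def nll(log_kappa: float) -> float:
        kappa = np.exp(log_kappa) + 3.0
        return -np.sum(stats.beta.logpdf(r2, 0.5, (kappa - 1.0) / 2.0))

    res = optimize.minimize_scalar(nll, bounds=(0.0, 15.0), method="bounded")
    kappa = float(np.exp(res.x) + 3.0)
    pv_flat = stats.beta.sf(r2, 0.5, (kappa - 1.0) / 2.0)
    pv = np.zeros_like(coef)
    pv[iu, ju] = pv[ju, iu] = pv_flat
    return pv


def pcor_significance(
    network: CorrelationNetwork,
    alpha: float = 0.01,
    method: str = "fisher_z",
) -> CorrelationNetwork:
    """Attach p/q-values and an FDR mask to a partial-correlation network.

    ``method="fisher_z"`` (default): z = atanh(r) scaled by the effective
    degrees of freedom ``df = n - k - 2 - c`` for a partial correlation of
    order ``k + c`` (k = other variables in the network, c = confounders);
    two-sided normal p-values with standard error ``1/sqrt(df - 1)``.

    ``method="empirical_null"``: fit a null distribution to the observed
    coefficients (parity mode for GeneNet-style analyses).
    """
    if network.kind != "partial":
        raise ValueError("pcor_significance expects a partial-correlation network")
    n = network.n_samples
    k = network.n_vars - 2
    c = len(network.confounders)
    if method == "fisher_z":
        df = n - k - 2 - c
        if df < 3:
            raise ValueError(f"too few samples: effective df = {df}")
        rr = np.clip(network.coef, -1 + 1e-15, 1 - 1e-15)
        z = np.arctanh(rr) * np.sqrt(df - 1)
        pv = 2 * stats.norm.sf(np.abs(z))
    elif method == "empirical_null":
        pv = _empirical_null_pvalues(network.coef)
    else:
        raise ValueError(f"unknown significance method {method!r}")
    np.fill_diagonal(pv, 0.0)
    q, mask = _bh_mask(pv, alpha)
    return replace(network, pvalues=pv, qvalues=q, mask=mask, alpha=alpha)


def build_ggm(
    pearson_net: CorrelationNetwork, partial_net: CorrelationNetwork
) -> CorrelationNetwork:
    """Final GGM: partial-correlation edges masked by Pearson significance.

    An edge is kept iff its partial correlation *and* its Pearson
    correlation are both significant; the coefficient (and its sign) is
    the partial correlation's.
    """
    if pearson_net.labels != partial_net.labels:
        raise ValueError("Pearson and partial networks have different labels")
    for net in (pearson_net, partial_net):
        if net.mask is None:
            raise ValueError(f"{net.kind} network has no significance mask")
    mask = partial_net.mask & pearson_net.mask
    return replace(partial_net, mask=mask)


def ggm(
    values: pd.DataFrame,
    confounders: pd.DataFrame | None = None,
    alpha: float = 0.01,
    method: str = "fisher_z",
) -> tuple[CorrelationNetwork, CorrelationNetwork, CorrelationNetwork]:
    """Convenience pipeline: Pearson net, partial net, and the masked GGM."""
    pearson = pearson_network(values, alpha=alpha)
    partial = pcor_significance(
        partial_correlation(values, confounders), alpha=alpha, method=method
    )
    return pearson, partial, build_ggm(pearson, partial)


def consensus(networks: list[CorrelationNetwork]) -> CorrelationNetwork:
    """Per-edge replication counts across cohorts.

    An edge is *replicated* (mask True) iff significant in every input
    network; ``counts`` records in how many networks each edge was
    significant.
    """
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    labels = networks[0].labels
    for net in networks[1:]:
        if net.labels != labels:
            raise ValueError("networks are defined on different label sets")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    coef = np.zeros((len(labels), len(labels)))
    for net in networks:
        if net.mask is None:
            raise ValueError("all networks need significance masks")
        counts += net.mask.astype(int)
        coef += net.coef
    coef /= len(networks)
    np.fill_diagonal(coef, 1.0)
    np.fill_diagonal(counts, 0)
    return CorrelationNetwork(
        labels=labels,
        coef=coef,
        kind="consensus",
        n_samples=min(n.n_samples for n in networks),
        mask=counts == len(networks),
        counts=counts,
    )
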