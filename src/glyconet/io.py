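"""Plain-text readers and writers for the pipeline's artifacts.

All tabular formats are CSV/TSV for auditability; networks additionally
export to GraphML for interchange with graph tools.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netinfer import CorrelationNetwork
from .preprocess import GlycomicsMatrix

__all__ = [
    "read_abundance_csv",
    "read_covariates_csv",
    "read_kinship",
    "read_matrix",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]


def read_abundance_csv(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Sample x glycoform abundance table; first column = sample id,
    header row = glycoform labels."""
    sep = sep if sep is not None else ("\t" if str(path).endswith(".tsv") else ",")
    return pd.read_csv(path, sep=sep, index_col=0)


def read_covariates_csv(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Covariates table (sample id, age, sex)."""
    sep = sep if sep is not None else ("\t" if str(path).endswith(".tsv") else ",")
    return pd.read_csv(path, sep=sep, index_col=0)


def read_kinship(path: str | Path) -> pd.DataFrame:
    """Kinship as a square CSV (ids on both axes) or long-format
    triplets (id1, id2, kinship)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 2:  # long format
        long = df.reset_index()
        long.columns = ["id1", "id2", "kinship"]
        ids = sorted(set(long["id1"]) | set(long["id2"]))
        out = pd.DataFrame(0.0, index=ids, columns=ids)
        for _, row in long.iterrows():
            out.loc[row["id1"], row["id2"]] = row["kinship"]
            out.loc[row["id2"], row["id1"]] = row["kinship"]
        return out
    df.columns = df.columns.astype(df.index.dtype, errors="ignore")
    return df


def read_matrix(
    abundance_path: str | Path,
    covariates_path: str | Path | None = None,
    cohort: str | None = None,
) -> GlycomicsMatrix:
    values = read_abundance_csv(abundance_path)
    cov = (
        read_covariates_csv(covariates_path)
        if covariates_path is not None
        else pd.DataFrame(index=values.index)
    )
    return GlycomicsMatrix(values, cov, cohort)


def write_edge_list(network: CorrelationNetwork, path: str | Path) -> None:
    """Tab-separated per-pair table (node1, node2, coefficient, p, q,
    significant [, count])."""
    network.edges().to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def to_graph(network: CorrelationNetwork, significant_only: bool = True) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(network.labels)
    iu, ju = network.triu()
    for i, j in zip(iu, ju):
        if significant_only and network.mask is not None and not network.mask[i, j]:
            continue
        g.add_edge(
            network.labels[i],
            network.labels[j],
            weight=float(network.coef[i, j]),
            sign=int(np.sign(network.coef[i, j])),
        )
    return g


def write_graphml(network: CorrelationNetwork, path: str | Path) -> None:
    nx.write_graphml(to_graph(network), path)
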