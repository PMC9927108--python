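"""Covariate-adjusted Spearman coabundance network across kingdoms.

Edges connect differential features (bacterial species, fungal species,
vOTUs) whose rank correlation — after residualizing the ranks on age, sex
and BMI — exceeds 0.6 in absolute value. vOTUs are then partitioned into
bacterium-dependent (at least one retained edge to a bacterial species)
and bacterium-independent sets.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "partial_spearman",
    "build_network",
    "classify_votus",
    "degree_summary",
    "to_graph",
]


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> float:
    """Spearman rank correlation of ``x`` and ``y`` given covariates.

    Ranks x, y, and each covariate column, residualizes the rank vectors
    of x and y on the (rank-transformed) covariates by least squares with
    an intercept, and returns the Pearson correlation of the residuals.
    With no covariates this is the ordinary Spearman rho. Zero-variance
    input is undefined and returns NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if covariates is None:
        z = np.empty((len(x), 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    if len(x) < 4 + z.shape[1]:
        raise ValueError("too few observations for the requested adjustment")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance input; correlation undefined", stacklevel=2)
        return float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(len(x))] + [sps.rankdata(c) for c in z.T])
    rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        warnings.warn("covariates explain x or y exactly; correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))


def build_network(
    profiles: pd.DataFrame,
    kingdoms: Mapping[str, str] | pd.Series,
    covariates: pd.DataFrame | None = None,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Evaluate all feature pairs and retain strong adjusted correlations.

    ``profiles`` is samples x features (restricted by the caller to the
    differential sets); ``kingdoms`` maps feature -> kingdom label.
    Returns an undirected edge list with columns ``source, target,
    kingdom_source, kingdom_target, rho`` keeping ``|rho| > threshold``.
    """
    kingdoms = pd.Series(kingdoms)
    missing = [f for f in profiles.columns if f not in kingdoms.index]
    if missing:
        raise ValueError(f"features without kingdom labels: {missing[:5]} ...")
    cov = covariates.loc[profiles.index].to_numpy() if covariates is not None else None
    feats = list(profiles.columns)
    x = profiles.to_numpy(dtype=float)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, j in itertools.combinations(range(len(feats)), 2):
            rho = partial_spearman(x[:, i], x[:, j], cov)
            if np.isfinite(rho) and abs(rho) > threshold:
                rows.append(
                    {
                        "source": feats[i],
                        "target": feats[j],
                        "kingdom_source": kingdoms[feats[i]],
                        "kingdom_target": kingdoms[feats[j]],
                        "rho": rho,
                    }
                )
    return pd.DataFrame(
        rows, columns=["source", "target", "kingdom_source", "kingdom_target", "rho"]
    )


def classify_votus(edges: pd.DataFrame, votus: Iterable[str]) -> dict[str, str]:
    """Partition vOTUs into bacterium-dependent vs -independent.

    A vOTU is dependent iff it has at least one retained edge to a
    bacterial feature. Returns feature -> "dependent" | "independent";
    the partition is exhaustive over ``votus`` and disjoint.
    """
    dependent: set[str] = set()
    for _, e in edges.iterrows():
        if e["kingdom_source"] == "bacteria" and e["kingdom_target"] != "bacteria":
            dependent.add(e["target"])
        if e["kingdom_target"] == "bacteria" and e["kingdom_source"] != "bacteria":
            dependent.add(e["source"])
    return {v: ("dependent" if v in dependent else "independent") for v in votus}


def degree_summary(edges: pd.DataFrame, top_k: int = 20) -> pd.DataFrame:
    """Rank nodes by number of incident retained edges (ties by node id)."""
    if edges.empty:
        return pd.DataFrame(columns=["node", "kingdom", "degree"])
    nodes = pd.concat(
        [
            edges[["source", "kingdom_source"]].rename(
                columns={"source": "node", "kingdom_source": "kingdom"}
            ),
            edges[["target", "kingdom_target"]].rename(
                columns={"target": "node", "kingdom_target": "kingdom"}
            ),
        ]
    )
    summary = (
        nodes.groupby(["node", "kingdom"]).size().reset_index(name="degree")
    )
    summary = summary.sort_values(
        ["degree", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return summary.head(top_k)


def to_graph(edges: pd.DataFrame) -> nx.Graph:
    """Edge list -> networkx graph (e.g. for GraphML export)."""
    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_node(e["source"], kingdom=e["kingdom_source"])
        g.add_node(e["target"], kingdom=e["kingdom_target"])
        g.add_edge(e["source"], e["target"], rho=float(e["rho"]))
    return g
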