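"""Co-expression profiling of binary mismatch columns (WGCNA-style).

Pairwise Pearson correlation of the 0/1 TcEMM columns (for binary columns
this is the phi coefficient), unsigned soft-threshold adjacency
a_ij = |r_ij|^beta, and a thresholded graph whose connected components of
size >= 2 are the co-expression *profiles*; all other mismatches are
singletons. With the default beta = 4, the adjacency cutoff 0.3
corresponds to a correlation cutoff 0.3^(1/4) ~ 0.74.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .engine import TcEMMMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationNetwork",
    "Profile",
    "tcemm_correlation",
    "soft_adjacency",
    "build_profiles",
    "export_graph",
    "CoexpressionProfiler",
    "ANNOTATION_KEYS",
]

ANNOTATION_KEYS = ("aft_significant", "lasso_selected", "posi_significant")


@dataclass
class CorrelationNetwork:
    """Correlation and soft-threshold adjacency over mismatch columns."""

    tcemm_ids: List[str]
    correlation: np.ndarray
    beta: Optional[float] = None
    adjacency: Optional[np.ndarray] = None

    def edges(self, threshold: float) -> List[Tuple[str, str, float, float]]:
        """(node1, node2, r, adjacency) for pairs with adjacency >= threshold."""
        if self.adjacency is None:
            raise ValueError("adjacency not computed; call soft_adjacency first")
        out = []
        n = len(self.tcemm_ids)
        iu = np.triu_indices(n, k=1)
        for i, j in zip(*iu):
            if self.adjacency[i, j] >= threshold:
                out.append(
                    (self.tcemm_ids[i], self.tcemm_ids[j],
                     float(self.correlation[i, j]), float(self.adjacency[i, j]))
                )
        return out


@dataclass
class Profile:
    """A connected component of >= 2 co-expressed mismatches."""

    members: Set[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a profile needs at least 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


def tcemm_correlation(matrix: TcEMMMatrix, min_support: int = 1) -> CorrelationNetwork:
    """Exact Pearson (phi) correlation of binary mismatch columns.

    Columns with support below ``min_support`` and constant columns
    (all-absent or all-present: undefined variance) are dropped with a log
    entry.
    """
    dense = matrix.to_dense_df()
    support = dense.sum(axis=0)
    keep = dense.columns[(support >= min_support)]
    dropped = [c for c in dense.columns if c not in set(keep)]
    if dropped:
        logger.info("dropping %d low-support columns", len(dropped))
    dense = dense[keep]
    const = [c for c in dense.columns if dense[c].nunique() < 2]
    if const:
        logger.info("dropping %d constant columns: %s...", len(const), const[:3])
        dense = dense.drop(columns=const)
    if dense.shape[1] < 2:
        raise ValueError("fewer than 2 usable mismatch columns after filtering")
    corr = np.corrcoef(dense.to_numpy(float), rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return CorrelationNetwork(tcemm_ids=list(dense.columns), correlation=corr)


def soft_adjacency(network: CorrelationNetwork, beta: float = 4.0) -> CorrelationNetwork:
    """Unsigned soft-threshold adjacency a_ij = |r_ij|^beta (in place)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    adj = np.abs(network.correlation) ** beta
    np.fill_diagonal(adj, 1.0)
    network.beta = float(beta)
    network.adjacency = adj
    return network


def build_profiles(
    network: CorrelationNetwork, adjacency_threshold: float = 0.3
) -> Tuple[List[Profile], List[str]]:
    """Connected components of the thresholded adjacency graph.

    Components with >= 2 members are profiles; the rest are singletons.
    Profiles and singletons partition the node set.
    """
    if network.adjacency is None:
        raise ValueError("adjacency not computed; call soft_adjacency first")
    g = nx.Graph()
    g.add_nodes_from(network.tcemm_ids)
    for u, v, r, a in network.edges(adjacency_threshold):
        g.add_edge(u, v, r=r, adjacency=a)
    profiles, singletons = [], []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            profiles.append(Profile(members=set(comp)))
        else:
            singletons.extend(comp)
    profiles.sort(key=lambda p: (-p.size, min(p.members)))
    return profiles, sorted(singletons)


def export_graph(
    network: CorrelationNetwork,
    profiles: Sequence[Profile],
    annotations: Optional[Mapping[str, Mapping[str, bool]]] = None,
    adjacency_threshold: float = 0.3,
    path: str | Path | None = None,
) -> nx.Graph:
    """Annotated co-expression graph; GraphML written when ``path`` given.

    ``annotations`` maps an allowed key (screen/selection status flags) to a
    per-mismatch boolean map. Unknown keys raise.
    """
    annotations = annotations or {}
    unknown = set(annotations) - set(ANNOTATION_KEYS)
    if unknown:
        raise KeyError(f"unknown annotation key(s): {sorted(unknown)}")
    g = nx.Graph()
    member_of = {}
    for k, prof in enumerate(profiles):
        for m in prof.members:
            member_of[m] = k
    for node in network.tcemm_ids:
        attrs = {key: bool(val.get(node, False)) for key, val in annotations.items()}
        attrs["profile"] = member_of.get(node, -1)
        g.add_node(node, **attrs)
    if network.adjacency is not None:
        for u, v, r, a in network.edges(adjacency_threshold):
            g.add_edge(u, v, r=r, weight=a)
    if path is not None:
        nx.write_graphml(g, str(path))
    return g


class CoexpressionProfiler(BaseEstimator):
    """Estimator wrapper: fit the co-expression network on a mismatch matrix.

    ``fit(X)`` accepts a :class:`TcEMMMatrix` (or a binary DataFrame) and
    exposes ``network_``, ``profiles_``, ``singletons_`` and
    ``fraction_in_profiles_``.
    """

    def __init__(self, beta: float = 4.0, adjacency_threshold: float = 0.3, min_support: int = 1):
        self.beta = beta
        self.adjacency_threshold = adjacency_threshold
        self.min_support = min_support

    def fit(self, X, y=None) -> "CoexpressionProfiler":
        if isinstance(X, pd.DataFrame):
            from scipy import sparse

            mat = TcEMMMatrix(
                pair_ids=[str(i) for i in X.index],
                tcemm_ids=list(X.columns),
                entries=sparse.csr_matrix(X.to_numpy(np.int8)),
                scores=X.to_numpy().sum(axis=1),
            )
        else:
            mat = X
        net = tcemm_correlation(mat, min_support=self.min_support)
        soft_adjacency(net, beta=self.beta)
        self.network_ = net
        self.profiles_, self.singletons_ = build_profiles(net, self.adjacency_threshold)
        n_nodes = len(net.tcemm_ids)
        in_profiles = sum(p.size for p in self.profiles_)
        self.fraction_in_profiles_ = in_profiles / n_nodes if n_nodes else 0.0
        return self

    def profile_table(self) -> pd.DataFrame:
        rows = []
        for k, p in enumerate(self.profiles_):
            for m in sorted(p.members):
                rows.append({"profile": k, "size": p.size, "tcemm": m})
        for m in self.singletons_:
            rows.append({"profile": -1, "size": 1, "tcemm": m})
        return pd.DataFrame(rows, columns=["profile", "size", "tcemm"])
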