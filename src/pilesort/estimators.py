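"""Scikit-learn style estimators wrapping the co-sort pipeline.

``CoSortTransformer`` turns long-format sorting records into a square
co-placement count matrix; ``LouvainClusterer`` clusters a precomputed
affinity (co-placement) matrix by modularity maximisation.  Both follow the
scikit-learn estimator contract (``get_params``/``set_params``, fitted
attributes with a trailing underscore) so they compose with
:class:`sklearn.pipeline.Pipeline`:

>>> from sklearn.pipeline import make_pipeline
>>> pipe = make_pipeline(CoSortTransformer(), LouvainClusterer(random_state=0))

The module-level functions in :mod:`pilesort.community` are thin wrappers
over these estimators for script use.
"""

from __future__ import annotations

from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from . import community as _community
from .network import CoSortNetwork, build_cosort_network
from .sortdata import PilesortError, SortingStudy, make_study


def _coerce_study(X) -> SortingStudy:
    if isinstance(X, SortingStudy):
        return X
    if isinstance(X, pd.DataFrame):
        if X.shape[1] != 3:
            raise PilesortError(
                f"expected 3 columns (researcher, quote, pile), got {X.shape[1]}"
            )
        return make_study([tuple(row) for row in X.itertuples(index=False)])
    return make_study([tuple(row) for row in X])


class CoSortTransformer(TransformerMixin, BaseEstimator):
    """Transform sorting records into a co-placement count matrix.

    Input ``X`` is a :class:`~pilesort.sortdata.SortingStudy`, a three-column
    DataFrame ``(researcher, quote, pile)``, or an iterable of such triples.
    The output is a dense symmetric ``(n_quotes, n_quotes)`` integer array
    whose (i, j) entry counts the researchers who co-placed quotes i and j
    (zero diagonal).  Row/column order is the sorted quote-id order, exposed
    as ``quote_ids_`` after :meth:`fit`.
    """

    def fit(self, X, y=None):
        study = _coerce_study(X)
        self.quote_ids_ = list(study.quotes)
        self.n_researchers_ = study.n_researchers
        return self

    def transform(self, X) -> np.ndarray:
        study = _coerce_study(X)
        if not hasattr(self, "quote_ids_"):
            self.fit(study)
        net = build_cosort_network(study)
        index = {q: k for k, q in enumerate(self.quote_ids_)}
        mat = np.zeros((len(index), len(index)), dtype=int)
        for i, j, d in net.graph.edges(data=True):
            if i in index and j in index:
                mat[index[i], index[j]] = mat[index[j], index[i]] = int(d["weight"])
        return mat


class LouvainClusterer(ClusterMixin, BaseEstimator):
    """Community detection on a precomputed affinity matrix.

    Parameters
    ----------
    resolution : float, default 1.0
        Modularity resolution gamma; larger values favour more, smaller
        communities.
    random_state : int, default 0
        Seed for the node-visit shuffle (Louvain output is order
        dependent).
    weighted : bool, default True
        If False, every non-zero affinity is treated as weight 1.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Zero-based community labels, ordered by descending community size
        (ties towards the smallest member index).
    modularity_ : float
        Modularity of the returned partition at ``resolution``.
    n_communities_ : int
        Number of detected communities.
    """

    def __init__(
        self, resolution: float = 1.0, random_state: int = 0, weighted: bool = True
    ):
        self.resolution = resolution
        self.random_state = random_state
        self.weighted = weighted

    def _to_graph(self, X) -> nx.Graph:
        if isinstance(X, CoSortNetwork):
            return X.graph
        if isinstance(X, nx.Graph):
            return X
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise PilesortError(
                f"expected a square affinity matrix, got shape {A.shape}"
            )
        if not np.allclose(A, A.T):
            raise PilesortError("affinity matrix must be symmetric")
        if (A < 0).any():
            raise PilesortError("affinity matrix must be non-negative")
        g = nx.Graph()
        g.add_nodes_from(range(A.shape[0]))
        ii, jj = np.nonzero(np.triu(A, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(i, j, weight=float(A[i, j]))
        return g

    def fit(self, X, y=None):
        g = self._to_graph(X)
        assignment = _community.louvain(
            g,
            seed=self.random_state,
            resolution=self.resolution,
            weighted=self.weighted,
        )
        nodes = sorted(g.nodes)
        self.node_ids_ = nodes
        self.assignment_ = assignment
        self.labels_ = np.array([assignment[n] - 1 for n in nodes], dtype=int)
        self.n_communities_ = int(self.labels_.max()) + 1 if nodes else 0
        if g.number_of_edges() > 0:
            self.modularity_ = _community.modularity(
                g, assignment, resolution=self.resolution, weighted=self.weighted
            )
        else:
            self.modularity_ = 0.0
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
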