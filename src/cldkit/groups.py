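"""Grouping of genomic neighborhoods by subfamily content.

Neighborhoods carrying at least 10 genes are encoded as a binary
presence/absence matrix over subfamilies, reduced linearly (PCA, 50
components), embedded into two dimensions with t-SNE (perplexity 50, 5000
iterations), and grouped by density with DBSCAN (radius 4 in embedding units).
Points DBSCAN leaves unassigned form a single catch-all pseudo-group, mirroring
how diffuse neighborhoods are reported alongside the crisp groups.

The estimator follows scikit-learn conventions (``fit``, ``fit_predict``,
``labels_``) and composes with sklearn model-selection utilities; the
:func:`embed_and_group` wrapper returns a plain result object with full
parameter provenance. The embedding is stochastic: identical inputs and seeds
reproduce identical labels, but group *numbering* across seeds is arbitrary,
so downstream comparisons should use permutation-invariant scores such as the
adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import EmptyInputError, MissingIdError, ParameterError
from .neighborhoods import Neighborhood
from .subfamilies import SubfamilyAssignment

__all__ = [
    "MIN_NEIGHBORHOOD_GENES",
    "NOISE_LABEL",
    "presence_matrix",
    "NeighborhoodGrouper",
    "GroupingResult",
    "embed_and_group",
]

#: Minimum gene count for a neighborhood to enter the grouping analysis.
MIN_NEIGHBORHOOD_GENES = 10

#: DBSCAN's label for unassigned points, kept as their own pseudo-group.
NOISE_LABEL = -1


def presence_matrix(
    neighborhoods: Iterable[Neighborhood],
    assignment: SubfamilyAssignment | Mapping[str, str],
    min_genes: int = MIN_NEIGHBORHOOD_GENES,
) -> pd.DataFrame:
    """Binary subfamily presence/absence matrix over qualifying neighborhoods.

    Rows are neighborhoods with at least ``min_genes`` member genes; columns
    are subfamily ids (sorted); entries are 1 when any member protein of the
    neighborhood belongs to the subfamily. A subfamily occurring several times
    in one neighborhood still scores 1.
    """
    mapping = (
        assignment.membership
        if isinstance(assignment, SubfamilyAssignment)
        else assignment
    )
    content: dict[str, set[str]] = {}
    for nbh in neighborhoods:
        if nbh.n_genes < min_genes:
            continue
        sids = set()
        for pid in nbh.protein_ids:
            if pid not in mapping:
                raise MissingIdError(
                    f"protein {pid!r} in neighborhood {nbh.neighborhood_id!r} "
                    "has no subfamily assignment"
                )
            sids.add(mapping[pid])
        content[nbh.neighborhood_id] = sids

    columns = sorted(set().union(*content.values())) if content else []
    matrix = pd.DataFrame(0, index=list(content), columns=columns, dtype=np.int8)
    for nid, sids in content.items():
        matrix.loc[nid, sorted(sids)] = 1
    matrix.index.name = "neighborhood_id"
    return matrix


class NeighborhoodGrouper(BaseEstimator, ClusterMixin):
    """PCA → t-SNE → DBSCAN grouping of presence/absence profiles.

    Parameters
    ----------
    reduce_dims : int, default 50
        Target dimensionality of the initial linear reduction; clipped to
        ``min(reduce_dims, n_features, n_samples - 1)``.
    perplexity : float, default 50
        t-SNE perplexity. Fitting requires ``n_samples > 3 * perplexity``
        for the embedding to be well posed.
    iterations : int, default 5000
        t-SNE gradient-descent iterations.
    distance : float, default 4.0
        DBSCAN radius in the two embedding dimensions.
    min_samples : int, default 5
        DBSCAN core-point threshold (no published value; recorded in output).
    random_state : int or None
        Seed for both reduction and embedding; required for reproducibility.

    Attributes (after ``fit``)
    ----------
    labels_ : ndarray of int
        Group label per row; ``-1`` is the catch-all pseudo-group.
    embedding_ : ndarray of shape (n_samples, 2)
        t-SNE coordinates.
    n_components_ : int
        Linear components actually used after clipping.
    """

    def __init__(
        self,
        reduce_dims: int = 50,
        perplexity: float = 50.0,
        iterations: int = 5000,
        distance: float = 4.0,
        min_samples: int = 5,
        random_state: int | None = None,
    ):
        self.reduce_dims = reduce_dims
        self.perplexity = perplexity
        self.iterations = iterations
        self.distance = distance
        self.min_samples = min_samples
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError(f"expected a 2-d matrix, got shape {X.shape}")
        if X.shape[0] == 0:
            raise EmptyInputError("presence matrix has no qualifying rows")
        minimum = int(3 * self.perplexity) + 1
        if X.shape[0] <= 3 * self.perplexity:
            raise ParameterError(
                f"grouping needs more than 3 x perplexity = {3 * self.perplexity:g} "
                f"rows ({minimum} minimum); got {X.shape[0]}"
            )
        if self.distance <= 0:
            raise ParameterError(f"distance must be > 0, got {self.distance}")
        if self.iterations < 250:
            raise ParameterError(
                f"iterations must be >= 250, got {self.iterations}"
            )
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        n_samples, n_features = X.shape
        self.n_components_ = min(self.reduce_dims, n_features, n_samples - 1)
        reduced = PCA(
            n_components=self.n_components_, random_state=self.random_state
        ).fit_transform(X)
        self.embedding_ = TSNE(
            n_components=2,
            perplexity=self.perplexity,
            max_iter=self.iterations,
            random_state=self.random_state,
            init="pca",
        ).fit_transform(reduced)
        self.labels_ = DBSCAN(
            eps=self.distance, min_samples=self.min_samples
        ).fit_predict(self.embedding_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass(frozen=True)
class GroupingResult:
    """Grouping output with full parameter provenance."""

    labels: pd.Series  # neighborhood_id -> group label (NOISE_LABEL = catch-all)
    embedding: pd.DataFrame  # columns x, y
    parameters: dict

    @property
    def n_groups(self) -> int:
        """Distinct groups, counting the catch-all pseudo-group if present."""
        return int(pd.unique(self.labels).size)

    def to_frame(self) -> pd.DataFrame:
        out = self.embedding.copy()
        out.insert(0, "group", self.labels)
        return out.reset_index()


def embed_and_group(
    matrix: pd.DataFrame,
    seed: int | None = 0,
    reduce_dims: int = 50,
    perplexity: float = 50.0,
    iterations: int = 5000,
    distance: float = 4.0,
    min_samples: int = 5,
) -> GroupingResult:
    """Functional wrapper over :class:`NeighborhoodGrouper`."""
    grouper = NeighborhoodGrouper(
        reduce_dims=reduce_dims,
        perplexity=perplexity,
        iterations=iterations,
        distance=distance,
        min_samples=min_samples,
        random_state=seed,
    )
    grouper.fit(matrix)
    labels = pd.Series(grouper.labels_, index=matrix.index, name="group")
    embedding = pd.DataFrame(
        grouper.embedding_, index=matrix.index, columns=["x", "y"]
    )
    params = dict(
        seed=seed,
        reduce_dims=reduce_dims,
        n_components=grouper.n_components_,
        perplexity=perplexity,
        iterations=iterations,
        distance=distance,
        min_samples=min_samples,
    )
    return GroupingResult(labels=labels, embedding=embedding, parameters=params)
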