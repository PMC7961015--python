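"""Consensus k-means phenotyping with PAC-based model selection.

Cells are clustered in the standardised clustering-marker space with
k-means (k-means++ initialisation, best of several restarts).  The number
of clusters is chosen by consensus clustering: for each candidate k the
fit is repeated on random subsamples, the consensus matrix records how
often each pair of cells co-clusters among subsamples containing both, and
the PAC statistic (proportion of ambiguously clustered pairs, consensus
strictly inside an interval such as (0.1, 0.9)) measures how cleanly the
data separates.  The k with minimal PAC wins; ties go to the smaller k.

Fitted clusters are relabelled canonically by optimally matching centroids
to the six phenotype archetypes (assignment problem on Euclidean
distances), so that cluster numbers 1..6 carry the same marker semantics
in every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .errors import ConfigurationError, DataError


@dataclass
class ClusterModel:
    """A fitted k-means model; centroid row i corresponds to label i+1."""

    k: int
    centroids: np.ndarray  # (k, n_markers)
    markers: list[str]
    n_fitted: int
    seed: int

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.k < 2:
            raise ConfigurationError("k must be >= 2")
        if self.centroids.shape[0] != self.k:
            raise ConfigurationError("centroid count must equal k")


def _as_matrix(X) -> np.ndarray:
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def kmeans_fit(X, k: int, seed: int = 0, restarts: int = 10,
               markers: list[str] | None = None) -> ClusterModel:
    """Lloyd's k-means with k-means++ init, best of ``restarts`` by WCSS."""
    import pandas as pd

    if markers is None and isinstance(X, pd.DataFrame):
        markers = list(X.columns)
    Xm = _as_matrix(X)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if Xm.shape[0] < k:
        raise DataError(f"need at least k={k} rows, got {Xm.shape[0]}")
    if not np.all(np.isfinite(Xm)):
        raise DataError("clustering matrix contains non-finite values")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed % (2 ** 31), algorithm="lloyd")
    km.fit(Xm)
    return ClusterModel(k=k, centroids=km.cluster_centers_,
                        markers=markers or [f"m{i}" for i in range(Xm.shape[1])],
                        n_fitted=Xm.shape[0], seed=seed)


def assign_clusters(model: ClusterModel, X) -> np.ndarray:
    """Nearest-centroid labels (1..k); distance ties -> lowest label."""
    Xm = _as_matrix(X)
    if Xm.shape[1] != model.centroids.shape[1]:
        raise DataError("matrix width does not match model markers")
    d = cdist(Xm, model.centroids)
    return d.argmin(axis=1) + 1  # argmin takes the first (lowest) on ties


@dataclass
class ConsensusResult:
    """Per-k PAC values (and optionally consensus matrices) plus chosen k."""

    pac: dict[int, float]
    chosen_k: int
    reps: int
    subsample_fraction: float
    consensus_matrices: dict[int, np.ndarray] = field(default_factory=dict)


def compute_pac(consensus: np.ndarray, lower: float = 0.1,
                upper: float = 0.9) -> float:
    """Proportion of ambiguously clustered pairs.

    The fraction of defined (non-NaN) off-diagonal pairs whose consensus
    value lies strictly inside ``(lower, upper)``; entries exactly at a
    bound count as unambiguous.  Pairs never co-sampled (NaN) are excluded.
    """
    if not 0 <= lower < upper <= 1:
        raise ConfigurationError("need 0 <= lower < upper <= 1")
    c = np.asarray(consensus, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise DataError("consensus matrix must be square")
    iu = np.triu_indices(c.shape[0], k=1)
    vals = c[iu]
    defined = ~np.isnan(vals)
    if not defined.any():
        return 0.0
    vals = vals[defined]
    return float(((vals > lower) & (vals < upper)).mean())


def select_k(pac: dict[int, float]) -> int:
    """k with minimal PAC; ties broken toward the smallest k."""
    if not pac:
        raise ConfigurationError("no candidate k values")
    best = min(sorted(pac), key=lambda k: (pac[k], k))
    return best


def consensus_cluster(X, k_range=range(2, 16), reps: int = 100,
                      subsample_fraction: float = 0.8, seed: int = 0,
                      restarts: int = 2, pac_interval=(0.1, 0.9),
                      store_matrices: bool | None = None) -> ConsensusResult:
    """Consensus k-means over a range of k with PAC model selection.

    For each k, ``reps`` subsamples of ``ceil(fraction * n)`` rows (without
    replacement) are clustered; consensus(i, j) = co-clustering count /
    co-sampling count.  Pairs never co-sampled are treated as undefined and
    excluded from PAC.  Matrices are stored when n is small (or on request);
    PAC itself is computed from the pair counts either way.
    """
    Xm = _as_matrix(X)
    n = Xm.shape[0]
    if reps < 2:
        raise ConfigurationError("reps must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ConfigurationError("subsample_fraction must be in (0, 1]")
    m = int(np.ceil(subsample_fraction * n))
    if m < max(k_range):
        raise DataError("subsample smaller than largest k")
    if store_matrices is None:
        store_matrices = n <= 2000
    lower, upper = pac_interval

    rng = np.random.default_rng(seed)
    pac: dict[int, float] = {}
    matrices: dict[int, np.ndarray] = {}
    for k in k_range:
        # one-hot membership stacked over reps -> co-cluster counts by matmul
        M = np.zeros((n, reps * k), dtype=np.float32)
        S = np.zeros((n, reps), dtype=np.float32)
        for r in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            sub_seed = int(rng.integers(2 ** 31))
            km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                        random_state=sub_seed, algorithm="lloyd")
            labels = km.fit_predict(Xm[idx])
            M[idx, r * k + labels] = 1.0
            S[idx, r] = 1.0
        C = M @ M.T  # co-cluster counts
        N = S @ S.T  # co-sample counts
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.divide(C, N, out=np.full_like(C, np.nan), where=N > 0)
        # PAC over defined off-diagonal pairs (symmetric -> fraction equal
        # whether pairs are counted once or twice)
        off_defined = (N > 0)
        np.fill_diagonal(off_defined, False)
        n_defined = int(off_defined.sum())
        if n_defined:
            amb = (ratio > lower) & (ratio < upper) & off_defined
            pac[k] = float(amb.sum() / n_defined)
        else:
            pac[k] = 0.0
        if store_matrices:
            cm = ratio.astype(float)
            np.fill_diagonal(cm, 1.0)
            matrices[k] = cm
        del M, S, C, N, ratio
    chosen = select_k(pac)
    return ConsensusResult(pac=pac, chosen_k=chosen, reps=reps,
                           subsample_fraction=subsample_fraction,
                           consensus_matrices=matrices)


def canonicalize_labels(model: ClusterModel, archetypes) -> tuple[ClusterModel, dict]:
    """Relabel fitted clusters to canonical archetype numbering.

    Solves the assignment problem minimising total Euclidean distance
    between fitted centroids and archetype means.  Archetype vectors are
    over (ER, HER2, cMET, SLC7A5); they are reordered to the model's
    marker order when the model was fitted on those markers.  If k differs
    from the number of archetypes the model is returned unchanged with a
    warning.  Returns ``(relabelled model, {fitted label -> canonical
    label})``.
    """
    from .preprocess import CLUSTERING_MARKERS

    arch_means = np.array([a.mean_z for a in archetypes], dtype=float)
    if model.markers and set(model.markers) == set(CLUSTERING_MARKERS):
        order = [CLUSTERING_MARKERS.index(m) for m in model.markers]
        arch_means = arch_means[:, order]
    labels = [a.label for a in archetypes]
    if model.k != len(archetypes):
        warnings.warn(f"k={model.k} does not match {len(archetypes)} "
                      "archetypes; labels left in fit order", stacklevel=2)
        return model, {i + 1: i + 1 for i in range(model.k)}
    d = cdist(model.centroids, arch_means)
    rows, cols = linear_sum_assignment(d)
    mapping = {int(r) + 1: int(labels[c]) for r, c in zip(rows, cols)}
    order = np.argsort([mapping[i + 1] for i in range(model.k)])
    new = ClusterModel(k=model.k, centroids=model.centroids[order],
                       markers=model.markers, n_fitted=model.n_fitted,
                       seed=model.seed)
    return new, mapping
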