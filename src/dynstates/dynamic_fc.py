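"""Sliding-window dynamic functional connectivity and k-means state analysis.

Rectangular windows of 30 TRs (step 1) over the cleaned component time
courses give per-window Fisher-z connectivity vectors; k-means over all
windows of all subjects identifies recurring connectivity states, with the
cluster number chosen by the silhouette criterion over k = 2..10.  States
are relabelled so State 1 always has the strongest mean centroid
connectivity, matching the strong/weak characterisation used when reporting
two-state solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .static_fc import ATANH_CLIP

__all__ = [
    "WindowSpec",
    "StateModel",
    "make_windows",
    "windowed_fc",
    "select_k",
    "cluster_states",
    "group_centroids",
    "state_edge_ttest",
    "top_edges",
]


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular sliding-window geometry, in TRs."""

    width: int = 30
    step: int = 1

    def __post_init__(self):
        if self.width < 2:
            raise ValueError("width must be >= 2 TRs")
        if self.step < 1:
            raise ValueError("step must be >= 1 TR")


def make_windows(n_timepoints: int, spec: WindowSpec = WindowSpec()):
    """Half-open index ranges [i, i+width) for i = 0, step, 2*step, ...

    The window count is ``floor((n_timepoints - width) / step)`` — the
    convention under which 120 post-discard timepoints with width 30 and
    step 1 yield exactly 90 overlapping windows.
    """
    if spec.width >= n_timepoints:
        raise ValueError(
            f"window width {spec.width} must be < n_timepoints {n_timepoints}"
        )
    n = (n_timepoints - spec.width) // spec.step
    if n < 1:
        raise ValueError("window specification yields no windows")
    return [(i * spec.step, i * spec.step + spec.width) for i in range(n)]


def windowed_fc(timecourses: np.ndarray, windows) -> np.ndarray:
    """Per-window Fisher-z connectivity vectors.

    Pearson correlation within each window, Fisher z with clipping at the
    atanh boundary, upper triangle vectorised in fixed row-major order.
    Zero-variance segments produce zero edges and increment a warning
    counter instead of NaNs.
    """
    tc = np.asarray(timecourses, dtype=float)
    n_comp = tc.shape[1]
    iu = np.triu_indices(n_comp, k=1)
    out = np.empty((len(windows), len(iu[0])))
    n_degenerate = 0
    for w, (a, b) in enumerate(windows):
        seg = tc[a:b]
        if np.any(seg.std(axis=0) == 0):
            n_degenerate += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg.T)[iu]
        r = np.nan_to_num(r, nan=0.0)   # zero-variance segments -> zero edges
        out[w] = np.arctanh(np.clip(r, -ATANH_CLIP, ATANH_CLIP))
    if n_degenerate:
        warnings.warn(f"{n_degenerate} window(s) had zero-variance segments",
                      RuntimeWarning, stacklevel=2)
    return out


def _kmedians(X, k, n_init, seed, max_iter=300):
    """Lloyd-style k-means under the cityblock metric (median centroids)."""
    rng = np.random.default_rng(seed)
    best_cost, best = np.inf, None
    for _ in range(n_init):
        centroids = X[rng.choice(len(X), size=k, replace=False)]
        for _ in range(max_iter):
            d = cdist(X, centroids, metric="cityblock")
            lab = d.argmin(axis=1)
            new = np.array([
                np.median(X[lab == j], axis=0) if (lab == j).any() else centroids[j]
                for j in range(k)
            ])
            if np.allclose(new, centroids):
                break
            centroids = new
        cost = cdist(X, centroids, metric="cityblock").min(axis=1).sum()
        if cost < best_cost:
            best_cost, best = cost, (centroids.copy(), lab.copy())
    return best[0], best[1], best_cost


def _fit_kmeans(X, k, n_init, seed, distance):
    if distance == "sqeuclidean":
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        return km.cluster_centers_, lab, float(km.inertia_)
    if distance == "cityblock":
        return _kmedians(X, k, n_init, seed)
    raise ValueError(f"unknown distance {distance!r}")


@dataclass
class StateModel:
    """Fitted connectivity-state clustering."""

    k: int
    centroids: np.ndarray            # (k, n_edges), State 1 = strongest
    assignments: np.ndarray          # (n_subjects, n_windows), states 1..k
    occurrence: np.ndarray           # fraction of all windows per state
    inertia: float
    distance: str = "sqeuclidean"
    silhouette_curve: dict | None = None   # k -> mean silhouette

    @property
    def state_vectors(self):
        return {i: self.assignments[i] for i in range(self.assignments.shape[0])}


def select_k(all_windows: np.ndarray, k_range=range(2, 11), n_init: int = 20,
             seed=None, distance: str = "sqeuclidean"):
    """Silhouette-based choice of the cluster number.

    Runs k-means for each candidate k and scores the clustering with the
    mean silhouette under the clustering metric; returns
    ``(k_opt, curve_dict)``.
    """
    X = np.asarray(all_windows, dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate window set: all windows identical")
    metric = "euclidean" if distance == "sqeuclidean" else "cityblock"
    curve = {}
    for k in k_range:
        if k >= len(X):
            raise ValueError(f"k={k} >= number of windows {len(X)}")
        _, lab, _ = _fit_kmeans(X, k, n_init, seed, distance)
        if len(np.unique(lab)) < 2:
            curve[k] = -1.0
            continue
        curve[k] = float(silhouette_score(X, lab, metric=metric))
    k_opt = max(curve, key=curve.get)
    return k_opt, curve


def cluster_states(subject_windows: np.ndarray, k: int, n_init: int = 100,
                   seed=None, distance: str = "sqeuclidean",
                   silhouette_curve=None, max_retries: int = 5) -> StateModel:
    """k-means over the pooled windows of all subjects.

    ``subject_windows`` is (n_subjects, n_windows, n_edges).  The best of
    ``n_init`` random initialisations by within-cluster cost is kept; states
    are then relabelled in descending order of centroid mean connectivity so
    that State 1 is always the strongest.  An empty cluster triggers a rerun
    with a fresh seed, up to ``max_retries``.
    """
    W = np.asarray(subject_windows, dtype=float)
    if W.ndim != 3:
        raise ValueError("subject_windows must be (n_subjects, n_windows, n_edges)")
    if k < 2:
        raise ValueError("k must be >= 2")
    n_subj, n_win, n_edge = W.shape
    X = W.reshape(-1, n_edge)
    attempt_seed = seed
    for _ in range(max_retries):
        centroids, lab, inertia = _fit_kmeans(X, k, n_init, attempt_seed, distance)
        counts = np.bincount(lab, minlength=k)
        if np.all(counts > 0):
            break
        attempt_seed = (0 if attempt_seed is None else attempt_seed) + 1
    else:
        raise RuntimeError(f"empty cluster persisted over {max_retries} retries")
    order = np.argsort(-centroids.mean(axis=1))   # strongest first
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    centroids = centroids[order]
    states = relabel[lab] + 1
    occurrence = np.bincount(states - 1, minlength=k) / len(states)
    return StateModel(
        k=k,
        centroids=centroids,
        assignments=states.reshape(n_subj, n_win),
        occurrence=occurrence,
        inertia=float(inertia),
        distance=distance,
        silhouette_curve=silhouette_curve,
    )


def subject_state_centroids(model: StateModel, subject_windows: np.ndarray):
    """Per-subject mean window vector in each state.

    Returns an (n_subjects, k, n_edges) array with NaN rows for states a
    subject never visits.
    """
    W = np.asarray(subject_windows, dtype=float)
    n_subj, _, n_edge = W.shape
    out = np.full((n_subj, model.k, n_edge), np.nan)
    for i in range(n_subj):
        for s in range(1, model.k + 1):
            m = model.assignments[i] == s
            if m.any():
                out[i, s - 1] = W[i, m].mean(axis=0)
    return out


def group_centroids(model: StateModel, subject_windows: np.ndarray, groups):
    """Group-specific state centroids.

    The subject-specific centroid of a state is the mean of that subject's
    window vectors assigned to the state; the group centroid averages these
    over subjects that visit the state.  Returns
    ``(centroids, n_contributing)`` where ``centroids[group][state]`` may be
    NaN when no subject of the group visits the state (flagged by a zero
    count).
    """
    groups = np.asarray(groups)
    subj_cent = subject_state_centroids(model, subject_windows)
    out, counts = {}, {}
    for g in np.unique(groups):
        sel = subj_cent[groups == g]          # (n_g, k, E)
        visited = ~np.isnan(sel[:, :, 0])     # (n_g, k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[g] = np.nanmean(sel, axis=0)
        counts[g] = visited.sum(axis=0)
    return out, counts


def state_edge_ttest(model: StateModel, subject_windows: np.ndarray, groups,
                     alpha: float = 0.01):
    """Two-sample t-tests on subject-specific state centroids, per edge.

    For each state with at least 2 subjects per group, a two-sample t
    compares patients vs controls edge-wise.  ``groups`` is 0/1 (1 =
    patient); direction is the sign of patient minus control.  Returns a
    dict ``state -> dict(t, p, sig, direction)`` (states lacking subjects
    are reported with reason instead).
    """
    groups = np.asarray(groups).astype(bool)
    subj_cent = subject_state_centroids(model, subject_windows)
    results = {}
    for s in range(1, model.k + 1):
        vals = subj_cent[:, s - 1]
        have = ~np.isnan(vals[:, 0])
        ga = vals[have & groups]
        gb = vals[have & ~groups]
        if len(ga) < 2 or len(gb) < 2:
            results[s] = {"skipped": True,
                          "reason": f"fewer than 2 subjects per group in state {s}"}
            continue
        t, p = sps.ttest_ind(ga, gb, axis=0)
        results[s] = {
            "skipped": False,
            "t": t,
            "p": p,
            "sig": p < alpha,
            "direction": np.sign(ga.mean(axis=0) - gb.mean(axis=0)),
            "n_patient": len(ga),
            "n_control": len(gb),
        }
    return results


def top_edges(centroid: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Indices of the strongest centroid edges (the displayed top 5%).

    ``count = ceil(fraction * n_edges)``; ties break toward the fixed
    row-major edge order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    c = np.asarray(centroid, dtype=float)
    n = int(np.ceil(fraction * c.size))
    order = np.lexsort((np.arange(c.size), -c))   # value desc, index asc on ties
    return np.sort(order[:n])
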