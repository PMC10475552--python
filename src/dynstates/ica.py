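"""Group spatial ICA: two-stage PCA reduction, Infomax unmixing, multi-run
stability aggregation and dual-regression back-reconstruction.

The decomposition follows the standard group-ICA recipe for resting-state
fMRI: per-subject temporal PCA, temporal concatenation, group PCA to the
target model order, Infomax ICA (natural-gradient, logistic nonlinearity)
repeated over randomised runs with components matched across runs and
averaged after sign alignment, then per-subject spatial maps and time
courses recovered by dual regression against the aggregate group maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ReductionModel",
    "ComponentSet",
    "two_stage_pca",
    "infomax",
    "stability_aggregate",
    "back_reconstruct",
    "match_components",
]


@dataclass
class ReductionModel:
    """Bases and retained dimensions of the two-stage PCA reduction."""

    subject_bases: list            # per subject: (subj_dim, T) row basis
    group_basis: np.ndarray        # (group_dim, total_subj_dims)
    whitening_scale: np.ndarray    # per-row scale applied to whiten the output
    voxel_scale: np.ndarray        # mean per-voxel SD before normalisation;
                                   # multiply component maps by this to return
                                   # them to data units
    subj_dim: int
    group_dim: int
    explained_variance_ratio: float


@dataclass
class ComponentSet:
    """Aggregate group components and their subject-level realisations."""

    group_maps: np.ndarray                   # (n_components, n_voxels), z-scored
    stability_index: np.ndarray              # (n_components,) in [0, 1]
    subject_maps: list = field(default_factory=list)        # per subject (C, V)
    subject_timecourses: list = field(default_factory=list)  # per subject (T, C)
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.group_maps.shape[0]


def _variance_normalise(X: np.ndarray) -> np.ndarray:
    """Demean and unit-variance each voxel's time series (zero-variance kept 0)."""
    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return X / sd


def two_stage_pca(subject_data, subj_dim: int = 40, group_dim: int = 26,
                  normalise_voxels: bool = True):
    """Reduce a cohort of (timepoint, voxel) matrices to a whitened group matrix.

    Each subject is variance-normalised per voxel (switchable, as intensity
    normalisation ahead of reduction is a convention rather than a necessity)
    and reduced by temporal PCA to ``subj_dim`` rows; the reduced rows are
    concatenated across subjects and a second PCA takes the stack to
    ``group_dim`` rows, which are then whitened.

    Returns ``(model, reduced)`` where ``reduced`` is (group_dim, n_voxels).
    """
    subject_bases = []
    reduced_rows = []
    voxel_sds = []
    for i, X in enumerate(subject_data):
        X = np.asarray(X, dtype=float)
        voxel_sds.append(X.std(axis=0, ddof=0))
        if normalise_voxels:
            Xn = _variance_normalise(X)
        else:
            Xn = X - X.mean(axis=0, keepdims=True)
        d = min(subj_dim, min(Xn.shape))
        U, s, Vt = np.linalg.svd(Xn, full_matrices=False)
        rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
        if rank < min(subj_dim, group_dim):
            raise ValueError(
                f"subject {i}: rank {rank} below requested reduction "
                f"(subj_dim={subj_dim}, group_dim={group_dim})"
            )
        subject_bases.append(U[:, :d].T)              # (d, T)
        reduced_rows.append((s[:d, None] * Vt[:d]))   # (d, V) = U^T X
    C = np.vstack(reduced_rows)
    Ug, sg, Vgt = np.linalg.svd(C, full_matrices=False)
    rank_g = int((sg > sg[0] * 1e-10).sum())
    if rank_g < group_dim:
        raise ValueError(
            f"group matrix rank {rank_g} below requested group_dim={group_dim}"
        )
    reduced = sg[:group_dim, None] * Vgt[:group_dim]   # (group_dim, V)
    # rows are orthogonal; unit RMS makes the second-moment matrix identity
    scale = np.sqrt(np.mean(reduced**2, axis=1))
    reduced = reduced / scale[:, None]
    evr = float((sg[:group_dim] ** 2).sum() / (sg**2).sum())
    model = ReductionModel(
        subject_bases=subject_bases,
        group_basis=Ug[:, :group_dim].T,
        whitening_scale=scale,
        voxel_scale=np.mean(voxel_sds, axis=0),
        subj_dim=subj_dim,
        group_dim=group_dim,
        explained_variance_ratio=evr,
    )
    return model, reduced


def infomax(reduced: np.ndarray, seed=None, lr: float = None, tol: float = 1e-6,
            max_iter: int = 500, block: int = None, anneal: float = 0.97):
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    ``reduced`` is a whitened (dim, sample) matrix.  The weight update is
    ``W += lr * (I + (1 - 2*g(WX)) (WX)^T / n_block) W`` with
    ``g(u) = 1/(1+exp(-u))``, applied over shuffled sample blocks.  The
    learning rate is annealed geometrically each sweep (factor ``anneal``)
    and halved whenever an update diverges.  Convergence is declared when
    the Frobenius norm of the weight change per sweep drops below ``tol``;
    non-convergence sets a flag rather than raising.

    Note the logistic score limits recovery to super-Gaussian (sparse /
    heavy-tailed) sources, which spatial brain maps are.

    Returns ``(W, sources, converged)`` with sources scaled to unit variance.
    """
    X = np.asarray(reduced, dtype=float)
    d, n = X.shape
    rng = np.random.default_rng(seed)
    if lr is None:
        lr = 0.01 / np.log(max(d, 2))
    if block is None:
        block = int(min(n, max(8, np.floor(np.sqrt(n / 3.0)))))
    W = np.eye(d) + 0.01 * rng.standard_normal((d, d))
    I = np.eye(d)
    converged = False
    for _ in range(max_iter):
        W_old = W.copy()
        perm = rng.permutation(n)
        ok = True
        for start in range(0, n - block + 1, block):
            xb = X[:, perm[start:start + block]]
            u = W @ xb
            y = 1.0 / (1.0 + np.exp(-u))
            grad = (I + (1.0 - 2.0 * y) @ u.T / xb.shape[1]) @ W
            W = W + lr * grad
            if not np.isfinite(W).all() or np.abs(W).max() > 1e8:
                ok = False
                break
        if not ok:
            lr *= 0.5
            W = W_old
            continue
        delta = np.linalg.norm(W - W_old)
        if delta < tol:
            converged = True
            break
        lr *= anneal
    if not converged:
        warnings.warn("Infomax did not reach the convergence tolerance",
                      RuntimeWarning, stacklevel=2)
    S = W @ X
    sd = S.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    S = S / sd[:, None]
    W = W / sd[:, None]
    return W, S, converged


def match_components(reference: np.ndarray, candidate: np.ndarray):
    """One-to-one match of candidate components to a reference set.

    Components are matched by maximal absolute Pearson correlation between
    their maps using the Hungarian algorithm.  Returns ``(perm, signs, r)``
    such that ``signs[:, None] * candidate[perm]`` is aligned to
    ``reference`` and ``r`` holds the absolute correlations.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    rz = (ref - ref.mean(axis=1, keepdims=True))
    cz = (cand - cand.mean(axis=1, keepdims=True))
    rz /= np.linalg.norm(rz, axis=1, keepdims=True)
    cz /= np.linalg.norm(cz, axis=1, keepdims=True)
    corr = rz @ cz.T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(len(rows), dtype=int)
    signs = np.empty(len(rows))
    r = np.empty(len(rows))
    for i, j in zip(rows, cols):
        perm[i] = j
        signs[i] = 1.0 if corr[i, j] >= 0 else -1.0
        r[i] = abs(corr[i, j])
    return perm, signs, r


def stability_aggregate(reduced: np.ndarray, n_runs: int = 20, seed=None,
                        run_seeds=None, **infomax_kwargs) -> ComponentSet:
    """Multi-run Infomax with cross-run component matching.

    The first run serves as the reference; every other run's components are
    matched to it by absolute spatial correlation, sign-aligned and averaged.
    The stability index of a component is the mean absolute correlation of
    its cluster members with the aggregate map — 1.0 when all runs agree.
    Aggregate maps are returned z-scored across voxels.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if run_seeds is None:
        rng = np.random.default_rng(seed)
        run_seeds = rng.integers(0, 2**31, size=n_runs)
    elif len(run_seeds) != n_runs:
        raise ValueError("run_seeds must have length n_runs")
    runs = []
    all_converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in run_seeds:
            _, S, conv = infomax(reduced, seed=int(s), **infomax_kwargs)
            runs.append(S)
            all_converged &= conv
    ref = runs[0]
    aligned = [ref]
    for S in runs[1:]:
        perm, signs, _ = match_components(ref, S)
        aligned.append(signs[:, None] * S[perm])
    stack = np.stack(aligned)              # (n_runs, C, V)
    agg = stack.mean(axis=0)
    az = agg - agg.mean(axis=1, keepdims=True)
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    member = stack - stack.mean(axis=2, keepdims=True)
    member /= np.linalg.norm(member, axis=2, keepdims=True)
    stability = np.abs(np.einsum("cv,rcv->rc", az, member)).mean(axis=0)
    # sign convention: peak voxel positive (ICA signs are arbitrary)
    flip = np.where(np.abs(agg.min(axis=1)) > np.abs(agg.max(axis=1)), -1.0, 1.0)
    agg = agg * flip[:, None]
    # z-score maps across voxels (display/matching scale)
    zmaps = (agg - agg.mean(axis=1, keepdims=True)) / agg.std(axis=1, keepdims=True)
    return ComponentSet(group_maps=zmaps, stability_index=stability,
                        converged=all_converged)


def back_reconstruct(subject_data, group_maps: np.ndarray):
    """Dual-regression back-reconstruction.

    For each subject matrix X (timepoint, voxel), demeaned per voxel:
    spatial regression of X on the group maps yields subject time courses;
    temporal regression of X on those time courses yields subject maps.

    Returns ``(subject_timecourses, subject_maps)`` lists.
    """
    M = np.asarray(group_maps, dtype=float)
    cond = np.linalg.cond(M @ M.T)
    if cond > 1e8:
        warnings.warn(f"group maps nearly collinear (condition number {cond:.2g})",
                      RuntimeWarning, stacklevel=2)
    tcs, smaps = [], []
    pinv_M = np.linalg.pinv(M)
    for X in subject_data:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != M.shape[1]:
            raise ValueError("subject data and group maps must share the voxel grid")
        Xd = X - X.mean(axis=0, keepdims=True)
        tc = Xd @ pinv_M                   # (T, C)
        smap = np.linalg.lstsq(tc, Xd, rcond=None)[0]   # (C, V)
        tcs.append(tc)
        smaps.append(smap)
    return tcs, smaps
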