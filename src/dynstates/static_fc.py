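"""Static functional connectivity between retained components.

Subject-level Fisher-z correlation matrices over component time courses and
edge-wise group contrasts with age and sex as nuisance covariates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import glm_contrast_many

__all__ = [
    "ATANH_CLIP",
    "mean_ic_timecourse",
    "fisher_z",
    "static_matrix",
    "vectorize_edges",
    "edge_glm",
    "network_pair_summary",
]

#: Perfect correlations are clipped to atanh(1 - 1e-7) instead of propagating
#: infinities through the z matrices.
ATANH_CLIP = 1.0 - 1e-7


def mean_ic_timecourse(subject_data, ic_map, mode: str = "weighted",
                       z_threshold: float = 2.0, cleaned_timecourse=None,
                       ic: int = None):
    """Representative time course of one IC within a subject's 4-D data.

    ``weighted``: map-weighted average over voxels.  ``thresholded``:
    unweighted average over voxels with map z >= ``z_threshold``.
    ``backrecon``: pass through the cleaned back-reconstructed time course
    (the default source for connectivity, since the denoising pipeline is
    defined on back-reconstructed series).
    """
    if mode == "backrecon":
        if cleaned_timecourse is None:
            raise ValueError("mode='backrecon' requires cleaned_timecourse")
        return np.asarray(cleaned_timecourse, dtype=float)
    X = np.asarray(subject_data, dtype=float)   # (T, V)
    m = np.asarray(ic_map, dtype=float).ravel()
    if X.shape[1] != m.size:
        raise ValueError("subject data and IC map must share the voxel grid")
    if mode == "weighted":
        w = m / np.abs(m).sum()
        return X @ w
    if mode == "thresholded":
        sel = m >= z_threshold
        if not sel.any():
            raise ValueError(
                f"IC {ic if ic is not None else '?'}: no voxels with map z >= "
                f"{z_threshold}"
            )
        return X[:, sel].mean(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def fisher_z(r):
    """atanh with clipping at |r| = 1 - 1e-7 (warned, not propagated as inf)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= ATANH_CLIP):
        warnings.warn("perfect correlation clipped before Fisher z",
                      RuntimeWarning, stacklevel=2)
    return np.arctanh(np.clip(r, -ATANH_CLIP, ATANH_CLIP))


def static_matrix(timecourses: np.ndarray) -> np.ndarray:
    """Fisher-z Pearson correlation matrix of (timepoint, component) data.

    The diagonal is set to 0 by convention.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    flat = np.ptp(tc, axis=0) == 0
    if np.any(flat):
        raise ValueError(
            f"zero-variance component(s): {np.flatnonzero(flat).tolist()}")
    r = np.corrcoef(tc.T)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        z = np.arctanh(np.clip(r, -ATANH_CLIP, ATANH_CLIP))
    z = (z + z.T) / 2.0          # exact symmetry despite rounding
    np.fill_diagonal(z, 0.0)
    return z


def vectorize_edges(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle in fixed row-major edge order."""
    iu = np.triu_indices(matrix.shape[0], k=1)
    return np.asarray(matrix)[iu]


def edge_pairs(n_components: int):
    """(i, j) component pairs in the fixed row-major edge order."""
    iu = np.triu_indices(n_components, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def edge_glm(z_edges: np.ndarray, group, age, sex, alpha: float = 0.01,
             fdr: bool = False) -> pd.DataFrame:
    """Edge-wise GLM ``z ~ intercept + group + age + sex``.

    ``group`` is coded 0 = control, 1 = patient, so a negative group effect
    means patient < control ("decreased" connectivity).  Significance is the
    uncorrected two-sided p against ``alpha``; a Benjamini-Hochberg column is
    added when ``fdr`` is requested.
    """
    Z = np.asarray(z_edges, dtype=float)
    n = Z.shape[0]
    X = np.column_stack([np.ones(n), np.asarray(group, float),
                         np.asarray(age, float), np.asarray(sex, float)])
    beta, t, p = glm_contrast_many(Z, X, contrast_index=1)
    out = pd.DataFrame({"edge": np.arange(Z.shape[1]), "beta": beta,
                        "t": t, "p": p, "sig": p < alpha})
    if fdr:
        order = np.argsort(p)
        m = len(p)
        q = np.empty(m)
        q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        out["q_bh"] = np.minimum(q, 1.0)
        out["sig_bh"] = out["q_bh"] < alpha
    return out


def network_pair_summary(contrast: pd.DataFrame, component_networks,
                         network_names=None) -> pd.DataFrame:
    """Aggregate significant edges to network-pair granularity.

    Returns one row per unordered network pair with at least one significant
    edge: the significant-edge count, the mean group effect over those edges
    and a direction that is "decreased"/"increased" when all significant
    edges share a sign, else "mixed".
    """
    labels = list(component_networks)
    n_comp = len(labels)
    pairs = edge_pairs(n_comp)
    agg: dict = {}
    for _, row in contrast.iterrows():
        if not row["sig"]:
            continue
        i, j = pairs[int(row["edge"])]
        key = tuple(sorted((labels[i], labels[j])))
        agg.setdefault(key, []).append(float(row["beta"]))
    rows = []
    for (na, nb), betas in sorted(agg.items()):
        betas = np.asarray(betas)
        if np.all(betas < 0):
            direction = "decreased"
        elif np.all(betas > 0):
            direction = "increased"
        else:
            direction = "mixed"
        rows.append({"network_a": na, "network_b": nb, "n_sig_edges": len(betas),
                     "mean_beta": float(betas.mean()), "direction": direction})
    cols = ["network_a", "network_b", "n_sig_edges", "mean_beta", "direction"]
    return pd.DataFrame(rows, columns=cols)
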