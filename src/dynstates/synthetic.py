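"""Synthetic resting-state cohorts with known state-switching connectivity.

Generates a two-group cohort in which component time courses alternate
between two hidden connectivity regimes (a strongly coupled state and a
weakly coupled state) under a per-subject two-state Markov chain, optionally
mixes the components into 4-D voxel images for ICA testing, writes SPM-style
realignment traces, a 7-network label template and a cohort sheet, and keeps
the generating truth (state sequences, transition matrices, mixing maps,
window-resolution temporal metrics) for recovery tests.

The defaults emulate a paediatric epilepsy resting-state study: 23 patients
vs 32 controls, 130 volumes at TR = 2 s with the first 10 discarded, 20
network components spread over the 7 canonical cortical networks, and
group-dependent dwell behaviour in which patients persist less in the
strongly connected state.  Epilepsy duration is linearly coupled to each
patient's state-1 stay probability so that duration-metric correlations have
a recoverable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "NETWORK_NAMES",
    "CohortSpec",
    "SyntheticTruth",
    "default_state_covariances",
    "gen_state_sequence",
    "gen_component_timecourses",
    "make_mixing_maps",
    "gen_voxel_images",
    "gen_motion_trace",
    "gen_cohort",
    "majority_vote_window_labels",
]

#: The 7 canonical cortical networks, in template label order (label = index+1).
NETWORK_NAMES = ("VIS", "SMN", "DAN", "VAN", "Lim", "FPN", "DMN")

#: Components per network in the default cohort (sums to 20).
DEFAULT_NETWORK_SIZES = (6, 3, 2, 2, 1, 2, 4)


def default_state_covariances(network_sizes=DEFAULT_NETWORK_SIZES,
                              within: float = 0.6, between: float = 0.3,
                              weak_scale: float = 0.25):
    """Block-structured covariances for the strong and weak states.

    State 1 has within-network off-diagonal correlation ``within`` and
    between-network correlation ``between``; state 2 scales all off-diagonals
    by ``weak_scale``.  Both are positive definite by construction (a
    nonnegative mixture of rank-one block terms plus a positive diagonal).
    """
    sizes = np.asarray(network_sizes, dtype=int)
    n = int(sizes.sum())
    labels = np.repeat(np.arange(len(sizes)), sizes)
    same_net = labels[:, None] == labels[None, :]
    strong = np.where(same_net, within, between).astype(float)
    np.fill_diagonal(strong, 1.0)
    weak = strong * weak_scale
    np.fill_diagonal(weak, 1.0)
    return strong, weak


def _check_positive_definite(cov, name):
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{name} must be square, got {cov.shape}")
    if not np.allclose(cov, cov.T):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError(f"{name} is not positive definite")
    return cov


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``stay_prob`` maps each group to its (state-1, state-2) stay
    probabilities.  The defaults are calibrated from the mean dwell times
    reported for two-state solutions in paediatric generalised epilepsy
    (patients ~12.6 / 52.3 windows, controls ~28.4 / 43.4) via
    ``p = 1 - 1/MDT``, giving stationary state-1 occupancies of about 0.19
    for patients and 0.40 for controls — the occupancy gap the package is
    designed to detect.  ``duration_coupling`` shifts each patient's
    state-1 stay probability linearly with epilepsy duration.
    """

    n_group_a: int = 23              # patients
    n_group_b: int = 32              # controls
    n_timepoints: int = 130
    n_discard: int = 10
    tr_seconds: float = 2.0
    n_components: int = 20
    network_sizes: tuple = DEFAULT_NETWORK_SIZES
    stay_prob: dict = field(default_factory=lambda: {
        "patient": (0.920, 0.981),
        "control": (0.965, 0.977),
    })
    state_covariances: tuple | None = None   # (strong, weak); default blocks
    noise_sd: float = 0.5
    ar_coeff: float = 0.4
    # calibrated so the planted duration <-> state-1-occupancy partial
    # correlation sits near the ~0.5 reported for such cohorts
    duration_coupling: float = 0.16
    age_range_months: tuple = (24.0, 144.0)
    duration_range_months: tuple = (1.0, 120.0)
    spatial_grid: tuple = (20, 20, 10)
    blob_sigma: float = 1.0
    # unit-norm mixing maps put the peak blob voxel near 0.17, so 0.1 gives a
    # peak-voxel contrast-to-noise ratio around 1.7, typical of BOLD networks
    image_noise_sd: float = 0.1
    motion_drift_sd: float = 0.02
    motion_spike_prob: float = 0.01
    motion_spike_mm: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if sum(self.network_sizes) != self.n_components:
            raise ValueError(
                f"network_sizes sums to {sum(self.network_sizes)}, "
                f"expected n_components={self.n_components}"
            )
        if not 0 < self.n_discard < self.n_timepoints:
            if self.n_discard != 0:
                raise ValueError("need 0 <= n_discard < n_timepoints")
        for g, (p1, p2) in self.stay_prob.items():
            if not (0 < p1 < 1 and 0 < p2 < 1):
                raise ValueError(f"stay probabilities for {g} must be in (0,1)")
        if self.noise_sd < 0 or self.image_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.state_covariances is None:
            self.state_covariances = default_state_covariances(self.network_sizes)
        s1, s2 = self.state_covariances
        _check_positive_definite(s1, "state-1 covariance")
        _check_positive_definite(s2, "state-2 covariance")
        if s1.shape[0] != self.n_components:
            raise ValueError("covariance dimension must equal n_components")

    @property
    def n_kept(self) -> int:
        return self.n_timepoints - self.n_discard

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "network_sizes" in d:
            d["network_sizes"] = tuple(d["network_sizes"])
        if "stay_prob" in d:
            d["stay_prob"] = {k: tuple(v) for k, v in d["stay_prob"].items()}
        for key in ("spatial_grid", "age_range_months", "duration_range_months"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Generating ground truth for recovery tests."""

    subject_ids: list
    groups: list
    state_sequences: dict          # id -> post-discard per-timepoint states (1/2)
    transition_matrices: dict      # id -> 2x2 row-stochastic
    stay_probs: dict               # id -> (p1, p2)
    window_labels: dict            # id -> majority-vote label per window (filled by dFC tests)
    true_metrics: dict             # id -> {mdt_s1, mdt_s2, frac_s1, frac_s2, transitions}
    mixing_maps: np.ndarray | None  # component x voxel, unit norm per component

    def to_json_dict(self) -> dict:
        return {
            "subject_ids": self.subject_ids,
            "groups": self.groups,
            "state_sequences": {k: np.asarray(v).tolist()
                                for k, v in self.state_sequences.items()},
            "transition_matrices": {k: np.asarray(v).tolist()
                                    for k, v in self.transition_matrices.items()},
            "stay_probs": {k: list(v) for k, v in self.stay_probs.items()},
            "window_labels": {k: np.asarray(v).tolist()
                              for k, v in self.window_labels.items()},
            "true_metrics": self.true_metrics,
        }


def _stationary_2state(tm: np.ndarray) -> np.ndarray:
    q1, q2 = 1.0 - tm[0, 0], 1.0 - tm[1, 1]
    if q1 + q2 == 0:  # identity chain: uniform start
        return np.array([0.5, 0.5])
    return np.array([q2, q1]) / (q1 + q2)


def gen_state_sequence(length: int, transition_matrix, seed) -> np.ndarray:
    """Realise a two-state Markov chain (states 1 and 2).

    The initial state is drawn from the stationary distribution; with an
    identity (absorbing) matrix the start is uniform and the chain is
    constant.
    """
    tm = np.asarray(transition_matrix, dtype=float)
    if tm.shape != (2, 2) or np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be 2x2 row-stochastic")
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    seq = np.empty(length, dtype=int)
    seq[0] = rng.choice(2, p=_stationary_2state(tm))
    u = rng.random(length - 1)
    for t in range(1, length):
        seq[t] = seq[t - 1] if u[t - 1] < tm[seq[t - 1], seq[t - 1]] else 1 - seq[t - 1]
    return seq + 1


def gen_component_timecourses(states, spec: CohortSpec, seed) -> np.ndarray:
    """Component signals whose covariance follows the hidden state.

    Each timepoint is a zero-mean multivariate normal draw with the
    covariance of its hidden state, plus white noise of SD
    ``spec.noise_sd``.  The innovations carry AR(1) temporal correlation
    ``spec.ar_coeff`` (BOLD-like low-frequency weighting; the marginal
    cross-sectional covariance stays exactly the state covariance).
    Returns a (timepoint, component) matrix.
    """
    states = np.asarray(states, dtype=int)
    if not np.all(np.isin(states, (1, 2))):
        raise ValueError("states must be 1 or 2")
    rng = np.random.default_rng(seed)
    chols = [np.linalg.cholesky(np.asarray(c, dtype=float))
             for c in spec.state_covariances]
    z = rng.standard_normal((len(states), spec.n_components))
    rho = spec.ar_coeff
    if rho:
        scale = np.sqrt(1.0 - rho**2)
        for t in range(1, len(z)):
            z[t] = rho * z[t - 1] + scale * z[t]
    tc = np.empty_like(z)
    for s, chol in zip((1, 2), chols):
        m = states == s
        if m.any():
            tc[m] = z[m] @ chol.T
    if spec.noise_sd > 0:
        tc += spec.noise_sd * rng.standard_normal(tc.shape)
    return tc


def make_mixing_maps(spec: CohortSpec) -> np.ndarray:
    """One truncated-Gaussian blob per component, disjointly placed.

    Blob centres sit on a 3-D lattice with spacing 4 voxels; supports are
    truncated strictly inside radius 2 so neighbouring blobs never overlap.
    Maps are returned as a (component, voxel) matrix with unit L2 norm per
    component.
    """
    nx, ny, nz = spec.spatial_grid
    spacing, radius = 4, 2.0
    cx = np.arange(spacing // 2, nx - 1, spacing)
    cy = np.arange(spacing // 2, ny - 1, spacing)
    cz = np.arange(spacing // 2, nz - 1, spacing)
    centres = [(x, y, z) for z in cz for y in cy for x in cx]
    if len(centres) < spec.n_components:
        raise ValueError(
            f"grid {spec.spatial_grid} fits only {len(centres)} disjoint blobs, "
            f"need {spec.n_components}"
        )
    xi, yi, zi = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    maps = np.zeros((spec.n_components, nx * ny * nz))
    for c in range(spec.n_components):
        x0, y0, z0 = centres[c]
        d2 = (xi - x0) ** 2 + (yi - y0) ** 2 + (zi - z0) ** 2
        blob = np.exp(-d2 / (2.0 * spec.blob_sigma**2))
        blob[d2 >= radius**2] = 0.0
        maps[c] = blob.ravel()
        maps[c] /= np.linalg.norm(maps[c])
    return maps


def gen_voxel_images(timecourses, mixing_maps, noise_sd, spec: CohortSpec,
                     seed=None):
    """Mix component time courses into a 4-D voxel image.

    ``voxel signal = timecourses @ mixing_maps + noise``; the repetition time
    is recorded in the NIfTI header's 4th zoom.  Returns a nibabel image.
    """
    tc = np.asarray(timecourses, dtype=float)
    maps = np.asarray(mixing_maps, dtype=float)
    data = tc @ maps
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * rng.standard_normal(data.shape)
    vol = data.T.reshape(spec.spatial_grid + (tc.shape[0],))
    img = nib.Nifti1Image(vol.astype(np.float32), affine=np.diag([3.0, 3.0, 3.0, 1.0]))
    img.header.set_zooms((3.0, 3.0, 3.0, spec.tr_seconds))
    return img


def gen_motion_trace(length: int, drift_sd: float = 0.02, spike_prob: float = 0.01,
                     spike_mm: float = 0.3, seed=None) -> np.ndarray:
    """Random-walk realignment parameters with occasional spikes.

    Translations in mm, rotations in radians (rotation columns drift at a
    twentieth of the translation scale, keeping cumulative rotation well
    inside the 3-degree exclusion limit, as in a cohort with no motion
    exclusions).  Spikes of magnitude ``spike_mm`` hit single translation
    axes with per-timepoint probability ``spike_prob``.
    """
    if not (0 <= spike_prob <= 1):
        raise ValueError("spike_prob must be in [0, 1]")
    if drift_sd < 0 or spike_mm < 0:
        raise ValueError("drift_sd and spike_mm must be nonnegative")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((length, 6)) * drift_sd
    steps[:, 3:] *= 0.05
    steps[0] = 0.0
    trace = np.cumsum(steps, axis=0)
    spikes = rng.random(length) < spike_prob
    spikes[0] = False
    axes = rng.integers(0, 3, size=length)
    for t in np.flatnonzero(spikes):
        trace[t:, axes[t]] += spike_mm
    return trace


def majority_vote_window_labels(states, width: int, step: int = 1) -> np.ndarray:
    """Ground-truth label per sliding window: the state occupying most of it.

    Windows are the half-open ranges ``[i, i + width)`` for
    ``i = 0, step, ...`` with ``floor((T - width) / step)`` windows in total
    (the convention the dFC stage uses).  Ties break toward state 1.
    """
    states = np.asarray(states, dtype=int)
    n = (len(states) - width) // step
    labels = np.empty(n, dtype=int)
    for w in range(n):
        seg = states[w * step:w * step + width]
        labels[w] = 1 if (seg == 1).sum() >= (seg == 2).sum() else 2
    return labels


def _runs(vec):
    vec = np.asarray(vec)
    change = np.flatnonzero(np.diff(vec) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(vec)]])
    return [(vec[s], e - s) for s, e in zip(starts, ends)]


def _truth_metrics(window_labels) -> dict:
    runs = _runs(window_labels)
    out = {}
    for s in (1, 2):
        lens = [ln for st, ln in runs if st == s]
        out[f"mdt_s{s}"] = float(np.mean(lens)) if lens else 0.0
        out[f"frac_s{s}"] = float(np.mean(np.asarray(window_labels) == s))
    out["transitions"] = int(len(runs) - 1)
    return out


def gen_cohort(spec: CohortSpec, out_dir, write_images: bool = True,
               window_width: int = 30, window_step: int = 1) -> dict:
    """Generate a full cohort on disk and return a manifest.

    Writes per-subject 4-D NIfTI images (optional), realignment traces
    (6-column text), a 7-network integer label template painted over each
    component's blob, a TSV cohort sheet, the truth JSON and the true mixing
    maps as a 4-D NIfTI.  The manifest maps logical names to paths and also
    carries the in-memory truth and time courses for direct library use.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    n_total = spec.n_group_a + spec.n_group_b
    ids = [f"sub-{i + 1:03d}" for i in range(n_total)]
    groups = ["patient"] * spec.n_group_a + ["control"] * spec.n_group_b
    ages = rng.uniform(*spec.age_range_months, size=n_total)
    sexes = rng.integers(0, 2, size=n_total)
    durations = np.where(
        np.asarray(groups) == "patient",
        rng.uniform(*spec.duration_range_months, size=n_total),
        np.nan,
    )

    maps = make_mixing_maps(spec) if write_images else None
    truth = SyntheticTruth(ids, groups, {}, {}, {}, {}, {}, maps)
    timecourses = {}
    motion = {}

    lo, hi = spec.duration_range_months
    mid, span = (lo + hi) / 2.0, hi - lo
    for i, (sid, grp) in enumerate(zip(ids, groups)):
        p1, p2 = spec.stay_prob[grp]
        if grp == "patient" and spec.duration_coupling != 0:
            p1 = float(np.clip(
                p1 + spec.duration_coupling * (durations[i] - mid) / span,
                0.02, 0.995,
            ))
        tm = np.array([[p1, 1 - p1], [1 - p2, p2]])
        sub_seed = rng.integers(0, 2**31)
        full_states = gen_state_sequence(spec.n_timepoints, tm, sub_seed)
        tc = gen_component_timecourses(full_states, spec, sub_seed + 1)
        kept_states = full_states[spec.n_discard:]
        truth.state_sequences[sid] = kept_states
        truth.transition_matrices[sid] = tm
        truth.stay_probs[sid] = (p1, p2)
        wl = majority_vote_window_labels(kept_states, window_width, window_step)
        truth.window_labels[sid] = wl
        truth.true_metrics[sid] = _truth_metrics(wl)
        timecourses[sid] = tc
        motion[sid] = gen_motion_trace(
            spec.n_timepoints, spec.motion_drift_sd, spec.motion_spike_prob,
            spec.motion_spike_mm, seed=sub_seed + 2,
        )

    manifest = {
        "out_dir": str(out_dir),
        "subject_ids": ids,
        "images": {},
        "motion": {},
        "tr_seconds": spec.tr_seconds,
        "n_discard": spec.n_discard,
    }

    for sid in ids:
        mpath = out_dir / f"rp_{sid}.txt"
        np.savetxt(mpath, motion[sid], fmt="%.8f")
        manifest["motion"][sid] = str(mpath)
        if write_images:
            img = gen_voxel_images(timecourses[sid], maps, spec.image_noise_sd,
                                   spec, seed=rng.integers(0, 2**31))
            ipath = out_dir / f"{sid}_bold.nii.gz"
            nib.save(img, ipath)
            manifest["images"][sid] = str(ipath)

    if write_images:
        # Template: each blob support painted with its network label (1..7).
        labels = np.repeat(np.arange(1, len(spec.network_sizes) + 1),
                           spec.network_sizes)
        tmpl = np.zeros(maps.shape[1], dtype=np.int16)
        for c in range(spec.n_components):
            tmpl[maps[c] > 0] = labels[c]
        tmpl_img = nib.Nifti1Image(tmpl.reshape(spec.spatial_grid),
                                   affine=np.diag([3.0, 3.0, 3.0, 1.0]))
        tpath = out_dir / "template_labels.nii.gz"
        nib.save(tmpl_img, tpath)
        manifest["template"] = str(tpath)
        maps_img = nib.Nifti1Image(
            maps.T.reshape(spec.spatial_grid + (spec.n_components,)).astype(np.float32),
            affine=np.diag([3.0, 3.0, 3.0, 1.0]))
        mpath = out_dir / "truth_mixing_maps.nii.gz"
        nib.save(maps_img, mpath)
        manifest["truth_maps"] = str(mpath)

    sheet_path = out_dir / "cohort.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("subject_id\tgroup\tage_months\tsex\tduration_months\n")
        for i, sid in enumerate(ids):
            dur = "" if np.isnan(durations[i]) else f"{durations[i]:.1f}"
            fh.write(f"{sid}\t{groups[i]}\t{ages[i]:.1f}\t{sexes[i]}\t{dur}\n")
    manifest["sheet"] = str(sheet_path)

    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.to_json_dict(), fh)
    manifest["truth"] = str(truth_path)

    manifest["_truth_obj"] = truth
    manifest["_timecourses"] = timecourses
    return manifest
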