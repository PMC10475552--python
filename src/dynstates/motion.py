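"""Head-motion quality control.

Framewise displacement (FD) from 6-parameter rigid-body realignment traces,
subject exclusion rules, group FD comparison and initial-volume discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import SummaryGroup, welch_t_from_summary

__all__ = [
    "load_motion_trace",
    "framewise_displacement",
    "QcReport",
    "apply_exclusion",
    "compare_group_fd",
    "discard_initial",
]

#: Default exclusion thresholds: mean FD >= 0.5 mm, more than 20% of
#: timepoints with FD > 0.5 mm, any |translation| > 3 mm or |rotation| > 3 deg.
MEAN_FD_LIMIT_MM = 0.5
FD_SPIKE_MM = 0.5
SPIKE_FRACTION_LIMIT = 0.2
TRANSLATION_LIMIT_MM = 3.0
ROTATION_LIMIT_DEG = 3.0


def load_motion_trace(path) -> np.ndarray:
    """Read a whitespace-delimited 6-column realignment trace (rp_*.txt dialect).

    Columns are 3 translations (mm) then 3 rotations (radians).
    """
    trace = np.loadtxt(path, ndmin=2)
    if trace.shape[1] != 6:
        raise ValueError(
            f"motion trace must have 6 columns, got {trace.shape[1]} in {path}"
        )
    return trace


def framewise_displacement(
    trace: np.ndarray,
    head_radius_mm: float = 50.0,
    rotations_in_degrees: bool = False,
) -> np.ndarray:
    """Power-style framewise displacement.

    ``FD_t = sum_i |delta p_i(t)|`` over the 6 realignment parameters, with
    rotations converted to arc length on a sphere of ``head_radius_mm``
    (default 50 mm).  The first timepoint has FD 0 by convention.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"motion trace must be (T, 6), got {trace.shape}")
    if trace.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to compute FD")
    rot = trace[:, 3:6]
    if rotations_in_degrees:
        rot = np.deg2rad(rot)
    params = np.column_stack([trace[:, :3], rot * head_radius_mm])
    fd = np.zeros(trace.shape[0])
    fd[1:] = np.abs(np.diff(params, axis=0)).sum(axis=1)
    return fd


@dataclass
class QcReport:
    """Per-subject motion QC summary."""

    subject_id: str
    fd: np.ndarray
    mean_fd: float
    spike_fraction: float
    max_translation_mm: float
    max_rotation_deg: float
    excluded: bool
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "mean_fd": self.mean_fd,
            "spike_fraction": self.spike_fraction,
            "max_translation_mm": self.max_translation_mm,
            "max_rotation_deg": self.max_rotation_deg,
            "excluded": self.excluded,
            "reasons": ";".join(self.reasons),
        }


def apply_exclusion(
    trace: np.ndarray,
    subject_id: str = "",
    head_radius_mm: float = 50.0,
    rotations_in_degrees: bool = False,
    mean_fd_limit: float = MEAN_FD_LIMIT_MM,
    fd_spike: float = FD_SPIKE_MM,
    spike_fraction_limit: float = SPIKE_FRACTION_LIMIT,
    translation_limit: float = TRANSLATION_LIMIT_MM,
    rotation_limit_deg: float = ROTATION_LIMIT_DEG,
) -> QcReport:
    """Evaluate the exclusion rules on one subject's realignment trace.

    A subject is excluded iff mean FD >= ``mean_fd_limit``, OR strictly more
    than ``spike_fraction_limit`` of timepoints have FD > ``fd_spike``, OR any
    absolute translation exceeds ``translation_limit`` mm, OR any absolute
    rotation exceeds ``rotation_limit_deg`` degrees.  The mean-FD rule is
    boundary-inclusive; the spike-fraction rule is strict ("more than 20%").
    """
    trace = np.asarray(trace, dtype=float)
    fd = framewise_displacement(trace, head_radius_mm, rotations_in_degrees)
    rot = trace[:, 3:6] if rotations_in_degrees else np.rad2deg(trace[:, 3:6])
    mean_fd = float(fd.mean())
    spike_fraction = float((fd > fd_spike).mean())
    max_trans = float(np.abs(trace[:, :3]).max())
    max_rot = float(np.abs(rot).max())

    reasons = []
    if mean_fd >= mean_fd_limit:
        reasons.append(f"mean FD {mean_fd:.3f} >= {mean_fd_limit} mm")
    if spike_fraction > spike_fraction_limit:
        reasons.append(
            f"{spike_fraction:.1%} of timepoints with FD > {fd_spike} mm "
            f"(limit {spike_fraction_limit:.0%})"
        )
    if max_trans > translation_limit:
        reasons.append(f"max |translation| {max_trans:.2f} > {translation_limit} mm")
    if max_rot > rotation_limit_deg:
        reasons.append(f"max |rotation| {max_rot:.2f} > {rotation_limit_deg} deg")

    return QcReport(
        subject_id=subject_id,
        fd=fd,
        mean_fd=mean_fd,
        spike_fraction=spike_fraction,
        max_translation_mm=max_trans,
        max_rotation_deg=max_rot,
        excluded=bool(reasons),
        reasons=reasons,
    )


def compare_group_fd(mean_fds, groups):
    """Welch t-test on per-subject mean FD between two groups.

    ``groups`` is a boolean/0-1 vector (1 = patient).  Returns ``(t, df, p)``.
    """
    mean_fds = np.asarray(mean_fds, dtype=float)
    groups = np.asarray(groups).astype(bool)
    a, b = mean_fds[groups], mean_fds[~groups]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    sa = SummaryGroup(float(a.mean()), float(a.std(ddof=1)), len(a))
    sb = SummaryGroup(float(b.mean()), float(b.std(ddof=1)), len(b))
    return welch_t_from_summary(sa, sb)


def discard_initial(data: np.ndarray, n_discard: int = 10, time_axis: int = 0):
    """Drop the first ``n_discard`` timepoints (magnetisation-equilibrium discard).

    Works on any array with a time axis: a (T, C) time-course matrix
    (``time_axis=0``) or a 4-D image array (``time_axis=-1``).
    """
    data = np.asarray(data)
    n_t = data.shape[time_axis]
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= n_t:
        raise ValueError(f"n_discard={n_discard} >= n_timepoints={n_t}")
    index = [slice(None)] * data.ndim
    index[time_axis] = slice(n_discard, None)
    return data[tuple(index)]
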