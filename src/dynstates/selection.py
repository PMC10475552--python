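"""Component labelling and time-course cleaning.

Labels group ICs against a 7-network integer template (retain when the best
spatial correlation exceeds 0.2), flags artifact components by their
high-frequency spectral power, builds Friston-24 motion regressors and
cleans component time courses (linear detrend -> nuisance regression ->
0.01-0.1 Hz zero-phase Butterworth band-pass, in that order).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .synthetic import NETWORK_NAMES

__all__ = [
    "template_match",
    "spectral_artifact_flag",
    "friston24_regressors",
    "clean_timecourse",
]

TEMPLATE_MATCH_THRESHOLD = 0.2


def template_match(group_maps: np.ndarray, template_labels: np.ndarray,
                   threshold: float = TEMPLATE_MATCH_THRESHOLD,
                   network_names=NETWORK_NAMES) -> pd.DataFrame:
    """Label each IC by its best-correlated network indicator map.

    ``template_labels`` is a flat voxel vector of integers 0..7 (0 =
    background).  For each IC the spatial Pearson correlation with each
    network's binary indicator is computed; the IC is retained iff its best
    correlation exceeds ``threshold`` and labelled with the argmax network.

    Returns a DataFrame with columns ``ic, network, r, retained`` plus one
    ``r_<name>`` column per network.
    """
    maps = np.asarray(group_maps, dtype=float)
    labels = np.asarray(template_labels).ravel()
    if maps.shape[1] != labels.size:
        raise ValueError(
            f"template grid ({labels.size} voxels) does not match maps "
            f"({maps.shape[1]} voxels)"
        )
    present = np.unique(labels[labels > 0])
    rows = []
    for ic in range(maps.shape[0]):
        m = maps[ic]
        rs = {}
        for k in range(1, len(network_names) + 1):
            if k not in present:
                rs[network_names[k - 1]] = 0.0
                continue
            ind = (labels == k).astype(float)
            r = np.corrcoef(m, ind)[0, 1]
            rs[network_names[k - 1]] = float(0.0 if np.isnan(r) else r)
        best = max(rs, key=rs.get)
        row = {"ic": ic, "network": best, "r": rs[best],
               "retained": rs[best] > threshold}
        row.update({f"r_{k}": v for k, v in rs.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def spectral_artifact_flag(timecourse, tr_seconds: float, cutoff_hz: float = 0.1,
                           max_high_fraction: float = 0.5):
    """Flag a time course whose periodogram power is mostly above ``cutoff_hz``.

    Returns ``(flagged, high_fraction, reason)``.  A constant time course has
    no defined spectrum and is flagged with its own reason.
    """
    tc = np.asarray(timecourse, dtype=float)
    if np.ptp(tc) == 0:
        return True, np.nan, "constant time course (undefined spectrum)"
    freqs, power = spsig.periodogram(tc, fs=1.0 / tr_seconds)
    total = power[1:].sum()   # exclude DC
    if total == 0:
        return True, np.nan, "zero spectral power"
    frac = float(power[1:][freqs[1:] > cutoff_hz].sum() / total)
    if frac > max_high_fraction:
        return True, frac, (f"high-frequency power fraction {frac:.2f} > "
                            f"{max_high_fraction}")
    return False, frac, ""


def friston24_regressors(trace: np.ndarray) -> np.ndarray:
    """24-parameter motion regressor matrix.

    Columns: the 6 realignment parameters p(t), their one-timepoint lags
    p(t-1) (first row zero-padded), and the squares of both.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"motion trace must be (T, 6), got {trace.shape}")
    lag = np.zeros_like(trace)
    lag[1:] = trace[:-1]
    return np.column_stack([trace, lag, trace**2, lag**2])


def clean_timecourse(timecourse, regressors=None, tr_seconds: float = 2.0,
                     band=(0.01, 0.1), order: int = 4) -> np.ndarray:
    """Denoise one component time course.

    Linear detrend, then OLS residualisation on the nuisance ``regressors``
    (an intercept is added internally), then a zero-phase Butterworth
    band-pass of the given ``order`` over ``band`` Hz.
    """
    tc = np.asarray(timecourse, dtype=float)
    lo, hi = band
    nyq = 0.5 / tr_seconds
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist={nyq}")
    out = spsig.detrend(tc, type="linear")
    if regressors is not None and np.asarray(regressors).size:
        R = np.asarray(regressors, dtype=float)
        if R.ndim == 1:
            R = R[:, None]
        if R.shape[0] != len(out):
            raise ValueError(
                f"regressors length {R.shape[0]} != timecourse length {len(out)}"
            )
        Z = np.column_stack([np.ones(len(out)), R])
        coef, *_ = np.linalg.lstsq(Z, out, rcond=None)
        out = out - Z @ coef
    sos = spsig.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    return spsig.sosfiltfilt(sos, out)
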