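"""Time-series denoising and head-motion quality control.

Operates on already-extracted regional signals (T x N arrays).  The
denoising chain is, in order: linear detrend, ideal band-pass filter
(0.01-0.08 Hz by default), and multiple regression of nuisance signals
(white matter, CSF, global signal and the 24 Friston motion regressors).
Each step preserves the array shape and is idempotent on its own output.

Motion QC excludes a subject when any rotation exceeds 2.0 degrees, any
translation exceeds 2.0 mm, or the mean volume-to-volume (relative) RMS
translation displacement exceeds 0.2 mm.  Relative RMS is computed from
the three translation parameters only: ``rms_t = ||trans_t - trans_{t-1}||``
averaged over t = 1..T-1 (the rigid-body convention is stated here because
published exclusion rules rarely define it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "detrend_linear",
    "bandpass_filter",
    "friston24",
    "regress_nuisance",
    "motion_qc",
    "denoise",
    "QCResult",
]

MAX_TRANSLATION_MM = 2.0
MAX_ROTATION_DEG = 2.0
MAX_MEAN_RMS_MM = 0.2


def _as_2d(series) -> np.ndarray:
    X = np.asarray(getattr(series, "values", series), dtype=np.float64)
    if X.ndim == 1:
        X = X[:, np.newaxis]
    if X.ndim != 2:
        raise ValueError("series must be T x N")
    return X


def detrend_linear(series) -> np.ndarray:
    """Remove each column's least-squares line against the time index.

    Residual columns have zero mean and zero slope.
    """
    X = _as_2d(series)
    T = X.shape[0]
    if T < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(T, dtype=np.float64)
    basis = np.column_stack([np.ones(T), t])
    coef, *_ = np.linalg.lstsq(basis, X, rcond=None)
    return X - basis @ coef


def bandpass_filter(series, tr: float, low_hz: float = 0.01,
                    high_hz: float = 0.08) -> np.ndarray:
    """Ideal (discrete-frequency mask) band-pass filter.

    The real FFT of each column is masked to keep bins whose frequency
    lies in ``[low_hz, high_hz]`` (inclusive) and zero everything else,
    then inverted.  An ideal mask is used rather than an IIR/FIR design so
    the operation is exactly idempotent and bit-reproducible; pure tones
    in the passband are preserved, stopband tones are removed entirely.
    ``low_hz > 0`` removes the DC component (mean).
    """
    X = _as_2d(series)
    T = X.shape[0]
    nyquist = 0.5 / tr
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below the Nyquist "
                         f"frequency {nyquist} for TR={tr}")
    freqs = np.fft.rfftfreq(T, d=tr)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(X, axis=0)
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def friston24(motion) -> np.ndarray:
    """24-parameter motion regressor expansion.

    From the 6 rigid-body parameters ``R(t)`` builds
    ``[R(t), R(t-1), R(t)^2, R(t-1)^2]`` (T x 24); the lagged block is
    zero-padded at t = 0.
    """
    M = _as_2d(motion)
    if M.shape[1] != 6:
        raise ValueError(f"motion trace must have 6 columns, got {M.shape[1]}")
    if M.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    lag = np.vstack([np.zeros((1, 6)), M[:-1]])
    return np.hstack([M, lag, M ** 2, lag ** 2])


def regress_nuisance(series, regressors) -> np.ndarray:
    """Residualize each column on [intercept, regressors] by OLS.

    Rank-deficient regressor sets are handled by dropping dependent
    columns (with a warning naming their indices); residuals are
    orthogonal to every retained regressor.
    """
    X = _as_2d(series)
    R = _as_2d(regressors)
    T, K = R.shape
    if X.shape[0] != T:
        raise ValueError("series and regressors disagree on T")
    if T <= K + 1:
        raise ValueError("need more time points than regressors")
    design = np.column_stack([np.ones(T), R])
    # drop columns that add no rank (constant duplicates, collinear sets)
    keep = [0]
    for j in range(1, design.shape[1]):
        trial = design[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    if len(keep) < design.shape[1]:
        dropped = sorted(set(range(design.shape[1])) - set(keep))
        warnings.warn(f"dropping rank-deficient regressor column(s) "
                      f"{[j - 1 for j in dropped]}", RuntimeWarning)
        design = design[:, keep]
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ coef


@dataclass
class QCResult:
    include: bool
    max_translation_mm: float
    max_rotation_deg: float
    mean_rms_mm: float
    reasons: list[str] = field(default_factory=list)


def motion_qc(motion) -> QCResult:
    """Apply the head-motion exclusion rule to a 6-parameter trace.

    Columns 0-2 are translations in mm, columns 3-5 rotations in degrees.
    Excluded when max |translation| > 2.0 mm, max |rotation| > 2.0 deg, or
    the mean relative RMS translation displacement > 0.2 mm.
    """
    M = _as_2d(motion)
    if M.shape[1] != 6:
        raise ValueError("motion trace must have 6 columns")
    trans, rot = M[:, :3], M[:, 3:]
    max_trans = float(np.abs(trans).max())
    max_rot = float(np.abs(rot).max())
    if M.shape[0] > 1:
        step = np.diff(trans, axis=0)
        mean_rms = float(np.linalg.norm(step, axis=1).mean())
    else:
        mean_rms = 0.0
    reasons = []
    if max_trans > MAX_TRANSLATION_MM:
        reasons.append("translation")
    if max_rot > MAX_ROTATION_DEG:
        reasons.append("rotation")
    if mean_rms > MAX_MEAN_RMS_MM:
        reasons.append("meanRMS")
    return QCResult(include=not reasons, max_translation_mm=max_trans,
                    max_rotation_deg=max_rot, mean_rms_mm=mean_rms,
                    reasons=reasons)


def denoise(series, tr: float, motion=None, nuisance=None,
            low_hz: float = 0.01, high_hz: float = 0.08,
            order: tuple[str, ...] = ("detrend", "bandpass", "regress"),
            ) -> np.ndarray:
    """Full denoising chain in the listed order.

    ``nuisance`` is a T x K array of nuisance signals (WM, CSF, global);
    ``motion`` a T x 6 trace expanded to the 24 Friston regressors.  The
    default order (detrend, band-pass, then nuisance regression) follows
    the conventional listing; ``order`` may swap filtering and regression.
    """
    X = _as_2d(series)
    regs = []
    if nuisance is not None:
        regs.append(_as_2d(nuisance))
    if motion is not None:
        regs.append(friston24(motion))
    R = np.hstack(regs) if regs else None
    for step in order:
        if step == "detrend":
            X = detrend_linear(X)
        elif step == "bandpass":
            X = bandpass_filter(X, tr, low_hz, high_hz)
        elif step == "regress":
            if R is not None:
                X = regress_nuisance(X, R)
        else:
            raise ValueError(f"unknown denoising step {step!r}")
    return X


def qc_report(traces: dict[str, np.ndarray]) -> pd.DataFrame:
    """Motion QC table for a set of subjects (subject_id -> T x 6 trace)."""
    rows = []
    for sid, trace in traces.items():
        r = motion_qc(trace)
        rows.append({"subject_id": sid,
                     "max_trans": r.max_translation_mm,
                     "max_rot": r.max_rotation_deg,
                     "mean_rms": r.mean_rms_mm,
                     "decision": "include" if r.include else "exclude",
                     "reasons": ";".join(r.reasons)})
    return pd.DataFrame(rows)
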