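"""Motion-aware cleaning of parcellated BOLD time series.

The stage order is fixed and mirrors the analysis contract of the package:

1. framewise displacement (FD) from the six rigid-body motion estimates,
2. zero-phase low-pass filtering of the FD trace (default 0.3 Hz) to keep
   respiration-band oscillations from inflating apparent motion,
3. frame censoring ("scrubbing") at an FD threshold (default 0.3 mm), also
   removing one frame before and two after every flagged frame,
4. nuisance regression on the retained frames: intercept, the 6 motion
   estimates and their first differences (the "12 motion parameters"),
   ventricle and white-matter signals and their first differences, and the
   global signal.

Rotations are converted to arc length on a 50 mm sphere, the conventional
head-radius approximation, and FD is the Euclidean (L2) norm of the
six-element displacement delta.  First differences are backward differences
computed on the full series before censoring, so gaps do not corrupt the
derivative regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ParcellatedTimeSeries",
    "ScrubResult",
    "framewise_displacement",
    "lowpass_filter_fd",
    "scrub_mask",
    "scrub",
    "regress_nuisance",
]

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: names of the nuisance design columns, in order
DESIGN_COLUMNS = (
    ("intercept",)
    + MOTION_COLUMNS
    + tuple("d_" + c for c in MOTION_COLUMNS)
    + ("ventricle", "white_matter", "d_ventricle", "d_white_matter", "global")
)


@dataclass(frozen=True)
class ParcellatedTimeSeries:
    """One subject's region-by-frame BOLD matrix plus frame timing."""

    subject_id: str
    data: np.ndarray
    tr: float
    region_ids: tuple

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("data must be a regions x frames matrix")
        if d.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if d.shape[1] < 10:
            raise ValueError("need at least 10 frames")
        if d.shape[0] != len(self.region_ids):
            raise ValueError("region_ids length does not match data rows")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite values in time series")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        object.__setattr__(self, "data", d)

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ScrubResult:
    """FD traces, the frame keep-mask and the censoring count."""

    fd_raw: np.ndarray
    fd_filtered: np.ndarray
    keep_mask: np.ndarray

    @property
    def n_censored(self) -> int:
        return int((~self.keep_mask).sum())


def framewise_displacement(
    motion: np.ndarray, rotation_radius: float = 50.0
) -> np.ndarray:
    """Per-frame head displacement in mm.

    ``motion`` holds 3 translations (mm) then 3 rotations (radians), one row
    per frame.  FD at frame t is the L2 norm of the six frame-to-frame
    deltas, rotations converted to arc length at ``rotation_radius`` mm.
    The first frame has no predecessor and gets FD 0 by convention.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must be a frames x 6 matrix")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite motion values")
    delta = np.diff(m, axis=0)
    delta[:, 3:] *= rotation_radius
    fd = np.zeros(m.shape[0])
    fd[1:] = np.linalg.norm(delta, axis=1)
    return fd


def lowpass_filter_fd(fd: np.ndarray, cutoff_hz: float, tr: float) -> np.ndarray:
    """Zero-phase low-pass of the FD trace (order-2 Butterworth, filtfilt).

    Unit DC gain, so a constant trace passes through unchanged; raises if
    the cutoff is at or above the Nyquist frequency rather than silently
    passing data through.
    """
    fd = np.asarray(fd, dtype=float)
    nyquist = 1.0 / (2.0 * tr)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is not below Nyquist {nyquist:.4g} Hz "
            f"for tr={tr}"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    b, a = signal.butter(2, cutoff_hz, btype="low", fs=1.0 / tr)
    padlen = 3 * max(len(a), len(b))
    if fd.size <= padlen:
        raise ValueError(f"FD trace too short for filter warm-up ({padlen + 1})")
    return signal.filtfilt(b, a, fd)


def scrub_mask(
    fd_filtered: np.ndarray,
    threshold: float = 0.3,
    n_before: int = 1,
    n_after: int = 2,
) -> np.ndarray:
    """Boolean keep-mask from the filtered FD trace.

    A frame is censored iff it lies within ``n_before`` frames before or
    ``n_after`` frames after (inclusive) some frame whose FD exceeds the
    threshold; windows are clipped at the series boundaries.
    """
    fd = np.asarray(fd_filtered, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = np.ones(fd.size, dtype=bool)
    for f in np.flatnonzero(fd > threshold):
        lo = max(0, f - n_before)
        hi = min(fd.size, f + n_after + 1)
        keep[lo:hi] = False
    return keep


def scrub(
    motion: np.ndarray,
    tr: float,
    threshold: float = 0.3,
    cutoff_hz: float = 0.3,
    rotation_radius: float = 50.0,
    n_before: int = 1,
    n_after: int = 2,
) -> ScrubResult:
    """FD computation, FD low-pass and censoring in one step."""
    fd_raw = framewise_displacement(motion, rotation_radius)
    fd_filt = lowpass_filter_fd(fd_raw, cutoff_hz, tr)
    keep = scrub_mask(fd_filt, threshold, n_before, n_after)
    return ScrubResult(fd_raw, fd_filt, keep)


def _backward_diff(x: np.ndarray) -> np.ndarray:
    """Backward first difference along axis 0, first element 0."""
    x = np.asarray(x, dtype=float)
    return np.diff(x, axis=0, prepend=x[:1])


def regress_nuisance(
    ts: ParcellatedTimeSeries,
    motion: np.ndarray,
    ventricle: np.ndarray,
    white_matter: np.ndarray,
    global_signal: np.ndarray,
    keep_mask: np.ndarray | None = None,
) -> ParcellatedTimeSeries:
    """Residualize every region series on the nuisance design.

    The design (see :data:`DESIGN_COLUMNS`) is built on the full series so
    the difference regressors are well defined, then the least-squares fit
    and residuals are computed on retained frames only; the returned series
    contains only those frames and each region has exactly zero mean.
    """
    motion = np.asarray(motion, dtype=float)
    vent = np.asarray(ventricle, dtype=float).ravel()
    wm = np.asarray(white_matter, dtype=float).ravel()
    gs = np.asarray(global_signal, dtype=float).ravel()
    n = ts.n_frames
    for name, arr in [("motion", motion), ("ventricle", vent),
                      ("white_matter", wm), ("global", gs)]:
        if arr.shape[0] != n:
            raise ValueError(f"{name} frame count {arr.shape[0]} != {n}")
    if motion.shape[1] != 6:
        raise ValueError("motion must have 6 columns")
    if keep_mask is None:
        keep_mask = np.ones(n, dtype=bool)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    if keep_mask.shape[0] != n:
        raise ValueError("keep_mask length mismatch")

    design = np.column_stack(
        [
            np.ones(n),
            motion,
            _backward_diff(motion),
            vent,
            wm,
            _backward_diff(vent),
            _backward_diff(wm),
            gs,
        ]
    )
    k = design.shape[1]
    if keep_mask.sum() < k + 2:
        raise ValueError(
            f"only {int(keep_mask.sum())} retained frames for {k} regressors"
        )
    x = design[keep_mask]
    if np.linalg.matrix_rank(x) < k:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [DESIGN_COLUMNS[piv[i]] for i in range(k) if diag[i] <= tol]
        raise ValueError(f"rank-deficient nuisance design; collinear: {bad}")

    y = ts.data[:, keep_mask].T
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = (y - x @ beta).T
    resid -= resid.mean(axis=1, keepdims=True)
    return ParcellatedTimeSeries(ts.subject_id, resid, ts.tr, ts.region_ids)
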