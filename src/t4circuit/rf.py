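"""Reverse-correlation receptive fields and directional statistics.

The linear spatiotemporal receptive field of a cell is estimated by
cross-correlating a white-noise stimulus with the simultaneously
recorded, drift-corrected and baseline-subtracted membrane voltage:

    K(x, tau) = sum_t S(x, t - tau) * V_m(t) * dt

for lags tau from -0.5 s to +3.0 s at the stimulus frame rate.  Kernels
are converted to standard scores; cells without a clear peak (|z| below
a criterion, default 4 s.d.) or with centres too close to the screen
bezel are excluded.  Directional statistics (preferred direction by
vector sum, the tuning index L_dir, Voigt-profile response amplitudes)
follow the standard definitions for fly motion-vision electrophysiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stimuli import StimulusMovie

__all__ = [
    "SpatioTemporalRF",
    "RFRejection",
    "TuningCurve",
    "drift_correct",
    "reverse_correlate",
    "zscore_center_filter",
    "average_rfs",
    "preferred_direction",
    "UndefinedPD",
    "ldir",
    "tuning_from_edges",
]


@dataclass
class SpatioTemporalRF:
    """A reverse-correlation kernel over (lag, elevation, azimuth)."""

    kernel: np.ndarray            # (n_lags, n_elev, n_azim)
    lags_s: np.ndarray
    pixel_pitch: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        if self.kernel.shape[0] != self.lags_s.size:
            raise ValueError("lag axis mismatch")

    def zscored(self) -> np.ndarray:
        """Kernel as standard scores over the whole kernel."""
        mu, sd = self.kernel.mean(), self.kernel.std()
        if sd == 0:
            raise ValueError("flat kernel cannot be z-scored")
        return (self.kernel - mu) / sd

    def extremum(self) -> tuple[tuple[int, int, int], float]:
        """Index and value (in s.d.) of the max-|z| kernel entry."""
        z = self.zscored()
        idx = np.unravel_index(np.argmax(np.abs(z)), z.shape)
        return tuple(int(i) for i in idx), float(z[idx])


@dataclass
class RFRejection:
    """Typed outcome for cells excluded by the peak or edge criterion."""

    reason: str
    peak_sd: float


@dataclass
class CenteredRF:
    """An accepted, z-scored RF with its extremum at spatial offset 0."""

    z: np.ndarray                 # (n_lags, n_elev, n_azim)
    lags_s: np.ndarray
    center_px: tuple[int, int]    # (elev, azim) index of the extremum
    peak_lag_s: float
    peak_sd: float
    pixel_pitch: float


def drift_correct(vm: np.ndarray, fs_hz: float, sigma_s: float = 60.0) -> np.ndarray:
    """Remove slow drift by subtracting a Gaussian low-pass (sigma 60 s)."""
    vm = np.asarray(vm, dtype=float)
    slow = ndimage.gaussian_filter1d(vm, sigma=sigma_s * fs_hz, mode="nearest")
    return vm - slow


def reverse_correlate(
    movie: StimulusMovie,
    vm: np.ndarray,
    vm_fs_hz: float | None = None,
    lag_range_s: tuple[float, float] = (-0.5, 3.0),
) -> SpatioTemporalRF:
    """First-order reverse correlation of ``vm`` against a stimulus movie.

    ``vm`` is the baseline-subtracted membrane voltage, time-locked to
    the movie.  If recorded at a different rate it is resampled to the
    stimulus clock (frame-wise averaging), which makes the kernel
    independent of the physiological sampling rate.  Lags run over
    ``lag_range_s`` in steps of one stimulus frame; the sum over time is
    multiplied by the frame duration to approximate the integral.
    """
    vm = np.asarray(vm, dtype=float)
    fr = movie.frame_rate
    if vm_fs_hz is not None and vm_fs_hz != fr:
        factor = vm_fs_hz / fr
        n = movie.n_frames
        idx = (np.arange(vm.size) / factor).astype(int)
        resampled = np.bincount(idx, weights=vm, minlength=n)
        counts = np.bincount(idx, minlength=n)
        vm = np.divide(resampled[:n], np.maximum(counts[:n], 1))
    n = min(vm.size, movie.n_frames)
    lag_lo = int(round(lag_range_s[0] * fr))
    lag_hi = int(round(lag_range_s[1] * fr))
    if n <= max(abs(lag_lo), abs(lag_hi)):
        raise ValueError("trace shorter than the maximum lag")
    lags = np.arange(lag_lo, lag_hi + 1)
    dt = 1.0 / fr
    frames = movie.frames[:n].reshape(n, -1)
    v = vm[:n]
    kern = np.empty((lags.size,) + movie.frames.shape[1:])
    for j, lag in enumerate(lags):
        # K(x, tau) = sum_t S(x, t - tau) V(t) dt
        if lag >= 0:
            k = frames[: n - lag].T @ v[lag:]
        else:
            k = frames[-lag:].T @ v[: n + lag]
        kern[j] = (k * dt).reshape(movie.frames.shape[1:])
    return SpatioTemporalRF(kern, lags / fr, movie.pixel_pitch, movie.origin)


def zscore_center_filter(
    rf: SpatioTemporalRF,
    peak_sd: float = 4.0,
    edge_margin_deg: float = 22.48,
) -> CenteredRF | RFRejection:
    """Apply the peak and screen-edge inclusion criteria and centre the RF.

    The kernel is z-scored; its extremum (maximum or minimum with the
    largest |z|) must exceed ``peak_sd`` standard deviations and must lie
    at least ``edge_margin_deg`` from every screen edge, guaranteeing
    full coverage of the surround.  Failing cells yield an
    :class:`RFRejection`; accepted cells are returned with the spatial
    origin shifted so the extremum sits at 0 degrees.
    """
    (ilag, ielev, iazim), zpeak = rf.extremum()
    if abs(zpeak) < peak_sd:
        return RFRejection("peak below criterion", abs(zpeak))
    n_elev, n_azim = rf.kernel.shape[1:]
    margin_px = edge_margin_deg / rf.pixel_pitch
    if (iazim < margin_px or ielev < margin_px
            or (n_azim - 1 - iazim) < margin_px
            or (n_elev - 1 - ielev) < margin_px):
        return RFRejection("centre too close to screen edge", abs(zpeak))
    return CenteredRF(
        z=rf.zscored(),
        lags_s=rf.lags_s,
        center_px=(ielev, iazim),
        peak_lag_s=float(rf.lags_s[ilag]),
        peak_sd=abs(zpeak),
        pixel_pitch=rf.pixel_pitch,
    )


def average_rfs(
    rfs: list[CenteredRF],
    upsample: int = 10,
    smooth_sd_px: float = 1.8,
    rotate_to_pd_deg: list[float] | None = None,
) -> np.ndarray:
    """Population-average spatial RF at the extremum lag.

    Each accepted RF contributes its z-scored spatial map at the peak
    lag, recentred on its extremum.  Maps are cropped to the largest
    region common to all cells, optionally rotated so that each cell's
    preferred direction points along +azimuth, averaged, upsampled by
    linear interpolation and smoothed with a Gaussian (s.d. in
    upsampled pixels).
    """
    if not rfs:
        raise ValueError("no receptive fields to average")
    maps = []
    for k, rf in enumerate(rfs):
        ilag = int(np.argmin(np.abs(rf.lags_s - rf.peak_lag_s)))
        m = rf.z[ilag]
        if rotate_to_pd_deg is not None:
            m = ndimage.rotate(m, rotate_to_pd_deg[k], reshape=False,
                               order=1, mode="nearest")
        maps.append((m, rf.center_px))
    # largest common window around each centre
    up = min(c[0] for _, c in maps)
    down = min(m.shape[0] - 1 - c[0] for m, c in maps)
    left = min(c[1] for _, c in maps)
    right = min(m.shape[1] - 1 - c[1] for m, c in maps)
    cropped = [m[c[0] - up:c[0] + down + 1, c[1] - left:c[1] + right + 1]
               for m, c in maps]
    mean = np.mean(cropped, axis=0)
    if upsample > 1:
        mean = ndimage.zoom(mean, upsample, order=1)
    if smooth_sd_px > 0:
        mean = ndimage.gaussian_filter(mean, smooth_sd_px, mode="nearest")
    return mean


class UndefinedPD(ValueError):
    """Raised when the resultant vector of the responses is zero."""


def preferred_direction(directions_deg, magnitudes) -> float:
    """Preferred direction: angle of the resultant of |v(phi)| vectors, deg."""
    phi = np.deg2rad(np.asarray(directions_deg, dtype=float))
    mag = np.asarray(magnitudes, dtype=float)
    if phi.size < 2:
        raise ValueError("need at least two directions")
    if np.any(mag < 0):
        raise ValueError("magnitudes must be non-negative")
    x = float(np.sum(mag * np.cos(phi)))
    y = float(np.sum(mag * np.sin(phi)))
    r = np.hypot(x, y)
    if r < 1e-12 * max(mag.sum(), 1.0):
        raise UndefinedPD("zero resultant vector; preferred direction undefined")
    return float(np.rad2deg(np.arctan2(y, x)) % 360.0)


def ldir(directions_deg, magnitudes) -> float:
    """Directional tuning index L_dir = |sum v(phi)| / sum |v(phi)|.

    1 when all response mass lies in a single direction, 0 under full
    directional symmetry; invariant to uniform scaling of magnitudes.
    """
    phi = np.deg2rad(np.asarray(directions_deg, dtype=float))
    mag = np.asarray(magnitudes, dtype=float)
    if np.any(mag < 0):
        raise ValueError("magnitudes must be non-negative")
    total = mag.sum()
    if total <= 0:
        raise ValueError("all-zero responses; L_dir undefined")
    x = np.sum(mag * np.cos(phi))
    y = np.sum(mag * np.sin(phi))
    return float(np.hypot(x, y) / total)


@dataclass
class TuningCurve:
    """Direction -> response magnitude, with PD and L_dir attached."""

    directions_deg: np.ndarray
    magnitudes: np.ndarray
    pd_deg: float
    l_dir: float
    normalized: bool = False

    def aligned(self) -> "TuningCurve":
        """Shift directions so the preferred direction reads 0 degrees."""
        d = (self.directions_deg - self.pd_deg) % 360.0
        order = np.argsort(d)
        return TuningCurve(d[order], self.magnitudes[order], 0.0,
                           self.l_dir, self.normalized)


def _voigt_amplitude(t: np.ndarray, y: np.ndarray) -> float:
    """Peak of a Voigt profile fitted to (t, y); falls back to max(y)."""
    import warnings
    from lmfit.models import VoigtModel, ConstantModel

    model = VoigtModel() + ConstantModel()
    i0 = int(np.argmax(y))
    span = max(t[-1] - t[0], 1e-9)
    pars = model.make_params(
        amplitude=max(float(np.ptp(y)) * span / 4, 1e-9),
        center=float(t[i0]),
        sigma=span / 8,
        gamma=1e-6,
        c=float(np.min(y)),
    )
    pars["center"].set(min=t[0], max=t[-1])
    pars["sigma"].set(min=1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(y, pars, x=t)
        tt = np.linspace(t[0], t[-1], 4 * t.size)
        return float(np.max(res.eval(x=tt)))
    except Exception:
        return float(np.max(y))


def tuning_from_edges(
    episodes: dict[float, np.ndarray],
    fs_hz: float = 1000.0,
    window_ms: float = 700.0,
    baseline_s: float = 1.0,
    normalize: bool = True,
    voigt: bool = True,
) -> TuningCurve:
    """Directional tuning curve from edge responses.

    ``episodes`` maps a motion direction (deg) to the mean stimulus-
    locked voltage trace (mV).  Per direction the 1 s pre-stimulus mean
    is subtracted and the response magnitude is the maximum of a Voigt
    profile fitted within a ``window_ms`` window surrounding the raw
    peak (the fit exploits more samples than the raw maximum alone;
    non-converging fits fall back to the raw peak).  When ``normalize``
    the curve is aligned to PD = 0 and min-max normalized.
    """
    if not episodes:
        raise ValueError("no directions supplied")
    dirs = np.array(sorted(episodes), dtype=float)
    mags = np.empty(dirs.size)
    n_base = max(1, int(round(baseline_s * fs_hz)))
    half = int(round(window_ms / 2 * 1e-3 * fs_hz))
    for i, d in enumerate(dirs):
        tr = np.asarray(episodes[d], dtype=float)
        y = tr - np.mean(tr[:min(n_base, tr.size)])
        ipk = int(np.argmax(y))
        lo, hi = max(0, ipk - half), min(y.size, ipk + half + 1)
        if voigt and hi - lo > 8:
            t = np.arange(lo, hi) / fs_hz
            mags[i] = _voigt_amplitude(t, y[lo:hi])
        else:
            mags[i] = float(np.max(y[lo:hi]))
    mags = np.maximum(mags, 0.0)
    try:
        pd_deg = preferred_direction(dirs, mags)
    except UndefinedPD:
        pd_deg = float("nan")
    l = ldir(dirs, mags)
    curve = TuningCurve(dirs, mags, pd_deg, l)
    if normalize:
        if np.isfinite(pd_deg):
            curve = curve.aligned()
        lo_m, hi_m = curve.magnitudes.min(), curve.magnitudes.max()
        if hi_m > lo_m:
            curve.magnitudes = (curve.magnitudes - lo_m) / (hi_m - lo_m)
        curve.normalized = True
    return curve
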