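"""Visual stimulus generation.

All stimuli used by the physiology emulation and the receptive-field
analysis are movies on a flat virtual screen: binary spatiotemporal white
noise, moving ON/OFF contrast edges, and drifting square-wave gratings.
A small photodiode emulator (:func:`luminance_at`) reads back the mean
luminance in an aperture, which is how stimulus/recording alignment is
verified experimentally.

Conventions
-----------
Frames are stored as ``(time, elevation, azimuth)`` with luminance in
``[0, 1]``; time is always axis 0.  Angular positions are given as
``(azimuth_deg, elevation_deg)`` pairs on a flat screen; the cylindrical
pre-distortion used by projection hardware is display compensation and is
not modelled.  A pixel's nominal position is its centre; moving edges are
anti-aliased by fractional pixel coverage so that the luminance at a fixed
point crosses 0.5 exactly when the ideal edge passes the pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusMovie",
    "EdgeSpec",
    "make_white_noise",
    "make_edge",
    "make_grating",
    "luminance_at",
]


@dataclass
class StimulusMovie:
    """A luminance movie over ``(time, elevation, azimuth)``.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_elevation, n_azimuth)`` with values
        in ``[0, 1]``.
    frame_rate
        Frames per second (Hz), > 0.
    pixel_pitch
        Angular size of one pixel in degrees, > 0.
    origin
        ``(azimuth_deg, elevation_deg)`` of the centre of pixel
        ``[..., 0, 0]``.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, elevation, azimuth)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        fmin, fmax = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=0.0))
        if fmin < -1e-12 or fmax > 1 + 1e-12:
            raise ValueError("luminance values must lie in [0, 1]")

    # -- geometry ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Frame onset times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def azimuths(self) -> np.ndarray:
        """Azimuth of each pixel column centre (deg)."""
        return self.origin[0] + self.pixel_pitch * np.arange(self.frames.shape[2])

    @property
    def elevations(self) -> np.ndarray:
        """Elevation of each pixel row centre (deg)."""
        return self.origin[1] + self.pixel_pitch * np.arange(self.frames.shape[1])

    @property
    def extent_deg(self) -> tuple[float, float, float, float]:
        """(azim_min, azim_max, elev_min, elev_max) spanned by pixel centres."""
        az, el = self.azimuths, self.elevations
        return float(az[0]), float(az[-1]), float(el[0]), float(el[-1])

    def contains(self, point_deg: tuple[float, float]) -> bool:
        a0, a1, e0, e1 = self.extent_deg
        az, el = point_deg
        return a0 <= az <= a1 and e0 <= el <= e1


@dataclass
class EdgeSpec:
    """A moving contrast edge.

    ``direction_deg`` is the direction of motion, measured counter-
    clockwise from the +azimuth axis.  ON edges brighten (dark to bright),
    OFF edges darken.  ``extent`` is ``(azim_min, azim_max, elev_min,
    elev_max)`` in degrees.
    """

    polarity: str = "ON"
    direction_deg: float = 0.0
    velocity_deg_s: float = 30.0
    extent: tuple[float, float, float, float] = (0.0, 56.0, 0.0, 56.0)
    pad_s: float = 0.0  # static time before the edge starts moving

    def __post_init__(self) -> None:
        self.polarity = self.polarity.upper()
        if self.polarity not in ("ON", "OFF"):
            raise ValueError("polarity must be 'ON' or 'OFF'")
        if not (0.0 <= self.direction_deg < 360.0):
            self.direction_deg = float(np.mod(self.direction_deg, 360.0))
        if self.velocity_deg_s <= 0:
            raise ValueError("velocity must be positive")


def make_white_noise(
    width_px: int,
    height_px: int,
    duration_s: float,
    frame_rate: float = 60.0,
    pixel_pitch: float = 2.8,
    seed: int | np.random.Generator = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> StimulusMovie:
    """Binary spatiotemporal white noise: each pixel i.i.d. Bernoulli(0.5).

    Samples are redrawn once per frame; under a fixed ``seed`` the movie is
    reproducible bit for bit.
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("dimensions must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    frames = rng.integers(0, 2, size=(n_frames, height_px, width_px)).astype(float)
    return StimulusMovie(frames, frame_rate, pixel_pitch, origin)


def make_edge(
    spec: EdgeSpec,
    frame_rate: float = 60.0,
    pixel_pitch: float = 2.8,
) -> StimulusMovie:
    """Render a straight edge sweeping across ``spec.extent``.

    The edge front is orthogonal to the direction of motion and traverses
    the full extent at ``spec.velocity_deg_s``.  Luminance at any fixed
    point is a monotone step in time (increasing for ON, decreasing for
    OFF); the step midpoint at a pixel occurs exactly when the ideal edge
    line crosses the pixel centre.
    """
    a0, a1, e0, e1 = spec.extent
    if a1 - a0 < pixel_pitch or e1 - e0 < pixel_pitch:
        raise ValueError("extent smaller than one pixel")
    n_az = int(np.floor((a1 - a0) / pixel_pitch)) + 1
    n_el = int(np.floor((e1 - e0) / pixel_pitch)) + 1
    az = a0 + pixel_pitch * np.arange(n_az)
    el = e0 + pixel_pitch * np.arange(n_el)
    azg, elg = np.meshgrid(az, el)

    phi = np.deg2rad(spec.direction_deg)
    # signed position of each pixel along the motion axis
    s = np.cos(phi) * (azg - 0.5 * (a0 + a1)) + np.sin(phi) * (elg - 0.5 * (e0 + e1))
    s_min, s_max = float(s.min()), float(s.max())

    travel_s = (s_max - s_min + pixel_pitch) / spec.velocity_deg_s
    n_frames = int(np.ceil((travel_s + spec.pad_s) * frame_rate)) + 1
    t = np.arange(n_frames) / frame_rate

    # front position over time; held at the start during the pad
    front = s_min - 0.5 * pixel_pitch + spec.velocity_deg_s * np.maximum(t - spec.pad_s, 0.0)
    cover = (front[:, None, None] - s[None, :, :]) / pixel_pitch + 0.5
    frames = np.clip(cover, 0.0, 1.0)
    if spec.polarity == "OFF":
        frames = 1.0 - frames
    return StimulusMovie(frames, frame_rate, pixel_pitch, origin=(a0, e0))


def make_grating(
    wavelength_deg: float,
    temporal_freq_hz: float,
    direction_deg: float = 0.0,
    duration_s: float = 4.0,
    frame_rate: float = 60.0,
    pixel_pitch: float = 2.8,
    extent: tuple[float, float, float, float] = (0.0, 56.0, 0.0, 56.0),
) -> StimulusMovie:
    """Full-contrast square-wave grating drifting in ``direction_deg``.

    The drift speed is ``temporal_freq_hz * wavelength_deg`` deg/s; with
    zero temporal frequency the pattern is static.
    """
    if wavelength_deg <= 0:
        raise ValueError("wavelength must be positive")
    if temporal_freq_hz < 0:
        raise ValueError("temporal frequency must be non-negative")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    a0, a1, e0, e1 = extent
    n_az = int(np.floor((a1 - a0) / pixel_pitch)) + 1
    n_el = int(np.floor((e1 - e0) / pixel_pitch)) + 1
    az = a0 + pixel_pitch * np.arange(n_az)
    el = e0 + pixel_pitch * np.arange(n_el)
    azg, elg = np.meshgrid(az, el)
    phi = np.deg2rad(direction_deg)
    s = np.cos(phi) * azg + np.sin(phi) * elg

    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    phase = s[None, :, :] / wavelength_deg - temporal_freq_hz * t[:, None, None]
    # quantize to avoid float fuzz flipping pixels exactly on a stripe boundary
    phase = np.round(phase * 1e9) / 1e9 % 1.0
    frames = (phase < 0.5).astype(float)
    return StimulusMovie(frames, frame_rate, pixel_pitch, origin=(a0, e0))


def luminance_at(
    movie: StimulusMovie,
    point_deg: tuple[float, float],
    aperture_deg: float = 5.0,
) -> np.ndarray:
    """Photodiode emulation: mean luminance per frame in a square aperture.

    ``point_deg`` is the aperture centre ``(azimuth, elevation)``; pixels
    contribute by the fraction of their area inside the aperture, so the
    trace varies smoothly as an edge sweeps through.
    """
    if not movie.contains(point_deg):
        raise ValueError(f"point {point_deg} outside movie extent {movie.extent_deg}")
    if aperture_deg <= 0:
        raise ValueError("aperture must be positive")
    az, el = movie.azimuths, movie.elevations
    half = 0.5 * aperture_deg
    p = movie.pixel_pitch

    def coverage(centers: np.ndarray, lo: float, hi: float) -> np.ndarray:
        left = np.maximum(centers - 0.5 * p, lo)
        right = np.minimum(centers + 0.5 * p, hi)
        return np.clip(right - left, 0.0, None) / p

    waz = coverage(az, point_deg[0] - half, point_deg[0] + half)
    wel = coverage(el, point_deg[1] - half, point_deg[1] + half)
    w = wel[:, None] * waz[None, :]
    total = w.sum()
    if total <= 0:
        raise ValueError("aperture covers no pixels")
    return np.tensordot(movie.frames, w / total, axes=([1, 2], [0, 1]))
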