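"""Synthetic confocal imaging: kymographs and 2D scans with PSF blur and shot noise.

Emitters (unbleached DNA-bound ParB) are rendered with a Gaussian point
spread function (default FWHM 250 nm, the diffraction-limited resolution
of the instrument), sampled on a 100 nm pixel grid with a 0.1 ms pixel
dwell, and photon counts are Poisson-distributed around the expected
count.  Kymographs are repeated single-line scans along the DNA axis
(one row per line period); 2D scans add a transverse Gaussian profile of
the same sigma across rows.  Emitter positions are frozen at the start
of each scan line: the line period (tens of ms) is much longer than the
pixel dwell, so intra-line motion blur is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TrajectorySet

__all__ = ["OpticsConfig", "KymographImage", "ScanImage", "render_kymograph", "render_scan"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548
_PSF_TRUNC_SIGMAS = 4.0


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition geometry and photon budget of the confocal scan head."""

    pixel_size_nm: float = 100.0
    psf_fwhm_nm: float = 250.0
    photon_rate: float = 5.0e5       # counts/s per unbleached emitter
    background_rate: float = 1.0e4   # counts/s per pixel
    line_period_s: float = 0.025
    pixel_dwell_s: float = 1.0e-4

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "psf_fwhm_nm", "photon_rate",
                     "background_rate", "line_period_s", "pixel_dwell_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.psf_fwhm_nm < self.pixel_size_nm:
            raise ValueError("PSF FWHM must be at least one pixel")

    @property
    def sigma_nm(self) -> float:
        return self.psf_fwhm_nm * _FWHM_TO_SIGMA


@dataclass
class KymographImage:
    """Photon-count matrix: rows = scan lines (time), columns = position pixels."""

    counts: np.ndarray          # (n_lines, n_pixels) non-negative integers
    line_times: np.ndarray      # s
    pixel_positions: np.ndarray  # nm along the DNA axis
    optics: OpticsConfig

    @property
    def pixel_size_nm(self) -> float:
        return self.optics.pixel_size_nm


@dataclass
class ScanImage:
    """One confocal frame: rows = transverse lines, columns = axial pixels."""

    counts: np.ndarray
    row_positions: np.ndarray   # nm, transverse offset from the DNA axis
    pixel_positions: np.ndarray  # nm along the DNA axis
    t_start: float
    optics: OpticsConfig
    axis_row: int = 0

    @property
    def frame_time_s(self) -> float:
        return len(self.row_positions) * self.optics.line_period_s


def _axial_mass(pixel_positions: np.ndarray, emitters_nm: np.ndarray,
                optics: OpticsConfig) -> np.ndarray:
    """Expected PSF mass per axial pixel per unit (rate*dwell), summed over emitters."""
    sigma = optics.sigma_nm
    out = np.zeros_like(pixel_positions)
    for xe in emitters_nm:
        d = pixel_positions - xe
        sel = np.abs(d) <= _PSF_TRUNC_SIGMAS * sigma
        out[sel] += (
            optics.pixel_size_nm
            / (sigma * np.sqrt(2.0 * np.pi))
            * np.exp(-0.5 * (d[sel] / sigma) ** 2)
        )
    return out


def _pixel_grid(ts: TrajectorySet, optics: OpticsConfig) -> np.ndarray:
    contour_nm = ts.substrate.contour_length_nm
    n_px = int(np.ceil(contour_nm / optics.pixel_size_nm)) + 1
    return np.arange(n_px) * optics.pixel_size_nm


def render_kymograph(ts: TrajectorySet, optics: OpticsConfig = OpticsConfig(),
                     seed: int = 0) -> KymographImage:
    """Render repeated line scans of a trajectory set into a kymograph.

    Expected count in pixel j of the line scanned at time t is
    ``background*dwell + sum_e rate*dwell*G(x_j - x_e; sigma)`` over the
    unbleached bound emitters at t (G: pixel-integrated Gaussian PSF,
    truncated at 4 sigma); realized counts are Poisson.
    """
    sim_dt = ts.times[1] - ts.times[0] if len(ts.times) > 1 else np.inf
    if sim_dt > optics.line_period_s + 1e-12:
        raise ValueError("trajectory sampling must be at least as fine as the line period")
    rng = np.random.default_rng(seed)
    px = _pixel_grid(ts, optics)
    line_times = np.arange(0.0, ts.times[-1] + 1e-12, optics.line_period_s)
    rise = ts.substrate.rise_per_bp
    bg = optics.background_rate * optics.pixel_dwell_s
    amp = optics.photon_rate * optics.pixel_dwell_s

    expected = np.empty((len(line_times), len(px)))
    for i, t in enumerate(line_times):
        emitters_nm = ts.emitter_positions_bp(t) * rise
        expected[i] = bg + amp * _axial_mass(px, emitters_nm, optics)
    counts = rng.poisson(expected).astype(np.uint16)
    return KymographImage(counts=counts, line_times=line_times, pixel_positions=px,
                          optics=optics)


def render_scan(ts: TrajectorySet, t0: float, optics: OpticsConfig = OpticsConfig(),
                n_lines: int = 11, seed: int = 0) -> ScanImage:
    """Render one confocal frame starting at t0 (row i scanned at t0 + i*period).

    The PSF is the same Gaussian in both directions (2D-normalised mass);
    the DNA axis sits on the centre row.
    """
    if not (ts.times[0] <= t0 <= ts.times[-1]):
        raise ValueError("t0 outside the simulation time span")
    rng = np.random.default_rng(seed)
    px = _pixel_grid(ts, optics)
    axis_row = n_lines // 2
    rows_nm = (np.arange(n_lines) - axis_row) * optics.pixel_size_nm
    rise = ts.substrate.rise_per_bp
    sigma = optics.sigma_nm
    bg = optics.background_rate * optics.pixel_dwell_s
    amp = optics.photon_rate * optics.pixel_dwell_s

    expected = np.full((n_lines, len(px)), bg)
    for i, y in enumerate(rows_nm):
        t = t0 + i * optics.line_period_s
        emitters_nm = ts.emitter_positions_bp(min(t, ts.times[-1])) * rise
        trans = (
            optics.pixel_size_nm
            / (sigma * np.sqrt(2.0 * np.pi))
            * np.exp(-0.5 * (y / sigma) ** 2)
        )
        if trans > 0:
            expected[i] += amp * trans * _axial_mass(px, emitters_nm, optics)
    counts = rng.poisson(expected).astype(np.uint16)
    return ScanImage(counts=counts, row_positions=rows_nm, pixel_positions=px,
                     t_start=t0, optics=optics, axis_row=axis_row)
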