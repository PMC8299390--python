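"""Kymograph analysis: particle tracking, MSD, diffusion constants, profiles.

A tracked particle gives a 1D trajectory x(t) along the DNA.  The
time-averaged mean squared displacement at lag k*delta is

    MSD(k*delta) = mean_i (x_{i+k} - x_i)^2            (overlapping pairs)

and the diffusion constant follows from the linear model
``MSD = 2*D*t + offset`` fitted by ordinary least squares over a lag
window; D is half the slope and the intercept absorbs static
localization noise.  Trajectories are clipped to their first 2.5 s
before the MSD so that every track contributes a comparable statistical
sample, and per-trajectory D values (negatives included) are averaged
into an ensemble mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .substrate import SubstrateMap
from .imaging import KymographImage, ScanImage

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionEstimate",
    "IntensityProfile",
    "detect_peaks",
    "link_tracks",
    "track_kymograph",
    "compute_msd",
    "fit_diffusion",
    "ensemble_D",
    "is_immobile",
    "extract_profile",
    "quantify_region",
    "fit_bleach_decay",
]

TRAJECTORY_CLIP_S = 2.5  # analysis window per track, matches the acquisition protocol
DEFAULT_FIT_LAGS = (2, 10)  # lag-1 excluded to reduce localization-noise bias
IMMOBILE_D_THRESHOLD = 0.05  # um^2/s
IMMOBILE_PARS_WINDOW_NM = 250.0


@dataclass
class Trajectory:
    """One tracked particle: times (s), positions (um), peak intensities."""

    times: np.ndarray
    positions_um: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class MSDCurve:
    lag_times: np.ndarray   # s
    msd: np.ndarray         # um^2
    pair_counts: np.ndarray


@dataclass
class DiffusionEstimate:
    D: float                # um^2/s
    offset: float           # um^2, localization-noise intercept
    lag_window: tuple[int, int]
    residual_norm: float
    mean_position_um: float = np.nan


@dataclass
class IntensityProfile:
    positions_um: np.ndarray
    mean_counts: np.ndarray
    band_width_nm: float
    background: float


# ---------------------------------------------------------------------------
# peak detection and linking


def detect_peaks(line: np.ndarray, threshold: float, min_separation: float = 3.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel peak positions (pixels) and heights in one scan line.

    Local maxima above ``threshold`` are refined by 3-point parabolic
    interpolation; peaks closer than ``min_separation`` pixels are merged
    keeping the brighter one.
    """
    y = np.asarray(line, dtype=float)
    if len(y) < 3:
        return np.array([]), np.array([])
    interior = y[1:-1]
    is_max = (interior >= y[:-2]) & (interior >= y[2:]) & (interior > threshold)
    idx = np.flatnonzero(is_max) + 1
    # plateaus: keep only the first pixel of each run of equal maxima
    if len(idx) > 1:
        keep = np.concatenate([[True], np.diff(idx) > 1])
        idx = idx[keep]
    positions, heights = [], []
    for i in idx:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        delta = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        positions.append(i + delta)
        heights.append(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)
    pos = np.asarray(positions)
    hgt = np.asarray(heights)
    # merge close pairs, brighter wins
    changed = True
    while changed and len(pos) > 1:
        changed = False
        gaps = np.diff(pos)
        close = np.flatnonzero(gaps < min_separation)
        if len(close):
            i = close[0]
            drop = i if hgt[i] < hgt[i + 1] else i + 1
            pos = np.delete(pos, drop)
            hgt = np.delete(hgt, drop)
            changed = True
    return pos, hgt


def link_tracks(peaks_per_line: list[tuple[np.ndarray, np.ndarray]],
                max_jump_px: float, min_length: int = 10
                ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Greedy nearest-neighbour frame-to-frame linking (no gap closing).

    Returns tracks as (line_indices, positions_px, intensities); tracks
    shorter than ``min_length`` lines are discarded.
    """
    if max_jump_px <= 0:
        raise ValueError("max_jump must be positive")
    open_tracks: list[dict] = []
    done: list[dict] = []
    for li, (pos, hgt) in enumerate(peaks_per_line):
        pos = np.asarray(pos, dtype=float)
        claimed = np.zeros(len(pos), dtype=bool)
        # candidate links sorted by distance, greedy assignment
        cands = []
        for ti, tr in enumerate(open_tracks):
            d = np.abs(pos - tr["pos"][-1])
            for pi in np.flatnonzero(d <= max_jump_px):
                cands.append((d[pi], ti, pi))
        cands.sort()
        matched_tracks = set()
        for _, ti, pi in cands:
            if ti in matched_tracks or claimed[pi]:
                continue
            tr = open_tracks[ti]
            tr["lines"].append(li)
            tr["pos"].append(pos[pi])
            tr["int"].append(hgt[pi])
            matched_tracks.add(ti)
            claimed[pi] = True
        # close unmatched tracks
        still_open = []
        for ti, tr in enumerate(open_tracks):
            (still_open if ti in matched_tracks else done).append(tr)
        open_tracks = still_open
        # new tracks from unclaimed peaks
        for pi in np.flatnonzero(~claimed):
            open_tracks.append({"lines": [li], "pos": [pos[pi]], "int": [hgt[pi]]})
    done.extend(open_tracks)
    out = []
    for tr in done:
        if len(tr["lines"]) >= min_length:
            out.append(
                (np.asarray(tr["lines"]), np.asarray(tr["pos"]), np.asarray(tr["int"]))
            )
    out.sort(key=lambda t: (t[0][0], t[1][0]))
    return out


def track_kymograph(kymo: KymographImage, threshold: float,
                    min_separation_px: float = 3.0,
                    max_jump_um: float = 0.5,
                    min_length: int = 10) -> list[Trajectory]:
    """Full tracker: peaks per line -> linked tracks in physical units."""
    peaks = [detect_peaks(row, threshold, min_separation_px) for row in kymo.counts]
    px_um = kymo.pixel_size_nm / 1000.0
    tracks = link_tracks(peaks, max_jump_px=max_jump_um / px_um, min_length=min_length)
    out = []
    for lines, pos, inten in tracks:
        out.append(
            Trajectory(
                times=kymo.line_times[lines],
                positions_um=pos * px_um,
                intensities=inten,
            )
        )
    return out


# ---------------------------------------------------------------------------
# MSD and diffusion


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.25,
                clip_s: float = TRAJECTORY_CLIP_S) -> MSDCurve:
    """Time-averaged MSD with overlapping displacement pairs.

    The trajectory is clipped to its first ``clip_s`` seconds; lags run
    from one sample up to ``max_lag_fraction`` of the clipped length.
    """
    keep = traj.times - traj.times[0] <= clip_s + 1e-12
    x = traj.positions_um[keep]
    t = traj.times[keep]
    n = len(x)
    max_lag = int(np.floor(max_lag_fraction * n))
    if max_lag < 3:
        raise ValueError(f"track too short for MSD: {n} samples give {max_lag} lags (<3)")
    dt = np.median(np.diff(t))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=int)
    for j, k in enumerate(lags):
        d = x[k:] - x[:-k]
        msd[j] = np.mean(d * d)
        counts[j] = len(d)
    return MSDCurve(lag_times=lags * dt, msd=msd, pair_counts=counts)


def fit_diffusion(msd: MSDCurve, lag_window: tuple[int, int] = DEFAULT_FIT_LAGS
                  ) -> DiffusionEstimate:
    """OLS fit of MSD = 2*D*t + offset over the lag-index window (inclusive)."""
    lo, hi = lag_window
    sel = slice(max(lo - 1, 0), hi)
    t = msd.lag_times[sel]
    y = msd.msd[sel]
    if len(t) < 3:
        raise ValueError("need at least 3 MSD points in the fit window")
    if np.ptp(t) == 0:
        raise ValueError("degenerate lag window")
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    return DiffusionEstimate(
        D=slope / 2.0,
        offset=intercept,
        lag_window=(lo, min(hi, len(msd.lag_times))),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
    )


def ensemble_D(estimates: list[DiffusionEstimate] | np.ndarray
               ) -> tuple[float, float, int]:
    """Mean, SEM and n of per-trajectory D values (negatives retained)."""
    if len(estimates) and isinstance(estimates[0], DiffusionEstimate):
        d = np.array([e.D for e in estimates])
    else:
        d = np.asarray(estimates, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 estimates for an ensemble mean")
    return float(np.mean(d)), float(np.std(d, ddof=1) / np.sqrt(len(d))), len(d)


def trim_parS_dwell(traj: Trajectory, substrate: SubstrateMap,
                    window_nm: float = IMMOBILE_PARS_WINDOW_NM) -> Trajectory | None:
    """Drop the leading track portion while inside a parS window (+/- window).

    Diffusion is measured on non-specific DNA, so the immobile parS-bound
    prefix of a track (the particle's residence before clamp conversion)
    is removed; the remainder starts at the first sample outside every
    parS window.  Returns None if the track never leaves parS.
    """
    pos_nm = traj.positions_um * 1000.0
    inside = np.zeros(len(traj), dtype=bool)
    for s in substrate.parS_sites:
        lo = s.start * substrate.rise_per_bp - window_nm
        hi = s.end * substrate.rise_per_bp + window_nm
        inside |= (pos_nm >= lo) & (pos_nm <= hi)
    out_idx = np.flatnonzero(~inside)
    if len(out_idx) == 0:
        return None
    i0 = out_idx[0]
    if i0 == 0:
        return traj
    return Trajectory(times=traj.times[i0:], positions_um=traj.positions_um[i0:],
                      intensities=traj.intensities[i0:])


def is_immobile(est: DiffusionEstimate, mean_position_um: float,
                substrate: SubstrateMap,
                d_threshold: float = IMMOBILE_D_THRESHOLD,
                pars_window_nm: float = IMMOBILE_PARS_WINDOW_NM) -> bool:
    """parS-bound classification: slow AND sitting within a parS window."""
    if est.D >= d_threshold:
        return False
    pos_nm = mean_position_um * 1000.0
    for s in substrate.parS_sites:
        lo = s.start * substrate.rise_per_bp - pars_window_nm
        hi = s.end * substrate.rise_per_bp + pars_window_nm
        if lo <= pos_nm <= hi:
            return True
    return False


# ---------------------------------------------------------------------------
# intensity profiles


def extract_profile(image: ScanImage | KymographImage,
                    band_width_nm: float = 500.0) -> IntensityProfile:
    """Axial intensity profile averaged over a transverse band (or over time).

    For a 2D scan the band is centred on the DNA axis row and the
    background is the median of pixels at least 3 sigma off the axis; for
    a kymograph the profile is the time average of all lines and the
    background is taken from the line-wise minimum region (no off-axis
    pixels exist).
    """
    if isinstance(image, ScanImage):
        half = band_width_nm / 2.0
        band = np.abs(image.row_positions) <= half
        if not band.any():
            raise ValueError("band width smaller than one row spacing")
        profile = image.counts[band].mean(axis=0)
        off = np.abs(image.row_positions) >= 3.0 * image.optics.sigma_nm
        background = float(np.median(image.counts[off])) if off.any() else 0.0
    else:
        profile = image.counts.mean(axis=0)
        background = float(np.median(image.counts.min(axis=1)))
    return IntensityProfile(
        positions_um=image.pixel_positions / 1000.0,
        mean_counts=profile.astype(float),
        band_width_nm=band_width_nm,
        background=background,
    )


def quantify_region(profile: IntensityProfile, window_um: tuple[float, float]) -> float:
    """Background-subtracted mean profile intensity over an axial window (um)."""
    lo, hi = window_um
    sel = (profile.positions_um >= lo) & (profile.positions_um <= hi)
    if not sel.any():
        raise ValueError(f"window {window_um} lies outside the imaged field")
    return float(profile.mean_counts[sel].mean() - profile.background)


def fit_bleach_decay(times: np.ndarray, intensities: np.ndarray
                     ) -> tuple[float, float, float]:
    """Least-squares single-exponential fit I(t) = A*exp(-k*t) + floor.

    Returns (rate k in 1/s, amplitude A, floor).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    floor0 = float(np.min(y))
    amp0 = max(float(y[0] - floor0), 1e-9)
    span = max(t[-1] - t[0], 1e-9)
    p0 = (1.0 / span, amp0, floor0)

    def model(t, k, a, c):
        return a * np.exp(-k * t) + c

    popt, _ = curve_fit(model, t, y, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1]), float(popt[2])
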