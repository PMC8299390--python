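"""Magnetic-tweezers mechanics: worm-like chain fitting and condensation metrics.

Force-extension curves of naked DNA in the <= 5 pN range follow the
Marko-Siggia interpolation of the worm-like chain,

    F = (kBT/Lp) * [ 1/(4*(1 - x/Lc)^2) - 1/4 + x/Lc ],

with persistence length Lp and contour length Lc; the enthalpic
stretching correction is negligible at these forces.  Fitted molecules
whose contour length deviates more than +/-15% from the expected
(sequence) length are discarded as mis-tethered.  Pulling forces are
calibrated from the Brownian excursions of the bead via the
inverted-pendulum equipartition relation F = kBT * L / <x^2>.

Condensation is quantified phenomenologically: after the force is
dropped to ~0.33 pN the tether extension decays; the condensed fraction
is the plateau deficit relative to the naked-DNA extension, and the
maximum condensation force is the largest force at which the measured
extension falls short of the WLC prediction by more than a deficit
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "KB_PN_NM_PER_K",
    "kbt",
    "ForceExtensionCurve",
    "WlcFit",
    "CondensationTrace",
    "wlc_force",
    "wlc_extension",
    "fit_wlc",
    "filter_contour",
    "force_from_excursions",
    "condensation_metrics",
    "max_condensation_force",
    "generate_fec",
    "generate_condensing_fec",
    "generate_condensation_trace",
    "simulate_tethered_bead_axis",
]

KB_PN_NM_PER_K = 1.380649e-2  # Boltzmann constant in pN*nm/K
DEFAULT_TEMPERATURE_K = 298.0
CONTOUR_FILTER_TOL = 0.15
DEFAULT_DEFICIT_THRESHOLD = 0.25
DEFAULT_HOLD_FORCE_PN = 0.33


def kbt(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy in pN*nm (4.114 pN*nm at 298 K)."""
    return KB_PN_NM_PER_K * temperature_k


@dataclass
class ForceExtensionCurve:
    """One molecule's force ramp (forces in pN, descending; extensions in um)."""

    forces_pn: np.ndarray
    extensions_um: np.ndarray
    molecule_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.forces_pn = np.asarray(self.forces_pn, dtype=float)
        self.extensions_um = np.asarray(self.extensions_um, dtype=float)
        if np.any(self.forces_pn <= 0):
            raise ValueError("forces must be positive")
        if len(self.forces_pn) != len(self.extensions_um):
            raise ValueError("one extension per force required")


@dataclass
class WlcFit:
    persistence_nm: float
    contour_um: float
    residual_norm: float
    accepted: bool | None = None
    converged: bool = True


@dataclass
class CondensationTrace:
    """Tether extension vs time at a low constant hold force."""

    times: np.ndarray
    extension_um: np.ndarray
    hold_force_pn: float = DEFAULT_HOLD_FORCE_PN

    def __post_init__(self) -> None:
        d = np.diff(self.times)
        if len(d) and not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise ValueError("condensation trace must be uniformly sampled")


# ---------------------------------------------------------------------------
# WLC model


def wlc_force(x_over_lc, persistence_nm: float,
              temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Marko-Siggia force (pN) at relative extension x/Lc in [0, 1)."""
    r = np.asarray(x_over_lc, dtype=float)
    if np.any((r < 0) | (r >= 1)):
        raise ValueError("relative extension must satisfy 0 <= x/Lc < 1")
    if persistence_nm <= 0:
        raise ValueError("persistence length must be positive")
    f = (kbt(temperature_k) / persistence_nm) * (0.25 / (1.0 - r) ** 2 - 0.25 + r)
    return float(f) if f.ndim == 0 else f


def wlc_extension(force_pn, persistence_nm: float, contour_um: float,
                  temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Extension (um) at a given force: numerical inverse of wlc_force."""
    f_arr = np.atleast_1d(np.asarray(force_pn, dtype=float))
    if np.any(f_arr < 0):
        raise ValueError("force must be >= 0")
    out = np.empty_like(f_arr)
    for i, f in enumerate(f_arr):
        if f == 0:
            out[i] = 0.0
            continue
        g = lambda r: wlc_force(r, persistence_nm, temperature_k) - f
        out[i] = brentq(g, 0.0, 1.0 - 1e-12, xtol=1e-15, rtol=1e-12) * contour_um
    return float(out[0]) if np.isscalar(force_pn) or np.ndim(force_pn) == 0 else out


def fit_wlc(curve: ForceExtensionCurve,
            temperature_k: float = DEFAULT_TEMPERATURE_K) -> WlcFit:
    """Least squares on extension residuals over (Lp, Lc), deterministic multi-start.

    Grid starts: Lp in {30, 50, 70} nm, Lc in {0.8, 1.0, 1.2} x max extension.
    """
    sel = curve.forces_pn < 5.0 + 1e-9
    f = curve.forces_pn[sel]
    x = curve.extensions_um[sel]
    if len(f) < 5:
        raise ValueError("need at least 5 points at or below 5 pN")
    max_ext = float(np.max(x))

    def residuals(p):
        lp, lc = p
        return wlc_extension(f, lp, lc, temperature_k) - x

    best = None
    for lp0 in (30.0, 50.0, 70.0):
        for s in (0.8, 1.0, 1.2):
            lc0 = max(s * max_ext, 1e-3)
            try:
                res = least_squares(
                    residuals, x0=[lp0, lc0],
                    bounds=([1.0, max(max_ext, 1e-3)], [500.0, 10.0 * max_ext + 1.0]),
                    xtol=1e-12, ftol=1e-12,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise RuntimeError("WLC fit failed from every grid start")
    return WlcFit(
        persistence_nm=float(best.x[0]),
        contour_um=float(best.x[1]),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
    )


def filter_contour(fit: WlcFit, expected_contour_um: float,
                   tol: float = CONTOUR_FILTER_TOL) -> bool:
    """Quality filter: accept iff |Lc - expected| / expected <= tol (inclusive)."""
    if expected_contour_um <= 0:
        raise ValueError("expected contour length must be positive")
    ratio = abs(fit.contour_um - expected_contour_um) / expected_contour_um
    # inclusive boundary, robust to float rounding at exactly +/-tol
    accepted = ratio <= tol or bool(np.isclose(ratio, tol, rtol=1e-9, atol=1e-12))
    fit.accepted = bool(accepted)
    return fit.accepted


def force_from_excursions(mean_sq_excursion_nm2: float, extension_nm: float,
                          temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Equipartition force calibration: F = kBT * L / <x^2> (pendulum geometry)."""
    if mean_sq_excursion_nm2 <= 0:
        raise ValueError("mean squared excursion must be positive")
    if extension_nm <= 0:
        raise ValueError("extension must be positive")
    return kbt(temperature_k) * extension_nm / mean_sq_excursion_nm2


# ---------------------------------------------------------------------------
# condensation metrics


@dataclass
class CondensationMetrics:
    condensed_fraction: float
    initial_rate_nm_s: float
    condensed: bool


def condensation_metrics(trace: CondensationTrace, naked_extension_um: float,
                         deficit_threshold: float = DEFAULT_DEFICIT_THRESHOLD,
                         hold_s: float = 30.0,
                         rate_window_s: float = 30.0) -> CondensationMetrics:
    """Condensed fraction, initial condensation rate, and verdict for a time course.

    Condensed fraction = 1 - plateau/naked (plateau: median of the last 10%
    of the trace).  Initial rate = minus the least-squares extension slope
    over the first ``rate_window_s``.  Verdict: condensed if the extension
    deficit exceeds ``deficit_threshold`` continuously for >= ``hold_s``.
    """
    t = trace.times
    if t[-1] - t[0] < 60.0:
        raise ValueError("condensation trace must span at least 60 s")
    ext = trace.extension_um
    n_tail = max(int(0.1 * len(ext)), 1)
    plateau = float(np.median(ext[-n_tail:]))
    fraction = 1.0 - plateau / naked_extension_um

    early = t - t[0] <= rate_window_s
    slope = np.polyfit(t[early], ext[early], 1)[0]  # um/s
    initial_rate = -slope * 1000.0

    deficit = 1.0 - ext / naked_extension_um
    above = deficit > deficit_threshold
    condensed = False
    start = None
    for i, b in enumerate(above):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if t[i - 1] - t[start] >= hold_s:
                condensed = True
                break
            start = None
    if start is not None and t[-1] - t[start] >= hold_s:
        condensed = True
    return CondensationMetrics(
        condensed_fraction=float(fraction),
        initial_rate_nm_s=float(initial_rate),
        condensed=condensed,
    )


def max_condensation_force(curve: ForceExtensionCurve, reference: WlcFit,
                           deficit_threshold: float = DEFAULT_DEFICIT_THRESHOLD,
                           temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Largest force at which the extension falls short of the naked-DNA WLC.

    A force qualifies when measured extension < (1 - threshold) * WLC
    prediction from the reference fit; 0 when no force qualifies.
    """
    if len(curve.forces_pn) < 3:
        raise ValueError("need at least 3 sampled forces")
    pred = wlc_extension(curve.forces_pn, reference.persistence_nm,
                         reference.contour_um, temperature_k)
    short = curve.extensions_um < (1.0 - deficit_threshold) * pred
    if not np.any(short):
        return 0.0
    return float(np.max(curve.forces_pn[short]))


# ---------------------------------------------------------------------------
# synthetic generators


def default_force_grid(n: int = 25) -> np.ndarray:
    """Descending force ramp 5 -> 0.01 pN (log-spaced), as acquired."""
    return np.geomspace(5.0, 0.01, n)


def generate_fec(persistence_nm: float = 50.0, contour_um: float = 2.0,
                 forces_pn: np.ndarray | None = None,
                 noise_fraction: float = 0.0, seed: int = 0,
                 temperature_k: float = DEFAULT_TEMPERATURE_K,
                 molecule_id: str = "", condition: str = "no ParB"
                 ) -> ForceExtensionCurve:
    """Naked-DNA WLC curve with optional multiplicative extension noise."""
    f = default_force_grid() if forces_pn is None else np.asarray(forces_pn, dtype=float)
    ext = wlc_extension(f, persistence_nm, contour_um, temperature_k)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        ext = ext * (1.0 + noise_fraction * rng.normal(size=len(f)))
    return ForceExtensionCurve(forces_pn=f, extensions_um=np.asarray(ext),
                               molecule_id=molecule_id, condition=condition)


def generate_condensing_fec(persistence_nm: float = 50.0, contour_um: float = 2.0,
                            condensation_force_pn: float = 1.0,
                            deficit: float = 0.5,
                            forces_pn: np.ndarray | None = None,
                            noise_fraction: float = 0.0, seed: int = 0,
                            temperature_k: float = DEFAULT_TEMPERATURE_K
                            ) -> ForceExtensionCurve:
    """Protein curve: WLC above the condensation force, shortened below it."""
    f = default_force_grid() if forces_pn is None else np.asarray(forces_pn, dtype=float)
    ext = np.asarray(wlc_extension(f, persistence_nm, contour_um, temperature_k))
    ext = np.where(f < condensation_force_pn, ext * (1.0 - deficit), ext)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        ext = ext * (1.0 + noise_fraction * rng.normal(size=len(f)))
    return ForceExtensionCurve(forces_pn=f, extensions_um=ext, condition="ParB")


def generate_condensation_trace(naked_extension_um: float,
                                condensing: bool = True,
                                plateau_fraction: float = 0.3,
                                decay_s: float = 20.0,
                                duration_s: float = 300.0,
                                sample_hz: float = 10.0,
                                noise_um: float = 0.01,
                                hold_force_pn: float = DEFAULT_HOLD_FORCE_PN,
                                seed: int = 0) -> CondensationTrace:
    """Exponential extension-decay time course (or a flat naked-DNA control)."""
    n = int(round(duration_s * sample_hz))
    t = np.arange(n) / sample_hz
    if condensing:
        plateau = plateau_fraction * naked_extension_um
        ext = plateau + (naked_extension_um - plateau) * np.exp(-t / decay_s)
    else:
        ext = np.full(n, naked_extension_um)
    rng = np.random.default_rng(seed)
    ext = ext + noise_um * rng.normal(size=n)
    return CondensationTrace(times=t, extension_um=ext, hold_force_pn=hold_force_pn)


def simulate_tethered_bead_axis(force_pn: float, extension_nm: float,
                                duration_s: float = 300.0,
                                rate_hz: float = 120.0,
                                correlation_time_s: float = 0.1,
                                temperature_k: float = DEFAULT_TEMPERATURE_K,
                                seed: int = 0) -> np.ndarray:
    """In-plane bead fluctuations (nm) at equipartition variance kBT*L/F (OU)."""
    if force_pn <= 0 or extension_nm <= 0:
        raise ValueError("force and extension must be positive")
    sigma = np.sqrt(kbt(temperature_k) * extension_nm / force_pn)
    n = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    rho = np.exp(-dt / correlation_time_s)
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=n)
    out = np.empty(n)
    out[0] = noise[0]
    scale = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + scale * noise[i]
    return sigma * out
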