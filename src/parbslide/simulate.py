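"""Stochastic simulation of the ParB sliding-clamp mechanism.

The model is the three-step loading/sliding scheme: (1) apo ParB binds a
vacant *parS* site and stays there as an immobile open clamp; (2) CTP
binding converts it into a closed sliding clamp that leaves *parS* and
diffuses one-dimensionally along non-specific DNA with diffusion
constant ``D``; (3) clamps are reflected by bound protein roadblocks
(and, by default, by the bead-occluded DNA ends), may unbind from
non-specific DNA, and photobleach once the illumination starts.

Nucleotide conditions and protein variants map onto rates via
:func:`condition_preset`: the parS-binding mutant R149G cannot load
(``load_rate = 0``); apo, CDP, EDTA and the CTP-binding mutant R80A
cannot close the clamp (``convert_rate = 0``); CTP and the
non-hydrolysable CTPgammaS behave identically because hydrolysis is not
required for sliding.

Dynamics are fixed-timestep Brownian dynamics: sliding clamps take
Gaussian steps of variance 2*D*dt and discrete state transitions fire
with per-step probability 1 - exp(-rate*dt).  Identical (config,
substrate) input reproduces bit-identical trajectories.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .substrate import SubstrateMap, bp_to_nm

__all__ = [
    "SimConfig",
    "ParticleRecord",
    "TrajectorySet",
    "condition_preset",
    "simulate",
    "occupancy_profile",
    "CONDITIONS",
    "VARIANTS",
]

CONDITIONS = ("apo", "CTP", "CTPgammaS", "CDP", "EDTA")
VARIANTS = ("WT", "R80A", "R149G")

# particle states
PARS_BOUND = "parS_bound"
CLAMP = "clamp"
BLEACHED = "bleached"
DETACHED = "detached"


@dataclass(frozen=True)
class SimConfig:
    """Rates and integration settings for one simulation run.

    Absolute loading / unbinding / bleaching rates are free parameters of
    the model (no measured values exist for them); the defaults are
    order-of-magnitude choices documented in docs/methods.md.  ``D`` is
    the 1D diffusion constant of the closed clamp in um^2/s.
    """

    condition: str = "CTP"
    variant: str = "WT"
    load_rate: float = 0.2        # events/s per vacant parS site
    convert_rate: float = 0.5     # open clamp -> sliding clamp, 1/s
    D: float = 0.4                # um^2/s
    unbind_rate: float = 0.02     # sliding clamp leaves nsDNA, 1/s
    parS_unbind_rate: float = 0.01  # open clamp leaves parS, 1/s
    bleach_rate: float = 0.1      # under illumination, 1/s
    illumination_start: float = 0.0  # s
    dt: float = 0.005             # s
    duration: float = 30.0        # s
    seed: int = 0
    roadblocks_active: bool = False
    end_behavior: str = "reflect"  # "reflect" | "absorb"
    unload_rate: float = 0.0      # extra CTP-hydrolysis unloading, CTP only

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.end_behavior not in ("reflect", "absorb"):
            raise ValueError("end_behavior must be 'reflect' or 'absorb'")
        for name in ("load_rate", "convert_rate", "D", "unbind_rate",
                     "parS_unbind_rate", "bleach_rate", "unload_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")

    def validate_for(self, substrate: SubstrateMap) -> None:
        """Enforce the step-size bound: rms step <= 5% of contour length."""
        step_um = np.sqrt(2.0 * self.D * self.dt)
        contour_um = substrate.contour_length_nm / 1000.0
        if step_um > 0.05 * contour_um:
            raise ValueError(
                f"dt={self.dt} too coarse: rms step {step_um:.3g} um exceeds "
                f"5% of the {contour_um:.3g} um contour; reduce dt"
            )


def condition_preset(condition: str, variant: str = "WT", **overrides) -> SimConfig:
    """Map a nucleotide condition and protein variant onto simulation rates.

    R149G cannot bind parS at all; apo/CDP/EDTA give no clamp conversion,
    as does the CTP-binding mutant R80A; CTP and CTPgammaS are identical
    because clamp closure needs CTP binding, not hydrolysis.
    """
    cfg = SimConfig(condition=condition, variant=variant)
    if variant == "R149G":
        cfg = replace(cfg, load_rate=0.0)
    if condition in ("apo", "CDP", "EDTA") or variant == "R80A":
        cfg = replace(cfg, convert_rate=0.0)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


@dataclass
class ParticleRecord:
    """Per-step history of one ParB dimer (positions in bp, NaN when absent)."""

    id: int
    birth_time: float
    positions: np.ndarray  # float bp, aligned with TrajectorySet.times
    states: np.ndarray     # object array of state strings ('' before birth)

    def alive_mask(self) -> np.ndarray:
        return np.isin(self.states, (PARS_BOUND, CLAMP, BLEACHED))

    def emitting_mask(self) -> np.ndarray:
        return np.isin(self.states, (PARS_BOUND, CLAMP))


@dataclass
class TrajectorySet:
    """Ground-truth ensemble from one simulation on one substrate."""

    substrate: SubstrateMap
    config: SimConfig
    particles: list[ParticleRecord]
    times: np.ndarray

    def emitter_positions_bp(self, t: float) -> np.ndarray:
        """Positions (bp) of unbleached bound particles at the sample nearest t."""
        i = int(np.clip(np.searchsorted(self.times, t), 0, len(self.times) - 1))
        out = [p.positions[i] for p in self.particles if p.emitting_mask()[i]]
        return np.asarray(out, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (particle_id, time_s, position_bp, state)."""
        rows = []
        for p in self.particles:
            mask = p.states != ""
            rows.append(
                pd.DataFrame(
                    {
                        "particle_id": p.id,
                        "time_s": self.times[mask],
                        "position_bp": p.positions[mask],
                        "state": p.states[mask],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=["particle_id", "time_s", "position_bp", "state"])
        return pd.concat(rows, ignore_index=True)

    def config_json(self) -> str:
        meta = asdict(self.config)
        meta["substrate"] = self.substrate.name
        return json.dumps(meta, indent=2, sort_keys=True)


def _segments(substrate: SubstrateMap, roadblocks_active: bool) -> np.ndarray:
    """Diffusion segments [lo, hi] in bp delimited by active roadblocks and ends."""
    bounds = [0.0]
    if roadblocks_active:
        for rb in substrate.roadblocks:
            bounds.extend([float(rb.start), float(rb.end)])
    bounds.append(float(substrate.length))
    b = np.asarray(bounds)
    return b.reshape(-1, 2)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] (specular reflection)."""
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def simulate(config: SimConfig, substrate: SubstrateMap) -> TrajectorySet:
    """Run the clamp-loading / sliding simulation on one substrate.

    Loading occurs only at vacant parS sites (one resident open clamp per
    site); parS-bound particles are immobile; sliding clamps take Gaussian
    steps of variance 2*D*dt in contour coordinates and are reflected by
    roadblock footprints and (by default) by the DNA ends; bleaching only
    after ``illumination_start``.  Fully reproducible from (config,
    substrate).
    """
    config.validate_for(substrate)
    rng = np.random.default_rng(config.seed)

    n_steps = int(round(config.duration / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    rise = substrate.rise_per_bp
    step_sd_bp = np.sqrt(2.0 * config.D * config.dt) * 1000.0 / rise
    segs = _segments(substrate, config.roadblocks_active)
    seg_starts = segs[:, 0]

    pars = substrate.parS_sites
    site_centers = np.array([s.center for s in pars])
    site_occupant: list[int | None] = [None] * len(pars)

    p_load = 1.0 - np.exp(-config.load_rate * config.dt)
    p_convert = 1.0 - np.exp(-config.convert_rate * config.dt)
    p_pars_off = 1.0 - np.exp(-config.parS_unbind_rate * config.dt)
    off_rate = config.unbind_rate + (config.unload_rate if config.condition == "CTP" else 0.0)
    p_unbind = 1.0 - np.exp(-off_rate * config.dt)
    p_bleach = 1.0 - np.exp(-config.bleach_rate * config.dt)

    particles: list[ParticleRecord] = []
    # live bookkeeping: index into particles of active (non-detached) ones
    live: list[int] = []
    pos: dict[int, float] = {}
    motion: dict[int, str] = {}   # PARS_BOUND | CLAMP
    bleached: dict[int, bool] = {}
    site_of: dict[int, int] = {}

    def record(step: int) -> None:
        for idx in live:
            p = particles[idx]
            p.positions[step] = pos[idx]
            p.states[step] = BLEACHED if bleached[idx] else motion[idx]

    record(0)
    for step in range(1, n_steps + 1):
        t = times[step]
        # 1. loading at vacant parS sites
        if p_load > 0 and len(pars):
            u = rng.random(len(pars))
            for si in range(len(pars)):
                if site_occupant[si] is None and u[si] < p_load:
                    idx = len(particles)
                    particles.append(
                        ParticleRecord(
                            id=idx,
                            birth_time=t,
                            positions=np.full(n_steps + 1, np.nan),
                            states=np.full(n_steps + 1, "", dtype=object),
                        )
                    )
                    live.append(idx)
                    pos[idx] = float(site_centers[si])
                    motion[idx] = PARS_BOUND
                    bleached[idx] = False
                    site_of[idx] = si
                    site_occupant[si] = idx

        detached_now: list[int] = []
        for idx in live:
            if motion[idx] == PARS_BOUND:
                # 2. conversion to sliding clamp, else possible parS unbinding
                if rng.random() < p_convert:
                    motion[idx] = CLAMP
                    site_occupant[site_of.pop(idx)] = None
                elif rng.random() < p_pars_off:
                    site_occupant[site_of.pop(idx)] = None
                    detached_now.append(idx)
                    continue
            else:
                # 3. Brownian step with reflection inside the current segment
                x = pos[idx] + rng.normal(0.0, step_sd_bp)
                seg_i = int(np.searchsorted(seg_starts, pos[idx], side="right") - 1)
                lo, hi = segs[seg_i]
                at_left_end = lo == 0.0
                at_right_end = hi == float(substrate.length)
                if config.end_behavior == "absorb" and (
                    (x < lo and at_left_end) or (x > hi and at_right_end)
                ):
                    detached_now.append(idx)
                    continue
                pos[idx] = _reflect(x, lo, hi)
                # 4. unbinding from nsDNA
                if p_unbind > 0 and rng.random() < p_unbind:
                    detached_now.append(idx)
                    continue
            # 5. photobleaching under illumination
            if (
                not bleached[idx]
                and p_bleach > 0
                and t >= config.illumination_start
                and rng.random() < p_bleach
            ):
                bleached[idx] = True

        for idx in detached_now:
            particles[idx].states[step] = DETACHED
            particles[idx].positions[step] = pos[idx]
            live.remove(idx)
            pos.pop(idx), motion.pop(idx), bleached.pop(idx)
        record(step)

    return TrajectorySet(substrate=substrate, config=config, particles=particles, times=times)


def occupancy_profile(ts: TrajectorySet, bin_bp: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged bound-particle density along the substrate.

    Returns ``(bin_edges_bp, occupancy_per_bp)``; the profile integrates to
    the mean number of DNA-bound particles:
    ``sum(occupancy) * bin_bp == mean particle count``.
    """
    if bin_bp < 1:
        raise ValueError("bin width must be >= 1 bp")
    edges = np.arange(0, ts.substrate.length + bin_bp, bin_bp, dtype=float)
    counts = np.zeros(len(edges) - 1)
    n_times = len(ts.times)
    for p in ts.particles:
        mask = p.alive_mask()
        if mask.any():
            counts += np.histogram(p.positions[mask], bins=edges)[0]
    return edges, counts / (n_times * bin_bp)
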