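"""End-to-end experiment archetypes binding simulation, rendering and analysis.

Three archetypes mirror the three instrument setups:

* ``ctrap`` -- simulate clamp loading/sliding on a long substrate, render
  kymographs, track particles, and report the ensemble diffusion constant
  (mean +/- SEM over per-trajectory MSD fits).
* ``mt``   -- magnetic-tweezers condensation time courses at a low hold
  force, analysed for condensed fraction and verdicts.
* ``tpm``  -- tethered-bead traces analysed with the drift-suppressed
  windowed RMS and a sustained-drop condensation detector.

All randomness flows from one root seed through per-stage derived
streams, so an identical configuration reproduces an identical bundle.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .imaging import OpticsConfig, render_kymograph
from .kymo import (
    Trajectory,
    compute_msd,
    ensemble_D,
    fit_diffusion,
    is_immobile,
    track_kymograph,
    trim_parS_dwell,
)
from .simulate import condition_preset, simulate
from .substrate import SUBSTRATE_NAMES, build_substrate, make_tandem
from .tpm import DEFAULT_TAU_S, detect_condensation, mean_rms_tau, rms_windowed, simulate_bead_trace
from .wlc import (
    condensation_metrics,
    generate_condensation_trace,
    wlc_extension,
)

__all__ = ["RunConfig", "run_pipeline", "derive_seeds", "diffusion_recovery_experiment"]

log = logging.getLogger("parbslide")

ARCHETYPES = ("ctrap", "mt", "tpm")
# condensation in the tweezers requires enough parS loading sites against the
# residual pulling force; at zero force (TPM) a single site suffices
MIN_PARS_FOR_MT_CONDENSATION = 5


def derive_seeds(root_seed: int, n: int) -> list[int]:
    """Independent per-stage seeds derived from one root seed (each < 2**31)."""
    state = np.random.SeedSequence(root_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class RunConfig:
    """One experiment run: archetype, substrate, condition and overrides."""

    archetype: str
    substrate: str = "39x_parS"
    condition: str = "CTP"
    variant: str = "WT"
    seed: int = 0
    outdir: str = "."
    n_molecules: int = 10
    sim: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"archetype must be one of {ARCHETYPES}")
        if self.substrate not in SUBSTRATE_NAMES:
            raise ValueError(f"unknown substrate {self.substrate!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _log_effective(cfg, user_keys) -> None:
    """Audit every default the user did not set explicitly."""
    for f in dataclasses.fields(cfg):
        if f.name not in user_keys:
            log.info("default %s.%s = %r", type(cfg).__name__, f.name, getattr(cfg, f.name))


def _ctrap(config: RunConfig, outdir: Path) -> dict:
    substrate = build_substrate(config.substrate)
    optics = OpticsConfig(**config.optics)
    _log_effective(optics, config.optics)
    threshold = config.analysis.get("threshold", 5.0)
    min_length = config.analysis.get("min_length", 40)
    seeds = derive_seeds(config.seed, 2 * config.n_molecules)
    estimates = []
    n_immobile = 0
    for m in range(config.n_molecules):
        sim_cfg = condition_preset(config.condition, config.variant,
                                   seed=seeds[2 * m], **config.sim)
        if m == 0:
            _log_effective(sim_cfg, set(config.sim) | {"condition", "variant", "seed"})
        ts = simulate(sim_cfg, substrate)
        kymo = render_kymograph(ts, optics, seed=seeds[2 * m + 1])
        pio.write_kymograph_ascii(outdir / f"kymograph_{m:03d}.txt", kymo)
        pio.write_trajectories_tsv(outdir / f"trajectories_{m:03d}.tsv", ts)
        for tr in track_kymograph(kymo, threshold=threshold, min_length=min_length):
            try:
                est = fit_diffusion(compute_msd(tr))
            except ValueError:
                continue
            if is_immobile(est, float(np.mean(tr.positions_um)), substrate):
                n_immobile += 1
                continue
            estimates.append(est)
    summary: dict = {
        "n_tracks": len(estimates),
        "n_immobile_tracks": n_immobile,
        "n_molecules": config.n_molecules,
    }
    if len(estimates) >= 2:
        mean, sem, n = ensemble_D(estimates)
        summary.update({"D_um2_s": mean, "D_sem": sem, "n": n})
    return summary


def _mt(config: RunConfig, outdir: Path) -> dict:
    substrate = build_substrate(config.substrate)
    preset = condition_preset(config.condition, config.variant)
    n_pars = len(substrate.parS_sites)
    condensing = (
        preset.load_rate > 0
        and preset.convert_rate > 0
        and n_pars >= MIN_PARS_FOR_MT_CONDENSATION
    )
    contour_um = substrate.contour_length_nm / 1000.0
    lp = config.analysis.get("persistence_nm", 50.0)
    hold = config.analysis.get("hold_force_pn", 0.33)
    naked = float(wlc_extension(hold, lp, contour_um))
    seeds = derive_seeds(config.seed, config.n_molecules)
    verdicts = []
    fractions = []
    for m in range(config.n_molecules):
        trace = generate_condensation_trace(
            naked_extension_um=naked, condensing=condensing,
            hold_force_pn=hold, seed=seeds[m],
        )
        pio.write_json(outdir / f"mt_trace_{m:03d}.json",
                       {"condensing": condensing, "seed": seeds[m]})
        metrics = condensation_metrics(trace, naked_extension_um=naked)
        verdicts.append(metrics.condensed)
        fractions.append(metrics.condensed_fraction)
    return {
        "n_molecules": config.n_molecules,
        "n_condensed": int(np.sum(verdicts)),
        "mean_condensed_fraction": float(np.mean(fractions)),
        "naked_extension_um": naked,
    }


def _tpm(config: RunConfig, outdir: Path) -> dict:
    substrate = build_substrate(config.substrate)
    preset = condition_preset(config.condition, config.variant)
    condensing = (
        preset.load_rate > 0 and preset.convert_rate > 0 and len(substrate.parS_sites) >= 1
    )
    tau = config.analysis.get("tau_s", DEFAULT_TAU_S)
    step_time = config.analysis.get("step_time_s", 100.0)
    seeds = derive_seeds(config.seed, config.n_molecules)
    verdicts = []
    rms_values = []
    for m in range(config.n_molecules):
        trace = simulate_bead_trace(
            tether_bp=substrate.length,
            step_time=step_time if condensing else None,
            seed=seeds[m],
        )
        pio.write_bead_trace_tsv(outdir / f"tpm_trace_{m:03d}.tsv", trace)
        series = rms_windowed(trace, tau=tau)
        verdicts.append(detect_condensation(series).condensed)
        rms_values.append(mean_rms_tau(series))
    return {
        "n_molecules": config.n_molecules,
        "n_condensed": int(np.sum(verdicts)),
        "mean_rms_tau_nm": float(np.mean(rms_values)),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute one archetype end to end; returns and persists the summary JSON."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = {"ctrap": _ctrap, "mt": _mt, "tpm": _tpm}[config.archetype]
    try:
        summary = stage(config, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {config.archetype!r} failed: {exc}") from exc
    summary.update(
        {
            "archetype": config.archetype,
            "substrate": config.substrate,
            "condition": config.condition,
            "variant": config.variant,
            "seed": config.seed,
        }
    )
    pio.write_json(outdir / "summary.json", summary)
    return summary


# ---------------------------------------------------------------------------
# parameter-recovery experiment (simulate -> render -> track -> MSD -> fit)


def diffusion_recovery_experiment(
    d_true: float,
    min_tracks: int = 300,
    seed: int = 0,
    substrate_name: str = "2x_parS",
    max_molecules: int = 6000,
    duration_s: float = 3.0,
    threshold: float = 5.0,
    min_length: int = 40,
) -> dict:
    """Recover a known diffusion constant through the full imaging pipeline.

    Simulates clamp loading and sliding at ground-truth ``d_true`` on many
    tandem (double-length) molecules, renders a kymograph per molecule,
    tracks the particles, trims each track to its non-parS portion, fits
    per-trajectory MSDs, and pools mobile tracks until at least
    ``min_tracks`` estimates are collected.  Returns the ensemble mean,
    SEM, track count and the ground truth.

    Design choices of the validation ensemble: labelled particles are
    sparse (low loading rate, as in quantum-dot labelling); DNA ends
    absorb rather than reflect, so the estimator is validated against
    unconfined diffusion (reflecting bead-occluded ends suppress the MSD
    of tracks dwelling near an end); the linking radius scales with the
    expected per-line step so large steps are not censored; low and
    negative per-track estimates are retained (dropping them biases the
    ensemble mean upward).
    """
    substrate = make_tandem(build_substrate(substrate_name))
    optics = OpticsConfig()
    max_jump_um = max(0.5, 4.5 * np.sqrt(2.0 * d_true * optics.line_period_s))
    seeds = derive_seeds(seed, 2 * max_molecules)
    estimates = []
    molecules = 0
    while len(estimates) < min_tracks and molecules < max_molecules:
        cfg = condition_preset(
            "CTP", "WT",
            D=d_true, load_rate=0.02, convert_rate=2.0,
            unbind_rate=0.0, parS_unbind_rate=0.0, bleach_rate=0.0,
            duration=duration_s, dt=0.005, seed=seeds[2 * molecules],
            end_behavior="absorb",
        )
        ts = simulate(cfg, substrate)
        kymo = render_kymograph(ts, optics, seed=seeds[2 * molecules + 1])
        for tr in track_kymograph(kymo, threshold=threshold, min_length=min_length,
                                  max_jump_um=max_jump_um, min_separation_px=2.0):
            tr = trim_parS_dwell(tr, substrate)
            if tr is None or len(tr) < min_length:
                continue
            try:
                est = fit_diffusion(compute_msd(tr))
            except ValueError:
                continue
            estimates.append(est)
        molecules += 1
    if len(estimates) < 2:
        raise RuntimeError("recovered fewer than 2 mobile tracks")
    mean, sem, n = ensemble_D(estimates)
    return {
        "D_true": d_true,
        "D_mean": mean,
        "D_sem": sem,
        "n_tracks": n,
        "n_molecules": molecules,
    }
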