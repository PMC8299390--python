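"""Readers and writers for the package's plain-text and TIFF artifact formats.

Kymographs and scans round-trip losslessly as ASCII count matrices (the
instrument-export format) and as 16-bit unsigned TIFF; trajectories and
bead traces round-trip as tab-separated tables with JSON sidecars for
the generating configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import KymographImage, OpticsConfig
from .simulate import TrajectorySet
from .tpm import BeadTrace
from .wlc import ForceExtensionCurve

__all__ = [
    "write_ascii_matrix",
    "read_ascii_matrix",
    "write_kymograph_ascii",
    "read_kymograph_ascii",
    "write_tiff",
    "read_tiff",
    "write_trajectories_tsv",
    "read_trajectories_tsv",
    "write_bead_trace_tsv",
    "read_bead_trace_tsv",
    "write_fec_tsv",
    "read_fec_tsv",
    "write_json",
    "read_json",
]


def write_ascii_matrix(path: str | Path, counts: np.ndarray,
                       metadata: dict | None = None) -> None:
    """Integer count matrix as whitespace-separated text with '#key=value' header."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        np.savetxt(fh, np.asarray(counts, dtype=np.int64), fmt="%d")


def read_ascii_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[int]] = []
    width = None
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            body = ln.lstrip("# ")
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: malformed header field {body!r}")
            k, v = body.split("=", 1)
            meta[k] = v
            continue
        try:
            row = [int(tok) for tok in ln.split()]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer matrix entry ({exc})") from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(
                f"{path}:{lineno}: expected {width} columns, got {len(row)}"
            )
        rows.append(row)
    return np.asarray(rows, dtype=np.int64), meta


def write_kymograph_ascii(path: str | Path, kymo: KymographImage) -> None:
    write_ascii_matrix(
        path,
        kymo.counts,
        metadata={
            "line_period_s": kymo.optics.line_period_s,
            "pixel_size_nm": kymo.optics.pixel_size_nm,
            "pixel_dwell_s": kymo.optics.pixel_dwell_s,
            "psf_fwhm_nm": kymo.optics.psf_fwhm_nm,
            "photon_rate": kymo.optics.photon_rate,
            "background_rate": kymo.optics.background_rate,
        },
    )


def read_kymograph_ascii(path: str | Path) -> KymographImage:
    counts, meta = read_ascii_matrix(path)
    optics = OpticsConfig(
        pixel_size_nm=float(meta["pixel_size_nm"]),
        psf_fwhm_nm=float(meta["psf_fwhm_nm"]),
        photon_rate=float(meta["photon_rate"]),
        background_rate=float(meta["background_rate"]),
        line_period_s=float(meta["line_period_s"]),
        pixel_dwell_s=float(meta["pixel_dwell_s"]),
    )
    n_lines, n_px = counts.shape
    return KymographImage(
        counts=counts.astype(np.uint16),
        line_times=np.arange(n_lines) * optics.line_period_s,
        pixel_positions=np.arange(n_px) * optics.pixel_size_nm,
        optics=optics,
    )


def write_tiff(path: str | Path, frames: np.ndarray) -> None:
    """Single- or multi-frame 16-bit unsigned TIFF."""
    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.uint16))


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_trajectories_tsv(path: str | Path, ts: TrajectorySet) -> None:
    """Tidy TSV (particle_id, time_s, position_bp, state) + JSON config sidecar."""
    path = Path(path)
    ts.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
    path.with_suffix(path.suffix + ".json").write_text(ts.config_json())


def read_trajectories_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bead_trace_tsv(path: str | Path, trace: BeadTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "x_nm": trace.x, "y_nm": trace.y}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_bead_trace_tsv(path: str | Path) -> BeadTrace:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return BeadTrace(times=df["time_s"].to_numpy(), x=df["x_nm"].to_numpy(),
                     y=df["y_nm"].to_numpy())


def write_fec_tsv(path: str | Path, curve: ForceExtensionCurve) -> None:
    pd.DataFrame(
        {"force_pN": curve.forces_pn, "extension_um": curve.extensions_um}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_fec_tsv(path: str | Path) -> ForceExtensionCurve:
    df = pd.read_csv(path, sep="\t")
    for col in ("force_pN", "extension_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return ForceExtensionCurve(
        forces_pn=df["force_pN"].to_numpy(), extensions_um=df["extension_um"].to_numpy()
    )


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
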