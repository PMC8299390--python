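"""DNA substrate coordinate maps for ParB/parS single-molecule experiments.

A :class:`SubstrateMap` is a 0-based, half-open coordinate map (in base
pairs) of the features on one DNA molecule: 16 bp palindromic *parS*
loading sites and merged EcoRI roadblock footprints, plus the total
length.  The named constructs assembled by :func:`build_substrate`
reproduce every printed inter-feature distance of the corresponding
experimental DNA (inter-cluster gap, parS-to-roadblock gap, ...);
spacings that were never printed (within-group parS repeat spacing,
exact EcoRI coordinates) are configurable defaults.

Conversions between base pairs and nanometres assume B-form DNA with a
rise of 0.34 nm per base pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "FeatureSite",
    "SubstrateMap",
    "SUBSTRATE_NAMES",
    "build_substrate",
    "feature_distance",
    "make_tandem",
    "bp_to_nm",
    "nm_to_bp",
    "RISE_NM_PER_BP",
    "PARS_FOOTPRINT_BP",
]

RISE_NM_PER_BP = 0.34
PARS_FOOTPRINT_BP = 16  # length of the parS palindrome

# Spacings below are not printed anywhere for the real constructs; they are
# package defaults chosen once (see docs/methods.md), not measured values.
DEFAULT_PARS_SPACING_BP = 50   # start-to-start spacing of parS repeats in a group
DEFAULT_GROUP_GAP_BP = 200     # gap between adjacent groups inside one cluster
ECORI_GROUP_FOOTPRINT_BP = 60  # merged footprint of one 5x EcoRI group
DEFAULT_ROADBLOCK_GAP_BP = 500  # upstream EcoRI group to first parS

LAMBDA_LENGTH_BP = 48502  # full phage lambda genome, the parS-free control

# Flank lengths of the long optical-tweezers constructs (lambda-derived
# PCR fragments C1/C2 of the cloning scheme).
_CTRAP_LEFT_FLANK_BP = 9035   # lambda 5475-14509
_CTRAP_RIGHT_FLANK_BP = 5011  # lambda 33464-38474
_CTRAP_ECORI_LEFT_OUTER_BP = 1255  # shortened lambda 13254-14509 fragment
INTERCLUSTER_GAP_BP = 1905     # printed gap between the two 39x parS clusters
PARS_TO_ECORI_GAP_BP = 3613    # printed gap, last parS to downstream EcoRI group

# Magnetic-tweezers substrates: ~6 kbp central fragment + two ~1 kbp handles.
_MT_TOTAL_BP = 8000
_MT_HANDLE_BP = 1000

# parS group sizes per construct, grouped by cluster.  The 39x construct has
# 39 sites in six groups forming two clusters, the smaller with two groups.
_CLUSTER_PLANS: dict[str, tuple[tuple[int, ...], ...]] = {
    "39x": ((6, 7), (7, 6, 7, 6)),
    "26x": ((7, 6, 7, 6),),
    "13x": ((6, 7),),
    "7x": ((7,),),
    "4x": ((4,),),
    "2x": ((2,),),
    "1x": ((1,),),
}

SUBSTRATE_NAMES = (
    "39x_parS",
    "ecoRI_39x_parS",
    "ecoRI_7x_parS",
    "2x_parS",
    "26x",
    "13x",
    "7x",
    "4x",
    "1x",
    "scrambled",
    "lambda_control",
    "tpm_1717",
)


@dataclass(frozen=True)
class FeatureSite:
    """One feature on the substrate: a parS palindrome or a roadblock footprint."""

    kind: str  # "parS" | "roadblock"
    start: int  # bp, 0-based inclusive
    end: int    # bp, exclusive
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("parS", "roadblock"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class SubstrateMap:
    """Coordinate map of one DNA molecule (features in bp, sorted, disjoint)."""

    name: str
    length: int
    sites: tuple[FeatureSite, ...]
    rise_per_bp: float = RISE_NM_PER_BP

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("substrate length must be positive")
        prev_end = 0
        for s in self.sites:
            if s.start < prev_end:
                raise ValueError(f"sites overlap or are unsorted at {s.label}")
            if s.end > self.length:
                raise ValueError(f"site {s.label} extends past substrate end")
            prev_end = s.end

    @property
    def contour_length_nm(self) -> float:
        return self.length * self.rise_per_bp

    @property
    def parS_sites(self) -> tuple[FeatureSite, ...]:
        return tuple(s for s in self.sites if s.kind == "parS")

    @property
    def roadblocks(self) -> tuple[FeatureSite, ...]:
        return tuple(s for s in self.sites if s.kind == "roadblock")

    def parS_clusters(self) -> tuple[tuple[FeatureSite, ...], ...]:
        """Group parS sites by the cluster index encoded in their labels."""
        clusters: dict[str, list[FeatureSite]] = {}
        for s in self.parS_sites:
            key = s.label.split("_")[1] if s.label.startswith("parS_c") else "c1"
            clusters.setdefault(key, []).append(s)
        return tuple(tuple(v) for _, v in sorted(clusters.items()))

    # ---- serialization -------------------------------------------------
    def to_bed_text(self) -> str:
        buf = io.StringIO()
        buf.write(
            f"# substrate={self.name}\tlength={self.length}\t"
            f"rise_per_bp={self.rise_per_bp}\n"
        )
        for s in self.sites:
            buf.write(f"{s.label}\t{s.start}\t{s.end}\t{s.kind}\n")
        return buf.getvalue()

    @classmethod
    def from_bed_text(cls, text: str) -> "SubstrateMap":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("#"):
            raise ValueError("missing substrate header line ('# substrate=...')")
        header: dict[str, str] = {}
        for tok in lines[0].lstrip("# ").split("\t"):
            if "=" not in tok:
                raise ValueError(f"malformed header field {tok!r}")
            k, v = tok.split("=", 1)
            header[k] = v
        sites = []
        for i, ln in enumerate(lines[1:], start=2):
            parts = ln.split("\t")
            if len(parts) != 4:
                raise ValueError(f"line {i}: expected 4 tab-separated fields, got {len(parts)}")
            label, start, end, kind = parts
            sites.append(FeatureSite(kind=kind, start=int(start), end=int(end), label=label))
        return cls(
            name=header["substrate"],
            length=int(header["length"]),
            sites=tuple(sites),
            rise_per_bp=float(header.get("rise_per_bp", RISE_NM_PER_BP)),
        )

    def to_gff3(self) -> str:
        out = ["##gff-version 3", f"##sequence-region {self.name} 1 {self.length}"]
        for s in self.sites:
            out.append(
                "\t".join(
                    [
                        self.name,
                        "parbslide",
                        "protein_binding_site" if s.kind == "parS" else "protein_bind",
                        str(s.start + 1),
                        str(s.end),
                        ".",
                        "+",
                        ".",
                        f"ID={s.label};kind={s.kind}",
                    ]
                )
            )
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# construction


class _Builder:
    def __init__(self) -> None:
        self.cursor = 0
        self.sites: list[FeatureSite] = []

    def gap(self, bp: int) -> None:
        self.cursor += int(bp)

    def parS_group(
        self, n: int, cluster: int, group: int, spacing: int = DEFAULT_PARS_SPACING_BP
    ) -> None:
        for k in range(n):
            start = self.cursor + k * spacing
            self.sites.append(
                FeatureSite("parS", start, start + PARS_FOOTPRINT_BP, f"parS_c{cluster}_g{group}_s{k + 1}")
            )
        self.cursor += (n - 1) * spacing + PARS_FOOTPRINT_BP

    def parS_clusters(self, plan: tuple[tuple[int, ...], ...], intercluster_gap: int) -> None:
        group_no = 0
        for ci, cluster in enumerate(plan, start=1):
            if ci > 1:
                self.gap(intercluster_gap)
            for gi, n in enumerate(cluster):
                if gi > 0:
                    self.gap(DEFAULT_GROUP_GAP_BP)
                group_no += 1
                self.parS_group(n, cluster=ci, group=group_no)

    def roadblock(self, label: str, footprint: int = ECORI_GROUP_FOOTPRINT_BP) -> None:
        self.sites.append(FeatureSite("roadblock", self.cursor, self.cursor + footprint, label))
        self.cursor += footprint


def _pars_region_span(plan: tuple[tuple[int, ...], ...], intercluster_gap: int) -> int:
    b = _Builder()
    b.parS_clusters(plan, intercluster_gap)
    return b.cursor


def build_substrate(name: str) -> SubstrateMap:
    """Assemble the coordinate map of one named experimental DNA construct.

    Valid names: optical-tweezers substrates ``39x_parS``, ``ecoRI_39x_parS``,
    ``ecoRI_7x_parS``, ``2x_parS``; magnetic-tweezers substrates ``26x``,
    ``13x``, ``7x``, ``4x``, ``1x``, ``scrambled``; the parS-free
    ``lambda_control``; and the 1717 bp single-parS ``tpm_1717`` tether.
    """
    if name not in SUBSTRATE_NAMES:
        raise ValueError(
            f"unknown substrate {name!r}; valid identifiers: {', '.join(SUBSTRATE_NAMES)}"
        )

    b = _Builder()
    if name == "39x_parS":
        b.gap(_CTRAP_LEFT_FLANK_BP)
        b.parS_clusters(_CLUSTER_PLANS["39x"], INTERCLUSTER_GAP_BP)
        b.gap(_CTRAP_RIGHT_FLANK_BP)
    elif name in ("ecoRI_39x_parS", "ecoRI_7x_parS"):
        plan = _CLUSTER_PLANS["39x" if "39x" in name else "7x"]
        b.gap(_CTRAP_ECORI_LEFT_OUTER_BP)
        b.roadblock("EcoRI_A")
        b.gap(DEFAULT_ROADBLOCK_GAP_BP)
        b.parS_clusters(plan, INTERCLUSTER_GAP_BP)
        b.gap(PARS_TO_ECORI_GAP_BP)
        b.roadblock("EcoRI_B")
        b.gap(_CTRAP_RIGHT_FLANK_BP)
    elif name == "2x_parS":
        b.gap(_CTRAP_LEFT_FLANK_BP)
        b.parS_clusters(_CLUSTER_PLANS["2x"], 0)
        b.gap(_CTRAP_RIGHT_FLANK_BP)
    elif name in ("26x", "13x", "7x", "4x", "1x"):
        plan = _CLUSTER_PLANS[name]
        span = _pars_region_span(plan, 0)
        central = _MT_TOTAL_BP - 2 * _MT_HANDLE_BP
        if span > central:
            raise ValueError("parS region does not fit the MT central fragment")
        b.gap(_MT_HANDLE_BP + (central - span) // 2)
        b.parS_clusters(plan, 0)
        b.cursor = _MT_TOTAL_BP
    elif name == "scrambled":
        b.cursor = _MT_TOTAL_BP
    elif name == "lambda_control":
        b.cursor = LAMBDA_LENGTH_BP
    elif name == "tpm_1717":
        b.gap((1717 - PARS_FOOTPRINT_BP) // 2)
        b.parS_group(1, cluster=1, group=1)
        b.cursor = 1717

    return SubstrateMap(name=name, length=b.cursor, sites=tuple(b.sites))


# ---------------------------------------------------------------------------
# queries


def _resolve(smap: SubstrateMap, selector: str) -> tuple[float, float]:
    """Resolve a site selector to a (start, end) interval in bp.

    Accepts an exact or uniquely-prefixing site label, ``parS_first`` /
    ``parS_last``, ``roadblock_first`` / ``roadblock_last``, and cluster
    boundaries ``cluster<N>_start`` / ``cluster<N>_end`` (zero-width).
    """
    if selector in ("parS_first", "parS_last", "roadblock_first", "roadblock_last"):
        kind, which = selector.rsplit("_", 1)
        group = smap.parS_sites if kind == "parS" else smap.roadblocks
        if not group:
            raise ValueError(f"substrate {smap.name!r} has no {kind} sites")
        s = group[0] if which == "first" else group[-1]
        return (float(s.start), float(s.end))
    if selector.startswith("cluster") and selector.endswith(("_start", "_end")):
        idx_str, boundary = selector[len("cluster"):].split("_")
        clusters = smap.parS_clusters()
        idx = int(idx_str)
        if not 1 <= idx <= len(clusters):
            raise ValueError(f"substrate {smap.name!r} has {len(clusters)} parS clusters")
        cl = clusters[idx - 1]
        pos = float(cl[0].start) if boundary == "start" else float(cl[-1].end)
        return (pos, pos)
    exact = [s for s in smap.sites if s.label == selector]
    if len(exact) == 1:
        return (float(exact[0].start), float(exact[0].end))
    pref = [s for s in smap.sites if s.label.startswith(selector)]
    if len(pref) == 1:
        return (float(pref[0].start), float(pref[0].end))
    if len(pref) == 0:
        raise ValueError(f"selector {selector!r} matches no site on {smap.name!r}")
    raise ValueError(
        f"selector {selector!r} is ambiguous on {smap.name!r} ({len(pref)} matches)"
    )


def feature_distance(smap: SubstrateMap, a: str, b: str) -> float:
    """Gap in bp between two features (0 for identical or touching features)."""
    ia, ib = _resolve(smap, a), _resolve(smap, b)
    if ia == ib:
        return 0.0
    if ia[0] > ib[0]:
        ia, ib = ib, ia
    return max(0.0, ib[0] - ia[1])


def make_tandem(smap: SubstrateMap) -> SubstrateMap:
    """Head-to-head double-length tether: second copy mirror-appended.

    The site pattern is palindromic about the ligation junction, so site
    counts double, as observed for tandem tethers in the dual-trap assay.
    """
    twol = 2 * smap.length
    mirrored = [
        replace(s, start=twol - s.end, end=twol - s.start, label=s.label + "_mirror")
        for s in smap.sites
    ]
    sites = tuple(sorted([*smap.sites, *mirrored], key=lambda s: s.start))
    return SubstrateMap(
        name=smap.name + "_tandem", length=twol, sites=sites, rise_per_bp=smap.rise_per_bp
    )


# ---------------------------------------------------------------------------
# unit conversions


def bp_to_nm(x_bp, rise: float = RISE_NM_PER_BP):
    """Base pairs to nanometres of contour (rise per bp, default 0.34 nm)."""
    import numpy as np

    x = np.asarray(x_bp, dtype=float)
    if np.any(x < 0):
        raise ValueError("bp coordinate must be non-negative")
    out = x * rise
    return float(out) if out.ndim == 0 else out


def nm_to_bp(x_nm, rise: float = RISE_NM_PER_BP):
    """Inverse of :func:`bp_to_nm`."""
    import numpy as np

    x = np.asarray(x_nm, dtype=float)
    if np.any(x < 0):
        raise ValueError("nm coordinate must be non-negative")
    out = x / rise
    return float(out) if out.ndim == 0 else out


def diffusion_um2_to_bp2(d_um2_s: float, rise: float = RISE_NM_PER_BP) -> float:
    """Convert a 1D diffusion constant from um^2/s to bp^2/s (0.34 nm/bp)."""
    if d_um2_s < 0:
        raise ValueError("diffusion constant must be non-negative")
    return d_um2_s * 1.0e6 / rise**2
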