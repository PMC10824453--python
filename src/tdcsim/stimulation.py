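"""tDCS montages: electrode pairs, targeted region sets, excitability changes.

A montage is an anode/cathode pair of 10-20 scalp positions, e.g.
``PO7a-AF4c`` (first token the anode, suffix ``a``; second the cathode,
suffix ``c``).  Current-flow modeling - performed outside this package -
summarizes, per cortical region, the fraction of its area covered by a
sufficiently strong electric field and whether the region lies nearer the
anode or the cathode.  Regions covered on at least half of their area are
targeted, binarily: anodal regions have the excitatory threshold ``Vd1``
lowered from 7 to 5 (more excitable), cathodal regions have it raised to
9 (less excitable), and the change is sustained once applied.

For self-contained studies a seeded generator produces plausible coverage
tables over a schematic scalp layout for the twenty standard montage ids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .neural_mass import NeuralMassParameters

__all__ = [
    "Montage",
    "RegionFieldCoverage",
    "ELECTRODE_POSITIONS",
    "STANDARD_MONTAGE_IDS",
    "ANODAL_VD1",
    "CATHODAL_VD1",
    "regions_from_coverage",
    "reverse_polarity",
    "apply_montage",
    "synthetic_coverage",
]

ANODAL_VD1 = 5.0
CATHODAL_VD1 = 9.0
DEFAULT_VD1 = 7.0

#: Schematic 2-D scalp coordinates (x toward the right ear, y toward the
#: nose, unit head radius) for the 10-20/10-10 positions used by the
#: standard montage set.  Approximate azimuthal-equidistant projection.
ELECTRODE_POSITIONS: dict[str, tuple[float, float]] = {
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    "PO7": (-0.59, -0.81), "PO8": (0.59, -0.81),
    "P5": (-0.69, -0.54), "P6": (0.69, -0.54),
    "F3": (-0.55, 0.48), "F4": (0.55, 0.48),
    "F7": (-0.81, 0.59), "F8": (0.81, 0.59),
    "AF3": (-0.34, 0.82), "AF4": (0.34, 0.82),
    "FC3": (-0.64, 0.25), "FC4": (0.64, 0.25),
    "FC5": (-0.87, 0.30), "FC6": (0.87, 0.30),
    "FT9": (-0.98, 0.33), "FT10": (0.98, 0.33),
}

#: The twenty montage ids of the standard comparison study.
STANDARD_MONTAGE_IDS: tuple[str, ...] = (
    "PO7a-AF4c", "PO8a-AF3c", "F7a-F4c", "F8a-F3c", "P5a-P6c", "P6a-P5c",
    "O1a-F3c", "O2a-F4c", "FC5a-FC6c", "FT10a-FC3c", "F4a-O2c", "F3a-F8c",
    "FC4a-FT9c", "FC3a-FT10c", "FC6a-FC5c", "F3a-O1c", "F4a-F7c",
    "FT9a-FC4c", "AF4a-PO7c", "AF3a-PO8c",
)

_ID_RE = re.compile(r"^([A-Z]+[0-9]*)a-([A-Z]+[0-9]*)c$", re.IGNORECASE)


def _parse_id(montage_id: str) -> tuple[str, str]:
    m = _ID_RE.match(montage_id)
    if not m:
        raise ValueError(
            f"montage id {montage_id!r} does not parse as '<anode>a-<cathode>c'"
        )
    return m.group(1), m.group(2)


@dataclass(frozen=True)
class Montage:
    """An electrode pair with its current-flow-targeted region sets."""

    id: str
    anodal_regions: frozenset[int] = field(default_factory=frozenset)
    cathodal_regions: frozenset[int] = field(default_factory=frozenset)
    anode_pos: str = ""
    cathode_pos: str = ""

    def __post_init__(self) -> None:
        anode, cathode = _parse_id(self.id)
        if not self.anode_pos:
            object.__setattr__(self, "anode_pos", anode)
        if not self.cathode_pos:
            object.__setattr__(self, "cathode_pos", cathode)
        if (self.anode_pos, self.cathode_pos) != (anode, cathode):
            raise ValueError(f"montage id {self.id!r} disagrees with electrode positions")
        overlap = self.anodal_regions & self.cathodal_regions
        if overlap:
            raise ValueError(f"regions {sorted(overlap)} assigned to both electrodes")
        object.__setattr__(self, "anodal_regions", frozenset(self.anodal_regions))
        object.__setattr__(self, "cathodal_regions", frozenset(self.cathodal_regions))

    @property
    def region_count_ratio(self) -> float:
        """Anodal-to-cathodal targeted region count ratio."""
        return len(self.anodal_regions) / max(len(self.cathodal_regions), 1)


@dataclass(frozen=True)
class RegionFieldCoverage:
    """Per-region field coverage from current-flow modeling.

    ``fraction``: share of the region's area where the field strength
    exceeds the relative-strength threshold; ``nearest``: whether that
    field patch lies nearer the anode or the cathode.
    """

    fraction: Mapping[int, float]
    nearest: Mapping[int, str]

    def __post_init__(self) -> None:
        for r, f in self.fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"coverage fraction of region {r} outside [0, 1]")
        for r, side in self.nearest.items():
            if side not in ("anode", "cathode"):
                raise ValueError(f"region {r}: nearest electrode must be anode|cathode")


def regions_from_coverage(
    cov: RegionFieldCoverage, area_threshold: float = 0.5
) -> tuple[frozenset[int], frozenset[int]]:
    """Binary targeting rule: include a region iff its covered-area
    fraction reaches ``area_threshold``, assigning it to its nearest
    electrode's set."""
    anodal, cathodal = set(), set()
    for region, frac in cov.fraction.items():
        if frac >= area_threshold:
            side = cov.nearest.get(region)
            if side is None:
                raise ValueError(f"region {region} has coverage but no nearest electrode")
            (anodal if side == "anode" else cathodal).add(region)
    if anodal & cathodal:
        raise ValueError("malformed coverage table: region on both electrodes")
    return frozenset(anodal), frozenset(cathodal)


def reverse_polarity(m: Montage) -> Montage:
    """Swap anode and cathode; region sets exchange roles accordingly."""
    return Montage(
        id=f"{m.cathode_pos}a-{m.anode_pos}c",
        anodal_regions=m.cathodal_regions,
        cathodal_regions=m.anodal_regions,
    )


def apply_montage(
    params: Sequence[NeuralMassParameters], m: Montage
) -> list[NeuralMassParameters]:
    """Set ``Vd1`` to 5 in anodal and 9 in cathodal regions; all other
    parameters and regions untouched.  Returns a new parameter list."""
    n = len(params)
    bad = [i for i in (m.anodal_regions | m.cathodal_regions) if not 0 <= i < n]
    if bad:
        raise IndexError(f"montage {m.id} targets region indices {sorted(bad)} outside 0..{n - 1}")
    out = []
    for i, p in enumerate(params):
        if i in m.anodal_regions:
            out.append(replace(p, Vd1=ANODAL_VD1))
        elif i in m.cathodal_regions:
            out.append(replace(p, Vd1=CATHODAL_VD1))
        else:
            out.append(p)
    return out


def synthetic_coverage(
    montage_id: str,
    region_xy: np.ndarray,
    reach: float = 1.2,
    strength_profile: float = 1.2,
    posterior_spread: float = 1.5,
    anterior_spread: float = 0.85,
) -> RegionFieldCoverage:
    """Plausible coverage table for a montage over a schematic layout.

    Synthetic stand-in for finite-element current-flow output: each
    electrode projects a field patch whose covered-area fraction decays
    with distance (zero beyond its reach), sharpened by the
    ``strength_profile`` exponent; a region's fraction is the stronger of
    the two patches and the stronger patch assigns the side.  Posterior
    electrodes (negative y) spread wider than anterior ones, emulating
    the diffuse parieto-occipital versus focal frontal current-flow
    patterns of the reference maps.  Deterministic, and invariant under
    polarity reversal up to the anode/cathode role swap.
    """
    anode, cathode = _parse_id(montage_id)
    xy = np.asarray(region_xy, dtype=float)

    def patch(name: str) -> np.ndarray:
        pos = np.array(ELECTRODE_POSITIONS[name])
        spread = reach * (posterior_spread if pos[1] < 0 else anterior_spread)
        d = np.linalg.norm(xy - pos, axis=1)
        return np.clip(1.0 - d / spread, 0.0, 1.0) ** strength_profile

    fa, fc = patch(anode), patch(cathode)
    frac = np.maximum(fa, fc)
    nearest = np.where(fa >= fc, "anode", "cathode")
    keep = frac > 0
    return RegionFieldCoverage(
        fraction={int(i): float(frac[i]) for i in np.flatnonzero(keep)},
        nearest={int(i): str(nearest[i]) for i in np.flatnonzero(keep)},
    )
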