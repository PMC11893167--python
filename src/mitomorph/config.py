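"""Run configuration: every threshold the analysis applies, in one place.

Defaults reproduce the published analysis conventions: a 95 A exit-tunnel
cutoff for import orientation, a 250 A center proximity band, 150 A membrane
patches, an 18-30 nm crista-junction distance band expanded by 15 nm, a
Ripley radius range of 27-166 nm read out in 10 nm intervals, a 30 nm
polysome neighbor rule, and 100-bin distance histograms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    exit_cutoff: float = 95.0          # A, exit-tunnel -> OMM for import class
    proximity_cutoff: float = 250.0    # A, center -> OMM for "near membrane"
    patch_radius: float = 150.0        # A, membrane patch growth radius
    cj_band: tuple = (18.0, 30.0)      # nm, IMM->OMM band marking crista junctions
    crista_expand: float = 15.0        # nm, dilation of CJ-projected OMM
    k_r_range: tuple = (27.0, 166.0)   # nm, Ripley radius range
    k_interval: float = 10.0           # nm, interval width for K-ratio maxima
    k_n_radii: int = 140               # grid density over k_r_range
    k_n_resamples: int = 50            # Monte-Carlo resamples for the CSR null
    polysome_neighbor: float = 30.0    # nm, center-to-center neighbor rule
    adjacency_cutoff: float = 60.0     # A, mRNA entry <-> exit adjacency
    histogram_bins: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exit_cutoff", "proximity_cutoff", "patch_radius",
                     "crista_expand", "k_interval", "polysome_neighbor",
                     "adjacency_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("cj_band", "k_r_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy min < max")
            setattr(self, name, (float(lo), float(hi)))
        if self.histogram_bins < 1 or self.k_n_radii < 2:
            raise ValueError("histogram_bins >= 1 and k_n_radii >= 2 required")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config fields: {sorted(extra)}")
        for name in ("cj_band", "k_r_range"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)
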