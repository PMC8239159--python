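"""Pipeline configuration with the tool's standard defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class Config:
    """All tunables of the pipeline; every field can come from YAML or CLI.

    Defaults: 10 ppm mass tolerance, charges up to +3, proton adduct,
    dextrin ladder GU 2-12, cubic polynomial calibration, envelope
    Pearson cutoff 0.9, XIC boundary at 50% of apex, composition bounds
    HexNAc<=12 Hex<=12 Fuc<=5 NeuAc<=4, permethylated derivatization.
    """

    tol_ppm: float = 10.0
    max_charge: int = 3
    adducts: tuple[str, ...] = ("proton",)
    gu_min: int = 2
    gu_max: int = 12
    fit_kind: str = "polynomial"  # or "logarithmic"
    fit_order: int = 3
    score_cutoff: float = 0.9
    boundary_cutoff: float = 0.5
    bounds: tuple[int, int, int, int] = (12, 12, 5, 4)
    derivatization: str = "permethylated"
    reduced_end: bool = False
    area_mode: str = "trapezoid"  # or "sum" (raw intensity summation)
    isomer_rt_window: float = 0.2  # min, cross-charge isomer apex merging
    min_apex: float = 0.0  # absolute XIC apex floor (0 = off)
    min_ladder_intensity: float = 0.0  # ladder observation floor (0 = off)
    n_isotope_peaks: int = 10
    seed: int = 0  # synthetic-run generation only

    def __post_init__(self):
        self.adducts = tuple(self.adducts)
        self.bounds = tuple(self.bounds)
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if not 1 <= self.max_charge <= 10:
            raise ValueError("max_charge must be in [1, 10]")
        if not 0 < self.boundary_cutoff < 1:
            raise ValueError("boundary_cutoff must be in (0, 1)")
        if self.fit_kind not in ("polynomial", "logarithmic"):
            raise ValueError(f"unknown fit kind {self.fit_kind!r}")
        if self.gu_min < 1 or self.gu_max < self.gu_min:
            raise ValueError("invalid GU range")

    def tol_da(self, m: float) -> float:
        """ppm tolerance converted to Th at m/z ``m``."""
        return self.tol_ppm * 1e-6 * m

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adducts"] = list(self.adducts)
        d["bounds"] = list(self.bounds)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
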