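"""Physical-constant configuration: Mg-ATP equilibrium constants and 31P T1 values.

The Mg2+ readout inverts a species-population model of the alpha-beta ATP
chemical-shift difference.  The formation constants and limiting shifts of the
five ATP species (ATP, HATP, MgATP, MgHATP, Mg2ATP) are *data*, not code: they
come from titration studies and differ between literature sources (ionic
strength, temperature).  The package therefore refuses to compute [Mg2+]
without an explicit, source-tagged constants set.  A representative default
set ships with the package for simulation and round-trip testing; for real
analyses you should load the constant set matching your calibration
literature.

The same applies to the metabolite T1 values used for saturation correction
at TR << T1: they are config entries with a source tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "EquilibriumConstants",
    "T1Table",
    "default_equilibrium_constants",
    "default_t1_table",
    "load_equilibrium_constants",
    "load_t1_table",
]


@dataclass(frozen=True)
class EquilibriumConstants:
    """Formation constants (M^-1 scale) and limiting alpha-beta shifts (ppm).

    Shift convention: ``delta = delta(alpha-ATP) - delta(beta-ATP) > 0``
    (downfield-positive ppm axis, PCr = 0).  ``flip_sign`` accommodates
    constant sets tabulated with the opposite difference convention.
    """

    k_h: float        # ATP^4- + H+  <-> HATP^3-
    k_mg: float       # ATP^4- + Mg2+ <-> MgATP^2-
    k_mgh: float      # HATP^3- + Mg2+ <-> MgHATP^-
    k_mg2: float      # MgATP^2- + Mg2+ <-> Mg2ATP
    d_atp: float      # limiting shifts, ppm
    d_hatp: float
    d_mgatp: float
    d_mghatp: float
    d_mg2atp: float
    source: str = "unspecified"
    flip_sign: bool = False

    def __post_init__(self) -> None:
        for name in ("k_h", "k_mg", "k_mgh", "k_mg2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"formation constant {name} must be > 0")
        shifts = (self.d_atp, self.d_hatp, self.d_mgatp, self.d_mghatp, self.d_mg2atp)
        if not all(map(lambda s: s == s and abs(s) < 1e3, shifts)):
            raise ValueError("limiting shifts must be finite")

    def signed(self, delta: float) -> float:
        """Map a raw limiting/observed shift onto the internal (positive) convention."""
        return -delta if self.flip_sign else delta


@dataclass(frozen=True)
class T1Table:
    """Per-metabolite longitudinal relaxation times (seconds) with provenance tag."""

    t1: dict[str, float] = field(default_factory=dict)
    source: str = "unspecified"

    def __post_init__(self) -> None:
        for name, value in self.t1.items():
            if value <= 0:
                raise ValueError(f"T1 for {name} must be > 0, got {value}")

    def __getitem__(self, metabolite: str) -> float:
        try:
            return self.t1[metabolite]
        except KeyError:
            raise KeyError(
                f"no T1 entry for {metabolite!r}; available: {sorted(self.t1)}"
            ) from None


def _data_path(name: str):
    return resources.files("p31quant.data").joinpath(name)


def load_equilibrium_constants(path: str | Path) -> EquilibriumConstants:
    """Load a constants set from a YAML mapping (keys as in EquilibriumConstants)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return EquilibriumConstants(**raw)


def load_t1_table(path: str | Path) -> T1Table:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return T1Table(t1={k: float(v) for k, v in raw["t1"].items()}, source=raw.get("source", "unspecified"))


def default_equilibrium_constants() -> EquilibriumConstants:
    """Package-default Mg-ATP constants set (synthetic-representative values)."""
    raw = yaml.safe_load(_data_path("mg_atp_constants.yaml").read_text())
    return EquilibriumConstants(**raw)


def default_t1_table() -> T1Table:
    """Package-default 7 T muscle 31P T1 table (synthetic-representative values)."""
    raw = yaml.safe_load(_data_path("t1_31p_7t.yaml").read_text())
    return T1Table(t1={k: float(v) for k, v in raw["t1"].items()}, source=raw.get("source", "unspecified"))
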