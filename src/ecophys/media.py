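"""Deterministic medium-design calculators for seawater culture media.

Three small, exact computations recur when designing artificial seawater
media for marine oligotrophs:

* converting the chlorinity of the base salts to salinity with the classical
  oceanographic factor, salinity (ppt) = 1.80655 x Cl (ppt);
* building a salinity series by mixing two medium batches (e.g. 0 and
  50 ppt) in linear proportions;
* accounting total organic carbon of a defined substrate mix in uM carbon
  atoms, and scaling a molar-ratio mix to hit a target carbon concentration.

Everything here is linear and exact; no tolerance beyond float rounding.
Carbon atom counts are always supplied explicitly (a reference table for
common substrates is bundled) — they are never inferred from compound names.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import MixingRangeError

__all__ = [
    "CHLORINITY_TO_SALINITY",
    "CARBON_ATOMS",
    "CarbonComponent",
    "MixingSeries",
    "chlorinity_to_salinity",
    "mixing_fractions",
    "carbon_total",
    "mix_for_target",
]

#: Classical oceanographic chlorinity-to-salinity conversion factor.
CHLORINITY_TO_SALINITY = 1.80655

#: Carbon atoms per molecule for common defined-medium substrates.
CARBON_ATOMS: Mapping[str, int] = {
    "methionine": 5,
    "glycine": 2,
    "pyruvate": 3,
    "asparagine": 4,
    "glucose": 6,
    "ribose": 5,
    "taurine": 2,
    "n-acetyl-glucosamine": 8,
    "ethanol": 2,
}


@dataclass(frozen=True)
class CarbonComponent:
    """One substrate in a carbon mix: concentration in uM, C atoms/molecule."""

    name: str
    concentration_uM: float
    carbon_atoms: int

    def __post_init__(self) -> None:
        if self.concentration_uM < 0:
            raise ValueError("concentration must be >= 0")
        if self.carbon_atoms <= 0:
            raise ValueError("carbon atoms per molecule must be > 0")

    @property
    def carbon_uM(self) -> float:
        return self.concentration_uM * self.carbon_atoms


@dataclass(frozen=True)
class MixingSeries:
    """Fractions of the high-salinity batch that realize each target."""

    lo_salinity: float
    hi_salinity: float
    targets: tuple[float, ...]
    fractions_hi: tuple[float, ...]

    def reconstruct(self) -> tuple[float, ...]:
        """Salinities achieved by the fractions; equals targets exactly."""
        lo, hi = self.lo_salinity, self.hi_salinity
        return tuple(lo + f * (hi - lo) for f in self.fractions_hi)


def chlorinity_to_salinity(cl_ppt: float) -> float:
    """Salinity (ppt) from chlorinity (ppt) of the base salts."""
    if cl_ppt < 0:
        raise ValueError("chlorinity must be >= 0")
    return CHLORINITY_TO_SALINITY * cl_ppt


def mixing_fractions(
    lo: float, hi: float, targets: Sequence[float]
) -> MixingSeries:
    """Two-batch mixing fractions for a series of target salinities.

    fraction_hi = (target - lo) / (hi - lo); mixing the batches at that
    fraction reproduces each target exactly.
    """
    if lo >= hi:
        raise MixingRangeError("low endpoint must be below high endpoint")
    fracs = []
    for t in targets:
        if not (lo <= t <= hi):
            raise MixingRangeError(
                f"target {t} outside mixing endpoints [{lo}, {hi}]"
            )
        fracs.append((t - lo) / (hi - lo))
    return MixingSeries(
        lo_salinity=float(lo),
        hi_salinity=float(hi),
        targets=tuple(float(t) for t in targets),
        fractions_hi=tuple(fracs),
    )


def carbon_total(components: Sequence[CarbonComponent]) -> float:
    """Total carbon in uM atoms: sum of concentration x atoms per molecule."""
    return float(sum(c.carbon_uM for c in components))


def mix_for_target(
    ratio: Mapping[str, float],
    carbon_atoms: Mapping[str, int],
    target_carbon_uM: float,
) -> dict[str, float]:
    """Scale a molar-ratio mix so its total carbon equals the target.

    ``ratio`` gives relative molar proportions (e.g. methionine:glycine:
    pyruvate = 1:5:5); the returned concentrations (uM) satisfy
    ``carbon_total == target_carbon_uM`` exactly.
    """
    if target_carbon_uM < 0:
        raise ValueError("target carbon must be >= 0")
    if not ratio:
        raise ValueError("empty ratio")
    carbon_per_unit = 0.0
    for name, parts in ratio.items():
        if parts <= 0:
            raise ValueError(f"ratio entry for {name!r} must be > 0")
        if name not in carbon_atoms:
            raise KeyError(f"no carbon atom count supplied for {name!r}")
        carbon_per_unit += parts * carbon_atoms[name]
    if carbon_per_unit <= 0:
        raise ValueError("mix carries no carbon per ratio unit")
    scale = target_carbon_uM / carbon_per_unit
    return {name: parts * scale for name, parts in ratio.items()}
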