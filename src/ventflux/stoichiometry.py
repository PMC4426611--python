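"""Chemoautotrophic sulfur ↔ carbon stoichiometry.

Couples carbon-fixation and sulfur-oxidation currencies: the symbionts
oxidise ~6.21 mol sulfide or ~6.64 mol thiosulfate per mol C fixed (ratios
that already embed an assumed 10% efficiency of energy conservation).
This supports (a) predicting individual sulfur-oxidation rates from
individual ¹³C fixation rates, (b) attributing an aquarium's bulk sulfur
uptake to its most productive occupants, and (c) expressing excretion of
partially oxidised sulfur compounds as a fraction of uptake on a
sulfur-atom basis (thiosulfate carries two S atoms per molecule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence


@dataclass(frozen=True)
class ThermoConstants:
    """Reference standard Gibbs free energies of complete aerobic oxidation."""

    dG_sulfide_kJ_per_mol: float = -732.6
    dG_thiosulfate_kJ_per_mol: float = -738.7

    def __post_init__(self) -> None:
        if self.dG_sulfide_kJ_per_mol >= 0 or self.dG_thiosulfate_kJ_per_mol >= 0:
            raise ValueError("free energies of oxidation must be negative")


@dataclass(frozen=True)
class StoichiometryParams:
    """Molar coupling between sulfur oxidised and carbon fixed.

    ``s_per_c_*`` are mol substrate oxidised per mol C fixed; ``efficiency``
    is informational (already folded into the defaults). ``s_atoms`` counts
    sulfur atoms per molecule of each analyte; the polysulfide chain length
    is configurable (1–8), default 1.
    """

    s_per_c_sulfide: float = 6.21
    s_per_c_thiosulfate: float = 6.64
    efficiency: float = 0.10
    s_atoms: Mapping[str, float] = field(
        default_factory=lambda: {"sulfide": 1.0, "thiosulfate": 2.0, "polysulfide": 1.0}
    )

    def __post_init__(self) -> None:
        if min(self.s_per_c_sulfide, self.s_per_c_thiosulfate, self.efficiency) <= 0:
            raise ValueError("stoichiometric parameters must be positive")
        for k, v in self.s_atoms.items():
            if v <= 0:
                raise ValueError(f"s_atoms[{k!r}] must be positive")
        ps = self.s_atoms.get("polysulfide", 1.0)
        if not 1 <= ps <= 8:
            raise ValueError("polysulfide chain length must be in [1, 8]")

    def s_per_c(self, substrate: str) -> float:
        if substrate == "sulfide":
            return self.s_per_c_sulfide
        if substrate == "thiosulfate":
            return self.s_per_c_thiosulfate
        raise ValueError(f"no C-fixation coupling for substrate {substrate!r}")

    def atoms(self, analyte: str) -> float:
        try:
            return float(self.s_atoms[analyte])
        except KeyError:
            raise ValueError(f"unknown analyte {analyte!r}") from None


def predicted_sulfur_rate(
    c_inc_wet: float,
    substrate: str,
    params: StoichiometryParams = StoichiometryParams(),
) -> float:
    """Substrate-oxidation rate implied by a carbon-fixation rate.

    µmol C g⁻¹ h⁻¹ × (mol S-substrate / mol C) → µmol substrate g⁻¹ h⁻¹.
    """
    if c_inc_wet < 0:
        raise ValueError("carbon fixation rate must be >= 0")
    return c_inc_wet * params.s_per_c(substrate)


def attribution_fraction(
    individuals: Sequence[tuple[float, float]],
    substrate: str,
    aquarium_rate: float,
    total_gill_wet_g: float,
    params: StoichiometryParams = StoichiometryParams(),
    top_k: int = 2,
) -> tuple[float, bool]:
    """Share of the aquarium's bulk oxidation attributable to its top fixers.

    ``individuals`` are (wet C_inc rate, gill wet mass) pairs;
    ``aquarium_rate`` is the measured mass-specific uptake (negative).
    Returns (percent, capped) where ``capped`` marks predictions exceeding
    the measured total.
    """
    if total_gill_wet_g <= 0:
        raise ValueError("total gill mass must be > 0")
    if aquarium_rate >= 0:
        raise ValueError("aquarium rate must be negative (net uptake) to attribute")
    if not 0 < top_k <= len(individuals):
        raise ValueError("top_k must be in [1, n individuals]")
    ranked = sorted(individuals, key=lambda t: t[0], reverse=True)[:top_k]
    predicted = sum(
        predicted_sulfur_rate(c, substrate, params) * gill for c, gill in ranked
    )
    total = abs(aquarium_rate) * total_gill_wet_g
    pct = 100.0 * predicted / total
    return pct, pct > 100.0


def excretion_fraction(
    excretion_rate: float,
    uptake_rate: float,
    excreted_analyte: str,
    consumed_analyte: str,
    params: StoichiometryParams = StoichiometryParams(),
) -> float:
    """Excretion as a percent of uptake, on a sulfur-atom basis.

    E.g. thiosulfate (2 S) excreted at +0.92 against sulfide (1 S) taken up
    at −6.8 µmol g⁻¹ h⁻¹ is 100·0.92·2/6.8 ≈ 27.1%.
    """
    if excretion_rate < 0:
        raise ValueError("excretion rate must be >= 0")
    if uptake_rate >= 0:
        raise ValueError("uptake rate must be negative (net uptake)")
    return (
        100.0
        * excretion_rate
        * params.atoms(excreted_analyte)
        / (abs(uptake_rate) * params.atoms(consumed_analyte))
    )


def excretion_fraction_band(
    excretion_mean: float,
    excretion_sd: float,
    uptake_mean: float,
    uptake_sd: float,
    excreted_analyte: str,
    consumed_analyte: str,
    params: StoichiometryParams = StoichiometryParams(),
) -> tuple[float, float, float]:
    """(point, lo, hi) excretion fraction with ±sd interval arithmetic.

    The bounds are the min/max of the quotient over the ±1 sd boxes of the
    two mean rates, reproducing band-style statements such as "24–30%".
    """
    if excretion_sd < 0 or uptake_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    point = excretion_fraction(
        excretion_mean, uptake_mean, excreted_analyte, consumed_analyte, params
    )
    exc_lo = max(excretion_mean - excretion_sd, 0.0)
    exc_hi = excretion_mean + excretion_sd
    up_small = abs(uptake_mean) - uptake_sd
    up_big = abs(uptake_mean) + uptake_sd
    if up_small <= 0:
        raise ValueError("uptake ±sd interval crosses zero; band undefined")
    ratio = params.atoms(excreted_analyte) / params.atoms(consumed_analyte)
    lo = 100.0 * exc_lo * ratio / up_big
    hi = 100.0 * exc_hi * ratio / up_small
    return point, lo, hi
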