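"""¹³C-tracer carbon-fixation rates from tissue isotope measurements.

Animals incubated in seawater whose dissolved inorganic carbon (DIC) is
enriched in ¹³C fix labelled carbon into symbiont-containing gill tissue;
symbiont-free foot tissue of the same individual provides the unlabelled
baseline. The chain is:

    %13C_inc  = 100 · (A%_gill − A%_foot) / (A%_water − A%_foot)
    W13C_inc  = (%13C_inc / 100) · DW_g · %C          [g ¹³C]
    DryC_inc  = 10⁶ · W13C_inc / (MW_13C · t · DW_g)  [µmol ¹³C g⁻¹ dry h⁻¹]
    C_inc     = DryC_inc · DW_g / W_g                 [µmol ¹³C g⁻¹ wet h⁻¹]

where A% is atomic percent ¹³C, DW_g/W_g gill dry/wet weight, %C the carbon
fraction of dry tissue, t the incubation duration and MW_13C the molar mass
of ¹³C. The %13C_inc and DryC_inc forms are the unique ones dimensionally
consistent with the defined terms and the stated output units.
"""

from __future__ import annotations

from dataclasses import dataclass

#: VPDB 13C/12C isotope ratio, used by the delta-notation helpers.
R_VPDB = 0.0111802

#: natural-abundance atomic percent 13C
NATURAL_ABUNDANCE_A_PCT = 1.11


@dataclass(frozen=True)
class IsotopeConstants:
    MW_13C: float = 13.00335  # g/mol, exact isotope mass

    def __post_init__(self) -> None:
        if self.MW_13C <= 0:
            raise ValueError("MW_13C must be > 0")


@dataclass(frozen=True)
class TissueIsotopeSample:
    """Per-animal gill/foot isotopic and gravimetric measurements.

    ``C_pct`` may be given on either a percent (0–100) or fraction (0–1)
    scale; declare which with ``c_pct_unit``. Internally normalised to a
    fraction.
    """

    animal_id: str
    A_pct_gill: float
    A_pct_foot: float
    A_pct_water: float
    DW_g: float
    C_pct: float
    W_g: float
    t_h: float
    c_pct_unit: str = "fraction"

    def __post_init__(self) -> None:
        for name in ("A_pct_gill", "A_pct_foot", "A_pct_water"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100), got {v}")
        if self.A_pct_water <= self.A_pct_foot:
            raise ValueError("label water must be enriched above the foot baseline")
        if self.DW_g <= 0 or self.W_g <= 0 or self.DW_g > self.W_g:
            raise ValueError("need 0 < DW_g <= W_g")
        if self.t_h <= 0:
            raise ValueError("t_h must be > 0")
        if self.c_pct_unit == "fraction":
            frac = self.C_pct
        elif self.c_pct_unit == "percent":
            frac = self.C_pct / 100.0
        else:
            raise ValueError(f"c_pct_unit must be 'fraction' or 'percent'")
        if not 0 < frac <= 1:
            raise ValueError(f"carbon content out of range: {self.C_pct} {self.c_pct_unit}")
        object.__setattr__(self, "C_pct", frac)
        object.__setattr__(self, "c_pct_unit", "fraction")


@dataclass(frozen=True)
class CarbonIncRate:
    animal_id: str
    pct_13C_inc: float
    W13C_inc_g: float
    dry_rate: float  # µmol 13C / g dry gill / h
    wet_rate: float  # µmol 13C / g wet gill / h
    clamped: bool = False


def percent_13c_inc(A_pct_gill: float, A_pct_foot: float, A_pct_water: float) -> float:
    """Percent of gill carbon newly incorporated from the labelled DIC pool.

    Three-endmember mixing of the gill signal between the foot (initial)
    and water (label) endmembers. May be negative on noisy input.
    """
    if A_pct_water == A_pct_foot:
        raise ValueError("no label contrast: A%_water equals A%_foot")
    return 100.0 * (A_pct_gill - A_pct_foot) / (A_pct_water - A_pct_foot)


def weight_13c_inc(pct_13c_inc: float, DW_g: float, C_pct: float) -> float:
    """Grams of ¹³C incorporated: label fraction × dry weight × carbon content."""
    if DW_g < 0 or not 0 <= C_pct <= 1:
        raise ValueError("DW_g >= 0 and C_pct in [0, 1] required")
    return (pct_13c_inc / 100.0) * DW_g * C_pct


def dry_c_inc(
    W13C_inc_g: float,
    constants: IsotopeConstants = IsotopeConstants(),
    t_h: float = 1.0,
    DW_g: float = 1.0,
) -> float:
    """Dry-mass-specific incorporation rate, µmol ¹³C g⁻¹ dry h⁻¹."""
    if t_h <= 0:
        raise ValueError("t_h must be > 0")
    if DW_g <= 0:
        raise ValueError("DW_g must be > 0")
    return 1e6 * W13C_inc_g / (constants.MW_13C * t_h * DW_g)


def wet_c_inc(dry_rate: float, DW_g: float, W_g: float) -> float:
    """Convert a dry-mass rate to wet-mass basis by the dry:wet ratio."""
    if W_g <= 0:
        raise ValueError("W_g must be > 0")
    return dry_rate * DW_g / W_g


def c_inc_pipeline(
    sample: TissueIsotopeSample,
    constants: IsotopeConstants = IsotopeConstants(),
    clamp_negative: bool = True,
) -> CarbonIncRate:
    """Full chain from tissue measurements to the wet-mass fixation rate.

    Slightly negative raw incorporation (gill below the foot baseline, as
    measurement noise permits) is clamped to zero with a flag by default —
    the "no carbon incorporation" reporting convention — or passed through
    raw when ``clamp_negative`` is off.
    """
    pct = percent_13c_inc(sample.A_pct_gill, sample.A_pct_foot, sample.A_pct_water)
    clamped = False
    if pct < 0 and clamp_negative:
        pct = 0.0
        clamped = True
    w13 = weight_13c_inc(pct, sample.DW_g, sample.C_pct)
    dry = dry_c_inc(w13, constants, sample.t_h, sample.DW_g)
    wet = wet_c_inc(dry, sample.DW_g, sample.W_g)
    return CarbonIncRate(
        animal_id=sample.animal_id,
        pct_13C_inc=pct,
        W13C_inc_g=w13,
        dry_rate=dry,
        wet_rate=wet,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# delta-notation helpers for IRMS users

def delta13c_to_atom_pct(delta_permil: float) -> float:
    """Convert δ¹³C (‰ vs VPDB) to atomic percent ¹³C."""
    r = R_VPDB * (1.0 + delta_permil / 1000.0)
    return 100.0 * r / (1.0 + r)


def atom_pct_to_delta13c(a_pct: float) -> float:
    """Convert atomic percent ¹³C to δ¹³C (‰ vs VPDB)."""
    if not 0 < a_pct < 100:
        raise ValueError("atomic percent must be in (0, 100)")
    r = a_pct / (100.0 - a_pct)
    return 1000.0 * (r / R_VPDB - 1.0)
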