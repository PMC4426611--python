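"""Mass-specific net sulfur flux rates from interval concentrations.

The net rate for a genus in a set is the control-differenced effluent
concentration scaled by flow and normalised to total wet gill mass:

    rate = (C_exp − C_ref) · F / M_gill      [µM · L h⁻¹ / g = µmol g⁻¹ h⁻¹]

Negative rates are net uptake (oxidation); positive rates net excretion.
Only data collected after both a minimum elapsed time and a minimum number
of aquarium water turnovers are used (gating).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ventflux.voltammetry import ANALYTES, IntervalConcentration


@dataclass(frozen=True)
class AquariumConfig:
    """One flow-through aquarium: identity, plumbing and occupant gill mass."""

    id: str
    role: str  # experimental | control | input
    flow_L_per_h: float
    volume_L: float
    total_gill_wet_g: float = 0.0
    genus: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("experimental", "control", "input"):
            raise ValueError(f"unknown aquarium role {self.role!r}")
        if self.flow_L_per_h <= 0 or self.volume_L <= 0:
            raise ValueError("flow and volume must be > 0")
        if self.total_gill_wet_g < 0:
            raise ValueError("gill mass must be >= 0")
        if self.role == "control" and self.total_gill_wet_g != 0:
            raise ValueError("control aquarium holds no animals")

    @property
    def turnover_h(self) -> float:
        """Hours for one full exchange of the aquarium volume."""
        return self.volume_L / self.flow_L_per_h


@dataclass(frozen=True)
class GatingPolicy:
    """Temporal gate: data before max(min_elapsed_h, min_turnovers·τ) are dropped."""

    min_elapsed_h: float = 10.0
    min_turnovers: float = 3.0

    def __post_init__(self) -> None:
        if self.min_elapsed_h < 0 or self.min_turnovers < 0:
            raise ValueError("gating bounds must be >= 0")

    def cutoff_h(self, aquarium: AquariumConfig) -> float:
        return max(self.min_elapsed_h, self.min_turnovers * aquarium.turnover_h)


@dataclass(frozen=True)
class FluxRate:
    """A signed mass-specific rate: negative = net uptake, positive = net excretion."""

    genus: str
    analyte: str
    set_index: int
    rate_umol_g_h: float
    reference_channel: str
    flag: str = ""  # "", "bdl", "bdl_pair"

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate_umol_g_h):
            raise ValueError("rate must be finite")


def net_rate(
    exp: IntervalConcentration,
    ref: IntervalConcentration,
    aquarium: AquariumConfig,
    substitution_uM: float = 0.0,
) -> FluxRate:
    """Control-differenced, flow-scaled, gill-mass-normalised net rate.

    Interval concentrations that are below detection enter as
    ``substitution_uM`` (0 by default); the rate is flagged ``bdl`` when
    one side is censored and ``bdl_pair`` when both are.
    """
    if exp.analyte != ref.analyte:
        raise ValueError(f"analyte mismatch: {exp.analyte} vs {ref.analyte}")
    if exp.set_index != ref.set_index:
        raise ValueError(f"set mismatch: {exp.set_index} vs {ref.set_index}")
    if aquarium.total_gill_wet_g <= 0:
        raise ValueError("aquarium has zero gill mass; nothing to normalise to")
    c_exp = substitution_uM if exp.is_bdl else exp.mean_uM
    c_ref = substitution_uM if ref.is_bdl else ref.mean_uM
    rate = (c_exp - c_ref) * aquarium.flow_L_per_h / aquarium.total_gill_wet_g
    if exp.is_bdl and ref.is_bdl:
        flag = "bdl_pair"
    elif exp.is_bdl or ref.is_bdl:
        flag = "bdl"
    else:
        flag = ""
    return FluxRate(
        genus=aquarium.genus or aquarium.id,
        analyte=exp.analyte,
        set_index=exp.set_index,
        rate_umol_g_h=rate,
        reference_channel=ref.channel,
        flag=flag,
    )


def gate_sets(
    intervals: Sequence[IntervalConcentration],
    aquarium: AquariumConfig,
    policy: GatingPolicy = GatingPolicy(),
) -> tuple[list[IntervalConcentration], float]:
    """Retain intervals starting at or after the gating cutoff.

    Returns the retained intervals and the applied cutoff in hours.
    """
    cutoff_h = policy.cutoff_h(aquarium)
    kept = [ic for ic in intervals if ic.start_s >= cutoff_h * 3600.0]
    if not kept:
        warnings.warn(
            f"gating at {cutoff_h:g} h removed every interval for "
            f"aquarium {aquarium.id}",
            stacklevel=2,
        )
    return kept, cutoff_h


def pair_intervals(
    ics: Sequence[IntervalConcentration],
    exp_channel: str,
    reference_channel: str,
    analyte: str,
    mode: str = "per_set",
) -> list[tuple[IntervalConcentration, IntervalConcentration]]:
    """Pair each experimental interval with its set's reference interval.

    ``per_set`` (default) uses the single reference interval of the same
    2-h set. ``interpolate`` instead pairs against a synthetic reference
    whose mean is linearly interpolated in time between neighbouring
    reference intervals.
    """
    exps = sorted(
        (i for i in ics if i.channel == exp_channel and i.analyte == analyte),
        key=lambda i: i.start_s,
    )
    refs = sorted(
        (i for i in ics if i.channel == reference_channel and i.analyte == analyte),
        key=lambda i: i.start_s,
    )
    if not refs:
        raise ValueError(f"no reference intervals on channel {reference_channel!r}")
    pairs: list[tuple[IntervalConcentration, IntervalConcentration]] = []
    if mode == "per_set":
        by_set = {r.set_index: r for r in refs}
        for e in exps:
            r = by_set.get(e.set_index)
            if r is not None:
                pairs.append((e, r))
    elif mode == "interpolate":
        import numpy as np

        t = np.array([r.start_s for r in refs])
        v = np.array([r.mean_uM for r in refs])
        for e in exps:
            mean = float(np.interp(e.start_s, t, v))
            proto = min(refs, key=lambda r: abs(r.start_s - e.start_s))
            pairs.append(
                (
                    e,
                    IntervalConcentration(
                        channel=reference_channel,
                        analyte=analyte,
                        start_s=e.start_s,
                        mean_uM=mean,
                        n_used=proto.n_used,
                        n_discarded=proto.n_discarded,
                        frac_censored=proto.frac_censored,
                        is_bdl=proto.is_bdl,
                        set_index=e.set_index,
                        position=proto.position,
                    ),
                )
            )
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    return pairs


def summarize_rates(rates: Sequence[FluxRate]) -> pd.DataFrame:
    """Per genus × analyte summary of set-level rates.

    Plain arithmetic mean and sample (ddof=1) standard deviation; sd is
    reported as 0 with ``n_sets = 1`` for singletons. Rates flagged
    ``bdl_pair`` are excluded.
    """
    usable = [r for r in rates if r.flag != "bdl_pair"]
    if not usable:
        raise ValueError("no usable rates to summarise")
    rows = []
    keys = sorted({(r.genus, r.analyte) for r in usable})
    for genus, analyte in keys:
        vals = [r.rate_umol_g_h for r in usable if r.genus == genus and r.analyte == analyte]
        n = len(vals)
        mean = sum(vals) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        else:
            sd = 0.0
        rows.append(
            {
                "genus": genus,
                "analyte": analyte,
                "mean_rate_umol_g_h": mean,
                "sd_rate_umol_g_h": sd,
                "min_rate_umol_g_h": min(vals),
                "max_rate_umol_g_h": max(vals),
                "n_sets": n,
                "direction": "excretion" if mean > 0 else ("uptake" if mean < 0 else "none"),
            }
        )
    return pd.DataFrame(rows)


def sustained_excretion(
    pairs: Sequence[tuple[IntervalConcentration, IntervalConcentration]],
    min_consecutive: int = 2,
) -> bool:
    """Whether a compound absent from the reference is persistently excreted.

    True when the effluent is above detection while the paired reference is
    below detection across at least ``min_consecutive`` consecutive gated
    sets.
    """
    ordered = sorted(pairs, key=lambda p: p[0].set_index)
    run = 0
    for exp, ref in ordered:
        if (not exp.is_bdl) and ref.is_bdl:
            run += 1
            if run >= min_consecutive:
                return True
        else:
            run = 0
    return False


def rates_to_frame(rates: Iterable[FluxRate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genus": r.genus,
                "analyte": r.analyte,
                "set_index": r.set_index,
                "rate_umol_g_h": r.rate_umol_g_h,
                "reference_channel": r.reference_channel,
                "flag": r.flag,
            }
            for r in rates
        ],
        columns=["genus", "analyte", "set_index", "rate_umol_g_h", "reference_channel", "flag"],
    )
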