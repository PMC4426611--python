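"""Synthetic high-pressure flow-through incubations with known ground truth.

Generates complete in-silico experiments — animal cohorts, voltammetric
scan series and tissue-isotope tables — whose true per-animal uptake and
carbon-fixation rates are recorded, so the processing chain can be tested
end to end without shipboard data.

The emulated physics, deliberately simple:

* three experimental aquaria (one genus each) plus a reference channel
  (an empty control aquarium in *rate* experiments, input water in
  *variation* experiments) sampled on a cyclic 4 × 30-min schedule;
* well-mixed steady-state chemistry: effluent = input − Σ(uptake·gill)/flow,
  with a linear ramp-in over the first three turnovers so the temporal
  gating rule has something to exclude;
* two 21-scan bursts per interval; the first scans of each interval relax
  exponentially from the previously sampled channel's concentration
  (electrode carry-over); Gaussian measurement noise; analyte-specific
  detection-limit censoring;
* animals stacked by position: per-animal fixation (and coupled sulfur
  uptake) decays geometrically with distance from the water input;
* gill ¹³C enrichment is the exact algebraic inverse of the tissue-isotope
  rate chain, so zero-noise recovery is an identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ventflux.flux import AquariumConfig
from ventflux.isotope import NATURAL_ABUNDANCE_A_PCT, IsotopeConstants
from ventflux.stoichiometry import StoichiometryParams
from ventflux.voltammetry import ANALYTES, DetectionLimits, SetSchedule

GENERA = ("Alviniconcha", "Ifremeria", "Bathymodiolus")

#: per-genus allometric truth (slope g gill / g body, intercept g) and body-mass
#: distribution (mean, sd, grams wet); scaled so ~5 animals total ~20 g gill.
_GENUS_TRAITS = {
    "Alviniconcha": {"slope": 0.16, "intercept": 0.3, "body_mean": 26.0, "body_sd": 5.0},
    "Ifremeria": {"slope": 0.14, "intercept": 0.4, "body_mean": 27.0, "body_sd": 5.0},
    "Bathymodiolus": {"slope": 0.18, "intercept": 0.2, "body_mean": 24.0, "body_sd": 4.0},
}


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated incubation."""

    experiment_kind: str = "variation"  # rate | variation
    substrate: str = "sulfide"  # sulfide | thiosulfate | sulfur_free
    input_concentration_uM: float = 350.0
    n_animals_per_genus: int = 10
    duration_h: float = 24.0
    flow_L_per_h: float = 1.0
    volume_L: float = 2.0
    noise_sd_uM: float = 1.0  # scan noise sd at a 100 µM signal (scales with signal)
    transient_scans: int = 10
    transient_decay: float = 0.5  # per-scan relaxation fraction toward steady state
    positional_attenuation: float = 0.3  # per-position depletion of activity
    excretion_rules: dict[str, tuple[str, float]] = field(default_factory=dict)
    label_A_pct_water: float = 5.0
    base_c_inc: float = 3.3  # µmol C g⁻¹ wet h⁻¹ at position 1
    control_loss_fraction: float = 0.0  # abiotic loss seen by every aquarium
    gill_noise_sd_g: float = 0.15
    dry_to_wet: float = 0.15
    c_content_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment_kind not in ("rate", "variation"):
            raise ValueError("experiment_kind must be 'rate' or 'variation'")
        if self.substrate not in ("sulfide", "thiosulfate", "sulfur_free"):
            raise ValueError("substrate must be sulfide|thiosulfate|sulfur_free")
        if self.input_concentration_uM < 0 or self.noise_sd_uM < 0:
            raise ValueError("concentrations and noise must be >= 0")
        for frac in (self.transient_decay, self.positional_attenuation,
                     self.control_loss_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def reference_channel(self) -> str:
        return "control" if self.experiment_kind == "rate" else "input"

    def schedule(self) -> SetSchedule:
        return SetSchedule(
            channels=("experimental-1", "experimental-2", "experimental-3",
                      self.reference_channel)
        )

    def aquaria(self, truth: "GroundTruth") -> list[AquariumConfig]:
        out = []
        for i, genus in enumerate(GENERA, start=1):
            sub = truth.animals[truth.animals.genus == genus]
            out.append(
                AquariumConfig(
                    id=f"experimental-{i}",
                    role="experimental",
                    flow_L_per_h=self.flow_L_per_h,
                    volume_L=self.volume_L,
                    total_gill_wet_g=float(sub.gill_wet_g.sum()),
                    genus=genus,
                )
            )
        out.append(
            AquariumConfig(
                id=self.reference_channel,
                role=self.reference_channel if self.reference_channel == "input" else "control",
                flow_L_per_h=self.flow_L_per_h,
                volume_L=self.volume_L,
                total_gill_wet_g=0.0,
            )
        )
        return out


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    animals: pd.DataFrame  # per-animal truths
    aquaria: pd.DataFrame  # per-aquarium steady effluent concentrations
    seed: int


def _stoich_params() -> StoichiometryParams:
    return StoichiometryParams()


def gen_cohort(config: ScenarioConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the animal cohort and its per-animal true rates.

    True fixation decays geometrically with stacking position,
    ``base_c_inc · (1 − attenuation)^(position−1)``; true sulfur uptake is
    coupled to fixation by the substrate's S:C molar ratio.
    """
    rng = rng or np.random.default_rng(config.seed)
    params = _stoich_params()
    rows = []
    for gi, genus in enumerate(GENERA, start=1):
        traits = _GENUS_TRAITS[genus]
        n = config.n_animals_per_genus
        body = rng.normal(traits["body_mean"], traits["body_sd"], size=n).clip(min=5.0)
        gill = (
            traits["slope"] * body
            + traits["intercept"]
            + rng.normal(0.0, config.gill_noise_sd_g, size=n)
        ).clip(min=0.2)
        for pos in range(1, n + 1):
            factor = (1.0 - config.positional_attenuation) ** (pos - 1)
            c_inc = config.base_c_inc * factor
            if config.substrate == "sulfur_free":
                c_inc = 0.0
                uptake = 0.0
            else:
                uptake = c_inc * params.s_per_c(config.substrate)
            rows.append(
                {
                    "animal_id": f"{genus[:3].lower()}-{pos:02d}",
                    "genus": genus,
                    "aquarium": f"experimental-{gi}",
                    "position": pos,
                    "body_wet_g": float(body[pos - 1]),
                    "gill_wet_g": float(gill[pos - 1]),
                    "true_uptake_umol_g_h": uptake,
                    "true_c_inc_wet": c_inc,
                }
            )
    animals = pd.DataFrame(rows)
    aquaria = _steady_state(config, animals)
    return GroundTruth(animals=animals, aquaria=aquaria, seed=config.seed)


def _steady_state(config: ScenarioConfig, animals: pd.DataFrame) -> pd.DataFrame:
    """Per-channel steady effluent concentration for every analyte."""
    params = _stoich_params()
    supplied = config.substrate if config.substrate != "sulfur_free" else None
    base_in = config.input_concentration_uM if supplied else 0.0
    seen_by_aquaria = base_in * (1.0 - config.control_loss_fraction)

    rows = []
    channels = [f"experimental-{i}" for i in range(1, 4)] + [config.reference_channel]
    for ch in channels:
        conc = {a: 0.0 for a in ANALYTES}
        if ch == "input":
            if supplied:
                conc[supplied] = base_in
        elif ch == "control":
            if supplied:
                conc[supplied] = seen_by_aquaria
        else:
            sub = animals[animals.aquarium == ch]
            if supplied:
                removed = float(
                    (sub.true_uptake_umol_g_h * sub.gill_wet_g).sum()
                ) / config.flow_L_per_h
                c = seen_by_aquaria - removed
                if c < 0:
                    warnings.warn(
                        f"{ch}: uptake exceeds supply; steady effluent floored at 0",
                        stacklevel=2,
                    )
                    c = 0.0
                conc[supplied] = c
                rule = config.excretion_rules.get(supplied)
                if rule is not None:
                    excreted, fraction = rule
                    atoms = params.atoms(supplied) / params.atoms(excreted)
                    exc_total = float(
                        (fraction * sub.true_uptake_umol_g_h * atoms * sub.gill_wet_g).sum()
                    )
                    conc[excreted] += exc_total / config.flow_L_per_h
        for analyte in ANALYTES:
            rows.append({"channel": ch, "analyte": analyte, "steady_uM": conc[analyte]})
    return pd.DataFrame(rows)


def gen_scan_series(
    config: ScenarioConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    limits: DetectionLimits | None = None,
) -> pd.DataFrame:
    """Emit the full voltammetric scan table for the incubation.

    Scans follow the 4-channel 30-min cycle with two 21-scan bursts per
    interval (minute 0 and minute 15, 2-s cadence). Concentrations ramp
    linearly from the supplied level to steady state over the first three
    turnovers; the first ``transient_scans`` of each interval relax
    exponentially from the previous channel's level; Gaussian noise is
    added and sub-detection values flagged censored.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    limits = limits or DetectionLimits()
    schedule = config.schedule()
    steady = {
        (r.channel, r.analyte): r.steady_uM for r in truth.aquaria.itertuples()
    }
    supplied = config.substrate if config.substrate != "sulfur_free" else None
    start_level = {
        (ch, a): (
            config.input_concentration_uM * (1.0 - config.control_loss_fraction)
            if (supplied and a == supplied and ch != "input")
            else steady[(ch, a)]
        )
        for ch in schedule.channels
        for a in ANALYTES
    }
    ramp_end_s = 3.0 * config.volume_L / config.flow_L_per_h * 3600.0

    def noise_sd(true_uM: float, limit: float) -> float:
        # signal-proportional instrumental noise plus a small baseline term,
        # so zero-analyte channels stay convincingly below detection
        return config.noise_sd_uM * true_uM / 100.0 + 0.05 * limit

    def level(ch: str, analyte: str, t: float) -> float:
        s = steady[(ch, analyte)]
        if ch == "input" or t >= ramp_end_s or ramp_end_s == 0:
            return s
        s0 = start_level[(ch, analyte)]
        return s0 + (s - s0) * t / ramp_end_s

    n_sets = int(config.duration_h * 3600.0 // schedule.set_duration_s)
    rows = []
    prev_channel: str | None = None
    for set_i in range(n_sets):
        for pos, ch in enumerate(schedule.channels):
            t0 = set_i * schedule.set_duration_s + pos * schedule.interval_s
            times = [t0 + burst + 2.0 * k for burst in (0.0, 900.0) for k in range(21)]
            for analyte in ANALYTES:
                true_vals = np.array([level(ch, analyte, t) for t in times])
                if prev_channel is not None and config.transient_scans > 0:
                    carry = level(prev_channel, analyte, t0)
                    for k in range(min(config.transient_scans, len(true_vals))):
                        w = config.transient_decay ** (k + 1)
                        true_vals[k] = true_vals[k] + (carry - true_vals[k]) * w
                lim = limits.limit(analyte)
                sds = np.array([noise_sd(v, lim) for v in true_vals])
                noisy = true_vals + rng.normal(0.0, 1.0, size=len(times)) * sds
                noisy = noisy.clip(min=0.0)
                for t, v in zip(times, noisy):
                    rows.append(
                        {
                            "time_s": t,
                            "channel": ch,
                            "analyte": analyte,
                            "concentration_uM": float(v),
                            "censored": int(v < lim),
                        }
                    )
            prev_channel = ch
    return pd.DataFrame(rows)


def gen_isotope_samples(
    config: ScenarioConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    noise_sd_A_pct: float = 0.0,
    constants: IsotopeConstants = IsotopeConstants(),
) -> pd.DataFrame:
    """Tissue-isotope table whose gill enrichment encodes the true rates.

    A%_gill is set by inverting the fixation-rate chain, so the processing
    pipeline recovers each true rate exactly at zero noise.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    a_w = config.label_A_pct_water
    rows = []
    for r in truth.animals.itertuples():
        w_g = r.gill_wet_g
        dw_g = config.dry_to_wet * w_g
        a_f = NATURAL_ABUNDANCE_A_PCT
        dry_rate = r.true_c_inc_wet * w_g / dw_g
        pct_inc = dry_rate * constants.MW_13C * config.duration_h / (
            1e4 * config.c_content_fraction
        )
        a_g = a_f + (pct_inc / 100.0) * (a_w - a_f)
        if a_g > a_w:
            raise ValueError(
                f"{r.animal_id}: true rate {r.true_c_inc_wet} unreachable with "
                f"label at {a_w} atom%"
            )
        if noise_sd_A_pct > 0:
            a_g += rng.normal(0.0, noise_sd_A_pct)
            a_f += rng.normal(0.0, noise_sd_A_pct)
        rows.append(
            {
                "animal_id": r.animal_id,
                "A_pct_gill": a_g,
                "A_pct_foot": a_f,
                "A_pct_water": a_w,
                "DW_g": dw_g,
                "C_pct": config.c_content_fraction,
                "W_g": w_g,
                "t_h": config.duration_h,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets mirroring the five incubations

SCENARIOS: Mapping[str, dict] = {
    # rate experiments: reference = empty control aquarium
    "sulfide_rate": dict(
        experiment_kind="rate", substrate="sulfide", input_concentration_uM=105.0,
        n_animals_per_genus=5, base_c_inc=0.7, control_loss_fraction=0.37,
    ),
    "thiosulfate_rate": dict(
        experiment_kind="rate", substrate="thiosulfate", input_concentration_uM=300.0,
        n_animals_per_genus=5, base_c_inc=0.7, control_loss_fraction=0.08,
    ),
    "sulfur_free": dict(
        experiment_kind="rate", substrate="sulfur_free", input_concentration_uM=0.0,
        n_animals_per_genus=5, base_c_inc=0.0,
    ),
    # variation experiments: reference = input water
    "sulfide_variation": dict(
        experiment_kind="variation", substrate="sulfide", input_concentration_uM=350.0,
        n_animals_per_genus=10, base_c_inc=3.3,
        excretion_rules={"sulfide": ("thiosulfate", 0.27)},
    ),
    "thiosulfate_variation": dict(
        experiment_kind="variation", substrate="thiosulfate",
        input_concentration_uM=300.0, n_animals_per_genus=8, base_c_inc=2.0,
    ),
}


def scenario_config(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    kwargs = {**SCENARIOS[name], **overrides, "seed": seed}
    return ScenarioConfig(**kwargs)


def generate_scenario(
    name: str, seed: int = 0, out_dir: str | Path | None = None, **overrides
) -> tuple[ScenarioConfig, GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Generate a preset scenario; optionally write the four CSVs + config.

    Returns (config, truth, scans, tissue). Every output file starts with a
    ``# seed=N`` header line.
    """
    config = scenario_config(name, seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    truth = gen_cohort(config, rng)
    scans = gen_scan_series(config, truth, rng)
    tissue = gen_isotope_samples(config, truth, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# seed={seed}\n"

        def dump(df: pd.DataFrame, name_: str) -> None:
            path = out / name_
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)

        animals_out = truth.animals.rename(columns={"gill_wet_g": "gill_wet_g_measured"})
        dump(scans, "scans.csv")
        dump(animals_out, "animals.csv")
        dump(tissue, "tissue.csv")
        dump(truth.aquaria, "truth_aquaria.csv")
        cfg = asdict(config)
        cfg["scenario"] = name
        cfg["excretion_rules"] = {
            k: list(v) for k, v in config.excretion_rules.items()
        }
        with open(out / "config.yaml", "w") as fh:
            fh.write(header)
            yaml.safe_dump(cfg, fh, sort_keys=True)
    return config, truth, scans, tissue
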