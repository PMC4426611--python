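"""End-to-end orchestration: raw CSVs → intervals → rates → report.

Consumes a directory holding ``scans.csv``, ``animals.csv``, ``tissue.csv``
and ``config.yaml`` (the layout the synthetic generator emits, equally
writable by hand for real data) and produces interval, rate, fixation,
attribution and excretion tables, a concentration/rate summary shaped like
the study's result tables, a plain-text report and a reproducibility
manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import ventflux
from ventflux.allometry import fill_gill_masses
from ventflux.flux import (
    AquariumConfig,
    GatingPolicy,
    gate_sets,
    net_rate,
    pair_intervals,
    rates_to_frame,
    summarize_rates,
    sustained_excretion,
)
from ventflux.isotope import IsotopeConstants, TissueIsotopeSample, c_inc_pipeline
from ventflux.stoichiometry import (
    StoichiometryParams,
    attribution_fraction,
    excretion_fraction_band,
)
from ventflux.voltammetry import (
    ANALYTES,
    DetectionLimits,
    SetSchedule,
    assemble_intervals,
    interval_concentration,
    intervals_to_frame,
    read_scans,
)

FLOAT_FORMAT = "%.6g"  # fixed serialisation precision for reproducible diffs


class SchemaError(ValueError):
    """Input CSV violates the expected schema; message itemises rows."""


@dataclass
class RunManifest:
    config_hash: str
    input_checksums: dict[str, str]
    seed: int | None
    version: str
    gating_cutoff_h: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "input_checksums": self.input_checksums,
                "seed": self.seed,
                "version": self.version,
                "gating_cutoff_h": self.gating_cutoff_h,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _validate_animals(df: pd.DataFrame) -> None:
    _require_columns(df, ["animal_id", "genus", "aquarium", "position", "body_wet_g"], "animals.csv")
    bad = df.index[df["body_wet_g"] <= 0].tolist()
    if bad:
        raise SchemaError(f"animals.csv: non-positive body_wet_g at rows {bad}")


def _validate_tissue(df: pd.DataFrame) -> None:
    cols = ["animal_id", "A_pct_gill", "A_pct_foot", "A_pct_water", "DW_g", "C_pct", "W_g", "t_h"]
    _require_columns(df, cols, "tissue.csv")
    bad = df.index[(df["DW_g"] <= 0) | (df["W_g"] <= 0) | (df["t_h"] <= 0)].tolist()
    if bad:
        raise SchemaError(f"tissue.csv: non-positive weights/duration at rows {bad}")


def _read_seed(path: Path) -> int | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# seed="):
        return int(first.strip().split("=", 1)[1])
    return None


def run_pipeline(
    data_dir: str | Path,
    out_dir: str | Path,
    config_path: str | Path | None = None,
) -> RunManifest:
    """Run the full processing chain on one experiment directory."""
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_path = Path(config_path) if config_path else data / "config.yaml"
    for fname in ("scans.csv", "animals.csv", "tissue.csv"):
        if not (data / fname).exists():
            raise FileNotFoundError(f"missing required input {data / fname}")
    if not config_path.exists():
        raise FileNotFoundError(f"missing config {config_path}")

    cfg = yaml.safe_load(config_path.read_text())
    flow = float(cfg.get("flow_L_per_h", 1.0))
    volume = float(cfg.get("volume_L", 2.0))
    substrate = cfg.get("substrate", "sulfide")
    kind = cfg.get("experiment_kind", "variation")
    reference_channel = cfg.get(
        "reference_channel", "control" if kind == "rate" else "input"
    )
    policy = GatingPolicy(
        min_elapsed_h=float(cfg.get("min_elapsed_h", 10.0)),
        min_turnovers=float(cfg.get("min_turnovers", 3.0)),
    )
    censor_policy = cfg.get("censor_policy", "zero")
    limits = DetectionLimits(**cfg.get("detection_limits", {}))
    stoich = StoichiometryParams()
    top_k = int(cfg.get("top_k", 2))
    discard_n = int(cfg.get("transient_scans", 10))

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        scans = read_scans(data / "scans.csv")
        animals = pd.read_csv(data / "animals.csv", comment="#")
        tissue = pd.read_csv(data / "tissue.csv", comment="#")
        _validate_animals(animals)
        _validate_tissue(tissue)

        # gill masses: measured where available, per-genus allometric otherwise
        if "gill_wet_g_measured" not in animals.columns:
            animals["gill_wet_g_measured"] = float("nan")
        animals = fill_gill_masses(animals)

        # channel cycle in order of first appearance in the scan record
        seen: list[str] = []
        for s in scans:
            if s.channel not in seen:
                seen.append(s.channel)
        if reference_channel not in seen:
            raise SchemaError(
                f"reference channel {reference_channel!r} absent from scans.csv"
            )
        if len(seen) != 4:
            raise SchemaError(f"expected a 4-channel cycle, found {seen}")
        schedule = SetSchedule(channels=tuple(seen))

        intervals = assemble_intervals(scans, schedule)
        ics = []
        for iv in intervals:
            for analyte in iv.analytes:
                ics.append(
                    interval_concentration(
                        iv, analyte, limits, discard_n=discard_n,
                        censor_policy=censor_policy,
                    )
                )
        intervals_to_frame(ics).to_csv(
            out / "intervals.csv", index=False, float_format=FLOAT_FORMAT
        )

        # aquarium configs from the completed animal table
        aquaria: dict[str, AquariumConfig] = {}
        for aq_id, grp in animals.groupby("aquarium"):
            aquaria[aq_id] = AquariumConfig(
                id=aq_id,
                role="experimental",
                flow_L_per_h=flow,
                volume_L=volume,
                total_gill_wet_g=float(grp["gill_wet_g"].sum()),
                genus=str(grp["genus"].iloc[0]),
            )

        # gating, pairing, rates
        rates = []
        cutoffs: dict[str, float] = {}
        excretion_obs: list[dict] = []
        for aq_id, aq in sorted(aquaria.items()):
            gated, cutoff_h = gate_sets(ics, aq, policy)
            cutoffs[aq_id] = cutoff_h
            for analyte in ANALYTES:
                pairs = pair_intervals(gated, aq_id, reference_channel, analyte)
                for exp_ic, ref_ic in pairs:
                    rates.append(net_rate(exp_ic, ref_ic, aq))
                if pairs and sustained_excretion(pairs):
                    excretion_obs.append(
                        {"genus": aq.genus, "analyte": analyte, "sustained": True}
                    )
        rates_df = rates_to_frame(rates)
        rates_df.to_csv(out / "rates.csv", index=False, float_format=FLOAT_FORMAT)

        usable = [r for r in rates if r.flag != "bdl_pair"]
        rate_summary = summarize_rates(rates) if usable else pd.DataFrame()
        rate_summary.to_csv(
            out / "rate_summary.csv", index=False, float_format=FLOAT_FORMAT
        )

        conc_summary = _concentration_summary(ics, cutoffs, schedule, limits)
        conc_summary.to_csv(
            out / "concentration_summary.csv", index=False, float_format=FLOAT_FORMAT
        )

        # carbon fixation per animal
        cinc_rows = []
        for r in tissue.itertuples(index=False):
            sample = TissueIsotopeSample(
                animal_id=str(r.animal_id),
                A_pct_gill=float(r.A_pct_gill),
                A_pct_foot=float(r.A_pct_foot),
                A_pct_water=float(r.A_pct_water),
                DW_g=float(r.DW_g),
                C_pct=float(r.C_pct),
                W_g=float(r.W_g),
                t_h=float(r.t_h),
                c_pct_unit=cfg.get("c_pct_unit", "fraction"),
            )
            res = c_inc_pipeline(sample, IsotopeConstants())
            cinc_rows.append(
                {
                    "animal_id": res.animal_id,
                    "pct_13C_inc": res.pct_13C_inc,
                    "W13C_inc_g": res.W13C_inc_g,
                    "dry_rate_umol_g_h": res.dry_rate,
                    "wet_rate_umol_g_h": res.wet_rate,
                    "clamped": int(res.clamped),
                }
            )
        cinc = pd.DataFrame(cinc_rows).merge(
            animals[["animal_id", "genus", "aquarium", "position", "gill_wet_g"]],
            on="animal_id",
            how="left",
        )
        cinc.to_csv(out / "cinc.csv", index=False, float_format=FLOAT_FORMAT)

        # stoichiometric attribution and excretion fractions
        attribution = _attribution_table(
            cinc, rate_summary, aquaria, substrate, stoich, top_k
        )
        attribution.to_csv(
            out / "attribution.csv", index=False, float_format=FLOAT_FORMAT
        )
        excretion = _excretion_table(rate_summary, substrate, stoich)
        excretion.to_csv(out / "excretion.csv", index=False, float_format=FLOAT_FORMAT)
        pd.DataFrame(
            excretion_obs, columns=["genus", "analyte", "sustained"]
        ).to_csv(out / "sustained_excretion.csv", index=False)

        caught = [str(w.message) for w in wrec]

    seed = _read_seed(data / "scans.csv")
    manifest = RunManifest(
        config_hash=_sha256(config_path),
        input_checksums={
            f: _sha256(data / f) for f in ("scans.csv", "animals.csv", "tissue.csv")
        },
        seed=seed,
        version=ventflux.__version__,
        gating_cutoff_h=cutoffs,
        warnings=caught,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")

    report = _render_report(
        conc_summary, rate_summary, cinc, attribution, excretion, excretion_obs, manifest
    )
    (out / "report.txt").write_text(report)
    return manifest


def _concentration_summary(ics, cutoffs, schedule, limits) -> pd.DataFrame:
    """Average (min, max) interval concentration per channel × analyte.

    Computed over temporally gated intervals; min/max are over interval
    concentrations. Cells render 'BDL' when the mean is below detection;
    a below-detection minimum renders 'BDL' inside the range.
    """
    rows = []
    default_cutoff = max(cutoffs.values()) if cutoffs else 0.0
    for channel in schedule.channels:
        cutoff = cutoffs.get(channel, default_cutoff)
        for analyte in ANALYTES:
            sel = [
                ic for ic in ics
                if ic.channel == channel and ic.analyte == analyte
                and ic.start_s >= cutoff * 3600.0
            ]
            if not sel:
                continue
            mean = sum(ic.mean_uM for ic in sel) / len(sel)
            is_bdl = mean < limits.limit(analyte)
            lo = min(sel, key=lambda ic: ic.mean_uM)
            hi = max(sel, key=lambda ic: ic.mean_uM)
            rendered = (
                "BDL"
                if is_bdl
                else f"{mean:.3g} ({'BDL' if lo.is_bdl else format(lo.mean_uM, '.3g')},"
                     f" {format(hi.mean_uM, '.3g')})"
            )
            rows.append(
                {
                    "channel": channel,
                    "analyte": analyte,
                    "mean_uM": mean,
                    "min_uM": lo.mean_uM,
                    "max_uM": hi.mean_uM,
                    "n_intervals": len(sel),
                    "is_bdl": int(is_bdl),
                    "rendered": rendered,
                }
            )
    return pd.DataFrame(rows)


def _attribution_table(cinc, rate_summary, aquaria, substrate, stoich, top_k):
    rows = []
    if substrate not in ("sulfide", "thiosulfate") or rate_summary.empty:
        return pd.DataFrame(columns=["aquarium", "substrate", "top_k", "percent", "capped"])
    for aq_id, aq in sorted(aquaria.items()):
        sub = rate_summary[
            (rate_summary.genus == aq.genus) & (rate_summary.analyte == substrate)
        ]
        if sub.empty or float(sub.mean_rate_umol_g_h.iloc[0]) >= 0:
            continue
        individuals = [
            (float(r.wet_rate_umol_g_h), float(r.gill_wet_g))
            for r in cinc[cinc.aquarium == aq_id].itertuples()
        ]
        if len(individuals) < top_k:
            continue
        pct, capped = attribution_fraction(
            individuals,
            substrate,
            float(sub.mean_rate_umol_g_h.iloc[0]),
            aq.total_gill_wet_g,
            stoich,
            top_k=top_k,
        )
        rows.append(
            {
                "aquarium": aq_id,
                "substrate": substrate,
                "top_k": top_k,
                "percent": pct,
                "capped": int(capped),
            }
        )
    return pd.DataFrame(rows, columns=["aquarium", "substrate", "top_k", "percent", "capped"])


def _excretion_table(rate_summary, substrate, stoich):
    cols = ["genus", "excreted", "consumed", "percent", "percent_lo", "percent_hi"]
    rows = []
    if rate_summary.empty or substrate not in ("sulfide", "thiosulfate"):
        return pd.DataFrame(columns=cols)
    for genus, grp in rate_summary.groupby("genus"):
        up = grp[(grp.analyte == substrate) & (grp.mean_rate_umol_g_h < 0)]
        if up.empty:
            continue
        up_mean = float(up.mean_rate_umol_g_h.iloc[0])
        up_sd = float(up.sd_rate_umol_g_h.iloc[0])
        for r in grp[(grp.analyte != substrate) & (grp.mean_rate_umol_g_h > 0)].itertuples():
            point, lo, hi = excretion_fraction_band(
                float(r.mean_rate_umol_g_h),
                float(r.sd_rate_umol_g_h),
                up_mean,
                up_sd,
                r.analyte,
                substrate,
                stoich,
            )
            rows.append(
                {
                    "genus": genus,
                    "excreted": r.analyte,
                    "consumed": substrate,
                    "percent": point,
                    "percent_lo": lo,
                    "percent_hi": hi,
                }
            )
    return pd.DataFrame(rows, columns=cols)


def _render_report(conc, rates, cinc, attribution, excretion, excretion_obs, manifest):
    lines = [
        "ventflux pipeline report",
        "=" * 60,
        f"version {manifest.version}   seed {manifest.seed}",
        f"gating cutoffs (h): "
        + ", ".join(f"{k}={v:g}" for k, v in sorted(manifest.gating_cutoff_h.items())),
        "",
        "Effluent concentrations, average (min, max) µM over gated intervals",
        "-" * 60,
    ]
    for _, r in conc.iterrows():
        lines.append(f"  {r.channel:<16} {r.analyte:<12} {r.rendered}")
    lines += ["", "Net mass-specific rates, µmol g⁻¹ wet gill h⁻¹ (− uptake, + excretion)",
              "-" * 60]
    if not rates.empty:
        for _, r in rates.iterrows():
            lines.append(
                f"  {r.genus:<14} {r.analyte:<12} {r.mean_rate_umol_g_h:+.3g} "
                f"± {r.sd_rate_umol_g_h:.2g}  (n={r.n_sets}, {r.direction})"
            )
    for obs in excretion_obs:
        lines.append(f"  sustained excretion: {obs['genus']} -> {obs['analyte']}")
    lines += ["", "Carbon fixation, µmol ¹³C g⁻¹ wet gill h⁻¹", "-" * 60]
    for genus, grp in cinc.groupby("genus"):
        lines.append(
            f"  {genus:<14} mean {grp.wet_rate_umol_g_h.mean():.3g}  "
            f"max {grp.wet_rate_umol_g_h.max():.3g}  n={len(grp)}"
        )
    if not attribution.empty:
        lines += ["", "Attribution of bulk oxidation to most productive animals", "-" * 60]
        for _, r in attribution.iterrows():
            lines.append(
                f"  {r.aquarium:<16} top-{r.top_k} predicted {r.percent:.3g}% of total"
                + ("  [capped]" if r.capped else "")
            )
    if not excretion.empty:
        lines += ["", "Excretion as % of uptake (sulfur-atom basis)", "-" * 60]
        for _, r in excretion.iterrows():
            lines.append(
                f"  {r.genus:<14} {r.excreted} / {r.consumed}: {r.percent:.3g}% "
                f"(±sd band {r.percent_lo:.3g}–{r.percent_hi:.3g}%)"
            )
    lines.append("")
    return "\n".join(lines)
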