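"""Per-genus body-mass → gill-mass allometric prediction.

Gill wet mass is needed to normalise fluxes but is not always measured
directly; for those animals it is predicted from total body wet mass by a
per-genus ordinary least-squares line (optionally on log-log axes).
Measured gill masses always take precedence over predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st


@dataclass(frozen=True)
class AllometricModel:
    genus: str
    slope: float  # g gill per g body (per log-g on log-log axes)
    intercept: float
    n: int
    r_squared: float
    log_log: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two training pairs")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared out of [0, 1]")


def fit_allometry(
    pairs: Sequence[tuple[float, float]],
    genus: str,
    log_log: bool = False,
) -> AllometricModel:
    """OLS fit of gill wet mass on body wet mass for one genus."""
    if len(pairs) < 2:
        raise ValueError("need at least two (body, gill) pairs")
    body = np.asarray([p[0] for p in pairs], dtype=float)
    gill = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(body) == 0:
        raise ValueError("degenerate design: all body masses identical")
    if log_log:
        if (body <= 0).any() or (gill <= 0).any():
            raise ValueError("log-log fit requires positive masses")
        body, gill = np.log(body), np.log(gill)
    res = _st.linregress(body, gill)
    return AllometricModel(
        genus=genus,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(pairs),
        r_squared=float(res.rvalue**2),
        log_log=log_log,
    )


def predict_gill_mass(
    model: AllometricModel,
    body_wet_g: float,
    floor_g: float = 0.0,
) -> float:
    """Evaluate the allometric line, flooring non-positive predictions."""
    if body_wet_g <= 0:
        raise ValueError("body mass must be > 0")
    if model.log_log:
        pred = math.exp(model.slope * math.log(body_wet_g) + model.intercept)
    else:
        pred = model.slope * body_wet_g + model.intercept
    if pred <= floor_g:
        warnings.warn(
            f"allometric line for {model.genus} predicts {pred:.4g} g gill at "
            f"{body_wet_g:g} g body; floored to {floor_g:g} g",
            stacklevel=2,
        )
        return floor_g
    return pred


def fill_gill_masses(
    animals: pd.DataFrame,
    models: dict[str, AllometricModel] | None = None,
) -> pd.DataFrame:
    """Complete an animal table's gill masses, fitting per genus as needed.

    Expects columns ``genus``, ``body_wet_g`` and ``gill_wet_g_measured``
    (NaN where unmeasured). Appends ``gill_wet_g_predicted``, ``gill_wet_g``
    (measured where present, else predicted) and ``gill_source``.
    """
    out = animals.copy()
    measured = out["gill_wet_g_measured"]
    if models is None:
        models = {}
        for genus, grp in out[measured.notna()].groupby("genus"):
            if len(grp) >= 2 and grp["body_wet_g"].nunique() >= 2:
                models[genus] = fit_allometry(
                    list(zip(grp["body_wet_g"], grp["gill_wet_g_measured"])), genus
                )
    preds = []
    for _, row in out.iterrows():
        m = models.get(row["genus"])
        preds.append(
            predict_gill_mass(m, row["body_wet_g"]) if m is not None else float("nan")
        )
    out["gill_wet_g_predicted"] = preds
    out["gill_wet_g"] = measured.where(measured.notna(), out["gill_wet_g_predicted"])
    out["gill_source"] = np.where(measured.notna(), "measured", "predicted")
    if out["gill_wet_g"].isna().any():
        missing = out.loc[out["gill_wet_g"].isna(), "genus"].unique()
        raise ValueError(
            f"cannot complete gill masses: no allometric model for {list(missing)}"
        )
    return out
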