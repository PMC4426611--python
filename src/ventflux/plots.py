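"""Simple diagnostic figures: rate vs time and fixation vs stacking position."""

from __future__ import annotations

import pandas as pd


def rate_vs_time(rates: pd.DataFrame, ax=None):
    """Set-level net rates over the experiment, one line per genus × analyte."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (genus, analyte), grp in rates.groupby(["genus", "analyte"]):
        grp = grp.sort_values("set_index")
        ax.plot(grp.set_index * 2.0, grp.rate_umol_g_h, marker="o",
                label=f"{genus} {analyte}")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("net rate (µmol g⁻¹ wet gill h⁻¹)")
    ax.legend(fontsize="small")
    return ax


def cinc_vs_position(cinc: pd.DataFrame, ax=None):
    """Per-animal carbon fixation against position in the aquarium stack."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for genus, grp in cinc.groupby("genus"):
        grp = grp.sort_values("position")
        ax.plot(grp.position, grp.wet_rate_umol_g_h, marker="s", ls="--", label=genus)
    ax.set_xlabel("position in stack (1 = closest to input)")
    ax.set_ylabel("C fixation (µmol ¹³C g⁻¹ wet gill h⁻¹)")
    ax.legend(fontsize="small")
    return ax
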