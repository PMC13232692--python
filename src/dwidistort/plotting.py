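"""Figure helpers: air-vs-distortion scatter and paired position box plots."""

from __future__ import annotations

import pandas as pd


def plot_air_distortion_scatter(scatter: pd.DataFrame, ax=None):
    """Scatter of posterior distortion against proximal air volume by position.

    ``scatter`` is the long-format table produced by the study results
    (columns position, air_cm3, distortion_mm).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    styles = {"supine": dict(marker="s", color="tab:red"),
              "prone": dict(marker="o", color="tab:blue")}
    for pos, grp in scatter.groupby("position"):
        ax.scatter(grp["air_cm3"], grp["distortion_mm"], label=pos,
                   alpha=0.7, **styles.get(pos, {}))
    ax.set_xlabel("rectal air within 20 mm of prostate (cm$^3$)")
    ax.set_ylabel("posterior distortion RMS (mm)")
    ax.legend()
    return ax


def plot_paired_boxes(cohort: pd.DataFrame, variable: str = "distortion", ax=None):
    """Supine vs prone box plots for 'distortion' or 'air'."""
    import matplotlib.pyplot as plt

    cols = {"distortion": ("distortion_supine_mm", "distortion_prone_mm", "mm"),
            "air": ("air_supine_cm3", "air_prone_cm3", "cm$^3$")}
    sup, pro, unit = cols[variable]
    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot([cohort[sup], cohort[pro]], tick_labels=["supine", "prone"])
    ax.set_ylabel(f"{variable} ({unit})")
    return ax


__all__ = ["plot_air_distortion_scatter", "plot_paired_boxes"]
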