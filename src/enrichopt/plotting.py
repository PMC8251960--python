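"""Minimal plotting helpers for rule maps and operating characteristics."""

from __future__ import annotations

import pandas as pd

__all__ = ["rule_map_heatmap", "power_curve"]


def rule_map_heatmap(table: pd.DataFrame, value: str = "r1_2", ax=None):
    """Heatmap of an adaptation-rule-map column over (z1, z2).

    Unstable grid points (where the maximum conditional expected utility is
    below 0.01 and the optimizer falls back to no adaptation) are masked.
    """
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots()
    piv = table.pivot(index="z2", columns="z1", values=value)
    stable = table.pivot(index="z2", columns="z1", values="stable").astype(bool)
    data = np.where(stable.to_numpy(), piv.to_numpy(), np.nan)
    mesh = ax.pcolormesh(piv.columns, piv.index, data, shading="nearest")
    ax.figure.colorbar(mesh, ax=ax, label=value)
    ax.set_xlabel("$Z_1^{(1)}$")
    ax.set_ylabel("$Z_2^{(1)}$")
    return ax


def power_curve(reports: pd.DataFrame, x: str = "theta1", ax=None):
    """Rejection probabilities and average utility against a truth axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for col in ("p_reject_H01", "p_reject_H02", "avg_utility"):
        if col in reports:
            ax.plot(reports[x], reports[col], marker="o", label=col)
    ax.set_xlabel(x)
    ax.set_ylabel("probability / utility")
    ax.legend()
    return ax
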