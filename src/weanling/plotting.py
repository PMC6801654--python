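"""Per-animal diagnostic plots: observed weights vs fitted curves."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .calibration import FitResult, WeightTrajectory


def plot_animal(
    traj: WeightTrajectory,
    gompertz_fit: Optional[FitResult] = None,
    perturbed_fit: Optional[FitResult] = None,
    reference_fit: Optional[FitResult] = None,
    horizon: float = 75.0,
    ax=None,
):
    """Observed weights (circles) with the fitted curves overlaid.

    Gompertz: solid; perturbed Gompertz-Makeham: dashed; unperturbed
    reference: dotted.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mask = traj.times <= horizon
    ax.plot(traj.times[mask], traj.weights[mask], "o", mfc="none",
            color="k", label="observed")
    tt = np.linspace(0.0, min(horizon, traj.times[mask][-1]), 400)
    for fit, style, label in (
        (gompertz_fit, "-", "Gompertz"),
        (perturbed_fit, "--", "perturbed (Gompertz-Makeham)"),
        (reference_fit, ":", "unperturbed reference"),
    ):
        if fit is not None:
            ax.plot(tt, fit.predict(tt), style, label=label)
    ax.set_xlabel("days since weaning")
    ax.set_ylabel("body weight (kg)")
    ax.set_title(str(traj.animal_id))
    ax.legend(frameon=False, fontsize=8)
    return ax
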