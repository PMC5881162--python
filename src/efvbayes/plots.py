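"""Advisory figures: posterior-vs-concentration curves and population
concentration–time bands. Plots are outputs only; nothing downstream reads
them."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bayes import PosteriorCurve
from .dataset import CohortDataset
from .phenotype import PHENOTYPES

_COLORS = {"EM": "tab:green", "IM": "tab:orange", "PM": "tab:red"}


def plot_posterior_curve(curve: PosteriorCurve, path: str | Path) -> None:
    """Posterior probability of each phenotype across concentration bins at
    the model's sampling time."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for ph in PHENOTYPES:
        ax.plot(
            curve.bin_centers,
            curve.posteriors[ph],
            label=ph.value,
            color=_COLORS[ph.value],
        )
    ax.set_xlabel("Concentration (ng/mL)")
    ax.set_ylabel(f"P(phenotype | concentration at {curve.sampling_time:g} h)")
    ax.set_ylim(0, 1)
    ax.legend(title="Phenotype")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_concentration_bands(
    cohorts: Mapping[str, CohortDataset], path: str | Path
) -> None:
    """Median and 5–95% percentile band of the simulated concentration–time
    profiles, one panel per phenotype."""
    fig, axes = plt.subplots(1, len(cohorts), figsize=(4.2 * len(cohorts), 3.6), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (label, ds) in zip(axes, cohorts.items()):
        wide = ds.wide()
        times = wide.columns.to_numpy(float)
        lo, med, hi = np.percentile(wide.to_numpy(float), [5, 50, 95], axis=0)
        color = _COLORS.get(label, "tab:blue")
        ax.fill_between(times, lo, hi, alpha=0.25, color=color, label="5–95%")
        ax.plot(times, med, color=color, label="median")
        ax.set_title(label)
        ax.set_xlabel("Time (h)")
    axes[0].set_ylabel("Concentration (ng/mL)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
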