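"""QC figures for the two pipelines.

Plots a representative fitted diffusion curve, the group α time courses
from 03, and the swelling time courses from 04.  Purely illustrative —
all numbers live in the CSV/JSON outputs of the earlier scripts.
Writes results/figures/*.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ecsastro.rti_fitting import fit_tissue, preprocess_curve
from ecsastro.rti_model import pulse_increment_mM
from ecsastro.synthetic_data import (CurveSimConfig, DEFAULT_CALIBRATION,
                                     DEFAULT_TISSUE_PARAMS,
                                     simulate_diffusion_trace)

RESULTS = Path(__file__).resolve().parents[1] / "results"
FIGS = RESULTS / "figures"


def plot_example_fit(ax):
    cfg = CurveSimConfig(params_true=DEFAULT_TISSUE_PARAMS,
                         noise_sigma_rel=0.02, seed=5)
    trace = simulate_diffusion_trace(cfg)
    curve = preprocess_curve(trace.voltage_mV, trace.times,
                             DEFAULT_CALIBRATION, cfg.source, t_on=0.0)
    res = fit_tissue(curve, n=0.35, D=1.2e-5)
    ax.plot(curve.t, curve.c_mM, ".", ms=2, alpha=0.5, label="measured")
    model = curve.baseline_mM + pulse_increment_mM(curve.t, curve.source,
                                                   res.params)
    ax.plot(curve.t, model, "r-", lw=1.5,
            label=(f"fit: α={res.params.alpha:.3f}, "
                   f"λ={res.params.lam:.2f}"))
    ax.set(xlabel="time (s)", ylabel="[TMA⁺] (mM)",
           title="diffusion curve, 200 nA / 24 s pulse")
    ax.legend(fontsize=8)


def plot_group_csv(ax, path, ylabel, title):
    df = pd.read_csv(path)
    for g, sub in df.groupby("group"):
        ax.errorbar(sub["t"], sub["mean"], yerr=sub["sem"], marker="o",
                    ms=3, capsize=2, label=g)
    ax.set(xlabel="time (min)", ylabel=ylabel, title=title)
    ax.legend(fontsize=8)


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    plot_example_fit(axes[0])
    alpha_csv = RESULTS / "tissue_group_alpha.csv"
    if alpha_csv.exists():
        plot_group_csv(axes[1], alpha_csv, "ECS volume fraction α",
                       "50 mM K⁺ challenge + washout")
    swell_csv = RESULTS / "swelling_groups.csv"
    if swell_csv.exists():
        plot_group_csv(axes[2], swell_csv, "soma volume (% of t=0)",
                       "astrocyte swelling")
    fig.tight_layout()
    fig.savefig(FIGS / "overview.png", dpi=120)
    print(f"wrote {FIGS / 'overview.png'}")


if __name__ == "__main__":
    main()
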