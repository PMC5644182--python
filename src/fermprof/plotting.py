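"""Growth-curve plots with shaded exponential / non-exponential phases."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt

from .model import FermentationKineticsResults


def plot_run(result: FermentationKineticsResults, ax=None):
    """CO2 %, dry weight and glucose against time for one fitted run.

    The exponential window is shaded orange, the non-exponential phase
    grey, in the style of standard fermentation-profile figures.
    Returns the matplotlib axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    run, seg = result.run, result.segmentation
    gas = run.offgas
    ax.plot(gas.time_h, gas.co2_pct, color="tab:blue", lw=0.8, label="CO2 exhaust (%)")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("CO2 in exhaust (% v/v)", color="tab:blue")

    ax.axvspan(seg.exp_start_h, seg.exp_end_h, color="orange", alpha=0.25,
               label="exponential phase")
    if seg.nonexp_duration_h > 0:
        ax.axvspan(seg.exp_end_h, seg.t_co2max_h, color="grey", alpha=0.25,
                   label="non-exponential phase")

    samples = run.samples
    if samples.dw_time_h.size or samples.glucose_time_h.size:
        ax2 = ax.twinx()
        if samples.dw_time_h.size:
            ax2.plot(samples.dw_time_h, samples.dw_g_l, "ko", ms=4,
                     label="dry weight (g/L)")
        if samples.glucose_time_h.size:
            ax2.plot(samples.glucose_time_h, samples.glucose_g_l, "o", ms=4,
                     mfc="none", mec="k", label="glucose (g/L)")
        ax2.set_ylabel("dry weight / glucose (g/L)")
    ax.set_title(run.run_id)
    ax.legend(loc="upper left", fontsize=8)
    return ax


def save_run_plot(result: FermentationKineticsResults, path) -> None:
    ax = plot_run(result)
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
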