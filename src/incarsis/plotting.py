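"""Summary figures: prevalence bands, recidivism panels, ODE bifurcation."""

from __future__ import annotations

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

_COLORS = {"black": "0.1", "white": "0.6"}


def plot_prevalence_bands(summaries: dict, path) -> None:
    """Ensemble mean prevalence with 2.5/97.5 percentile bands per scenario."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, df in summaries.items():
        c = _COLORS.get(name)
        ax.plot(df["month"] / 12, 100 * df["mean"], label=name, color=c)
        ax.fill_between(df["month"] / 12, 100 * df["p2.5"], 100 * df["p97.5"],
                        alpha=0.2, color=c)
    ax.set_xlabel("years")
    ax.set_ylabel("incarceration prevalence (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_recidivism_panels(tables_dir, path) -> None:
    """2x2 panel: rate by prior count / age / sentence length, cumulative curve."""
    d = pathlib.Path(tables_dir)
    panels = [
        ("recidivism_by_prior_count.csv", "prior incarcerations", True),
        ("recidivism_by_age.csv", "age at release", True),
        ("recidivism_by_sentence.csv", "sentence length (months)", True),
        ("recidivism_cumulative.csv", "months since release", False),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for ax, (fname, xlabel, as_bar) in zip(axes.ravel(), panels):
        df = pd.read_csv(d / fname)
        x = range(len(df))
        if as_bar:
            ax.bar(x, df["mean"], color="0.4")
            ax.set_xticks(list(x))
            ax.set_xticklabels(df["bin"], rotation=45, fontsize=7)
        else:
            ax.plot(df["bin"], df["mean"], color="0.1")
        ax.plot(x, df["p2.5"], "k--", lw=0.8)
        ax.plot(x, df["p97.5"], "k--", lw=0.8)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("recidivism rate")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bifurcation(sweep: pd.DataFrame, sentence_means: dict, path) -> None:
    """Steady-state prevalence vs sentence length, with scenario means marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep["sentence_months"], 100 * sweep["steady_state_prevalence"],
            color="0.1")
    for name, s in sentence_means.items():
        ax.axvline(s, ls=":", color=_COLORS.get(name, "0.5"), label=f"{name} mean")
    ax.set_xlabel("sentence length (months)")
    ax.set_ylabel("steady-state prevalence (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
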