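"""Diagnostic and report figures: traces, IRR histograms, outcome Q-Q plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy import stats  # noqa: E402

from .mcmc import PosteriorSamples  # noqa: E402
from .model import dispersion_from_moments  # noqa: E402
from .posterior import PosteriorSummary  # noqa: E402


def trace_plot(samples: PosteriorSamples, path, max_params: int = 16) -> None:
    """Per-chain post-warmup trace series, one panel per parameter."""
    pw = samples.post_warmup()
    names = samples.param_names[:max_params]
    n = len(names)
    ncols = 2
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(10, 2.2 * nrows), squeeze=False)
    for j, name in enumerate(names):
        ax = axes[j // ncols][j % ncols]
        for c in range(samples.n_chains):
            ax.plot(pw[c, :, j], lw=0.4, alpha=0.8)
        ax.set_title(name, fontsize=9)
    for j in range(n, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def irr_histogram(summary: PosteriorSummary, path, title: str = "Posterior IRR draws") -> None:
    """Histogram of exponentiated GROUP-coefficient draws with threshold markers."""
    fig, ax = plt.subplots(figsize=(7, 4))
    edges = np.asarray(summary.hist_edges)
    ax.bar(edges[:-1], summary.hist_counts, width=np.diff(edges), align="edge",
           color="#4878b0", edgecolor="white", lw=0.3)
    for t in summary.thresholds:
        ax.axvline(t, color="crimson", ls="--", lw=1)
    ax.set_xlabel("incidence rate ratio")
    ax.set_ylabel("draws")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def qq_plot(values: np.ndarray, path, kind: str = "nb") -> None:
    """Q-Q plot of outcomes against theoretical NB2 (default) or normal quantiles.

    NB2 theoretical quantiles use moment-matched (mu, phi) from the sample;
    if the sample is not over-dispersed the plot falls back to normal
    quantiles with a note in the title.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    title = "Outcome Q-Q plot"
    if kind == "nb":
        mean, sd = values.mean(), values.std(ddof=1)
        try:
            phi = dispersion_from_moments(mean, sd)
            theo = stats.nbinom.ppf(probs, phi, phi / (phi + mean))
            title += " (NB2 quantiles)"
        except ValueError:
            theo = stats.norm.ppf(probs, loc=mean, scale=sd)
            title += " (normal quantiles; sample not over-dispersed)"
    elif kind == "normal":
        theo = stats.norm.ppf(probs, loc=values.mean(), scale=values.std(ddof=1))
        title += " (normal quantiles)"
    else:
        raise ValueError(f"unknown Q-Q kind {kind!r}")
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(theo, values, "o", ms=3, alpha=0.6)
    lims = [min(theo.min(), values.min()), max(theo.max(), values.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("observed g/week")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
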