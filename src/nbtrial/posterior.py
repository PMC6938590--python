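"""Posterior summaries: IRR draws, threshold probabilities, table-shaped output.

The headline Bayesian quantity is the marginal posterior probability that the
incidence rate ratio ``exp(theta_GROUP)`` lies strictly below each of a set
of prespecified thresholds (default 1, 0.96, 0.92), computed by counting
pooled post-warmup draws.  Probabilities are reported as percentages to one
decimal with the raw counts carried alongside, so nothing is lost to
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default IRR thresholds: direction of effect, then two magnitude markers
DEFAULT_THRESHOLDS = (1.0, 0.96, 0.92)


@dataclass
class ThresholdSpec:
    """Strictly decreasing positive IRR thresholds; comparison is strict '<'."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t or any(x <= 0 for x in t) or any(nxt >= prev for prev, nxt in zip(t, t[1:])):
            raise ValueError("thresholds must be positive and strictly decreasing")


@dataclass
class PosteriorSummary:
    """Threshold probabilities plus histogram data for one IRR draw pool."""

    thresholds: tuple[float, ...]
    probabilities: list[float]  # percent, 1 decimal, aligned to thresholds
    counts_below: list[int]
    total_draws: int
    hist_edges: list[float]
    hist_counts: list[int]
    irr_mean: float
    irr_quantiles: dict[str, float]  # supplementary only
    irr_draws: np.ndarray | None = None

    def to_dict(self, include_draws: bool = True) -> dict:
        d = {
            "thresholds": list(self.thresholds),
            "probabilities": self.probabilities,
            "counts_below": self.counts_below,
            "total_draws": self.total_draws,
            "hist_edges": self.hist_edges,
            "hist_counts": self.hist_counts,
            "irr_mean": self.irr_mean,
            "irr_quantiles": self.irr_quantiles,
        }
        if include_draws and self.irr_draws is not None:
            d["irr_draws"] = self.irr_draws.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PosteriorSummary":
        draws = np.asarray(d["irr_draws"]) if "irr_draws" in d else None
        return cls(
            thresholds=tuple(d["thresholds"]),
            probabilities=list(d["probabilities"]),
            counts_below=list(d["counts_below"]),
            total_draws=d["total_draws"],
            hist_edges=list(d["hist_edges"]),
            hist_counts=list(d["hist_counts"]),
            irr_mean=d["irr_mean"],
            irr_quantiles=dict(d["irr_quantiles"]),
            irr_draws=draws,
        )


def irr_draws(pooled: np.ndarray, column_map: list[tuple[str, str]]) -> np.ndarray:
    """Element-wise ``exp`` of the GROUP-coefficient draws from a pooled matrix.

    ``pooled`` has one column per parameter in design order (dispersion last,
    if present); ``column_map`` locates the GROUP column.
    """
    for j, (src, _) in enumerate(column_map):
        if src == "group":
            return np.exp(np.asarray(pooled)[:, j])
    raise KeyError("column_map has no GROUP column")


def threshold_probability(irr: np.ndarray, t: float) -> float:
    """Percent of draws strictly below ``t``, rounded to 1 decimal.

    Ties at the threshold count as not-below.
    """
    irr = np.asarray(irr)
    if irr.size == 0:
        raise ValueError("empty draw vector")
    return round(100.0 * int((irr < t).sum()) / irr.size, 1)


def threshold_counts(irr: np.ndarray, t: float) -> tuple[int, int]:
    """Raw (draws strictly below t, total draws)."""
    irr = np.asarray(irr)
    if irr.size == 0:
        raise ValueError("empty draw vector")
    return int((irr < t).sum()), int(irr.size)


def threshold_table(irr: np.ndarray, spec: ThresholdSpec | None = None,
                    n_bins: int = 50, keep_draws: bool = True) -> PosteriorSummary:
    """One probability per threshold plus histogram data for plotting.

    The histogram uses ``n_bins`` equal-width bins over the central 99.9%
    range of the draws.
    """
    spec = spec or ThresholdSpec()
    irr = np.asarray(irr, dtype=float)
    if irr.size == 0:
        raise ValueError("empty draw vector")
    probs, counts = [], []
    for t in spec.thresholds:
        c, n = threshold_counts(irr, t)
        counts.append(c)
        probs.append(round(100.0 * c / n, 1))
    lo, hi = np.quantile(irr, [0.0005, 0.9995])
    if lo == hi:  # degenerate point-mass pool
        lo, hi = lo - 0.5, hi + 0.5
    hist, edges = np.histogram(irr, bins=n_bins, range=(float(lo), float(hi)))
    qs = np.quantile(irr, [0.025, 0.25, 0.5, 0.75, 0.975])
    return PosteriorSummary(
        thresholds=tuple(spec.thresholds),
        probabilities=probs,
        counts_below=counts,
        total_draws=int(irr.size),
        hist_edges=edges.tolist(),
        hist_counts=hist.tolist(),
        irr_mean=float(irr.mean()),
        irr_quantiles={q: float(v) for q, v in zip(["2.5%", "25%", "50%", "75%", "97.5%"], qs)},
        irr_draws=irr if keep_draws else None,
    )
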