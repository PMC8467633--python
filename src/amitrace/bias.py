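"""Genome-representation biases of a coverage profile.

Two biases dominate MDA-amplified single-cell libraries of AT-rich genomes:

* **GC bias** — the slope of an ordinary least-squares fit of normalized
  coverage on window GC content over the 9-50% GC range the genome spans,
  reported per 10% GC (b_GC);
* **terminal bias** — the under-representation of scaffold ends, summarised
  as the OLS slope of normalized median window coverage on distance from the
  nearer terminus up to 30 kb, reported per 10 kb (b_Ter). The underlying
  relationship is parabolic; the linear slope is the field's summary of it.

The module also provides the depth-compensation arithmetic: normalized
coverage expected at an offset from the reference point when sequencing at a
given extra depth, ``(1 - n_units * slope) * depth_fold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BiasEstimate",
    "InsufficientDataError",
    "bin_by_gc",
    "estimate_gc_bias",
    "terminal_profile_points",
    "estimate_terminal_bias",
    "compensated_coverage",
]


class InsufficientDataError(ValueError):
    """Raised when too few usable points remain for a regression."""


@dataclass(frozen=True)
class BiasEstimate:
    """A fitted bias slope.

    ``slope`` is the change of normalized coverage per 10% GC (kind ``gc``)
    or per 10 kb of distance from the terminus (kind ``terminal``).
    """

    kind: str
    slope: float
    intercept: float
    fit_range: tuple[float, float]
    n_points: int


def bin_by_gc(windows: pd.DataFrame) -> pd.DataFrame:
    """Bin window coverage by integer GC percent.

    Normalization is by the genome-wide mean base coverage (length-weighted
    window mean), so the window-weighted mean of ``normalized_coverage`` is 1.
    GC binning floors to integer percent; empty bins are omitted.
    """
    if len(windows) == 0:
        raise ValueError("empty window table")
    lens = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    cov = windows["coverage"].to_numpy(dtype=float)
    genome_mean = np.average(cov, weights=lens)
    if genome_mean <= 0:
        raise ValueError("degenerate input: genome-wide coverage is zero")
    pct = np.floor(windows["gc"].to_numpy(dtype=float) * 100).astype(int)
    df = pd.DataFrame({"gc_percent": pct, "coverage": cov, "length": lens})
    grouped = df.groupby("gc_percent")
    out = pd.DataFrame(
        {
            "n_windows": grouped.size(),
            "mean_coverage": grouped.apply(
                lambda g: np.average(g["coverage"], weights=g["length"]),
                include_groups=False,
            ),
        }
    ).reset_index()
    out["normalized_coverage"] = out["mean_coverage"] / genome_mean
    return out.sort_values("gc_percent", ignore_index=True)


def estimate_gc_bias(
    bins: pd.DataFrame,
    fit_range: tuple[float, float] = (9.0, 50.0),
    min_bin_windows: int = 10,
) -> BiasEstimate:
    """OLS of normalized coverage on GC percent, slope per 10% GC.

    The fit is restricted to ``fit_range`` (defaults to the 9-50% GC span of
    the genome) and, to limit leverage of sparsely populated composition
    extremes, to bins holding at least ``min_bin_windows`` windows. The
    regression is unweighted: one point per bin.
    """
    lo, hi = fit_range
    sel = bins[
        (bins["gc_percent"] >= lo)
        & (bins["gc_percent"] <= hi)
        & (bins["n_windows"] >= min_bin_windows)
    ]
    if len(sel) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable GC bins in [{lo}, {hi}]%, found {len(sel)}"
        )
    slope_pct, intercept = np.polyfit(
        sel["gc_percent"].to_numpy(float), sel["normalized_coverage"].to_numpy(float), 1
    )
    return BiasEstimate(
        kind="gc",
        slope=float(slope_pct * 10.0),
        intercept=float(intercept),
        fit_range=(float(lo), float(hi)),
        n_points=int(len(sel)),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def terminal_profile_points(
    windows: pd.DataFrame,
    scaffolds,
    span_kb: int = 50,
    window_kb: int = 2,
    step_kb: int = 1,
    min_scaffold_bp: int = 100_000,
) -> pd.DataFrame:
    """Median-coverage points of sliding terminal windows, both ends pooled.

    For each telomere-capped scaffold end, 49 windows of ``window_kb`` kb at
    ``step_kb`` kb steps span the first ``span_kb`` kb; each contributes the
    median base coverage of the window, normalized by the genome-wide median
    base coverage, at a distance equal to the window centre (kb) from the
    nearer terminus. Scaffolds shorter than ``min_scaffold_bp`` are skipped
    with a warning.
    """
    scaf = scaffolds.scaffolds if hasattr(scaffolds, "scaffolds") else scaffolds
    capped = scaf[scaf["telomere_capped"]]
    if len(capped) == 0:
        raise InsufficientDataError("no telomere-capped scaffolds")

    lens = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    genome_median = _weighted_median(windows["coverage"].to_numpy(dtype=float), lens)
    if genome_median <= 0:
        raise ValueError("degenerate input: genome-wide median coverage is zero")

    span = span_kb * 1000
    n_win = (span_kb - window_kb) // step_kb + 1
    rows = []
    for _, s in capped.iterrows():
        L = int(s["length"])
        if L < min_scaffold_bp:
            warnings.warn(
                f"scaffold {s['scaffold_id']} shorter than {min_scaffold_bp} bp; skipped"
            )
            continue
        g = windows[windows["scaffold_id"] == s["scaffold_id"]].sort_values("start")
        base = np.repeat(
            g["coverage"].to_numpy(dtype=float),
            (g["end"] - g["start"]).to_numpy(dtype=int),
        )
        for end_label, arr in (("left", base[:span]), ("right", base[-span:][::-1])):
            for i in range(n_win):
                seg = arr[i * step_kb * 1000 : i * step_kb * 1000 + window_kb * 1000]
                rows.append(
                    {
                        "scaffold_id": s["scaffold_id"],
                        "end": end_label,
                        "distance_kb": i * step_kb + window_kb / 2.0,
                        "median_coverage": float(np.median(seg)),
                    }
                )
    if not rows:
        raise InsufficientDataError("no usable telomere-capped scaffolds")
    out = pd.DataFrame(rows)
    out["normalized_coverage"] = out["median_coverage"] / genome_median
    return out


def estimate_terminal_bias(
    windows: pd.DataFrame,
    scaffolds,
    fit_max_kb: float = 30.0,
    **profile_kwargs,
) -> BiasEstimate:
    """OLS of normalized terminal-window coverage on distance, slope per 10 kb.

    The regression pools both ends of every usable telomere-capped scaffold
    and is restricted to distances up to ``fit_max_kb`` (beyond which the
    coverage recovery plateaus).
    """
    pts = terminal_profile_points(windows, scaffolds, **profile_kwargs)
    sel = pts[pts["distance_kb"] <= fit_max_kb]
    if len(sel) < 3:
        raise InsufficientDataError("fewer than 3 terminal points inside the fit range")
    slope_kb, intercept = np.polyfit(
        sel["distance_kb"].to_numpy(float), sel["normalized_coverage"].to_numpy(float), 1
    )
    return BiasEstimate(
        kind="terminal",
        slope=float(slope_kb * 10.0),
        intercept=float(intercept),
        fit_range=(0.0, float(fit_max_kb)),
        n_points=int(len(sel)),
    )


def compensated_coverage(bias, slope_units: float, depth_fold: float) -> float:
    """Expected normalized coverage after depth compensation.

    ``(1 - slope_units * slope) * depth_fold``, where ``slope_units`` is the
    offset from the reference point expressed in the slope's own units: 2 for
    a point 20 kb inside the 30-kb reduced-representation zone of a terminal
    fit, or 2 for a composition 20% GC below the mean of a GC fit.
    """
    if depth_fold <= 0:
        raise ValueError("depth_fold must be positive")
    slope = bias.slope if isinstance(bias, BiasEstimate) else float(bias)
    return (1.0 - slope_units * slope) * depth_fold
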