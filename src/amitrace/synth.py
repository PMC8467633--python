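"""Synthetic inputs for every downstream stage of the pipeline.

Emulates, without any real sequencing data:

* a fragmented AT-rich somatic genome (mean window GC ~28%, spanning roughly
  9-50%) organised in telomere-capped scaffolds tiled by fixed-size windows;
* per-window read coverage with a tunable positive GC bias and a parabolic
  coverage drop-off towards scaffold termini (the signature biases of
  MDA-based single-cell whole-genome amplification);
* per-IES read-support tables in the ParTIES MIRET column dialect, with
  left/right boundary counts drawn binomially around a true retention level;
* multi-replicate, multi-timepoint cohorts whose hidden true retention levels
  evolve under a chosen assortment model.

All randomness flows from one root seed through per-operation substreams
(see :mod:`amitrace._rng`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from ._rng import substream
from .assort import AssortmentModel, sample_division

__all__ = [
    "ScaffoldSet",
    "IesLocus",
    "CohortDataset",
    "generate_genome",
    "simulate_window_coverage",
    "place_ies_loci",
    "locus_depths",
    "simulate_support_counts",
    "evolve_cohort",
]

#: Truncation range of the window-GC distribution; covers the 9-50% GC span
#: over which the bias regression is fitted.
GC_TRUNCATION = (0.05, 0.55)


@dataclass
class ScaffoldSet:
    """A toy genome: scaffold table plus a gap-free window tiling.

    ``scaffolds`` has columns (scaffold_id, length, telomere_capped);
    ``windows`` has columns (scaffold_id, start, end, gc) with 0-based
    half-open coordinates tiling each scaffold without gaps.
    """

    scaffolds: pd.DataFrame
    windows: pd.DataFrame

    def lengths(self) -> pd.Series:
        return self.scaffolds.set_index("scaffold_id")["length"]


@dataclass(frozen=True)
class IesLocus:
    """One IES insertion point in somatic (IES-free) coordinates."""

    locus_id: str
    scaffold_id: str
    insertion_point: int
    length: int = 50
    gc: float = 0.2


@dataclass
class CohortDataset:
    """Samples x loci support tables with (synthetic-only) hidden truth.

    ``samples``: (sample_id, timepoint, generation); ``support``: long table
    of MIRET-dialect counts keyed by (sample_id, ID); ``truth``: long table
    (sample_id, ID, true_irs) or None for real data.
    """

    samples: pd.DataFrame
    support: pd.DataFrame
    truth: pd.DataFrame | None = None

    def timepoints(self) -> list[str]:
        order = self.samples.sort_values("generation")["timepoint"]
        return list(dict.fromkeys(order))

    def sample_ids(self, timepoint: str | None = None) -> list[str]:
        s = self.samples
        if timepoint is not None:
            s = s[s["timepoint"] == timepoint]
        return list(s["sample_id"])

    def support_for(self, sample_id: str) -> pd.DataFrame:
        return self.support[self.support["sample_id"] == sample_id]

    def truth_wide(self) -> pd.DataFrame | None:
        if self.truth is None:
            return None
        return self.truth.pivot(index=io.ID, columns="sample_id", values="true_irs")


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError("gc_sd too large for a Beta distribution with this mean")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def _draw_truncated_beta(rng, a: float, b: float, n: int, lo: float, hi: float) -> np.ndarray:
    out = rng.beta(a, b, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():  # rejection: resample out-of-range draws
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_genome(
    n_scaffolds: int,
    length_range,
    gc_mean: float = 0.28,
    gc_sd: float = 0.06,
    window: int = 1000,
    seed: int = 0,
    telomere_capped: bool = True,
) -> ScaffoldSet:
    """Generate a window-tiled toy genome with Beta-distributed window GC.

    Parameters
    ----------
    n_scaffolds
        Number of scaffolds.
    length_range
        Either a single length (bases) or a (lo, hi) tuple for uniform
        integer scaffold lengths.
    gc_mean, gc_sd
        Mean and SD of the per-window GC fraction; the Beta distribution is
        re-parameterised from these and truncated to ``GC_TRUNCATION``.
    window
        Window size in bases (>= 100); the last window of a scaffold may be
        shorter so that windows tile exactly.
    """
    if n_scaffolds <= 0:
        raise ValueError("n_scaffolds must be positive")
    if window < 100:
        raise ValueError("window must be >= 100 bases")
    if not (0.0 < gc_mean - 2 * gc_sd and gc_mean + 2 * gc_sd < 1.0):
        raise ValueError("gc_mean +/- 2*gc_sd must lie within (0, 1)")
    if np.isscalar(length_range):
        lo = hi = int(length_range)
    else:
        lo, hi = (int(x) for x in length_range)
    if lo <= 0 or hi < lo:
        raise ValueError("scaffold lengths must be positive with lo <= hi")

    rng = substream(seed, "genome")
    lengths = rng.integers(lo, hi + 1, size=n_scaffolds)
    a, b = _beta_params(gc_mean, gc_sd)

    scaf_rows, win_rows = [], []
    for i, L in enumerate(lengths):
        sid = f"scaffold_{i + 1:04d}"
        scaf_rows.append({"scaffold_id": sid, "length": int(L), "telomere_capped": telomere_capped})
        starts = np.arange(0, L, window)
        ends = np.minimum(starts + window, L)
        gcs = _draw_truncated_beta(rng, a, b, len(starts), *GC_TRUNCATION)
        win_rows.append(
            pd.DataFrame({"scaffold_id": sid, "start": starts, "end": ends, "gc": gcs})
        )
    return ScaffoldSet(
        scaffolds=pd.DataFrame(scaf_rows),
        windows=pd.concat(win_rows, ignore_index=True),
    )


def _terminal_factor(dist_kb: np.ndarray, profile) -> np.ndarray:
    """Parabolic terminal drop-off rising from profile[0] at 1 kb to 1 at plateau."""
    if profile is None:
        return np.ones_like(dist_kb)
    frac_1kb, plateau_kb = profile
    if not (0.0 <= frac_1kb <= 1.0) or plateau_kb <= 1.0:
        raise ValueError("terminal profile must be (fraction at 1 kb in [0,1], plateau > 1 kb)")
    a = (1.0 - frac_1kb) / (plateau_kb - 1.0) ** 2
    f = 1.0 - a * (plateau_kb - dist_kb) ** 2
    return np.where(dist_kb >= plateau_kb, 1.0, np.maximum(f, 0.0))


def simulate_window_coverage(
    scaffolds: ScaffoldSet,
    mean_depth: float = 100.0,
    gc_slope: float = 0.0,
    terminal_profile: tuple[float, float] | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    gc_mean: float | None = None,
) -> pd.DataFrame:
    """Simulate per-window coverage with GC and terminal biases.

    Expected normalized coverage of a window is
    ``(1 + gc_slope * (gc - gc_mean) / 0.10) * terminal_factor(distance)``
    times multiplicative Gamma noise of unit mean and CV ``noise_cv``;
    ``gc_slope`` is on the field's per-10%-GC scale. The terminal factor is
    the stated parabola, applied to telomere-capped scaffolds only, with
    distance measured from the nearer terminus at the window centre.

    Returns a coverage table (scaffold_id, start, end, gc, coverage).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = substream(seed, "coverage")
    w = scaffolds.windows.copy()
    lens = w["end"] - w["start"]
    if gc_mean is None:
        gc_mean = float(np.average(w["gc"], weights=lens))

    expected = 1.0 + gc_slope * (w["gc"].to_numpy() - gc_mean) / 0.10
    expected = np.maximum(expected, 0.0)

    capped = set(
        scaffolds.scaffolds.loc[scaffolds.scaffolds["telomere_capped"], "scaffold_id"]
    )
    if terminal_profile is not None and capped:
        length = scaffolds.lengths()
        centre = (w["start"] + w["end"]).to_numpy() / 2.0
        scaf_len = w["scaffold_id"].map(length).to_numpy(dtype=float)
        dist_kb = np.minimum(centre, scaf_len - centre) / 1000.0
        factor = _terminal_factor(dist_kb, terminal_profile)
        is_capped = w["scaffold_id"].isin(capped).to_numpy()
        expected = np.where(is_capped, expected * factor, expected)

    if noise_cv > 0:
        shape = 1.0 / (noise_cv * noise_cv)
        noise = rng.gamma(shape, 1.0 / shape, size=len(w))
    else:
        noise = 1.0
    w["coverage"] = mean_depth * expected * noise
    return w[["scaffold_id", "start", "end", "gc", "coverage"]]


def place_ies_loci(
    scaffolds: ScaffoldSet,
    n_loci: int,
    seed: int = 0,
    length_range: tuple[int, int] = (26, 150),
    gc: float = 0.2,
) -> list[IesLocus]:
    """Scatter IES insertion points uniformly over the genome.

    Loci are AT-rich and short (default 26-150 bp), sorted by (scaffold,
    position) with unique ids.
    """
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    rng = substream(seed, "loci")
    lens = scaffolds.lengths()
    total = int(lens.sum())
    pos = np.sort(rng.choice(total, size=n_loci, replace=False))
    bounds = np.cumsum(lens.to_numpy())
    scaf_idx = np.searchsorted(bounds, pos, side="right")
    offsets = pos - np.concatenate([[0], bounds[:-1]])[scaf_idx]
    ids = lens.index.to_numpy()
    loci = [
        IesLocus(
            locus_id=f"IES.{i:05d}",
            scaffold_id=str(ids[s]),
            insertion_point=int(o),
            length=int(rng.integers(length_range[0], length_range[1] + 1)),
            gc=gc,
        )
        for i, (s, o) in enumerate(zip(scaf_idx, offsets))
    ]
    return loci


def locus_depths(loci: Sequence[IesLocus], coverage: pd.DataFrame) -> np.ndarray:
    """Mean depth at each locus: the coverage of the window containing it."""
    depths = np.empty(len(loci))
    by_scaf = {sid: g.sort_values("start") for sid, g in coverage.groupby("scaffold_id")}
    for i, l in enumerate(loci):
        g = by_scaf[l.scaffold_id]
        idx = np.searchsorted(g["start"].to_numpy(), l.insertion_point, side="right") - 1
        depths[i] = g["coverage"].iloc[idx]
    return depths


def _locus_ids(loci) -> list[str]:
    return [l.locus_id if isinstance(l, IesLocus) else str(l) for l in loci]


def _draw_support(
    rng: np.random.Generator,
    ids: list[str],
    true_irs: np.ndarray,
    depth: np.ndarray,
    discordance: float = 0.0,
    poisson_depth: bool = True,
) -> pd.DataFrame:
    p_left = np.clip(true_irs + discordance / 2.0, 0.0, 1.0)
    p_right = np.clip(true_irs - discordance / 2.0, 0.0, 1.0)
    if poisson_depth:
        d_left = rng.poisson(depth / 2.0)
        d_right = rng.poisson(depth / 2.0)
    else:
        d = np.asarray(np.round(depth), dtype=np.int64)
        d_left = d // 2
        d_right = d - d_left
    left = rng.binomial(d_left, p_left)
    right = rng.binomial(d_right, p_right)
    mac_left = d_left - left
    mac_right = d_right - right
    return pd.DataFrame(
        {
            io.ID: ids,
            io.SUPPORT_MAC: mac_left + mac_right,
            io.SUPPORT_LEFT: left,
            io.SUPPORT_RIGHT: right,
            io.SUPPORT_MAC_LEFT: mac_left,
            io.SUPPORT_MAC_RIGHT: mac_right,
        }
    )


def simulate_support_counts(
    loci,
    true_irs,
    locus_depth,
    seed: int = 0,
    discordance: float = 0.0,
    poisson_depth: bool = True,
) -> pd.DataFrame:
    """Draw a MIRET-dialect support table around true retention levels.

    Retention-supporting reads at each boundary are binomial with probability
    ``true_irs`` (optionally offset by ``+/- discordance/2`` to emulate
    differential boundary usage); excision reads make up the remainder.
    Per-locus read totals are split between boundaries, Poisson-distributed
    around ``locus_depth/2`` by default.
    """
    ids = _locus_ids(loci)
    true_irs = np.broadcast_to(np.asarray(true_irs, dtype=float), (len(ids),)).copy()
    if np.any((true_irs < 0) | (true_irs > 1)):
        raise ValueError("true_irs must lie in [0, 1]")
    depth = np.broadcast_to(np.asarray(locus_depth, dtype=float), (len(ids),)).copy()
    if np.any(depth < 0):
        raise ValueError("locus_depth must be non-negative")
    rng = substream(seed, "counts")
    return _draw_support(rng, ids, true_irs, depth, discordance, poisson_depth)


def evolve_cohort(
    model: AssortmentModel,
    irs0,
    schedule: Sequence[int],
    n_replicates: int,
    depth_model: float = 100.0,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    loci=None,
    discordance: float = 0.0,
) -> CohortDataset:
    """Evolve replicate lineages under an assortment model and sample reads.

    Each replicate is a lineage whose integer IES+ copy state per locus is
    iterated through the model's single-division kernel; the same lineage is
    observed at every timepoint of ``schedule`` (generations, non-decreasing),
    emulating a daily re-isolation time course. At each observation a support
    table is drawn via the binomial read model at mean depth ``depth_model``.
    The hidden truth (copy fraction) is retained per sample and locus.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must name at least one timepoint")
    schedule = [int(g) for g in schedule]
    if any(g < 0 for g in schedule) or any(
        b < a for a, b in zip(schedule, schedule[1:])
    ):
        raise ValueError("schedule must be non-negative and non-decreasing")
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    irs0 = np.atleast_1d(np.asarray(irs0, dtype=float))
    if np.any((irs0 < 0) | (irs0 > 1)):
        raise ValueError("irs0 must lie in [0, 1]")
    if labels is None:
        labels = [f"t{i}" for i in range(len(schedule))]
    if len(labels) != len(schedule):
        raise ValueError("labels must match schedule length")
    ids = _locus_ids(loci) if loci is not None else [f"IES.{i:05d}" for i in range(len(irs0))]
    if len(ids) != len(irs0):
        raise ValueError("loci and irs0 lengths differ")

    rng = substream(seed, "cohort")
    k = model.ploidy_k
    states = np.tile(np.round(irs0 * k).astype(np.int64), (n_replicates, 1))

    samples, support_parts, truth_parts = [], [], []
    g_prev = 0
    for label, g in zip(labels, schedule):
        for _ in range(g - g_prev):
            states = sample_division(model, states.ravel(), rng).reshape(states.shape)
        g_prev = g
        for r in range(n_replicates):
            sample_id = f"{label}_r{r + 1}"
            truth = states[r] / k
            samples.append({"sample_id": sample_id, "timepoint": label, "generation": g})
            sup = _draw_support(
                rng, ids, truth, np.full(len(ids), float(depth_model)), discordance
            )
            sup.insert(0, "sample_id", sample_id)
            support_parts.append(sup)
            truth_parts.append(
                pd.DataFrame({"sample_id": sample_id, io.ID: ids, "true_irs": truth})
            )
    return CohortDataset(
        samples=pd.DataFrame(samples),
        support=pd.concat(support_parts, ignore_index=True),
        truth=pd.concat(truth_parts, ignore_index=True),
    )
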