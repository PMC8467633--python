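"""Tracking retention-level drift against model-based confidence bands.

From a multi-timepoint cohort the module selects a "track set" of loci that
are well measured in every sample (IRS above a floor, coverage above a read
floor), takes the replicate-mean retention at the first timepoint as the
starting level IRS0, and builds a 95% confidence band IRS0 +/- 2 sigma
around it, with sigma the analytic assortment SD for the elapsed
generations. Observed later-timepoint retention values are then scored
against the band, and replicate dispersion (SD_IRS) is compared between
timepoints and against the measurement-error distribution with one-sided
rank tests (signed-rank when paired, rank-sum otherwise), effect size
r = |Z|/sqrt(N), and BH adjustment across the comparisons performed.

The band deliberately contains only assortment drift — measurement error is
quantified separately by the retention module's error model — so empirical
coverage below the nominal 95% is itself informative.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import io, retention
from .assort import AssortmentModel, sigma_analytic
from .synth import CohortDataset

__all__ = [
    "TrackSet",
    "RankTestResult",
    "select_track_set",
    "construct_ci",
    "within_ci_fraction",
    "dispersion_stats",
    "compare_dispersion",
    "dispersion_comparisons",
]


@dataclass
class TrackSet:
    """Loci tracked across the time course with their starting levels."""

    locus_ids: list[str]
    irs0: pd.Series  # indexed by locus_id
    n_samples_required: int
    timepoint: str


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    effect_size_r: float
    n: int


def _irs_matrix(cohort: CohortDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled IRS and coverage matrices (loci x samples) from the support table."""
    scores = []
    for sid in cohort.sample_ids():
        rec = retention.score_table(cohort.support_for(sid))
        rec["sample_id"] = sid
        scores.append(rec)
    long = pd.concat(scores, ignore_index=True)
    irs = long.pivot(index="locus_id", columns="sample_id", values="irs")
    cov = long.pivot(index="locus_id", columns="sample_id", values="coverage")
    return irs, cov


def select_track_set(
    cohort: CohortDataset,
    min_irs: float = 0.1,
    min_reads: int = 20,
    timepoint: str | None = None,
) -> TrackSet:
    """Select loci with IRS > ``min_irs`` and coverage > ``min_reads`` in
    every sample of the cohort (both thresholds strict), and set IRS0 as the
    mean pooled IRS across the replicates of ``timepoint`` (default: the
    earliest timepoint).
    """
    if timepoint is None:
        timepoint = cohort.timepoints()[0]
    if timepoint not in cohort.timepoints():
        raise ValueError(f"unknown timepoint {timepoint!r}")
    irs, cov = _irs_matrix(cohort)
    ok = ((irs > min_irs) & (cov > min_reads)).all(axis=1)
    kept = irs.index[ok]
    if len(kept) == 0:
        warnings.warn("track set is empty under the given thresholds")
    first = cohort.sample_ids(timepoint)
    irs0 = irs.loc[kept, first].mean(axis=1)
    irs0.name = "irs0"
    return TrackSet(
        locus_ids=list(kept),
        irs0=irs0,
        n_samples_required=len(cohort.sample_ids()),
        timepoint=timepoint,
    )


def construct_ci(
    track: TrackSet, model: AssortmentModel, delta_generations: int
) -> pd.DataFrame:
    """95% band IRS0 +/- 2 sigma(IRS0, delta_generations), clamped to [0, 1]."""
    if delta_generations <= 0:
        raise ValueError("delta_generations must be positive")
    irs0 = track.irs0.to_numpy(dtype=float)
    sigma = sigma_analytic(model, irs0, delta_generations)
    return pd.DataFrame(
        {
            "locus_id": track.irs0.index,
            "irs0": irs0,
            "delta_generations": int(delta_generations),
            "sigma": sigma,
            "lo": np.clip(irs0 - 2 * sigma, 0.0, 1.0),
            "hi": np.clip(irs0 + 2 * sigma, 0.0, 1.0),
        }
    )


def within_ci_fraction(
    cohort: CohortDataset, cis: pd.DataFrame, timepoint: str
) -> tuple[float, pd.DataFrame]:
    """Fraction of (locus x replicate) observations inside their CI at a timepoint.

    Missing observations are excluded from the denominator with a warning.
    Returns the fraction and a per-observation flag table.
    """
    irs, _ = _irs_matrix(cohort)
    samples = cohort.sample_ids(timepoint)
    if not samples:
        raise ValueError(f"no samples at timepoint {timepoint!r}")
    ci = cis.set_index("locus_id")
    rows = []
    n_missing = 0
    for lid in ci.index:
        lo, hi = ci.at[lid, "lo"], ci.at[lid, "hi"]
        for sid in samples:
            val = irs.at[lid, sid] if lid in irs.index else np.nan
            if np.isnan(val):
                n_missing += 1
                continue
            rows.append(
                {
                    "locus_id": lid,
                    "sample_id": sid,
                    "irs": float(val),
                    "inside": bool(lo <= val <= hi),
                }
            )
    if n_missing:
        warnings.warn(f"{n_missing} missing observations excluded from the denominator")
    flags = pd.DataFrame(rows, columns=["locus_id", "sample_id", "irs", "inside"])
    frac = float(flags["inside"].mean()) if len(flags) else np.nan
    return frac, flags


def dispersion_stats(
    cohort: CohortDataset, track: TrackSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate SD of IRS per locus per timepoint, and pairwise SD ratios.

    The SD uses the n-1 denominator across the replicates of a timepoint.
    Ratios (later/earlier) are computed for every ordered timepoint pair on
    loci whose denominator SD is nonzero; others are dropped from that ratio.
    """
    irs, _ = _irs_matrix(cohort)
    if track is not None:
        irs = irs.loc[[l for l in track.locus_ids if l in irs.index]]
    tps = cohort.timepoints()
    sd = pd.DataFrame(index=irs.index)
    for tp in tps:
        cols = cohort.sample_ids(tp)
        if len(cols) < 2:
            raise ValueError(f"timepoint {tp!r} needs >= 2 replicates for an SD")
        sd[tp] = irs[cols].std(axis=1, ddof=1)
    ratio_rows = []
    for early, late in itertools.combinations(tps, 2):
        denom_ok = sd[early] > 0
        for lid in sd.index[denom_ok]:
            ratio_rows.append(
                {
                    "pair": f"{late}/{early}",
                    "locus_id": lid,
                    "ratio": sd.at[lid, late] / sd.at[lid, early],
                }
            )
    return sd, pd.DataFrame(ratio_rows, columns=["pair", "locus_id", "ratio"])


def compare_dispersion(a, b, paired: bool = True) -> RankTestResult:
    """One-sided rank test of H1: sample ``b`` is stochastically larger than ``a``.

    Paired comparisons use the Wilcoxon signed-rank test on aligned loci,
    unpaired ones the rank-sum (Mann-Whitney) test; both report the
    normal-approximation Z and effect size r = |Z|/sqrt(N).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must be aligned on the same loci")
        n = len(a)
        if n < 5:
            warnings.warn("fewer than 5 pairs: rank test is underpowered")
        diffs = b - a
        if np.all(diffs == 0):
            return RankTestResult(statistic=0.0, p_value=1.0, effect_size_r=0.0, n=n)
        res = stats.wilcoxon(b, a, alternative="greater", method="approx")
        z = float(res.zstatistic)
        return RankTestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            effect_size_r=abs(z) / np.sqrt(n),
            n=n,
        )
    n1, n2 = len(b), len(a)
    if min(n1, n2) < 5:
        warnings.warn("fewer than 5 observations in a group: rank test is underpowered")
    res = stats.mannwhitneyu(b, a, alternative="greater")
    u = float(res.statistic)
    mu = n1 * n2 / 2.0
    # tie-corrected normal approximation for the effect size
    pooled = np.concatenate([b, a])
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma_u = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (u - mu) / sigma_u if sigma_u > 0 else 0.0
    return RankTestResult(
        statistic=u,
        p_value=float(res.pvalue),
        effect_size_r=abs(z) / np.sqrt(n),
        n=n,
    )


def dispersion_comparisons(
    sd: pd.DataFrame, pairs=None, paired: bool = True
) -> pd.DataFrame:
    """Run :func:`compare_dispersion` over timepoint pairs with BH adjustment.

    ``pairs`` defaults to every ordered (earlier, later) column pair of the
    SD table; each test asks whether the later timepoint's dispersion is
    stochastically larger.
    """
    if pairs is None:
        pairs = list(itertools.combinations(sd.columns, 2))
    rows = []
    for early, late in pairs:
        res = compare_dispersion(sd[early].to_numpy(), sd[late].to_numpy(), paired=paired)
        rows.append(
            {
                "comparison": f"{late} vs {early}",
                "statistic": res.statistic,
                "p_value": res.p_value,
                "effect_size_r": res.effect_size_r,
                "n": res.n,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = retention.bh_adjust(out["p_value"])
    return out
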