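"""IES retention scores, the filter cascade, and the measurement-error model.

The retention score (IRS) of a locus is the fraction of somatic genome
copies that retain the IES, estimated as IES+ reads over IES+ plus IES-
reads. Boundary scores are computed separately at the left and right IES
junctions; their mean (bIRS), two-value sample SD (SD_bIRS = |l - r|/sqrt(2))
and coefficient of variation (CV = SD_bIRS/bIRS) quantify the random
measurement error of a single sample's estimate.

A support row carries SUPPORT_LEFT / SUPPORT_RIGHT retention reads and
excision reads. Real MIRET tables expose a single shared SUPPORT_MAC count
(reads crossing the excised junction support excision at both boundaries);
per-boundary excision counts SUPPORT_MAC_LEFT / SUPPORT_MAC_RIGHT are used
when present, falling back to the shared column otherwise.

The error-set filter cascade removes loci with
(1) coverage below 20 reads, (2) both boundary scores below 0.1,
(3) exactly identical boundary scores (short IESs whose boundaries are
spanned by the same reads), and (4) significantly discordant boundaries
(exact binomial test, Benjamini-Hochberg adjusted p below alpha), which
flags rare differential usage of IES boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from . import io

__all__ = [
    "IesSupport",
    "RetentionRecord",
    "compute_irs",
    "score_table",
    "bh_adjust",
    "boundary_discordance_test",
    "filter_error_set",
    "error_distribution",
]


@dataclass(frozen=True)
class IesSupport:
    """Read support at one IES locus (MIRET dialect)."""

    locus_id: str
    support_mac: int
    support_left: int
    support_right: int
    support_mac_left: int | None = None
    support_mac_right: int | None = None

    def mac_left(self) -> int:
        return self.support_mac if self.support_mac_left is None else self.support_mac_left

    def mac_right(self) -> int:
        return self.support_mac if self.support_mac_right is None else self.support_mac_right


@dataclass(frozen=True)
class RetentionRecord:
    locus_id: str
    irs: float
    irs_left: float
    irs_right: float
    b_irs: float
    sd_birs: float
    cv: float  # NaN when b_irs == 0
    coverage: int


def compute_irs(support: IesSupport) -> RetentionRecord:
    """Score a single locus.

    Pooled IRS uses both boundaries' retention reads over all reads informing
    either boundary; boundary scores divide each side's retention reads by
    that side's total. The SD of the two boundary scores uses the two-value
    sample formula |l - r|/sqrt(2).
    """
    left, right = support.support_left, support.support_right
    ml, mr = support.mac_left(), support.mac_right()
    if min(left, right, ml, mr) < 0:
        raise ValueError("read counts must be non-negative")
    total = left + right + ml + mr
    if total <= 0:
        raise ValueError(f"locus {support.locus_id!r}: no reads, score undefined")
    irs = (left + right) / total
    irs_left = left / (left + ml) if left + ml > 0 else math.nan
    irs_right = right / (right + mr) if right + mr > 0 else math.nan
    b = (irs_left + irs_right) / 2.0
    sd = abs(irs_left - irs_right) / math.sqrt(2.0)
    cv = sd / b if b > 0 else math.nan
    coverage = support.support_mac + left + right
    return RetentionRecord(
        locus_id=support.locus_id,
        irs=irs,
        irs_left=irs_left,
        irs_right=irs_right,
        b_irs=b,
        sd_birs=sd,
        cv=cv,
        coverage=int(coverage),
    )


def _boundary_counts(df: pd.DataFrame):
    left = df[io.SUPPORT_LEFT].to_numpy(dtype=float)
    right = df[io.SUPPORT_RIGHT].to_numpy(dtype=float)
    mac = df[io.SUPPORT_MAC].to_numpy(dtype=float)
    ml = df[io.SUPPORT_MAC_LEFT].to_numpy(dtype=float) if io.SUPPORT_MAC_LEFT in df else mac
    mr = df[io.SUPPORT_MAC_RIGHT].to_numpy(dtype=float) if io.SUPPORT_MAC_RIGHT in df else mac
    return left, right, ml, mr, mac


def score_table(support: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`compute_irs` over a support table.

    Loci with zero total reads get NaN scores (they are dropout, not errors,
    at table scale).
    """
    left, right, ml, mr, mac = _boundary_counts(support)
    total = left + right + ml + mr
    with np.errstate(divide="ignore", invalid="ignore"):
        irs = np.where(total > 0, (left + right) / total, np.nan)
        irs_left = np.where(left + ml > 0, left / (left + ml), np.nan)
        irs_right = np.where(right + mr > 0, right / (right + mr), np.nan)
    b = (irs_left + irs_right) / 2.0
    sd = np.abs(irs_left - irs_right) / math.sqrt(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(b > 0, sd / b, np.nan)
    return pd.DataFrame(
        {
            "locus_id": support[io.ID].to_numpy(),
            "irs": irs,
            "irs_left": irs_left,
            "irs_right": irs_right,
            "b_irs": b,
            "sd_birs": sd,
            "cv": cv,
            "coverage": (mac + left + right).astype(int),
        }
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def boundary_discordance_test(support: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Exact binomial test of left-boundary retention against the right score.

    Left IES+ reads among the left boundary's total are tested against a
    success probability equal to the right boundary score (two-sided). When
    the right score is degenerate (0 or 1) but the left is not, the roles
    are swapped; when both are degenerate the locus is flagged untestable.
    P values are BH-adjusted across the testable loci; ``discordant`` marks
    adjusted p < ``alpha``.
    """
    left, right, ml, mr, _ = _boundary_counts(support)
    n_left, n_right = left + ml, right + mr
    ids = support[io.ID].to_numpy()
    pvals = np.full(len(ids), np.nan)
    untestable = np.zeros(len(ids), dtype=bool)
    for i in range(len(ids)):
        if n_left[i] < 1 or n_right[i] < 1:
            untestable[i] = True
            continue
        s_left = left[i] / n_left[i]
        s_right = right[i] / n_right[i]
        if 0.0 < s_right < 1.0:
            k, n, p0 = int(left[i]), int(n_left[i]), s_right
        elif 0.0 < s_left < 1.0:
            k, n, p0 = int(right[i]), int(n_right[i]), s_left
        else:
            untestable[i] = True
            continue
        pvals[i] = binomtest(k, n, p0).pvalue
    padj = np.full(len(ids), np.nan)
    testable = ~np.isnan(pvals)
    if testable.any():
        padj[testable] = bh_adjust(pvals[testable])
    return pd.DataFrame(
        {
            "locus_id": ids,
            "p_value": pvals,
            "p_adj": padj,
            "discordant": np.where(testable, padj < alpha, False),
            "untestable": untestable,
        }
    )


def filter_error_set(
    records: pd.DataFrame,
    support: pd.DataFrame | None = None,
    min_reads: int = 20,
    min_score: float = 0.1,
    alpha: float = 0.05,
    test_discordance: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four-rule filter cascade; return (filtered records, removal log).

    Rules 1-3 (low coverage, both boundary scores below ``min_score``,
    exactly identical boundary scores) are set intersections and
    order-independent; the discordance test (rule 4) runs on the loci that
    survive them, with BH adjustment across those tested. The removal log
    lists one row per (locus, rule) with reason codes ``low_coverage``,
    ``low_score``, ``identical_boundaries``, ``discordant``.
    """
    rec = records.set_index("locus_id", drop=False)
    low_cov = rec["coverage"] < min_reads
    low_score = (rec["irs_left"] < min_score) & (rec["irs_right"] < min_score)
    identical = (
        rec["irs_left"].notna() & (rec["irs_left"] == rec["irs_right"])
    )
    log_rows = []
    for rule, mask in (
        ("low_coverage", low_cov),
        ("low_score", low_score),
        ("identical_boundaries", identical),
    ):
        for lid in rec.index[mask.fillna(False)]:
            log_rows.append({"locus_id": lid, "rule": rule})
    removed = low_cov.fillna(False) | low_score.fillna(False) | identical

    surviving = rec.index[~removed]
    if test_discordance and len(surviving) > 0:
        if support is None:
            raise ValueError("support table required for the discordance test")
        sup = support[support[io.ID].isin(surviving)]
        disc = boundary_discordance_test(sup, alpha=alpha)
        flagged = disc.loc[disc["discordant"], "locus_id"]
        for lid in flagged:
            log_rows.append({"locus_id": lid, "rule": "discordant"})
            removed.loc[lid] = True
    filtered = rec.loc[~removed].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["locus_id", "rule"])
    return filtered, log


def error_distribution(records: pd.DataFrame) -> pd.DataFrame:
    """Per-locus random-error table (b_irs, sd_birs, cv) of a filtered set.

    ``cv`` is the relative random error of the retention estimate; ``sd_birs``
    is the absolute error used for comparison against observed dispersion.
    """
    if len(records) == 0:
        raise ValueError("filtered record set is empty")
    return records[["locus_id", "b_irs", "sd_birs", "cv"]].reset_index(drop=True)
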