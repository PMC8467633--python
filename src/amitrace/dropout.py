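"""IES locus dropout: detection, decomposition and count correction.

A locus "drops out" when its read coverage (sum of the three MIRET support
columns) is at or below a threshold — 20 reads by default, the minimum for a
robust retention estimate. Total dropout decomposes additively into a
terminal component (loci within 30 kb of a scaffold end, where MDA coverage
collapses), a residual component unrelated to amplification (scaled from a
bulk reference by the ratio of mapped read pairs), and a GC component
defined as the remainder, clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io

__all__ = [
    "DropoutReport",
    "DropoutFlags",
    "flag_dropout",
    "decompose_dropout",
    "correct_count",
    "count_zscore",
]

TERMINAL_ZONE_BP = 30_000


@dataclass(frozen=True)
class DropoutReport:
    """Additive decomposition of the total dropout fraction."""

    total: float
    terminal: float
    gc: float
    residual: float
    mapped_ratio: float | None = None


@dataclass
class DropoutFlags:
    """Per-locus dropout calls plus the summary fractions."""

    flags: pd.Series  # bool, indexed by locus ID
    total: float
    terminal: float | None = None


def flag_dropout(
    support: pd.DataFrame,
    threshold: int = 20,
    loci=None,
    scaffold_lengths=None,
    terminal_zone_bp: int = TERMINAL_ZONE_BP,
) -> DropoutFlags:
    """Call dropout per locus: coverage <= ``threshold`` reads.

    Coverage is SUPPORT_MAC + SUPPORT_LEFT + SUPPORT_RIGHT. When ``loci``
    (IesLocus sequence) is given, the terminal-zone dropout fraction — the
    fraction of loci lying within ``terminal_zone_bp`` of either scaffold
    end that drop out — is reported too; this requires ``scaffold_lengths``
    (mapping scaffold_id -> length).
    """
    if len(support) == 0:
        raise ValueError("empty support table")
    cov = (
        support[io.SUPPORT_MAC] + support[io.SUPPORT_LEFT] + support[io.SUPPORT_RIGHT]
    )
    flags = pd.Series((cov <= threshold).to_numpy(), index=support[io.ID].to_numpy())
    total = float(flags.mean())

    terminal = None
    if loci is not None:
        if scaffold_lengths is None:
            raise ValueError("scaffold_lengths required to compute the terminal fraction")
        lengths = dict(scaffold_lengths)
        is_term = {}
        for l in loci:
            try:
                L = lengths[l.scaffold_id]
            except KeyError:
                raise ValueError(f"missing length for scaffold {l.scaffold_id!r}")
            pt = l.insertion_point
            is_term[l.locus_id] = pt < terminal_zone_bp or L - pt <= terminal_zone_bp
        term_ids = [i for i, t in is_term.items() if t and i in flags.index]
        terminal = float(flags.loc[term_ids].mean()) if term_ids else 0.0
    return DropoutFlags(flags=flags, total=total, terminal=terminal)


def decompose_dropout(
    total: float,
    terminal: float,
    residual_reference: float,
    mapped_ratio: float = 1.0,
) -> DropoutReport:
    """Decompose total dropout into terminal, residual and GC components.

    ``residual = residual_reference / mapped_ratio`` (the bulk reference's
    residual dropout scaled by the single-cell/bulk ratio of mapped read
    pairs) and ``gc = max(0, total - terminal - residual)``: the dropout
    unexplained by position or mapping depth is attributed to the positive
    GC bias, clamped at zero because components are fractions of loci.
    """
    if mapped_ratio <= 0:
        raise ValueError("mapped_ratio must be positive")
    for name, v in (("total", total), ("terminal", terminal), ("residual_reference", residual_reference)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    residual = residual_reference / mapped_ratio
    gc = max(0.0, total - (terminal + residual))
    return DropoutReport(
        total=float(total),
        terminal=float(terminal),
        gc=float(gc),
        residual=float(residual),
        mapped_ratio=float(mapped_ratio),
    )


def correct_count(observed: float, total_dropout: float) -> float:
    """Correct an observed somatic-IES count for dropout: n / (1 - dropout)."""
    if not 0.0 <= total_dropout < 1.0:
        raise ValueError("total_dropout must lie in [0, 1)")
    return float(observed) / (1.0 - total_dropout)


def count_zscore(count: float, reference: float, sd: float) -> float:
    """Standard score of a somatic-IES count against a reference: (n - ref)/sd."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return (float(count) - float(reference)) / float(sd)
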