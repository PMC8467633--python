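"""Plain-text readers and writers for the package's table formats.

Formats follow the field's conventions: window coverage tables are
bedgraph-compatible TSVs (scaffold, start, end, coverage, + gc), IES support
tables use the ParTIES MIRET column dialect (ID, SUPPORT_MAC, SUPPORT_LEFT,
SUPPORT_RIGHT, optionally per-boundary SUPPORT_MAC_LEFT/RIGHT), IES
annotations are 0-based half-open BED, and cohort truth is a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

#: MIRET-dialect support table columns.
ID = "ID"
SUPPORT_MAC = "SUPPORT_MAC"
SUPPORT_LEFT = "SUPPORT_LEFT"
SUPPORT_RIGHT = "SUPPORT_RIGHT"
SUPPORT_MAC_LEFT = "SUPPORT_MAC_LEFT"
SUPPORT_MAC_RIGHT = "SUPPORT_MAC_RIGHT"
SUPPORT_COLUMNS = [ID, SUPPORT_MAC, SUPPORT_LEFT, SUPPORT_RIGHT]

COVERAGE_COLUMNS = ["scaffold_id", "start", "end", "coverage", "gc"]


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_coverage(path) -> pd.DataFrame:
    """Read a window coverage TSV (scaffold_id, start, end, coverage[, gc])."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    return df


def write_coverage(df: pd.DataFrame, path) -> None:
    cols = [c for c in COVERAGE_COLUMNS if c in df.columns]
    write_tsv(df[cols], path)


def read_support(path) -> pd.DataFrame:
    """Read a MIRET-dialect support table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SUPPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"support table missing columns: {sorted(missing)}")
    return df


def write_support(df: pd.DataFrame, path) -> None:
    write_tsv(df, path)


def read_scaffolds(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"scaffold_id", "length"} - set(df.columns)
    if missing:
        raise ValueError(f"scaffold table missing columns: {sorted(missing)}")
    if "telomere_capped" not in df.columns:
        df["telomere_capped"] = True
    return df


def write_bed(loci, path) -> None:
    """Write IES loci as 0-based half-open BED (insertion point, 1 bp)."""
    rows = [
        {
            "chrom": l.scaffold_id,
            "start": int(l.insertion_point),
            "end": int(l.insertion_point) + 1,
            "name": l.locus_id,
        }
        for l in loci
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_fasta(scaffold_set, path, seed: int = 0) -> None:
    """Emit a toy FASTA whose per-window base composition matches window GC."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from ._rng import substream

    rng = substream(seed, "sequence")
    records = []
    for sid, grp in scaffold_set.windows.groupby("scaffold_id", sort=False):
        parts = []
        for _, w in grp.iterrows():
            n = int(w.end - w.start)
            gc = float(w.gc)
            p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
            parts.append("".join(rng.choice(list("GCAT"), size=n, p=p)))
        records.append(SeqRecord(Seq("".join(parts)), id=str(sid), description=""))
    SeqIO.write(records, str(path), "fasta")


def write_cohort(cohort, directory) -> None:
    """Write a cohort as samples.tsv + support.tsv + truth.json sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_tsv(cohort.samples, d / "samples.tsv")
    write_tsv(cohort.support, d / "support.tsv")
    if cohort.truth is not None:
        truth = {
            sid: dict(zip(grp[ID], grp["true_irs"]))
            for sid, grp in cohort.truth.groupby("sample_id", sort=False)
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(directory):
    from .synth import CohortDataset

    d = Path(directory)
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    support = read_support(d / "support.tsv")
    truth = None
    tj = d / "truth.json"
    if tj.exists():
        raw = json.loads(tj.read_text())
        truth = pd.DataFrame(
            [
                {"sample_id": sid, ID: locus, "true_irs": v}
                for sid, loci in raw.items()
                for locus, v in loci.items()
            ]
        )
    return CohortDataset(samples=samples, support=support, truth=truth)
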