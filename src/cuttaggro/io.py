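"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython; BED and the tabular formats are pandas
DataFrames with fixed column contracts. All interval output is BED (0-based,
half-open); all tables are TSV with headers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .motifs import MicrosatelliteLocus, ResponseElement

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA (wrapped or unwrapped) -> {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed6(path: str | Path) -> pd.DataFrame:
    """BED with >= 3 columns -> DataFrame with BED6 columns (defaults filled).

    Malformed lines are reported with their 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "0"
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}: line {lineno}: invalid strand {strand!r}")
            rows.append((fields[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


def intervals_to_bed(
    intervals: Iterable[GenomicInterval],
    names: Iterable[str] | None = None,
    scores: Iterable[int] | None = None,
) -> pd.DataFrame:
    ivs = list(intervals)
    names = list(names) if names is not None else ["."] * len(ivs)
    scores = list(scores) if scores is not None else [0] * len(ivs)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
            "name": names,
            "score": scores,
            "strand": [iv.strand for iv in ivs],
        }
    )


def elements_to_bed(elements: Sequence[ResponseElement]) -> pd.DataFrame:
    """Response elements -> BED6 (name = element class, score = unit_count*100
    for microsatellites, 0 otherwise), sorted by (chrom, start)."""
    rows = []
    for el in elements:
        iv = el.interval
        score = el.site.unit_count * 100 if isinstance(el.site, MicrosatelliteLocus) else 0
        rows.append((iv.chrom, iv.start, iv.end, el.element_class, score, iv.strand))
    df = pd.DataFrame(rows, columns=BED6_COLUMNS)
    return df.sort_values(["chrom", "start", "end", "name"], kind="mergesort").reset_index(drop=True)


def bed_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples(index=False)
    ]


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", **kwargs)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Sample manifest: TSV with columns sample_id, condition, replicate, path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "condition", "replicate", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df
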