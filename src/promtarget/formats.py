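"""Readers and writers for the on-disk dialects.

Promoters travel as BED6 TSS records (the feature is the 1-bp TSS, the
score column holds the annotated TSS count, and the promoter interval is
re-derived strand-aware on read). Probes, log-ratios and expression
matrices are plain TSV. Peak sequences are FASTA. Everything is 0-based
half-open on disk and in memory.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DEFAULT_DOWNSTREAM,
    DEFAULT_UPSTREAM,
    PROBE_LENGTH_BOUNDS,
    ParseError,
    PromoterModel,
    TilingProbe,
    ValidationError,
)

logger = logging.getLogger("promtarget")

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "promoter_id", "is_control"]


# ---------------------------------------------------------------------------
# promoters

def read_promoters(
    path: str | Path,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[PromoterModel]:
    """Read TSS BED6 records and derive promoter intervals.

    Each line is ``chrom  tss  tss+1  gene_id  n_tss  strand``. Duplicate
    gene ids are rejected; an empty file yields an empty list with a
    logged warning.
    """
    promoters: list[PromoterModel] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
            chrom, start_s, end_s, gene_id, n_tss_s, strand = fields[:6]
            try:
                tss = int(start_s)
                end = int(end_s)
                n_tss = int(n_tss_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate ({exc})") from None
            if end != tss + 1:
                raise ParseError(f"{path}:{lineno}: TSS record must span exactly 1 bp")
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            promoters.append(
                PromoterModel.from_tss(gene_id, chrom, strand, tss, upstream, downstream, n_tss)
            )
    if not promoters:
        logger.warning("no promoter records in %s", path)
    return promoters


def write_promoters(promoters: Iterable[PromoterModel], path: str | Path) -> None:
    """Write promoters as 1-bp TSS BED6 records (inverse of read_promoters)."""
    with open(path, "w") as handle:
        for p in promoters:
            handle.write(f"{p.chrom}\t{p.tss}\t{p.tss + 1}\t{p.gene_id}\t{p.n_tss}\t{p.strand}\n")


# ---------------------------------------------------------------------------
# probes

def read_probe_table(
    path: str | Path,
    promoters: Sequence[PromoterModel] | None = None,
    length_bounds: tuple[int, int] = PROBE_LENGTH_BOUNDS,
) -> list[TilingProbe]:
    """Read the probe TSV, validate lengths/assignments, sort by (chrom, start)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "promoter_id": str})
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    known = {p.gene_id for p in promoters} if promoters is not None else None
    lo, hi = length_bounds
    probes: list[TilingProbe] = []
    for row in df.itertuples(index=False):
        is_control = bool(row.is_control)
        promoter_id = None if is_control or pd.isna(row.promoter_id) or row.promoter_id == "." else row.promoter_id
        length = int(row.end) - int(row.start)
        if not lo <= length <= hi:
            raise ValidationError(
                f"{path}: probe {row.probe_id} length {length} outside [{lo}, {hi}]"
            )
        if known is not None and promoter_id is not None and promoter_id not in known:
            raise ValidationError(f"{path}: probe {row.probe_id} assigned to unknown promoter {promoter_id!r}")
        probes.append(
            TilingProbe(str(row.probe_id), str(row.chrom), int(row.start), int(row.end), promoter_id, is_control)
        )
    probes.sort(key=lambda p: (p.chrom, p.start, p.probe_id))
    return probes


def write_probe_table(probes: Iterable[TilingProbe], path: str | Path) -> None:
    rows = [
        (p.probe_id, p.chrom, p.start, p.end, p.promoter_id or ".", int(p.is_control))
        for p in probes
    ]
    pd.DataFrame(rows, columns=PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# log-ratio arrays

def read_log_ratios(
    path: str | Path,
    probes: Sequence[TilingProbe] | None = None,
) -> pd.Series:
    """Read one replicate's probe log2(IP/input) ratios as a Series.

    The TSV has columns ``probe_id`` and ``value``. Values must be finite;
    probe ids must resolve against the probe table when one is given.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if not {"probe_id", "value"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns probe_id, value")
    values = pd.Series(df["value"].to_numpy(float), index=df["probe_id"], name="value")
    if not values.map(lambda v: v == v and abs(v) != float("inf")).all():
        raise ValidationError(f"{path}: non-finite log-ratio values")
    if probes is not None:
        known = {p.probe_id for p in probes}
        unknown = set(values.index) - known
        if unknown:
            raise ValidationError(f"{path}: unknown probe ids, e.g. {sorted(unknown)[:3]}")
    return values


def write_log_ratios(values: Mapping[str, float] | pd.Series, path: str | Path) -> None:
    series = pd.Series(values, name="value")
    series.rename_axis("probe_id").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic BED / FASTA

def write_bed(records: Iterable[tuple], path: str | Path) -> None:
    """Write BED6 tuples (chrom, start, end, name, score, strand)."""
    with open(path, "w") as handle:
        for chrom, start, end, name, score, strand in records:
            handle.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple]:
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED fields")
            chrom, start, end, name, score, strand = fields[:6]
            records.append((chrom, int(start), int(end), name, score, strand))
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# expression matrices

def write_expression(values: pd.DataFrame, arms: pd.Series, prefix: str | Path) -> None:
    """Write a genes x samples matrix and its sample/arm table.

    ``prefix`` yields ``<prefix>.matrix.tsv`` and ``<prefix>.samples.tsv``.
    """
    prefix = str(prefix)
    values.rename_axis("gene_id").to_csv(prefix + ".matrix.tsv", sep="\t")
    arms.rename("arm").rename_axis("sample_id").reset_index().to_csv(
        prefix + ".samples.tsv", sep="\t", index=False
    )


def read_expression(prefix: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    prefix = str(prefix)
    values = pd.read_csv(prefix + ".matrix.tsv", sep="\t", index_col="gene_id")
    samples = pd.read_csv(prefix + ".samples.tsv", sep="\t", index_col="sample_id")
    arms = samples["arm"]
    bad = set(arms.unique()) - {"silenced", "control"}
    if bad:
        raise ValidationError(f"unknown arm labels {sorted(bad)}")
    if set(values.columns) != set(arms.index):
        raise ValidationError("matrix columns and sample table disagree")
    return values, arms.loc[values.columns]
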