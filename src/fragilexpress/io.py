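"""Readers and writers for the text formats the pipeline touches.

Conventions applied at the boundary, exactly once per reader:

* SEG tables carry 1-based, inclusive coordinates (the convention of the
  TCGA segmentation files); they are converted to the internal 0-based,
  half-open form on read and back on write.
* BED and bedGraph are natively 0-based half-open and are passed through.
* Chromosome names are normalized to the ``chrN`` form on read.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CoverageTrack,
    ExpressionPanel,
    GenomicInterval,
    RegionSet,
    SegmentRecord,
)

PathLike = Union[str, Path]

SEG_COLUMNS = ("sample", "chrom", "start", "end", "n_markers", "seg_mean")


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


def read_seg(
    path: PathLike,
    columns: Sequence[str] = SEG_COLUMNS,
) -> list[SegmentRecord]:
    """Read a SEG copy-number table into :class:`SegmentRecord` objects.

    The file is tab-separated with a header. ``columns`` maps the six
    required fields to header names, in the order
    ``(sample, chrom, start, end, n_markers, seg_mean)``. Input
    coordinates are 1-based inclusive and are shifted to the internal
    0-based half-open convention here.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {}
        for field, col in zip(SEG_COLUMNS, columns):
            if col not in header:
                raise FormatError(f"{path}: header lacks column {col!r}")
            idx[field] = header.index(col)
        records: list[SegmentRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
            try:
                start1 = int(parts[idx["start"]])
                end1 = int(parts[idx["end"]])
                n_markers = int(parts[idx["n_markers"]])
                seg_mean = float(parts[idx["seg_mean"]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if not math.isfinite(seg_mean):
                raise FormatError(f"{path}:{lineno}: non-finite seg_mean")
            try:
                interval = GenomicInterval(
                    parts[idx["chrom"]], start1 - 1, end1
                )
                records.append(
                    SegmentRecord(
                        sample_id=parts[idx["sample"]],
                        interval=interval,
                        n_markers=n_markers,
                        seg_mean=seg_mean,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_seg(records: Iterable[SegmentRecord], path: PathLike) -> None:
    """Write segments as a SEG table (1-based inclusive coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                f"{rec.sample_id}\t{rec.interval.chrom}\t"
                f"{rec.interval.start + 1}\t{rec.interval.end}\t"
                f"{rec.n_markers}\t{float(rec.seg_mean)!r}\n"
            )


def read_bed(path: PathLike, kind: str) -> RegionSet:
    """Read a 3-6 column BED file into a :class:`RegionSet`.

    BED coordinates are already 0-based half-open and are preserved.
    Duplicate names are an error: downstream stages key regions by name.
    """
    path = Path(path)
    regions: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                name = parts[3] if len(parts) > 3 else None
                strand = parts[5] if len(parts) > 5 else "."
                # en-dash minus sometimes leaks out of annotation exports
                strand = "-" if strand in {"-", "−"} else strand
                regions.append(
                    GenomicInterval(
                        parts[0], int(parts[1]), int(parts[2]),
                        name=name, strand=strand,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(regions, kind=kind)


def write_bed(regions: RegionSet, path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in regions:
            score = "0"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n"
            )


def read_expression(
    path_matrix: PathLike,
    path_metadata: PathLike,
    path_gene_flags: Optional[PathLike] = None,
) -> ExpressionPanel:
    """Read an FPKM matrix (genes x samples TSV) plus sample metadata.

    The metadata TSV must contain ``sample_id``, ``tumour_type``,
    ``is_tumour`` and ``purity`` columns; an empty purity cell is
    recorded as missing. ``path_gene_flags`` is an optional TSV with
    ``gene_id`` and ``protein_coding``; without it every gene is flagged
    protein-coding.
    """
    values = pd.read_csv(path_matrix, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = None
    values.columns.name = None
    meta = pd.read_csv(path_metadata, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "tumour_type", "is_tumour", "purity"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{path_metadata}: metadata needs columns {sorted(required)}"
        )
    meta = meta.set_index("sample_id")
    meta["is_tumour"] = meta["is_tumour"].astype(bool)
    meta["purity"] = pd.to_numeric(meta["purity"], errors="coerce")
    if path_gene_flags is not None:
        flags = pd.read_csv(path_gene_flags, sep="\t", dtype={"gene_id": str})
        flags = flags.set_index("gene_id")["protein_coding"].astype(bool)
    else:
        flags = pd.Series(True, index=values.index)
    return ExpressionPanel(values=values, metadata=meta, protein_coding=flags)


def write_expression(panel: ExpressionPanel, path_matrix: PathLike,
                     path_metadata: PathLike,
                     path_gene_flags: Optional[PathLike] = None) -> None:
    panel.values.to_csv(path_matrix, sep="\t", index_label="gene_id")
    meta = panel.metadata.copy()
    meta.to_csv(path_metadata, sep="\t", index_label="sample_id")
    if path_gene_flags is not None:
        flags = panel.protein_coding.rename("protein_coding")
        flags.to_csv(path_gene_flags, sep="\t", index_label="gene_id")


def read_bedgraph(path: PathLike, region: GenomicInterval,
                  sample_id: Optional[str] = None) -> CoverageTrack:
    """Read a sorted bedGraph into a dense track over ``region``.

    Bases of ``region`` not covered by any record get signal 0.
    Overlapping or unsorted records on the region's chromosome are an
    error: the signal would be ambiguous.
    """
    path = Path(path)
    signal = np.zeros(region.length(), dtype=float)
    last_end = -1
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                chrom = parts[0]
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            from .core import normalize_chrom

            if normalize_chrom(chrom) != region.chrom:
                continue
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage value")
            if start < last_end:
                raise FormatError(
                    f"{path}:{lineno}: records overlap or are unsorted"
                )
            last_end = end
            lo = max(start, region.start)
            hi = min(end, region.end)
            if lo < hi:
                signal[lo - region.start : hi - region.start] = value
    return CoverageTrack(
        sample_id=sample_id if sample_id is not None else path.stem,
        region=region,
        signal=signal,
    )


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    """Write a track as a run-length-collapsed bedGraph; zero runs kept."""
    path = Path(path)
    sig = track.signal
    with path.open("w") as fh:
        if len(sig) == 0:
            return
        run_start = 0
        for i in range(1, len(sig) + 1):
            if i == len(sig) or sig[i] != sig[run_start]:
                fh.write(
                    f"{track.region.chrom}\t{track.region.start + run_start}\t"
                    f"{track.region.start + i}\t{float(sig[run_start])!r}\n"
                )
                run_start = i


def read_signature_list(path: PathLike) -> list[str]:
    """Read a one-gene-symbol-per-line signature file."""
    path = Path(path)
    genes: list[str] = []
    with path.open() as fh:
        for line in fh:
            symbol = line.strip()
            if symbol and not symbol.startswith("#"):
                genes.append(symbol)
    return genes
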