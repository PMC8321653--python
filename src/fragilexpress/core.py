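"""Core domain types shared by every pipeline stage.

All genomic coordinates inside the package are 0-based, half-open
``[start, end)``. Readers are responsible for converting from their
source convention exactly once, at the parsing boundary (see
:mod:`fragilexpress.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}

REGION_KINDS = {"fragile_site", "gene", "exon", "element"}


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome name to the ``chrN`` form.

    Copy-number tables and annotation sources disagree on whether the
    ``chr`` prefix is present; a single form is enforced at read time.
    """
    chrom = chrom.strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    if chrom.lower().startswith("chr"):
        return "chr" + chrom[3:]
    return "chr" + chrom


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based, half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Bases shared with ``other`` (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment of one sample.

    ``seg_mean`` is the segmentation value: the log2 copy-number ratio of
    the segment; negative values indicate loss.
    """

    sample_id: str
    interval: GenomicInterval
    n_markers: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.n_markers < 0:
            raise ValueError("n_markers must be non-negative")
        if not np.isfinite(self.seg_mean):
            raise ValueError("seg_mean must be finite")


class RegionSet:
    """An ordered, name-keyed collection of genomic intervals.

    ``kind`` labels what the intervals annotate (fragile sites, gene
    bodies, exons of one gene, or a sub-genic element such as an intronic
    pseudogene). Names must be unique; for ``kind="exon"`` the intervals
    must additionally be non-overlapping.
    """

    def __init__(self, regions: Iterable[GenomicInterval], kind: str):
        if kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {kind!r}")
        self.kind = kind
        self._regions: dict[str, GenomicInterval] = {}
        for i, region in enumerate(regions):
            name = region.name if region.name is not None else f"region_{i}"
            if name in self._regions:
                raise ValueError(f"duplicate region name {name!r}")
            self._regions[name] = region
        if kind == "exon":
            self._check_exons_disjoint()

    def _check_exons_disjoint(self) -> None:
        by_coord = sorted(self._regions.values(), key=lambda r: (r.chrom, r.start))
        for a, b in zip(by_coord, by_coord[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"exons overlap: {a.name} [{a.start},{a.end}) and "
                    f"{b.name} [{b.start},{b.end})"
                )

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._regions.values())

    def __contains__(self, name: str) -> bool:
        return name in self._regions

    def __getitem__(self, name: str) -> GenomicInterval:
        return self._regions[name]

    @property
    def names(self) -> list[str]:
        return list(self._regions)

    def sorted_by_coordinate(self) -> list[GenomicInterval]:
        return sorted(self._regions.values(), key=lambda r: (r.chrom, r.start, r.end))

    def in_transcription_order(self) -> list[GenomicInterval]:
        """Intervals ordered along the direction of transcription.

        For minus-strand regions the coordinate-sorted list is reversed,
        so ordinal 1 is always the 5'-most exon of the transcript.
        """
        ordered = self.sorted_by_coordinate()
        if ordered and all(r.strand == "-" for r in ordered):
            ordered = ordered[::-1]
        return ordered


@dataclass
class ExpressionPanel:
    """An FPKM expression matrix with per-sample and per-gene metadata.

    ``values``: genes x samples matrix of non-negative FPKM.
    ``metadata``: per-sample table with columns ``tumour_type`` (str),
    ``is_tumour`` (bool) and ``purity`` (float in [0, 1], NaN if
    unknown; purity is only meaningful for tumour samples).
    ``protein_coding``: per-gene boolean flags.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    protein_coding: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(
                f"samples present in matrix but absent from metadata: {sorted(missing)}"
            )
        self.metadata = self.metadata.loc[list(self.values.columns)]
        for col in ("tumour_type", "is_tumour", "purity"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("FPKM values must be non-negative")
        purity = self.metadata["purity"].to_numpy(dtype=float)
        ok = np.isnan(purity) | ((purity >= 0.0) & (purity <= 1.0))
        if not ok.all():
            bad = self.metadata.index[~ok].tolist()
            raise ValueError(f"purity outside [0, 1] for samples: {bad}")
        if not self.protein_coding.index.equals(self.values.index):
            self.protein_coding = self.protein_coding.reindex(self.values.index)
            if self.protein_coding.isna().any():
                raise ValueError("protein_coding flags missing for some genes")
        self.protein_coding = self.protein_coding.astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def tumour_samples(self, tumour_type: Optional[str] = None) -> list[str]:
        mask = self.metadata["is_tumour"].astype(bool)
        if tumour_type is not None:
            mask &= self.metadata["tumour_type"] == tumour_type
        return list(self.metadata.index[mask])

    def normal_samples(self, tumour_type: Optional[str] = None) -> list[str]:
        mask = ~self.metadata["is_tumour"].astype(bool)
        if tumour_type is not None:
            mask &= self.metadata["tumour_type"] == tumour_type
        return list(self.metadata.index[mask])


@dataclass
class CoverageTrack:
    """Dense per-base signal of one sample over one contiguous region."""

    sample_id: str
    region: GenomicInterval
    signal: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if len(self.signal) != self.region.length():
            raise ValueError(
                f"signal length {len(self.signal)} does not match region "
                f"length {self.region.length()}"
            )
        if np.any(self.signal < 0):
            raise ValueError("coverage signal must be non-negative")

    def values_over(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base signal over ``interval``; errors if outside the track."""
        if not self.region.contains(interval):
            raise ValueError(
                f"interval {interval.chrom}:[{interval.start},{interval.end}) "
                f"outside track extent {self.region.chrom}:"
                f"[{self.region.start},{self.region.end})"
            )
        off = interval.start - self.region.start
        return self.signal[off : off + interval.length()]
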