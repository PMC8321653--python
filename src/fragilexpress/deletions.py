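"""Per-patient deletion calls over named regions from copy-number segments.

The procedure mirrors the standard focal-deletion screen on segmented
copy-number data: segments are first filtered on their segmentation value
(log2 copy ratio strictly below -0.1 by default), and a patient is called
deleted for a region when at least one qualifying segment overlaps it by
one or more bases. A base-pair-weighted mean segmentation value over the
region is carried alongside the boolean call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import math

import pandas as pd

from .core import GenomicInterval, RegionSet, SegmentRecord

DEFAULT_SEG_THRESHOLD = -0.1


@dataclass(frozen=True)
class DeletionCall:
    """Deletion status of one sample over one named region.

    ``weighted_seg_value`` is the overlap-weighted mean seg_mean of the
    qualifying segments, sum(overlap_i * seg_mean_i) / sum(overlap_i),
    or NaN when no qualifying segment touches the region.
    """

    sample_id: str
    region_name: str
    deleted: bool
    overlap_bp: int
    weighted_seg_value: float

    def __post_init__(self) -> None:
        if self.overlap_bp < 0:
            raise ValueError("overlap_bp must be non-negative")
        if self.deleted != (self.overlap_bp > 0):
            raise ValueError("deleted flag must equal overlap_bp > 0")


def filter_segments(
    segments: Iterable[SegmentRecord],
    threshold: float = DEFAULT_SEG_THRESHOLD,
) -> list[SegmentRecord]:
    """Keep segments with seg_mean strictly below ``threshold``.

    The boundary value itself (seg_mean == threshold) is excluded; order
    is preserved.
    """
    return [s for s in segments if s.seg_mean < threshold]


def call_deletions(
    filtered_segments: Iterable[SegmentRecord],
    regions: RegionSet,
    samples: Sequence[str],
) -> list[DeletionCall]:
    """One :class:`DeletionCall` per (sample, region) pair.

    ``samples`` is the full cohort: samples without any qualifying
    segment still get calls (deleted=False). Segments must already be
    filtered. A segment from a sample absent from ``samples`` is an
    error, since silently dropping it would bias deletion frequencies.
    """
    sample_set = set(samples)
    by_sample: dict[str, list[SegmentRecord]] = {s: [] for s in samples}
    for seg in filtered_segments:
        if seg.sample_id not in sample_set:
            raise ValueError(
                f"segment sample {seg.sample_id!r} absent from sample list"
            )
        by_sample[seg.sample_id].append(seg)

    calls: list[DeletionCall] = []
    for sample in samples:
        for region in regions:
            total_bp = 0
            weighted_sum = 0.0
            pieces: list[tuple[int, int]] = []
            for seg in by_sample[sample]:
                bp = seg.interval.overlap_bp(region)
                if bp > 0:
                    total_bp += bp
                    weighted_sum += bp * seg.seg_mean
                    pieces.append(
                        (
                            max(seg.interval.start, region.start),
                            min(seg.interval.end, region.end),
                        )
                    )
            # overlap_bp counts region bases covered by >= 1 qualifying
            # segment (union), while the weighted value uses per-segment
            # overlaps as weights
            overlap_bp = 0
            last = -1
            for start, end in sorted(pieces):
                start = max(start, last)
                if end > start:
                    overlap_bp += end - start
                    last = end
                last = max(last, end)
            calls.append(
                DeletionCall(
                    sample_id=sample,
                    region_name=region.name,
                    deleted=overlap_bp > 0,
                    overlap_bp=overlap_bp,
                    weighted_seg_value=(
                        weighted_sum / total_bp if total_bp > 0 else math.nan
                    ),
                )
            )
    return calls


def calls_to_frame(calls: Iterable[DeletionCall]) -> pd.DataFrame:
    """Tabulate calls as a DataFrame (one row per sample x region)."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "region_name": c.region_name,
                "deleted": c.deleted,
                "overlap_bp": c.overlap_bp,
                "weighted_seg_value": c.weighted_seg_value,
            }
            for c in calls
        ]
    )


def deletion_status(
    calls: Iterable[DeletionCall], region_name: str
) -> dict[str, bool]:
    """Per-sample deleted flag for one region."""
    status: dict[str, bool] = {}
    for c in calls:
        if c.region_name == region_name:
            status[c.sample_id] = c.deleted
    return status


GENE_LABELS = ("wild_type", "central_deleted", "three_prime_deleted", "other")


def classify_gene_deletion(
    calls: Iterable[DeletionCall],
    five_prime: str,
    central: str,
    three_prime: str,
    sub_regions: Optional[RegionSet] = None,
) -> dict[str, str]:
    """Label each sample by which portion of a gene its deletions hit.

    The three named sub-regions must partition the gene body (checked for
    disjointness when ``sub_regions`` is given). Labels, with precedence
    for deletions spanning several portions:

    * ``three_prime_deleted`` — the 3' portion is hit (regardless of the
      rest; this is the contrast of interest for breakpoint profiles);
    * ``central_deleted`` — the central portion is hit but the 3' is not;
    * ``other`` — only the 5' portion is hit;
    * ``wild_type`` — no portion is hit.
    """
    if sub_regions is not None:
        regs = [sub_regions[name] for name in (five_prime, central, three_prime)]
        for i, a in enumerate(regs):
            for b in regs[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(
                        f"gene sub-regions {a.name} and {b.name} overlap"
                    )
    hit: dict[str, set[str]] = {}
    for c in calls:
        if c.region_name in (five_prime, central, three_prime):
            hit.setdefault(c.sample_id, set())
            if c.deleted:
                hit[c.sample_id].add(c.region_name)
    labels: dict[str, str] = {}
    for sample, portions in hit.items():
        if three_prime in portions:
            labels[sample] = "three_prime_deleted"
        elif central in portions:
            labels[sample] = "central_deleted"
        elif five_prime in portions:
            labels[sample] = "other"
        else:
            labels[sample] = "wild_type"
    return labels


def overlap_fraction_events(
    events: Sequence[GenomicInterval],
    element: GenomicInterval,
) -> tuple[int, int, float]:
    """Fraction of deletion events that also overlap a sub-genic element.

    ``events`` are deletion intervals already restricted to those hitting
    the gene of interest. Overlap is >= 1 bp under the half-open
    convention (an event ending exactly at the element start does not
    overlap). Returns ``(n_events, n_overlapping, fraction)``; with no
    events the fraction is NaN.
    """
    n_events = len(events)
    n_overlapping = sum(1 for e in events if e.overlaps(element))
    fraction = n_overlapping / n_events if n_events > 0 else math.nan
    return n_events, n_overlapping, fraction


def deletion_frequency_table(
    calls: Iterable[DeletionCall],
    tumour_type: Mapping[str, str],
) -> pd.DataFrame:
    """Per-(region, tumour type) deletion frequency summary."""
    df = calls_to_frame(calls)
    df["tumour_type"] = df["sample_id"].map(tumour_type)
    grouped = df.groupby(["region_name", "tumour_type"], as_index=False).agg(
        n_samples=("deleted", "size"), n_deleted=("deleted", "sum")
    )
    grouped["frequency"] = grouped["n_deleted"] / grouped["n_samples"]
    return grouped
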