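"""Nascent-transcription (TT-seq) exon-expression profile.

For a gene with an intronic element of interest (e.g. an antisense
pseudogene), the per-exon nascent signal is computed across a set of
coverage tracks as

    E_{e,i} = (sum of per-base signal of track i over exon e) / length(e)
    expression_e = log(1 + sum_i E_{e,i})        (natural log)
    rescaled_e = (expression_e - min) / (max - min)   in [0, 1]

A signed post-element drop statistic (mean rescaled expression of exons
after the element minus before it) summarizes whether transcription
attenuates past the element; negative values indicate a drop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CoverageTrack, GenomicInterval, RegionSet

logger = logging.getLogger(__name__)


@dataclass
class ExonProfile:
    """Exon-resolved nascent expression of one gene.

    Exon ordinals (1-based) follow the direction of transcription: for a
    minus-strand gene the coordinate-sorted exon list is reversed.
    """

    gene: str
    exon_names: list[str]
    raw_E: pd.DataFrame  # exons (transcription order) x samples
    expression: np.ndarray
    rescaled: np.ndarray


def exon_signal(
    tracks: Sequence[CoverageTrack], exons: RegionSet
) -> pd.DataFrame:
    """Length-normalized signal per (exon, track).

    Every exon must lie within every track's extent. Rows are exons in
    transcription order, columns are track sample ids.
    """
    ordered = exons.in_transcription_order()
    data = {}
    for track in tracks:
        col = [track.values_over(exon).sum() / exon.length() for exon in ordered]
        data[track.sample_id] = col
    return pd.DataFrame(data, index=[e.name for e in ordered])


def exon_expression(raw_E: pd.DataFrame) -> np.ndarray:
    """Per-exon expression log(1 + sum over samples of E)."""
    values = raw_E.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("length-normalized exon signal must be non-negative")
    return np.log1p(values.sum(axis=1))


def rescale_unit(expression: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all zeros."""
    expression = np.asarray(expression, dtype=float)
    if expression.size < 2:
        raise ValueError("need at least two exons to rescale")
    lo, hi = expression.min(), expression.max()
    if hi == lo:
        warnings.warn(
            "constant exon expression: rescaled profile set to all zeros",
            stacklevel=2,
        )
        return np.zeros_like(expression)
    return (expression - lo) / (hi - lo)


def exon_profile(
    tracks: Sequence[CoverageTrack], exons: RegionSet, gene: str = "gene"
) -> ExonProfile:
    """Full profile: length-normalized signal, log expression, [0,1] rescale."""
    raw = exon_signal(tracks, exons)
    expr = exon_expression(raw)
    return ExonProfile(
        gene=gene,
        exon_names=list(raw.index),
        raw_E=raw,
        expression=expr,
        rescaled=rescale_unit(expr),
    )


def post_element_drop(profile: ExonProfile, element_after_exon: int) -> float:
    """Signed drop statistic around an intronic element.

    ``element_after_exon`` is the 1-based transcription-order ordinal k of
    the last exon upstream of the element (the element sits between exons
    k and k+1). Returns mean(rescaled expression of exons > k) minus
    mean(exons <= k); negative values indicate a post-element reduction
    in nascent transcription.
    """
    k = element_after_exon
    n = len(profile.rescaled)
    if not 1 <= k < n:
        raise ValueError(f"element position k={k} out of range for {n} exons")
    upstream = profile.rescaled[:k]
    downstream = profile.rescaled[k:]
    return float(downstream.mean() - upstream.mean())


def element_position(exons: RegionSet, element: GenomicInterval) -> int:
    """Transcription-order ordinal of the exon immediately upstream of an
    intronic element; errors if the element overlaps an exon or lies
    outside the gene body."""
    ordered = exons.in_transcription_order()
    for exon in ordered:
        if exon.overlaps(element):
            raise ValueError(f"element overlaps exon {exon.name}")
    coord_sorted = exons.sorted_by_coordinate()
    after = sum(1 for e in coord_sorted if e.end <= element.start)
    if after == 0 or after == len(coord_sorted):
        raise ValueError("element does not lie between two exons of the gene")
    minus = all(e.strand == "-" for e in ordered)
    return len(coord_sorted) - after if minus else after


def profile_to_frame(profile: ExonProfile) -> pd.DataFrame:
    """Tabular view: ordinal, raw sum, log expression, rescaled value."""
    return pd.DataFrame(
        {
            "exon_index": np.arange(1, len(profile.exon_names) + 1),
            "exon_name": profile.exon_names,
            "sum_E": profile.raw_E.sum(axis=1).to_numpy(),
            "expression": profile.expression,
            "rescaled": profile.rescaled,
        }
    )
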