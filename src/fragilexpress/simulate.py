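"""Synthetic multi-tumour-type cohorts with planted fragile-site deletions.

The generator emulates the statistical structure the analysis assumes,
so that every downstream stage is testable without any data download:

* copy-number segments: deleted tumours carry one focal segment with a
  clearly negative log2 ratio overlapping the fragile site; all samples
  additionally carry near-zero background segments;
* expression: simulated on the natural-log scale as
  baseline + effect * deletion * purity + Gaussian noise, then
  exponentiated to FPKM. Effects are specified as z-shifts (units of the
  expression noise SD), so the planted shift equals the expected z-score
  difference downstream when purity is 1;
* tumour purity: Beta-distributed, multiplying the planted effect — the
  bulk signal of a lesion is diluted by the normal-cell fraction, which
  makes purity a genuine confounder the regression covariate must absorb;
* normal reference samples: baseline + noise only;
* exon panels with a breakpoint discontinuity and coverage tracks with a
  post-element signal drop, for the exon-contrast and nascent-
  transcription statistics.

Identical seed and configuration give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CoverageTrack,
    ExpressionPanel,
    GenomicInterval,
    RegionSet,
    SegmentRecord,
)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``effect_sizes`` maps (gene_name, site_name) to a signed z-shift: the
    expected z-score change of that gene in tumours whose site is deleted,
    at purity 1. ``deletion_prevalence`` maps site name to the per-tumour
    deletion probability (a bare float applies to every site).
    """

    seed: int = 0
    n_tumours: int = 200
    n_normals: int = 50
    tumour_types: tuple[str, ...] = ("COAD",)
    deletion_prevalence: float | Mapping[str, float] = 0.3
    effect_sizes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    purity_alpha: float = 6.0
    purity_beta: float = 2.0
    expression_noise_sd: float = 0.5
    baseline_log_fpkm: float | Mapping[str, float] = 5.0
    deleted_seg_mean_range: tuple[float, float] = (-1.0, -0.3)
    neutral_seg_mean_sd: float = 0.02
    min_deleted_fraction: float = 0.5  # of the site length

    def validate(self) -> None:
        if self.n_normals < 2:
            raise ValueError("n_normals must be >= 2 (z-scores need an SD)")
        if self.n_tumours < 1:
            raise ValueError("n_tumours must be >= 1")
        prevs = (
            [self.deletion_prevalence]
            if isinstance(self.deletion_prevalence, (int, float))
            else list(self.deletion_prevalence.values())
        )
        if any(not 0.0 <= p <= 1.0 for p in prevs):
            raise ValueError("deletion prevalences must lie in [0, 1]")
        lo, hi = self.deleted_seg_mean_range
        if not (lo <= hi < -0.1):
            raise ValueError(
                "deleted_seg_mean_range must lie entirely below -0.1"
            )
        if self.expression_noise_sd <= 0:
            raise ValueError("expression_noise_sd must be positive")
        if self.purity_alpha <= 0 or self.purity_beta <= 0:
            raise ValueError("purity Beta parameters must be positive")
        if not 0.0 < self.min_deleted_fraction <= 1.0:
            raise ValueError("min_deleted_fraction must lie in (0, 1]")

    def prevalence_of(self, site_name: str) -> float:
        if isinstance(self.deletion_prevalence, (int, float)):
            return float(self.deletion_prevalence)
        return float(self.deletion_prevalence[site_name])

    def baseline_of(self, gene_name: str) -> float:
        if isinstance(self.baseline_log_fpkm, (int, float)):
            return float(self.baseline_log_fpkm)
        return float(self.baseline_log_fpkm[gene_name])


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort, for recovery tests.

    ``deleted``: samples x sites boolean table. ``deleted_intervals``:
    the planted deleted sub-interval per (sample, site). ``direction``:
    the planted expression direction per gene ("up", "down" or "none").
    """

    deleted: pd.DataFrame
    deleted_intervals: dict[tuple[str, str], GenomicInterval]
    direction: dict[str, str]
    purity: pd.Series


def _planted_directions(
    genes: Sequence[str], effect_sizes: Mapping[tuple[str, str], float]
) -> dict[str, str]:
    direction = {g: "none" for g in genes}
    for (gene, _site), shift in effect_sizes.items():
        if gene in direction and shift != 0:
            direction[gene] = "up" if shift > 0 else "down"
    return direction


def simulate_cohort(
    config: CohortConfig,
    sites: RegionSet,
    genes: RegionSet,
) -> tuple[list[SegmentRecord], ExpressionPanel, SyntheticTruth]:
    """Generate copy-number segments, an FPKM panel and the ground truth."""
    config.validate()
    if len(sites) == 0 or len(genes) == 0:
        raise ValueError("annotation must contain >= 1 site and >= 1 gene")
    rng = np.random.default_rng(config.seed)

    tumour_ids = [f"T{i:04d}" for i in range(config.n_tumours)]
    normal_ids = [f"N{i:04d}" for i in range(config.n_normals)]
    types = [
        config.tumour_types[i % len(config.tumour_types)]
        for i in range(config.n_tumours)
    ]
    normal_types = [
        config.tumour_types[i % len(config.tumour_types)]
        for i in range(config.n_normals)
    ]

    purity = pd.Series(
        rng.beta(config.purity_alpha, config.purity_beta, size=config.n_tumours),
        index=tumour_ids,
    )

    site_list = list(sites)
    deleted = pd.DataFrame(
        False, index=tumour_ids, columns=[s.name for s in site_list]
    )
    deleted_intervals: dict[tuple[str, str], GenomicInterval] = {}
    segments: list[SegmentRecord] = []
    lo, hi = config.deleted_seg_mean_range

    for sample, ttype in zip(tumour_ids, types):
        for site in site_list:
            if rng.random() < config.prevalence_of(site.name):
                deleted.loc[sample, site.name] = True
                # focal deletion: a sub-interval of the site, at least
                # min_deleted_fraction of its length, uniformly placed
                min_len = max(1, int(config.min_deleted_fraction * site.length()))
                length = int(rng.integers(min_len, site.length() + 1))
                start = site.start + int(
                    rng.integers(0, site.length() - length + 1)
                )
                interval = GenomicInterval(site.chrom, start, start + length)
                deleted_intervals[(sample, site.name)] = interval
                seg_mean = float(rng.uniform(lo, hi))
                segments.append(
                    SegmentRecord(sample, interval, n_markers=max(10, length // 5000),
                                  seg_mean=seg_mean)
                )
        # near-zero background segment spanning each annotated chromosome
        for chrom in sorted({s.chrom for s in site_list}):
            span = [s for s in site_list if s.chrom == chrom]
            start = min(s.start for s in span)
            end = max(s.end for s in span)
            segments.append(
                SegmentRecord(
                    sample,
                    GenomicInterval(chrom, max(0, start - 10_000), end + 10_000),
                    n_markers=100,
                    seg_mean=float(rng.normal(0.0, config.neutral_seg_mean_sd)),
                )
            )

    gene_names = [g.name for g in genes]
    direction = _planted_directions(gene_names, config.effect_sizes)

    n_total = config.n_tumours + config.n_normals
    baseline = np.array([config.baseline_of(g) for g in gene_names])
    log_expr = (
        baseline[:, None]
        + rng.normal(0.0, config.expression_noise_sd, size=(len(gene_names), n_total))
    )
    for (gene, site_name), z_shift in config.effect_sizes.items():
        if gene not in gene_names or site_name not in deleted.columns:
            continue
        gi = gene_names.index(gene)
        shift = z_shift * config.expression_noise_sd
        for si, sample in enumerate(tumour_ids):
            if deleted.loc[sample, site_name]:
                log_expr[gi, si] += shift * purity[sample]

    fpkm = np.exp(log_expr)
    values = pd.DataFrame(fpkm, index=gene_names, columns=tumour_ids + normal_ids)
    metadata = pd.DataFrame(
        {
            "tumour_type": types + normal_types,
            "is_tumour": [True] * config.n_tumours + [False] * config.n_normals,
            "purity": list(purity) + [np.nan] * config.n_normals,
        },
        index=tumour_ids + normal_ids,
    )
    panel = ExpressionPanel(
        values=values,
        metadata=metadata,
        protein_coding=pd.Series(True, index=values.index),
    )
    truth = SyntheticTruth(
        deleted=deleted,
        deleted_intervals=deleted_intervals,
        direction=direction,
        purity=purity,
    )
    return segments, panel, truth


def simulate_exon_profile(
    exons: RegionSet,
    deleted_block: tuple[int, int],
    shift: float = 1.0,
    n_deleted: int = 30,
    n_wild_type: int = 30,
    noise_sd: float = 1.0,
    seed: int = 0,
    sample_labels: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Per-sample exon panel with a breakpoint discontinuity.

    ``deleted_block`` gives the 0-based (first, last) transcription-order
    indices of the exons lost to the focal deletion. In deleted samples,
    exons outside the block are shifted up by ``shift`` and exons inside
    shifted down by the same amount (residual expression of a lost exon);
    wild-type samples are flat. Returns ``(values, labels, exon_truth)``
    where values is exons x samples, labels maps samples to
    {"three_prime_deleted", "wild_type"} and exon_truth maps exon names
    to the planted direction in the deleted group.

    ``sample_labels`` optionally supplies existing sample ids with their
    group labels instead of generating fresh ones; samples labelled
    "three_prime_deleted" get the breakpoint pattern, all others are
    flat (``n_deleted``/``n_wild_type`` are then ignored).
    """
    ordered = exons.in_transcription_order()
    n_exons = len(ordered)
    first, last = deleted_block
    if not (0 <= first <= last < n_exons):
        raise ValueError(f"deleted block {deleted_block} out of range")
    if first == 0 and last == n_exons - 1:
        raise ValueError("deleted block covers every exon; nothing remains")
    rng = np.random.default_rng(seed)
    if sample_labels is not None:
        labels = dict(sample_labels)
        sample_ids = list(labels)
    else:
        del_ids = [f"D{i:03d}" for i in range(n_deleted)]
        wt_ids = [f"W{i:03d}" for i in range(n_wild_type)]
        labels = {s: "three_prime_deleted" for s in del_ids}
        labels.update({s: "wild_type" for s in wt_ids})
        sample_ids = del_ids + wt_ids
    inside = np.zeros(n_exons, dtype=bool)
    inside[first : last + 1] = True
    mean_deleted = np.where(inside, -shift, shift)

    values = rng.normal(0.0, noise_sd, size=(n_exons, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        if labels[s] == "three_prime_deleted":
            values[:, j] += mean_deleted
    frame = pd.DataFrame(values, index=[e.name for e in ordered],
                         columns=sample_ids)
    if shift == 0:
        exon_truth = {e.name: "none" for e in ordered}
    else:
        exon_truth = {
            e.name: ("down" if inside[i] else "up") if shift > 0
            else ("up" if inside[i] else "down")
            for i, e in enumerate(ordered)
        }
    return frame, labels, exon_truth


def simulate_coverage(
    exons: RegionSet,
    element: GenomicInterval,
    drop_factor: float,
    n_tracks: int = 14,
    mean_coverage: float = 100.0,
    seed: int = 0,
) -> list[CoverageTrack]:
    """Poisson coverage tracks with a post-element signal drop.

    Per-base counts are Poisson with mean ``mean_coverage`` upstream of
    the element (in transcription direction) and
    ``mean_coverage * drop_factor`` downstream. The element must lie
    between two exons of the gene.
    """
    if not 0.0 <= drop_factor <= 1.0:
        raise ValueError("drop_factor must lie in [0, 1]")
    ordered = exons.sorted_by_coordinate()
    if not ordered:
        raise ValueError("empty exon set")
    chrom = ordered[0].chrom
    if element.chrom != chrom:
        raise ValueError("element on a different chromosome than the exons")
    region = GenomicInterval(chrom, ordered[0].start, ordered[-1].end)
    if not (region.start < element.start and element.end < region.end):
        raise ValueError("element does not lie between two exons of the gene")
    minus = all(e.strand == "-" for e in ordered)

    positions = np.arange(region.start, region.end)
    if minus:
        downstream = positions < element.end
    else:
        downstream = positions >= element.start
    mu = np.where(downstream, mean_coverage * drop_factor, mean_coverage)

    rng = np.random.default_rng(seed)
    tracks = []
    for i in range(n_tracks):
        signal = rng.poisson(mu).astype(float)
        tracks.append(CoverageTrack(f"track{i:02d}", region, signal))
    return tracks


def default_annotation(
    n_background_genes: int = 29,
    include_cin_genes: bool = True,
) -> dict[str, RegionSet]:
    """A compact annotation modelled on a fragile-site locus.

    Synthetic stand-in for a real genome annotation: one fragile site
    ("FRA4F"-like, chr4) hosting one resident gene ("CCSER1"-like) with
    11 exons and an intronic antisense element between exons 8 and 9,
    plus background genes on other chromosomes. With
    ``include_cin_genes`` the first background genes carry the CIN25
    signature symbols, so signature scoring is exercised on the same
    cohort. Coordinates are invented but keep realistic magnitudes.
    """
    site = GenomicInterval("chr4", 90_100_000, 91_600_000, name="FRA4F")
    # gene body compressed to 24 kb so per-base coverage tracks stay small;
    # the downstream statistics depend only on exon structure, not span
    gene = GenomicInterval("chr4", 90_200_000, 90_224_000, name="CCSER1", strand="+")
    exon_len = 200
    # 11 exons spread over the gene body; the element sits in intron 8
    exon_starts = np.linspace(gene.start, gene.end - exon_len, 11).astype(int)
    exons = [
        GenomicInterval("chr4", int(s), int(s) + exon_len, name=f"exon_{i+1}",
                        strand="+")
        for i, s in enumerate(exon_starts)
    ]
    element_mid = (exons[7].end + exons[8].start) // 2
    element = GenomicInterval(
        "chr4", element_mid - 500, element_mid + 500, name="TMSB4XP8", strand="-"
    )
    if include_cin_genes:
        from .signatures import load_builtin_signature

        cin = list(load_builtin_signature("CIN25").genes)
    else:
        cin = []
    bg_names = cin[:n_background_genes] + [
        f"BG{i:03d}" for i in range(max(0, n_background_genes - len(cin)))
    ]
    background = [
        GenomicInterval(
            f"chr{(i % 10) + 5}",
            1_000_000 + 200_000 * i,
            1_050_000 + 200_000 * i,
            name=name,
            strand="+",
        )
        for i, name in enumerate(bg_names)
    ]
    return {
        "sites": RegionSet([site], kind="fragile_site"),
        "genes": RegionSet([gene] + background, kind="gene"),
        "exons": RegionSet(exons, kind="exon"),
        "element": RegionSet([element], kind="element"),
    }


def default_config(seed: int = 0, z_shift: float = 1.5) -> CohortConfig:
    """The default study conditions: one planted up-regulated gene in the
    deleted fragile site, prevalence 0.3, 200 tumours and 50 normals."""
    return CohortConfig(
        seed=seed,
        effect_sizes={("CCSER1", "FRA4F"): z_shift},
    )
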