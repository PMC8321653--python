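"""End-to-end pipeline: deletion calling, association, exon contrast,
instability-signature comparison and the nascent-transcription profile,
driven by a single configuration.

Every run writes TSV outputs plus a machine-readable provenance record
(the full configuration, package version and seeds), so that re-running
with the same configuration reproduces the outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    correct_and_filter,
    exon_contrast,
    results_to_frame,
    robust_association,
    zscore_vs_normal,
)
from .core import GenomicInterval, RegionSet
from .deletions import (
    DEFAULT_SEG_THRESHOLD,
    call_deletions,
    calls_to_frame,
    classify_gene_deletion,
    deletion_status,
    filter_segments,
)
from . import io as fio
from .signatures import (
    compare_groups,
    load_builtin_signature,
    score_signature,
    stratify_by_element,
)
from .ttseq import element_position, exon_profile, post_element_drop, profile_to_frame

logger = logging.getLogger(__name__)

ALL_STAGES = ("call_deletions", "associate", "exon_contrast", "cin", "ttseq")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Defaults follow the analysis constants: segmentation-value filter at
    -0.1 (strictly below) and Bonferroni-adjusted significance at 0.01.
    """

    out_dir: str
    seg_path: str
    sites_bed: str
    expr_matrix: str
    expr_metadata: str
    gene_flags: Optional[str] = None
    subregions_bed: Optional[str] = None  # gene 5'/central/3' portions
    exon_matrix: Optional[str] = None  # exons x samples TSV (z or FPKM)
    element_bed: Optional[str] = None
    exons_bed: Optional[str] = None
    tracks: list[str] = field(default_factory=list)  # bedGraph paths
    threshold: float = DEFAULT_SEG_THRESHOLD
    alpha: float = 0.01
    log_transform: bool = True
    signature: str = "CIN25"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    bootstrap_samples: int = 1000

    def validate(self) -> None:
        errors = []
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            errors.append(f"unknown stages: {sorted(unknown)}")
        for name in ("seg_path", "sites_bed", "expr_matrix", "expr_metadata"):
            if not Path(getattr(self, name)).exists():
                errors.append(f"{name}: no such file {getattr(self, name)!r}")
        if "exon_contrast" in self.stages and not (
            self.exon_matrix and self.subregions_bed
        ):
            errors.append("exon_contrast stage needs exon_matrix and subregions_bed")
        if "cin" in self.stages and not self.element_bed:
            errors.append("cin stage needs element_bed")
        if "ttseq" in self.stages and not (
            self.exons_bed and self.element_bed and self.tracks
        ):
            errors.append("ttseq stage needs exons_bed, element_bed and tracks")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the enabled stages in order; returns the result bundle.

    Writes per-stage TSVs, a plain-text summary and a provenance JSON to
    ``config.out_dir``. A failing stage aborts the run with an error
    naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, object] = {}
    summary: list[str] = []

    def _stage(name):
        return name in config.stages

    try:
        segments = fio.read_seg(config.seg_path)
        sites = fio.read_bed(config.sites_bed, kind="fragile_site")
        panel = fio.read_expression(
            config.expr_matrix, config.expr_metadata, config.gene_flags
        )
    except Exception as exc:
        raise StageError(f"input reading failed: {exc}") from exc
    summary.append(f"inputs: {len(segments)} segments, {len(sites)} region(s), "
                   f"{len(panel.gene_ids)} genes x {len(panel.sample_ids)} samples")

    filtered = filter_segments(segments, config.threshold)
    summary.append(
        f"segment filter (< {config.threshold}): {len(filtered)}/{len(segments)} kept"
    )

    calls = None
    if _stage("call_deletions"):
        try:
            tumours = panel.tumour_samples()
            calls = call_deletions(filtered, sites, tumours)
            frame = calls_to_frame(calls)
            frame.to_csv(out / "deletion_calls.tsv", sep="\t", index=False)
            bundle["calls"] = calls
            n_del = int(frame["deleted"].sum())
            summary.append(f"deletion calls: {n_del}/{len(frame)} (sample,region) deleted")
        except Exception as exc:
            raise StageError(f"call_deletions stage failed: {exc}") from exc

    zpanels = {}
    if _stage("associate") or _stage("cin"):
        try:
            for ttype in sorted(set(panel.metadata["tumour_type"])):
                if panel.tumour_samples(ttype) and len(panel.normal_samples(ttype)) >= 2:
                    zpanels[ttype] = zscore_vs_normal(
                        panel, ttype, log_transform=config.log_transform
                    )
        except Exception as exc:
            raise StageError(f"z-scoring failed: {exc}") from exc

    if _stage("associate"):
        try:
            if calls is None:
                calls = call_deletions(filtered, sites, panel.tumour_samples())
            purity = panel.metadata["purity"].to_dict()
            all_results = []
            for ttype, zp in zpanels.items():
                for site in sites:
                    status = deletion_status(calls, site.name)
                    all_results.extend(
                        robust_association(zp, status, purity, site.name)
                    )
            adjusted, significant, m = correct_and_filter(
                all_results, panel.protein_coding.to_dict(), alpha=config.alpha
            )
            results_to_frame(adjusted).to_csv(
                out / "association_results.tsv", sep="\t", index=False
            )
            sig_frame = (
                results_to_frame(significant) if significant else pd.DataFrame()
            )
            sig_frame.to_csv(out / "significant_genes.tsv", sep="\t", index=False)
            bundle["association"] = adjusted
            bundle["significant"] = significant
            bundle["family_size"] = m
            summary.append(
                f"association: m={m} tests, {len(significant)} significant "
                f"protein-coding gene(s) at adjusted p < {config.alpha}"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"associate stage failed: {exc}") from exc

    if _stage("exon_contrast"):
        try:
            sub = fio.read_bed(config.subregions_bed, kind="gene")
            names = sub.names
            if len(names) != 3:
                raise ValueError("subregions BED must contain exactly 3 regions")
            sub_calls = call_deletions(filtered, sub, panel.tumour_samples())
            labels = classify_gene_deletion(
                sub_calls, names[0], names[1], names[2], sub_regions=sub
            )
            exon_values = pd.read_csv(config.exon_matrix, sep="\t", index_col=0)
            contrast = exon_contrast(
                exon_values, labels,
                n_boot=config.bootstrap_samples, seed=config.seed,
            )
            pd.DataFrame(
                {
                    "exon": contrast.exon_names,
                    "difference": contrast.difference,
                    "ci_low": contrast.ci_low,
                    "ci_high": contrast.ci_high,
                }
            ).to_csv(out / "exon_contrast.tsv", sep="\t", index=False)
            bundle["exon_contrast"] = contrast
            summary.append(
                f"exon contrast: {contrast.n_deleted} three-prime-deleted vs "
                f"{contrast.n_wild_type} wild-type samples"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"exon_contrast stage failed: {exc}") from exc

    if _stage("cin"):
        try:
            element_set = fio.read_bed(config.element_bed, kind="element")
            element_name = element_set.names[0]
            tumours = panel.tumour_samples()
            el_calls = call_deletions(filtered, element_set, tumours)
            status = deletion_status(el_calls, element_name)
            groups = stratify_by_element(status, tumours)
            signature = load_builtin_signature(config.signature)
            # one pooled score table across tumour types
            scores = []
            for ttype, zp in zpanels.items():
                table = score_signature(zp, signature, groups)
                scores.append(table)
            if not scores:
                raise ValueError("no z-score panel available for signature scoring")
            table = scores[0]
            for extra in scores[1:]:
                table.scores = pd.concat([table.scores, extra.scores])
                table.groups = pd.concat([table.groups, extra.groups])
            u, p = compare_groups(table)
            pd.DataFrame(
                {"sample_id": table.scores.index,
                 "score": table.scores.to_numpy(),
                 "group": table.groups.to_numpy()}
            ).to_csv(out / "cin_scores.tsv", sep="\t", index=False)
            bundle["cin"] = {"U": u, "p": p, "signature": signature.name,
                             "n_genes_found": table.n_signature_genes_found,
                             "aggregation": "mean z-score of signature genes"}
            summary.append(
                f"{signature.name}: Mann-Whitney U={u:.1f}, two-sided p={p:.3g} "
                f"({table.n_signature_genes_found} signature genes found)"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"cin stage failed: {exc}") from exc

    if _stage("ttseq"):
        try:
            exons = fio.read_bed(config.exons_bed, kind="exon")
            element_set = fio.read_bed(config.element_bed, kind="element")
            element = next(iter(element_set))
            ordered = exons.sorted_by_coordinate()
            region = GenomicInterval(
                ordered[0].chrom, ordered[0].start, ordered[-1].end
            )
            tracks = [fio.read_bedgraph(p, region) for p in config.tracks]
            profile = exon_profile(tracks, exons)
            k = element_position(exons, element)
            drop = post_element_drop(profile, k)
            profile_to_frame(profile).to_csv(
                out / "ttseq_profile.tsv", sep="\t", index=False
            )
            bundle["ttseq"] = {"profile": profile, "drop": drop,
                               "element_after_exon": k}
            summary.append(
                f"nascent transcription: post-element drop statistic {drop:+.3f} "
                f"(element after exon {k}, {len(tracks)} tracks)"
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"ttseq stage failed: {exc}") from exc

    provenance = {
        "package": "fragilexpress",
        "version": __version__,
        "config": dataclasses.asdict(config),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    for line in summary:
        logger.info(line)
    bundle["summary"] = summary
    return bundle


def make_fixtures(out_dir: Union[str, Path], seed: int = 0,
                  drop_factor: float = 0.3) -> RunConfig:
    """Write a complete miniature cohort and a ready-to-run configuration.

    Generates the default synthetic cohort (one planted up-regulated gene
    inside the fragile site), an exon-level panel whose breakpoint
    pattern follows the actual per-sample deletion classification, and
    nascent-coverage tracks with a post-element drop; everything is
    written through the package's own writers so the fixtures re-read
    into the in-memory cohort exactly.
    """
    from .simulate import (
        default_annotation,
        default_config,
        simulate_cohort,
        simulate_coverage,
        simulate_exon_profile,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = default_annotation()
    config = default_config(seed=seed)
    segments, panel, truth = simulate_cohort(config, ann["sites"], ann["genes"])

    fio.write_seg(segments, out / "cohort.seg")
    fio.write_bed(ann["sites"], out / "sites.bed")
    fio.write_bed(ann["genes"], out / "genes.bed")
    fio.write_bed(ann["exons"], out / "exons.bed")
    fio.write_bed(ann["element"], out / "element.bed")
    fio.write_expression(panel, out / "expression.tsv", out / "metadata.tsv",
                         out / "gene_flags.tsv")
    truth.deleted.to_csv(out / "truth_deleted.tsv", sep="\t",
                         index_label="sample_id")
    pd.DataFrame(
        {"gene": list(truth.direction), "direction": list(truth.direction.values())}
    ).to_csv(out / "truth_direction.tsv", sep="\t", index=False)

    # gene sub-portions: 5' = exons 1-5, central = exons 6-8 (deleted
    # block), 3' = exons 9-11; boundaries at intron midpoints
    gene = ann["genes"]["CCSER1"]
    exons = ann["exons"].sorted_by_coordinate()
    b1 = (exons[4].end + exons[5].start) // 2
    b2 = (exons[7].end + exons[8].start) // 2
    sub = RegionSet(
        [
            GenomicInterval(gene.chrom, gene.start, b1, name="CCSER1_5p"),
            GenomicInterval(gene.chrom, b1, b2, name="CCSER1_central"),
            GenomicInterval(gene.chrom, b2, gene.end, name="CCSER1_3p"),
        ],
        kind="gene",
    )
    fio.write_bed(sub, out / "subregions.bed")

    # exon panel consistent with the classified per-sample deletions
    filtered = filter_segments(segments)
    sub_calls = call_deletions(filtered, sub, panel.tumour_samples())
    labels = classify_gene_deletion(
        sub_calls, "CCSER1_5p", "CCSER1_central", "CCSER1_3p", sub_regions=sub
    )
    exon_values, _, _ = simulate_exon_profile(
        ann["exons"], deleted_block=(5, 7), shift=1.0, seed=seed + 1,
        sample_labels=labels,
    )
    exon_values.to_csv(out / "exon_matrix.tsv", sep="\t", index_label="exon")

    element = ann["element"]["TMSB4XP8"]
    tracks = simulate_coverage(
        ann["exons"], element, drop_factor=drop_factor, n_tracks=14,
        mean_coverage=100.0, seed=seed + 2,
    )
    track_paths = []
    for t in tracks:
        p = out / f"{t.sample_id}.bedgraph"
        fio.write_bedgraph(t, p)
        track_paths.append(str(p))

    run_config = RunConfig(
        out_dir=str(out / "results"),
        seg_path=str(out / "cohort.seg"),
        sites_bed=str(out / "sites.bed"),
        expr_matrix=str(out / "expression.tsv"),
        expr_metadata=str(out / "metadata.tsv"),
        gene_flags=str(out / "gene_flags.tsv"),
        subregions_bed=str(out / "subregions.bed"),
        exon_matrix=str(out / "exon_matrix.tsv"),
        element_bed=str(out / "element.bed"),
        exons_bed=str(out / "exons.bed"),
        tracks=track_paths,
        seed=seed,
    )
    run_config.to_yaml(out / "config.yaml")
    return run_config
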