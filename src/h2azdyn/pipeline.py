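"""End-to-end orchestration: tags -> peaks -> feature/profile/occupancy reports.

``run_pipeline`` runs every analysis stage for a set of samples against one
annotation, writes each intermediate to the output directory, and returns a
machine-readable run report (also written as JSON) with per-sample
summaries, output paths, and content checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import feature_assignment, occupancy_dynamics, profiles
from .genome_model import ChromSizes, build_partition, read_gene_models
from .peakcall import PeakCallParams, call_peaks, read_tags, summarize_peaks, write_peaks

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input fingerprint."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {cause}")
        self.stage = stage
        self.fingerprint = fingerprint


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run."""

    samples: dict[str, str]            # sample_id -> tag BED path
    annotation: str
    sizes: str
    out_dir: str
    expression: str | None = None
    annotation_format: str | None = None
    promoter_bp: int = 2000
    downstream_bp: int = 2000
    p_threshold: float = 1e-4
    bandwidth: int = 300
    extension: int = 150
    flank: int = 5000
    window: int = 200
    read_length: int = 49

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the run report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}, "samples": {},
                    "outputs": {}}

    def stage(name, fingerprint, fn):
        t0 = time.monotonic()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, fingerprint, exc) from exc
        report["stages"][name] = {"seconds": round(time.monotonic() - t0, 3)}
        logger.info("stage %s done in %.2fs", name, time.monotonic() - t0)
        return result

    sizes = stage("read_sizes", config.sizes, lambda: ChromSizes.read(config.sizes))
    genes = stage("read_annotation", config.annotation,
                  lambda: read_gene_models(config.annotation, config.annotation_format))
    partition = stage("build_partition", config.annotation,
                      lambda: build_partition(genes, sizes, config.promoter_bp,
                                              config.downstream_bp))
    partition.write_bed(out / "partition.bed")
    partition.write_base_counts(out / "partition_base_counts.tsv")

    expression = None
    if config.expression is not None:
        expression = stage("read_expression", config.expression,
                           lambda: profiles.read_expression(config.expression))
    else:
        report["stages"]["expression_stratification"] = {"skipped": "no expression table"}

    params = PeakCallParams(p_threshold=config.p_threshold, bandwidth=config.bandwidth,
                            extension=config.extension)
    occupancy: dict[str, set[str]] = {}
    for sample_id, tag_path in config.samples.items():
        srep: dict = {}
        tags = stage(f"read_tags[{sample_id}]", tag_path,
                     lambda: read_tags(tag_path, sample_id, sizes, config.read_length))
        srep["library_size"] = tags.library_size

        peaks = stage(f"call_peaks[{sample_id}]", tag_path,
                      lambda: call_peaks(tags, sizes, params))
        peak_path = out / f"{sample_id}_peaks.bed"
        write_peaks(peaks, peak_path)
        if peaks:
            ps = summarize_peaks(peaks)
            srep["peak_summary"] = dataclasses.asdict(ps)
            dist = feature_assignment.peak_distribution(peaks, partition)
            enr = feature_assignment.relative_enrichment(dist, partition)
            feature_assignment.write_enrichment(dist, enr,
                                                out / f"{sample_id}_enrichment.tsv")
            srep["distribution"] = dist.fractions
            srep["relative_enrichment"] = enr.relative_enrichment
        else:
            srep["peak_summary"] = None

        curves = {
            "TSS": stage(f"profile_tss[{sample_id}]", tag_path,
                         lambda: profiles.composite_profile(
                             tags, genes, sizes, "TSS", config.flank, config.window,
                             config.extension)),
            "TES": stage(f"profile_tes[{sample_id}]", tag_path,
                         lambda: profiles.composite_profile(
                             tags, genes, sizes, "TES", config.flank, config.window,
                             config.extension)),
        }
        profiles.write_profiles(curves, out / f"{sample_id}_profiles.tsv")

        if expression is not None:
            strat = stage(f"stratified_profiles[{sample_id}]", tag_path,
                          lambda: profiles.stratified_profiles(
                              tags, genes, sizes, expression, flank=config.flank,
                              window=config.window, extension=config.extension))
            profiles.write_profiles(strat, out / f"{sample_id}_stratified_profiles.tsv")
            srep["stratified_max_rpm"] = {k: float(v.values.max())
                                          for k, v in strat.items()}

        occupancy[sample_id] = occupancy_dynamics.occupied_genes(
            peaks, genes, promoter_bp=config.promoter_bp)
        srep["occupied_genes"] = len(occupancy[sample_id])
        report["samples"][sample_id] = srep

    occupancy_dynamics.sample_gene_lists(occupancy, out / "gene_lists")
    if len(occupancy) == 3:
        venn = occupancy_dynamics.venn_counts(occupancy)
        venn.write_json(out / "venn_counts.json")
        report["venn_counts"] = venn.to_dict()

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "run_report.json":
            report["outputs"][str(p.relative_to(out))] = _sha256(p)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
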