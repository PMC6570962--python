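"""End-to-end batch workflow: discover → condition → segment → measure →
classify → report.

For every sub-directory of the input root this writes a raw per-particle
CSV and, per image, two indexed QC overlay PNGs (pellets / dispersed) in
a mirror of the source layout under the output root. At the root level
it writes one CSV per descriptor per analysed class and — when both
morphologies are analysed — the single pelleted-fraction CSV covering
all sub-directories.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import classify_report, imaging_io, preprocess, segmentation, shape_metrics
from .errors import PelletmorphError
from .imaging_io import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Summary of one pipeline run."""

    images_processed: int = 0
    class_counts: dict = field(default_factory=lambda: {"pellet": 0, "dispersed": 0})
    artefacts_removed: int = 0
    qc_removed: int = 0
    outputs: list[Path] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    pellet_fractions: dict = field(default_factory=dict)


def _qc_keys(path: Path, input_root: Path) -> set[str]:
    # bare file names are ambiguous across sub-directories; flags must use
    # the absolute path or the path relative to the input root
    keys = {str(path)}
    try:
        keys.add(path.relative_to(input_root).as_posix())
    except ValueError:
        pass
    return keys


def process_image(
    record: imaging_io.ImageRecord, config: RunConfig
) -> tuple[classify_report.ImageResult, list, int]:
    """Run one image through the pipeline.

    Returns the classified result (analysed classes only), the matching
    (metrics, particle) pairs for overlay rendering, and the artefact count.
    """
    mask = preprocess.preprocess_record(
        record,
        config.calibration,
        threshold_spec=config.threshold_spec,
        contrast_saturation=config.contrast_saturation,
    )
    particles = segmentation.label_particles(
        mask, connectivity=config.connectivity, source=record.path
    )
    particles = segmentation.apply_border_policy(particles, mask.shape, config.border_policy)
    metrics = [
        shape_metrics.compute_metrics(p, config.calibration, image=record.path.name)
        for p in particles
    ]
    labelled = classify_report.classify_all(metrics, config.class_config)
    n_artefacts = sum(1 for m in labelled if m.class_label == "artefact")
    if n_artefacts:
        logger.info("%s: %d artefacts removed", record.path.name, n_artefacts)
    keep = set(config.class_config.analysed_classes)
    pairs = [
        (m, p) for m, p in zip(labelled, particles) if m.class_label in keep
    ]
    result = classify_report.ImageResult(
        source=record.path, particles=[m for m, _ in pairs]
    )
    return result, pairs, n_artefacts


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow for every image under the input root."""
    report = RunReport()
    groups = imaging_io.discover_images(config.input_root, config.suffix)
    flags = (
        classify_report.read_qc_flags(config.qc_flags) if config.qc_flags else {}
    )
    all_rows: list[dict] = []
    fractions: dict[str, float] = {}
    for subdir, paths in groups.items():
        subdir_rows: list[dict] = []
        subdir_results: list[classify_report.ImageResult] = []
        out_dir = config.output_root / subdir if subdir != "." else config.output_root
        for path in paths:
            try:
                record = imaging_io.load_image(path, subdir=subdir)
                result, pairs, n_art = process_image(record, config)
                flagged: set[int] = set()
                for key in _qc_keys(path, config.input_root):
                    flagged |= flags.get(key, set())
                if flagged:
                    result = classify_report.drop_flagged(result, flagged)
                    report.qc_removed += len(flagged)
                    pairs = [(m, p) for m, p in pairs if m.index not in flagged]
                overlay_paths = classify_report.render_qc_overlays(record, pairs, out_dir)
                report.outputs.extend(overlay_paths)
            except PelletmorphError as exc:
                raise PelletmorphError(f"while processing {path}: {exc}") from exc
            report.images_processed += 1
            report.artefacts_removed += n_art
            for m in result.particles:
                report.class_counts[m.class_label] = (
                    report.class_counts.get(m.class_label, 0) + 1
                )
                row = m.as_row()
                subdir_rows.append(row)
                all_rows.append({**row, "subdir": subdir})
            subdir_results.append(result)
        report.outputs.append(
            imaging_io.write_raw_csv(config.output_root, subdir, subdir_rows)
        )
        if config.mode == "both":
            fractions[subdir] = classify_report.pellet_fraction(subdir_results)
    classes = config.class_config.analysed_classes
    tables = imaging_io.write_parameter_tables(config.output_root, all_rows, classes)
    report.outputs.extend(tables.values())
    if config.mode == "both":
        report.outputs.append(
            imaging_io.write_pellet_fraction_csv(config.output_root, fractions)
        )
        report.pellet_fractions = fractions
    logger.info(
        "processed %d images: %s, %d artefacts removed",
        report.images_processed,
        report.class_counts,
        report.artefacts_removed,
    )
    return report
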