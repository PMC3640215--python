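"""End-to-end pipeline driver with provenance.

Runs preprocess -> concatenate -> decompose -> characterize, either on
in-memory matrices (:func:`analyze_matrices`) or from files listed in a
:class:`PipelineConfig` (:func:`run_pipeline`), recording per-stage
parameters and counts in a :class:`RunReport` sufficient to re-run
identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import characterize as ch
from . import decompose as dc
from . import io as hio
from . import preprocess as pp

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    subjects: list[tuple[str, str | None]]  # (fmri path, motion path or None)
    mask: str
    tr_seconds: float | None = None
    discard_volumes: int = 24
    cutoff_hz: float | None = 0.25  # None disables the high-pass filter
    smooth_fwhm: float | None = None
    n_pcs: int = 76
    n_ics: int = 75
    contrast: str = "logcosh"
    band_edges: tuple[float, ...] = ch.HIGHFREQ_BAND_EDGES
    rules: ch.ClassificationRules = field(default_factory=ch.ClassificationRules)
    seed: int = 0
    output_dir: str = "hftica_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        subjects = [
            (s["fmri"], s.get("motion")) for s in raw.pop("subjects")
        ]
        rules = ch.ClassificationRules(**raw.pop("rules", {}))
        band_edges = tuple(raw.pop("band_edges", ch.HIGHFREQ_BAND_EDGES))
        return cls(subjects=subjects, rules=rules, band_edges=band_edges, **raw)

    def to_dict(self) -> dict:
        return {
            "subjects": [list(s) for s in self.subjects],
            "mask": self.mask,
            "tr_seconds": self.tr_seconds,
            "discard_volumes": self.discard_volumes,
            "cutoff_hz": self.cutoff_hz,
            "smooth_fwhm": self.smooth_fwhm,
            "n_pcs": self.n_pcs,
            "n_ics": self.n_ics,
            "contrast": self.contrast,
            "band_edges": list(self.band_edges),
            "rules": vars(self.rules),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


@dataclass
class RunReport:
    """Per-stage provenance plus the component summary."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    component_table: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, t0: float, **info) -> None:
        self.stages.append(
            {"stage": name, "duration_s": round(time.perf_counter() - t0, 4), **info}
        )

    def to_json(self) -> str:
        def _clean(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(
            {
                "config": self.config,
                "stages": self.stages,
                "warnings": self.warnings,
                "component_table": self.component_table,
            },
            indent=2,
            default=_clean,
        )


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and provenance so far."""

    def __init__(self, stage: str, report: RunReport, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.report = report


@dataclass
class AnalysisResult:
    group: dc.GroupMatrix
    decomposition: dc.Decomposition
    reports: list[ch.ComponentReport]


def analyze_matrices(
    matrices: list[pp.VoxelTimeSeriesMatrix],
    motion_tables: list[np.ndarray] | None = None,
    discard_volumes: int = 24,
    cutoff_hz: float | None = 0.25,
    smooth_fwhm: float | None = None,
    n_pcs: int = 76,
    n_ics: int = 75,
    contrast: str = "logcosh",
    band_edges: tuple[float, ...] = ch.HIGHFREQ_BAND_EDGES,
    rules: ch.ClassificationRules | None = None,
    seed: int = 0,
    report: RunReport | None = None,
) -> AnalysisResult:
    """The full in-memory analysis on already-loaded subject matrices."""
    report = report or RunReport(config={})
    filter_spec = (
        pp.FilterSpec(cutoff_hz=cutoff_hz) if cutoff_hz is not None else None
    )

    stage = "preprocess"
    try:
        t0 = time.perf_counter()
        processed = []
        n_constant = 0
        for i, m in enumerate(matrices):
            motion = motion_tables[i] if motion_tables is not None else None
            pm, rec = pp.preprocess_subject(
                m,
                motion=motion,
                n_discard=discard_volumes,
                smooth_fwhm=smooth_fwhm,
                filter_spec=filter_spec,
            )
            processed.append(pm)
            n_constant += rec.constant_columns
        report.add_stage(
            stage,
            t0,
            n_subjects=len(processed),
            discard_volumes=discard_volumes,
            cutoff_hz=cutoff_hz,
            constant_columns=n_constant,
        )

        stage = "concatenate"
        t0 = time.perf_counter()
        group = dc.concatenate_subjects(processed)
        report.add_stage(stage, t0, rows=group.n_rows, voxels=group.n_voxels)

        stage = "decompose"
        t0 = time.perf_counter()
        decomp = dc.decompose_group(
            group,
            n_pcs=n_pcs,
            n_ics=n_ics,
            seed=seed,
            contrast=contrast,
        )
        report.add_stage(
            stage,
            t0,
            n_pcs=decomp.n_pcs,
            n_ics=decomp.n_ics,
            convergence=decomp.convergence,
        )

        stage = "characterize"
        t0 = time.perf_counter()
        if cutoff_hz is None:
            edges = band_edges
            if edges == ch.HIGHFREQ_BAND_EDGES:
                edges = ch.LOWFREQ_BAND_EDGES
        else:
            edges = band_edges
        reports = ch.characterize_components(
            decomp.ic_timecourses,
            group.subject_boundaries,
            group.tr_seconds,
            spatial_maps=decomp.spatial_maps,
            band_edges=edges,
            rules=rules,
        )
        n_kept = sum(r.consistency.keep for r in reports)
        report.add_stage(
            stage, t0, n_components=len(reports), n_kept=n_kept
        )
    except Exception as err:
        raise PipelineError(stage, report, err) from err

    return AnalysisResult(group=group, decomposition=decomp, reports=reports)


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """File-based pipeline: load, analyze, write all outputs.

    Identical config (including seed) yields identical outputs; a stage
    failure raises :class:`PipelineError` naming the stage.
    """
    report = RunReport(config=config.to_dict())
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        t0 = time.perf_counter()
        matrices = []
        motions = []
        hashes = {}
        for fmri, motion_path in config.subjects:
            m = hio.load_masked_4d(fmri, config.mask, tr_seconds=config.tr_seconds)
            matrices.append(m)
            hashes[str(fmri)] = _file_hash(fmri)
            motions.append(
                hio.read_motion(motion_path) if motion_path else None
            )
        has_motion = all(mo is not None for mo in motions)
        if not has_motion and any(mo is not None for mo in motions):
            report.warnings.append(
                "motion files missing for some subjects; motion regression "
                "disabled for all"
            )
        report.add_stage(
            stage, t0, n_subjects=len(matrices), input_hashes=hashes
        )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, report, err) from err

    result = analyze_matrices(
        matrices,
        motion_tables=motions if has_motion else None,
        discard_volumes=config.discard_volumes,
        cutoff_hz=config.cutoff_hz,
        smooth_fwhm=config.smooth_fwhm,
        n_pcs=config.n_pcs,
        n_ics=config.n_ics,
        contrast=config.contrast,
        band_edges=config.band_edges,
        rules=config.rules,
        seed=config.seed,
        report=report,
    )

    stage = "write"
    try:
        t0 = time.perf_counter()
        hio.write_decomposition(result.decomposition, result.group, outdir)
        table = hio.write_component_table(
            result.reports, outdir / "components.tsv"
        )
        report.component_table = table.to_dict(orient="records")
        report.add_stage(stage, t0, output_dir=str(outdir))
        (outdir / "run_report.json").write_text(report.to_json())
    except Exception as err:
        raise PipelineError(stage, report, err) from err
    logger.info("pipeline complete: outputs in %s", outdir)
    return report
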