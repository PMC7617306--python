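"""End-to-end orchestration: FASTQ -> reference -> counts -> fates -> report.

A :class:`PipelineConfig` names the inputs (sample sheet with FASTQ paths,
library FASTQs) and all analysis thresholds; :func:`run_pipeline` executes
every stage, writes TSV outputs plus a machine-readable run manifest
(package/runtime versions, seed, config hash), and returns the report.
:func:`simulate_and_run` wires the synthetic generator in front of the
pipeline for self-tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import Thresholds
from .errors import CloneFateError, ConfigurationError
from .extract import HEAD_ANCHOR, TAIL_ANCHOR, BARCODE_LENGTH, write_qc_tsv
from .model import CloneFateModel
from .simulate import GeneratorConfig, simulate_experiment

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, anchors and thresholds of one pipeline run."""

    sample_sheet: str          # TSV: sample_id, fastq, cell_line, condition,
                               #      nk_genotype, timepoint, well, techrep
    library_fastqs: dict = field(default_factory=dict)  # sample_id -> path
    output_dir: str = "clonefate_out"
    head: str = HEAD_ANCHOR
    tail: str = TAIL_ANCHOR
    barcode_length: int = BARCODE_LENGTH
    min_total_reads: int = 100     # reference-library rule
    min_detect_total: int = 9      # detection filter
    reference_timepoint: str = "TP1"
    padj_cut: float = 0.05
    lfc_cut: float = 1.0
    v_alone_cut: float = 0.5
    v_nk_cut: float = 1.0
    high_well_bar: float = 1.0
    shrinkage_prior_df: float = 50.0
    seed: int = 0

    def thresholds(self) -> Thresholds:
        return Thresholds(self.padj_cut, self.lfc_cut, self.v_alone_cut,
                          self.v_nk_cut, self.high_well_bar)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", index_col="sample_id")
    required = {"fastq", "cell_line", "condition", "timepoint", "well", "techrep"}
    missing = required - set(sheet.columns)
    if missing:
        raise ConfigurationError(f"sample sheet missing columns: {sorted(missing)}")
    if "nk_genotype" not in sheet.columns:
        sheet["nk_genotype"] = np.where(sheet["condition"] == "nk", "WT", "none")
    return sheet


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute extract -> reference -> counts -> stats -> classify -> report.

    Returns the report dict; all tables land in ``config.output_dir``.
    Stage failures are re-raised with the stage name attached.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read-sample-sheet"
    try:
        sheet = _read_sample_sheet(config.sample_sheet)
        stage = "extract+reference+count"
        model = CloneFateModel.from_fastq(
            sheet, library_fastqs=config.library_fastqs or None,
            head=config.head, tail=config.tail,
            barcode_length=config.barcode_length,
            min_library_reads=config.min_total_reads,
            thresholds=config.thresholds(),
            min_detect_total=config.min_detect_total,
            reference_timepoint=config.reference_timepoint,
            shrinkage_prior_df=config.shrinkage_prior_df)
        stage = "stats+classify"
        results = model.fit()
        stage = "report"
        results.to_tsv(outdir)
        write_qc_tsv(model.extractions, outdir / "extraction_qc.tsv")
        if model.reference is not None:
            model.reference.to_tsv(outdir / "reference_library.tsv")
        (outdir / "summary.txt").write_text(results.summary() + "\n")
    except CloneFateError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    report = {
        "n_samples": int(len(sheet)),
        "n_reference_barcodes": (len(model.reference)
                                 if model.reference is not None else None),
        "n_retained_barcodes": int(len(results.retained)),
        "fate_counts": {
            tp: {k: int(v) for k, v in
                 results.fate_calls[tp].value_counts().items()}
            for tp in results.timepoints},
        "fate_proportions": {
            tp: {k: float(v) for k, v in results.fate_proportions(tp).items()}
            for tp in results.timepoints},
        "shannon": {sid: float(h) for sid, h
                    in results.diversity["shannon"].items()},
        "diversity_drop_TP2": results.diversity_drop("TP2"),
        "mean_discard_fraction": float(np.mean(
            [r.discard_fraction for r in model.extractions])),
    }
    manifest = {
        "package": "clonefate",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    report["_results"] = results
    report["_model"] = model
    return report


def simulate_and_run(gen_config: GeneratorConfig, workdir,
                     pipeline_overrides: dict | None = None) -> dict:
    """Synthesize an experiment, then run the full pipeline on its FASTQs."""
    workdir = Path(workdir)
    sim = simulate_experiment(gen_config, workdir / "sim")
    sheet = sim.coculture_counts.samples.copy()
    sheet.insert(0, "fastq", [str(sim.fastq[sid]) for sid in sheet.index])
    sheet_path = workdir / "sample_sheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index_label="sample_id")
    cfg = PipelineConfig(
        sample_sheet=str(sheet_path),
        library_fastqs={sid: str(p) for sid, p in sim.library_fastq.items()},
        output_dir=str(workdir / "out"),
        head=gen_config.head, tail=gen_config.tail,
        barcode_length=gen_config.barcode_length,
        seed=gen_config.seed,
        **(pipeline_overrides or {}))
    report = run_pipeline(cfg)
    report["_simulation"] = sim
    return report
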