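"""End-to-end pipeline: aggregate, align, filter, validate, intersect, report.

A single YAML config names the inputs and tunables::

    inputs:
      target: target.fasta        # first record is the target protein
      epitopes: epitopes.tsv
      binding: binding.tsv
      elisa: elisa.tsv            # or: reactive: reactive.tsv
    screen:
      min_identity: 7
      min_length: 12
      seed: 0
    elisa:
      cutoff_k: 1.0
      trim_k: 2.0
    output_dir: results

The run executes the stages in order, logs the per-stage counts, and writes
a hit table (``hits.tsv``), the reactive-antigen list it derived
(``reactive.tsv``) and a machine-readable ``report.json``. Reports are
byte-identical across reruns of the same inputs and config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .elisa import analyze_panel
from .io import (
    read_binding_table,
    read_elisa_table,
    read_epitope_table,
    read_fasta,
    read_reactive_list,
    write_hits_report,
    write_reactive_list,
)
from .matrices import load_matrix
from .screen import (
    immunogenicity_filter,
    intersect_with_reactive,
    screen_epitopes,
    summarize_by_disease,
)
from .types import FormatError, ScreenConfig

__all__ = ["PipelineError", "PipelineReport", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for actionable messages."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineReport:
    """Everything one pipeline run produced."""

    version: str
    seed: int
    config: dict
    stage_counts: dict[str, int]
    cutoff: float | None
    background_mean: float | None
    background_sd: float | None
    reactive_antigens: list[str]
    hits: list  # final MimicryHit objects
    disease_summary: pd.DataFrame = field(repr=False, default=None)
    paths: dict[str, str] = field(default_factory=dict)


def load_config(config_path: str | Path) -> dict:
    """Load and structurally validate a pipeline YAML config."""
    path = Path(config_path)
    if not path.exists():
        raise PipelineError("config", f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise PipelineError("config", f"{path}: expected a mapping with 'inputs'")
    inputs = cfg["inputs"]
    for key in ("target", "epitopes"):
        if key not in inputs:
            raise PipelineError("config", f"missing required input {key!r}")
    return cfg


def run_pipeline(
    config_path: str | Path, overrides: dict | None = None
) -> PipelineReport:
    """Run the full screen as configured; returns the report.

    ``overrides`` (flag > config > default precedence) are merged over the
    ``screen`` section. Outputs are written under ``output_dir`` when set.
    """
    cfg = load_config(config_path)
    inputs = cfg["inputs"]
    screen_cfg_dict = dict(cfg.get("screen") or {})
    if overrides:
        for k, v in overrides.items():
            if v is not None:
                logger.info("config override: %s = %r", k, v)
                screen_cfg_dict[k] = v
    try:
        config = ScreenConfig(**screen_cfg_dict)
    except (TypeError, ValueError) as exc:
        raise PipelineError("config", f"invalid screen settings: {exc}")
    elisa_cfg = dict(cfg.get("elisa") or {})
    counts: dict[str, int] = {}

    # stage 1: data aggregation
    try:
        proteins = read_fasta(inputs["target"])
        epitopes = read_epitope_table(
            inputs["epitopes"], column_map=cfg.get("column_map")
        )
    except FileNotFoundError as exc:
        raise PipelineError("aggregation", str(exc))
    except FormatError as exc:
        raise PipelineError("aggregation", str(exc))
    target = proteins[0]
    counts["epitopes_in"] = len(epitopes)
    logger.info("aggregation stage: %d epitopes, target %s (%d aa)",
                len(epitopes), target.id, len(target))

    # stage 2: sequence alignment + identity/length cutoff
    matrix = load_matrix(config.matrix_name)
    candidates = screen_epitopes(epitopes, target, config, matrix=matrix)
    counts["passed_identity_length"] = len(candidates)

    # stage 3: immunogenicity filtration
    if "binding" not in inputs:
        raise PipelineError(
            "immunogenicity", "config names no binding-prediction table"
        )
    try:
        binding = read_binding_table(inputs["binding"])
    except (FileNotFoundError, FormatError) as exc:
        raise PipelineError("immunogenicity", str(exc))
    immunogenic = immunogenicity_filter(candidates, binding, config)
    counts["immunogenic"] = len(immunogenic)

    # stage 4: cross-reactive antigen set (from ELISA ODs or a given list)
    cutoff = bg_mean = bg_sd = None
    if "reactive" in inputs:
        try:
            reactive = read_reactive_list(inputs["reactive"])
        except (FileNotFoundError, FormatError) as exc:
            raise PipelineError("reactivity", str(exc))
    elif "elisa" in inputs:
        try:
            measurements = read_elisa_table(inputs["elisa"])
        except (FileNotFoundError, FormatError) as exc:
            raise PipelineError("reactivity", str(exc))
        results, bg_mean, bg_sd, cutoff = analyze_panel(
            measurements,
            cutoff_k=elisa_cfg.get("cutoff_k", config.cutoff_k),
            trim_k=elisa_cfg.get("trim_k", 2.0),
            background_antigens=elisa_cfg.get("background_antigens"),
        )
        reactive = {r.antigen for r in results if r.reactive}
        logger.info(
            "reactivity stage: background mean %.4f sd %.4f cutoff %.4f; "
            "%d of %d antigens reactive",
            bg_mean, bg_sd, cutoff, len(reactive), len(measurements),
        )
    else:
        raise PipelineError(
            "reactivity", "config names neither an ELISA table nor a reactive list"
        )
    counts["reactive_antigens"] = len(reactive)

    # stage 5: intersection
    final = intersect_with_reactive(immunogenic, reactive)
    counts["final_hits"] = len(final)

    # stage 6: report
    summary = summarize_by_disease(final)
    report = PipelineReport(
        version=__version__,
        seed=config.seed,
        config={"screen": screen_cfg_dict, "elisa": elisa_cfg},
        stage_counts=counts,
        cutoff=cutoff,
        background_mean=bg_mean,
        background_sd=bg_sd,
        reactive_antigens=sorted(reactive),
        hits=final,
        disease_summary=summary,
    )

    outdir = cfg.get("output_dir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hits_path = outdir / "hits.tsv"
        write_hits_report(final, hits_path)
        reactive_path = outdir / "reactive.tsv"
        write_reactive_list(reactive, reactive_path)
        report_path = outdir / "report.json"
        payload = {
            "version": report.version,
            "seed": report.seed,
            "config": report.config,
            "stage_counts": report.stage_counts,
            "background_mean": bg_mean,
            "background_sd": bg_sd,
            "cutoff": cutoff,
            "reactive_antigens": report.reactive_antigens,
            "final_hits": [
                {
                    "epitope_id": h.epitope.epitope_id,
                    "parent_antigen": h.epitope.parent_antigen,
                    "human": h.alignment.aligned_query,
                    "mtg": h.alignment.aligned_target,
                    "ln": h.alignment.length,
                    "identity": h.alignment.n_identity,
                    "similarity": h.alignment.n_similarity,
                    "score": h.alignment.score,
                    "diseases": sorted(h.epitope.diseases),
                }
                for h in final
            ],
            "disease_summary": summary.to_dict(orient="records"),
        }
        report_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        report.paths = {
            "hits": str(hits_path),
            "reactive": str(reactive_path),
            "report": str(report_path),
        }
    return report
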