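"""End-to-end analysis pipeline: clean -> delineate -> diagnose -> score."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import delineation, signal_quality
from .diagnosis.network import ECGNet, NetworkConfig
from .diagnosis.training import predict
from .errors import EcgDeskError
from .health import RiskTable, score_from_items
from .io import read_record
from .signal_quality import FilterConfig

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    risk_table_path: str | None = None
    call_threshold: float = 0.5
    model_path: str | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        kwargs = {}
        if "filter" in raw:
            kwargs["filter"] = FilterConfig(**raw["filter"])
        if "network" in raw:
            kwargs["network"] = NetworkConfig(**raw["network"])
        for key in ("risk_table_path", "call_threshold", "model_path", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _risk_table(config: PipelineConfig) -> RiskTable:
    if config.risk_table_path:
        return RiskTable.from_csv(config.risk_table_path)
    return RiskTable.default()


def run_pipeline(record_path, config: PipelineConfig | None = None,
                 model: ECGNet | None = None) -> dict:
    """Run the full analysis chain on one record file.

    Returns a JSON-able dict; any stage failure is reported as a structured
    ``error`` object naming the stage.  If the record is flagged empty the
    pipeline halts after the quality stage.  Output is deterministic for
    fixed inputs and model.
    """
    config = config or PipelineConfig()
    result: dict = {"schema_version": SCHEMA_VERSION, "record": str(record_path)}

    stage = "read"
    try:
        record = read_record(record_path)
        result["sampling_rate"] = record.sampling_rate
        result["n_samples"] = record.n_samples

        stage = "quality"
        cleaned = signal_quality.clean(record, config.filter)
        result["provenance"] = sorted(cleaned.provenance)
        if cleaned.has_flag("empty"):
            result["status"] = "empty"
            return result

        stage = "delineation"
        peaks = delineation.detect_qrs(cleaned)
        annotations = delineation.delineate_waves(cleaned, peaks)
        result["annotations"] = annotations.as_dict()

        stage = "measurements"
        report = delineation.compute_measurements(annotations)
        result["measurements"] = report.as_dict()
        hrv = delineation.compute_hrv(peaks, cleaned.sampling_rate)
        result["hrv"] = hrv.as_dict()
        result["rr_scatter"] = delineation.rr_scatter(
            peaks, cleaned.sampling_rate
        ).as_dict()

        stage = "diagnosis"
        if model is None and config.model_path:
            model = ECGNet.load(config.model_path)
        if model is not None:
            diag = predict(model, cleaned, threshold=config.call_threshold)
            result["diagnosis"] = diag.as_dict()
            detected = {k for k, v in diag.calls.items() if v}
        else:
            result["diagnosis"] = None
            result["notices"] = ["diagnosis stage skipped: no trained model"]
            detected = set()

        stage = "score"
        score = score_from_items(detected & set(_risk_table(config).entries),
                                 _risk_table(config))
        result["health_score"] = score.as_dict()
        result["status"] = "ok"
    except EcgDeskError as exc:
        result["status"] = "error"
        result["error"] = {
            "stage": stage,
            "type": type(exc).__name__,
            "message": str(exc),
        }
    return result


def dump_result(result: dict, path=None) -> str:
    """Serialize a pipeline result with a stable key order."""
    text = json.dumps(result, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
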