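"""Structured analysis reports renderable to JSON, Markdown or HTML.

Every report opens with the Context-of-Use / Question-of-Interest header
and records input fingerprints and the seeds of all stochastic results, so
a report is regenerable bit-identically from the same inputs, seeds and
tool version.  The JSON rendering is lossless for numeric content and
deliberately excludes the timestamp so identical runs produce identical
bytes; Markdown and HTML include it.
"""

from __future__ import annotations

import dataclasses
import datetime
import html as _html
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ContextDoc

FORMATS = ("json", "markdown", "html")


def to_jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, numpy, pandas) to plain
    JSON-serializable structures."""
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": list(obj.columns),
            "index": list(obj.index),
            "rows": obj.to_numpy().tolist(),
        }
    if hasattr(obj, "to_dict"):
        return to_jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return str(obj)


@dataclass
class ResultBlock:
    """One analysis result: a kind label, parameters, the payload, and the
    seed when the analysis was stochastic."""

    kind: str
    payload: Any
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "parameters": to_jsonable(self.parameters),
            "seed": self.seed,
            "payload": to_jsonable(self.payload),
        }


@dataclass
class AnalysisReport:
    context: ContextDoc
    results: list[ResultBlock] = field(default_factory=list)
    inputs: list[dict] = field(default_factory=list)
    figures: list[str] = field(default_factory=list)
    tool_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
    )

    @property
    def seeds(self) -> list[int]:
        return [b.seed for b in self.results if b.seed is not None]

    def add(self, kind: str, payload: Any, parameters: dict | None = None,
            seed: int | None = None) -> None:
        self.results.append(
            ResultBlock(kind=kind, payload=payload,
                        parameters=parameters or {}, seed=seed)
        )

    def to_dict(self, with_timestamp: bool = False) -> dict:
        out = {
            "context": self.context.to_dict(),
            "tool_version": self.tool_version,
            "inputs": to_jsonable(self.inputs),
            "seeds": self.seeds,
            "results": [b.to_dict() for b in self.results],
            "figures": list(self.figures),
        }
        if with_timestamp:
            out["timestamp"] = self.timestamp
        return out


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Render the report; JSON is canonical (sorted keys, no timestamp)."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if format == "markdown":
        return _render_markdown(report)
    if format == "html":
        body = _render_markdown(report)
        return (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<title>Analysis report</title></head><body><pre>\n"
            + _html.escape(body)
            + "</pre></body></html>\n"
        )
    raise ValueError(f"unknown report format {format!r}; choose from {FORMATS}")


def _render_markdown(report: AnalysisReport) -> str:
    lines = [
        "# Analysis report",
        "",
        f"- Tool version: {report.tool_version}",
        f"- Generated: {report.timestamp}",
        "",
        "## Context of Use",
        "",
        report.context.cou or "(not provided)",
        "",
        "## Question of Interest",
        "",
        report.context.qoi or "(not provided)",
        "",
    ]
    if report.inputs:
        lines += ["## Inputs", ""]
        for fp in report.inputs:
            lines.append(
                f"- {fp.get('source', '?')} ({fp.get('provenance', '?')}): "
                f"{fp.get('n_rows', '?')} rows x {fp.get('n_columns', '?')} "
                f"columns, sha256 {str(fp.get('sha256', ''))[:12]}"
            )
        lines.append("")
    for block in report.results:
        lines += [f"## Result: {block.kind}", ""]
        if block.parameters:
            lines.append(
                "Parameters: "
                + json.dumps(to_jsonable(block.parameters), sort_keys=True)
            )
        if block.seed is not None:
            lines.append(f"Seed: {block.seed}")
        lines += [
            "",
            "```json",
            json.dumps(to_jsonable(block.payload), indent=2, sort_keys=True),
            "```",
            "",
        ]
    if report.figures:
        lines += ["## Figures", ""]
        lines += [f"- {path}" for path in report.figures]
        lines.append("")
    return "\n".join(lines)
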