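"""Structured JSON result report, validated through pydantic models.

``AnalysisReport.model_json_schema()`` is the schema the shipped
``report_schema.json`` mirrors; loading a report through
:func:`validate_report` enforces it.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict


class AIFReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    A1: float
    A2: float
    m1: float
    m2: float
    rss: float
    converged: bool


class GKMReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Ktrans: float | None
    Kep: float | None
    ve: float | None
    rss: float | None
    converged: bool
    offset: float | None = None


class TwoStageReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    split_min: float
    method: str
    stage2_mode: str
    stage1: GKMReport
    stage2: GKMReport
    weighted_ve: float | None


class AnalysisReport(BaseModel):
    model_config = ConfigDict(extra="forbid")
    input: str
    mode: str
    aif: AIFReport
    gkm: GKMReport | None = None
    two_stage: TwoStageReport | None = None

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def validate_report(path: str | Path) -> AnalysisReport:
    """Parse and schema-validate a report JSON file."""
    return AnalysisReport.model_validate(json.loads(Path(path).read_text()))


def schema() -> dict:
    return AnalysisReport.model_json_schema()


def gkm_report(fit) -> GKMReport:
    """Build a GKMReport from a :class:`dcekin.gkm.FitResult`."""
    import math

    return GKMReport(
        Ktrans=None if fit.params is None else fit.params.Ktrans,
        Kep=None if fit.params is None else fit.params.Kep,
        ve=None if (fit.params is None or math.isnan(fit.ve)) else fit.ve,
        rss=None if fit.rss != fit.rss else fit.rss,
        converged=fit.converged,
        offset=fit.offset,
    )
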