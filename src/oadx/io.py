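"""Tabular I/O, configuration and report rendering.

Specimens travel as UTF-8 comma-separated files with a header row.
Required columns: ``id``, ``comp_ng_ml``, ``il8_pg_ml``.  Optional:
``diagnosis``, ``comp_censor``, ``il8_censor``, ``kl_grade``, ``sex``,
``age`` and ``crystals``.  The ``crystals`` column encodes zero or more
microscopy observations as semicolon-separated
``shape:birefringence:parallel:perpendicular[:location]`` tokens, with
the literal ``none`` marking an examination that found no crystals; an
empty cell means microscopy was not performed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, TextIO, Union

from .accuracy import AccuracyReport, IntervalEstimate
from .crystals import CrystalObservation
from .errors import SchemaError, SpecimenValidationError
from .model import (
    CensorFlag,
    ClassificationResult,
    DecisionLimits,
    Diagnosis,
    Specimen,
    _round_half_up,
)

__all__ = [
    "RunConfig",
    "RowError",
    "LoadResult",
    "read_specimens",
    "write_specimens",
    "write_calls",
    "render_report",
    "parse_report",
]

REQUIRED_COLUMNS = ("id", "comp_ng_ml", "il8_pg_ml")
#: sentinel used when an infinite likelihood ratio must be printed
INFINITE_LR_SENTINEL = ">999"


@dataclass(frozen=True)
class RunConfig:
    """Validated run-level settings shared by the CLI commands."""

    limits: Optional[DecisionLimits] = None
    confidence: float = 0.95
    prevalence: Optional[float] = None
    roc_policy: str = "ratio_everywhere"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise SchemaError(f"confidence must be in (0, 1), got {self.confidence}")
        if self.prevalence is not None and not 0 < self.prevalence < 1:
            raise SchemaError(
                f"prevalence must be in (0, 1), got {self.prevalence}"
            )
        if self.roc_policy not in ("ratio_everywhere", "gated_zero"):
            raise SchemaError(f"unknown ROC policy {self.roc_policy!r}")


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based physical line number in the file
    message: str


@dataclass
class LoadResult:
    specimens: list[Specimen]
    errors: list[RowError] = field(default_factory=list)


def _parse_crystals(cell: str) -> Optional[list[CrystalObservation]]:
    cell = cell.strip()
    if not cell:
        return None
    if cell.lower() == "none":
        return []
    observations = []
    for token in cell.split(";"):
        parts = [p.strip() for p in token.split(":")]
        if len(parts) not in (4, 5):
            raise ValueError(
                f"crystal token {token!r} needs 4 or 5 colon-separated fields"
            )
        observations.append(
            CrystalObservation(
                shape=parts[0], birefringence=parts[1],
                parallel_color=parts[2], perpendicular_color=parts[3],
                location=parts[4] if len(parts) == 5 and parts[4] else None,
            )
        )
    return observations


def _crystals_to_cell(crystals) -> str:
    if crystals is None:
        return ""
    if not crystals:
        return "none"
    tokens = []
    for o in crystals:
        parts = [o.shape.value, o.birefringence.value,
                 o.parallel_color.value, o.perpendicular_color.value]
        if o.location is not None:
            parts.append(o.location.value)
        tokens.append(":".join(parts))
    return ";".join(tokens)


def read_specimens(
    source: Union[str, Path, TextIO],
    qc_hook: Optional[Callable[[Specimen], bool]] = None,
) -> LoadResult:
    """Load specimens from CSV, collecting row-level failures.

    A malformed row does not abort the load: it is recorded in
    ``errors`` with its physical line number while valid rows continue
    to parse.  Structural problems (missing required columns, an empty
    file) raise :class:`SchemaError`.

    ``qc_hook`` is an optional specimen-integrity predicate (e.g. an
    implementation of a spectrophotometric/cell-count acceptance range);
    specimens it rejects are recorded as row errors, mirroring the
    study's exclusion of diluted or blood-contaminated aspirates.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_specimens(fh, qc_hook=qc_hook)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise SchemaError("empty file: no header row")
    missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    specimens: list[Specimen] = []
    errors: list[RowError] = []
    n_rows = 0
    for row in reader:
        n_rows += 1
        line = reader.line_num
        try:
            specimens.append(_specimen_from_row(row))
        except (ValueError, SpecimenValidationError) as exc:
            errors.append(RowError(line=line, message=str(exc)))
            continue
        if qc_hook is not None and not qc_hook(specimens[-1]):
            bad = specimens.pop()
            errors.append(
                RowError(line=line, message=f"specimen {bad.id!r} failed QC")
            )
    if n_rows == 0:
        raise SchemaError("file contains a header but no specimen rows")
    return LoadResult(specimens=specimens, errors=errors)


def _specimen_from_row(row: dict) -> Specimen:
    def get(name: str) -> str:
        return (row.get(name) or "").strip()

    sid = get("id")
    if not sid:
        raise ValueError("missing specimen id")

    def number(col: str, required: bool) -> Optional[float]:
        cell = get(col)
        if not cell:
            if required:
                raise ValueError(f"missing value in column {col!r}")
            return None
        try:
            return float(cell)
        except ValueError:
            raise ValueError(f"unparseable number {cell!r} in column {col!r}")

    diagnosis = get("diagnosis") or "UNKNOWN"
    try:
        diagnosis = Diagnosis(diagnosis)
    except ValueError:
        raise ValueError(f"unknown diagnosis label {diagnosis!r}")
    kl = get("kl_grade")
    return Specimen(
        id=sid,
        comp=number("comp_ng_ml", required=True),
        il8=number("il8_pg_ml", required=True),
        diagnosis=diagnosis,
        comp_censor=CensorFlag(get("comp_censor") or "none"),
        il8_censor=CensorFlag(get("il8_censor") or "none"),
        kl_grade=int(kl) if kl else None,
        sex=get("sex") or None,
        age=number("age", required=False),
        crystals=_parse_crystals(get("crystals")),
    )


def write_specimens(specimens: Sequence[Specimen], sink: Union[str, Path, TextIO]) -> None:
    """Write specimens in the exact schema :func:`read_specimens` accepts."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            write_specimens(specimens, fh)
            return
    columns = list(REQUIRED_COLUMNS) + [
        "diagnosis", "comp_censor", "il8_censor", "kl_grade", "sex", "age",
        "crystals",
    ]
    writer = csv.writer(sink)
    writer.writerow(columns)
    for s in specimens:
        writer.writerow([
            s.id, repr(s.comp), repr(s.il8), s.diagnosis.value,
            s.comp_censor.value, s.il8_censor.value,
            s.kl_grade if s.kl_grade is not None else "",
            s.sex.value if s.sex is not None else "",
            repr(s.age) if s.age is not None else "",
            _crystals_to_cell(s.crystals),
        ])


def write_calls(
    specimens: Sequence[Specimen],
    results: Sequence[ClassificationResult],
    sink: Union[str, Path, TextIO],
) -> None:
    """Write per-specimen calls (id, call, reason, ratio) as CSV."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            write_calls(specimens, results, fh)
            return
    writer = csv.writer(sink)
    writer.writerow(["id", "call", "reason", "ratio"])
    for s, r in zip(specimens, results):
        writer.writerow([
            s.id, r.call, r.reason.value,
            repr(r.ratio) if r.ratio is not None else "",
        ])


# ---------------------------------------------------------------------------
# report rendering


def _pct(x: float) -> float:
    return _round_half_up(100.0 * x, 1)


def _ie_to_dict(ie: IntervalEstimate) -> dict:
    def enc(v: float):
        if math.isinf(v):
            return "inf"
        return v

    return {
        "point": enc(ie.point), "lower": enc(ie.lower), "upper": enc(ie.upper),
        "confidence": ie.confidence, "method": ie.method,
    }


def _ie_from_dict(d: dict) -> IntervalEstimate:
    def dec(v):
        return math.inf if v == "inf" else float(v)

    return IntervalEstimate(
        point=dec(d["point"]), lower=dec(d["lower"]), upper=dec(d["upper"]),
        confidence=float(d["confidence"]), method=d["method"],
    )


def report_to_dict(report: AccuracyReport) -> dict:
    ct = report.table
    return {
        "contingency": {"tp": ct.tp, "fn": ct.fn, "fp": ct.fp, "tn": ct.tn},
        "sensitivity": _ie_to_dict(report.sensitivity),
        "specificity": _ie_to_dict(report.specificity),
        "accuracy": _ie_to_dict(report.accuracy),
        "ppv": _ie_to_dict(report.ppv),
        "npv": _ie_to_dict(report.npv),
        "lr_pos": _ie_to_dict(report.lr_pos),
        "lr_neg": _ie_to_dict(report.lr_neg),
        "youden_j": report.youden_j,
        "prevalence_used": report.prevalence_used,
        "n": report.n,
        "confidence": report.confidence,
    }


def report_from_dict(d: dict) -> AccuracyReport:
    from .accuracy import ContingencyTable

    ct = ContingencyTable(**d["contingency"])
    return AccuracyReport(
        table=ct,
        sensitivity=_ie_from_dict(d["sensitivity"]),
        specificity=_ie_from_dict(d["specificity"]),
        accuracy=_ie_from_dict(d["accuracy"]),
        ppv=_ie_from_dict(d["ppv"]),
        npv=_ie_from_dict(d["npv"]),
        lr_pos=_ie_from_dict(d["lr_pos"]),
        lr_neg=_ie_from_dict(d["lr_neg"]),
        youden_j=float(d["youden_j"]),
        prevalence_used=float(d["prevalence_used"]),
        n=int(d["n"]),
        confidence=float(d["confidence"]),
    )


def _fmt_pct_ci(ie: IntervalEstimate) -> str:
    return f"{_pct(ie.point):.1f}% ({_pct(ie.lower):.1f}%–{_pct(ie.upper):.1f}%)"


def _fmt_lr(ie: IntervalEstimate, decimals: int) -> str:
    def one(v: float) -> str:
        if math.isinf(v):
            return INFINITE_LR_SENTINEL
        return f"{_round_half_up(v, decimals):.{decimals}f}"

    flag = "  [infinite: zero false-signal cell]" if math.isinf(ie.point) else ""
    if math.isinf(ie.point):
        return f"{one(ie.point)}{flag}"
    return f"{one(ie.point)} ({one(ie.lower)}–{one(ie.upper)})"


def render_report(report: AccuracyReport, format: str = "text") -> str:
    """Render an :class:`AccuracyReport` as JSON or an aligned text table.

    JSON round-trips losslessly through :func:`parse_report`.  The text
    layout prints percentages to one decimal with their confidence
    intervals, LR+ to one decimal and LR- to two, matching conventional
    diagnostic-accuracy reporting.
    """
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2)
    if format != "text":
        raise SchemaError(f"unknown report format {format!r}")
    ct = report.table
    prev_pct = _pct(report.prevalence_used)
    lines = [
        "Diagnostic accuracy report",
        "==========================",
        f"n = {report.n}   prevalence used = {prev_pct:.1f}%   "
        f"confidence = {report.confidence:.0%}",
        "",
        "              condition+  condition-",
        f"test positive {ct.tp:>10d}  {ct.fp:>10d}",
        f"test negative {ct.fn:>10d}  {ct.tn:>10d}",
        "",
        f"Sensitivity       {_fmt_pct_ci(report.sensitivity)}",
        f"Specificity       {_fmt_pct_ci(report.specificity)}",
        f"Overall accuracy  {_fmt_pct_ci(report.accuracy)}",
        f"PPV               {_fmt_pct_ci(report.ppv)}",
        f"NPV               {_fmt_pct_ci(report.npv)}",
        f"LR+               {_fmt_lr(report.lr_pos, 1)}",
        f"LR-               {_fmt_lr(report.lr_neg, 2)}",
        f"Youden J          {_round_half_up(report.youden_j, 2):.2f}",
    ]
    return "\n".join(lines) + "\n"


def parse_report(document: str) -> AccuracyReport:
    """Parse a JSON report document back into an :class:`AccuracyReport`."""
    return report_from_dict(json.loads(document))
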