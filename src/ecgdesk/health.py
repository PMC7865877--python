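"""Cardiovascular health scoring, passive alerts, and the retrospective report.

The score starts at 100 and each detected diagnosis item subtracts its
critical value (summed over items, floored at 0).  Two passive-alert rules
are evaluated over the score history: two consecutive scores below 85, or
three of the most recent five scores below 90.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field

from .diagnosis.items import ITEM_CODES
from .errors import ConfigError, ParseError, UnknownItemError

CATEGORIES = (
    "No Risk",
    "Medium-low Risk",
    "Medium Risk",
    "Medium-high Risk",
    "High Risk",
)

# Built-in risk table: item -> (category, critical value).
_BUILTIN_TABLE = {
    "SN": ("No Risk", 0),
    "SNA": ("Medium-low Risk", 2),
    "SNT": ("Medium-low Risk", 5),
    "SNB": ("Medium-low Risk", 5),
    "LBBB": ("Medium Risk", 9),
    "PVC": ("Medium Risk", 12),
    "PJC": ("Medium Risk", 12),
    "PAC": ("Medium Risk", 12),
    "RBBB": ("Medium Risk", 15),
    "WPW": ("Medium-high Risk", 16),
    "VE": ("Medium-high Risk", 16),
    "AE": ("Medium-high Risk", 16),
    "JE": ("Medium-high Risk", 16),
    "AVBI": ("Medium-high Risk", 16),
    "AFL": ("Medium-high Risk", 25),
    "AF": ("Medium-high Risk", 25),
    "AVBII": ("Medium-high Risk", 25),
    "VT": ("High Risk", 50),
    "SVT": ("High Risk", 50),
    "AVBIII": ("High Risk", 50),
}

ALERT_LOW_THRESHOLD = 85
ALERT_HIGH_THRESHOLD = 90

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RiskTable:
    """Item -> (risk category, critical value) mapping."""

    entries: dict = field(default_factory=lambda: dict(_BUILTIN_TABLE))
    version: str = "builtin-1"

    def __post_init__(self):
        if set(self.entries) != set(ITEM_CODES):
            missing = set(ITEM_CODES) - set(self.entries)
            extra = set(self.entries) - set(ITEM_CODES)
            raise ConfigError(
                f"risk table must cover all 20 items exactly once "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for item, (cat, value) in self.entries.items():
            if cat not in CATEGORIES:
                raise ConfigError(f"unknown category {cat!r} for {item}")
            if not (isinstance(value, int) and value >= 0):
                raise ConfigError(f"critical value for {item} must be a non-negative int")

    @classmethod
    def default(cls) -> "RiskTable":
        return cls()

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        entries = {}
        try:
            with open(path, newline="") as fh:
                for i, row in enumerate(csv.DictReader(fh)):
                    try:
                        entries[row["item"]] = (
                            row["category"],
                            int(row["critical_value"]),
                        )
                    except (KeyError, ValueError) as exc:
                        raise ParseError(f"{path}: bad row {i + 2}: {exc}") from exc
        except OSError as exc:
            raise ParseError(f"cannot read risk table {path}: {exc}") from exc
        return cls(entries=entries, version=str(path))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["item", "category", "critical_value"])
            for item in ITEM_CODES:
                cat, value = self.entries[item]
                writer.writerow([item, cat, value])

    def critical_value(self, item: str) -> int:
        self._check(item)
        return self.entries[item][1]

    def _check(self, item: str) -> None:
        if item not in self.entries:
            raise UnknownItemError(f"unknown diagnosis item {item!r}")


@dataclass(frozen=True)
class HealthScore:
    score: int
    detected_items: frozenset
    deductions: dict
    timestamp: str | None = None

    def as_dict(self) -> dict:
        return {
            "score": self.score,
            "detected_items": sorted(self.detected_items),
            "deductions": dict(sorted(self.deductions.items())),
            "timestamp": self.timestamp,
        }


@dataclass(frozen=True)
class AlertDecision:
    triggered: bool
    rule: str  # "none" | "two_consecutive_below_85" | "three_of_last_five_below_90"
    window: tuple

    def as_dict(self) -> dict:
        return {"triggered": self.triggered, "rule": self.rule,
                "window": list(self.window)}


def score_from_items(
    detected,
    table: RiskTable | None = None,
    combination: str = "sum",
    timestamp: str | None = None,
) -> HealthScore:
    """Score a detected item set: 100 minus the (clamped) deduction total.

    ``combination`` is ``"sum"`` (default: deductions add up) or ``"max"``
    (only the largest deduction counts).  SN carries no deduction.
    """
    table = table or RiskTable.default()
    detected = frozenset(detected)
    for item in detected:
        table._check(item)
    if combination not in ("sum", "max"):
        raise ConfigError(f"unknown combination rule {combination!r}")

    deductions = {
        item: table.critical_value(item)
        for item in detected
        if table.critical_value(item) > 0
    }
    if combination == "sum":
        total = sum(deductions.values())
    else:
        total = max(deductions.values(), default=0)
    return HealthScore(
        score=max(0, 100 - total),
        detected_items=detected,
        deductions=deductions,
        timestamp=timestamp,
    )


def risk_category(item: str, table: RiskTable | None = None) -> str:
    """The printed risk category of a diagnosis item."""
    table = table or RiskTable.default()
    table._check(item)
    return table.entries[item][0]


def evaluate_alert(history) -> AlertDecision:
    """Evaluate the two passive-alert rules over a time-ordered score history.

    Rule 1 fires iff the last two scores are both strictly below 85; rule 2
    fires iff at least 3 of the most recent min(5, n) scores are strictly
    below 90.  Rule 1 takes precedence when both fire.
    """
    history = list(history)
    if not history:
        raise ConfigError("score history must be non-empty")

    if len(history) >= 2 and all(s < ALERT_LOW_THRESHOLD for s in history[-2:]):
        return AlertDecision(True, "two_consecutive_below_85", tuple(history[-2:]))
    window = history[-5:]
    if sum(s < ALERT_HIGH_THRESHOLD for s in window) >= 3:
        return AlertDecision(True, "three_of_last_five_below_90", tuple(window))
    return AlertDecision(False, "none", tuple(window))


def build_retrospective_report(
    diagnoses,
    measurements=None,
    hrv=None,
    rr_points=None,
    scores=None,
    period: tuple[str, str] | None = None,
    average_beat_ref: str | None = None,
) -> dict:
    """Assemble the weekly-style retrospective report as a JSON-able dict.

    ``diagnoses`` is a sequence of per-recording detected item sets;
    ``measurements``/``hrv``/``rr_points`` are the corresponding summaries;
    ``scores`` the time-ordered score history for the period.
    """
    diagnoses = [frozenset(d) for d in (diagnoses or [])]
    if not diagnoses:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "empty": True,
            "period": list(period) if period else None,
        }

    counts = {item: 0 for item in ITEM_CODES}
    for detected in diagnoses:
        for item in detected:
            if item not in counts:
                raise UnknownItemError(f"unknown diagnosis item {item!r}")
            counts[item] += 1

    scores = list(scores or [])
    alert = evaluate_alert(scores).as_dict() if scores else None
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "empty": False,
        "period": list(period) if period else None,
        "generated_at": _dt.date.today().isoformat(),
        "n_recordings": len(diagnoses),
        "item_counts": counts,
        "measurements": measurements,
        "hrv": hrv,
        "rr_scatter": rr_points,
        "average_beat": average_beat_ref,
        "scores": scores,
        "alert": alert,
    }
    return report


def render_report_text(report: dict) -> str:
    """Plain-text rendering of a retrospective report."""
    if report.get("empty"):
        return "Retrospective report: no recordings in period.\n"
    lines = [
        f"Retrospective report (schema v{report['schema_version']})",
        f"Period: {report.get('period')}",
        f"Recordings: {report['n_recordings']}",
        "Detections:",
    ]
    for item, count in report["item_counts"].items():
        if count:
            lines.append(f"  {item}: {count}")
    if report.get("scores"):
        lines.append(f"Scores: {report['scores']}")
    if report.get("alert"):
        a = report["alert"]
        lines.append(f"Alert: triggered={a['triggered']} rule={a['rule']}")
    return "\n".join(lines) + "\n"
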