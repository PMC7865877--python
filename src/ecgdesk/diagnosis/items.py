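"""The 20 supported diagnostic items."""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import UnknownItemError


@dataclass(frozen=True)
class DiagnosisItem:
    abbreviation: str
    name: str
    group: str
    subgroup: str


ITEMS = (
    DiagnosisItem("SN", "Sinus Rhythm", "Sinus Rhythm", "Sinus Rhythm"),
    DiagnosisItem("SNA", "Sinus Arrhythmia", "Sinus Rhythm", "Sinus Abnormality"),
    DiagnosisItem("SNT", "Sinus Tachycardia", "Sinus Rhythm", "Sinus Abnormality"),
    DiagnosisItem("SNB", "Sinus Bradycardia", "Sinus Rhythm", "Sinus Abnormality"),
    DiagnosisItem("PVC", "Premature Ventricular Contraction", "Tachyarrhythmia",
                  "Premature Beat"),
    DiagnosisItem("PJC", "Premature Junctional Contraction", "Tachyarrhythmia",
                  "Premature Beat"),
    DiagnosisItem("PAC", "Premature Atrial Contraction", "Tachyarrhythmia",
                  "Premature Beat"),
    DiagnosisItem("VT", "Ventricular Tachycardia", "Tachyarrhythmia", "Tachycardia"),
    DiagnosisItem("SVT", "Supraventricular Tachycardia", "Tachyarrhythmia",
                  "Tachycardia"),
    DiagnosisItem("AFL", "Atrial Flutter", "Tachyarrhythmia",
                  "Flutter and Fibrillation"),
    DiagnosisItem("AF", "Atrial Fibrillation", "Tachyarrhythmia",
                  "Flutter and Fibrillation"),
    DiagnosisItem("WPW", "Wolff-Parkinson-White Syndrome", "Tachyarrhythmia",
                  "Pre-excitation"),
    DiagnosisItem("VE", "Ventricular Escape", "Bradyarrhythmia", "Escape Beat"),
    DiagnosisItem("AE", "Atrial Escape", "Bradyarrhythmia", "Escape Beat"),
    DiagnosisItem("JE", "Junctional Escape", "Bradyarrhythmia", "Escape Beat"),
    DiagnosisItem("AVBI", "First Degree Atrioventricular Block", "Bradyarrhythmia",
                  "Atrioventricular Block"),
    DiagnosisItem("AVBII", "Second Degree Atrioventricular Block", "Bradyarrhythmia",
                  "Atrioventricular Block"),
    DiagnosisItem("AVBIII", "Third Degree Atrioventricular Block", "Bradyarrhythmia",
                  "Atrioventricular Block"),
    DiagnosisItem("LBBB", "Left Bundle Branch Block", "Bradyarrhythmia",
                  "Intraventricular Block"),
    DiagnosisItem("RBBB", "Right Bundle Branch Block", "Bradyarrhythmia",
                  "Intraventricular Block"),
)

ITEM_CODES = tuple(item.abbreviation for item in ITEMS)
ITEM_INDEX = {code: i for i, code in enumerate(ITEM_CODES)}


def get_item(code: str) -> DiagnosisItem:
    try:
        return ITEMS[ITEM_INDEX[code]]
    except KeyError:
        raise UnknownItemError(f"unknown diagnosis item {code!r}") from None
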