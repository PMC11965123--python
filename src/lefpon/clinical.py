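"""Clinical response scoring: DAS28(4, ESR), EULAR categories, blood indices.

DAS28 uses the four-variable ESR form

    DAS28 = 0.56 * sqrt(TJC28) + 0.28 * sqrt(SJC28) + 0.70 * ln(ESR) + 0.014 * VAS

with VAS on the 0-100 mm scale. EULAR response is derived from the
improvement dDAS28 = baseline - month 6 and the month-6 endpoint; good
and moderate responders are pooled into a single "responder" flag for
the association analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

Category = Literal["good", "moderate", "none"]


@dataclass(frozen=True)
class ClinicalVisit:
    """Single-visit disease-activity components (28-joint assessment)."""

    tjc28: int
    sjc28: int
    esr: float
    vas: float

    def __post_init__(self) -> None:
        if not 0 <= self.tjc28 <= 28:
            raise ValueError(f"tjc28 out of range 0-28: {self.tjc28}")
        if not 0 <= self.sjc28 <= 28:
            raise ValueError(f"sjc28 out of range 0-28: {self.sjc28}")
        if not self.esr > 0:
            raise ValueError(f"esr must be strictly positive (mm/h): {self.esr}")
        if not 0 <= self.vas <= 100:
            raise ValueError(f"vas out of range 0-100 mm: {self.vas}")


@dataclass(frozen=True)
class ResponseAssessment:
    das28_baseline: float
    das28_month6: float
    delta_das28: float
    category: Category
    responder: int


@dataclass(frozen=True)
class InflammationIndices:
    nlr: float
    plr: float
    sii: float
    siri: float


def das28(visit: ClinicalVisit) -> float:
    """Four-variable DAS28-ESR for one visit."""
    return (
        0.56 * math.sqrt(visit.tjc28)
        + 0.28 * math.sqrt(visit.sjc28)
        + 0.70 * math.log(visit.esr)
        + 0.014 * visit.vas
    )


def classify_response(das28_baseline: float, das28_month6: float) -> ResponseAssessment:
    """EULAR response category from baseline and month-6 DAS28.

    good:     improvement > 1.2 and endpoint <= 3.2
    none:     improvement <= 0.6, or improvement in (0.6, 1.2] with endpoint > 5.1
    moderate: everything else

    The boundary improvement of exactly 0.6 counts as non-response
    regardless of endpoint (half-open middle band, standard EULAR table).
    """
    if not (math.isfinite(das28_baseline) and math.isfinite(das28_month6)):
        raise ValueError("DAS28 scores must be finite")
    delta = das28_baseline - das28_month6
    if delta > 1.2 and das28_month6 <= 3.2:
        category: Category = "good"
    elif delta <= 0.6 or (delta <= 1.2 and das28_month6 > 5.1):
        category = "none"
    else:
        category = "moderate"
    return ResponseAssessment(
        das28_baseline=das28_baseline,
        das28_month6=das28_month6,
        delta_das28=delta,
        category=category,
        responder=int(category != "none"),
    )


def inflammation_indices(
    neut: float, lymph: float, mono: float, plt: float
) -> InflammationIndices:
    """NLR, PLR, SII and SIRI from blood counts in 10^9/L.

    NLR = neut/lymph; PLR = plt/lymph; SII = neut*plt/lymph;
    SIRI = neut*mono/lymph.
    """
    if lymph <= 0:
        raise ValueError("lymphocyte count must be strictly positive")
    if neut <= 0 or mono <= 0 or plt <= 0:
        raise ValueError("blood counts must be strictly positive")
    return InflammationIndices(
        nlr=neut / lymph,
        plr=plt / lymph,
        sii=neut * plt / lymph,
        siri=neut * mono / lymph,
    )
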