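"""Scoring and severity banding for the four clinical instruments.

The study instruments are:

* **MINISM** — the MINI International Neuropsychiatric Interview's
  Suicidality Module.  Total score 0–52, banded as 0 (absence of risk),
  1–8 (low), 9–16 (moderate) and >= 17 (high suicide risk).  The high-risk
  flag used throughout the analysis is ``total >= 17``.
* **SDS / SAS** — the Zung Self-Rating Depression / Anxiety Scales.
  20 items each, rated 1–4; the standard score is the raw total times 1.25
  (so it lives on a 25–100 scale).  Severity is banded on the standard
  score by the Chinese normative cutoffs.
* **PHCSS** — the Piers-Harris Children's Self-Concept Scale.  60 yes/no
  items; a total of 52 or more counts as normal self-concept.

Standard scores are banded on their exact (possibly fractional) value with
closed lower bounds — no intermediate rounding, so 62.5 falls in the band
below 63, never in both.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence


class Severity(str, Enum):
    """Four-level symptom severity used for both depression and anxiety."""

    normal = "normal"
    mild_moderate = "mild_moderate"
    moderate_severe = "moderate_severe"
    severe = "severe"


class SuicideRiskBand(str, Enum):
    absence = "absence"
    low = "low"
    moderate = "moderate"
    high = "high"


class SelfConceptCategory(str, Enum):
    low = "low"
    normal = "normal"


#: Closed lower bounds of the mild_moderate / moderate_severe / severe bands,
#: applied to the standard score.  SDS: 25-52 normal, 53-62 mild-moderate,
#: 63-72 moderate-severe, >=73 severe.
SDS_BAND_LOWER_BOUNDS = (53.0, 63.0, 73.0)

#: SAS: 25-49 normal, 50-59 mild-moderate, 60-69 moderate-severe, >=70 severe.
#: The published cutoff text overlaps at 69; the severe band is taken to
#: start at 70 by analogy with the SDS band widths.
SAS_BAND_LOWER_BOUNDS = (50.0, 60.0, 70.0)

#: MINISM high-suicide-risk threshold (closed lower bound).
MINISM_HIGH_RISK_THRESHOLD = 17

#: PHCSS normal-self-concept threshold (closed lower bound).
PHCSS_NORMAL_THRESHOLD = 52

STANDARD_SCORE_FACTOR = 1.25


class ScaleValidationError(ValueError):
    """An item vector or total violates the instrument's domain."""


@dataclass(frozen=True)
class ScaleScore:
    """Scored SDS or SAS questionnaire."""

    instrument: str
    raw_total: int
    standard_score: float
    band: Severity


@dataclass(frozen=True)
class SuicideRiskAssessment:
    minism_total: int
    band: SuicideRiskBand
    high_risk: int


@dataclass(frozen=True)
class SelfConceptAssessment:
    phcss_total: int
    category: SelfConceptCategory


def _validate_items(items: Sequence[int], n: int, lo: int, hi: int, instrument: str) -> None:
    if len(items) != n:
        raise ScaleValidationError(
            f"{instrument} expects {n} items, got {len(items)}"
        )
    for i, v in enumerate(items):
        try:
            ok = lo <= int(v) <= hi and int(v) == v
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise ScaleValidationError(
                f"{instrument} item {i} = {v!r} outside allowed range {lo}..{hi}"
            )


def _band_standard(standard: float, lower_bounds: tuple[float, float, float]) -> Severity:
    mild, moderate, severe = lower_bounds
    if standard >= severe:
        return Severity.severe
    if standard >= moderate:
        return Severity.moderate_severe
    if standard >= mild:
        return Severity.mild_moderate
    return Severity.normal


def sds_from_total(raw_total: int) -> ScaleScore:
    """Score the SDS from a precomputed raw total (20..80)."""
    if not 20 <= raw_total <= 80:
        raise ScaleValidationError(f"SDS raw total {raw_total} outside 20..80")
    standard = raw_total * STANDARD_SCORE_FACTOR
    return ScaleScore("SDS", int(raw_total), standard, _band_standard(standard, SDS_BAND_LOWER_BOUNDS))


def sas_from_total(raw_total: int) -> ScaleScore:
    """Score the SAS from a precomputed raw total (20..80)."""
    if not 20 <= raw_total <= 80:
        raise ScaleValidationError(f"SAS raw total {raw_total} outside 20..80")
    standard = raw_total * STANDARD_SCORE_FACTOR
    return ScaleScore("SAS", int(raw_total), standard, _band_standard(standard, SAS_BAND_LOWER_BOUNDS))


def score_sds(items: Sequence[int]) -> ScaleScore:
    """Score a 20-item SDS response vector (each item 1..4)."""
    _validate_items(items, 20, 1, 4, "SDS")
    return sds_from_total(int(sum(items)))


def score_sas(items: Sequence[int]) -> ScaleScore:
    """Score a 20-item SAS response vector (each item 1..4)."""
    _validate_items(items, 20, 1, 4, "SAS")
    return sas_from_total(int(sum(items)))


def band_minism(total: int) -> SuicideRiskAssessment:
    """Band a MINISM total (0..52) into absence/low/moderate/high risk."""
    if not 0 <= total <= 52:
        raise ScaleValidationError(f"MINISM total {total} outside 0..52")
    total = int(total)
    if total >= MINISM_HIGH_RISK_THRESHOLD:
        band = SuicideRiskBand.high
    elif total >= 9:
        band = SuicideRiskBand.moderate
    elif total >= 1:
        band = SuicideRiskBand.low
    else:
        band = SuicideRiskBand.absence
    return SuicideRiskAssessment(total, band, int(band is SuicideRiskBand.high))


def phcss_from_total(total: int) -> SelfConceptAssessment:
    """Categorise a PHCSS total (0..60) as low or normal self-concept."""
    if not 0 <= total <= 60:
        raise ScaleValidationError(f"PHCSS total {total} outside 0..60")
    total = int(total)
    category = (
        SelfConceptCategory.normal
        if total >= PHCSS_NORMAL_THRESHOLD
        else SelfConceptCategory.low
    )
    return SelfConceptAssessment(total, category)


def score_phcss(items: Sequence[int]) -> SelfConceptAssessment:
    """Score a 60-item yes/no (1/0) PHCSS response vector."""
    _validate_items(items, 60, 0, 1, "PHCSS")
    return phcss_from_total(int(sum(items)))
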