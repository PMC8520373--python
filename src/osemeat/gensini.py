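"""Gensini coronary severity score and stenosed-vessel-count classification.

The Gensini system scores each coronary lesion as (severity points) x
(segment coefficient) and sums over lesions.  Severity points double
with each stenosis bracket: <=25% -> 1, 26-50% -> 2, 51-75% -> 4,
76-90% -> 8, 91-99% -> 16, total occlusion -> 32.  Segment coefficients
weight prognostically critical territory: left main 5, proximal
LAD/LCX 2.5, mid LAD 1.5, most other segments 1, second diagonal 0.5.

The number of stenosed coronary vessels (NSCV) counts which of the
three major vessels (LAD, LCX, RCA) carries at least one lesion at or
above a stenosis threshold (default 50%, the angiographic CHD
definition); left-main disease supplies both the LAD and the LCX and
therefore counts as two-vessel disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import pandas as pd


class Vessel(str, Enum):
    LAD = "LAD"
    LCX = "LCX"
    RCA = "RCA"


class CoronarySegment(str, Enum):
    LM = "LM"
    LAD_PROX = "LAD_PROX"
    LAD_MID = "LAD_MID"
    LAD_DIST = "LAD_DIST"
    LCX_PROX = "LCX_PROX"
    LCX_DIST = "LCX_DIST"
    OM = "OM"
    RCA_PROX = "RCA_PROX"
    RCA_MID = "RCA_MID"
    RCA_DIST = "RCA_DIST"
    PDA = "PDA"
    DIAG2 = "DIAG2"


SEGMENT_COEFFICIENTS: dict[CoronarySegment, float] = {
    CoronarySegment.LM: 5.0,
    CoronarySegment.LAD_PROX: 2.5,
    CoronarySegment.LCX_PROX: 2.5,
    CoronarySegment.LAD_MID: 1.5,
    CoronarySegment.LAD_DIST: 1.0,
    CoronarySegment.LCX_DIST: 1.0,
    CoronarySegment.OM: 1.0,
    CoronarySegment.RCA_PROX: 1.0,
    CoronarySegment.RCA_MID: 1.0,
    CoronarySegment.RCA_DIST: 1.0,
    CoronarySegment.PDA: 1.0,
    CoronarySegment.DIAG2: 0.5,
}

# left main feeds both the LAD and LCX territories
SEGMENT_VESSELS: dict[CoronarySegment, tuple[Vessel, ...]] = {
    CoronarySegment.LM: (Vessel.LAD, Vessel.LCX),
    CoronarySegment.LAD_PROX: (Vessel.LAD,),
    CoronarySegment.LAD_MID: (Vessel.LAD,),
    CoronarySegment.LAD_DIST: (Vessel.LAD,),
    CoronarySegment.DIAG2: (Vessel.LAD,),
    CoronarySegment.LCX_PROX: (Vessel.LCX,),
    CoronarySegment.LCX_DIST: (Vessel.LCX,),
    CoronarySegment.OM: (Vessel.LCX,),
    CoronarySegment.RCA_PROX: (Vessel.RCA,),
    CoronarySegment.RCA_MID: (Vessel.RCA,),
    CoronarySegment.RCA_DIST: (Vessel.RCA,),
    CoronarySegment.PDA: (Vessel.RCA,),
}


@dataclass(frozen=True)
class Lesion:
    segment: CoronarySegment
    stenosis_pct: float

    def __post_init__(self) -> None:
        seg = self.segment
        if not isinstance(seg, CoronarySegment):
            try:
                object.__setattr__(self, "segment", CoronarySegment(str(seg)))
            except ValueError as exc:
                raise ValueError(f"unknown coronary segment {seg!r}") from exc
        if not (0.0 <= self.stenosis_pct <= 100.0):
            raise ValueError("stenosis_pct must lie in [0, 100]")


@dataclass
class GensiniResult:
    total: float
    per_lesion: list[tuple[Lesion, int, float]] = field(default_factory=list)


@dataclass
class VesselClassification:
    stenosed_vessels: frozenset[Vessel]
    category: str  # none | single | double | multi
    threshold_pct: float = 50.0


def stenosis_points(pct: float) -> int:
    """Severity points for a luminal diameter stenosis percentage."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"stenosis percentage {pct} outside [0, 100]")
    if pct == 0:
        return 0
    if pct <= 25:
        return 1
    if pct <= 50:
        return 2
    if pct <= 75:
        return 4
    if pct <= 90:
        return 8
    if pct < 100:
        return 16
    return 32


def gensini_score(lesions: Iterable[Lesion]) -> GensiniResult:
    """Sum of points x segment coefficient over all lesions (empty -> 0)."""
    per_lesion: list[tuple[Lesion, int, float]] = []
    total = 0.0
    for lesion in lesions:
        pts = stenosis_points(lesion.stenosis_pct)
        contrib = pts * SEGMENT_COEFFICIENTS[lesion.segment]
        per_lesion.append((lesion, pts, contrib))
        total += contrib
    return GensiniResult(total=total, per_lesion=per_lesion)


def classify_nscv(
    lesions: Iterable[Lesion], threshold_pct: float = 50.0
) -> VesselClassification:
    """Classify disease extent by the number of stenosed major vessels."""
    stenosed: set[Vessel] = set()
    for lesion in lesions:
        if lesion.stenosis_pct >= threshold_pct:
            stenosed.update(SEGMENT_VESSELS[lesion.segment])
    category = {0: "none", 1: "single", 2: "double", 3: "multi"}[len(stenosed)]
    return VesselClassification(
        stenosed_vessels=frozenset(stenosed),
        category=category,
        threshold_pct=threshold_pct,
    )


def score_lesion_table(df: pd.DataFrame, threshold_pct: float = 50.0) -> pd.DataFrame:
    """Per-patient Gensini totals and NSCV categories from a lesion table.

    Expects columns ``patient_id``, ``segment``, ``stenosis_pct``; a
    patient whose rows all have 0% stenosis scores 0 and is 'none'.
    """
    required = {"patient_id", "segment", "stenosis_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lesion table missing columns: {sorted(missing)}")
    out = []
    for pid, rows in df.groupby("patient_id", sort=True):
        lesions = [
            Lesion(segment=r.segment, stenosis_pct=float(r.stenosis_pct))
            for r in rows.itertuples()
        ]
        out.append(
            {
                "patient_id": pid,
                "gensini": gensini_score(lesions).total,
                "nscv_category": classify_nscv(lesions, threshold_pct).category,
            }
        )
    return pd.DataFrame(out)
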