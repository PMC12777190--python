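"""Kauppila grading arithmetic for abdominal aortic calcification.

The Kauppila protocol grades the anterior and posterior aortic wall at each
lumbar level L1-L4 by the fraction of the segment length that is calcified:
grade 0 (none), 1 (< 1/3), 2 (1/3 to 2/3, inclusive), 3 (> 2/3).  The two
wall grades sum to a per-segment score (0-6); the four segment scores sum to
the total AACS (0-24), which is binned into three severity classes:
no/mild (total <= 4), moderate (4 < total <= 15), severe (15 < total <= 24).

Fractions of exactly 1/3 or 2/3 receive grade 2 (the middle interval is read
as inclusive); synthetic data avoids exact boundaries, so the convention only
matters for hand-typed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

SEGMENT_LEVELS = ("L1", "L2", "L3", "L4")
SEVERITY_CLASSES = ("no_mild", "moderate", "severe")

# float boundaries so that an input typed as 1/3 or 2/3 lands in the
# inclusive middle interval
_ONE_THIRD = 1.0 / 3.0
_TWO_THIRDS = 2.0 / 3.0


@dataclass(frozen=True)
class PlaqueSpec:
    """A single calcified plaque on one aortic wall.

    coverage_fraction is the fraction of the segment's superoinferior length
    the plaque spans; thickness is its anteroposterior extent in pixels.
    """

    segment_level: str
    wall: str  # "anterior" | "posterior"
    coverage_fraction: float
    thickness: float = 4.0
    start_fraction: float = 0.0  # offset of the plaque start along the segment

    def __post_init__(self) -> None:
        if self.segment_level not in SEGMENT_LEVELS:
            raise ValueError(f"unknown segment level {self.segment_level!r}")
        if self.wall not in ("anterior", "posterior"):
            raise ValueError(f"unknown wall {self.wall!r}")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError(
                f"coverage_fraction {self.coverage_fraction} outside [0, 1]"
            )


@dataclass(frozen=True)
class AACSRecord:
    """Per-segment scores, total AACS and severity class."""

    segment_scores: Mapping[str, int]
    total: int
    severity: str

    def to_dict(self) -> dict:
        return {
            "segment_scores": dict(self.segment_scores),
            "total": self.total,
            "severity": self.severity,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AACSRecord":
        return total_aacs({k: int(v) for k, v in d["segment_scores"].items()})


def wall_grade(coverage_fraction: float) -> int:
    """Grade one aortic wall from its calcified length fraction.

    0 if no calcification, 1 if < 1/3 of segment length, 2 if between 1/3 and
    2/3 (inclusive), 3 if > 2/3.
    """
    f = float(coverage_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"coverage fraction {f} outside [0, 1]")
    if f == 0.0:
        return 0
    if f < _ONE_THIRD:
        return 1
    if f <= _TWO_THIRDS:
        return 2
    return 3


def segment_score(anterior: int, posterior: int) -> int:
    """Per-segment score: anterior grade + posterior grade (0-6)."""
    for g in (anterior, posterior):
        if g not in (0, 1, 2, 3):
            raise ValueError(f"wall grade {g} outside 0-3")
    return anterior + posterior


def severity_class(total: int) -> str:
    """Severity bin of a total AACS: no_mild (<=4), moderate (<=15), severe."""
    if not 0 <= total <= 24:
        raise ValueError(f"total AACS {total} outside 0-24")
    if total <= 4:
        return "no_mild"
    if total <= 15:
        return "moderate"
    return "severe"


def total_aacs(segment_scores: Mapping[str, int]) -> AACSRecord:
    """Assemble an AACSRecord from the four per-segment scores."""
    missing = [lv for lv in SEGMENT_LEVELS if lv not in segment_scores]
    if missing:
        raise ValueError(f"missing segment level(s): {', '.join(missing)}")
    scores = {}
    for lv in SEGMENT_LEVELS:
        s = int(segment_scores[lv])
        if not 0 <= s <= 6:
            raise ValueError(f"segment score {s} for {lv} outside 0-6")
        scores[lv] = s
    total = sum(scores.values())
    return AACSRecord(segment_scores=scores, total=total,
                      severity=severity_class(total))


def score_from_annotation(plaques: Iterable[PlaqueSpec],
                          level: str) -> tuple[int, int]:
    """Oracle scoring of one segment from plaque annotations.

    Coverage per wall is the sum over that wall's (non-overlapping) plaques;
    the summed coverage is then graded.  Returns (anterior, posterior) grades.
    """
    if level not in SEGMENT_LEVELS:
        raise ValueError(f"unknown segment level {level!r}")
    coverage = {"anterior": 0.0, "posterior": 0.0}
    for p in plaques:
        if p.segment_level != level:
            raise ValueError(
                f"plaque at level {p.segment_level} passed for {level}")
        coverage[p.wall] += p.coverage_fraction
    for wall, c in coverage.items():
        if c > 1.0 + 1e-12:
            raise ValueError(
                f"summed {wall} coverage {c:.4f} exceeds the segment length")
    return (wall_grade(min(coverage["anterior"], 1.0)),
            wall_grade(min(coverage["posterior"], 1.0)))


def record_from_plaques(plaques: Iterable[PlaqueSpec]) -> AACSRecord:
    """Full AACSRecord from a phantom's plaque list (all four levels)."""
    by_level: dict[str, list[PlaqueSpec]] = {lv: [] for lv in SEGMENT_LEVELS}
    for p in plaques:
        by_level[p.segment_level].append(p)
    scores = {
        lv: segment_score(*score_from_annotation(by_level[lv], lv))
        for lv in SEGMENT_LEVELS
    }
    return total_aacs(scores)
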