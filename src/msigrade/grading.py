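"""Automated modified Tumor Regression Grade (mTRG) from pixel histology.

The mTRG scores the response of a colorectal-cancer liver metastasis to
preoperative chemotherapy on a 1-5 scale (higher = worse response) from
the relative areas of viable tumor, usual necrosis (UN, a feature of
tumor progression), infarct-like necrosis (ILN, a feature of treatment
response) and fibrosis/inflammation.  With

    T = % viable tumor + UN        F = % fibrosis + inflammation

over the lesion denominator (adjacent liver, mucin/matrix and
unclassified pixels excluded; fibrosis and inflammation merged because
the grade does not distinguish them):

    grade 1 : T = 0                 (tumor fully replaced)
    grade 2 : 0 < T < 7             (rare residual tumor foci)
    grade 3 : 7 <= T < 50
    grade 4 : T >= 50 and F >= 5
    grade 5 : T >= 50 and F < 5     (no meaningful fibrotic response)

The 7% cutoff operationalizes "rare" tumor foci.  Grades stratify into
response groups: major (1-2), partial (3), minor (4-5).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .core import HistologyLabel

#: Tumor percentage below which residual tumor counts as "rare" (grade 2).
RARE_TUMOR_CUTOFF = 7.0

#: Fibrosis percentage at or above which a bulky-tumor lesion is grade 4.
FIBROSIS_CUTOFF = 5.0

_SUM_TOL = 1e-9


class ResponseGroup(str, Enum):
    MAJOR = "major"
    PARTIAL = "partial"
    MINOR = "minor"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class Composition:
    """Lesion composition in percent over the grading denominator."""

    viable_tumor: float
    usual_necrosis: float
    infarct_like_necrosis: float
    fibrosis_inflammation: float

    def __post_init__(self) -> None:
        parts = (self.viable_tumor, self.usual_necrosis,
                 self.infarct_like_necrosis, self.fibrosis_inflammation)
        if any(p < 0 for p in parts):
            raise ValueError("composition percentages must be non-negative")
        if abs(sum(parts) - 100.0) > 1e-6:
            raise ValueError("composition must sum to 100 percent")

    @property
    def t_percent(self) -> float:
        """Viable tumor + usual necrosis, the tumor-burden term."""
        return self.viable_tumor + self.usual_necrosis

    @property
    def f_percent(self) -> float:
        """Merged fibrosis + inflammation, the response term."""
        return self.fibrosis_inflammation


@dataclass
class MTRGGrade:
    grade: int
    t_percent: float
    f_percent: float

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4, 5):
            raise ValueError("grade must be an integer 1-5")


#: Histologies entering the grading denominator.
GRADED_CLASSES = (
    HistologyLabel.TUMOR,
    HistologyLabel.USUAL_NECROSIS,
    HistologyLabel.NECROSIS_UNSPECIFIED,
    HistologyLabel.INFARCT_LIKE_NECROSIS,
    HistologyLabel.FIBROSIS,
    HistologyLabel.INFLAMMATION,
)


def composition_from_labels(labels, lesion_mask=None) -> Composition:
    """Pixel counts inside the lesion mask, as grading percentages.

    ``lesion_mask`` is a boolean sequence per pixel; by default every
    pixel is eligible, and adjacent liver, mucin/matrix and unclassified
    pixels are always excluded from the denominator.  Necrosis that has
    not been subtyped is counted as usual necrosis — the conservative
    (worse-response) reading.
    """
    labels = list(labels)
    if lesion_mask is None:
        mask = [True] * len(labels)
    else:
        mask = list(lesion_mask)
        if len(mask) != len(labels):
            raise ValueError("lesion mask length must match labels")
    counts = {c: 0 for c in GRADED_CLASSES}
    for keep, l in zip(mask, labels):
        if not keep or l is None:
            continue
        l = HistologyLabel(l)
        if l in counts:
            counts[l] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("lesion mask contains only excluded classes")
    pct = {c: 100.0 * n / total for c, n in counts.items()}
    return Composition(
        viable_tumor=pct[HistologyLabel.TUMOR],
        usual_necrosis=(pct[HistologyLabel.USUAL_NECROSIS]
                        + pct[HistologyLabel.NECROSIS_UNSPECIFIED]),
        infarct_like_necrosis=pct[HistologyLabel.INFARCT_LIKE_NECROSIS],
        fibrosis_inflammation=(pct[HistologyLabel.FIBROSIS]
                               + pct[HistologyLabel.INFLAMMATION]),
    )


def mtrg_score(c: Composition, tumor_tolerance: float = 0.0) -> MTRGGrade:
    """Apply the mTRG decision rules to a composition.

    ``tumor_tolerance`` (percent) lets noisy automated classifications
    still reach grade 1 when a trace of tumor pixels survives; the strict
    definition (exactly 0%) is the default.  The rules are evaluated
    top-down, so every composition receives exactly one grade, and the
    grade is monotone non-decreasing in T for fixed F.
    """
    t = c.t_percent
    f = c.f_percent
    if t <= tumor_tolerance + _SUM_TOL:
        grade = 1
    elif t < RARE_TUMOR_CUTOFF:
        grade = 2
    elif t < 50.0:
        grade = 3
    elif f >= FIBROSIS_CUTOFF:
        grade = 4
    else:
        grade = 5
    return MTRGGrade(grade, t, f)


def response_group(g: MTRGGrade | int) -> ResponseGroup:
    """Stratify a grade into major (1-2), partial (3) or minor (4-5)."""
    grade = g.grade if isinstance(g, MTRGGrade) else int(g)
    if grade in (1, 2):
        return ResponseGroup.MAJOR
    if grade == 3:
        return ResponseGroup.PARTIAL
    if grade in (4, 5):
        return ResponseGroup.MINOR
    raise ValueError("grade must be an integer 1-5")


def grade_lesion(labels, lesion_mask=None,
                 tumor_tolerance: float = 0.0
                 ) -> tuple[Composition, MTRGGrade, ResponseGroup]:
    """Composition -> mTRG -> response group for one lesion."""
    comp = composition_from_labels(labels, lesion_mask)
    grade = mtrg_score(comp, tumor_tolerance)
    return comp, grade, response_group(grade)


def grading_report(lesions: dict) -> pd.DataFrame:
    """Per-lesion grading table from ``{lesion_id: (Composition, MTRGGrade,
    ResponseGroup)}``."""
    rows = []
    for lesion_id, (comp, grade, group) in lesions.items():
        rows.append({
            "lesion_id": lesion_id,
            "viable_tumor_pct": comp.viable_tumor,
            "usual_necrosis_pct": comp.usual_necrosis,
            "infarct_like_necrosis_pct": comp.infarct_like_necrosis,
            "fibrosis_inflammation_pct": comp.fibrosis_inflammation,
            "t_percent": grade.t_percent,
            "f_percent": grade.f_percent,
            "mtrg": grade.grade,
            "response_group": group.value,
        })
    return pd.DataFrame(rows)
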