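"""Reader-agreement arm: Likert ratings, dichotomization, Cohen's kappa.

Ratings live on a 0-4 scale (0 = non-diagnostic; 1-2 = no manifest
synovitis; 3-4 = manifest synovitis) with a 1-3 level-of-confidence (LoC)
per rating.  The built-in 10-knee study fixture reconstructs the published
two-reader, two-modality rating table; every statistic computed from it
depends only on the joint category counts, which are fully constrained.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RatingRecord",
    "ContingencyTable",
    "AgreementResult",
    "NonDiagnosticError",
    "dichotomize",
    "cohens_kappa",
    "kappa_between",
    "landis_koch_label",
    "study_fixture",
    "loc_summary",
    "agreement_report",
    "read_ratings_csv",
    "write_ratings_csv",
    "round_half_up",
]

MODALITIES = ("ce", "dwi")
READERS = (1, 2)


class NonDiagnosticError(ValueError):
    """Category 0 (non-diagnostic image quality) cannot be dichotomized."""


@dataclass(frozen=True)
class RatingRecord:
    """One knee x one reading."""

    knee_id: str
    modality: str
    reader: int
    category: int
    loc: int

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.reader not in READERS:
            raise ValueError(f"reader must be one of {READERS}")
        if not 0 <= self.category <= 4:
            raise ValueError("category must be in 0..4")
        if not 1 <= self.loc <= 3:
            raise ValueError("LoC must be in 1..3")


def dichotomize(category: int) -> int:
    """Collapse categories 1-2 to 0 (no synovitis) and 3-4 to 1 (active)."""
    if category == 0:
        raise NonDiagnosticError("category 0 is non-diagnostic")
    if category not in (1, 2, 3, 4):
        raise ValueError("category must be in 1..4")
    return 0 if category <= 2 else 1


@dataclass
class ContingencyTable:
    """Square rater-A x rater-B count matrix over ordered category labels."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square with one row per label")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_pairs(cls, a, b, labels=None) -> "ContingencyTable":
        a, b = list(a), list(b)
        if len(a) != len(b) or not a:
            raise ValueError("a and b must be non-empty and paired")
        if labels is None:
            labels = tuple(sorted(set(a) | set(b)))
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)))
        for x, y in zip(a, b):
            counts[idx[x], idx[y]] += 1
        return cls(labels=tuple(labels), counts=counts)


@dataclass(frozen=True)
class AgreementResult:
    p_observed: float
    p_expected: float
    kappa: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_observed <= 1.0:
            raise ValueError("observed agreement out of [0, 1]")
        if self.kappa > 1.0 + 1e-12:
            raise ValueError("kappa cannot exceed 1")


def landis_koch_label(kappa: float) -> str:
    """Verbal band for a kappa value (poor / slight / ... / almost perfect)."""
    if kappa > 1.0 + 1e-12:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohens_kappa(table: ContingencyTable) -> AgreementResult:
    """Unweighted Cohen's kappa: (P_o - P_e) / (1 - P_e)."""
    n = table.n
    p_o = float(np.trace(table.counts)) / n
    row = table.counts.sum(axis=1) / n
    col = table.counts.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0:
        if p_o >= 1.0:
            kappa = 1.0  # all mass on one agreeing cell
        else:
            raise ValueError("kappa undefined: expected agreement is 1")
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(p_observed=p_o, p_expected=p_e, kappa=kappa, label=landis_koch_label(kappa))


def kappa_between(a, b, *, dichotomous: bool = False) -> AgreementResult:
    """Kappa between two paired rating sequences, optionally dichotomized."""
    if dichotomous:
        a = [dichotomize(x) for x in a]
        b = [dichotomize(x) for x in b]
    return cohens_kappa(ContingencyTable.from_pairs(a, b))


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding used when comparing against printed values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --- the reconstructed 10-knee study fixture --------------------------------

# Per knee: (ce cat/LoC, dwi cat/LoC) for reader 1, then reader 2.  The joint
# counts are fully determined by the published marginals and the described
# up/downgrades; which particular knee carries which change is an arbitrary
# consistent assignment (all reported statistics are invariant to it).
_FIXTURE_ROWS = [
    # knee   r1 ce     r1 dwi    r2 ce     r2 dwi
    ("k01", (2, 2), (2, 2), (1, 3), (3, 3)),
    ("k02", (2, 3), (2, 1), (2, 3), (1, 2)),
    ("k03", (3, 3), (3, 3), (2, 3), (4, 3)),
    ("k04", (3, 3), (3, 3), (3, 3), (2, 2)),
    ("k05", (3, 3), (3, 2), (3, 3), (3, 2)),
    ("k06", (3, 3), (3, 2), (3, 3), (3, 2)),
    ("k07", (3, 3), (3, 2), (4, 3), (3, 2)),
    ("k08", (4, 3), (3, 3), (3, 3), (3, 3)),
    ("k09", (4, 3), (3, 3), (3, 3), (4, 3)),
    ("k10", (4, 3), (4, 3), (3, 3), (4, 3)),
]


def study_fixture() -> list[RatingRecord]:
    """The reconstructed two-reader, two-modality rating table (40 records)."""
    records = []
    for knee, r1_ce, r1_dwi, r2_ce, r2_dwi in _FIXTURE_ROWS:
        for reader, modality, (cat, loc) in (
            (1, "ce", r1_ce),
            (1, "dwi", r1_dwi),
            (2, "ce", r2_ce),
            (2, "dwi", r2_dwi),
        ):
            records.append(RatingRecord(knee, modality, reader, cat, loc))
    return records


def _categories(records, reader: int, modality: str) -> list[int]:
    rows = sorted(
        (r for r in records if r.reader == reader and r.modality == modality),
        key=lambda r: r.knee_id,
    )
    return [r.category for r in rows]


def loc_summary(records) -> pd.DataFrame:
    """Per reader x modality: median LoC and the proportion at each level."""
    records = list(records)
    if not records:
        raise ValueError("no rating records")
    rows = []
    for reader in READERS:
        for modality in MODALITIES:
            locs = [r.loc for r in records if r.reader == reader and r.modality == modality]
            if not locs:
                continue
            n = len(locs)
            rows.append(
                {
                    "reader": reader,
                    "modality": modality,
                    "n": n,
                    "median_loc": float(statistics.median(locs)),
                    "prop_loc1": locs.count(1) / n,
                    "prop_loc2": locs.count(2) / n,
                    "prop_loc3": locs.count(3) / n,
                }
            )
    return pd.DataFrame(rows)


#: The pairwise comparisons reported for the study, as
#: (name, (reader_a, modality_a), (reader_b, modality_b), dichotomous, excluded)
REPORT_COMPARISONS = [
    ("r1_ce_vs_r1_dwi_categories", (1, "ce"), (1, "dwi"), False, False),
    ("r1_ce_vs_r1_dwi_dichotomous", (1, "ce"), (1, "dwi"), True, False),
    ("r1_ce_vs_r2_ce_categories", (1, "ce"), (2, "ce"), False, False),
    ("r1_ce_vs_r2_ce_dichotomous", (1, "ce"), (2, "ce"), True, False),
    # The published 4-category value for this comparison (0.220) is not
    # reproduced exactly by the unweighted formula on the reconstructed
    # table (0.219); flagged, not a reproduction target.
    ("r1_ce_vs_r2_dwi_categories", (1, "ce"), (2, "dwi"), False, True),
    ("r1_ce_vs_r2_dwi_dichotomous", (1, "ce"), (2, "dwi"), True, False),
]


def agreement_report(records) -> dict:
    """All pairwise kappas, Landis-Koch labels and LoC summaries."""
    records = list(records)
    comparisons = {}
    for name, (ra, ma), (rb, mb), dichotomous, excluded in REPORT_COMPARISONS:
        a = _categories(records, ra, ma)
        b = _categories(records, rb, mb)
        if not a or not b:
            continue
        res = kappa_between(a, b, dichotomous=dichotomous)
        comparisons[name] = {
            "kappa": res.kappa,
            "kappa_rounded": round_half_up(res.kappa, 3),
            "p_observed": res.p_observed,
            "p_expected": res.p_expected,
            "label": res.label,
            "dichotomous": dichotomous,
            "excluded_from_reproduction": excluded,
        }
    loc = loc_summary(records).to_dict(orient="records")
    r1_ce = _categories(records, 1, "ce")
    report = {"comparisons": comparisons, "loc_summary": loc}
    if r1_ce:
        report["n_knees"] = len(r1_ce)
        report["n_active_synovitis_reference"] = sum(dichotomize(c) for c in r1_ce)
    return report


# --- CSV ingest/egress ------------------------------------------------------

_CSV_COLUMNS = ["knee_id", "modality", "reader", "category", "loc"]


def write_ratings_csv(records, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "knee_id": r.knee_id,
                "modality": r.modality,
                "reader": r.reader,
                "category": r.category,
                "loc": r.loc,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def read_ratings_csv(path) -> list[RatingRecord]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
    return [
        RatingRecord(
            knee_id=str(row.knee_id),
            modality=str(row.modality),
            reader=int(row.reader),
            category=int(row.category),
            loc=int(row.loc),
        )
        for row in df.itertuples()
    ]
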