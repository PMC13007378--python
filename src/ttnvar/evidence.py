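"""Calibrated computational-evidence banding and ACMG point aggregation.

AlphaMissense scores (0-1, higher = more likely pathogenic) are mapped to
calibrated PP3/BP4 evidence bands following the ClinGen posterior-probability
calibration, expressed as signed points: Supporting = +/-1, Moderate = +/-2,
Strong = +/-4 (with a +3 "Pathogenic" band between Moderate and Strong on the
pathogenic side of the published interval list). Scores are rounded to three
decimals before lookup because the calibrated interval bounds are quoted to
three decimals; the printed intervals are closed as printed, and rounding
closes the residual gaps between adjacent bounds (e.g. 0.905 vs 0.906).

Classification follows the ClinGen point-based scale:
Pathogenic >= 10, Likely pathogenic 6..9, VUS 0..5,
Likely benign -6..-1, Benign <= -7.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Band",
    "EvidenceBandTable",
    "DEFAULT_BANDS",
    "band_for_score",
    "MafCategory",
    "maf_category",
    "OnsetTier",
    "meets_rarity",
    "pm3_points",
    "AcmgCriterion",
    "Classification",
    "aggregate_and_classify",
    "CLASSIFICATION_BANDS",
]


@dataclass(frozen=True)
class Band:
    lower: float
    upper: float
    label: str
    points: int
    #: ACMG criterion this band feeds (PP3 pathogenic side, BP4 benign side).
    criterion: str | None = None


class EvidenceBandTable:
    """Ordered, gap-free (after 3-decimal rounding) score->points map on [0,1]."""

    DECIMALS = 3

    def __init__(self, bands: Sequence[Band]):
        bands = sorted(bands, key=lambda b: b.lower)
        step = 10 ** -self.DECIMALS
        prev = None
        for b in bands:
            if round(b.lower, self.DECIMALS) > round(b.upper, self.DECIMALS):
                raise ValueError(f"band {b.label}: lower > upper")
            if prev is not None:
                if round(b.lower - prev.upper, self.DECIMALS) > step + 1e-9:
                    raise ValueError(
                        f"gap between {prev.label} and {b.label} exceeds one "
                        f"rounding step")
                if b.lower <= prev.upper - 1e-9:
                    raise ValueError(f"bands {prev.label} and {b.label} overlap")
                if b.points < prev.points:
                    raise ValueError("points must be monotone non-decreasing in score")
            prev = b
        if round(bands[0].lower, self.DECIMALS) > 0 or round(bands[-1].upper, self.DECIMALS) < 1:
            raise ValueError("bands must cover [0, 1]")
        self.bands = tuple(bands)

    def lookup(self, score: float) -> Band:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score out of [0,1]: {score}")
        s = round(score, self.DECIMALS)
        for b in self.bands:
            if round(b.lower, self.DECIMALS) <= s <= round(b.upper, self.DECIMALS):
                return b
        raise AssertionError(f"band table does not cover rounded score {s}")  # pragma: no cover


#: Calibrated AlphaMissense thresholds for PP3/BP4 at titin.
#: The source threshold list labels the benign bands "BP3"; we emit BP4,
#: the computational-evidence benign criterion, and keep the original
#: label available via ``Band.criterion`` metadata conventions.
DEFAULT_BANDS = EvidenceBandTable([
    Band(0.000, 0.070, "Benign", -3, "BP4"),
    Band(0.071, 0.099, "Benign Moderate", -2, "BP4"),
    Band(0.100, 0.169, "Benign Supporting", -1, "BP4"),
    Band(0.170, 0.791, "Indeterminate", 0, None),
    Band(0.792, 0.905, "Pathogenic Supporting", +1, "PP3"),
    Band(0.906, 0.971, "Pathogenic Moderate", +2, "PP3"),
    Band(0.972, 0.989, "Pathogenic", +3, "PP3"),
    Band(0.990, 1.000, "Pathogenic Strong", +4, "PP3"),
])

#: Band labels in ascending score order (useful for tabulations).
BAND_LABELS = tuple(b.label for b in DEFAULT_BANDS.bands)


def band_for_score(score: float, table: EvidenceBandTable = DEFAULT_BANDS) -> tuple[str, int]:
    """Return ``(label, signed points)`` for an AlphaMissense score."""
    b = table.lookup(score)
    return b.label, b.points


# ---------------------------------------------------------------------------
# MAF categories and onset-tier rarity
# ---------------------------------------------------------------------------

class MafCategory(str, enum.Enum):
    ABSENT = "absent"
    LE_0_01PCT = "<=0.01%"
    PCT_0_01_TO_0_1 = "(0.01%,0.1%]"
    PCT_0_1_TO_1 = "(0.1%,1%]"
    GT_1PCT = ">1%"


#: Category order for tabulations (rarest first).
MAF_CATEGORIES = (
    MafCategory.ABSENT,
    MafCategory.LE_0_01PCT,
    MafCategory.PCT_0_01_TO_0_1,
    MafCategory.PCT_0_1_TO_1,
    MafCategory.GT_1PCT,
)


def maf_category(maf: float | None) -> MafCategory:
    """Bin a gnomAD minor allele frequency; ``None`` = absent from gnomAD."""
    if maf is None:
        return MafCategory.ABSENT
    if maf < 0:
        raise ValueError(f"negative MAF: {maf}")
    if maf > 1:
        raise ValueError(f"MAF above 1: {maf}")
    if maf <= 1e-4:
        return MafCategory.LE_0_01PCT
    if maf <= 1e-3:
        return MafCategory.PCT_0_01_TO_0_1
    if maf <= 1e-2:
        return MafCategory.PCT_0_1_TO_1
    return MafCategory.GT_1PCT


class OnsetTier(str, enum.Enum):
    CONGENITAL = "congenital"
    CHILDHOOD = "childhood"
    ADULT = "adult"


#: Strict MAF upper cut-offs per onset tier. Severe early-onset disease is
#: expected to be depleted from population databases, so the congenital tier
#: uses the tighter 1e-4 cut-off; childhood/adult tiers use the study-wide
#: 1e-2.
RARITY_CUTOFFS = {
    OnsetTier.CONGENITAL: 1e-4,
    OnsetTier.CHILDHOOD: 1e-2,
    OnsetTier.ADULT: 1e-2,
}


def meets_rarity(maf: float | None, onset_tier: OnsetTier | str) -> bool:
    """Strict-inequality rarity test; absent MAF passes every tier."""
    tier = OnsetTier(onset_tier)
    if maf is None:
        return True
    return maf < RARITY_CUTOFFS[tier]


# ---------------------------------------------------------------------------
# ACMG criteria and point aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcmgCriterion:
    code: str
    points: int

    def __post_init__(self):
        if abs(self.points) > 8:
            raise ValueError(f"|points| > 8 for {self.code}")


def pm3_points(n_trans_probands: int, partner_is_lp_or_p: bool,
               single_points: int = 2, cap: int = 4) -> int:
    """PM3 points for a variant found in trans with a truncating partner.

    0 unless the partner is (likely) pathogenic; Moderate (+2) for a single
    proband; capped at Strong (+4) for two or more unrelated probands. The
    scaling is configurable via ``single_points`` and ``cap``.
    """
    if n_trans_probands < 1:
        raise ValueError("n_trans_probands must be >= 1")
    if not partner_is_lp_or_p:
        return 0
    if n_trans_probands == 1:
        return single_points
    return cap


@dataclass(frozen=True)
class Classification:
    total_points: int
    label: str


#: Point-scale classification bands (lower bound inclusive, descending).
CLASSIFICATION_BANDS = (
    (10, "Pathogenic"),
    (6, "Likely pathogenic"),
    (0, "VUS"),
    (-6, "Likely benign"),
)
_BENIGN_LABEL = "Benign"  # total <= -7


def aggregate_and_classify(
    criteria: Iterable[AcmgCriterion] | Mapping[str, int],
) -> Classification:
    """Sum ACMG criterion points and classify on the point scale.

    Accepts either AcmgCriterion objects or a ``{code: points}`` mapping.
    Duplicate criterion codes raise (double-counting guard).
    """
    if isinstance(criteria, Mapping):
        crits = [AcmgCriterion(c, p) for c, p in criteria.items()]
    else:
        crits = list(criteria)
    seen: set[str] = set()
    for c in crits:
        if c.code in seen:
            raise ValueError(f"duplicate ACMG criterion: {c.code}")
        seen.add(c.code)
    total = sum(c.points for c in crits)
    for lower, label in CLASSIFICATION_BANDS:
        if total >= lower:
            return Classification(total, label)
    return Classification(total, _BENIGN_LABEL)
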