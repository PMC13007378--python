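"""Cohort inclusion filtering, summaries, recurrence, PSI flags, haplotypes.

A patient genotype couples one haplotype carrying 1-2 candidate missense
variants (two when in cis) with a truncating variant (TTNtv: nonsense,
frameshift or canonical splice) expected on the other haplotype. Phase is an
input recorded upstream (segregation or population co-occurrence evidence);
it is never inferred here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .core import TRUNCATING, Variant
from .evidence import OnsetTier

__all__ = [
    "Phase",
    "PatientGenotype",
    "FamilyVariantSet",
    "PsiAnnotation",
    "InclusionDecision",
    "include_patient",
    "cohort_summary",
    "recurrent_variants",
    "haplotype_intersection",
    "annotate_psi",
    "classify_residue_exposure",
    "HMERF_TMD_EXONS",
]

#: Exons whose missense variants cause the dominant titinopathies HMERF
#: (exon 344) and tibial muscular dystrophy (exon 364); excluded from the
#: recessive-cohort analysis.
HMERF_TMD_EXONS = frozenset({344, 364})


class Phase(str, enum.Enum):
    CONFIRMED_TRANS = "confirmed_trans"
    PRESUMED_TRANS = "presumed_trans"
    CIS = "cis"
    UNKNOWN = "unknown"


TRANS_PHASES = frozenset({Phase.CONFIRMED_TRANS, Phase.PRESUMED_TRANS})


@dataclass
class PatientGenotype:
    family_id: str
    patient_id: str
    missense_alleles: list[Variant]      # 1-2 variants sharing one haplotype
    ttntv: Variant | None
    phase: Phase = Phase.UNKNOWN
    onset_tier: OnsetTier = OnsetTier.CONGENITAL

    def __post_init__(self):
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if not 1 <= len(self.missense_alleles) <= 2:
            raise ValueError("a genotype carries 1-2 missense alleles (2 = in cis)")
        self.phase = Phase(self.phase)
        self.onset_tier = OnsetTier(self.onset_tier)


@dataclass
class FamilyVariantSet:
    """All TTN variants (including polymorphisms) typed in one family."""

    family_id: str
    variants: frozenset[str]

    def __init__(self, family_id: str, variants):
        self.family_id = family_id
        vs = list(variants)
        self.variants = frozenset(vs)
        if len(self.variants) != len(vs):
            raise ValueError(f"duplicate variants in family {family_id}")


# ---------------------------------------------------------------------------
# Inclusion filter
# ---------------------------------------------------------------------------

@dataclass
class InclusionDecision:
    included: bool
    #: Reason codes for every failed clause, empty when included.
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.included


def _allele_failures(v: Variant, maf_cutoff: float, score_cutoff: float) -> list[str]:
    fails = []
    if v.maf is not None and not v.maf < maf_cutoff:
        fails.append("maf")
    if v.am_score is None:
        fails.append("unscorable")
    elif not v.am_score >= score_cutoff:
        fails.append("score")
    if v.exon in HMERF_TMD_EXONS:
        fails.append("hmerf_tmd_exon")
    return fails


def include_patient(g: PatientGenotype, *, maf_cutoff: float = 0.010,
                    score_cutoff: float = 0.792) -> InclusionDecision:
    """Apply the study inclusion filter to one patient genotype.

    Included iff at least one missense allele is rare (MAF < cutoff or absent
    from gnomAD), scores at or above the calibrated pathogenic-supporting
    cut-off, and lies outside the HMERF/TMD exons; AND a truncating partner
    variant is present; AND the two alleles are in (confirmed or presumed)
    trans. Reason codes name every failed clause.
    """
    reasons: list[str] = []

    per_allele = [_allele_failures(v, maf_cutoff, score_cutoff)
                  for v in g.missense_alleles]
    if not any(len(f) == 0 for f in per_allele):
        # no qualifying allele: surface the union of allele-level failures
        for fails in per_allele:
            for code in fails:
                if code not in reasons:
                    reasons.append(code)

    if g.ttntv is None:
        reasons.append("no_ttntv")
    elif g.ttntv.consequence not in TRUNCATING:
        reasons.append("partner_not_truncating")

    if g.phase not in TRANS_PHASES:
        reasons.append("phase")

    return InclusionDecision(included=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# Cohort summaries and recurrence
# ---------------------------------------------------------------------------

def cohort_summary(cohort: list[PatientGenotype]) -> dict[str, int]:
    """Patient/family counts and distinct variant counts for a filtered cohort.

    Distinctness is keyed on the whitespace/case-normalised cDNA string
    (protein string as fallback); both members of an in-cis missense pair
    count toward the distinct-missense tally.
    """
    missense = {v.key for g in cohort for v in g.missense_alleles}
    ttntv = {g.ttntv.key for g in cohort if g.ttntv is not None}
    return {
        "n_patients": len({(g.family_id, g.patient_id) for g in cohort}),
        "n_families": len({g.family_id for g in cohort}),
        "n_distinct_missense": len(missense),
        "n_distinct_ttntv": len(ttntv),
    }


def recurrent_variants(cohort: list[PatientGenotype]) -> dict[str, set[str]]:
    """Missense variants observed in >= 2 families, with their family sets."""
    families: dict[str, set[str]] = {}
    for g in cohort:
        for v in g.missense_alleles:
            families.setdefault(v.key, set()).add(g.family_id)
    return {k: fams for k, fams in families.items() if len(fams) >= 2}


def recurrent_family_total(cohort: list[PatientGenotype]) -> int:
    """Number of distinct families carrying any recurrent missense variant."""
    rec = recurrent_variants(cohort)
    return len(set().union(*rec.values())) if rec else 0


# ---------------------------------------------------------------------------
# Haplotype intersection
# ---------------------------------------------------------------------------

def haplotype_intersection(
    sets: list[FamilyVariantSet],
    partial: FamilyVariantSet | None = None,
) -> tuple[frozenset[str], dict[str, int]]:
    """Exact intersection of fully-typed family variant sets.

    Returns the shared variant set and, per family, its overlap count with
    the shared set. When ``partial`` is given (a family with only pre-filtered
    data, so absence is uninformative), its overlap with the shared core is
    reported without constraining the intersection.
    """
    if len(sets) < 2:
        raise ValueError("haplotype intersection needs >= 2 fully-typed families")
    shared = frozenset.intersection(*(s.variants for s in sets))
    overlaps = {s.family_id: len(s.variants & shared) for s in sets}
    if partial is not None:
        overlaps[partial.family_id] = len(partial.variants & shared)
    return shared, overlaps


# ---------------------------------------------------------------------------
# PSI flags and residue exposure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsiAnnotation:
    prenatal: float
    postnatal: float
    flags: frozenset[str]

    @property
    def developmentally_decreasing(self) -> bool:
        return "developmentally_decreasing" in self.flags

    @property
    def low_usage(self) -> bool:
        return "low_usage" in self.flags


def annotate_psi(prenatal: float, postnatal: float, *,
                 rel_drop: float = 0.30, low_cutoff: float = 30.0) -> PsiAnnotation:
    """Flag exon-usage patterns from prenatal and postnatal PSI percentages.

    ``developmentally_decreasing``: the exon loses at least ``rel_drop``
    (default 30%) of its prenatal inclusion level after birth. A relative
    criterion is used because developmentally regulated exons span a wide
    range of baseline inclusion (an 80-point drop from 90% and a 6-point drop
    from 7% both reflect strong down-regulation).
    ``low_usage``: both values below ``low_cutoff`` percent (default 30),
    i.e. the exon is a minor contributor at both stages.
    """
    for v in (prenatal, postnatal):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"PSI out of [0,100]: {v}")
    flags = set()
    if prenatal > 0 and (prenatal - postnatal) / prenatal >= rel_drop:
        flags.add("developmentally_decreasing")
    if prenatal < low_cutoff and postnatal < low_cutoff:
        flags.add("low_usage")
    return PsiAnnotation(prenatal, postnatal, frozenset(flags))


def classify_residue_exposure(relative_accessibility: float,
                              threshold: float = 0.25) -> str:
    """Classify a residue as 'buried' or 'exposed' from its relative
    solvent-accessible surface area (strictly below threshold = buried)."""
    if not 0.0 <= relative_accessibility <= 1.0:
        raise ValueError(f"relative accessibility out of [0,1]: {relative_accessibility}")
    return "buried" if relative_accessibility < threshold else "exposed"
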