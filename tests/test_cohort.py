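"""Inclusion filtering, cohort summaries, recurrence, haplotypes, PSI."""

import dataclasses

import pytest

from ttnvar.cohort import (
    FamilyVariantSet, PatientGenotype, Phase, annotate_psi,
    classify_residue_exposure, cohort_summary, haplotype_intersection,
    include_patient, recurrent_family_total, recurrent_variants,
)
from ttnvar.core import Consequence, Variant
from ttnvar.evidence import OnsetTier
from ttnvar.synthetic import CohortConfig, HaplotypeConfig, gen_cohort, \
    gen_family_haplotypes


def _missense(**kw):
    base = dict(cdna="c.21068A>C", protein="p.(Gln7023Pro)",
                consequence=Consequence.MISSENSE, aa_pos=7023,
                ref_aa="Q", alt_aa="P", exon=75, am_score=0.81,
                maf=5.578e-6)
    base.update(kw)
    return Variant(**base)


def _ttntv(**kw):
    base = dict(cdna="c.55351C>T", protein="p.(Arg18451Ter)",
                consequence=Consequence.NONSENSE, aa_pos=18451,
                ref_aa="R", exon=287)
    base.update(kw)
    return Variant(**base)


def _patient(missense=None, ttntv=None, phase=Phase.CONFIRMED_TRANS, fam="F1"):
    return PatientGenotype(
        family_id=fam, patient_id=f"{fam}-P1",
        missense_alleles=missense if isinstance(missense, list)
        else [missense or _missense()],
        ttntv=_ttntv() if ttntv is None else ttntv, phase=phase)


def test_qualifying_genotype_is_included():
    decision = include_patient(_patient())
    assert decision.included and decision.reasons == []


@pytest.mark.parametrize("patch,reason", [
    (dict(am_score=0.50), "score"),
    (dict(am_score=None), "unscorable"),
    (dict(exon=364), "hmerf_tmd_exon"),
    (dict(exon=344), "hmerf_tmd_exon"),
    (dict(maf=0.02), "maf"),
    (dict(maf=0.010), "maf"),   # strict: MAF must be < 0.010
])
def test_failing_missense_clauses_are_named(patch, reason):
    decision = include_patient(_patient(missense=_missense(**patch)))
    assert not decision.included
    assert reason in decision.reasons


@pytest.mark.parametrize("phase", [Phase.CIS, Phase.UNKNOWN])
def test_non_trans_phase_excludes(phase):
    decision = include_patient(_patient(phase=phase))
    assert not decision.included and "phase" in decision.reasons


def test_missing_or_non_truncating_partner_excludes():
    g = PatientGenotype("F1", "F1-P1", [_missense()], None,
                        phase=Phase.CONFIRMED_TRANS)
    assert "no_ttntv" in include_patient(g).reasons
    not_tv = _ttntv(consequence=Consequence.MISSENSE, protein=None,
                    cdna="c.1A>C", alt_aa="T")
    d = include_patient(_patient(ttntv=not_tv))
    assert "partner_not_truncating" in d.reasons


def test_one_qualifying_cis_allele_suffices():
    """An in-cis pair passes if either member clears every clause."""
    good, bad = _missense(), _missense(cdna="c.99A>C", am_score=0.3)
    d = include_patient(_patient(missense=[good, bad]))
    assert d.included


def test_reason_codes_are_complete_toggles():
    """Fixing exactly the named failing attribute flips the decision."""
    fixes = {"score": dict(am_score=0.95), "maf": dict(maf=1e-6),
             "hmerf_tmd_exon": dict(exon=100)}
    for reason, fix in fixes.items():
        broken = {"score": dict(am_score=0.5), "maf": dict(maf=0.5),
                  "hmerf_tmd_exon": dict(exon=364)}[reason]
        g = _patient(missense=_missense(**broken))
        assert include_patient(g).reasons == [reason]
        g2 = _patient(missense=_missense(**{**broken, **fix}))
        assert include_patient(g2).included


def test_absent_maf_passes_rarity_clause():
    d = include_patient(_patient(missense=_missense(maf=None)))
    assert d.included


def test_cohort_summary_counts_and_invariance():
    cohort, truth = gen_cohort(CohortConfig(seed=5, n_families=10,
                                            recurrence_k=3, n_cis_pairs=2))
    s = cohort_summary(cohort)
    assert s == {k: truth[k] for k in s}
    relabeled = [dataclasses.replace(g, family_id="X" + g.family_id,
                                     patient_id="X" + g.patient_id)
                 for g in reversed(cohort)]
    assert cohort_summary(relabeled) == s


def test_cohort_summary_empty():
    assert cohort_summary([]) == {"n_patients": 0, "n_families": 0,
                                  "n_distinct_missense": 0,
                                  "n_distinct_ttntv": 0}


def test_recurrence_recovers_planted_variant():
    cohort, truth = gen_cohort(CohortConfig(seed=7, n_families=12,
                                            recurrence_k=6, n_cis_pairs=0))
    rec = recurrent_variants(cohort)
    assert set(rec) == {truth["recurrent_key"]}
    assert len(rec[truth["recurrent_key"]]) == 6
    assert recurrent_family_total(cohort) == 6


def test_all_unique_cohort_has_no_recurrence():
    cohort, _ = gen_cohort(CohortConfig(seed=7, n_families=8, recurrence_k=0,
                                        n_cis_pairs=0))
    assert recurrent_variants(cohort) == {}
    assert recurrent_family_total(cohort) == 0


def test_all_cis_cohort_is_fully_rejected():
    cohort, _ = gen_cohort(CohortConfig(seed=1, n_families=5, recurrence_k=0,
                                        n_cis_pairs=0, phase=Phase.CIS))
    assert all(not include_patient(g) for g in cohort)


# ---------------------------------------------------------------------------
# Haplotype intersection
# ---------------------------------------------------------------------------

def test_intersection_identical_and_disjoint_sets():
    a = FamilyVariantSet("A", {"c.1A>G", "c.2C>T"})
    b = FamilyVariantSet("B", {"c.1A>G", "c.2C>T"})
    shared, overlaps = haplotype_intersection([a, b])
    assert shared == a.variants and overlaps == {"A": 2, "B": 2}
    c = FamilyVariantSet("C", {"c.9G>A"})
    shared, _ = haplotype_intersection([a, c])
    assert shared == frozenset()


def test_intersection_requires_two_sets():
    with pytest.raises(ValueError):
        haplotype_intersection([FamilyVariantSet("A", {"x"})])


def test_intersection_recovers_planted_core_and_partial_overlap():
    fams, core = gen_family_haplotypes(HaplotypeConfig(seed=2, n_families=4,
                                                       core_size=45, n_private=20))
    partial = FamilyVariantSet("partial", set(list(core)[:2]) | {"c.999999A>T"})
    shared, overlaps = haplotype_intersection(fams, partial=partial)
    assert shared == core
    assert overlaps["partial"] == 2
    assert all(overlaps[f.family_id] == 45 for f in fams)


def test_intersection_equals_pairwise_fold():
    fams, _ = gen_family_haplotypes(HaplotypeConfig(seed=3, n_families=5))
    shared, _ = haplotype_intersection(fams)
    folded = fams[0].variants
    for f in fams[1:]:
        folded = folded & f.variants
    assert shared == folded


# ---------------------------------------------------------------------------
# PSI flags and residue exposure
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pre,post,decreasing,low", [
    (57, 10, True, False),
    (94, 94, False, False),
    (21, 22, False, True),
    (7, 1, True, True),     # strong relative drop at low baseline
    (58, 39, True, False),
    (35, 21, True, False),
    (67, 46, True, False),
    (89, 70, False, False),  # 21% relative drop: below the flag threshold
    (96, 85, False, False),
])
def test_psi_flags(pre, post, decreasing, low):
    ann = annotate_psi(pre, post)
    assert ann.developmentally_decreasing is decreasing
    assert ann.low_usage is low


def test_psi_range_validation():
    with pytest.raises(ValueError):
        annotate_psi(101, 50)
    with pytest.raises(ValueError):
        annotate_psi(50, -1)


@pytest.mark.parametrize("rsa,expected", [
    (0.0, "buried"), (1.0, "exposed"), (0.25, "exposed"), (0.249, "buried"),
])
def test_residue_exposure_boundary(rsa, expected):
    assert classify_residue_exposure(rsa) == expected


def test_residue_exposure_range():
    with pytest.raises(ValueError):
        classify_residue_exposure(1.5)
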