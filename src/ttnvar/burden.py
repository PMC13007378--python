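"""Population burden of compound TTNtv + high-scoring-missense genotypes.

The model multiplies three quantities:

* ``p_tv_carrier`` — probability an individual carries a truncating TTN
  variant in a constitutively expressed (high-PSI) exon. Default 0.0005
  (0.05%), interpreted as a carrier frequency; an allele-frequency
  interpretation (carrier = 1 - (1 - q)^2) is selectable.
* the cumulative carrier frequency of qualifying missense alleles, computed
  under Hardy-Weinberg independence as f = 1 - prod(1 - q_i)^2 over alleles
  not observed in homozygosity,
* ``p_trans`` — probability the two variants lie on opposite haplotypes,
  a flat 0.5 with no linkage modelling.

Alleles observed in homozygosity are removed before aggregation: a variant
tolerated in the homozygous state is unlikely to act as a severe recessive
allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "QualifyingAllele",
    "BurdenParams",
    "missense_carrier_frequency",
    "compound_het_prevalence",
    "BurdenResult",
]


@dataclass(frozen=True)
class QualifyingAllele:
    q: float                      # population allele frequency
    hom_observed: bool = False    # seen homozygous in the population database

    def __post_init__(self):
        if not 0.0 <= self.q <= 0.5:
            raise ValueError(f"allele frequency out of [0, 0.5]: {self.q}")


@dataclass
class BurdenParams:
    qualifying_alleles: list[QualifyingAllele] = field(default_factory=list)
    p_tv_carrier: float = 0.0005
    p_trans: float = 0.5
    #: "carrier": p_tv_carrier is already a carrier frequency;
    #: "allele": it is an allele frequency, converted via HWE.
    tv_interpretation: str = "carrier"

    def __post_init__(self):
        for name in ("p_tv_carrier", "p_trans"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if self.tv_interpretation not in ("carrier", "allele"):
            raise ValueError(f"unknown tv_interpretation: {self.tv_interpretation}")


def missense_carrier_frequency(params: BurdenParams) -> tuple[float, float]:
    """Cumulative carrier frequency of qualifying missense alleles.

    Returns ``(f_exact, f_approx)``: the exact Hardy-Weinberg form
    ``1 - prod(1 - q_i)^2`` and the rare-allele approximation ``2 * sum(q_i)``,
    both over alleles without observed homozygotes.
    """
    qs = [a.q for a in params.qualifying_alleles if not a.hom_observed]
    log_not = sum(math.log1p(-q) for q in qs)
    f_exact = -math.expm1(2.0 * log_not)
    f_approx = 2.0 * sum(qs)
    return f_exact, f_approx


@dataclass(frozen=True)
class BurdenResult:
    f_exact: float
    f_approx: float
    prevalence: float
    one_in_n: int | None     # None when prevalence is 0

    def as_dict(self) -> dict:
        return {"f_exact": self.f_exact, "f_approx": self.f_approx,
                "prevalence": self.prevalence, "one_in_n": self.one_in_n}


def compound_het_prevalence(params: BurdenParams) -> BurdenResult:
    """P(TTNtv carrier AND qualifying-missense carrier AND in trans).

    Prevalence = p_tv_carrier x f_exact x p_trans, reported both as a
    probability and in rounded "1 in N" form.
    """
    f_exact, f_approx = missense_carrier_frequency(params)
    p_tv = params.p_tv_carrier
    if params.tv_interpretation == "allele":
        p_tv = -math.expm1(2.0 * math.log1p(-p_tv))
    prevalence = p_tv * f_exact * params.p_trans
    one_in_n = round(1.0 / prevalence) if prevalence > 1e-300 else None
    return BurdenResult(f_exact, f_approx, prevalence, one_in_n)
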