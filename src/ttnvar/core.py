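"""Core domain types: variants, HGVS-lite parsing, and the standard genetic code.

Positions are 1-based amino-acid coordinates on the canonical titin isoform
(UniProt Q8WZ42-1). Exon numbers (2..364) are carried as annotations supplied
by the caller; no transcript or genome coordinate mapping is performed.

HGVS support is deliberately "lite": simple nucleotide and amino-acid
substitutions are parsed fully, while indels, duplications and intronic
changes are classified to kind only with a best-effort position. The full
HGVS grammar is out of scope.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "Consequence",
    "Variant",
    "GeneticCode",
    "STANDARD_CODE",
    "SubstitutionCounts",
    "ProteinChange",
    "CdnaChange",
    "HgvsParseError",
    "parse_protein_hgvs",
    "parse_cdna_hgvs",
    "format_protein_hgvs",
    "enumerate_codon_substitutions",
    "AA_3TO1",
    "AA_1TO3",
    "AMINO_ACIDS",
]

# ---------------------------------------------------------------------------
# Amino-acid alphabets and the standard genetic code (NCBI translation table 1)
# ---------------------------------------------------------------------------

AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

#: The 20 standard amino acids, one-letter, in alphabetical order.
AMINO_ACIDS = tuple(sorted(a for a in AA_1TO3 if a != "*"))

_BASES = "ACGT"

STOP = "*"


def _build_standard_code() -> dict[str, str]:
    bases = "TCAG"
    aas = ("FFLLSSSSYY**CC*W"
           "LLLLPPPPHHQQRRRR"
           "IIIMTTTTNNKKSSRR"  # note AGA/AGG = Arg, ATA = Ile
           "VVVVAAAADDEEGGGG")
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


class GeneticCode:
    """Codon -> amino-acid map. Defaults to the standard (NCBI table 1) code.

    The initiator codon receives no special handling; ATG is plain Met.
    """

    def __init__(self, table: dict[str, str] | None = None):
        self.table = dict(table) if table is not None else _build_standard_code()
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.table)}")
        n_stop = sum(1 for aa in self.table.values() if aa == STOP)
        if n_stop != 3:
            raise ValueError(f"standard-layout code expects 3 stop codons, got {n_stop}")

    def translate(self, codon: str) -> str:
        codon = codon.upper()
        try:
            return self.table[codon]
        except KeyError:
            raise ValueError(f"not a DNA codon: {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return self.translate(codon) == STOP


STANDARD_CODE = GeneticCode()


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


#: Consequence classes treated as titin-truncating (TTNtv).
TRUNCATING = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE})


@dataclass
class Variant:
    """A single TTN variant with its annotations.

    Annotations (exon number, AlphaMissense score, gnomAD MAF, homozygote
    count, prenatal/postnatal skeletal-muscle PSI) are trusted as given;
    nothing is recomputed from sequence.
    """

    cdna: str
    protein: str | None = None
    consequence: Consequence = Consequence.OTHER
    aa_pos: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    exon: int | None = None
    am_score: float | None = None
    maf: float | None = None
    hom_count: int = 0
    psi_prenatal: float | None = None
    psi_postnatal: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.aa_pos is not None and self.aa_pos < 1:
            raise ValueError(f"aa_pos must be >= 1, got {self.aa_pos}")
        if (self.consequence is Consequence.MISSENSE
                and self.ref_aa is not None and self.ref_aa == self.alt_aa):
            raise ValueError(f"missense variant with ref_aa == alt_aa ({self.ref_aa})")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf out of [0,1]: {self.maf}")
        if self.am_score is not None and not (0.0 <= self.am_score <= 1.0):
            raise ValueError(f"am_score out of [0,1]: {self.am_score}")
        if self.hom_count < 0:
            raise ValueError("hom_count must be non-negative")
        if self.maf is None and self.hom_count:
            raise ValueError("hom_count > 0 requires a MAF (variant absent from gnomAD)")
        for psi in (self.psi_prenatal, self.psi_postnatal):
            if psi is not None and not (0.0 <= psi <= 100.0):
                raise ValueError(f"PSI out of [0,100]: {psi}")

    @property
    def key(self) -> str:
        """Normalised identity key: whitespace-stripped, case-folded cDNA
        string; falls back to the protein string when cDNA is empty."""
        s = re.sub(r"\s+", "", self.cdna or "")
        if not s and self.protein:
            s = re.sub(r"\s+", "", self.protein)
        return s.lower()


# ---------------------------------------------------------------------------
# HGVS-lite parsing
# ---------------------------------------------------------------------------

class HgvsParseError(ValueError):
    """Raised when an HGVS-like string cannot be interpreted."""


class ProteinChange(NamedTuple):
    aa_pos: int
    ref_aa: str
    alt_aa: str | None
    consequence: Consequence


class CdnaChange(NamedTuple):
    position: int
    offset: int          # intronic offset, e.g. -1 in c.7856-1G>A; 0 for exonic
    ref_base: str | None
    alt_base: str | None
    kind: str            # substitution | intronic_substitution | deletion |
                         # duplication | insertion | delins


_P_SUB = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|Ter|\*)$")
_P_FS = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})?fs(?:Ter|\*)?\d*$")
_P_DELINS = re.compile(r"^([A-Z][a-z]{2})(\d+)(?:_([A-Z][a-z]{2})(\d+))?delins((?:[A-Z][a-z]{2}|Ter)+)$")


def _aa1(token: str) -> str:
    if token in ("Ter", "*"):
        return STOP
    try:
        return AA_3TO1[token]
    except KeyError:
        raise HgvsParseError(f"unknown amino-acid code {token!r}") from None


def parse_protein_hgvs(s: str) -> ProteinChange:
    """Parse a protein HGVS string such as ``p.(Gln7023Pro)``.

    Substitutions are parsed fully; ``Ter`` (or ``*``) targets give nonsense,
    ``fsTer`` gives frameshift, and delins blocks are classified as nonsense
    when they introduce a stop, inframe_indel otherwise.
    """
    if not s or not s.strip():
        raise HgvsParseError("empty protein HGVS string")
    body = s.strip()
    if body.startswith("p."):
        body = body[2:]
    body = body.strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]

    m = _P_SUB.match(body)
    if m:
        ref3, pos, alt3 = m.groups()
        ref1, alt1 = _aa1(ref3), _aa1(alt3)
        if alt1 == STOP:
            return ProteinChange(int(pos), ref1, None, Consequence.NONSENSE)
        if ref1 == STOP:
            raise HgvsParseError(f"stop codon as reference residue in {s!r}")
        if ref1 == alt1:
            raise HgvsParseError(f"synonymous change written as substitution: {s!r}")
        return ProteinChange(int(pos), ref1, alt1, Consequence.MISSENSE)

    m = _P_FS.match(body)
    if m:
        ref3, pos = m.group(1), m.group(2)
        return ProteinChange(int(pos), _aa1(ref3), None, Consequence.FRAMESHIFT)

    m = _P_DELINS.match(body)
    if m:
        ref3, pos, inserted = m.group(1), m.group(2), m.group(5)
        cons = (Consequence.NONSENSE if inserted.endswith("Ter")
                else Consequence.INFRAME_INDEL)
        return ProteinChange(int(pos), _aa1(ref3), None, cons)

    raise HgvsParseError(f"unparseable protein HGVS: {s!r} (offending token {body!r})")


def format_protein_hgvs(aa_pos: int, ref_aa: str, alt_aa: str | None) -> str:
    """Inverse of :func:`parse_protein_hgvs` for simple substitutions."""
    ref3 = AA_1TO3[ref_aa]
    alt3 = "Ter" if alt_aa in (None, STOP) else AA_1TO3[alt_aa]
    return f"p.({ref3}{aa_pos}{alt3})"


_C_SUB = re.compile(r"^(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_C_RANGE = re.compile(
    r"^(\d+)([+-]\d+)?(?:_(\d+)([+-]\d+)?)?"
    r"(del[ACGT]*|dup[ACGT]*|ins[ACGT]+|delins[ACGT]+)$")


def parse_cdna_hgvs(s: str) -> CdnaChange:
    """Parse a cDNA HGVS string such as ``c.14486A>C``.

    Substitutions (including intronic ones like ``c.7856-1G>A``) are parsed
    fully; del/dup/ins/delins are classified to kind with the start position.
    Embedded whitespace (as found in typeset tables, ``c.24729C > A``) is
    tolerated.
    """
    if not s or not s.strip():
        raise HgvsParseError("empty cDNA HGVS string")
    body = re.sub(r"\s+", "", s)
    if body.startswith("c."):
        body = body[2:]

    m = _C_SUB.match(body)
    if m:
        pos, off, ref, alt = m.groups()
        offset = int(off) if off else 0
        kind = "intronic_substitution" if offset else "substitution"
        return CdnaChange(int(pos), offset, ref, alt, kind)

    m = _C_RANGE.match(body)
    if m:
        pos, off = m.group(1), m.group(2)
        op = m.group(5)
        if op.startswith("delins"):
            kind = "delins"
        elif op.startswith("del"):
            kind = "deletion"
        elif op.startswith("dup"):
            kind = "duplication"
        else:
            kind = "insertion"
        return CdnaChange(int(pos), int(off) if off else 0, None, None, kind)

    raise HgvsParseError(f"unparseable cDNA HGVS: {s!r} (offending token {body!r})")


# ---------------------------------------------------------------------------
# Codon-level substitution enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionCounts:
    """Classification of the nine single-base substitutions of one codon."""

    missense: int
    synonymous: int
    nonsense: int

    def __post_init__(self):
        if self.missense + self.synonymous + self.nonsense != 9:
            raise ValueError("single-codon substitution counts must sum to 9")

    def __add__(self, other: "SubstitutionCounts"):
        # sums over codons no longer satisfy the per-codon invariant
        return (self.missense + other.missense,
                self.synonymous + other.synonymous,
                self.nonsense + other.nonsense)


def enumerate_codon_substitutions(
    codon: str, code: GeneticCode = STANDARD_CODE
) -> SubstitutionCounts:
    """Classify all 9 single-nucleotide substitutions of a coding codon.

    Each of the 3 positions admits 3 alternative bases; every resulting codon
    is translated and compared with the original residue. Raises ValueError
    for a stop codon (not a residue).
    """
    codon = codon.upper()
    aa = code.translate(codon)  # validates the codon
    if aa == STOP:
        raise ValueError(f"stop codon {codon} encodes no residue")
    missense = synonymous = nonsense = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = code.translate(codon[:i] + b + codon[i + 1:])
            if alt == aa:
                synonymous += 1
            elif alt == STOP:
                nonsense += 1
            else:
                missense += 1
    return SubstitutionCounts(missense, synonymous, nonsense)
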