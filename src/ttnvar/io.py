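"""Readers and writers for the package's tabular interchange formats.

TSV is the canonical interchange format. The cohort/variant table schema has
one row per variant with columns::

    family  patient  role{missense|ttntv}  cdna  protein  exon  consequence
    am_score  maf  hom_count  psi_prenatal  psi_postnatal  phase  onset
    [psi_note ...]

``consequence`` is optional; when absent it is inferred from the protein
HGVS string (or classified as splice for intronic cDNA changes). A minimal
VCF 4.2 reader (via pysam) accepts the INFO keys AM_SCORE, AF, NHOMALT,
EXON and CSQ_CLASS, trusting annotations as given.
"""

from __future__ import annotations

import json
import sys
from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort import PatientGenotype, Phase
from .core import (Consequence, HgvsParseError, Variant, parse_cdna_hgvs,
                   parse_protein_hgvs)
from .evidence import EvidenceBandTable, OnsetTier, band_for_score

__all__ = [
    "packaged_cohort_path",
    "read_variant_table",
    "read_vcf",
    "write_variant_report",
    "write_provenance",
    "VariantTableError",
]

MANDATORY_COLUMNS = ("family", "patient", "role", "cdna")


class VariantTableError(ValueError):
    """Schema or row-level error in a variant table, with line context."""


def packaged_cohort_path() -> Path:
    """Path of the packaged cohort fixture (transcribed clinical tables)."""
    return Path(resources.files("ttnvar").joinpath("data/cohort_tables_1_2.tsv"))


def _opt_float(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return float(v)


def _row_to_variant(row: dict, line_no: int) -> Variant:
    cdna = str(row.get("cdna", "")).strip()
    protein = row.get("protein")
    protein = None if (protein is None or pd.isna(protein) or not str(protein).strip()) \
        else str(protein).strip()
    try:
        consequence = row.get("consequence")
        if consequence and not pd.isna(consequence):
            consequence = Consequence(str(consequence).strip())
            pc = parse_protein_hgvs(protein) if protein else None
        elif protein:
            pc = parse_protein_hgvs(protein)
            consequence = pc.consequence
        else:
            c = parse_cdna_hgvs(cdna)
            consequence = (Consequence.SPLICE if c.kind == "intronic_substitution"
                           else Consequence.OTHER)
            pc = None
    except HgvsParseError as e:
        raise VariantTableError(f"line {line_no}: {e}") from e

    exon = row.get("exon")
    hom = row.get("hom_count")
    try:
        return Variant(
            cdna=cdna,
            protein=protein,
            consequence=consequence,
            aa_pos=pc.aa_pos if pc else None,
            ref_aa=pc.ref_aa if pc else None,
            alt_aa=pc.alt_aa if pc else None,
            exon=None if exon is None or pd.isna(exon) else int(exon),
            am_score=_opt_float(row, "am_score"),
            maf=_opt_float(row, "maf"),
            hom_count=0 if hom is None or pd.isna(hom) else int(hom),
            psi_prenatal=_opt_float(row, "psi_prenatal"),
            psi_postnatal=_opt_float(row, "psi_postnatal"),
            meta={k: row[k] for k in ("psi_note",)
                  if k in row and not pd.isna(row[k])},
        )
    except ValueError as e:
        raise VariantTableError(f"line {line_no}: {e}") from e


def read_variant_table(path, *, strict: bool = True
                       ) -> tuple[list[PatientGenotype], list[str]]:
    """Read a cohort variant table into patient genotypes.

    Returns ``(genotypes, errors)``; in strict mode (default) the first
    malformed row aborts with a line-numbered :class:`VariantTableError`,
    otherwise errors are collected and offending rows skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"missing mandatory columns: {missing}")

    # line numbers for messages: header precedes data; comment lines shift
    # numbering, so report 1-based data-row index instead
    errors: list[str] = []
    patients: dict[tuple[str, str], dict] = {}
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            role = str(row["role"]).strip().lower()
            if role not in ("missense", "ttntv"):
                raise VariantTableError(f"row {i}: unknown role {row['role']!r}")
            v = _row_to_variant(row, i)
            key = (str(row["family"]).strip(), str(row["patient"]).strip())
            rec = patients.setdefault(key, {
                "missense": [], "ttntv": None,
                "phase": Phase(str(row.get("phase", "unknown")).strip()),
                "onset": OnsetTier(str(row.get("onset", "congenital")).strip()),
            })
            if role == "missense":
                rec["missense"].append(v)
            else:
                if rec["ttntv"] is not None:
                    raise VariantTableError(f"row {i}: second TTNtv for patient {key}")
                rec["ttntv"] = v
        except (VariantTableError, ValueError) as e:
            msg = str(e) if str(e).startswith(("row", "line")) else f"row {i}: {e}"
            if strict:
                raise VariantTableError(msg) from e
            errors.append(msg)

    genotypes = []
    for (fam, pat), rec in patients.items():
        try:
            genotypes.append(PatientGenotype(
                family_id=fam, patient_id=f"{fam}-{pat}",
                missense_alleles=rec["missense"], ttntv=rec["ttntv"],
                phase=rec["phase"], onset_tier=rec["onset"]))
        except ValueError as e:
            if strict:
                raise VariantTableError(f"patient {fam}-{pat}: {e}") from e
            errors.append(f"patient {fam}-{pat}: {e}")
    return genotypes, errors


def read_vcf(path) -> list[Variant]:
    """Minimal VCF 4.2 reader trusting INFO annotations as given.

    Recognised INFO keys: AM_SCORE, AF, NHOMALT, EXON, CSQ_CLASS (a
    :class:`Consequence` value). HGVS strings are taken from the ID column
    when formatted as ``cdna|protein``.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            info = rec.info
            cdna, protein = "", None
            if rec.id and "|" in rec.id:
                cdna, protein = rec.id.split("|", 1)
                protein = protein or None
            elif rec.id:
                cdna = rec.id
            csq = info.get("CSQ_CLASS")
            consequence = Consequence(csq) if csq else Consequence.OTHER
            pc = None
            if protein:
                try:
                    pc = parse_protein_hgvs(protein)
                    if not csq:
                        consequence = pc.consequence
                except HgvsParseError:
                    pc = None
            af = info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            out.append(Variant(
                cdna=cdna or f"{rec.chrom}:{rec.pos}{rec.ref}>{rec.alts[0] if rec.alts else '.'}",
                protein=protein,
                consequence=consequence,
                aa_pos=pc.aa_pos if pc else None,
                ref_aa=pc.ref_aa if pc else None,
                alt_aa=pc.alt_aa if pc else None,
                exon=info.get("EXON"),
                am_score=info.get("AM_SCORE"),
                maf=None if af is None else float(af),
                hom_count=int(info.get("NHOMALT", 0) or 0),
            ))
    return out


def write_variant_report(variants: list[Variant], table: EvidenceBandTable,
                         tsv_path=None, json_path=None) -> pd.DataFrame:
    """Per-variant evidence report: band, points for every scored variant."""
    rows = []
    for v in variants:
        if v.am_score is None:
            band, points = None, None
        else:
            band, points = band_for_score(v.am_score, table)
        rows.append({"cdna": v.cdna, "protein": v.protein,
                     "consequence": v.consequence.value,
                     "am_score": v.am_score, "maf": v.maf,
                     "band": band, "points": points})
    df = pd.DataFrame(rows)
    if tsv_path:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path:
        Path(json_path).write_text(json.dumps(rows, indent=2, default=str))
    return df


def write_provenance(path, *, command: str, inputs: dict, thresholds: dict,
                     seed: int | None = None) -> None:
    """Machine-readable record of a run: inputs, thresholds, seed, versions."""
    from . import __version__

    record = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "thresholds": thresholds,
        "seed": seed,
        "versions": {"ttnvar": __version__,
                     "python": sys.version.split()[0],
                     "pandas": pd.__version__},
    }
    Path(path).write_text(json.dumps(record, indent=2))
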