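"""Exhaustive substitution-landscape summaries over a per-SNV score table.

The input is a table with one row per possible single-nucleotide missense
variant (an amino-acid change reachable by more than one distinct SNV
contributes one row per SNV — this matches counting possible SNVs rather
than unique protein-level changes). Summaries:

* band counts over the calibrated evidence bands,
* band x MAF-category cross-tabulation,
* 20x20 (ref residue x alt residue) counts and possibly-pathogenic fractions,
* enumeration of SNV-reachable missense substitutions from a CDS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, GeneticCode, STANDARD_CODE, STOP
from .evidence import (DEFAULT_BANDS, EvidenceBandTable, MAF_CATEGORIES,
                       MafCategory, maf_category)

__all__ = [
    "REQUIRED_COLUMNS",
    "read_score_table",
    "validate_rows",
    "count_by_band",
    "possibly_pathogenic_total",
    "score_maf_crosstab",
    "SubstitutionLandscape",
    "substitution_heatmap",
    "possible_pairs_from_cds",
]

#: Default possibly-pathogenic score threshold: the lower bound of the
#: weakest pathogenic evidence band (Pathogenic Supporting).
DEFAULT_THRESHOLD = 0.792

REQUIRED_COLUMNS = ("protein_variant", "ref_aa", "alt_aa", "aa_pos", "am_score")


def read_score_table(path) -> pd.DataFrame:
    """Read a per-SNV score table in the AlphaMissense release TSV dialect.

    Comment lines start with ``#``. The column ``am_pathogenicity`` is
    accepted as a synonym for ``am_score``. ``protein_variant`` entries like
    ``W123R`` are split into ref_aa / aa_pos / alt_aa when those columns are
    missing. A ``maf`` column, if present, uses empty cells for variants
    absent from the population database.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_variant": str})
    if "am_pathogenicity" in df.columns and "am_score" not in df.columns:
        df = df.rename(columns={"am_pathogenicity": "am_score"})
    if "ref_aa" not in df.columns:
        pv = df["protein_variant"].str.extract(r"^([A-Z*])(\d+)([A-Z*])$")
        df["ref_aa"], df["aa_pos"], df["alt_aa"] = pv[0], pv[1].astype("Int64"), pv[2]
    if "maf" in df.columns:
        df["maf"] = pd.to_numeric(df["maf"], errors="coerce")
    return validate_rows(df)


def validate_rows(rows: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    bad = rows.index[(rows["am_score"] < 0) | (rows["am_score"] > 1)
                     | rows["am_score"].isna()]
    if len(bad):
        raise ValueError(f"am_score out of [0,1] at row index {bad[0]}")
    same = rows.index[rows["ref_aa"] == rows["alt_aa"]]
    if len(same):
        raise ValueError(f"ref_aa == alt_aa at row index {same[0]}")
    return rows


def _band_labels_for(scores: pd.Series, table: EvidenceBandTable) -> pd.Categorical:
    labels = [b.label for b in table.bands]
    edges = [table.bands[0].lower - 0.5] + [
        round(b.upper, table.DECIMALS) + 0.5 * 10 ** -table.DECIMALS
        for b in table.bands]
    binned = pd.cut(scores.round(table.DECIMALS), bins=edges, labels=labels)
    return binned


def count_by_band(rows: pd.DataFrame,
                  table: EvidenceBandTable = DEFAULT_BANDS) -> pd.Series:
    """Count rows per calibrated evidence band (ascending score order)."""
    if len(rows) == 0:
        raise ValueError("empty score table")
    validate_rows(rows)
    binned = _band_labels_for(rows["am_score"], table)
    counts = binned.value_counts().reindex([b.label for b in table.bands])
    counts.name = "count"
    return counts.astype(int)


def possibly_pathogenic_total(rows: pd.DataFrame,
                              table: EvidenceBandTable = DEFAULT_BANDS) -> int:
    """Rows in any band with positive points (score >= the Supporting bound)."""
    counts = count_by_band(rows, table)
    path_labels = [b.label for b in table.bands if b.points >= 1]
    return int(counts.loc[path_labels].sum())


def score_maf_crosstab(rows: pd.DataFrame,
                       table: EvidenceBandTable = DEFAULT_BANDS) -> pd.DataFrame:
    """Band x MAF-category contingency table with fixed row/column order.

    Row marginals equal :func:`count_by_band`; a missing ``maf`` column (or
    empty cells) maps rows to the ``absent`` category.
    """
    validate_rows(rows)
    bands = _band_labels_for(rows["am_score"], table)
    maf = rows["maf"] if "maf" in rows.columns else pd.Series(np.nan, index=rows.index)
    cats = pd.Categorical(
        [maf_category(None if pd.isna(m) else float(m)).value for m in maf],
        categories=[c.value for c in MAF_CATEGORIES])
    tab = pd.crosstab(bands, cats, dropna=False)
    tab = tab.reindex(index=[b.label for b in table.bands],
                      columns=[c.value for c in MAF_CATEGORIES], fill_value=0)
    tab.index.name, tab.columns.name = "band", "maf_category"
    return tab.astype(int)


@dataclass
class SubstitutionLandscape:
    """20x20 per-(ref, alt) substitution counts and pathogenic fractions.

    Rows index the reference residue, columns the alternate residue, both in
    alphabetical one-letter order. ``path_fraction`` is NaN for pairs with no
    possible substitution (structurally impossible under the table), which
    includes the diagonal.
    """

    counts: pd.DataFrame
    path_fraction: pd.DataFrame
    threshold: float

    @property
    def impossible(self) -> pd.DataFrame:
        """Boolean mask of structurally impossible (count == 0) pairs."""
        return self.counts == 0

    def fraction_from(self, ref_aa: str) -> float:
        """Aggregate possibly-pathogenic fraction over all changes from one
        residue (pooled over SNV rows, not averaged over pairs)."""
        row_counts = self.counts.loc[ref_aa]
        n = int(row_counts.sum())
        if n == 0:
            return float("nan")
        hits = np.nansum(self.path_fraction.loc[ref_aa] * row_counts)
        return float(hits / n)


def substitution_heatmap(rows: pd.DataFrame,
                         threshold: float = DEFAULT_THRESHOLD) -> SubstitutionLandscape:
    """Per amino-acid-pair counts and fraction of rows scoring >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold out of [0,1]: {threshold}")
    validate_rows(rows)
    idx = pd.Index(AMINO_ACIDS, name="ref_aa")
    cols = pd.Index(AMINO_ACIDS, name="alt_aa")
    grouped = rows.groupby(["ref_aa", "alt_aa"], observed=True)["am_score"]
    counts = grouped.size().unstack(fill_value=0).reindex(
        index=idx, columns=cols, fill_value=0).astype(int)
    hits = grouped.apply(lambda s: int((s >= threshold).sum())).unstack(fill_value=0)
    hits = hits.reindex(index=idx, columns=cols, fill_value=0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = hits / counts.where(counts > 0)
    return SubstitutionLandscape(counts=counts, path_fraction=frac,
                                 threshold=threshold)


def possible_pairs_from_cds(cds: str, code: GeneticCode = STANDARD_CODE
                            ) -> tuple[pd.DataFrame, int]:
    """Enumerate SNV-reachable missense substitutions along a CDS.

    Returns a (ref residue x alt residue) count matrix and its total. Each
    distinct single-base substitution counts once, so a protein change
    reachable via two SNVs of the same codon contributes two.
    """
    cds = cds.upper().replace("\n", "").replace(" ", "")
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError("CDS length must be a positive multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    # a trailing stop codon is tolerated and skipped; internal stops are not
    if code.is_stop(codons[-1]):
        codons = codons[:-1]
    if not codons:
        raise ValueError("CDS contains no coding codons")
    mat = pd.DataFrame(0, index=pd.Index(AMINO_ACIDS, name="ref_aa"),
                       columns=pd.Index(AMINO_ACIDS, name="alt_aa"), dtype=int)
    for j, codon in enumerate(codons):
        aa = code.translate(codon)
        if aa == STOP:
            raise ValueError(f"internal stop codon at codon {j + 1}")
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                alt = code.translate(codon[:i] + b + codon[i + 1:])
                if alt != aa and alt != STOP:
                    mat.loc[aa, alt] += 1
    return mat, int(mat.to_numpy().sum())
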