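"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator is a pure function of its configuration (fixed seed => fixed
output) and returns the planted truth alongside the data, so every stage of
the package is testable without external downloads:

* a per-SNV score table emulating the layout and score mixture of a
  genome-wide missense prediction release,
* patient cohorts with planted recurrence and in-cis pairs,
* family variant sets with a planted shared haplotype core,
* fluorescence cell scenes (diffuse-nuclear vs punctate expression) with
  ground-truth cell and nucleus masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, Consequence, Variant, format_protein_hgvs
from .cohort import FamilyVariantSet, PatientGenotype, Phase
from .evidence import OnsetTier

__all__ = [
    "ScoreTableConfig",
    "gen_score_table",
    "CohortConfig",
    "gen_cohort",
    "HaplotypeConfig",
    "gen_family_haplotypes",
    "ImageConfig",
    "gen_cell_images",
]


# ---------------------------------------------------------------------------
# Score table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreTableConfig:
    """Mixture model for a per-SNV pathogenicity-score table.

    Default weights put ~21% of rows in the possibly-pathogenic bands
    (score >= 0.792) and ~40% in the indeterminate band, with the remainder
    benign — the global proportions expected of titin. MAF: 90% of rows are
    absent from the population database; present rows draw a log-uniform
    frequency on [1e-6, 2e-2].
    """

    seed: int = 0
    n_variants: int = 10_000
    weight_benign: float = 0.39
    weight_indeterminate: float = 0.40
    weight_pathogenic: float = 0.21
    p_maf_absent: float = 0.90
    maf_range: tuple[float, float] = (1e-6, 2e-2)
    protein_length: int = 35_991      # canonical titin length (residues)

    # sampling windows chosen so that 3-decimal rounding cannot move a draw
    # across a band-family boundary
    _BENIGN = (0.0005, 0.1685)
    _INDET = (0.1705, 0.7905)
    _PATH = (0.7925, 0.9995)

    def weights(self) -> np.ndarray:
        w = np.array([self.weight_benign, self.weight_indeterminate,
                      self.weight_pathogenic], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError(f"mixture weights must be non-negative and sum to 1: {w}")
        return w


def gen_score_table(cfg: ScoreTableConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Draw a score table; return (rows, truth) where truth counts rows per
    mixture component as planted at draw time."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_variants
    if n == 0:
        empty = pd.DataFrame(columns=["protein_variant", "ref_aa", "alt_aa",
                                      "aa_pos", "am_score", "maf"])
        return empty, {"benign": 0, "indeterminate": 0, "pathogenic": 0}

    comp = rng.choice(3, size=n, p=cfg.weights())
    windows = np.array([cfg._BENIGN, cfg._INDET, cfg._PATH])
    lo, hi = windows[comp, 0], windows[comp, 1]
    scores = rng.uniform(lo, hi)

    pos = rng.integers(1, cfg.protein_length + 1, size=n)
    ref_idx = rng.integers(0, 20, size=n)
    # alt drawn uniformly among the other 19 residues
    alt_idx = (ref_idx + rng.integers(1, 20, size=n)) % 20
    aas = np.array(AMINO_ACIDS)
    ref, alt = aas[ref_idx], aas[alt_idx]

    absent = rng.random(n) < cfg.p_maf_absent
    log_lo, log_hi = np.log(cfg.maf_range[0]), np.log(cfg.maf_range[1])
    maf = np.exp(rng.uniform(log_lo, log_hi, size=n))
    maf[absent] = np.nan

    rows = pd.DataFrame({
        "protein_variant": [f"{r}{p}{a}" for r, p, a in zip(ref, pos, alt)],
        "ref_aa": ref, "alt_aa": alt, "aa_pos": pos,
        "am_score": scores, "maf": maf,
    })
    truth = {"benign": int((comp == 0).sum()),
             "indeterminate": int((comp == 1).sum()),
             "pathogenic": int((comp == 2).sum())}
    return rows, truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator: one patient per family, all genotypes constructed to
    pass the study inclusion filter unless ``phase`` says otherwise."""

    seed: int = 0
    n_families: int = 26
    recurrence_k: int = 6       # families sharing the planted recurrent missense
    n_cis_pairs: int = 2        # families whose patient carries 2 in-cis missense
    p_maf_absent: float = 0.5
    onset_weights: tuple[float, float, float] = (0.7, 0.2, 0.1)  # cong/child/adult
    phase: Phase = Phase.CONFIRMED_TRANS


def _mk_missense(rng, aa_pos: int, p_maf_absent: float = 0.5) -> Variant:
    aas = [a for a in AMINO_ACIDS if a != "P"]  # keep alt pool simple
    ref = rng.choice(aas)
    alt = rng.choice([a for a in AMINO_ACIDS if a != ref])
    cdna_pos = 3 * aa_pos - 1
    absent = rng.random() < p_maf_absent
    return Variant(
        cdna=f"c.{cdna_pos}A>C",
        protein=format_protein_hgvs(aa_pos, ref, alt),
        consequence=Consequence.MISSENSE,
        aa_pos=aa_pos, ref_aa=ref, alt_aa=alt,
        exon=int(rng.integers(2, 344)),
        am_score=float(rng.uniform(0.80, 0.999)),
        maf=None if absent else float(np.exp(rng.uniform(np.log(1e-7), np.log(9e-5)))),
    )


def _mk_ttntv(rng, aa_pos: int) -> Variant:
    ref = rng.choice([a for a in AMINO_ACIDS if a != "W"])
    return Variant(
        cdna=f"c.{3 * aa_pos - 2}G>T",
        protein=format_protein_hgvs(aa_pos, ref, None),
        consequence=Consequence.NONSENSE,
        aa_pos=aa_pos, ref_aa=ref,
        exon=int(rng.integers(2, 344)),
        psi_prenatal=float(rng.uniform(85, 100)),
        psi_postnatal=float(rng.uniform(80, 95)),
    )


def gen_cohort(cfg: CohortConfig) -> tuple[list[PatientGenotype], dict]:
    """Generate a cohort with one planted recurrent missense variant.

    The recurrent variant is shared by the first ``recurrence_k`` families;
    the last ``n_cis_pairs`` families carry an in-cis missense pair. Distinct
    variants use disjoint amino-acid positions so cDNA keys never collide.
    """
    if cfg.recurrence_k > cfg.n_families:
        raise ValueError("recurrence_k cannot exceed n_families")
    if cfg.recurrence_k + cfg.n_cis_pairs > cfg.n_families:
        raise ValueError("recurrent and in-cis families must not overlap")
    rng = np.random.default_rng(cfg.seed)
    cohort: list[PatientGenotype] = []
    if cfg.n_families == 0:
        return cohort, {"n_patients": 0, "n_families": 0,
                        "n_distinct_missense": 0, "n_distinct_ttntv": 0,
                        "recurrent_key": None, "recurrence_k": 0}

    # disjoint position pools: recurrent=1000; singles 2000+; cis extras 20000+;
    # TTNtv 30000+
    recurrent = _mk_missense(rng, 1000, cfg.p_maf_absent)
    n_distinct_missense = 0
    for i in range(cfg.n_families):
        fam = f"SF{i + 1}"
        if i < cfg.recurrence_k:
            alleles = [recurrent]
        else:
            alleles = [_mk_missense(rng, 2000 + 10 * i, cfg.p_maf_absent)]
            n_distinct_missense += 1
        if i >= cfg.n_families - cfg.n_cis_pairs:
            alleles.append(_mk_missense(rng, 20_000 + 10 * i, cfg.p_maf_absent))
            n_distinct_missense += 1
        cohort.append(PatientGenotype(
            family_id=fam, patient_id=f"{fam}-P1",
            missense_alleles=alleles,
            ttntv=_mk_ttntv(rng, 30_000 + 10 * i),
            phase=cfg.phase,
            onset_tier=list(OnsetTier)[rng.choice(3, p=cfg.onset_weights)],
        ))
    if cfg.recurrence_k > 0:
        n_distinct_missense += 1
    truth = {
        "n_patients": cfg.n_families,
        "n_families": cfg.n_families,
        "n_distinct_missense": n_distinct_missense,
        "n_distinct_ttntv": cfg.n_families,
        "recurrent_key": recurrent.key if cfg.recurrence_k >= 2 else None,
        "recurrence_k": cfg.recurrence_k,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# Family haplotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeConfig:
    seed: int = 0
    n_families: int = 4
    core_size: int = 45          # planted shared haplotype variants
    n_private: int = 20          # private variants per family

    def __post_init__(self):
        if self.core_size < 0:
            raise ValueError("core_size must be non-negative")
        if self.n_private < 0:
            raise ValueError("n_private must be non-negative")


def gen_family_haplotypes(cfg: HaplotypeConfig
                          ) -> tuple[list[FamilyVariantSet], frozenset[str]]:
    """Family variant sets sharing a planted core.

    Private variants draw from per-family disjoint position pools, so the
    intersection of the returned sets is exactly the core.
    """
    rng = np.random.default_rng(cfg.seed)
    core = frozenset(f"c.{100 + 3 * i}A>G" for i in range(cfg.core_size))
    fams = []
    for i in range(cfg.n_families):
        base = 10_000 * (i + 1)
        pool = [f"c.{base + 2 * j}C>T" for j in range(max(cfg.n_private * 3, 1))]
        private = rng.choice(pool, size=cfg.n_private, replace=False) if cfg.n_private else []
        fams.append(FamilyVariantSet(f"HF{i + 1}", set(core) | set(private)))
    return fams, core


# ---------------------------------------------------------------------------
# Cell images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageConfig:
    """Synthetic COS-7-like scene: one elliptical cell per image.

    ``diffuse_nuclear`` scenes place a brighter elliptical nucleus on a
    uniformly expressing cell; ``punctate`` scenes dim the cytoplasm, keep
    the nucleus at background level (nuclear exclusion) and scatter bright
    Gaussian puncta outside the nucleus. Additive Gaussian noise emulates
    camera/shot noise.
    """

    seed: int = 0
    n_images: int = 30
    shape: tuple[int, int] = (128, 128)
    cell_radii: tuple[float, float] = (42.0, 34.0)
    nucleus_radii: tuple[float, float] = (13.0, 11.0)
    background: float = 5.0
    cytoplasm_intensity: float = 40.0
    nucleus_intensity: float = 120.0
    punctate_cytoplasm: float = 30.0
    n_puncta: int = 12
    puncta_amplitude: float = 150.0
    puncta_sigma: float = 1.2
    noise_sd: float = 3.0

    def __post_init__(self):
        if (self.nucleus_radii[0] >= self.cell_radii[0]
                or self.nucleus_radii[1] >= self.cell_radii[1]):
            raise ValueError("nucleus must fit inside the cell")
        if min(self.shape) < 64:
            raise ValueError("image dimensions must be >= 64x64")


def _ellipse_mask(shape, center, radii, angle) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def gen_cell_images(cfg: ImageConfig, pattern: str
                    ) -> list[tuple[np.ndarray, dict[str, np.ndarray]]]:
    """Generate ``n_images`` scenes of the requested expression pattern.

    Returns a list of (image, truth) pairs, truth holding the ground-truth
    ``cell_mask`` and ``nucleus_mask``.
    """
    if pattern not in ("diffuse_nuclear", "punctate"):
        raise ValueError(f"unknown pattern: {pattern!r}")
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    out = []
    for _ in range(cfg.n_images):
        center = (h / 2 + rng.uniform(-6, 6), w / 2 + rng.uniform(-6, 6))
        angle = rng.uniform(0, np.pi)
        cell = _ellipse_mask(cfg.shape, center, cfg.cell_radii, angle)
        nuc_center = (center[0] + rng.uniform(-5, 5), center[1] + rng.uniform(-5, 5))
        nucleus = _ellipse_mask(cfg.shape, nuc_center, cfg.nucleus_radii, angle)
        nucleus &= cell

        img = np.full(cfg.shape, cfg.background, dtype=float)
        if pattern == "diffuse_nuclear":
            img[cell] = cfg.cytoplasm_intensity
            img[nucleus] = cfg.nucleus_intensity
        else:
            img[cell] = cfg.punctate_cytoplasm
            img[nucleus] = cfg.background  # nuclear exclusion
            yy, xx = np.mgrid[0:h, 0:w]
            placed = 0
            while placed < cfg.n_puncta:
                py = rng.uniform(0, h)
                px = rng.uniform(0, w)
                iy, ix = int(py), int(px)
                if not (0 <= iy < h and 0 <= ix < w):
                    continue
                if not cell[iy, ix] or nucleus[iy, ix]:
                    continue
                img += cfg.puncta_amplitude * np.exp(
                    -((yy - py) ** 2 + (xx - px) ** 2) / (2 * cfg.puncta_sigma ** 2))
                placed += 1
        if cfg.noise_sd > 0:
            img = img + rng.normal(0, cfg.noise_sd, size=cfg.shape)
        img = np.clip(img, 0, None)
        out.append((img, {"cell_mask": cell, "nucleus_mask": nucleus}))
    return out
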