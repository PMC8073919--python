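"""Effect-allele dosage extraction from VCF and genotype utilities.

Scoring needs each genotype expressed as the number of copies (0, 1 or 2)
of the *effect allele* the GWAS beta refers to, which rarely coincides with
the VCF ALT allele.  :func:`read_dosages` harmonizes: it counts ALT copies
when ALT is the effect allele, complements the count when REF is, and falls
back to the reverse-complement strand for non-palindromic variants.
Palindromic (A/T, C/G) variants must match literally — strand cannot be
resolved from alleles alone and frequency-based disambiguation is
deliberately not attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from sklearn.decomposition import PCA

from .weights import WeightTable

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeError(ValueError):
    """Raised for harmonization or missingness failures."""


@dataclass
class DosageMatrix:
    """Individuals x variants effect-allele dosage counts.

    ``dosages`` are in [0, 2]: integers for hard calls, fractional after
    mean-dosage imputation.  ``missing_mask`` is True where the original
    call was missing (the provisional dosage there is 0 until
    :func:`impute_missing` runs).  ``effect_allele_freq`` is computed over
    non-missing calls only.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    missing_mask: np.ndarray
    effect_allele_freq: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.sample_ids), len(self.variant_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.effect_allele_freq = np.asarray(self.effect_allele_freq, dtype=float)
        if self.dosages.shape != (n, m) or self.missing_mask.shape != (n, m):
            raise GenotypeError("dosage/mask dimensions inconsistent with ids")
        if self.effect_allele_freq.shape != (m,):
            raise GenotypeError("effect_allele_freq length inconsistent")
        if np.any((self.dosages < 0) | (self.dosages > 2)):
            raise GenotypeError("dosages must lie in [0, 2]")
        ok = ~np.isnan(self.effect_allele_freq)
        if np.any((self.effect_allele_freq[ok] < 0) | (self.effect_allele_freq[ok] > 1)):
            raise GenotypeError("effect allele frequencies must lie in [0, 1]")

    @classmethod
    def from_dosages(
        cls,
        sample_ids: list[str],
        variant_ids: list[str],
        dosages: np.ndarray,
        missing_mask: np.ndarray | None = None,
    ) -> "DosageMatrix":
        """Build a matrix, deriving allele frequencies from non-missing calls."""
        dosages = np.asarray(dosages, dtype=float)
        if missing_mask is None:
            missing_mask = np.zeros_like(dosages, dtype=bool)
        missing_mask = np.asarray(missing_mask, dtype=bool)
        freqs = np.empty(dosages.shape[1])
        for j in range(dosages.shape[1]):
            obs = dosages[~missing_mask[:, j], j]
            freqs[j] = obs.sum() / (2 * obs.size) if obs.size else np.nan
        return cls(list(sample_ids), list(variant_ids), dosages, missing_mask, freqs)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.variant_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def _effect_dosage(alt_count: np.ndarray, ref: str, alt: str, effect: str) -> np.ndarray | None:
    """ALT-count -> effect-allele dosage, or None if alleles cannot be matched."""
    if alt == effect:
        return alt_count
    if ref == effect:
        return 2 - alt_count
    # palindromic variants: strand is unresolvable, literal match only
    if _COMPLEMENT[ref] == alt:
        return None
    flipped = _COMPLEMENT.get(effect)
    if flipped == alt:
        return alt_count
    if flipped == ref:
        return 2 - alt_count
    return None


def read_dosages(
    vcf_path: str | Path,
    weights: WeightTable,
    mismatch_policy: str = "error",
) -> DosageMatrix:
    """Read effect-allele dosages for the weight-table variants from a VCF.

    Variants are matched primarily by rsID (the ID column), with a
    chromosome/position fallback for records lacking an ID.  Missing
    genotypes get a provisional dosage of 0 with ``missing_mask`` set;
    impute before scoring.

    Parameters
    ----------
    mismatch_policy
        ``"error"`` raises on any allele mismatch; ``"drop"`` excludes the
        variant with a warning.
    """
    if mismatch_policy not in ("error", "drop"):
        raise ValueError("mismatch_policy must be 'error' or 'drop'")
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)

    wanted = {r.rsid: r for r in weights}
    by_locus = {(r.chrom.removeprefix("chr"), r.pos): r for r in weights}

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    columns: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    mismatched: list[str] = []
    for rec in vcf:
        rid = rec.ID
        target = wanted.get(rid) if rid else None
        if target is None:
            target = by_locus.get((str(rec.CHROM).removeprefix("chr"), rec.POS))
        if target is None or target.rsid in columns:
            continue
        if len(rec.ALT) != 1:
            raise GenotypeError(
                f"{target.rsid}: multiallelic record at a scoring variant"
            )
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=int)
        missing = np.any(alleles < 0, axis=1)
        alt_count = np.where(missing, 0, (alleles == 1).sum(axis=1)).astype(float)
        dosage = _effect_dosage(alt_count, ref, alt, target.effect_allele)
        if dosage is None:
            if mismatch_policy == "error":
                raise GenotypeError(
                    f"{target.rsid}: alleles {ref}/{alt} do not match effect "
                    f"allele {target.effect_allele} (nor its complement)"
                )
            mismatched.append(target.rsid)
            continue
        dosage = np.where(missing, 0.0, dosage)
        columns[target.rsid] = (dosage, missing)
    if mismatched:
        warnings.warn(
            f"dropped {len(mismatched)} variant(s) with unmatched alleles: "
            f"{', '.join(mismatched)}"
        )
    absent = [r.rsid for r in weights if r.rsid not in columns and r.rsid not in mismatched]
    if absent:
        raise GenotypeError(
            f"weight-table variant(s) absent from {vcf_path.name}: {', '.join(absent)}"
        )

    order = [r.rsid for r in weights if r.rsid in columns]
    dosages = np.column_stack([columns[v][0] for v in order])
    mask = np.column_stack([columns[v][1] for v in order])
    return DosageMatrix.from_dosages(sample_ids, order, dosages, mask)


def impute_missing(matrix: DosageMatrix) -> DosageMatrix:
    """Replace missing dosages with twice the effect-allele frequency.

    This mean-dosage rule preserves the per-variant mean dosage exactly and
    keeps every individual in the analysis.  The missingness mask is kept
    for reporting.  Returns the input unchanged (same object) when nothing
    is missing.
    """
    if not matrix.missing_mask.any():
        return matrix
    dead = [
        matrix.variant_ids[j]
        for j in range(matrix.n_variants)
        if matrix.missing_mask[:, j].all()
    ]
    if dead:
        raise GenotypeError(
            f"variant(s) with zero non-missing calls cannot be imputed: {', '.join(dead)}"
        )
    dosages = matrix.dosages.copy()
    fill = np.broadcast_to(2.0 * matrix.effect_allele_freq, dosages.shape)
    dosages[matrix.missing_mask] = fill[matrix.missing_mask]
    return replace(matrix, dosages=dosages)


def compute_pcs(matrix: DosageMatrix, k: int) -> np.ndarray:
    """Principal-component scores of the column-centered dosage matrix.

    Columns are ordered by decreasing explained variance and are mutually
    orthogonal.  Sign convention: within each component the
    largest-magnitude variant loading is made positive, so scores are
    reproducible across runs and platforms.

    This is a convenience for small simulated panels; real ancestry PCs
    come from genome-wide data and are supplied as covariates.
    """
    centered = matrix.dosages - matrix.dosages.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if k > rank:
        raise GenotypeError(f"k={k} exceeds the rank ({rank}) of the centered matrix")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(centered)
    for j in range(k):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores
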