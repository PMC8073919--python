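"""Weighted polygenic score and per-SD standardization.

The score for individual *i* is ``PRS_i = sum_j x_ij * beta_j`` where
``x_ij`` is the effect-allele dosage (0/1/2, fractional after imputation)
and ``beta_j`` the discovery-GWAS weight.  Association models use the
per-standard-deviation scale: the in-sample z-score of the raw PRS, with
the sample (n-1) standard deviation, so coefficients read as "per SD of
the PRS in this cohort".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import DosageMatrix
from .weights import WeightTable


class PrsError(ValueError):
    pass


@dataclass
class PrsResult:
    sample_ids: list[str]
    raw_score: np.ndarray
    z_score: np.ndarray | None
    n_variants_used: int
    weights_provenance: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw_score": self.raw_score,
                "z_score": np.full(len(self.sample_ids), np.nan)
                if self.z_score is None
                else self.z_score,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compute_prs(matrix: DosageMatrix, weights: WeightTable) -> PrsResult:
    """Raw weighted dosage sum over the matrix's variants in weight-table order.

    Every matrix variant must appear in the weight table, and missing calls
    must already be imputed (see :func:`bdrprs.genotypes.impute_missing`).
    """
    betas = weights.betas
    absent = [v for v in matrix.variant_ids if v not in betas]
    if absent:
        raise PrsError(f"variant(s) not in weight table: {', '.join(absent)}")
    if matrix.missing_mask.any():
        raise PrsError("dosage matrix contains unimputed missing calls")
    table_order = [v for v in weights.rsids if v in set(matrix.variant_ids)]
    idx = [matrix.variant_ids.index(v) for v in table_order]
    w = np.array([betas[v] for v in table_order])
    raw = matrix.dosages[:, idx] @ w
    return PrsResult(
        sample_ids=list(matrix.sample_ids),
        raw_score=raw,
        z_score=None,
        n_variants_used=len(table_order),
        weights_provenance=weights.provenance,
    )


def standardize(result: PrsResult) -> PrsResult:
    """Fill in-sample z-scores: ``(raw - mean) / SD`` with the n-1 SD."""
    raw = np.asarray(result.raw_score, dtype=float)
    if raw.size < 2:
        raise PrsError("standardization needs at least 2 individuals")
    sd = raw.std(ddof=1)
    # relative floor: scores equal up to float rounding are still "constant"
    if sd <= 1e-12 * max(1.0, float(np.abs(raw).max())):
        raise PrsError("raw scores are constant; z-score undefined")
    return replace(result, z_score=(raw - raw.mean()) / sd)
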