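"""GWAS summary-statistic parsing and CADD-prioritized variant selection.

The scoring weights come from a discovery GWAS of bronchodilator response
(Himes et al. 2012, doi:10.1016/j.ajhg.2012.05.023): candidate variants are
the top GWAS polymorphisms (p < 0.001), and of those, the ones whose
PHRED-scaled CADD deleteriousness score is 10 or higher are retained for
scoring.  The 16-variant weight table from that selection ships as package
data (:func:`packaged_weight_table`).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

NUCLEOTIDES = frozenset("ACGT")

#: Default inclusion thresholds: top GWAS variants at p < 0.001, kept when
#: the PHRED-scaled CADD score is 10 or higher (inclusive).
DEFAULT_P_MAX = 0.001
DEFAULT_CADD_MIN = 10.0

_SUMMARY_COLUMNS = ["chrom", "pos", "rsid", "effect_allele", "beta", "p_value"]
_WEIGHT_COLUMNS = ["Chr", "bp", "rsID", "EffectAllele", "Beta"]


class WeightTableError(ValueError):
    """Raised for malformed summary statistics or weight tables."""


@dataclass(frozen=True)
class VariantRecord:
    """One GWAS summary-statistic row, a candidate for PRS inclusion.

    ``beta`` is the GWAS effect size on BDR % per copy of ``effect_allele``;
    ``cadd_phred`` is the PHRED-scaled CADD score (``None`` when the variant
    was not annotated).
    """

    chrom: str
    pos: int
    rsid: str
    effect_allele: str
    beta: float
    p_value: float | None = None
    cadd_phred: float | None = None
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise WeightTableError("rsid must be nonempty")
        if self.effect_allele not in NUCLEOTIDES:
            raise WeightTableError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not a "
                "single nucleotide A/C/G/T"
            )
        if not math.isfinite(self.beta):
            raise WeightTableError(f"{self.rsid}: beta must be finite")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise WeightTableError(f"{self.rsid}: p-value must lie in (0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise WeightTableError(f"{self.rsid}: CADD score must be >= 0")


@dataclass
class WeightTable:
    """Ordered set of scoring variants with signed effect-allele weights."""

    entries: list[VariantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise WeightTableError("weight table must be nonempty")
        counts = Counter(r.rsid for r in self.entries)
        dups = sorted(rsid for rsid, n in counts.items() if n > 1)
        if dups:
            raise WeightTableError(f"duplicate rsIDs in weight table: {', '.join(dups)}")

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.entries]

    @property
    def betas(self) -> dict[str, float]:
        return {r.rsid: r.beta for r in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subset(self, rsids: Iterable[str]) -> "WeightTable":
        """Restrict to ``rsids``, preserving table order."""
        keep = set(rsids)
        return WeightTable(
            [r for r in self.entries if r.rsid in keep], provenance=self.provenance
        )


def _chrom_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):03d}") if c.isdigit() else (1, c)


def load_summary_stats(path: str | Path) -> list[VariantRecord]:
    """Parse a tab-separated GWAS summary-statistics file.

    Required columns: ``chrom, pos, rsid, effect_allele, beta, p_value``;
    optional: ``cadd_phred`` (empty = unannotated), ``gene``.  Rows whose
    beta or p-value does not parse as a number are rejected with 1-based
    data-row diagnostics; duplicate rsIDs are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise WeightTableError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    records: list[VariantRecord] = []
    bad_rows: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            beta = float(getattr(row, "beta"))
            p = float(getattr(row, "p_value"))
            if not (math.isfinite(beta) and math.isfinite(p)):
                raise ValueError
        except ValueError:
            bad_rows.append(f"row {i} (rsid={getattr(row, 'rsid', '?')})")
            continue
        cadd_raw = getattr(row, "cadd_phred", "")
        gene = getattr(row, "gene", "") or None
        records.append(
            VariantRecord(
                chrom=str(getattr(row, "chrom")),
                pos=int(getattr(row, "pos")),
                rsid=str(getattr(row, "rsid")),
                effect_allele=str(getattr(row, "effect_allele")).upper(),
                beta=beta,
                p_value=p,
                cadd_phred=float(cadd_raw) if str(cadd_raw).strip() else None,
                gene_label=gene,
            )
        )
    if bad_rows:
        raise WeightTableError(
            f"{path}: unparseable beta/p-value on {', '.join(bad_rows)}"
        )
    counts = pd.Series([r.rsid for r in records]).value_counts()
    dups = sorted(counts[counts > 1].index)
    if dups:
        raise WeightTableError(f"{path}: duplicate rsIDs: {', '.join(dups)}")
    return records


def select_prs_variants(
    records: list[VariantRecord],
    p_max: float = DEFAULT_P_MAX,
    cadd_min: float = DEFAULT_CADD_MIN,
) -> WeightTable:
    """Apply the two-stage filter: p < ``p_max`` then CADD >= ``cadd_min``.

    The p-value cut is strict; the CADD cut is inclusive.  Records without a
    CADD annotation fail the CADD filter.  The output is ranked by
    descending CADD score (ties broken by ascending chromosome, position),
    reflecting the prioritization role the score plays in selection.
    """
    selected = [
        r
        for r in records
        if r.p_value is not None
        and r.p_value < p_max
        and r.cadd_phred is not None
        and r.cadd_phred >= cadd_min
    ]
    if not selected:
        raise WeightTableError(
            f"no variants pass p < {p_max} and CADD >= {cadd_min}; "
            "review the thresholds or the annotation coverage"
        )
    selected.sort(key=lambda r: (-r.cadd_phred, _chrom_key(r.chrom), r.pos))
    return WeightTable(selected, provenance=f"selected: p<{p_max}, CADD>={cadd_min}")


def read_weight_table(path: str | Path) -> WeightTable:
    """Read a tab-separated weight table (Chr, bp, rsID, EffectAllele, Beta,
    optional P, CADD, Gene)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise WeightTableError(f"{path}: missing column(s): {', '.join(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        p = getattr(row, "P", "")
        cadd = getattr(row, "CADD", "")
        gene = getattr(row, "Gene", "") or None
        entries.append(
            VariantRecord(
                chrom=str(row.Chr),
                pos=int(row.bp),
                rsid=str(row.rsID),
                effect_allele=str(row.EffectAllele).upper(),
                beta=float(row.Beta),
                p_value=float(p) if str(p).strip() else None,
                cadd_phred=float(cadd) if str(cadd).strip() else None,
                gene_label=gene,
            )
        )
    return WeightTable(entries, provenance=str(path))


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    """Write ``table`` so that ``read_weight_table`` round-trips all fields.

    Betas and p-values are serialized with ``repr`` precision.
    """
    rows = []
    for r in table.entries:
        rows.append(
            {
                "Chr": r.chrom,
                "bp": r.pos,
                "rsID": r.rsid,
                "EffectAllele": r.effect_allele,
                "Beta": repr(r.beta),
                "P": "" if r.p_value is None else repr(r.p_value),
                "CADD": "" if r.cadd_phred is None else repr(r.cadd_phred),
                "Gene": r.gene_label or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _data_path(name: str) -> Path:
    return Path(resources.files("bdrprs").joinpath("data", name))


def packaged_weight_table() -> WeightTable:
    """The published 16-variant bronchodilator-response scoring table.

    Weights (betas, BDR % per effect allele) are the discovery-GWAS effect
    sizes of Himes et al. for the 16 variants that pass the p < 0.001 and
    CADD >= 10 filters.
    """
    table = read_weight_table(_data_path("himes_bdr_weights.tsv"))
    table.provenance = "Himes et al. 2012 BDR GWAS, CADD-prioritized (16 SNPs)"
    return table


def packaged_summary_stats_path() -> Path:
    """Path to the packaged synthetic summary-statistics demo file.

    Contains the 16 scoring variants plus 10 decoy rows that each fail the
    p-value or CADD filter; per-variant p and CADD values for the 16 are
    synthetic placeholders consistent with the filters (the discovery GWAS
    did not publish them per SNP).
    """
    return _data_path("summary_stats_synthetic.tsv")
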