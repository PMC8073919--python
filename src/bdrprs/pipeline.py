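"""End-to-end orchestration: weights -> dosages -> PRS -> association models.

``run_pipeline`` executes the full analysis on either real inputs (VCF +
phenotype CSV + weight table or summary statistics) or a synthetic cohort
generated on the fly, and returns a machine-readable
:class:`PipelineReport`.  Every stage logs counts to standard error.
"""

from __future__ import annotations

import json
import logging
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .association import fit_linear_adjusted, fit_logistic_threshold, test_interaction
from .genotypes import impute_missing, read_dosages
from .phenotypes import dichotomize_bdr, read_cohort_csv
from .prs import compute_prs, standardize
from .simulate import (
    CovariateParams,
    MixtureParams,
    SimulationConfig,
    generate_cohort,
)
from .weights import (
    load_summary_stats,
    packaged_weight_table,
    read_weight_table,
    select_prs_variants,
    DEFAULT_P_MAX,
    DEFAULT_CADD_MIN,
)

log = logging.getLogger("bdrprs")

REPORT_SCHEMA_VERSION = "1"


class WeightTableSummary(BaseModel):
    n_selected: int
    p_max: float | None = None
    cadd_min: float | None = None
    provenance: str = ""


class CohortSummary(BaseModel):
    n: int
    bdr_mean: float | None = None
    bdr_sd: float | None = None
    responder_fraction_12: float | None = None
    responder_fraction_8: float | None = None
    prs_raw_mean: float
    prs_raw_sd: float
    n_variants: int


class AssociationEntry(BaseModel):
    model: str
    outcome: str
    estimate: float
    odds_ratio: float | None = None
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    covariate_estimates: dict[str, float]
    formula: str


class PipelineReport(BaseModel):
    """Versioned, JSON-serializable record of one pipeline run."""

    schema_version: str = REPORT_SCHEMA_VERSION
    software_version: str = __version__
    seed: int | None = None
    config_echo: dict[str, Any] = Field(default_factory=dict)
    weight_table_summary: WeightTableSummary
    cohort_summary: CohortSummary
    association_results: list[AssociationEntry]
    interaction_p_values: dict[str, float] = Field(default_factory=dict)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    def to_text(self) -> str:
        lines = [
            f"bdrprs {self.software_version} pipeline report (schema v{self.schema_version})",
            f"variants in score: {self.weight_table_summary.n_selected}",
            f"cohort n = {self.cohort_summary.n}; "
            f"raw PRS mean {self.cohort_summary.prs_raw_mean:.3f}, "
            f"SD {self.cohort_summary.prs_raw_sd:.3f}",
        ]
        if self.cohort_summary.bdr_mean is not None:
            lines.append(
                f"BDR mean {self.cohort_summary.bdr_mean:.2f}%, "
                f"SD {self.cohort_summary.bdr_sd:.2f}%; "
                f"responders >=12%: {100 * self.cohort_summary.responder_fraction_12:.1f}%, "
                f">=8%: {100 * self.cohort_summary.responder_fraction_8:.1f}%"
            )
        for r in self.association_results:
            if r.model == "linear":
                lines.append(
                    f"linear {r.outcome}: {r.estimate:+.3f} BDR%/SD "
                    f"(95% CI {r.ci_low:.3f} to {r.ci_high:.3f}, p = {r.p_value:.3g}, n = {r.n})"
                )
            else:
                lines.append(
                    f"logistic {r.outcome}: OR {r.odds_ratio:.3f}/SD "
                    f"(95% CI {r.ci_low:.3f} to {r.ci_high:.3f}, p = {r.p_value:.3g}, n = {r.n})"
                )
        for mod, p in self.interaction_p_values.items():
            flag = "" if p > 0.10 else " *"
            lines.append(f"interaction {mod} x PRS: p = {p:.3g}{flag}")
        return "\n".join(lines)


def _simulation_config_from_dict(block: dict, seed: int | None) -> SimulationConfig:
    kwargs = dict(block)
    if seed is not None:
        kwargs.setdefault("seed", seed)
    if "noise" in kwargs and isinstance(kwargs["noise"], dict):
        kwargs["noise"] = MixtureParams(**kwargs["noise"])
    if "covariate_params" in kwargs and isinstance(kwargs["covariate_params"], dict):
        kwargs["covariate_params"] = CovariateParams(**kwargs["covariate_params"])
    if "allele_freqs" in kwargs and kwargs["allele_freqs"] is not None:
        kwargs["allele_freqs"] = np.asarray(kwargs["allele_freqs"], dtype=float)
    return SimulationConfig(**kwargs)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> PipelineReport:
    """Execute select -> dosages -> impute -> PRS -> models -> report.

    ``config`` keys (all optional unless noted):

    * ``weights``: weight-table path (default: the packaged 16-variant table)
    * ``summary_stats`` (+ ``p_max``, ``cadd_min``): derive the weight table
      from annotated summary statistics instead
    * ``vcf`` and ``phenotypes``: cohort input files; or ``simulation``: a
      block of :class:`~bdrprs.simulate.SimulationConfig` fields to generate
      a cohort on the fly
    * ``thresholds``: BDR % cut-points for the logistic models (default [12, 8])
    * ``interactions``: modifiers to test on the linear model
      (default ["sex", "age", "bmi_category"])
    * ``mismatch_policy``: allele-mismatch handling, "error" (default) or "drop"
    * ``seed``: master seed for simulation
    """
    seed = config.get("seed")
    config_echo = {k: v for k, v in config.items() if k != "weights_table"}

    # stage 1: scoring weights
    if config.get("summary_stats"):
        p_max = config.get("p_max", DEFAULT_P_MAX)
        cadd_min = config.get("cadd_min", DEFAULT_CADD_MIN)
        records = load_summary_stats(config["summary_stats"])
        weights = select_prs_variants(records, p_max=p_max, cadd_min=cadd_min)
        wsum = WeightTableSummary(
            n_selected=len(weights), p_max=p_max, cadd_min=cadd_min,
            provenance=weights.provenance,
        )
        log.info("weights: selected %d of %d candidate variants", len(weights), len(records))
    elif config.get("weights"):
        weights = read_weight_table(config["weights"])
        wsum = WeightTableSummary(n_selected=len(weights), provenance=weights.provenance)
        log.info("weights: loaded %d variants from %s", len(weights), config["weights"])
    else:
        weights = packaged_weight_table()
        wsum = WeightTableSummary(n_selected=len(weights), provenance=weights.provenance)
        log.info("weights: packaged table, %d variants", len(weights))

    # stage 2: cohort inputs (real files or on-the-fly simulation)
    tmp = None
    if config.get("simulation") is not None:
        sim_cfg = _simulation_config_from_dict(dict(config["simulation"]), seed)
        sim_cfg.weights = weights
        if out_dir is None:
            tmp = tempfile.TemporaryDirectory()
            target = Path(tmp.name)
        else:
            target = Path(out_dir) / "simulated_cohort"
        paths = generate_cohort(sim_cfg, target)
        vcf_path, pheno_path = paths["vcf"], paths["phenotypes"]
        log.info("simulation: wrote cohort n=%d to %s", sim_cfg.n, target)
    else:
        vcf_path, pheno_path = config.get("vcf"), config.get("phenotypes")
        if not vcf_path or not pheno_path:
            raise ValueError("config must provide vcf+phenotypes or a simulation block")

    try:
        matrix = read_dosages(vcf_path, weights, config.get("mismatch_policy", "error"))
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"genotypes stage: {exc}") from exc
    log.info(
        "genotypes: %d samples x %d variants, %.3f%% missing calls",
        matrix.n_samples, matrix.n_variants, 100 * matrix.missing_mask.mean(),
    )
    matrix = impute_missing(matrix)
    try:
        cohort = read_cohort_csv(pheno_path)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"phenotypes stage: {exc}") from exc
    if tmp is not None:
        tmp.cleanup()

    # stage 3: score and standardize
    prs = standardize(compute_prs(matrix, weights))
    log.info(
        "prs: %d variants used; raw mean %.3f, SD %.3f",
        prs.n_variants_used, prs.raw_score.mean(), prs.raw_score.std(ddof=1),
    )

    # stage 4: association models
    results = []
    interactions: dict[str, float] = {}
    has_bdr = "bdr_percent" in cohort.data.columns
    thresholds = config.get("thresholds", [12.0, 8.0])
    if has_bdr:
        results.append(fit_linear_adjusted(cohort, prs))
        for t in thresholds:
            results.append(fit_logistic_threshold(cohort, prs, threshold=t))
        for mod in config.get("interactions", ["sex", "age", "bmi_category"]):
            interactions[mod] = test_interaction(cohort, prs, mod)
    else:
        # threshold-mode cohort: a single precomputed responder outcome
        thr = config.get("simulation", {}).get("threshold", 12.0)
        results.append(fit_logistic_threshold(cohort, prs, threshold=thr))
    for r in results:
        log.info("model %s/%s: estimate %.4f (p=%.3g)", r.model, r.outcome, r.estimate, r.p_value)

    bdr = cohort.bdr_percent if has_bdr else None
    cohort_summary = CohortSummary(
        n=len(cohort),
        bdr_mean=float(np.mean(bdr)) if has_bdr else None,
        bdr_sd=float(np.std(bdr, ddof=1)) if has_bdr else None,
        responder_fraction_12=float(np.mean(dichotomize_bdr(bdr, 12))) if has_bdr else None,
        responder_fraction_8=float(np.mean(dichotomize_bdr(bdr, 8))) if has_bdr else None,
        prs_raw_mean=float(prs.raw_score.mean()),
        prs_raw_sd=float(prs.raw_score.std(ddof=1)),
        n_variants=prs.n_variants_used,
    )
    return PipelineReport(
        seed=seed,
        config_echo=config_echo,
        weight_table_summary=wsum,
        cohort_summary=cohort_summary,
        association_results=[AssociationEntry(**r.to_dict()) for r in results],
        interaction_p_values=interactions,
    )


def report_json_schema() -> dict:
    """The versioned JSON Schema the report validates against."""
    return PipelineReport.model_json_schema()


def shipped_report_schema() -> dict:
    """The copy of the report schema distributed as package data."""
    from importlib import resources

    path = resources.files("bdrprs").joinpath("data", "report_schema.json")
    return json.loads(path.read_text())


def validate_report_json(path: str | Path) -> PipelineReport:
    """Load and schema-validate a report written by :meth:`PipelineReport.write_json`."""
    return PipelineReport.model_validate(json.loads(Path(path).read_text()))
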