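"""End-to-end cohort analysis: filter -> classify -> phase -> signatures /
TMB -> survival and clinicopathological statistics, written as a report
bundle of TSV tables plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .variant_io import (
    ClinicalRecord,
    FilterCriteria,
    apply_filters,
    read_blacklist,
    read_clinical,
    read_maf,
)
from .mm_core import (
    GeneCatalog,
    MMClassification,
    classify_mm,
    count_per_gene,
    gene_mm_fraction,
    impact_distribution,
    read_gene_catalog,
    stratify_by_catalog,
)
from .phasing import phase_gene, read_evidence_tsv
from .mutational_context import (
    build_catalogs,
    compute_tmb,
    dichotomize_tmb,
    fit_signatures,
    read_signature_matrix,
    synthetic_signature_matrix,
    DEFAULT_TARGET_SIZE_MB,
)
from .clinical_stats import (
    CLINICAL_CUTOFFS,
    cox_fit,
    expression_by_mm,
    group_compare,
    km_estimate,
    logrank_test,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "tcga_frequencies"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    maf: str
    clinical: Optional[str] = None
    out_dir: str = "mm_report"
    maf_dialect: str = "tcga"
    gene_catalog: Optional[str] = None
    read_evidence: Optional[str] = None
    expression: Optional[str] = None
    genome_fasta: Optional[str] = None
    signatures: Optional[str] = None  # TSV; falls back to the synthetic matrix
    blacklist: Optional[str] = None
    # filter thresholds
    min_quality: float = 60.0
    min_depth: int = 20
    min_avg_clipped_length: float = 100.0
    min_avg_pos_as_fraction: float = 0.05
    # analysis parameters
    focus_genes: tuple[str, ...] = ("CTNNB1L", "MUC16L")
    min_mutated_samples: int = 20          # gene-summary inclusion threshold
    min_cocover: int = 2
    target_size_mb: float = DEFAULT_TARGET_SIZE_MB
    tmb_cutoff: Optional[float] = 6.65     # per-Mb; None -> percentile mode
    tmb_percentile: float = 95.0
    signature_weight_cutoff: float = 0.06
    cox_ties: str = "efron"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "focus_genes" in raw:
            raw["focus_genes"] = tuple(raw["focus_genes"])
        return cls(**raw)


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def _binary_design(
    clinical: Sequence[ClinicalRecord],
    classification: MMClassification,
    tmb_strata: Mapping[str, str],
) -> pd.DataFrame:
    """Table-1-style binary covariate design, one row per clinical record."""
    rows = []
    for rec in clinical:
        cov = rec.covariates
        rows.append(
            {
                "sample_id": rec.sample_id,
                "mm_present": float(
                    classification.per_sample.get(rec.sample_id) == "MM_tumor"
                ),
                "tmb_hyper": float(tmb_strata.get(rec.sample_id) == "hyper"),
                "sex_male": float(cov.get("sex") == "M"),
                "age_ge_70": float(
                    float(cov.get("age_years", np.nan)) >= CLINICAL_CUTOFFS["age_years"]
                ),
                "viral_positive": float(cov.get("viral") in ("HBV", "HCV")),
                "icg_ge_20": float(
                    float(cov.get("icg_r15_percent", np.nan))
                    >= CLINICAL_CUTOFFS["icg_r15_percent"]
                ),
                "afp_ge_200": float(
                    float(cov.get("afp_ng_ml", np.nan)) >= CLINICAL_CUTOFFS["afp_ng_ml"]
                ),
                "pivka2_ge_100": float(
                    float(cov.get("pivka2_mau_ml", np.nan))
                    >= CLINICAL_CUTOFFS["pivka2_mau_ml"]
                ),
                "size_ge_30": float(
                    float(cov.get("tumor_size_mm", np.nan))
                    >= CLINICAL_CUTOFFS["tumor_size_mm"]
                ),
                "macrovascular_invasion": float(cov.get("macrovascular_invasion", 0)),
                "microvascular_invasion": float(cov.get("microvascular_invasion", 0)),
                "cirrhosis": float(cov.get("cirrhosis", 0)),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _km_rows(label: str, times, events) -> list[dict]:
    fit = km_estimate(times, events)
    return [
        {"group": label, "time": t, "survival": s, "n_at_risk": r}
        for t, s, r in zip(fit.times, fit.survival, fit.n_at_risk)
    ]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and return the mapping of report names to paths.

    Any failure aborts with :class:`PipelineStageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # ---- inputs ----------------------------------------------------------
    stage = "read_inputs"
    try:
        calls = read_maf(config.maf, dialect=config.maf_dialect)
        clinical = read_clinical(config.clinical) if config.clinical else []
        catalog = (
            read_gene_catalog(config.gene_catalog)
            if config.gene_catalog
            else GeneCatalog(entries={})
        )
        evidence = (
            read_evidence_tsv(config.read_evidence) if config.read_evidence else []
        )
        expression = (
            pd.read_csv(config.expression, sep="\t") if config.expression else None
        )
        signatures = (
            read_signature_matrix(config.signatures)
            if config.signatures
            else synthetic_signature_matrix()
        )
        blacklist = (
            read_blacklist(config.blacklist) if config.blacklist else frozenset()
        )
        genome = None
        if config.genome_fasta:
            from pyfaidx import Fasta

            genome = Fasta(config.genome_fasta, as_raw=True)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- filter ----------------------------------------------------------
    stage = "filter"
    try:
        criteria = FilterCriteria(
            min_quality=config.min_quality,
            min_depth=config.min_depth,
            min_avg_clipped_length=config.min_avg_clipped_length,
            min_avg_pos_as_fraction=config.min_avg_pos_as_fraction,
            blacklist=blacklist,
        )
        kept, discard_log = apply_filters(calls, criteria)
        paths["discard_log"] = _write(
            pd.DataFrame(
                [
                    {
                        "sample_id": c.sample_id, "gene": c.gene, "chrom": c.chrom,
                        "pos": c.pos, "ref": c.ref, "alt": c.alt,
                        "failed_criteria": ";".join(fails),
                    }
                    for c, fails in discard_log
                ],
                columns=["sample_id", "gene", "chrom", "pos", "ref", "alt",
                         "failed_criteria"],
            ),
            out / "discard_log.tsv",
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- classify --------------------------------------------------------
    stage = "classify"
    try:
        all_samples = sorted(
            {r.sample_id for r in clinical} | {c.sample_id for c in kept}
        )
        counts = count_per_gene(kept)
        classification = classify_mm(counts, all_samples)
        gene_df, sample_df = classification.to_frames()
        paths["gene_classification"] = _write(gene_df, out / "gene_classification.tsv")
        paths["sample_classification"] = _write(
            sample_df, out / "sample_classification.tsv"
        )
        summary_rows = []
        for gene in sorted({g for (_, g) in counts}):
            frac = gene_mm_fraction(classification, gene)
            if frac.n_single + frac.n_multiple >= config.min_mutated_samples:
                summary_rows.append(
                    {
                        "gene": gene, "n_wild": frac.n_wild,
                        "n_single": frac.n_single, "n_multiple": frac.n_multiple,
                        "mm_fraction_of_mutated": frac.mm_fraction_of_mutated,
                    }
                )
        paths["gene_summary"] = _write(
            pd.DataFrame(
                summary_rows,
                columns=["gene", "n_wild", "n_single", "n_multiple",
                         "mm_fraction_of_mutated"],
            ),
            out / "gene_summary.tsv",
        )
        strata = stratify_by_catalog(classification, catalog)
        paths["catalog_stratification"] = _write(
            pd.DataFrame(
                [{"role": role, "n_samples_with_mm": n} for role, n in sorted(strata.items())]
            ),
            out / "catalog_stratification.tsv",
        )
        paths["impact_distribution"] = _write(
            impact_distribution(kept, classification), out / "impact_distribution.tsv"
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- phase -----------------------------------------------------------
    stage = "phase"
    try:
        phase_rows, phase_summary = [], []
        if evidence:
            for gene in config.focus_genes:
                mm_in_gene = any(
                    g == gene and label == "multiple"
                    for (_, g), (_, label) in classification.per_gene.items()
                )
                if not mm_in_gene:
                    continue
                result = phase_gene(
                    classification, gene, kept, evidence,
                    min_cocover=config.min_cocover,
                )
                for r in result.results:
                    phase_rows.append(
                        {
                            "gene": gene, "sample_id": r.pair[0].sample_id,
                            "pos_a": r.pair[0].pos, "pos_b": r.pair[1].pos,
                            "call": r.call, "n_both_alt": r.n_both_alt,
                            "n_exclusive": r.n_exclusive,
                            "n_cocovering": r.n_cocovering,
                        }
                    )
                phase_summary.append(
                    {"gene": gene, "n_cis": result.n_cis, "n_trans": result.n_trans,
                     "cis_fraction": result.cis_fraction}
                )
        paths["phasing_pairs"] = _write(
            pd.DataFrame(
                phase_rows,
                columns=["gene", "sample_id", "pos_a", "pos_b", "call",
                         "n_both_alt", "n_exclusive", "n_cocovering"],
            ),
            out / "phasing_pairs.tsv",
        )
        paths["phasing_summary"] = _write(
            pd.DataFrame(phase_summary, columns=["gene", "n_cis", "n_trans",
                                                 "cis_fraction"]),
            out / "phasing_summary.tsv",
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- signatures & TMB ------------------------------------------------
    stage = "signatures_tmb"
    try:
        tmb_records = compute_tmb(kept, target_size_mb=config.target_size_mb)
        if config.tmb_cutoff is not None:
            tmb_records, cutoff_used = dichotomize_tmb(
                tmb_records, cutoff=config.tmb_cutoff
            )
        else:
            tmb_records, cutoff_used = dichotomize_tmb(
                tmb_records, percentile=config.tmb_percentile
            )
        tmb_strata = {r.sample_id: r.stratum for r in tmb_records}
        paths["tmb"] = _write(
            pd.DataFrame(
                [
                    {"sample_id": r.sample_id, "n_mutations": r.n_mutations,
                     "tmb_per_mb": r.tmb, "stratum": r.stratum}
                    for r in tmb_records
                ]
            ),
            out / "tmb.tsv",
        )
        tmb_by_status = {
            status: [
                r.tmb for r in tmb_records
                if classification.per_sample.get(r.sample_id) == status
            ]
            for status in ("MM_tumor", "SM_tumor")
        }
        test_rows = []
        if all(len(v) >= 2 for v in tmb_by_status.values()):
            cmp = group_compare(
                [tmb_by_status["MM_tumor"], tmb_by_status["SM_tumor"]],
                test="mann_whitney",
            )
            test_rows.append(
                {"comparison": "tmb_mm_vs_sm", "test": cmp.test,
                 "statistic": cmp.statistic, "p_raw": cmp.p_raw,
                 "p_adjusted": cmp.p_adjusted}
            )

        exposure_rows = []
        if genome is not None:
            catalogs = build_catalogs(kept, genome)
            exposures = {
                s: fit_signatures(
                    cat, signatures, weight_cutoff=config.signature_weight_cutoff
                )
                for s, cat in sorted(catalogs.items())
            }
            for s, exp in exposures.items():
                for sig, w in sorted(exp.weights.items()):
                    exposure_rows.append(
                        {"sample_id": s, "signature": sig, "weight": w,
                         "residual_sse": exp.residual_sse,
                         "n_mutations": exp.n_mutations_used,
                         "low_confidence": exp.low_confidence}
                    )
            # per-signature MM vs SM comparison (Bonferroni over signatures)
            sig_names = sorted({r["signature"] for r in exposure_rows})
            for sig in sig_names:
                groups = {
                    status: [
                        exposures[s].weights.get(sig, 0.0)
                        for s in exposures
                        if classification.per_sample.get(s) == status
                    ]
                    for status in ("MM_tumor", "SM_tumor")
                }
                if all(len(v) >= 2 for v in groups.values()):
                    cmp = group_compare(
                        [groups["MM_tumor"], groups["SM_tumor"]],
                        test="mann_whitney", m_comparisons=len(sig_names),
                    )
                    test_rows.append(
                        {"comparison": f"signature_{sig}_mm_vs_sm", "test": cmp.test,
                         "statistic": cmp.statistic, "p_raw": cmp.p_raw,
                         "p_adjusted": cmp.p_adjusted}
                    )
        paths["signature_exposures"] = _write(
            pd.DataFrame(
                exposure_rows,
                columns=["sample_id", "signature", "weight", "residual_sse",
                         "n_mutations", "low_confidence"],
            ),
            out / "signature_exposures.tsv",
        )
        paths["group_tests"] = _write(
            pd.DataFrame(
                test_rows,
                columns=["comparison", "test", "statistic", "p_raw", "p_adjusted"],
            ),
            out / "group_tests.tsv",
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- survival --------------------------------------------------------
    stage = "survival"
    try:
        km_rows, logrank_rows, cox_rows = [], [], []
        if clinical:
            by_sample = {r.sample_id: r for r in clinical}
            statuses = {
                s: classification.per_sample.get(s, "no_mutation")
                for s in by_sample
            }
            mm_group = [
                (r.rfs_months, r.rfs_event) for r in clinical
                if statuses[r.sample_id] == "MM_tumor"
            ]
            sm_group = [
                (r.rfs_months, r.rfs_event) for r in clinical
                if statuses[r.sample_id] != "MM_tumor"
            ]
            if mm_group and sm_group:
                mm_t, mm_e = zip(*mm_group)
                sm_t, sm_e = zip(*sm_group)
                km_rows += _km_rows("MM_tumor", mm_t, mm_e)
                km_rows += _km_rows("SM_or_no_mutation", sm_t, sm_e)
                statistic, p = logrank_test([(mm_t, mm_e), (sm_t, sm_e)])
                logrank_rows.append(
                    {"comparison": "rfs_mm_vs_sm", "statistic": statistic, "p": p}
                )
            # per-gene three-class survival for focus genes
            for gene in config.focus_genes:
                groups = {"wild_type": [], "single": [], "multiple": []}
                for r in clinical:
                    groups[classification.label(r.sample_id, gene)].append(
                        (r.rfs_months, r.rfs_event)
                    )
                for (a, b) in (("wild_type", "single"), ("single", "multiple")):
                    if len(groups[a]) >= 2 and len(groups[b]) >= 2:
                        ta, ea = zip(*groups[a])
                        tb, eb = zip(*groups[b])
                        statistic, p = logrank_test([(ta, ea), (tb, eb)])
                        logrank_rows.append(
                            {"comparison": f"rfs_{gene}_{a}_vs_{b}",
                             "statistic": statistic, "p": p}
                        )

            design = _binary_design(clinical, classification, tmb_strata)
            times = np.array([r.rfs_months for r in clinical])
            events = np.array([r.rfs_event for r in clinical])
            usable = []
            for cov in design.columns:  # univariate rows
                if design[cov].nunique() <= 1:
                    continue
                try:
                    fit = cox_fit(design[[cov]], times, events, ties=config.cox_ties)
                except (RuntimeError, np.linalg.LinAlgError) as exc:
                    logger.warning("univariate Cox for %r not estimable: %s", cov, exc)
                    continue
                usable.append(cov)
                coef = fit[cov]
                cox_rows.append(
                    {"model": "univariate", "variable": cov,
                     "n": int(design[cov].sum()),
                     "hazard_ratio": coef.hazard_ratio, "ci_low": coef.ci_low,
                     "ci_high": coef.ci_high, "p": coef.p_value}
                )
            if len(usable) >= 2:
                try:
                    fit = cox_fit(design[usable], times, events, ties=config.cox_ties)
                    for coef in fit.coefficients:
                        cox_rows.append(
                            {"model": "multivariate", "variable": coef.covariate,
                             "n": int(design[coef.covariate].sum()),
                             "hazard_ratio": coef.hazard_ratio,
                             "ci_low": coef.ci_low, "ci_high": coef.ci_high,
                             "p": coef.p_value}
                        )
                except (RuntimeError, np.linalg.LinAlgError) as exc:
                    logger.warning("multivariate Cox not estimable: %s", exc)
        paths["km_curves"] = _write(
            pd.DataFrame(km_rows, columns=["group", "time", "survival", "n_at_risk"]),
            out / "km_curves.tsv",
        )
        paths["logrank_tests"] = _write(
            pd.DataFrame(logrank_rows, columns=["comparison", "statistic", "p"]),
            out / "logrank_tests.tsv",
        )
        paths["cox_table"] = _write(
            pd.DataFrame(
                cox_rows,
                columns=["model", "variable", "n", "hazard_ratio", "ci_low",
                         "ci_high", "p"],
            ),
            out / "cox_table.tsv",
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- clinicopathological table (per focus gene) ----------------------
    stage = "clinicopath"
    try:
        rows = []
        if clinical:
            continuous = ["age_years", "icg_r15_percent", "afp_ng_ml",
                          "pivka2_mau_ml", "tumor_size_mm"]
            log_scaled = {"afp_ng_ml", "pivka2_mau_ml"}
            binary = ["macrovascular_invasion", "microvascular_invasion", "cirrhosis"]
            for gene in config.focus_genes:
                labels = {
                    r.sample_id: classification.label(r.sample_id, gene)
                    for r in clinical
                }
                classes = ("wild_type", "single", "multiple")
                for var in continuous:
                    groups = [
                        [
                            float(r.covariates[var])
                            for r in clinical
                            if labels[r.sample_id] == cls and var in r.covariates
                        ]
                        for cls in classes
                    ]
                    groups = [g for g in groups if len(g) >= 2]
                    if len(groups) < 2:
                        continue
                    if var in log_scaled:
                        from .clinical_stats import log10_transform

                        groups = [list(log10_transform(g)) for g in groups]
                    cmp = group_compare(groups, test="anova")
                    rows.append(
                        {"gene": gene, "variable": var, "test": "anova",
                         "statistic": cmp.statistic, "p_raw": cmp.p_raw,
                         "p_adjusted": cmp.p_adjusted}
                    )
                for var in binary:
                    table = []
                    for cls in classes:
                        members = [
                            r for r in clinical
                            if labels[r.sample_id] == cls and var in r.covariates
                        ]
                        if len(members) >= 2:
                            pos = sum(float(r.covariates[var]) > 0 for r in members)
                            table.append([pos, len(members) - pos])
                    if len(table) < 2 or any(
                        sum(col) == 0 for col in zip(*table)
                    ):
                        continue
                    cmp = group_compare(table, test="chi_square")
                    rows.append(
                        {"gene": gene, "variable": var, "test": "chi_square",
                         "statistic": cmp.statistic, "p_raw": cmp.p_raw,
                         "p_adjusted": cmp.p_adjusted}
                    )
        paths["clinicopath_table"] = _write(
            pd.DataFrame(
                rows,
                columns=["gene", "variable", "test", "statistic", "p_raw",
                         "p_adjusted"],
            ),
            out / "clinicopath_table.tsv",
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- expression ------------------------------------------------------
    stage = "expression"
    try:
        rows = []
        if expression is not None:
            for gene in config.focus_genes:
                col = f"fold_change_{gene}"
                if col not in expression.columns:
                    continue
                fold_changes = dict(
                    zip(expression["sample_id"].astype(str), expression[col])
                )
                results = expression_by_mm(fold_changes, classification, gene)
                for (a, b), cmp in sorted(results.items()):
                    rows.append(
                        {"gene": gene, "comparison": f"{a}_vs_{b}", "test": cmp.test,
                         "statistic": cmp.statistic, "p_raw": cmp.p_raw,
                         "p_adjusted": cmp.p_adjusted, "note": cmp.note}
                    )
        paths["expression_tests"] = _write(
            pd.DataFrame(
                rows,
                columns=["gene", "comparison", "test", "statistic", "p_raw",
                         "p_adjusted", "note"],
            ),
            out / "expression_tests.tsv",
        )
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- manifest --------------------------------------------------------
    stage = "manifest"
    try:
        manifest = {
            "package_version": __version__,
            "python": platform.python_version(),
            "library_versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "seed": config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
            },
            "n_input_calls": len(calls),
            "n_kept_calls": len(kept),
            "n_samples": len(all_samples),
            "tmb_cutoff_used": cutoff_used,
            "outputs": {k: str(v) for k, v in paths.items()},
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        paths["manifest"] = manifest_path
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    logger.info("pipeline complete: %d report files in %s", len(paths), out)
    return paths


def tcga_frequencies(maf: str | Path, gene: str) -> tuple[float, float]:
    """Fractions of MAF samples with exactly one / two-or-more calls in a
    gene, over all distinct samples in the MAF.

    Duplicate calls at the same site are collapsed first, matching the
    MM counting rule. Returns ``(fraction_single, fraction_multiple)``;
    a gene absent from the MAF yields (0, 0) with a warning.
    """
    calls = read_maf(maf, dialect="tcga")
    if not calls:
        raise ValueError(f"{maf}: empty MAF")
    counts = count_per_gene(calls)
    samples = {c.sample_id for c in calls}
    gene_counts = [n for (s, g), n in counts.items() if g == gene]
    if not gene_counts:
        logger.warning("gene %r not present in %s", gene, maf)
        return 0.0, 0.0
    n_single = sum(n == 1 for n in gene_counts)
    n_multiple = sum(n >= 2 for n in gene_counts)
    return n_single / len(samples), n_multiple / len(samples)
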