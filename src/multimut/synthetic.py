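"""Synthetic somatic-mutation cohorts with full ground-truth bookkeeping.

The generator emulates the statistical structure the analysis assumes,
so every pipeline stage can be verified end to end without access to a
controlled patient cohort:

* heavy-tailed per-sample mutation totals (log-normal), sized so the
  cohort's 95th-percentile TMB lands near the hypermutation regime of a
  45 Mb exome;
* a small panel of named genes with elevated mutation rates, hotspot
  concentration and per-gene MM enrichment (the probability of a second
  mutation given a first is multiplied by the enrichment factor), on top
  of a large pool of background genes whose chance co-occurrences set the
  cohort MM prevalence (~80% at the defaults, by a birthday-collision
  argument over ~3200 genes at a median of 100 mutations);
* allele assignment of within-gene mutation pairs (cis with a configured
  probability, default 0.83) and fragment-level read evidence over both
  sites with configurable depth, co-coverage and per-base error;
* relapse-free survival coupled to MM status through a proportional
  hazard (default hazard ratio 1.72) alongside clinical covariates with
  their own effects, and independent censoring;
* tumour/normal expression fold changes with an additive log2 shift for
  MM carriers of selected genes.

Every gene occupies its own synthetic contig (named after the gene); the
genome is drawn first and substitution types are then sampled at each
site in proportion to a fixed signature mixture evaluated at the site's
trinucleotide context, keeping genome and mutation catalog consistent.
All randomness derives from one integer seed through named child
streams, so re-running any part reproduces identical bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mm_core import GeneCatalog
from .mutational_context import CONTEXTS_96, synthetic_signature_matrix
from .phasing import ReadEvidence, write_evidence_tsv
from .variant_io import VariantCall

__all__ = [
    "SyntheticGene",
    "SyntheticCohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_reads",
]

_BASES = "ACGT"
# base codes 0..3 = A,C,G,T; complement is 3 - code
_CLASSIFICATIONS = (
    ("Missense_Mutation", 0.62),
    ("Silent", 0.15),
    ("Nonsense_Mutation", 0.06),
    ("Splice_Site", 0.05),
    ("3'UTR", 0.07),
    ("5'UTR", 0.05),
)

# named RNG streams (spawn keys off the single cohort seed)
_STREAMS = {
    "genome": 0,
    "counts": 1,
    "positions": 2,
    "alts": 3,
    "consequence": 4,
    "phase": 5,
    "reads": 6,
    "covariates": 7,
    "survival": 8,
    "expression": 9,
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class SyntheticGene:
    """One panel gene: length in bp, allocation rate, hotspot behaviour.

    ``rate`` is the probability that any single mutation event lands in
    this gene; ``hotspot_concentration`` is the probability that a
    mutation in the gene falls inside its hotspot window (a short
    exon-3-like segment); ``mm_enrichment`` multiplies the per-event
    probability of additional mutations once the gene is hit.
    """

    name: str
    length: int
    rate: float
    hotspot_concentration: float = 0.2
    mm_enrichment: float = 1.0
    role: str = "unclassified"

    def __post_init__(self) -> None:
        if self.length < 200:
            raise ValueError(f"{self.name}: gene length too short")
        if not 0 < self.rate < 1:
            raise ValueError(f"{self.name}: rate must be in (0, 1)")
        if not 0 <= self.hotspot_concentration <= 1:
            raise ValueError(f"{self.name}: hotspot_concentration in [0, 1]")
        if self.mm_enrichment < 1:
            raise ValueError(f"{self.name}: mm_enrichment must be >= 1")


def _default_panel() -> tuple[SyntheticGene, ...]:
    # a beta-catenin-like short gene with a strong hotspot and a mucin-like
    # very long gene with dispersed mutations, plus 18 generic panel genes
    panel = [
        SyntheticGene("CTNNB1L", length=2400, rate=0.0043,
                      hotspot_concentration=0.8, mm_enrichment=1.2,
                      role="oncogene"),
        SyntheticGene("MUC16L", length=43000, rate=0.0023,
                      hotspot_concentration=0.15, mm_enrichment=1.2,
                      role="oncogene"),
    ]
    lengths = (1500, 2100, 3000, 4500, 2700, 3600)
    rates = (0.0020, 0.0015, 0.0012, 0.0010, 0.0008, 0.0006)
    for i in range(18):
        role = "tsg" if i < 6 else "oncogene" if i < 12 else "unclassified"
        panel.append(
            SyntheticGene(
                f"SYN{i + 1:02d}",
                length=lengths[i % len(lengths)],
                rate=rates[i % len(rates)],
                hotspot_concentration=0.2,
                mm_enrichment=1.0,
                role=role,
            )
        )
    return tuple(panel)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort-level generator settings; defaults are the study conditions."""

    n_samples: int = 223
    genes: tuple[SyntheticGene, ...] = field(default_factory=_default_panel)
    n_background_genes: int = 3200
    background_gene_length: int = 600
    tmb_log_mean: float = math.log(100.0)   # median ~100 exonic mutations
    tmb_log_sigma: float = 0.65             # 95th pct ~6.5 mutations/Mb at 45 Mb
    target_size_mb: float = 45.0
    cis_probability: float = 0.83
    mm_hazard_ratio: float = 1.72
    baseline_hazard: float = 0.02           # relapses per month, non-MM
    covariate_log_hr: Mapping[str, float] = field(
        default_factory=lambda: {"microvascular_invasion": math.log(1.96)}
    )
    censoring_rate: float = 0.008           # per month, independent
    followup_cap_months: float = 120.0
    expression_genes: tuple[str, ...] = ("CTNNB1L", "MUC16L")
    expression_shift: float = 1.0           # log2 shift for MM carriers
    expression_sigma: float = 0.5
    signature_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "Signature.16": 0.5, "Signature.1": 0.3, "Signature.5": 0.2
        }
    )
    read_depth: int = 40
    read_error_rate: float = 0.0
    co_cover_fraction: float = 0.9
    emit_reads: bool = True
    emit_expression: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.cis_probability <= 1:
            raise ValueError("cis_probability must be in [0, 1]")
        if not 0 <= self.co_cover_fraction <= 1:
            raise ValueError("co_cover_fraction must be in [0, 1]")
        if not 0 <= self.read_error_rate < 0.5:
            raise ValueError("read_error_rate must be in [0, 0.5)")
        if min(self.mm_hazard_ratio, self.baseline_hazard,
               self.censoring_rate, self.target_size_mb) <= 0:
            raise ValueError("rates and ratios must be > 0")
        total_panel_rate = sum(g.rate for g in self.genes)
        if total_panel_rate >= 1:
            raise ValueError("panel gene rates must sum to < 1")
        weights = sum(self.signature_mixture.values())
        if abs(weights - 1.0) > 1e-9:
            raise ValueError("signature_mixture weights must sum to 1")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate panel gene names")


@dataclass
class GroundTruth:
    """Generator bookkeeping: the values the pipeline should recover."""

    mm_status: dict[str, str]                       # sample -> MM_tumor/SM_tumor/no_mutation
    per_gene_counts: dict[str, dict[str, int]]      # sample -> {gene: count}
    phase_assignments: dict[str, list[dict]]        # "sample|gene" -> pair records
    contexts: dict[str, list[str]]                  # sample -> context labels
    true_log_hazard: dict[str, float]
    mm_prevalence: float
    cis_pair_fraction: Optional[float]              # among panel-gene pairs
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    """In-memory cohort plus writers for the on-disk exchange formats."""

    config: SyntheticCohortConfig
    maf: pd.DataFrame
    clinical: pd.DataFrame
    expression: pd.DataFrame
    read_evidence: list[ReadEvidence]
    genome: dict[str, str]
    gene_catalog: GeneCatalog
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit cohort.maf, clinical.tsv, expression.tsv, read_evidence.tsv,
        gene_catalog.tsv, genome.fa and ground_truth.json into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": outdir / "cohort.maf",
            "clinical": outdir / "clinical.tsv",
            "expression": outdir / "expression.tsv",
            "read_evidence": outdir / "read_evidence.tsv",
            "gene_catalog": outdir / "gene_catalog.tsv",
            "genome": outdir / "genome.fa",
            "ground_truth": outdir / "ground_truth.json",
        }
        self.maf.to_csv(paths["maf"], sep="\t", index=False)
        self.clinical.to_csv(paths["clinical"], sep="\t", index=False)
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        write_evidence_tsv(self.read_evidence, paths["read_evidence"])
        pd.DataFrame(
            sorted(self.gene_catalog.entries.items()), columns=["gene", "role"]
        ).to_csv(paths["gene_catalog"], sep="\t", index=False)
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        self.ground_truth.to_json(paths["ground_truth"])
        return paths


# ---------------------------------------------------------------------------


def simulate_reads(
    pair: tuple[VariantCall, VariantCall],
    phase: str,
    depth: int,
    error_rate: float = 0.0,
    co_cover_fraction: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    id_prefix: str = "frag",
) -> list[ReadEvidence]:
    """Fragment evidence for one mutation pair with known configuration.

    Each of ``depth`` fragments is drawn from one of the two allele copies
    (variant allele fraction 0.5), covers both sites with probability
    ``co_cover_fraction`` (otherwise one site, chosen uniformly), and
    reports each covered allele flipped ref<->alt with ``error_rate``.
    """
    if phase not in ("cis", "trans"):
        raise ValueError("phase must be 'cis' or 'trans'")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    a, b = pair
    site_a, site_b = (a.chrom, a.pos), (b.chrom, b.pos)
    # truth per allele copy: haplotype 0 / haplotype 1
    if phase == "cis":
        hap_alleles = [{site_a: a.alt, site_b: b.alt}, {site_a: a.ref, site_b: b.ref}]
    else:
        hap_alleles = [{site_a: a.alt, site_b: b.ref}, {site_a: a.ref, site_b: b.alt}]
    ref_at = {site_a: a.ref, site_b: b.ref}
    alt_at = {site_a: a.alt, site_b: b.alt}

    reads: list[ReadEvidence] = []
    for k in range(depth):
        hap = hap_alleles[int(rng.integers(2))]
        if rng.random() < co_cover_fraction:
            sites = [site_a, site_b]
        else:
            sites = [site_a if rng.random() < 0.5 else site_b]
        observed: dict[tuple[str, int], str] = {}
        for site in sites:
            allele = hap[site]
            if error_rate > 0 and rng.random() < error_rate:
                allele = alt_at[site] if allele == ref_at[site] else ref_at[site]
            observed[site] = allele
        reads.append(
            ReadEvidence(
                read_id=f"{id_prefix}:{k}", sample_id=a.sample_id, alleles=observed
            )
        )
    return reads


def _draw_positions(
    rng: np.random.Generator, gene: SyntheticGene, count: int
) -> np.ndarray:
    """``count`` distinct 1-based positions, pairwise >= 3 bp apart."""
    lo, hi = 2, gene.length - 1
    hs_len = max(30, gene.length // 20)
    hs_lo = gene.length // 4
    for _ in range(200):
        in_hotspot = rng.random(count) < gene.hotspot_concentration
        pos = np.where(
            in_hotspot,
            hs_lo + rng.integers(0, hs_len, size=count),
            rng.integers(lo, hi + 1, size=count),
        )
        pos = np.clip(pos, lo, hi)
        if count == 1 or np.diff(np.sort(pos)).min() >= 3:
            return pos
    raise RuntimeError(f"could not place {count} spaced mutations in {gene.name}")


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    See the module docstring for the generative model. Returns the cohort
    in memory; use :meth:`SyntheticCohort.write` for the file formats the
    readers consume.
    """
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    panel = config.genes
    n_panel = len(panel)
    background_names = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]
    gene_names = [g.name for g in panel] + background_names
    gene_lengths = np.array(
        [g.length for g in panel]
        + [config.background_gene_length] * config.n_background_genes
    )

    # --- genome: one contig per gene, drawn before any mutation ------------
    rng_genome = _stream(config.seed, "genome")
    total_len = int(gene_lengths.sum())
    buffer = rng_genome.integers(0, 4, size=total_len, dtype=np.int8)
    offsets = np.concatenate([[0], np.cumsum(gene_lengths)[:-1]])

    # --- per-sample totals and per-gene allocation -------------------------
    rng_counts = _stream(config.seed, "counts")
    totals = np.maximum(
        1,
        np.rint(
            rng_counts.lognormal(
                config.tmb_log_mean, config.tmb_log_sigma, size=config.n_samples
            )
        ).astype(int),
    )
    panel_rates = np.array([g.rate for g in panel])
    bg_rate = (1.0 - panel_rates.sum()) / config.n_background_genes
    probs = np.concatenate([panel_rates, np.full(config.n_background_genes, bg_rate)])
    counts = rng_counts.multinomial(totals, probs)  # (n_samples, n_genes)

    # MM enrichment: once a panel gene is hit, further hits arrive with the
    # enriched per-event probability over the remaining draws
    enrich = np.array([g.mm_enrichment for g in panel])
    extra_p = np.clip((enrich - 1.0) * panel_rates, 0.0, 1.0)
    if (extra_p > 0).any():
        extra = rng_counts.binomial((totals - 1)[:, None], extra_p[None, :])
        counts[:, :n_panel] += extra * (counts[:, :n_panel] >= 1)

    # --- expand to one row per mutation ------------------------------------
    sample_idx_flat, gene_idx_flat = np.nonzero(counts)
    cell_counts = counts[sample_idx_flat, gene_idx_flat]
    sample_idx = np.repeat(sample_idx_flat, cell_counts)
    gene_idx = np.repeat(gene_idx_flat, cell_counts)
    n_mut = sample_idx.size

    rng_pos = _stream(config.seed, "positions")
    positions = np.empty(n_mut, dtype=int)
    cursor = 0
    panel_by_idx = list(panel) + [
        SyntheticGene(name, config.background_gene_length, bg_rate or 1e-9)
        for name in background_names
    ]
    for cell, (gi, c) in enumerate(zip(gene_idx_flat, cell_counts)):
        gene = panel_by_idx[gi]
        if c == 1:
            lo, hi = 2, gene.length - 1
            if rng_pos.random() < gene.hotspot_concentration:
                hs_len = max(30, gene.length // 20)
                positions[cursor] = min(hi, gene.length // 4 + int(rng_pos.integers(0, hs_len)))
            else:
                positions[cursor] = int(rng_pos.integers(lo, hi + 1))
        else:
            positions[cursor : cursor + c] = _draw_positions(rng_pos, gene, int(c))
        cursor += c

    # --- substitution types from the signature mixture at each site --------
    signatures = synthetic_signature_matrix()
    mix = np.zeros(96)
    for sig, w in config.signature_mixture.items():
        mix += w * signatures[sig].to_numpy()

    flat_pos = offsets[gene_idx] + positions - 1  # 0-based index into buffer
    ref_code = buffer[flat_pos].astype(int)
    five_code = buffer[flat_pos - 1].astype(int)
    three_code = buffer[flat_pos + 1].astype(int)
    is_purine = (ref_code == 0) | (ref_code == 2)  # A or G
    p_ref = np.where(is_purine, 3 - ref_code, ref_code)
    p_five = np.where(is_purine, 3 - three_code, five_code)
    p_three = np.where(is_purine, 3 - five_code, three_code)

    # candidate pyrimidine alt codes and their context indices
    alt_options = np.where(
        (p_ref == 1)[:, None],
        np.array([0, 2, 3])[None, :],  # C>A, C>G, C>T
        np.array([0, 1, 2])[None, :],  # T>A, T>C, T>G
    )
    class_base = np.where(p_ref == 1, 0, 3)
    ctx_candidates = (
        (class_base[:, None] + np.arange(3)[None, :]) * 16
        + p_five[:, None] * 4
        + p_three[:, None]
    )
    rng_alts = _stream(config.seed, "alts")
    probs3 = mix[ctx_candidates]
    probs3 = probs3 / probs3.sum(axis=1, keepdims=True)
    u = rng_alts.random(n_mut)
    choice = np.minimum((u[:, None] > np.cumsum(probs3, axis=1)).sum(axis=1), 2)
    alt_pyr = alt_options[np.arange(n_mut), choice]
    ctx_idx = ctx_candidates[np.arange(n_mut), choice]
    alt_code = np.where(is_purine, 3 - alt_pyr, alt_pyr)

    rng_cons = _stream(config.seed, "consequence")
    class_names = [c for c, _ in _CLASSIFICATIONS]
    class_probs = np.array([p for _, p in _CLASSIFICATIONS])
    cons_idx = rng_cons.choice(len(class_names), size=n_mut, p=class_probs)

    base_arr = np.array(list(_BASES))
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": [gene_names[g] for g in gene_idx],
            "Chromosome": [gene_names[g] for g in gene_idx],
            "Start_Position": positions,
            "Reference_Allele": base_arr[ref_code],
            "Tumor_Seq_Allele2": base_arr[alt_code],
            "Variant_Classification": [class_names[i] for i in cons_idx],
            "Tumor_Sample_Barcode": [samples[s] for s in sample_idx],
            "quality": 99.0,
            "depth": 100,
            "alt_fwd": 25,
            "alt_rev": 25,
            "avg_clipped_length": 140.0,
            "avg_pos_as_fraction": 0.45,
        }
    )

    # --- ground-truth counts, MM status, contexts --------------------------
    per_gene_counts: dict[str, dict[str, int]] = {s: {} for s in samples}
    for s_i, g_i, c in zip(sample_idx_flat, gene_idx_flat, cell_counts):
        per_gene_counts[samples[s_i]][gene_names[g_i]] = int(c)
    mm_status = {}
    for s in samples:
        gene_counts = per_gene_counts[s]
        if not gene_counts:
            mm_status[s] = "no_mutation"
        elif max(gene_counts.values()) >= 2:
            mm_status[s] = "MM_tumor"
        else:
            mm_status[s] = "SM_tumor"
    mm_prevalence = sum(v == "MM_tumor" for v in mm_status.values()) / len(samples)

    contexts: dict[str, list[str]] = {s: [] for s in samples}
    for s_i, c_i in zip(sample_idx, ctx_idx):
        contexts[samples[s_i]].append(CONTEXTS_96[c_i])

    # --- phase assignment and read evidence for panel-gene MM pairs --------
    rng_phase = _stream(config.seed, "phase")
    rng_reads = _stream(config.seed, "reads")
    phase_assignments: dict[str, list[dict]] = {}
    read_evidence: list[ReadEvidence] = []
    n_cis_pairs = n_pairs = 0

    panel_cells = [
        (int(s), int(g), int(c))
        for s, g, c in zip(sample_idx_flat, gene_idx_flat, cell_counts)
        if g < n_panel and c >= 2
    ]
    mut_order = np.lexsort((positions, gene_idx, sample_idx))
    pos_by_cell: dict[tuple[int, int], list[int]] = {}
    for idx in mut_order:
        pos_by_cell.setdefault((int(sample_idx[idx]), int(gene_idx[idx])), []).append(
            int(positions[idx])
        )
    mut_by_site = {
        (int(sample_idx[i]), int(gene_idx[i]), int(positions[i])): i
        for i in range(n_mut)
    }

    for s_i, g_i, c in panel_cells:
        sample, gene = samples[s_i], gene_names[g_i]
        site_positions = pos_by_cell[(s_i, g_i)]
        alleles = [0]
        for _ in range(c - 1):
            alleles.append(0 if rng_phase.random() < config.cis_probability else 1)
        records = []
        for i in range(c):
            for j in range(i + 1, c):
                phase = "cis" if alleles[i] == alleles[j] else "trans"
                records.append(
                    {"pos_a": site_positions[i], "pos_b": site_positions[j],
                     "phase": phase}
                )
                n_pairs += 1
                n_cis_pairs += phase == "cis"
                if config.emit_reads:
                    mi = mut_by_site[(s_i, g_i, site_positions[i])]
                    mj = mut_by_site[(s_i, g_i, site_positions[j])]
                    pair = (
                        _call_from_row(maf, mi),
                        _call_from_row(maf, mj),
                    )
                    read_evidence.extend(
                        simulate_reads(
                            pair,
                            phase,
                            depth=config.read_depth,
                            error_rate=config.read_error_rate,
                            co_cover_fraction=config.co_cover_fraction,
                            rng=rng_reads,
                            id_prefix=f"{sample}:{gene}:{site_positions[i]}-{site_positions[j]}",
                        )
                    )
        phase_assignments[f"{sample}|{gene}"] = records

    cis_fraction = n_cis_pairs / n_pairs if n_pairs else None

    # --- clinical covariates and survival ----------------------------------
    rng_cov = _stream(config.seed, "covariates")
    n = config.n_samples
    covariates = pd.DataFrame(
        {
            "sample_id": samples,
            "sex": np.where(rng_cov.random(n) < 0.82, "M", "F"),
            "age_years": np.clip(
                np.rint(rng_cov.normal(70, 8, size=n)), 30, 95
            ).astype(int),
            "viral": rng_cov.choice(
                ["HCV", "HBV", "NBNC"], size=n, p=[0.31, 0.19, 0.50]
            ),
            "icg_r15_percent": np.round(
                rng_cov.lognormal(math.log(10), 0.5, size=n), 1
            ),
            "afp_ng_ml": np.round(rng_cov.lognormal(math.log(10), 2.0, size=n), 1),
            "pivka2_mau_ml": np.round(
                rng_cov.lognormal(math.log(150), 1.8, size=n), 1
            ),
            "tumor_size_mm": np.round(
                rng_cov.lognormal(math.log(35), 0.6, size=n), 0
            ).astype(int),
            "macrovascular_invasion": (rng_cov.random(n) < 0.07).astype(int),
            "microvascular_invasion": (rng_cov.random(n) < 0.33).astype(int),
            "cirrhosis": (rng_cov.random(n) < 0.39).astype(int),
        }
    )

    rng_surv = _stream(config.seed, "survival")
    mm_flag = np.array([mm_status[s] == "MM_tumor" for s in samples], dtype=float)
    log_hazard = (
        math.log(config.baseline_hazard)
        + math.log(config.mm_hazard_ratio) * mm_flag
    )
    for cov, beta in config.covariate_log_hr.items():
        log_hazard = log_hazard + beta * covariates[cov].to_numpy(dtype=float)
    event_time = rng_surv.exponential(1.0 / np.exp(log_hazard))
    censor_time = np.minimum(
        rng_surv.exponential(1.0 / config.censoring_rate, size=n),
        config.followup_cap_months,
    )
    rfs = np.minimum(event_time, censor_time)
    rfs_event = (event_time <= censor_time).astype(int)
    # overall survival: later, flatter endpoint with the same MM coupling
    os_time = rng_surv.exponential(1.0 / (0.5 * np.exp(log_hazard)))
    os_cap = np.minimum(
        rng_surv.exponential(1.0 / config.censoring_rate, size=n),
        config.followup_cap_months,
    )
    clinical = covariates.copy()
    clinical.insert(1, "rfs_months", np.round(rfs, 2))
    clinical.insert(2, "rfs_event", rfs_event)
    clinical.insert(3, "os_months", np.round(np.minimum(os_time, os_cap), 2))
    clinical.insert(4, "os_event", (os_time <= os_cap).astype(int))

    # --- expression fold changes -------------------------------------------
    rng_expr = _stream(config.seed, "expression")
    expr_cols: dict[str, object] = {"sample_id": samples}
    if config.emit_expression:
        for gene in config.expression_genes:
            log2fc = rng_expr.normal(0.0, config.expression_sigma, size=n)
            is_mm = np.array(
                [per_gene_counts[s].get(gene, 0) >= 2 for s in samples], dtype=float
            )
            log2fc = log2fc + config.expression_shift * is_mm
            expr_cols[f"fold_change_{gene}"] = np.round(2.0**log2fc, 4)
    expression = pd.DataFrame(expr_cols)

    # --- assemble ----------------------------------------------------------
    genome = {}
    for gi, name in enumerate(gene_names):
        start, length = offsets[gi], gene_lengths[gi]
        genome[name] = "".join(base_arr[buffer[start : start + length]])

    catalog = GeneCatalog(entries={g.name: g.role for g in panel})
    ground_truth = GroundTruth(
        mm_status=mm_status,
        per_gene_counts=per_gene_counts,
        phase_assignments=phase_assignments,
        contexts=contexts,
        true_log_hazard={s: float(h) for s, h in zip(samples, log_hazard)},
        mm_prevalence=mm_prevalence,
        cis_pair_fraction=cis_fraction,
        seed=config.seed,
    )
    # deterministic row order: sample, then contig, then position
    maf = maf.sort_values(
        ["Tumor_Sample_Barcode", "Chromosome", "Start_Position"], kind="mergesort"
    ).reset_index(drop=True)
    return SyntheticCohort(
        config=config,
        maf=maf,
        clinical=clinical,
        expression=expression,
        read_evidence=read_evidence,
        genome=genome,
        gene_catalog=catalog,
        ground_truth=ground_truth,
    )


def _call_from_row(maf: pd.DataFrame, row_idx: int) -> VariantCall:
    row = maf.iloc[row_idx]
    return VariantCall(
        sample_id=str(row["Tumor_Sample_Barcode"]),
        gene=str(row["Hugo_Symbol"]),
        chrom=str(row["Chromosome"]),
        pos=int(row["Start_Position"]),
        ref=str(row["Reference_Allele"]),
        alt=str(row["Tumor_Seq_Allele2"]),
    )
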