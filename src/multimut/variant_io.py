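"""Readers for somatic mutation calls and clinical tables, plus the
six-criterion false-positive filter.

Somatic calls arrive either as a cohort MAF (TCGA column dialect or a
minimal internal dialect) or as single-sample VCF 4.x files, and are
normalised to :class:`VariantCall`. The filter discards a call when it
fails at least one of six quality criteria (quality score, depth, strand
support, clipped read length, in-read position, blacklist) and logs every
failed criterion per discarded call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "FilterCriteria",
    "ClinicalRecord",
    "SchemaError",
    "read_maf",
    "read_vcf",
    "apply_filters",
    "read_clinical",
    "read_blacklist",
    "CONSEQUENCE_VOCABULARY",
    "TCGA_CLASSIFICATION_MAP",
]


class SchemaError(ValueError):
    """An input table does not match its declared schema."""


#: Controlled consequence vocabulary. ``other`` collects annotations with no
#: protein-level interpretation (flanks, introns, RNA genes, ...).
CONSEQUENCE_VOCABULARY = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice_site",
        "inframe_indel",
        "synonymous",
        "utr",
        "start_lost",
        "stop_lost",
        "other",
    }
)

#: TCGA Variant_Classification -> internal consequence term.
TCGA_CLASSIFICATION_MAP: Mapping[str, str] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "stop_lost",
    "Translation_Start_Site": "start_lost",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice_site",
    "Silent": "synonymous",
    "3'UTR": "utr",
    "5'UTR": "utr",
    "3'Flank": "other",
    "5'Flank": "other",
    "Intron": "other",
    "IGR": "other",
    "RNA": "other",
    "Targeted_Region": "other",
    "Splice_Region": "other",
    "De_novo_Start_InFrame": "other",
    "De_novo_Start_OutOfFrame": "other",
}


@dataclass(frozen=True, slots=True)
class VariantCall:
    """One somatic mutation call.

    QC fields (``quality``, ``depth``, strand counts, ``avg_clipped_length``,
    ``avg_pos_as_fraction``) may be ``None`` when the source format does not
    carry them; unknown values pass the corresponding filter criterion.
    Coordinates are 1-based, fully closed (VCF/MAF convention).
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str = "other"
    quality: Optional[float] = None
    depth: Optional[int] = None
    alt_fwd: Optional[int] = None
    alt_rev: Optional[int] = None
    avg_clipped_length: Optional[float] = None
    avg_pos_as_fraction: Optional[float] = None
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref!r}")
        if self.alt_fwd is not None and self.alt_fwd < 0:
            raise ValueError("alt_fwd must be >= 0")
        if self.alt_rev is not None and self.alt_rev < 0:
            raise ValueError("alt_rev must be >= 0")
        if (
            self.depth is not None
            and self.alt_fwd is not None
            and self.alt_rev is not None
            and self.depth < self.alt_fwd + self.alt_rev
        ):
            raise ValueError("depth must cover alt_fwd + alt_rev")
        if self.avg_pos_as_fraction is not None and not (
            0.0 <= self.avg_pos_as_fraction <= 1.0
        ):
            raise ValueError("avg_pos_as_fraction must lie in [0, 1]")

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True, slots=True)
class FilterCriteria:
    """Thresholds of the six-criterion false-positive filter.

    Defaults follow the screening used for amplicon-based tumour-normal
    exomes: quality score >= 60, depth >= 20, variant reads on both strands,
    mean clipped read length >= 100 bases, mean in-read variant position
    fraction >= 0.05, plus an optional site blacklist.
    """

    min_quality: float = 60.0
    min_depth: int = 20
    require_both_strands: bool = True
    min_avg_clipped_length: float = 100.0
    min_avg_pos_as_fraction: float = 0.05
    blacklist: frozenset[tuple[str, int, str, str]] = frozenset()

    def __post_init__(self) -> None:
        if min(self.min_quality, self.min_depth, self.min_avg_clipped_length,
               self.min_avg_pos_as_fraction) < 0:
            raise ValueError("filter thresholds must be >= 0")

    def failed_criteria(self, call: VariantCall) -> list[str]:
        """Names of every criterion the call fails (empty list = keep).

        A ``None`` QC value passes its criterion: public MAFs typically lack
        these columns and are assumed pre-filtered upstream.
        """
        failed: list[str] = []
        if call.quality is not None and call.quality < self.min_quality:
            failed.append("quality")
        if call.depth is not None and call.depth < self.min_depth:
            failed.append("depth")
        if (
            self.require_both_strands
            and call.alt_fwd is not None
            and call.alt_rev is not None
            and (call.alt_fwd == 0 or call.alt_rev == 0)
        ):
            failed.append("strand")
        if (
            call.avg_clipped_length is not None
            and call.avg_clipped_length < self.min_avg_clipped_length
        ):
            failed.append("clipped_length")
        if (
            call.avg_pos_as_fraction is not None
            and call.avg_pos_as_fraction < self.min_avg_pos_as_fraction
        ):
            failed.append("read_position")
        if call.site_key in self.blacklist:
            failed.append("blacklist")
        return failed


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical annotation: survival endpoints plus covariates.

    AFP and PIVKA-II are stored on their natural scale (ng/mL, mAU/mL);
    log10 is applied only at comparison time.
    """

    sample_id: str
    rfs_months: float
    rfs_event: int
    os_months: Optional[float] = None
    os_event: Optional[int] = None
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rfs_months < 0:
            raise ValueError(f"{self.sample_id}: negative rfs_months")
        if self.rfs_event not in (0, 1):
            raise ValueError(f"{self.sample_id}: rfs_event must be 0/1")
        if self.os_months is not None and self.os_months < 0:
            raise ValueError(f"{self.sample_id}: negative os_months")
        if self.os_event is not None and self.os_event not in (0, 1):
            raise ValueError(f"{self.sample_id}: os_event must be 0/1")


# ---------------------------------------------------------------------------
# MAF reading

_TCGA_REQUIRED = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
]
_MINIMAL_REQUIRED = ["sample_id", "gene", "chrom", "pos", "ref", "alt"]

#: optional QC columns shared by both dialects (bam-readcount style names)
_QC_COLUMNS = {
    "quality": float,
    "depth": int,
    "alt_fwd": int,
    "alt_rev": int,
    "avg_clipped_length": float,
    "avg_pos_as_fraction": float,
}


def _qc_value(row: Mapping[str, object], col: str, cast) -> Optional[object]:
    if col not in row:
        return None
    value = row[col]
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "unknown":
        return None
    return cast(value)


def read_maf(path: str | Path, dialect: str = "tcga") -> list[VariantCall]:
    """Read a cohort MAF into :class:`VariantCall` records.

    ``dialect='tcga'`` expects the standard TCGA column names;
    ``dialect='minimal'`` expects ``sample_id, gene, chrom, pos, ref, alt``
    with optional ``consequence`` and QC columns. Multi-allelic rows
    (comma-separated ALT) are rejected. QC columns absent from the dialect
    are left unknown and treated as passing by the filter (a warning is
    logged once per file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"{path}: empty MAF, returning no calls")
        return []

    if dialect == "tcga":
        required = _TCGA_REQUIRED
    elif dialect == "minimal":
        required = _MINIMAL_REQUIRED
    else:
        raise ValueError(f"unknown MAF dialect {dialect!r}")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required MAF column {col!r}")

    missing_qc = sorted(set(_QC_COLUMNS) - set(df.columns))
    if missing_qc:
        logger.warning(
            "%s: QC columns %s absent; values treated as unknown/passing",
            path, ", ".join(missing_qc),
        )

    calls: list[VariantCall] = []
    for row in df.to_dict("records"):
        if dialect == "tcga":
            alt = str(row["Tumor_Seq_Allele2"])
            if "," in alt:
                raise SchemaError(f"{path}: multi-allelic MAF row (alt={alt!r})")
            classification = str(row["Variant_Classification"])
            consequence = TCGA_CLASSIFICATION_MAP.get(classification)
            if consequence is None:
                logger.warning(
                    "unrecognised Variant_Classification %r mapped to 'other'",
                    classification,
                )
                consequence = "other"
            base = dict(
                sample_id=str(row["Tumor_Sample_Barcode"]),
                gene=str(row["Hugo_Symbol"]),
                chrom=str(row["Chromosome"]),
                pos=int(row["Start_Position"]),
                ref=str(row["Reference_Allele"]),
                alt=alt,
                consequence=consequence,
                protein_change=str(row["HGVSp_Short"]) or None
                if "HGVSp_Short" in row else None,
            )
        else:
            alt = str(row["alt"])
            if "," in alt:
                raise SchemaError(f"{path}: multi-allelic MAF row (alt={alt!r})")
            consequence = str(row.get("consequence") or "other")
            if consequence not in CONSEQUENCE_VOCABULARY:
                raise SchemaError(
                    f"{path}: consequence {consequence!r} not in vocabulary"
                )
            base = dict(
                sample_id=str(row["sample_id"]),
                gene=str(row["gene"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=alt,
                consequence=consequence,
                protein_change=str(row["protein_change"]) or None
                if "protein_change" in row else None,
            )
        for col, cast in _QC_COLUMNS.items():
            base[col] = _qc_value(row, col, cast)
        calls.append(VariantCall(**base))

    logger.info("read %d calls from %s (%s dialect)", len(calls), path, dialect)
    if not calls:
        warnings.warn(f"{path}: MAF contains no records")
    return calls


# ---------------------------------------------------------------------------
# VCF reading


def read_vcf(path: str | Path, sample_id: Optional[str] = None) -> list[VariantCall]:
    """Read a single-sample VCF 4.x into :class:`VariantCall` records.

    Records with FILTER other than PASS/``.`` are excluded; multi-allelic
    records are split into one call per ALT allele sharing the site-level
    stats. Gene symbols are harvested from an ``INFO/GENE`` key when present.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on parse failure
        raise SchemaError(f"{path}: malformed VCF ({exc})") from exc

    if sample_id is None:
        if len(vcf.samples) != 1:
            raise SchemaError(
                f"{path}: expected exactly one sample, found {len(vcf.samples)}"
            )
        sample_id = vcf.samples[0]

    calls: list[VariantCall] = []
    for rec in vcf:
        if rec.FILTER is not None:  # None means PASS / '.'
            continue
        gene = rec.INFO.get("GENE") or rec.INFO.get("Gene") or "unknown"
        depth = rec.INFO.get("DP")
        qual = rec.QUAL
        saf, sar = rec.INFO.get("SAF"), rec.INFO.get("SAR")
        for alt in rec.ALT:
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    gene=str(gene),
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    quality=float(qual) if qual is not None else None,
                    depth=int(depth) if depth is not None else None,
                    alt_fwd=int(saf) if saf is not None else None,
                    alt_rev=int(sar) if sar is not None else None,
                )
            )
    logger.info("read %d PASS calls from %s", len(calls), path)
    return calls


# ---------------------------------------------------------------------------
# Filtering


def apply_filters(
    calls: Sequence[VariantCall], criteria: FilterCriteria | None = None
) -> tuple[list[VariantCall], list[tuple[VariantCall, list[str]]]]:
    """Partition calls into kept vs discarded under the six criteria.

    Returns ``(kept, discard_log)`` where the log holds, for each discarded
    call, the full list of criterion names it failed. A call is discarded
    iff it fails at least one criterion; input order is preserved on both
    sides, so the filter is a pure, idempotent partition.
    """
    if criteria is None:
        criteria = FilterCriteria()
    kept: list[VariantCall] = []
    discard_log: list[tuple[VariantCall, list[str]]] = []
    for call in calls:
        failed = criteria.failed_criteria(call)
        if failed:
            discard_log.append((call, failed))
        else:
            kept.append(call)
    logger.info(
        "filter kept %d / %d calls (%d discarded)",
        len(kept), len(calls), len(discard_log),
    )
    return kept, discard_log


def read_blacklist(path: str | Path) -> frozenset[tuple[str, int, str, str]]:
    """Read a site blacklist TSV with columns chrom, pos, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise SchemaError(f"{path}: blacklist missing column {col!r}")
    keys = frozenset(
        (str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"]))
        for r in df.to_dict("records")
    )
    logger.info("read %d blacklist sites from %s", len(keys), path)
    return keys


# ---------------------------------------------------------------------------
# Clinical table

_CLINICAL_REQUIRED = ["sample_id", "rfs_months", "rfs_event"]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical TSV (one row per sample).

    Required columns: sample_id, rfs_months, rfs_event; optional os_months,
    os_event. Every other column is preserved as a covariate. Numeric-looking
    covariate values are parsed to float; the rest stay strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _CLINICAL_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing clinical column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")

    known = {"sample_id", "rfs_months", "rfs_event", "os_months", "os_event"}
    records: list[ClinicalRecord] = []
    for row in df.to_dict("records"):
        covariates: dict[str, object] = {}
        for key, value in row.items():
            if key in known:
                continue
            try:
                covariates[key] = float(value)
            except (TypeError, ValueError):
                covariates[key] = value
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                rfs_months=float(row["rfs_months"]),
                rfs_event=int(row["rfs_event"]),
                os_months=float(row["os_months"]) if row.get("os_months") not in (None, "") else None,
                os_event=int(row["os_event"]) if row.get("os_event") not in (None, "") else None,
                covariates=covariates,
            )
        )
    logger.info("read %d clinical records from %s", len(records), path)
    return records
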