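"""Per-gene multiple-mutation (MM) classification.

A tumour sample is an *MM tumour* when at least one gene carries two or
more passing somatic mutations; a sample whose mutated genes each carry
exactly one mutation is an *SM tumour*. This module counts passing calls
per sample x gene, assigns the wild_type / single / multiple labels,
summarises per-gene MM fractions, stratifies MM samples by an
oncogene/TSG catalog, and maps consequence terms onto the four functional
impact levels (high / moderate / low / modifier).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .variant_io import CONSEQUENCE_VOCABULARY, SchemaError, VariantCall

__all__ = [
    "GeneCatalog",
    "MMClassification",
    "GeneMMFraction",
    "IMPACT_LEVELS",
    "count_per_gene",
    "classify_mm",
    "gene_mm_fraction",
    "stratify_by_catalog",
    "classify_impact",
    "impact_distribution",
    "read_gene_catalog",
]

GENE_LABELS = ("wild_type", "single", "multiple")
SAMPLE_STATUSES = ("no_mutation", "SM_tumor", "MM_tumor")

#: consequence term -> functional impact level (total over the vocabulary)
IMPACT_LEVELS: Mapping[str, str] = {
    "nonsense": "high",
    "frameshift": "high",
    "splice_site": "high",
    "start_lost": "high",
    "stop_lost": "high",
    "missense": "moderate",
    "inframe_indel": "moderate",
    "synonymous": "low",
    "utr": "modifier",
    "other": "modifier",
}


@dataclass(frozen=True)
class GeneCatalog:
    """Gene -> role map (oncogene / tsg / both / unclassified).

    Unknown genes look up as ``unclassified``.
    """

    entries: Mapping[str, str]

    _ROLES = frozenset({"oncogene", "tsg", "both", "unclassified"})

    def __post_init__(self) -> None:
        bad = {r for r in self.entries.values() if r not in self._ROLES}
        if bad:
            raise ValueError(f"unknown catalog roles: {sorted(bad)}")

    def role(self, gene: str) -> str:
        return self.entries.get(gene, "unclassified")

    def roles(self, gene: str) -> frozenset[str]:
        """Role set for counting: 'both' expands to {oncogene, tsg}."""
        r = self.role(gene)
        return frozenset({"oncogene", "tsg"}) if r == "both" else frozenset({r})


@dataclass(frozen=True)
class MMClassification:
    """Gene-level labels and sample-level MM status for a cohort."""

    per_gene: Mapping[tuple[str, str], tuple[int, str]]
    per_sample: Mapping[str, str]

    def label(self, sample_id: str, gene: str) -> str:
        return self.per_gene.get((sample_id, gene), (0, "wild_type"))[1]

    def count(self, sample_id: str, gene: str) -> int:
        return self.per_gene.get((sample_id, gene), (0, "wild_type"))[0]

    def mm_samples(self) -> list[str]:
        return [s for s, st in self.per_sample.items() if st == "MM_tumor"]

    def mm_prevalence(self) -> float:
        """Fraction of all samples classified MM_tumor."""
        if not self.per_sample:
            raise ValueError("empty classification")
        return sum(st == "MM_tumor" for st in self.per_sample.values()) / len(
            self.per_sample
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(gene-level, sample-level) tables for TSV export."""
        gene_df = pd.DataFrame(
            [
                {"sample_id": s, "gene": g, "count": c, "label": lab}
                for (s, g), (c, lab) in sorted(self.per_gene.items())
            ],
            columns=["sample_id", "gene", "count", "label"],
        )
        sample_df = pd.DataFrame(
            [{"sample_id": s, "status": st} for s, st in sorted(self.per_sample.items())],
            columns=["sample_id", "status"],
        )
        return gene_df, sample_df


@dataclass(frozen=True)
class GeneMMFraction:
    """Cohort wild/single/multiple breakdown for one gene."""

    gene: str
    n_wild: int
    n_single: int
    n_multiple: int
    mm_fraction_of_mutated: Optional[float]  # None when no sample is mutated


def count_per_gene(calls: Sequence[VariantCall]) -> dict[tuple[str, str], int]:
    """Count passing calls per (sample, gene).

    Exact duplicates (same sample, site and alleles) are deduplicated so
    merged caller outputs cannot inflate MM counts. Genes with zero calls
    are absent from the map.
    """
    seen: set[tuple[str, str, int, str, str]] = set()
    counts: Counter[tuple[str, str]] = Counter()
    for call in calls:
        key = (call.sample_id, call.chrom, call.pos, call.ref, call.alt)
        if key in seen:
            continue
        seen.add(key)
        counts[(call.sample_id, call.gene)] += 1
    return dict(counts)


def classify_mm(
    counts: Mapping[tuple[str, str], int],
    all_samples: Iterable[str],
) -> MMClassification:
    """Assign gene labels and sample-level MM status.

    ``all_samples`` must cover every sample appearing in ``counts``; samples
    without any passing call get status ``no_mutation``.
    """
    all_samples = list(all_samples)
    sample_set = set(all_samples)
    missing = {s for s, _ in counts} - sample_set
    if missing:
        raise ValueError(
            f"counts reference samples absent from all_samples: {sorted(missing)[:5]}"
        )

    per_gene: dict[tuple[str, str], tuple[int, str]] = {}
    has_mm: set[str] = set()
    has_any: set[str] = set()
    for (sample, gene), n in counts.items():
        if n <= 0:
            continue
        label = "multiple" if n >= 2 else "single"
        per_gene[(sample, gene)] = (n, label)
        has_any.add(sample)
        if n >= 2:
            has_mm.add(sample)

    per_sample = {
        s: ("MM_tumor" if s in has_mm else "SM_tumor" if s in has_any else "no_mutation")
        for s in all_samples
    }
    return MMClassification(per_gene=per_gene, per_sample=per_sample)


def gene_mm_fraction(classification: MMClassification, gene: str) -> GeneMMFraction:
    """Wild/single/multiple sample counts for one gene.

    The MM fraction is taken over mutated samples only,
    ``n_multiple / (n_single + n_multiple)``, and is ``None`` when the gene
    is never mutated.
    """
    if not gene:
        raise ValueError("gene symbol must be non-empty")
    n_single = n_multiple = 0
    for (sample, g), (n, label) in classification.per_gene.items():
        if g != gene:
            continue
        if label == "multiple":
            n_multiple += 1
        else:
            n_single += 1
    n_wild = len(classification.per_sample) - n_single - n_multiple
    mutated = n_single + n_multiple
    fraction = n_multiple / mutated if mutated else None
    return GeneMMFraction(gene, n_wild, n_single, n_multiple, fraction)


def stratify_by_catalog(
    classification: MMClassification, catalog: GeneCatalog
) -> dict[str, int]:
    """Number of samples with >= 1 MM gene in each catalog role.

    A sample counts under a role iff at least one gene of that role carries
    the ``multiple`` label; a sample with MM genes in several roles counts
    under each of them ('both' genes count under oncogene and tsg).
    """
    samples_by_role: dict[str, set[str]] = {
        "oncogene": set(), "tsg": set(), "unclassified": set()
    }
    for (sample, gene), (n, label) in classification.per_gene.items():
        if label != "multiple":
            continue
        for role in catalog.roles(gene):
            samples_by_role[role].add(sample)
    return {role: len(s) for role, s in samples_by_role.items()}


def classify_impact(consequence: str) -> str:
    """Map a consequence term to its functional impact level.

    Levels follow the four-tier convention used by SnpEff-style annotation:
    high (nonsense, frameshift, splice site, start/stop loss), moderate
    (missense, in-frame indel), low (synonymous), modifier (UTR and other
    non-coding annotations).
    """
    try:
        return IMPACT_LEVELS[consequence]
    except KeyError:
        raise ValueError(
            f"unknown consequence {consequence!r}; accepted terms: "
            f"{sorted(CONSEQUENCE_VOCABULARY)}"
        ) from None


def impact_distribution(
    calls: Sequence[VariantCall], classification: MMClassification
) -> pd.DataFrame:
    """Impact-level fractions for SM-mutations vs MM-mutations.

    A mutation belongs to the MM group iff its (sample, gene) label is
    ``multiple``. Returns a tidy frame with columns group, level, n,
    fraction; fractions sum to 1 within each non-empty group, and an empty
    group is emitted with n = 0 and fraction = NaN for every level.
    """
    levels = ("high", "moderate", "low", "modifier")
    tallies: dict[str, Counter[str]] = {"SM": Counter(), "MM": Counter()}
    for call in calls:
        group = "MM" if classification.label(call.sample_id, call.gene) == "multiple" else "SM"
        tallies[group][classify_impact(call.consequence)] += 1

    rows = []
    for group in ("SM", "MM"):
        total = sum(tallies[group].values())
        for level in levels:
            n = tallies[group][level]
            rows.append(
                {
                    "group": group,
                    "level": level,
                    "n": n,
                    "fraction": n / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def read_gene_catalog(path: str | Path) -> GeneCatalog:
    """Read a catalog TSV with columns gene, role."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "role"):
        if col not in df.columns:
            raise SchemaError(f"{path}: catalog missing column {col!r}")
    return GeneCatalog(entries=dict(zip(df["gene"], df["role"])))
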