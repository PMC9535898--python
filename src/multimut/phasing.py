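"""Read-backed cis/trans phasing of mutation pairs within a gene.

Two mutations in the same gene of one tumour may sit on the same allele
copy (cis) or on different copies (trans). Sequencing fragments that cover
both sites resolve this directly: in cis, fragments from the mutant allele
carry both alternate alleles; in trans, every mutant fragment carries
exactly one. Evidence is counted at fragment level (rows sharing a
read_id are one fragment, matching amplicon/paired-end semantics) and a
two-fragment majority is required before a configuration is called, so a
single chimeric or error-bearing read cannot decide a pair.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .mm_core import MMClassification
from .variant_io import SchemaError, VariantCall

__all__ = [
    "ReadEvidence",
    "PhasingResult",
    "GenePhasing",
    "phase_pair",
    "phase_gene",
    "read_evidence_tsv",
    "write_evidence_tsv",
]

MIN_COCOVER_DEFAULT = 2
#: fragments on a side must be >= this and strictly dominate the other side
MIN_SUPPORT = 2


@dataclass(frozen=True)
class ReadEvidence:
    """Alleles observed by one fragment at the sites it covers."""

    read_id: str
    sample_id: str
    alleles: Mapping[tuple[str, int], str]  # (chrom, pos) -> observed allele

    @property
    def covered_sites(self) -> frozenset[tuple[str, int]]:
        return frozenset(self.alleles)


@dataclass(frozen=True)
class PhasingResult:
    """Cis/trans/undetermined call for one mutation pair."""

    pair: tuple[VariantCall, VariantCall]
    call: str  # cis | trans | undetermined
    n_both_alt: int
    n_exclusive: int
    n_cocovering: int


@dataclass(frozen=True)
class GenePhasing:
    """All pair calls for one gene plus the cohort cis fraction."""

    gene: str
    results: tuple[PhasingResult, ...]
    cis_fraction: Optional[float]  # None when no pair is determinable

    @property
    def n_cis(self) -> int:
        return sum(r.call == "cis" for r in self.results)

    @property
    def n_trans(self) -> int:
        return sum(r.call == "trans" for r in self.results)


def _merge_fragments(
    reads: Iterable[ReadEvidence], sample_id: str
) -> dict[str, dict[tuple[str, int], str]]:
    """Collapse evidence rows to one allele map per fragment (read_id).

    Conflicting observations at a site within one fragment (e.g. both mates
    disagree) drop that site from the fragment.
    """
    fragments: dict[str, dict[tuple[str, int], str]] = defaultdict(dict)
    conflicts: dict[str, set[tuple[str, int]]] = defaultdict(set)
    for ev in reads:
        if ev.sample_id != sample_id:
            continue
        frag = fragments[ev.read_id]
        for site, allele in ev.alleles.items():
            if site in frag and frag[site] != allele:
                conflicts[ev.read_id].add(site)
            else:
                frag[site] = allele
    for read_id, sites in conflicts.items():
        for site in sites:
            fragments[read_id].pop(site, None)
    return fragments


def phase_pair(
    a: VariantCall,
    b: VariantCall,
    reads: Sequence[ReadEvidence],
    min_cocover: int = MIN_COCOVER_DEFAULT,
) -> PhasingResult:
    """Phase one mutation pair from fragment evidence.

    Decision rule: among fragments covering both sites, call cis when
    fragments carrying both alternate alleles number >= 2 and strictly
    outnumber fragments carrying exactly one (with the reference at the
    other site); trans in the mirrored case; otherwise undetermined.
    Fragments showing a third allele at either site are ignored. Symmetric
    in the two calls.
    """
    if min_cocover < 1:
        raise ValueError("min_cocover must be >= 1")
    if (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt):
        raise ValueError("cannot phase a mutation against itself")
    if a.sample_id != b.sample_id:
        raise ValueError(
            f"cross-sample pair: {a.sample_id!r} vs {b.sample_id!r}"
        )

    site_a, site_b = (a.chrom, a.pos), (b.chrom, b.pos)
    n_cocover = n_both = n_excl = 0
    for frag in _merge_fragments(reads, a.sample_id).values():
        if site_a not in frag or site_b not in frag:
            continue
        allele_a, allele_b = frag[site_a], frag[site_b]
        if allele_a not in (a.ref, a.alt) or allele_b not in (b.ref, b.alt):
            continue  # third allele: fragment ignored for this pair
        n_cocover += 1
        is_alt_a, is_alt_b = allele_a == a.alt, allele_b == b.alt
        if is_alt_a and is_alt_b:
            n_both += 1
        elif is_alt_a != is_alt_b:
            n_excl += 1

    if n_cocover < min_cocover:
        call = "undetermined"
    elif n_both >= MIN_SUPPORT and n_both > n_excl:
        call = "cis"
    elif n_excl >= MIN_SUPPORT and n_excl > n_both:
        call = "trans"
    else:
        call = "undetermined"
    return PhasingResult(
        pair=(a, b), call=call, n_both_alt=n_both,
        n_exclusive=n_excl, n_cocovering=n_cocover,
    )


def phase_gene(
    classification: MMClassification,
    gene: str,
    calls: Sequence[VariantCall],
    reads: Sequence[ReadEvidence],
    min_cocover: int = MIN_COCOVER_DEFAULT,
) -> GenePhasing:
    """Phase every unordered mutation pair in each MM sample of a gene.

    The cohort cis fraction is cis / (cis + trans) over determinable pairs,
    ``None`` when every pair is undetermined.
    """
    mm_samples = [
        s for (s, g), (n, label) in classification.per_gene.items()
        if g == gene and label == "multiple"
    ]
    if not mm_samples:
        raise ValueError(f"gene {gene!r} has no MM sample to phase")

    by_sample: dict[str, list[VariantCall]] = defaultdict(list)
    for call in calls:
        if call.gene == gene:
            by_sample[call.sample_id].append(call)

    results: list[PhasingResult] = []
    for sample in sorted(mm_samples):
        muts = sorted(by_sample.get(sample, []), key=lambda c: (c.chrom, c.pos, c.alt))
        for a, b in itertools.combinations(muts, 2):
            results.append(phase_pair(a, b, reads, min_cocover=min_cocover))

    n_cis = sum(r.call == "cis" for r in results)
    n_trans = sum(r.call == "trans" for r in results)
    fraction = n_cis / (n_cis + n_trans) if (n_cis + n_trans) else None
    return GenePhasing(gene=gene, results=tuple(results), cis_fraction=fraction)


# ---------------------------------------------------------------------------
# TSV exchange format (alignment-free; a BAM-backed extractor would emit the
# same rows: one per fragment x covered site)


def read_evidence_tsv(path: str | Path) -> list[ReadEvidence]:
    """Read evidence rows (read_id, sample_id, chrom, pos, allele) and merge
    rows of the same fragment into one :class:`ReadEvidence`."""
    df = pd.read_csv(path, sep="\t", dtype={"pos": int}, keep_default_na=False)
    for col in ("read_id", "sample_id", "chrom", "pos", "allele"):
        if col not in df.columns:
            raise SchemaError(f"{path}: read-evidence missing column {col!r}")
    grouped: dict[tuple[str, str], dict[tuple[str, int], str]] = defaultdict(dict)
    for row in df.to_dict("records"):
        key = (str(row["read_id"]), str(row["sample_id"]))
        grouped[key][(str(row["chrom"]), int(row["pos"]))] = str(row["allele"])
    return [
        ReadEvidence(read_id=rid, sample_id=sid, alleles=alleles)
        for (rid, sid), alleles in grouped.items()
    ]


def write_evidence_tsv(reads: Sequence[ReadEvidence], path: str | Path) -> None:
    rows = [
        {"read_id": ev.read_id, "sample_id": ev.sample_id,
         "chrom": chrom, "pos": pos, "allele": allele}
        for ev in reads
        for (chrom, pos), allele in sorted(ev.alleles.items())
    ]
    pd.DataFrame(rows, columns=["read_id", "sample_id", "chrom", "pos", "allele"]).to_csv(
        path, sep="\t", index=False
    )


class BamEvidenceExtractor:
    """Adapter stub: how a BAM-backed extractor would populate ReadEvidence.

    An integrator would, per MM sample and per mutation pair, fetch aligned
    fragments overlapping both sites (e.g. with pysam), read the base or
    indel each fragment reports at each site, and emit one evidence row per
    fragment x site in the TSV schema of :func:`write_evidence_tsv`.
    Alignment parsing itself is deliberately outside this package.
    """

    def __init__(self) -> None:
        raise NotImplementedError(
            "BAM extraction is left to integrators; emit the read-evidence "
            "TSV schema instead"
        )
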