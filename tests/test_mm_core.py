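from collections import Counter

import numpy as np
import pytest

from multimut import (
    GeneCatalog,
    classify_impact,
    classify_mm,
    count_per_gene,
    gene_mm_fraction,
    impact_distribution,
    stratify_by_catalog,
)

from conftest import make_call


def brute_force_classification(calls, all_samples):
    """Independent oracle: scan every (sample, gene) pair over the raw call
    list, deduplicating by site, without touching the implementation."""
    sites = {}
    for c in calls:
        sites[(c.sample_id, c.chrom, c.pos, c.ref, c.alt)] = c.gene
    per_pair = Counter()
    for (sample, _, _, _, _), gene in sites.items():
        per_pair[(sample, gene)] += 1
    labels = {
        pair: ("multiple" if n >= 2 else "single") for pair, n in per_pair.items()
    }
    statuses = {}
    for s in all_samples:
        genes = [g for (smp, g) in per_pair if smp == s]
        if not genes:
            statuses[s] = "no_mutation"
        elif any(per_pair[(s, g)] >= 2 for g in genes):
            statuses[s] = "MM_tumor"
        else:
            statuses[s] = "SM_tumor"
    return per_pair, labels, statuses


def random_cohort(rng, n_samples=None, n_genes=None):
    n_samples = n_samples or int(rng.integers(2, 21))
    n_genes = n_genes or int(rng.integers(1, 11))
    samples = [f"S{i}" for i in range(n_samples)]
    calls = []
    for _ in range(int(rng.integers(0, 60))):
        # gene is a function of position so a site never straddles two genes;
        # repeated positions within a sample exercise the dedup rule
        pos = int(rng.integers(1, 30))
        calls.append(
            make_call(
                sample_id=samples[rng.integers(n_samples)],
                gene=f"G{pos % n_genes}",
                chrom="chr1",
                pos=pos,
                ref="A",
                alt="C",
            )
        )
    return samples, calls


class TestCounting:
    def test_two_distinct_calls_same_gene(self):
        calls = [make_call(pos=10), make_call(pos=20)]
        assert count_per_gene(calls) == {("S1", "TP53"): 2}

    def test_exact_duplicates_deduplicated(self):
        calls = [make_call(pos=10), make_call(pos=10)]
        assert count_per_gene(calls) == {("S1", "TP53"): 1}

    def test_disjoint_samples(self):
        calls = [
            make_call(sample_id=f"S{i}", gene=f"G{i}", pos=10 + i) for i in range(3)
        ]
        assert count_per_gene(calls) == {
            (f"S{i}", f"G{i}"): 1 for i in range(3)
        }


class TestClassify:
    def test_two_singly_mutated_genes_is_sm(self):
        counts = {("S1", "TP53"): 1, ("S1", "ARID1A"): 1}
        cls = classify_mm(counts, ["S1"])
        assert cls.per_sample["S1"] == "SM_tumor"

    def test_one_gene_with_two_hits_is_mm(self):
        cls = classify_mm({("S1", "MUC16"): 2}, ["S1", "S2"])
        assert cls.per_sample == {"S1": "MM_tumor", "S2": "no_mutation"}
        assert cls.label("S1", "MUC16") == "multiple"
        assert cls.label("S2", "MUC16") == "wild_type"

    def test_prevalence_arithmetic(self):
        # 178 MM of 223 samples
        counts = {(f"S{i}", "G"): 2 for i in range(178)}
        counts.update({(f"S{i}", "G"): 1 for i in range(178, 223)})
        cls = classify_mm(counts, [f"S{i}" for i in range(223)])
        assert cls.mm_prevalence() == pytest.approx(178 / 223)
        assert round(100 * cls.mm_prevalence(), 1) == 79.8

    def test_unknown_sample_in_counts_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            classify_mm({("SX", "G"): 1}, ["S1"])

    def test_brute_force_oracle_and_order_invariance(self, rng):
        for _ in range(200):
            samples, calls = random_cohort(rng)
            counts = count_per_gene(calls)
            cls = classify_mm(counts, samples)
            oracle_counts, oracle_labels, oracle_status = brute_force_classification(
                calls, samples
            )
            assert counts == dict(oracle_counts)
            assert {k: v[1] for k, v in cls.per_gene.items()} == oracle_labels
            assert cls.per_sample == oracle_status
            # permuting the call list changes nothing
            perm = [calls[i] for i in rng.permutation(len(calls))]
            cls2 = classify_mm(count_per_gene(perm), samples)
            assert cls2 == cls

    def test_adding_a_mutation_never_demotes_mm(self, rng):
        for _ in range(50):
            samples, calls = random_cohort(rng)
            cls = classify_mm(count_per_gene(calls), samples)
            extra = make_call(
                sample_id=samples[rng.integers(len(samples))],
                gene="Gnew", chrom="chr9", pos=int(rng.integers(1, 1000)),
            )
            cls2 = classify_mm(count_per_gene(calls + [extra]), samples)
            for s in samples:
                if cls.per_sample[s] == "MM_tumor":
                    assert cls2.per_sample[s] == "MM_tumor"


class TestGeneFraction:
    def test_mucin_like_fraction(self):
        counts = {(f"S{i}", "MUC16"): 1 for i in range(39)}
        counts.update({(f"T{i}", "MUC16"): 2 for i in range(7)})
        cls = classify_mm(counts, [f"S{i}" for i in range(39)] + [f"T{i}" for i in range(7)])
        frac = gene_mm_fraction(cls, "MUC16")
        assert (frac.n_single, frac.n_multiple) == (39, 7)
        assert frac.mm_fraction_of_mutated == pytest.approx(7 / 46)
        assert round(100 * frac.mm_fraction_of_mutated, 1) == 15.2

    def test_catenin_like_fraction(self):
        counts = {(f"S{i}", "CTNNB1"): 1 for i in range(68)}
        counts.update({(f"T{i}", "CTNNB1"): 3 for i in range(11)})
        cls = classify_mm(
            counts, [f"S{i}" for i in range(68)] + [f"T{i}" for i in range(11)]
        )
        frac = gene_mm_fraction(cls, "CTNNB1")
        assert frac.mm_fraction_of_mutated == pytest.approx(11 / 79)

    def test_never_mutated_gene_undefined(self):
        cls = classify_mm({("S1", "G"): 1}, ["S1", "S2", "S3"])
        frac = gene_mm_fraction(cls, "ABSENT")
        assert (frac.n_wild, frac.n_single, frac.n_multiple) == (3, 0, 0)
        assert frac.mm_fraction_of_mutated is None

    def test_empty_symbol_rejected(self):
        cls = classify_mm({}, ["S1"])
        with pytest.raises(ValueError):
            gene_mm_fraction(cls, "")


class TestCatalog:
    def test_mm_counted_under_its_role_only(self):
        cls = classify_mm({("S1", "ONC"): 2, ("S1", "TSG"): 1}, ["S1"])
        catalog = GeneCatalog(entries={"ONC": "oncogene", "TSG": "tsg"})
        assert stratify_by_catalog(cls, catalog) == {
            "oncogene": 1, "tsg": 0, "unclassified": 0
        }

    def test_dual_role_counts_under_both(self):
        cls = classify_mm({("S1", "DUAL"): 2}, ["S1"])
        catalog = GeneCatalog(entries={"DUAL": "both"})
        strata = stratify_by_catalog(cls, catalog)
        assert strata["oncogene"] == 1 and strata["tsg"] == 1

    def test_empty_catalog_everything_unclassified(self):
        cls = classify_mm({("S1", "G1"): 2, ("S2", "G2"): 2}, ["S1", "S2"])
        assert stratify_by_catalog(cls, GeneCatalog(entries={})) == {
            "oncogene": 0, "tsg": 0, "unclassified": 2
        }

    def test_role_counts_bounded_by_mm_total(self, rng):
        from test_mm_core import random_cohort  # self-import for clarity

        for _ in range(20):
            samples, calls = random_cohort(rng)
            cls = classify_mm(count_per_gene(calls), samples)
            catalog = GeneCatalog(
                entries={f"G{i}": ("oncogene" if i % 2 else "tsg") for i in range(10)}
            )
            n_mm = len(cls.mm_samples())
            for count in stratify_by_catalog(cls, catalog).values():
                assert count <= n_mm

    def test_bad_role_rejected(self):
        with pytest.raises(ValueError):
            GeneCatalog(entries={"G": "driver"})


class TestImpact:
    @pytest.mark.parametrize(
        "consequence, level",
        [
            ("nonsense", "high"), ("frameshift", "high"), ("splice_site", "high"),
            ("missense", "moderate"), ("inframe_indel", "moderate"),
            ("synonymous", "low"), ("utr", "modifier"),
        ],
    )
    def test_four_level_mapping(self, consequence, level):
        assert classify_impact(consequence) == level

    def test_unknown_term_lists_vocabulary(self):
        with pytest.raises(ValueError, match="missense"):
            classify_impact("weird_term")

    def test_all_missense_both_groups_pure_moderate(self):
        calls = [
            make_call(sample_id="S1", pos=1), make_call(sample_id="S1", pos=5),
            make_call(sample_id="S2", gene="KRAS", pos=9),
        ]
        cls = classify_mm(count_per_gene(calls), ["S1", "S2"])
        dist = impact_distribution(calls, cls)
        for group in ("SM", "MM"):
            sub = dist[dist.group == group].set_index("level")
            assert sub.loc["moderate", "fraction"] == 1.0

    def test_hand_built_six_call_cohort(self):
        # S1 carries an MM gene with two frameshifts -> MM group 100% high;
        # remaining four SM calls: 2 missense, 1 synonymous, 1 utr
        calls = [
            make_call(sample_id="S1", gene="A", pos=1, consequence="frameshift"),
            make_call(sample_id="S1", gene="A", pos=9, consequence="frameshift"),
            make_call(sample_id="S1", gene="B", pos=20, consequence="missense"),
            make_call(sample_id="S2", gene="A", pos=30, consequence="missense"),
            make_call(sample_id="S2", gene="C", pos=40, consequence="synonymous"),
            make_call(sample_id="S3", gene="D", pos=50, consequence="utr"),
        ]
        cls = classify_mm(count_per_gene(calls), ["S1", "S2", "S3"])
        dist = impact_distribution(calls, cls).set_index(["group", "level"])
        assert dist.loc[("MM", "high"), "fraction"] == 1.0
        assert dist.loc[("MM", "high"), "n"] == 2
        assert dist.loc[("SM", "moderate"), "fraction"] == pytest.approx(2 / 4)
        sm = dist.loc["SM", "fraction"]
        assert sm.sum() == pytest.approx(1.0)

    def test_empty_mm_group_flagged(self):
        calls = [make_call()]
        cls = classify_mm(count_per_gene(calls), ["S1"])
        dist = impact_distribution(calls, cls)
        mm = dist[dist.group == "MM"]
        assert mm["n"].sum() == 0 and mm["fraction"].isna().all()
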