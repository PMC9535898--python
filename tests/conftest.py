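import numpy as np
import pandas as pd
import pytest

from multimut import FilterCriteria, VariantCall


def make_call(**overrides) -> VariantCall:
    """A fully passing variant call; override any field."""
    base = dict(
        sample_id="S1",
        gene="TP53",
        chrom="chr17",
        pos=7_578_406,
        ref="C",
        alt="T",
        consequence="missense",
        quality=90.0,
        depth=80,
        alt_fwd=20,
        alt_rev=18,
        avg_clipped_length=140.0,
        avg_pos_as_fraction=0.42,
    )
    base.update(overrides)
    return VariantCall(**base)


def random_call(rng: np.random.Generator, blacklist_sites=()) -> VariantCall:
    """Fuzzed call stressing every filter criterion, boundaries included."""
    maybe_none = lambda v: None if rng.random() < 0.1 else v
    pos = int(rng.integers(1, 50))
    site = ("chr1", pos, "A", "C")
    return VariantCall(
        sample_id=f"S{rng.integers(1, 6)}",
        gene=f"G{rng.integers(1, 6)}",
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="C",
        consequence="missense",
        quality=maybe_none(float(rng.choice([20, 59, 59.9, 60, 60.1, 95]))),
        depth=maybe_none(int(rng.choice([5, 19, 20, 21, 100]))),
        alt_fwd=maybe_none(int(rng.choice([0, 1, 2]))),
        alt_rev=maybe_none(int(rng.choice([0, 1, 2]))),
        avg_clipped_length=maybe_none(float(rng.choice([50, 99.9, 100, 150]))),
        avg_pos_as_fraction=maybe_none(
            float(rng.choice([0.0, 0.049, 0.05, 0.051, 0.5]))
        ),
    )


def reference_filter_verdict(call: VariantCall, criteria: FilterCriteria) -> bool:
    """Independent re-statement of the six discard criteria: True = discard.

    Written directly from the rule text, deliberately not sharing code with
    the implementation under test.
    """
    discard = False
    if call.quality is not None and call.quality < criteria.min_quality:
        discard = True
    if call.depth is not None and call.depth < criteria.min_depth:
        discard = True
    if criteria.require_both_strands and None not in (call.alt_fwd, call.alt_rev):
        if call.alt_fwd == 0 or call.alt_rev == 0:
            discard = True
    if (
        call.avg_clipped_length is not None
        and call.avg_clipped_length < criteria.min_avg_clipped_length
    ):
        discard = True
    if (
        call.avg_pos_as_fraction is not None
        and call.avg_pos_as_fraction < criteria.min_avg_pos_as_fraction
    ):
        discard = True
    if (call.chrom, call.pos, call.ref, call.alt) in criteria.blacklist:
        discard = True
    return discard


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def toy_maf(tmp_path):
    """Minimal-dialect MAF with 3 rows, QC columns present."""
    path = tmp_path / "toy.maf"
    pd.DataFrame(
        {
            "sample_id": ["S1", "S1", "S2"],
            "gene": ["TP53", "CTNNB1", "TP53"],
            "chrom": ["chr17", "chr3", "chr17"],
            "pos": [100, 200, 300],
            "ref": ["C", "G", "A"],
            "alt": ["T", "A", "G"],
            "consequence": ["missense", "nonsense", "synonymous"],
            "quality": [90.0, 61.0, 70.0],
            "depth": [50, 30, 40],
            "alt_fwd": [10, 5, 8],
            "alt_rev": [12, 6, 9],
            "avg_clipped_length": [130.0, 120.0, 150.0],
            "avg_pos_as_fraction": [0.4, 0.3, 0.2],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
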