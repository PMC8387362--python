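"""Allelic-imbalance test, LOH typing and copy-number event calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, chi2_contingency

from hrdscan.genome import (
    AlleleSpecificSegment,
    OverlappingSegmentsError,
    UncoveredLocusError,
)
from hrdscan.secondhit import (
    ZeroMarginError,
    allelic_imbalance_test,
    call_cn_events,
    classify_loh_type,
    detect_somatic_second_hit,
    evaluate_second_hit,
    retention_direction,
    somatic_biallelic_scan,
)
from hrdscan.variants import VariantObservation


def _sigfig(x, n=3):
    from math import floor, log10

    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (n - 1))


# Published worked examples: germline REF/ALT, tumor REF/ALT -> printed p.
WORKED_EXAMPLES = [
    ("APC", 80, 64, 134, 177, 0.013197),
    ("ATM", 191, 142, 8, 24, 0.000446),
    ("POLQ", 26, 28, 7, 21, 0.042667),
    ("REV1", 88, 80, 60, 93, 0.01811),
    ("CHEK2-R389C", 114, 128, 36, 67, 0.037132),
    ("CHEK2-N489D", 192, 180, 23, 49, 0.002237),
    ("LIG4", 148, 83, 29, 40, 0.001089),
    ("XIRP2", 69, 56, 18, 33, 0.016566),
]


@pytest.mark.parametrize("name,a,b,c,d,expected", WORKED_EXAMPLES)
def test_worked_examples_match_published_p_values(name, a, b, c, d, expected):
    p = allelic_imbalance_test(a, b, c, d)
    assert _sigfig(p) == _sigfig(expected), name


def test_identical_proportions_give_p_one():
    assert allelic_imbalance_test(50, 50, 50, 50) == pytest.approx(1.0)


def test_zero_margin_raises():
    with pytest.raises(ZeroMarginError):
        allelic_imbalance_test(0, 0, 10, 10)
    with pytest.raises(ZeroMarginError):
        allelic_imbalance_test(10, 0, 10, 0)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        allelic_imbalance_test(-1, 5, 5, 5)


@given(
    st.integers(0, 200), st.integers(0, 200),
    st.integers(0, 200), st.integers(0, 200),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_matches_scipy_and_is_ref_alt_symmetric(a, b, c, d):
    """Independent oracle: scipy's chi-squared without correction; and the
    p-value is invariant under swapping REF/ALT in both rows."""
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return
    p = allelic_imbalance_test(a, b, c, d)
    p_scipy = chi2_contingency([[a, b], [c, d]], correction=False)[1]
    assert p == pytest.approx(p_scipy, rel=1e-9)
    assert allelic_imbalance_test(b, a, d, c) == pytest.approx(p, rel=1e-12)


def test_continuity_flag_matches_yates():
    p = allelic_imbalance_test(42, 35, 12, 38, continuity=True)
    p_scipy = chi2_contingency([[42, 35], [12, 38]], correction=True)[1]
    assert p == pytest.approx(p_scipy, rel=1e-9)


@pytest.mark.parametrize("a,b,c,d", [(30, 20, 10, 25), (5, 6, 9, 2), (40, 10, 10, 40)])
def test_scaling_counts_strengthens_unequal_evidence(a, b, c, d):
    """Multiplying all counts by k >= 2 strictly decreases p when the two
    proportions differ; equal proportions stay at p = 1."""
    p1 = allelic_imbalance_test(a, b, c, d)
    for k in (2, 3, 5):
        assert allelic_imbalance_test(k * a, k * b, k * c, k * d) < p1
    assert allelic_imbalance_test(2 * a, 2 * b, 2 * a, 2 * b) == pytest.approx(1.0)


def test_vectorized_call_agrees_with_scalars():
    a = np.array([80, 191, 26])
    b = np.array([64, 142, 28])
    c = np.array([134, 8, 7])
    d = np.array([177, 24, 21])
    ps = allelic_imbalance_test(a, b, c, d)
    for i in range(3):
        assert ps[i] == pytest.approx(
            allelic_imbalance_test(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
        )


def test_retention_direction():
    # tumor VAF 0.569 > germline 0.444: the variant allele was retained
    assert retention_direction(80, 64, 134, 177) == "variant-retained"
    assert retention_direction(64, 80, 177, 134) == "wt-retained"
    assert retention_direction(10, 10, 30, 30) == "balanced"
    with pytest.raises(ZeroMarginError):
        retention_direction(0, 0, 10, 10)


def _variant(chrom="chr1", pos=50_000_000, **kw):
    base = dict(
        chrom=chrom, pos=pos, ref_allele="C", alt_allele="T",
        origin="germline", gene_symbol="GENE1", consequence="missense",
        germline_ref_count=80, germline_alt_count=64,
        tumor_ref_count=134, tumor_alt_count=177, patient_id="P0",
    )
    base.update(kw)
    return VariantObservation(**base)


CHR1 = "chr1"


def _seg(total, minor, start=1, end=249_250_621, chrom=CHR1):
    return AlleleSpecificSegment(chrom, start, end, total, minor)


@pytest.mark.parametrize(
    "total,minor,p,direction,expected",
    [
        (2, 0, 0.001, "variant-retained", "CN-LOH"),
        (1, 0, 0.001, "variant-retained", "DEL-LOH"),
        (3, 0, 0.001, "variant-retained", "DUP-LOH"),
        (5, 0, 0.001, "variant-retained", "DUP-LOH"),
        (2, 1, 0.001, "variant-retained", "none"),  # heterozygosity preserved
        (2, 0, 0.2, "variant-retained", "none"),  # not significant
        (2, 0, 0.001, "wt-retained", "none"),  # wrong direction
        (2, 0, 0.05, "variant-retained", "CN-LOH"),  # boundary p inclusive
        (0, 0, 0.001, "variant-retained", "none"),  # homozygous deletion
    ],
)
def test_classify_loh_type(total, minor, p, direction, expected):
    v = _variant()
    assert classify_loh_type(v, [_seg(total, minor)], p, direction) == expected


def test_classify_loh_type_segment_lookup_errors():
    v = _variant(pos=10)
    with pytest.raises(UncoveredLocusError):
        classify_loh_type(v, [_seg(2, 0, start=100, end=200)], 0.001,
                          "variant-retained")
    v_in_both = _variant(pos=60)
    overlapping = [_seg(2, 0, 1, 100), _seg(2, 1, 50, 200)]
    with pytest.raises(OverlappingSegmentsError):
        classify_loh_type(v_in_both, overlapping, 0.001, "variant-retained")


def test_boundary_position_belongs_to_containing_segment():
    v = _variant(pos=100)
    segs = [_seg(1, 0, 1, 100), _seg(2, 1, 101, 200)]
    assert classify_loh_type(v, segs, 0.001, "variant-retained") == "DEL-LOH"


def test_detect_somatic_second_hit():
    som = [
        _variant(origin="somatic", gene_symbol="GENE1", consequence="nonsense"),
        _variant(origin="somatic", gene_symbol="GENE2", consequence="synonymous"),
    ]
    assert detect_somatic_second_hit("GENE1", som) == som[0].key
    assert detect_somatic_second_hit("GENE2", som) is None  # synonymous
    assert detect_somatic_second_hit("GENE3", som) is None


def test_somatic_biallelic_scan():
    splice = _variant(origin="somatic", gene_symbol="RAD51C",
                      consequence="splice", pos=50)
    som_balanced = _variant(origin="somatic", gene_symbol="GENE2",
                            consequence="nonsense", pos=150)
    segs = [_seg(3, 0, 1, 100), _seg(2, 1, 101, 200)]
    hits = somatic_biallelic_scan([splice, som_balanced], segs,
                                  {"RAD51C", "GENE2"})
    assert hits == [("RAD51C", splice.key, "DUP-LOH")]
    assert somatic_biallelic_scan([], segs, {"RAD51C"}) == []


def test_evaluate_second_hit_integrates_all_evidence():
    v = _variant()  # APC-like counts on a CN-LOH segment
    res = evaluate_second_hit(v, [_seg(2, 0)], [])
    assert res.retention == "CN-LOH"
    assert res.p_value == pytest.approx(0.013197, abs=5e-6)
    assert res.direction == "variant-retained"
    assert res.has_second_hit


def test_call_cn_events():
    intervals = {
        "DELGENE": (CHR1, 1_000, 2_000),
        "ERBB2": (CHR1, 10_000, 20_000),
        "PTEN": (CHR1, 30_000, 40_000),
        "HEMI": (CHR1, 50_000, 60_000),
    }
    segs = [
        AlleleSpecificSegment(CHR1, 1, 5_000, 0, 0),
        AlleleSpecificSegment(CHR1, 5_001, 25_000, 7, 1),
        AlleleSpecificSegment(CHR1, 25_001, 45_000, 7, 1),
        AlleleSpecificSegment(CHR1, 45_001, 70_000, 1, 0),
    ]
    calls = call_cn_events(segs, intervals)
    assert calls["DELGENE"] == "homozygous-deletion"
    assert calls["ERBB2"] == "amplification"
    assert calls["PTEN"] == "none"  # amplification restricted to the panel
    assert calls["HEMI"] == "hemizygous-deletion"


def test_closed_form_statistic_oracle_small_sweep():
    """Spot-check the textbook closed form N(ad-bc)^2/((a+b)(c+d)(a+c)(b+d))
    on a grid (the exhaustive sweep lives in the acceptance tests)."""
    rng = np.random.default_rng(0)
    for _ in range(500):
        a, b, c, d = rng.integers(0, 51, size=4)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        n = a + b + c + d
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        p_closed = chi2.sf(stat, 1)
        assert allelic_imbalance_test(int(a), int(b), int(c), int(d)) == pytest.approx(
            p_closed, rel=1e-12, abs=1e-300
        )
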