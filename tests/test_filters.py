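"""Germline candidate selection and somatic filter contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrdscan.filters import (
    GermlineQualityThresholds,
    SomaticFilterThresholds,
    filter_germline_quality,
    filter_population_frequency,
    filter_somatic,
    predictor_consensus,
    route_candidate,
    select_germline_candidates,
)
from hrdscan.genes import assign_gene_category, placeholder_gene_lists
from hrdscan.variants import VariantObservation


def _v(**kw):
    base = dict(
        chrom="chr1", pos=1000, ref_allele="C", alt_allele="T",
        origin="germline", gene_symbol="GENE", consequence="missense",
        germline_ref_count=60, germline_alt_count=50,
        tumor_ref_count=70, tumor_alt_count=70,
        mapping_quality=60.0, patient_id="P0",
    )
    base.update(kw)
    return VariantObservation(**base)


class TestGermlineQuality:
    def test_all_rules_satisfied_kept(self):
        out = filter_germline_quality([_v()])  # AF ~0.455, depth 110, MQ 60
        assert len(out.kept) == 1 and not out.removed

    @pytest.mark.parametrize(
        "kw,reason",
        [
            (dict(germline_ref_count=2, germline_alt_count=2), "i:low-depth"),
            (dict(germline_ref_count=9, germline_alt_count=1), "ii:low-alt-support"),
            (dict(germline_ref_count=80, germline_alt_count=20), "iii:allelic-fraction"),
            (dict(mapping_quality=29.0), "iv:low-mapping-quality"),
        ],
    )
    def test_first_failing_rule_reported(self, kw, reason):
        out = filter_germline_quality([_v(**kw)])
        assert not out.kept
        assert out.removed[0][1] == reason

    def test_rule_order_low_depth_wins(self):
        # depth 4 AND low AF: rule (i) is reported, being first in order
        out = filter_germline_quality(
            [_v(germline_ref_count=4, germline_alt_count=0)]
        )
        assert out.removed[0][1] == "i:low-depth"

    def test_af_window_endpoints_inclusive(self):
        t = GermlineQualityThresholds()
        low = _v(germline_ref_count=65, germline_alt_count=35)  # 0.35
        high = _v(germline_ref_count=35, germline_alt_count=65)  # 0.65
        out = filter_germline_quality([low, high], t)
        assert len(out.kept) == 2

    def test_configurable_window(self):
        t = GermlineQualityThresholds(af_low=0.35, af_high=0.5)
        exactly_half = _v(germline_ref_count=50, germline_alt_count=50)
        above = _v(germline_ref_count=48, germline_alt_count=52)
        out = filter_germline_quality([exactly_half, above], t)
        assert [v.germline_af for v in out.kept] == [0.5]
        assert out.removed[0][1] == "iii:allelic-fraction"

    def test_missing_counts_unscorable(self):
        out = filter_germline_quality([_v(germline_ref_count=None)])
        assert out.removed[0][1] == "unscorable"

    def test_published_missense_read_counts_pass_default_window(self):
        """The germline read counts of the published retained missense
        variants all fall inside the default heterozygote window."""
        counts = [
            (80, 64), (191, 142), (114, 97), (42, 35), (112, 107),
            (211, 155), (114, 128), (192, 180), (35, 36), (155, 148),
            (109, 120), (138, 101), (26, 28), (129, 120), (88, 80),
        ]
        variants = [_v(germline_ref_count=r, germline_alt_count=a)
                    for r, a in counts]
        out = filter_germline_quality(variants)
        assert len(out.kept) == len(counts)


class TestPopulationFrequency:
    @pytest.mark.parametrize(
        "af,kept", [(0.009, True), (0.01, False), (0.5, False), (None, True), (0.0, True)]
    )
    def test_strict_threshold(self, af, kept):
        out = filter_population_frequency([_v(population_af=af)])
        assert bool(out.kept) == kept

    @given(st.floats(0, 1), st.floats(0.001, 0.2), st.floats(0.001, 0.2))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, af, t1, t2):
        lo, hi = sorted((t1, t2))
        kept_lo = bool(filter_population_frequency([_v(population_af=af)], lo).kept)
        kept_hi = bool(filter_population_frequency([_v(population_af=af)], hi).kept)
        # raising the threshold never removes a previously kept variant
        assert not (kept_lo and not kept_hi)


class TestPredictorConsensus:
    @pytest.mark.parametrize(
        "n_true,expected", [(0, False), (3, False), (4, True), (8, True)]
    )
    def test_quorum(self, n_true, expected):
        calls = (True,) * n_true + (False,) * (8 - n_true)
        assert predictor_consensus(calls) is expected

    def test_absent_calls_count_in_denominator_only(self):
        assert predictor_consensus((True, True, True, None, None, None, None, None)) is False
        assert predictor_consensus((True, True, True, True, None, None, None, None)) is True

    def test_more_than_eight_calls_rejected(self):
        with pytest.raises(ValueError):
            predictor_consensus((True,) * 9)


class TestGeneCategories:
    def test_category_precedence_and_fallback(self, gene_lists):
        assert assign_gene_category("CHEK2", gene_lists) == "BCSG"
        assert assign_gene_category("REV1", gene_lists) == "DNA-repair"
        assert assign_gene_category("APC", gene_lists) == "CSG"
        assert assign_gene_category("BRDT", gene_lists) == "C-HRG"
        assert assign_gene_category("NOT_A_GENE", gene_lists) == "other"

    def test_documented_list_sizes(self, gene_lists):
        assert len(gene_lists.bcsg) == 20
        assert len(gene_lists.csg) == 147
        assert len(gene_lists.dna_repair) == 103
        assert len(gene_lists.c_hrg) == 594


class TestRouting:
    def test_missense_non_bcsg_needs_predictor_quorum(self):
        five_of_eight = (True,) * 5 + (False,) * 3
        v = _v(clinvar_class="Unknown", acmg_class="VUS",
               predictor_calls=five_of_eight)
        assert route_candidate(v, "C-HRG") == "master-list"
        weak = _v(clinvar_class="VUS", predictor_calls=(True,) * 3 + (False,) * 5)
        assert route_candidate(weak, "C-HRG") == "dropped-prediction"

    def test_bcsg_missense_kept_regardless_of_predictors(self):
        v = _v(clinvar_class="VUS", predictor_calls=(False,) * 8)
        assert route_candidate(v, "BCSG") == "master-list"

    @pytest.mark.parametrize("cls", ["Likely benign", "Benign"])
    def test_clinvar_benign_dropped(self, cls):
        v = _v(clinvar_class=cls, predictor_calls=(True,) * 8)
        assert route_candidate(v, "C-HRG") == "dropped-benign"

    def test_acmg_used_when_clinvar_absent(self):
        v = _v(clinvar_class="Unknown", acmg_class="Likely benign")
        assert route_candidate(v, "C-HRG") == "dropped-benign"

    @pytest.mark.parametrize("cons", ["nonsense", "frameshift", "splice"])
    def test_truncating_and_splice_to_master_list(self, cons):
        v = _v(consequence=cons, clinvar_class="Unknown")
        assert route_candidate(v, "C-HRG") == "master-list"

    def test_synonymous_dropped(self):
        v = _v(consequence="synonymous")
        assert route_candidate(v, "C-HRG") == "dropped-consequence"


class TestSomaticFilter:
    def _s(self, **kw):
        base = dict(
            chrom="chr2", pos=5000, ref_allele="G", alt_allele="A",
            origin="somatic", consequence="missense",
            tumor_ref_count=50, tumor_alt_count=30,
            strand_alt_counts=(15, 15), patient_id="P0",
        )
        base.update(kw)
        return VariantObservation(**base)

    def test_balanced_deep_variant_kept(self):
        out = filter_somatic([self._s()], set(), set())
        assert len(out.kept) == 1

    def test_depth_below_ten_removed(self):
        v = self._s(tumor_ref_count=5, tumor_alt_count=4,
                    strand_alt_counts=(2, 2))
        out = filter_somatic([v], set(), set())
        assert out.removed[0][1] == "iv:low-depth"
        kept = self._s(tumor_ref_count=5, tumor_alt_count=5,
                       strand_alt_counts=(3, 2))
        assert filter_somatic([kept], set(), set()).kept

    def test_extreme_strand_skew_removed(self):
        v = self._s(tumor_alt_count=12, strand_alt_counts=(12, 0))
        out = filter_somatic([v], set(), set())
        assert out.removed[0][1] == "i:strand-bias"

    def test_few_alt_reads_not_strand_tested(self):
        v = self._s(tumor_alt_count=5, strand_alt_counts=(5, 0))
        assert filter_somatic([v], set(), set()).kept

    def test_germline_origin_removed(self):
        v = self._s()
        out = filter_somatic([v], set(), {v.key})
        assert out.removed[0][1] == "ii:germline-origin"

    def test_pon_membership_removed(self):
        v = self._s()
        out = filter_somatic([v], {v.key}, set())
        assert out.removed[0][1] == "iii:panel-of-normals"

    def test_strand_test_uses_reference_strand_ratio(self):
        # ALT all-forward is unremarkable when REF reads are also all-forward
        v = self._s(tumor_alt_count=12, strand_alt_counts=(12, 0),
                    strand_ref_counts=(50, 0))
        assert filter_somatic([v], set(), set()).kept


class TestPartitionAndOrderIndependence:
    def test_partition(self, small_cohort):
        germ = small_cohort.germline
        out = filter_germline_quality(germ)
        assert len(out.kept) + len(out.removed) == len(germ)
        kept_ids = {id(v) for v in out.kept}
        removed_ids = {id(v) for v, _ in out.removed}
        assert not (kept_ids & removed_ids)

    def test_order_independence(self, small_cohort, gene_lists):
        germ = list(small_cohort.germline)
        fwd, _ = select_germline_candidates(germ, gene_lists)
        rev, _ = select_germline_candidates(list(reversed(germ)), gene_lists)
        assert {id(v) for v, _ in fwd} == {id(v) for v, _ in rev}
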