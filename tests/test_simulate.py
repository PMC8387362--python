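"""The synthetic cohort generator: read-count models, scar-target profiles,
artifact injection, determinism and ground-truth completeness."""

import numpy as np
import pytest

from hrdscan.filters import filter_somatic
from hrdscan.genome import hg19_autosomes
from hrdscan.scars import scar_scores
from hrdscan.secondhit import allelic_imbalance_test
from hrdscan.simulate import (
    ScarTargetInfeasibleError,
    SimulationConfig,
    expected_tumor_vaf,
    inject_ffpe_artifacts,
    simulate_catalog,
    simulate_cohort,
    simulate_read_counts,
    simulate_segments,
    simulate_tumor_counts_at_locus,
    spike_causal_scenario,
)


class TestReadCounts:
    def test_pairs_sum_to_depth(self, rng):
        for _ in range(200):
            depth = int(rng.integers(1, 300))
            ref, alt = simulate_read_counts(rng.uniform(), depth, 0.05, rng)
            assert ref + alt == depth

    def test_degenerate_fractions(self):
        assert simulate_read_counts(0.0, 50) == (50, 0)
        assert simulate_read_counts(1.0, 50) == (0, 50)

    def test_binomial_mean(self, rng):
        draws = [simulate_read_counts(0.5, 200, 0.0, rng)[1] for _ in range(10_000)]
        se = np.sqrt(200 * 0.25) / np.sqrt(10_000)
        assert abs(np.mean(draws) - 100) < 3 * se

    def test_beta_binomial_variance(self, rng):
        # var = n p (1-p) (1 + (n-1) rho) = 25 * (1 + 99*0.1) = 272.5
        draws = [simulate_read_counts(0.5, 100, 0.1, rng)[1] for _ in range(10_000)]
        assert np.var(draws) == pytest.approx(272.5, rel=0.10)

    @pytest.mark.parametrize(
        "af,depth,rho",
        [(-0.1, 50, 0.0), (1.1, 50, 0.0), (0.5, -1, 0.0), (0.5, 50, 1.0)],
    )
    def test_invalid_parameters(self, af, depth, rho):
        with pytest.raises(ValueError):
            simulate_read_counts(af, depth, rho)


class TestTumorCounts:
    def test_pure_tumor_cnloh_vaf_one(self):
        assert expected_tumor_vaf(1.0, 2, 2) == 1.0

    def test_del_loh_half_purity(self):
        # (0.5*1 + 0.5*1) / (0.5*1 + 0.5*2) = 2/3
        assert expected_tumor_vaf(0.5, 1, 1) == pytest.approx(2 / 3)

    def test_zero_purity_is_heterozygous(self):
        assert expected_tumor_vaf(0.0, 5, 3) == 0.5

    def test_variant_cn_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            simulate_tumor_counts_at_locus(0.5, 0.6, total_cn=2, variant_cn=3,
                                           depth=100)

    def test_reference_bias_applied_at_half(self):
        assert expected_tumor_vaf(0.0, 2, 1, germline_af=0.47) == pytest.approx(0.47)


class TestCatalogSimulation:
    def test_single_signature_frequencies(self, matrix, rng):
        cat = simulate_catalog({"Signature_2": 1.0}, 10_000, matrix, rng)
        freq = cat.counts / cat.counts.sum()
        assert np.max(np.abs(freq - matrix.column("Signature_2"))) < 0.01

    def test_zero_mutations(self, matrix):
        cat = simulate_catalog({"Signature_3": 1.0}, 0, matrix)
        assert cat.n_mutations == 0

    def test_catalog_sums_to_n(self, matrix, rng):
        cat = simulate_catalog({"Signature_3": 0.5, "Signature_5": 0.5},
                               777, matrix, rng)
        assert cat.n_mutations == 777

    def test_exposures_must_sum_to_one(self, matrix):
        with pytest.raises(ValueError):
            simulate_catalog({"Signature_3": 0.5}, 10, matrix)

    def test_nnls_round_trip(self, matrix, rng):
        from hrdscan.signatures import fit_signature_exposures

        cat = simulate_catalog(
            {"Signature_3": 0.6, "Signature_8": 0.4}, 50_000, matrix, rng
        )
        fit = fit_signature_exposures(cat, matrix)
        assert fit.fractions["Signature_3"] == pytest.approx(0.6, abs=0.02)
        assert fit.fractions["Signature_8"] == pytest.approx(0.4, abs=0.02)


class TestSegmentTargets:
    @pytest.mark.parametrize(
        "targets",
        [(0, 0, 0), (3, 0, 0), (0, 5, 0), (0, 0, 4), (20, 15, 8), (24, 12, 8)],
    )
    def test_targets_hit_exactly(self, targets, layout):
        segs = simulate_segments(targets, layout)
        assert scar_scores(segs, layout).as_tuple() == targets

    def test_profile_tiles_every_chromosome(self, layout):
        segs = simulate_segments((2, 2, 2), layout)
        by_chrom = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for c in layout.chromosomes:
            parts = sorted(by_chrom[c.name], key=lambda s: s.start)
            assert parts[0].start == 1 and parts[-1].end == c.length
            for a, b in zip(parts, parts[1:]):
                assert b.start == a.end + 1

    def test_zero_targets_is_diploid(self, layout):
        segs = simulate_segments((0, 0, 0), layout)
        assert all(s.state == (2, 1) for s in segs)

    def test_infeasible_targets_raise(self, layout):
        with pytest.raises(ScarTargetInfeasibleError):
            simulate_segments((0, 0, 100), layout)  # more TAI than telomeres
        with pytest.raises(ScarTargetInfeasibleError):
            simulate_segments((-1, 0, 0), layout)

    def test_scar_positive_example(self, layout):
        from hrdscan.scars import call_scar_hrd

        segs = simulate_segments((20, 15, 8), layout)
        s = scar_scores(segs, layout)
        assert call_scar_hrd(s.hrd_loh, s.lst, s.tai) is True


class TestArtifacts:
    def test_rate_zero_identity(self):
        out, keys = inject_ffpe_artifacts([], 0.0, seed=1)
        assert out == [] and keys == set()

    def test_injected_records_are_ct_and_strand_skewed(self, rng):
        out, keys = inject_ffpe_artifacts([], 2.0, seed=rng)
        assert keys
        for v in out:
            assert (v.ref_allele, v.alt_allele) in (("C", "T"), ("G", "A"))
            fwd, rev = v.strand_alt_counts
            assert max(fwd, rev) >= 0.9 * (fwd + rev)

    def test_artifacts_removed_by_somatic_filters_on_cohort(self):
        """Injected artifacts must be overwhelmingly removed by the somatic
        filters on a 10-patient cohort."""
        cohort = simulate_cohort(SimulationConfig(n_patients=10, seed=77))
        removed = kept = 0
        for pid in cohort.patient_ids:
            som = [v for v in cohort.somatic if v.patient_id == pid]
            matched = {v.key for v in cohort.germline if v.patient_id == pid}
            out = filter_somatic(som, cohort.pon, matched)
            kept_keys = {v.key for v in out.kept}
            truth = cohort.truth.patients[pid]
            removed += len(truth.artifact_keys - kept_keys)
            kept += len(truth.artifact_keys & kept_keys)
        assert removed / (removed + kept) >= 0.95

    def test_true_somatic_variants_survive_filters(self):
        """True clonal SNVs at adequate VAF and depth are almost all kept."""
        cohort = simulate_cohort(SimulationConfig(n_patients=10, seed=78))
        total = kept = 0
        for pid in cohort.patient_ids:
            som = [v for v in cohort.somatic if v.patient_id == pid]
            matched = {v.key for v in cohort.germline if v.patient_id == pid}
            kept_keys = {v.key for v in filter_somatic(som, cohort.pon, matched).kept}
            truth = cohort.truth.patients[pid]
            for v in som:
                if v.key not in truth.true_somatic_keys:
                    continue
                if (v.tumor_af or 0) >= 0.2 and (v.tumor_depth or 0) >= 30:
                    total += 1
                    kept += v.key in kept_keys
        assert total > 0
        assert kept / total >= 0.95


class TestSpike:
    def test_spiked_locus_shows_allelic_imbalance(self, gene_intervals, layout):
        """The spiked CN-LOH locus yields a significant allelic-imbalance
        test in nearly all replicates at default depths."""
        cfg = SimulationConfig()
        hits = 0
        n = 100
        for i in range(n):
            rng = np.random.default_rng(9000 + i)
            v, _, _ = spike_causal_scenario("P0", "RAD51D", cfg, gene_intervals,
                                            layout, rng)
            p = allelic_imbalance_test(
                v.germline_ref_count, v.germline_alt_count,
                v.tumor_ref_count, v.tumor_alt_count,
            )
            hits += p <= 0.05
        assert hits / n >= 0.95

    def test_spiked_scar_targets_meet_threshold(self, gene_intervals, layout):
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        _, segs, truth = spike_causal_scenario("P0", "BRCA2", cfg, gene_intervals,
                                               layout, rng)
        assert sum(truth.scar) >= 42
        assert scar_scores(segs, layout).as_tuple() == truth.scar

    def test_unknown_gene_rejected(self, gene_intervals, layout):
        with pytest.raises(ValueError):
            spike_causal_scenario("P0", "NOT_A_GENE", SimulationConfig(),
                                  gene_intervals, layout,
                                  np.random.default_rng(0))


class TestCohort:
    def test_determinism(self):
        from hrdscan.io import variants_to_frame

        cfg = SimulationConfig(n_patients=4, seed=5)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert variants_to_frame(a.germline).equals(variants_to_frame(b.germline))
        assert variants_to_frame(a.somatic).equals(variants_to_frame(b.somatic))
        assert a.segments == b.segments
        assert a.pon == b.pon

    def test_ground_truth_completeness(self):
        cfg = SimulationConfig(n_patients=20, causal_fraction=0.1, seed=3)
        cohort = simulate_cohort(cfg)
        assert len(cohort.truth.spiked_patients) == round(0.1 * 20) == cfg.n_spiked

    def test_read_pairs_conserve_depth(self, small_cohort):
        for v in small_cohort.germline:
            assert v.germline_depth == v.germline_ref_count + v.germline_alt_count

    def test_ground_truth_not_in_emitted_tables(self, small_cohort):
        from hrdscan.io import variants_to_frame

        frame = variants_to_frame(small_cohort.somatic)
        assert "artifact" not in " ".join(frame.columns).lower()
        assert "causal" not in " ".join(frame.columns).lower()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(tumor_purity=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(overdispersion=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(causal_fraction=1.5)
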