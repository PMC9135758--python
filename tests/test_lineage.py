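import numpy as np
import pytest
from hypothesis import given, strategies as st

from lesionlineage.clonal_inference import TypedSegment
from lesionlineage.genome import make_genome
from lesionlineage.lineage import (
    UndefinedCorrelationError,
    call_lineage,
    cnv_correlation,
    copy_number_profile,
    shared_feature_analysis,
)
from lesionlineage.states import GenotypeState
from lesionlineage.synthetic_data import SimConfig, bin_state_map, simulate_pair

LAYOUT = make_genome(1, 2_000_000, 10_000)  # 200 bins


def seg(start_bin, end_bin, c, a, cluster, chrom="chr1"):
    return TypedSegment(
        chrom=chrom, start=start_bin * 10_000, end=end_bin * 10_000,
        genotype=GenotypeState(c, a), cluster=cluster,
        mean_log_ratio=0.0, mean_allelic_ratio=0.5, n_loci=end_bin - start_bin,
    )


class TestCnvCorrelation:
    def test_identical_profiles_correlate_perfectly(self):
        p = np.array([2.0, 3, 2, 1, 2, 4])
        assert cnv_correlation(p, p) == pytest.approx(1.0)

    def test_negated_profile_anticorrelates(self):
        p = np.array([0.5, -0.3, 0.8, 0.0])
        assert cnv_correlation(p, -p) == pytest.approx(-1.0)

    @given(st.integers(0, 50))
    def test_agrees_with_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 100))
        manual = float(
            np.sum((a - a.mean()) * (b - b.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        assert cnv_correlation(a, b) == pytest.approx(manual, abs=1e-12)

    def test_constant_profile_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            cnv_correlation(np.ones(10), np.arange(10.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cnv_correlation(np.arange(3.0), np.arange(4.0))


class TestSharedFeatures:
    def test_identical_segments_share_everything(self):
        segs = [seg(0, 50, 3, 1, 1), seg(50, 200, 2, 1, 1)]
        report = shared_feature_analysis(segs, segs, LAYOUT)
        assert report.top_pair.shared_fraction == 1.0
        assert report.top_pair.n_shared == 50

    def test_disjoint_alterations_share_nothing(self):
        a = [seg(0, 50, 1, 0, 1), seg(50, 200, 2, 1, 1)]
        b = [seg(0, 100, 2, 1, 1), seg(100, 150, 1, 0, 1), seg(150, 200, 2, 1, 1)]
        report = shared_feature_analysis(a, b, LAYOUT)
        assert report.top_pair.shared_fraction == 0.0

    def test_half_overlapping_gain_counts(self):
        """A: GAIN bins 0-99 (cluster 2); B: GAIN bins 50-149 (cluster 1):
        pair (2,1) shares 50 bins, 50 unique each side, fraction 1/3."""
        a = [seg(0, 100, 3, 1, 2), seg(100, 200, 2, 1, 1)]
        b = [seg(0, 50, 2, 1, 1), seg(50, 150, 3, 1, 1), seg(150, 200, 2, 1, 1)]
        report = shared_feature_analysis(a, b, LAYOUT)
        pair = {(p.cluster_a, p.cluster_b): p for p in report.pairs}[(2, 1)]
        assert (pair.n_shared, pair.n_unique_a, pair.n_unique_b) == (50, 50, 50)
        assert pair.shared_fraction == pytest.approx(1 / 3)

    def test_same_locus_different_type_not_shared(self):
        a = [seg(0, 50, 3, 1, 1), seg(50, 200, 2, 1, 1)]   # GAIN
        b = [seg(0, 50, 2, 0, 1), seg(50, 200, 2, 1, 1)]   # NLOH
        report = shared_feature_analysis(a, b, LAYOUT)
        assert report.top_pair.n_shared == 0

    def test_swapping_lesions_transposes_and_preserves_counts(self):
        a = [seg(0, 80, 3, 1, 1), seg(80, 120, 1, 0, 2), seg(120, 200, 2, 1, 1)]
        b = [seg(0, 40, 3, 1, 2), seg(40, 200, 2, 1, 1)]
        fwd = shared_feature_analysis(a, b, LAYOUT)
        rev = shared_feature_analysis(b, a, LAYOUT)
        fwd_map = {(p.cluster_a, p.cluster_b): p.n_shared for p in fwd.pairs}
        rev_map = {(p.cluster_b, p.cluster_a): p.n_shared for p in rev.pairs}
        assert fwd_map == rev_map

    def test_all_diploid_report_is_flagged_empty(self):
        a = [seg(0, 200, 2, 1, 1)]
        report = shared_feature_analysis(a, a, LAYOUT)
        assert report.empty and report.top_pair is None
        assert report.top_shared_fraction == 0.0


class TestLineageCall:
    def test_high_correlation_is_parallel(self):
        report = shared_feature_analysis(
            [seg(0, 200, 2, 1, 1)], [seg(0, 200, 2, 1, 1)], LAYOUT
        )
        assert call_lineage(0.95, report).verdict == "parallel"

    def test_no_evidence_is_independent(self):
        a = [seg(0, 50, 1, 0, 1), seg(50, 200, 2, 1, 1)]
        b = [seg(0, 100, 2, 1, 1), seg(100, 150, 1, 0, 1), seg(150, 200, 2, 1, 1)]
        report = shared_feature_analysis(a, b, LAYOUT)
        assert call_lineage(0.1, report).verdict == "independent"

    def test_subclonal_sharing_alone_is_parallel(self):
        """A pair can lack global CNV correlation yet share founder features
        in one small subclone; the disjunctive rule calls it parallel."""
        a = [seg(0, 70, 3, 1, 2), seg(70, 200, 2, 1, 1)]
        b = [seg(0, 70, 3, 1, 1), seg(70, 100, 1, 0, 1), seg(100, 200, 2, 1, 1)]
        report = shared_feature_analysis(a, b, LAYOUT)
        call = call_lineage(0.3, report)
        assert report.top_shared_fraction == pytest.approx(0.7)
        assert call.verdict == "parallel"

    def test_undefined_evidence_demands_review(self):
        report = shared_feature_analysis(
            [seg(0, 200, 2, 1, 1)], [seg(0, 200, 2, 1, 1)], LAYOUT
        )
        with pytest.raises(ValueError):
            call_lineage(None, report)

    def test_copy_number_profile_rasterization(self):
        segs = [seg(0, 10, 3, 1, 1), seg(10, 150, 2, 1, 1), seg(150, 200, 1, 0, 1)]
        prof = copy_number_profile(segs, LAYOUT)
        assert list(np.unique(prof[:10])) == [3.0]
        assert list(np.unique(prof[10:150])) == [2.0]
        assert list(np.unique(prof[150:])) == [1.0]


class TestRawProfileMonotonicity:
    def test_more_founder_events_never_lowers_expected_correlation(self):
        """Mean log-ratio-track correlation over replicates must grow with the
        founder event count in the parallel scenario."""
        mean_r = []
        for n_shared in (4, 12, 24):
            rs = []
            for rep in range(3):
                cfg = SimConfig(
                    n_chrom=1, chrom_len=20_000_000, n_het_sites=200,
                    n_shared_events=n_shared, n_private_events=2,
                    prevalences_A=(1.0,), prevalences_B=(1.0,),
                    event_len_bins=(20, 60),
                )
                truth, obs = simulate_pair("parallel", 50 + rep, cfg)
                a = truth.layout.log_ratio_vector(obs["A"][0])
                b = truth.layout.log_ratio_vector(obs["B"][0])
                rs.append(cnv_correlation(a, b))
            mean_r.append(np.mean(rs))
        assert mean_r[0] <= mean_r[1] <= mean_r[2]
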