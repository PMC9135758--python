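import logging

import numpy as np
import pytest

from conftest import assert_monotone
from oracle_hmm import enumerate_paths

from lesionlineage.clonal_inference import (
    ClonalModel,
    EMParams,
    LocusData,
    build_locus_grid,
    e_step,
    emission_log_matrix,
    fit_em,
    m_step,
    select_n_clusters,
    typed_segments,
)
from lesionlineage.genome import make_genome
from lesionlineage.hmm import structured_transition
from lesionlineage.states import GenotypeState, enumerate_states
from lesionlineage.synthetic_data import SimConfig, simulate_pair

STATES4 = enumerate_states(4)


def make_data(lr, ref=None, depth=None):
    """LocusData on a single chromosome, one locus per bin."""
    T = len(lr)
    ref = np.zeros(T, np.int64) if ref is None else np.asarray(ref, np.int64)
    depth = np.zeros(T, np.int64) if depth is None else np.asarray(depth, np.int64)
    return LocusData(
        chrom=np.zeros(T, np.int32),
        position=np.arange(T, dtype=np.int64) * 10_000,
        bin_index=np.arange(T, dtype=np.int64),
        log_ratio=np.asarray(lr, float),
        ref_count=ref,
        depth=depth,
        chrom_ranges=[(0, T)],
    )


def noiseless_data(assignments, phi, depth=1_000_000):
    """Loci exactly at the emission means of known (state, cluster) truth.

    ``assignments``: list of (state_index, cluster_index) per locus; binomial
    counts are rounded expectations at very high depth, so sampling error is
    negligible relative to 1e-3 parameter tolerances.
    """
    from lesionlineage.states import logratio_from_phi, reffraction_from_phi

    lr, ref, dep = [], [], []
    for g, z in assignments:
        st = STATES4[g]
        lr.append(logratio_from_phi(st.c, phi[z]))
        p = reffraction_from_phi(st.c, st.a, phi[z])
        ref.append(round(depth * p))
        dep.append(depth)
    return make_data(lr, ref, dep)


class TestEStepAgainstBruteForce:
    def test_single_locus_posterior_is_normalized_emission(self):
        params = EMParams(phi=np.array([0.7]), sigma=0.1)
        data = make_data([0.2], [20], [30])
        gamma, ll = e_step(data, params)
        log_emit = emission_log_matrix(data, params, STATES4)
        expected = np.exp(log_emit[0] - log_emit[0].max())
        expected /= expected.sum()
        assert np.allclose(gamma[0], expected, atol=1e-12)
        assert np.isfinite(ll)

    def test_two_cluster_chain_equals_exhaustive_enumeration(self):
        """5 loci, 2 clusters on the c_max=2 state space (10 joint states):
        posteriors and likelihood must match the sum over all 10^5 paths."""
        rng = np.random.default_rng(1)
        states = enumerate_states(2)
        params = EMParams(phi=np.array([0.7, 0.35]), sigma=0.15, rho=0.95)
        data = make_data(
            rng.normal(0, 0.3, 5), rng.integers(5, 25, 5), np.full(5, 30)
        )
        log_emit = emission_log_matrix(data, params, states)
        gamma, ll = e_step(data, params, states)
        oracle_gamma, oracle_ll, _ = enumerate_paths(
            log_emit, structured_transition(10, 0.95)
        )
        assert ll == pytest.approx(oracle_ll, abs=1e-8)
        assert np.allclose(gamma, oracle_gamma, atol=1e-8)

    def test_full_state_space_equals_exhaustive_enumeration(self):
        """3 loci over the full 14x2=28 joint states (28^3 paths)."""
        rng = np.random.default_rng(2)
        params = EMParams(phi=np.array([0.6, 0.2]), sigma=0.2, rho=0.99)
        data = make_data(
            rng.normal(0, 0.4, 3), rng.integers(5, 25, 3), np.full(3, 30)
        )
        log_emit = emission_log_matrix(data, params, STATES4)
        gamma, ll = e_step(data, params)
        oracle_gamma, oracle_ll, _ = enumerate_paths(
            log_emit, structured_transition(28, 0.99)
        )
        assert ll == pytest.approx(oracle_ll, abs=1e-8)
        assert np.allclose(gamma, oracle_gamma, atol=1e-8)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(3)
        params = EMParams(phi=np.array([0.7, 0.3]), sigma=0.15)
        data = make_data(rng.normal(0, 0.3, 100), rng.integers(0, 30, 100),
                         np.full(100, 30))
        gamma, _ = e_step(data, params)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_sharp_emissions_concentrate_posterior(self):
        """Data exactly at one state's means with tiny sigma puts all mass there."""
        phi = np.array([0.7])
        g = STATES4.index(GenotypeState(3, 2))
        data = noiseless_data([(g, 0)] * 5, phi, depth=100_000)
        gamma, _ = e_step(data, EMParams(phi=phi, sigma=1e-4))
        assert np.all(gamma[:, g] > 0.999)


class TestMStep:
    def test_noiseless_parameters_recovered(self):
        """Responsibilities concentrated on the truth recover phi to <= 1e-3."""
        truth = np.array([0.7, 0.196])
        assigns = (
            [(STATES4.index(GenotypeState(1, 1)), 0)] * 200
            + [(STATES4.index(GenotypeState(3, 2)), 1)] * 200
            + [(STATES4.index(GenotypeState(2, 1)), 0)] * 100
        )
        data = noiseless_data(assigns, truth)
        params = EMParams(phi=truth.copy(), sigma=0.05)
        gamma, _ = e_step(data, params)
        new = m_step(data, gamma, params)
        assert np.allclose(new.phi, truth, atol=1e-3)

    def test_em_fixed_point_on_noiseless_data(self):
        truth = np.array([0.7, 0.35])
        assigns = (
            [(STATES4.index(GenotypeState(1, 0)), 0)] * 150
            + [(STATES4.index(GenotypeState(3, 1)), 1)] * 150
            + [(STATES4.index(GenotypeState(2, 1)), 0)] * 100
        )
        data = noiseless_data(assigns, truth)
        model = fit_em(data, 2, init=EMParams(phi=truth.copy(), sigma=0.05))
        assert np.allclose(model.phi, truth, atol=1e-3)
        assert model.converged

    def test_diploid_only_data_warns_and_keeps_phi(self, caplog):
        """A purely diploid lesion carries no contamination signal."""
        het = STATES4.index(GenotypeState(2, 1))
        data = noiseless_data([(het, 0)] * 200, np.array([0.5]), depth=1000)
        params = EMParams(phi=np.array([0.5]), sigma=0.1)
        gamma, _ = e_step(data, params)
        with caplog.at_level(logging.WARNING, logger="lesionlineage.clonal_inference"):
            new = m_step(data, gamma, params)
        assert new.phi[0] == pytest.approx(0.5)
        assert any("unidentifiable" in r.message for r in caplog.records)

    def test_likelihood_trace_non_decreasing(self, small_config):
        truth, obs = simulate_pair("parallel", 21, small_config)
        bins, sites = obs["A"]
        data = build_locus_grid(bins, sites, truth.layout)
        model = fit_em(data, 2)
        assert_monotone(model.ll_trace)


class TestFitAndSelect:
    def test_contamination_recovered_at_small_scale(self, small_pair):
        truth, obs = small_pair
        bins, sites = obs["A"]
        data = build_locus_grid(bins, sites, truth.layout)
        model = fit_em(data, 2)
        assert model.normal_fraction == pytest.approx(0.30, abs=0.05)
        assert model.clusters[0][1] == 1.0  # top cluster clonal by convention
        s = [p for _, p in model.clusters]
        assert s == sorted(s, reverse=True)

    def test_single_clone_data_selects_one_cluster(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, prevalences_A=(1.0,), prevalences_B=(1.0,))
        truth, obs = simulate_pair("parallel", 31, cfg)
        bins, sites = obs["A"]
        data = build_locus_grid(bins, sites, truth.layout)
        model = select_n_clusters(data, z_max=2)
        assert model.n_clusters == 1

    def test_two_subclone_data_selects_two_clusters(self):
        """Model selection needs enough loci for the BIC penalty to dominate
        boundary noise; a 30 Mb chromosome with ~2,500 loci suffices."""
        cfg = SimConfig(
            n_chrom=1, chrom_len=30_000_000, n_het_sites=2000,
            n_shared_events=6, n_private_events=6, event_len_bins=(50, 120),
        )
        truth, obs = simulate_pair("parallel", 31, cfg)
        bins, sites = obs["A"]
        data = build_locus_grid(bins, sites, truth.layout)
        model = select_n_clusters(data, z_max=3)
        assert model.n_clusters == 2

    def test_flat_likelihood_prefers_fewer_clusters(self):
        """All-diploid data: every Z has (near) equal likelihood, so the BIC
        penalty must pick Z=1."""
        het = STATES4.index(GenotypeState(2, 1))
        data = noiseless_data([(het, 0)] * 300, np.array([0.5]), depth=100)
        model = select_n_clusters(data, z_max=3)
        assert model.n_clusters == 1

    def test_invalid_cluster_counts_rejected(self):
        data = make_data([0.0, 0.1])
        with pytest.raises(ValueError):
            fit_em(data, 0)
        with pytest.raises(ValueError):
            select_n_clusters(data, 0)


def _model_from_path(data, map_state, map_cluster, phi=(0.7,)):
    phi = np.array(phi)
    n = 1.0 - phi.max()
    return ClonalModel(
        normal_fraction=n,
        clusters=[(z + 1, float(p / phi.max())) for z, p in enumerate(phi)],
        phi=phi, sigma=0.1, rho=0.999,
        map_state=np.asarray(map_state, np.int32),
        map_cluster=np.asarray(map_cluster, np.int32),
        states=STATES4,
        log_likelihood=0.0, ll_trace=[0.0], n_iterations=1, converged=True,
        data=data,
    )


class TestTypedSegments:
    layout = make_genome(1, 200_000, 10_000)  # 20 bins

    def test_all_het_is_one_segment_per_chromosome(self):
        het = STATES4.index(GenotypeState(2, 1))
        data = make_data(np.zeros(20))
        model = _model_from_path(data, [het] * 20, [1] * 20)
        segs = typed_segments(model, self.layout)
        assert len(segs) == 1
        assert segs[0].genotype.loh_label == "HET"
        assert (segs[0].start, segs[0].end) == (0, 200_000)

    def test_single_gain_block_in_cluster_two(self):
        het = STATES4.index(GenotypeState(2, 1))
        gain = STATES4.index(GenotypeState(3, 1))
        state = [het] * 5 + [gain] * 6 + [het] * 9
        cluster = [1] * 5 + [2] * 6 + [1] * 9
        model = _model_from_path(make_data(np.zeros(20)), state, cluster, phi=(0.7, 0.3))
        segs = typed_segments(model, self.layout)
        amp = [s for s in segs if s.genotype.cnv_label == "AMP"]
        assert len(segs) == 3
        assert len(amp) == 1
        assert amp[0].cluster == 2
        assert amp[0].genotype.loh_label == "GAIN"
        assert (amp[0].start, amp[0].end) == (50_000, 110_000)
        assert amp[0].n_loci == 6

    def test_alternating_assignment_gives_segment_per_locus(self):
        het = STATES4.index(GenotypeState(2, 1))
        nloh = STATES4.index(GenotypeState(2, 0))
        state = [het, nloh] * 10
        model = _model_from_path(make_data(np.zeros(20)), state, [1] * 20)
        segs = typed_segments(model, self.layout)
        assert len(segs) == 20

    def test_segments_sorted_nonoverlapping_and_distinct(self, small_pair):
        truth, obs = small_pair
        bins, sites = obs["A"]
        data = build_locus_grid(bins, sites, truth.layout)
        model = fit_em(data, 2)
        segs = typed_segments(model, truth.layout)
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom:
                assert a.end == b.start
                assert (a.genotype, a.cluster) != (b.genotype, b.cluster)
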