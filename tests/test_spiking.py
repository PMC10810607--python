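"""Clustered E-I LIF network: architecture, dynamics, mean field, modes."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import timescale_reservoir as tr
from timescale_reservoir import spiking
from timescale_reservoir.rate import ValidationError


class TestDerivedParams:
    def test_assembly_count_and_factors_n2000(self):
        base = spiking.SpikingParams(N=2000)
        cl = spiking.derive_clustered_params(base, seed=0)
        assert cl.p == 18
        # JEI+ = p / (1 + (p-1)/gEI) with gEI = 10
        assert cl.JEI_plus == pytest.approx(18 / (1 + 17 / 10), rel=1e-12)
        assert cl.JEI_minus == pytest.approx(cl.JEI_plus / 10, rel=1e-12)
        assert cl.JIE_minus == pytest.approx(
            (18 / (1 + 17 / 8)) / 8, rel=1e-12
        )
        assert cl.JEE_plus == 14.0
        # sizes sum exactly to the clustered E total
        assert cl.sizes_E.sum() == int(0.8 * 2000 * 0.9)
        assert np.all(cl.sizes_I == np.round(cl.sizes_E / 4))

    def test_table_scalings_n10000(self):
        base = spiking.SpikingParams(N=10000)
        cl = spiking.derive_clustered_params(base, seed=0)
        assert base.NEclust_mean == 160.0
        assert cl.JEE_plus == pytest.approx(14 * 10000 / 2000)

    def test_small_network_rejected(self):
        with pytest.raises(ValidationError):
            spiking.derive_clustered_params(spiking.SpikingParams(N=500), 0)


class TestBuildNetwork:
    def test_homogeneous_weight_values(self):
        # one weight per (pre, post) type pair; E->E and E->I share the
        # same table magnitude, so three distinct values remain
        pr = spiking.SpikingParams(N=1000)
        net = spiking.build_spiking_network(pr, seed=1, clustered=False)
        vals = set(np.unique(net.W[net.W != 0.0]).round(12))
        expect = {
            round(v, 12)
            for v in (pr.JEE, pr.JIE, -pr.JEI, -pr.JII)
        }
        assert vals == expect

    def test_connection_density_binomial(self, clustered_net):
        net = clustered_net
        ee = net.W[np.ix_(net.is_E, net.is_E)]
        n_pairs = ee.size - net.is_E.sum()  # diagonal excluded
        dens = (ee != 0).sum() / n_pairs
        se = math.sqrt(0.2 * 0.8 / n_pairs)
        assert abs(dens - 0.2) < 3 * se

    def test_intra_assembly_weight_rule(self, clustered_net):
        net = clustered_net
        cl = net.clustered
        ids = np.nonzero(net.is_E & (net.membership == 1))[0]
        blk = net.W[np.ix_(ids, ids)]
        w = blk[blk != 0]
        assert np.allclose(w, net.params.JEE * cl.JEE_plus)

    def test_sign_convention(self, clustered_net):
        net = clustered_net
        from_E = net.W[:, net.is_E]
        from_I = net.W[:, ~net.is_E]
        assert np.all(from_E >= 0)
        assert np.all(from_I <= 0)

    def test_seed_determinism(self):
        p = spiking.SpikingParams(N=1000)
        a = spiking.build_spiking_network(p, seed=5)
        b = spiking.build_spiking_network(p, seed=5)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.membership, b.membership)


class TestLIFSimulation:
    def test_silent_below_rheobase(self):
        pr = spiking.SpikingParams(N=1000, rext=0.05)
        net = spiking.build_spiking_network(pr, seed=0, clustered=False)
        net.W[:] = 0.0
        spk = spiking.simulate_lif(net, 500.0, seed=1)
        assert spk.times.size == 0

    def test_deterministic_rate_closed_form(self):
        # single suprathreshold neuron: rate
        # 1/(tau_refr + tau_m ln[(mu tau_m - Vr)/(mu tau_m - Vthr)])
        pr = spiking.SpikingParams(N=2000)
        net = spiking.build_spiking_network(pr, seed=0, clustered=False)
        net.W[:] = 0.0
        spk = spiking.simulate_lif(net, 5000.0, dt=0.05, seed=2)
        ids_E = np.nonzero(net.is_E)[0]
        rate_sim = np.isin(spk.ids, ids_E).sum() / ids_E.size / 5.0
        mu = pr.Next * pr.JE0 * pr.rext / 1000.0 * pr.tau_m  # mV
        t_isi = pr.tau_refr + pr.tau_m * math.log(mu / (mu - pr.VEthr))
        assert rate_sim == pytest.approx(1000.0 / t_isi, rel=0.02)

    def test_refractory_invariant_and_determinism(self, clustered_net):
        spk = spiking.simulate_lif(clustered_net, 2000.0, seed=3)
        for nid in np.unique(spk.ids)[:50]:
            isi = np.diff(spk.times[spk.ids == nid])
            assert np.all(isi >= clustered_net.params.tau_refr - 1e-9)
        spk2 = spiking.simulate_lif(clustered_net, 2000.0, seed=3)
        assert np.array_equal(spk.times, spk2.times)
        assert np.array_equal(spk.ids, spk2.ids)


class TestTransferFunction:
    def test_subthreshold_limit(self):
        pr = spiking.SpikingParams()
        assert spiking.lif_transfer_rate(-5.0, 0.2, 1.43, pr) == 0.0

    def test_refractory_ceiling(self):
        pr = spiking.SpikingParams()
        r = spiking.lif_transfer_rate(500.0, 1.0, 1.43, pr)
        assert r == pytest.approx(1000.0 / pr.tau_refr, rel=0.05)

    def test_against_single_neuron_simulation(self):
        # white-noise-driven LIF ensemble vs the transfer formula; the
        # formula's sigma is the input convention, sqrt(2) times the
        # stationary membrane-potential dispersion
        pr0 = spiking.SpikingParams(a_bs=0.0)  # no synaptic filter
        tm, thr, tref = 20.0, pr0.VEthr, pr0.tau_refr
        dt = 0.01
        rng = np.random.default_rng(0)
        for mu_mv, sd_mv in [(1.2, 0.4), (1.5, 0.3), (1.0, 0.6)]:
            n = 100
            steps = int(3000.0 / dt)
            V = np.zeros(n)
            refr = np.zeros(n)
            count = 0
            a = sd_mv * math.sqrt(2 * dt / tm)
            for _ in range(steps):
                active = refr <= 0
                refr[~active] -= dt
                V[active] += (mu_mv - V[active]) / tm * dt + a * (
                    rng.standard_normal(int(active.sum()))
                )
                fired = active & (V >= thr)
                count += fired.sum()
                V[fired] = 0.0
                refr[fired] = tref
            rate_sim = count / n / (steps * dt / 1000.0)
            rate_th = spiking.lif_transfer_rate(
                mu_mv, math.sqrt(2.0) * sd_mv, thr, pr0
            )
            assert rate_sim == pytest.approx(rate_th, rel=0.05)


class TestMeanField:
    def test_balanced_state_rates(self):
        pr = spiking.SpikingParams(N=2000)
        rE, rI = spiking.mf_rates_homogeneous(pr)
        assert rE == pytest.approx(2.0, rel=0.15)
        assert rI == pytest.approx(5.0, rel=0.15)

    def test_threshold_calibration_matches_table(self):
        pr = spiking.SpikingParams(N=2000)
        vE, vI = spiking.calibrate_thresholds(pr, target=(2.0, 5.0))
        assert abs(vE - 1.43) < 0.1
        assert abs(vI - 0.74) < 0.1

    def test_rates_increase_with_drive(self):
        pr = spiking.SpikingParams(N=2000)
        r1 = spiking.mf_rates_homogeneous(pr)
        r2 = spiking.mf_rates_homogeneous(
            spiking.SpikingParams(N=2000, rext=10.0), r0=(20.0, 30.0)
        )
        assert r2[0] > r1[0] and r2[1] > r1[1]

    def test_inhibition_keeps_mean_drive_subthreshold(self):
        # fluctuation-driven regime: excitation alone would put the mean
        # stationary potential above threshold; recurrent inhibition
        # cancels enough of it to bring the mean below threshold, so
        # spiking at (2, 5) spk/s is noise-driven
        pr = spiking.SpikingParams(N=2000)
        rE, rI = 2.0, 5.0
        tm = pr.tau_m / 1000.0
        exc = tm * (
            pr.NE * pr.pEE * pr.JEE * rE + pr.Next * pr.JE0 * pr.rext
        )
        inh = tm * pr.NI * pr.pEI * pr.JEI * rI
        assert exc > pr.VEthr
        assert exc - inh < pr.VEthr
        assert inh > 0.25 * exc  # inhibition is a substantial component


class TestSelfCouplings:
    def test_parametric_value_n2000(self, clustered_net):
        s = spiking.assembly_self_couplings(clustered_net)
        cl = clustered_net.clustered
        pr = clustered_net.params
        k = 0
        expect = cl.sizes_E[k] * 0.2 * pr.JEE * 14.0
        assert s[k] == pytest.approx(expect, rel=1e-12)

    def test_homogeneous_reduction(self):
        # with JEE+ = 1 the formula reduces to C pEE JEE
        pr = spiking.SpikingParams(N=2000, jEE_plus=2000 / 2000)
        net = spiking.build_spiking_network(pr, seed=2)
        s = spiking.assembly_self_couplings(net)
        cl = net.clustered
        assert np.allclose(s, cl.sizes_E * 0.2 * pr.JEE * cl.JEE_plus)

    def test_empirical_vs_parametric(self, clustered_net):
        s_par = spiking.assembly_self_couplings(clustered_net)
        s_emp = spiking.assembly_self_couplings(
            clustered_net, empirical=True
        )
        assert np.all(np.abs(s_emp / s_par - 1.0) < 0.1)

    def test_scaling_consistency(self):
        # N=2000 vs N=10000 self-couplings differ exactly by the
        # N-dependent factors (sizes x weight scale x potentiation)
        s2 = spiking.SpikingParams(N=2000)
        s10 = spiking.SpikingParams(N=10000)
        ratio_theory = (
            (s10.NEclust_mean / s2.NEclust_mean)
            * (s10.JEE / s2.JEE)
            * (14 * 10000 / 2000) / 14.0
        )
        cl2 = spiking.derive_clustered_params(s2, seed=0)
        cl10 = spiking.derive_clustered_params(s10, seed=0)
        mean2 = np.mean(cl2.sizes_E) * 0.2 * s2.JEE * cl2.JEE_plus
        mean10 = np.mean(cl10.sizes_E) * 0.2 * s10.JEE * cl10.JEE_plus
        expected = (
            (np.mean(cl10.sizes_E) / np.mean(cl2.sizes_E))
            * (s10.JEE / s2.JEE)
            * (cl10.JEE_plus / cl2.JEE_plus)
        )
        assert mean10 / mean2 == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(ratio_theory, rel=0.1)


class TestActivationTimes:
    def test_constructed_alternation(self, clustered_net):
        # synthetic spikes: assembly 1 fires 100 ms on / 100 ms off
        net = clustered_net
        ids = np.nonzero(net.is_E & (net.membership == 1))[0]
        times, nids = [], []
        rng = np.random.default_rng(0)
        for start in np.arange(0.0, 10000.0, 200.0):
            for i in ids:
                n_in = rng.poisson(3.0)  # ~30 Hz in the on-phase
                times.extend(start + rng.uniform(0, 100.0, n_in))
                nids.extend([i] * n_in)
        order = np.argsort(times)
        spk = spiking.SpikeData(
            times=np.asarray(times)[order],
            ids=np.asarray(nids)[order],
            duration=10000.0,
            dt=0.05,
        )
        acts = spiking.assembly_activation_times(spk, net, bin_ms=25.0)
        a1 = acts[0]
        assert not a1.flagged
        assert a1.mean_T == pytest.approx(100.0, abs=25.0)

    def test_metastable_network_rank_correlation(self, spiking_dwell_data):
        # larger-s assemblies activate longer (rank correlation, pooled
        # over realizations)
        s, T = spiking_dwell_data
        assert len(s) >= 10
        rho, pval = spearmanr(s, T)
        assert rho > 0
        assert pval < 0.05


class TestDwellFit:
    def test_exact_quadratic_recovery(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0.5, 4.0, 40)
        logT = 0.14 * s**2 + 1.97 * s + 5.51
        fit = spiking.fit_dwell_vs_selfcoupling(s, np.exp(logT))
        assert fit["degree"] == 2
        assert np.allclose(
            fit["coefficients"], [0.14, 1.97, 5.51], atol=1e-10
        )

    def test_linear_data_selects_degree_one(self):
        # across independent draws of linear data the parsimony rule
        # settles on degree 1 (an occasional draw carries accidental
        # curvature; the modal choice is what matters)
        chosen = []
        for dseed in range(5):
            rng = np.random.default_rng(dseed)
            s = rng.uniform(0.0, 5.0, 60)
            logT = 2.0 * s + 1.0 + 0.1 * rng.standard_normal(60)
            chosen.append(
                spiking.fit_dwell_vs_selfcoupling(s, np.exp(logT))["degree"]
            )
        assert sorted(chosen)[len(chosen) // 2] == 1  # median draw
        assert max(chosen) <= 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            spiking.fit_dwell_vs_selfcoupling(
                np.arange(4.0), np.ones(4)
            )


class TestReducedMatrix:
    def test_spectrum_subset_of_block_averaged(self, clustered_net):
        from timescale_reservoir.spiking import _population_index

        JMF = spiking.reduced_weight_matrix(clustered_net)
        groups = _population_index(clustered_net)
        # block-averaged full matrix has the same nonzero spectrum
        N = clustered_net.W.shape[0]
        B = np.zeros((N, N))
        for ga in groups:
            for gb in groups:
                B[np.ix_(ga, gb)] = clustered_net.W[np.ix_(ga, gb)].mean()
        ev_full = np.linalg.eigvals(B)
        ev_red = np.linalg.eigvals(JMF)
        for lam in ev_red:
            assert np.min(np.abs(ev_full - lam)) < 1e-8

    def test_homogeneous_cluster_degeneracy(self):
        pr = spiking.SpikingParams(N=2000)
        net = spiking.build_spiking_network(pr, seed=4)
        # collapse potentiation -> all clustered blocks identical in
        # expectation; JMF built from expectations has p-1 degenerate modes
        cl = net.clustered
        p = cl.p
        k = 2 * p + 2
        JMF = np.zeros((k, k))
        sizes = np.concatenate(
            [cl.sizes_E, [net.is_E.sum() - cl.sizes_E.sum()],
             cl.sizes_I, [(~net.is_E).sum() - cl.sizes_I.sum()]]
        )
        for a in range(k):
            for b in range(k):
                pre_E = b < p + 1
                post_E = a < p + 1
                base = (
                    pr.JEE if pre_E and post_E
                    else -pr.JEI if post_E
                    else pr.JIE if pre_E
                    else -pr.JII
                )
                prob = (
                    pr.pEE if pre_E and post_E
                    else pr.pEI if post_E
                    else pr.pIE if pre_E
                    else pr.pII
                )
                JMF[a, b] = sizes[b] * prob * base
        ev = np.linalg.eigvals(JMF)
        # rank <= 2 block structure: all but <= 2 eigenvalues vanish
        assert (np.abs(ev) > 1e-9).sum() <= 2

    def test_gap_count_and_size_ordering(self, clustered_net):
        JMF = spiking.reduced_weight_matrix(clustered_net)
        ev = spiking.spectra(JMF)
        p = clustered_net.clustered.p
        re = np.sort(ev.real)[::-1]
        gaps = re[:-1] - re[1:]
        # largest spectral gap separates the slow outliers from the bulk
        k_gap = int(np.argmax(gaps[: 2 * p]) ) + 1
        assert abs(k_gap - (p - 1)) <= 1
        # leading eigenvalues track assembly sizes
        sm = spiking.schur_modes(JMF, p, n_leading=p - 1)
        sizes = clustered_net.clustered.sizes_E
        lead_sizes = [sizes[c - 1] for c in sm["cluster_map"]]
        rho, _ = spearmanr(np.arange(len(lead_sizes))[::-1], lead_sizes)
        assert rho > 0.9

    def test_schur_basis_orthonormal_triangular(self, clustered_net):
        JMF = spiking.reduced_weight_matrix(clustered_net)
        p = clustered_net.clustered.p
        sm = spiking.schur_modes(JMF, p)
        Q = sm["modes"]
        assert np.allclose(Q.conj().T @ Q, np.eye(Q.shape[0]), atol=1e-8)
        T = sm["T"]
        assert np.max(np.abs(np.tril(T, -1))) < 1e-7
        # diagonal ordered by descending real part
        d = np.diag(T).real
        assert np.all(np.diff(d) < 1e-7)
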