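"""Ancestry HMM: transition closed forms, Viterbi vs exhaustive path
enumeration, EM monotonicity and a hand-computable Baum-Welch update,
haploblock collapsing with IBD relabeling, and indel validation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainmosaic.config import SimConfig
from strainmosaic.hmm import (HmmModel, ObservationTrack,
                              build_observation_track,
                              collapse_to_haploblocks, default_model, em_fit,
                              forward_backward, transition_matrix,
                              validate_with_indels, viterbi_decode,
                              UNKNOWN_LABEL, _log_emissions)
from strainmosaic.simulate import (simulate_founder_panel,
                                   simulate_mosaic_strain, simulate_study)


def make_track(X, positions=None, cM=None, names=None):
    X = np.asarray(X, dtype=bool)
    n = X.shape[0]
    positions = np.arange(n) * 1000 if positions is None else np.asarray(positions)
    cM = positions / 1e6 * 0.5 if cM is None else np.asarray(cM, dtype=float)
    names = names or tuple(f"F{i}" for i in range(X.shape[1] - 1)) + ("Ref",)
    return ObservationTrack("chr1", positions, cM, X, tuple(names),
                            np.arange(n))


def random_model(rng, k, f):
    emission = rng.uniform(0.05, 0.95, size=(k, f))
    init = rng.dirichlet(np.ones(k))
    return HmmModel(tuple(f"S{i}" for i in range(k)),
                    tuple(f"I{i}" for i in range(f)),
                    emission, float(rng.uniform(1, 50)), init)


def brute_force_viterbi(track, model):
    """Exhaustive enumeration over all state paths (independent oracle)."""
    logb = _log_emissions(track, model)
    n, k = logb.shape
    from strainmosaic.hmm import interval_switch_probs
    q = interval_switch_probs(track.cM, model.switch_scale)
    best_lp, best_path = -math.inf, None
    for path in itertools.product(range(k), repeat=n):
        lp = math.log(model.init[path[0]]) + logb[0, path[0]]
        for t in range(1, n):
            if path[t] == path[t - 1]:
                lp += math.log1p(-q[t - 1]) if q[t - 1] < 1 else -math.inf
            else:
                lp += math.log(q[t - 1] / (k - 1)) if q[t - 1] > 0 else -math.inf
            lp += logb[t, path[t]]
        if lp > best_lp:  # strict: keeps the first (lexicographically
            best_lp, best_path = lp, path  # smallest) maximizer
    return np.array(best_path), best_lp


class TestTransitionMatrix:
    def test_zero_distance_is_identity(self):
        assert np.allclose(transition_matrix(0.0, 5.0, 6), np.eye(6))

    def test_large_distance_equalizes_off_diagonals(self):
        a = transition_matrix(1e9, 5.0, 6)
        off = a[~np.eye(6, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(a.sum(axis=1), 1.0)

    @given(s=st.floats(0.01, 100), d=st.floats(0.0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_off_diagonal_closed_form(self, s, d):
        a = transition_matrix(d, s, 6)
        expected = (1 - math.exp(-s * d / 100)) / 5
        assert a[0, 1] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(a.sum(axis=1), 1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(-1.0, 5.0, 6)


class TestForwardBackward:
    def test_posteriors_sum_to_one(self, rng):
        track = make_track(rng.random((50, 6)) < 0.5)
        model = random_model(rng, 6, 6)
        _, gamma, _, _ = forward_backward(track, model)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_loglik_matches_enumeration_on_tiny_instance(self, rng):
        track = make_track(rng.random((4, 3)) < 0.5)
        model = random_model(rng, 3, 3)
        loglik, _, _, _ = forward_backward(track, model)
        # oracle: sum over all 3^4 paths
        logb = _log_emissions(track, model)
        from strainmosaic.hmm import interval_switch_probs
        q = interval_switch_probs(track.cM, model.switch_scale)
        total = 0.0
        for path in itertools.product(range(3), repeat=4):
            p = model.init[path[0]] * math.exp(logb[0, path[0]])
            for t in range(1, 4):
                trans = (1 - q[t - 1]) if path[t] == path[t - 1] \
                    else q[t - 1] / 2
                p *= trans * math.exp(logb[t, path[t]])
            total += p
        assert loglik == pytest.approx(math.log(total), abs=1e-9)


class TestViterbi:
    def test_pure_signal_gives_constant_path(self):
        X = np.zeros((20, 6), dtype=bool)
        X[:, 2] = True
        track = make_track(X)
        model = default_model([f"F{i}" for i in range(5)], self_match=0.99,
                              off_match=0.01)
        path, _ = viterbi_decode(track, model)
        assert (path == 2).all()

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 6))
            k = int(rng.integers(2, 5))
            track = make_track(rng.random((n, k)) < 0.5,
                               positions=np.sort(rng.choice(10**6, n,
                                                            replace=False)))
            model = random_model(rng, k, k)
            path, lp = viterbi_decode(track, model)
            opath, olp = brute_force_viterbi(track, model)
            assert lp == pytest.approx(olp, abs=1e-9)
            assert np.array_equal(path, opath)

    def test_symmetric_tie_breaks_to_lower_state(self):
        # two founders, every site matches both equally: fully tied
        X = np.ones((10, 3), dtype=bool)
        model = default_model(["F0", "F1"], self_match=0.9, off_match=0.9)
        track = make_track(X, names=("F0", "F1", "Ref"))
        path, _ = viterbi_decode(track, model)
        assert (path == 0).all()

    def test_viterbi_beats_random_paths(self, rng):
        track = make_track(rng.random((30, 6)) < 0.4)
        model = random_model(rng, 6, 6)
        _, lp = viterbi_decode(track, model)
        logb = _log_emissions(track, model)
        from strainmosaic.hmm import interval_switch_probs
        q = interval_switch_probs(track.cM, model.switch_scale)
        for _ in range(200):
            path = rng.integers(0, 6, size=30)
            rlp = math.log(model.init[path[0]]) + logb[0, path[0]]
            for t in range(1, 30):
                rlp += (math.log1p(-q[t - 1]) if path[t] == path[t - 1]
                        else math.log(q[t - 1] / 5))
                rlp += logb[t, path[t]]
            assert lp >= rlp - 1e-9


class TestEm:
    def test_loglik_trace_monotone_on_synthetic_tracks(self):
        for seed in range(5):
            cfg = SimConfig(n_sites=300, seed=seed)
            panel = simulate_founder_panel(cfg)
            strain = simulate_mosaic_strain(panel, cfg)
            track = build_observation_track(
                panel, strain.called_alleles.astype(float), cfg.recomb_map)
            _, trace = em_fit(track, default_model(panel.founder_names),
                              max_iter=8)
            assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_mle_is_fixed_point(self):
        # all-ones patterns: the clamped empirical MLE emission is
        # (1 - floor) everywhere; starting there, one EM iteration must
        # leave the likelihood unchanged
        X = np.ones((30, 4), dtype=bool)
        track = make_track(X, names=("F0", "F1", "F2", "Ref"))
        model = default_model(["F0", "F1", "F2"], self_match=0.99,
                              off_match=0.99, error_floor=0.01)
        _, trace = em_fit(track, model, max_iter=2, fit_switch_scale=False)
        assert trace[1] == pytest.approx(trace[0], abs=1e-9)

    def test_baum_welch_update_matches_enumeration_oracle(self, rng):
        """3-site, 2-state toy: the emission update must equal the
        posterior-weighted indicator means computed by enumerating all
        2^3 hidden paths."""
        X = np.array([[1, 0], [0, 1], [1, 1]], dtype=bool)
        track = make_track(X, names=("F0", "Ref"))
        emission = np.array([[0.8, 0.3], [0.4, 0.6]])
        init = np.array([0.6, 0.4])
        model = HmmModel(("F0", UNKNOWN_LABEL), ("F0", "Ref"), emission,
                         switch_scale=20.0, init=init, error_floor=1e-6)

        # --- oracle: exact posteriors by path enumeration
        from strainmosaic.hmm import interval_switch_probs
        q = interval_switch_probs(track.cM, model.switch_scale)

        def emis(s, t):
            p = emission[s]
            x = X[t]
            return np.prod(np.where(x, p, 1 - p))

        joint = {}
        for path in itertools.product(range(2), repeat=3):
            p = init[path[0]] * emis(path[0], 0)
            for t in (1, 2):
                p *= (1 - q[t - 1]) if path[t] == path[t - 1] else q[t - 1]
                p *= emis(path[t], t)
            joint[path] = p
        z = sum(joint.values())
        gamma_o = np.zeros((3, 2))
        for path, p in joint.items():
            for t, s in enumerate(path):
                gamma_o[t, s] += p / z
        num = gamma_o.T @ X
        expected_p = num / gamma_o.sum(axis=0)[:, None]
        # exchangeability pooling applies to the last (unknown) state's
        # founder indicators; with one founder indicator it is a no-op
        expected_p = np.clip(expected_p, 1e-6, 1 - 1e-6)

        # --- one EM iteration of the implementation
        fitted, trace = em_fit(track, model, max_iter=1,
                               fit_switch_scale=False)
        assert np.allclose(fitted.emission, expected_p, atol=1e-9)
        # and the likelihood it reports equals the enumeration total
        assert trace[0] == pytest.approx(math.log(z), abs=1e-9)

    def test_label_permutation_symmetry(self):
        cfg = SimConfig(n_sites=400, seed=31)
        panel = simulate_founder_panel(cfg)
        strain = simulate_mosaic_strain(panel, cfg)
        alleles = strain.called_alleles.astype(float)

        track = build_observation_track(panel, alleles, cfg.recomb_map)
        model, trace = em_fit(track, default_model(panel.founder_names),
                              max_iter=5)
        path, lp = viterbi_decode(track, model)

        perm = [2, 0, 1, 4, 3]
        panel2 = simulate_founder_panel(cfg)
        panel2.alleles = panel.alleles[perm]
        panel2.founder_names = tuple(panel.founder_names[i] for i in perm)
        track2 = build_observation_track(panel2, alleles, cfg.recomb_map)
        model2, trace2 = em_fit(track2, default_model(panel2.founder_names),
                                max_iter=5)
        path2, lp2 = viterbi_decode(track2, model2)

        assert lp2 == pytest.approx(lp, abs=1e-6)
        assert trace2[-1] == pytest.approx(trace[-1], abs=1e-6)
        # decoded labels map through the permutation; block boundaries match
        inv = np.argsort(perm)
        remapped = np.where(path < 5, inv[np.minimum(path, 4)], path)
        assert np.array_equal(remapped, path2)

    def test_empty_track_rejected(self):
        track = make_track(np.zeros((0, 6), dtype=bool),
                           positions=np.zeros(0), cM=np.zeros(0))
        with pytest.raises(ValueError):
            em_fit(track, default_model([f"F{i}" for i in range(5)]))


class TestObservationTrack:
    def test_match_pattern_definition(self):
        cfg = SimConfig(n_sites=50, seed=1)
        panel = simulate_founder_panel(cfg)
        alleles = panel.alleles[0].astype(float)  # strain == founder 0
        track = build_observation_track(panel, alleles, cfg.recomb_map)
        assert track.X[:, 0].all()  # always matches founder 0
        # reference indicator true exactly where the strain allele is 0
        assert np.array_equal(track.X[:, -1], panel.alleles[0] == 0)

    def test_missing_sites_are_skipped(self):
        cfg = SimConfig(n_sites=100, seed=1)
        panel = simulate_founder_panel(cfg)
        alleles = panel.alleles[0].astype(float)
        alleles[:10] = np.nan
        track = build_observation_track(panel, alleles, cfg.recomb_map)
        assert track.n_sites == 90

    def test_uninformative_thinning(self):
        cfg = SimConfig(n_sites=200, unknown_fraction=0.0, seed=8)
        panel = simulate_founder_panel(cfg)
        panel.alleles[:] = 0  # every founder reference everywhere
        alleles = np.zeros(panel.n_sites)  # strain matches everything
        kept = build_observation_track(panel, alleles, cfg.recomb_map,
                                       keep_uninformative=0.0)
        assert kept.n_sites == 0
        full = build_observation_track(panel, alleles, cfg.recomb_map,
                                       keep_uninformative=1.0)
        assert full.n_sites == panel.n_sites


class TestHaploblocks:
    def _decode(self, cfg, seed=None):
        cfg = cfg
        panel = simulate_founder_panel(cfg)
        strain = simulate_mosaic_strain(panel, cfg)
        track = build_observation_track(
            panel, strain.called_alleles.astype(float), cfg.recomb_map)
        model, _ = em_fit(track, default_model(panel.founder_names),
                          max_iter=10)
        path, _ = viterbi_decode(track, model)
        _, gamma, _, _ = forward_backward(track, model)
        blocks = collapse_to_haploblocks(path, gamma, track, panel,
                                         cfg.chrom_length)
        return panel, strain, track, path, blocks

    def test_blocks_tile_chromosome(self):
        cfg = SimConfig(n_sites=500, seed=41)
        _, _, _, _, blocks = self._decode(cfg)
        assert blocks[0].start == 0
        assert blocks[-1].end == cfg.chrom_length
        for a, b in zip(blocks, blocks[1:]):
            assert a.end == b.start

    def test_ibd_relabeling_on_identical_founders(self):
        cfg = SimConfig(n_sites=60, unknown_fraction=0.0, seq_error=0.0,
                        homozygosity=1.0, switch_scale=0.0, seed=13)
        panel = simulate_founder_panel(cfg)
        panel.alleles[1] = panel.alleles[0]  # founders 0 and 1 identical
        strain = simulate_mosaic_strain(panel, cfg)
        strain.truth_states[:] = 0
        alleles = panel.alleles[0].astype(float)
        track = build_observation_track(panel, alleles, cfg.recomb_map)
        model = default_model(panel.founder_names, self_match=0.95,
                              off_match=0.3)
        path, _ = viterbi_decode(track, model)
        _, gamma, _, _ = forward_backward(track, model)
        blocks = collapse_to_haploblocks(path, gamma, track, panel,
                                         cfg.chrom_length)
        assert len(blocks) == 1
        assert blocks[0].label == frozenset({panel.founder_names[0],
                                             panel.founder_names[1]})

    def test_singleton_label_when_founders_differ(self):
        cfg = SimConfig(n_sites=200, unknown_fraction=0.0, seq_error=0.0,
                        homozygosity=1.0, switch_scale=0.0,
                        ibd_run_fraction=0.0, seed=14)
        panel, strain, track, path, blocks = self._decode(cfg)
        for blk in blocks:
            if blk.label != frozenset({UNKNOWN_LABEL}):
                assert len(blk.label) == 1

    def test_block_boundaries_near_truth_on_low_noise_mosaic(self):
        """Each decoded switch lies within 2 sites of the truth, beyond
        the stretch where the two flanking ancestors are locally
        identical (there the exact breakpoint is unidentifiable)."""
        cfg = SimConfig(n_sites=2000, seq_error=0.002, ibd_run_fraction=0.0,
                        seed=51)
        panel, strain, track, path, blocks = self._decode(cfg)
        truth = strain.truth_states[track.site_index]

        def state_alleles(s, idx):
            sites = track.site_index[idx]
            if s < panel.n_founders:
                return panel.alleles[s, sites]
            return panel.unknown_alleles[sites]

        true_breaks = np.flatnonzero(np.diff(truth) != 0)
        decoded_breaks = np.flatnonzero(np.diff(path) != 0)
        assert decoded_breaks.size
        n = truth.size
        for tb in true_breaks:
            s1, s2 = int(truth[tb]), int(truth[tb + 1])
            lo = tb
            while lo > 0 and state_alleles(s1, [lo]) == state_alleles(s2, [lo]):
                lo -= 1
            hi = tb + 1
            while hi < n - 1 and \
                    state_alleles(s1, [hi]) == state_alleles(s2, [hi]):
                hi += 1
            nearest = decoded_breaks[np.abs(decoded_breaks - tb).argmin()]
            assert lo - 2 <= nearest <= hi + 2


class TestIndelValidation:
    def _blocks(self, labels, bounds):
        return [type("B", (), {"start": s, "end": e, "label": frozenset(lab),
                               "label_str": "+".join(sorted(lab)),
                               "length": e - s})()
                for (s, e), lab in zip(bounds, labels)]

    def test_ancestor_carries_all_indels_gives_one(self):
        blocks = self._blocks([{"A"}], [(0, 1000)])
        per, mean = validate_with_indels(
            blocks, [100, 500], [True, True], [[True, True]], ["A"])
        assert per == [1.0] and mean == 1.0

    def test_ancestor_carries_none_gives_zero(self):
        blocks = self._blocks([{"A"}], [(0, 1000)])
        per, mean = validate_with_indels(
            blocks, [100, 500], [True, True], [[False, False]], ["A"])
        assert per == [0.0] and mean == 0.0

    def test_block_without_indels_is_missing_not_zero(self):
        blocks = self._blocks([{"A"}, {"A"}], [(0, 500), (500, 1000)])
        per, mean = validate_with_indels(
            blocks, [700], [True], [[True]], ["A"])
        assert per == [None, 1.0] and mean == 1.0

    def test_zero_noise_synthetic_consistency_is_one(self):
        cfg = SimConfig(n_sites=1500, seq_error=0.0, homozygosity=1.0,
                        seed=61)
        study = simulate_study(cfg, with_svs=False)
        panel, strain = study.panel, study.strains["strainA"]
        track = build_observation_track(
            panel, strain.called_alleles.astype(float), cfg.recomb_map)
        model, _ = em_fit(track, default_model(panel.founder_names),
                          max_iter=15)
        path, _ = viterbi_decode(track, model)
        _, gamma, _, _ = forward_backward(track, model)
        blocks = collapse_to_haploblocks(path, gamma, track, panel,
                                         cfg.chrom_length)
        ind = study.indels
        per, mean = validate_with_indels(
            blocks, ind.positions, ind.strain_carrier["strainA"],
            ind.founder_carrier, panel.founder_names, ind.unknown_carrier)
        assert mean == pytest.approx(1.0)
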