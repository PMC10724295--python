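"""Neural and model RDMs, with a brute-force trial-pair oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oddrsa as od
from oddrsa.rdm import (
    RDM,
    RDMError,
    neural_rdm_timecourse,
    spatiotemporal_features,
    symmetrize_from_lower,
    vectorize_lower_triangle,
)
from conftest import make_epochs


def _random_epochs(rng, table, n_per_char=3, n_channels=4, n_times=1000):
    """Epochs over the 9 inconsistent characters with random data."""
    chars = [c for c in table.inconsistent_ids for _ in range(n_per_char)]
    cats = [table.category_of(c) for c in chars]
    data = rng.normal(size=(len(chars), n_channels, n_times))
    return make_epochs(
        data, [f"ch{i}" for i in range(n_channels)],
        roles=["equiprobable"] * len(chars),
        categories=cats, characters=chars,
    )


class TestSpatiotemporalFeatures:
    def test_feature_counts_scale_with_channels(self, table):
        rng = np.random.default_rng(0)
        for n_ch, n_feat in ((2, 22), (61, 671)):
            ep = _random_epochs(rng, table, n_channels=n_ch)
            assert spatiotemporal_features(ep, 0.0).shape == (27, n_feat)

    def test_constant_channels_repeat_eleven_times(self, table):
        ep = _random_epochs(np.random.default_rng(1), table, n_channels=3)
        ep.data[:] = np.arange(3)[None, :, None]  # constant per channel
        f = spatiotemporal_features(ep, 100.0)
        np.testing.assert_array_equal(
            f[0], np.repeat(np.arange(3.0), 11)
        )

    def test_truncated_window_rejected(self, table):
        ep = _random_epochs(np.random.default_rng(2), table)
        with pytest.raises(RDMError):
            spatiotemporal_features(ep, -299.0)


class TestNeuralRDM:
    def test_matches_bruteforce_double_loop(self, table):
        rng = np.random.default_rng(3)
        ep = _random_epochs(rng, table, n_per_char=3, n_channels=4)
        times = np.array([0.0, 100.0])
        stack = neural_rdm_timecourse(ep, "equal_probability", table, times_ms=times)
        chars = np.asarray(ep.meta["character_id"])
        for ti, t in enumerate(times):
            F = spatiotemporal_features(ep, t)
            for i, ci in enumerate(stack.labels):
                for j, cj in enumerate(stack.labels):
                    if i == j:
                        continue
                    vals = [
                        1.0 - stats.pearsonr(F[a], F[b]).statistic
                        for a in np.flatnonzero(chars == ci)
                        for b in np.flatnonzero(chars == cj)
                    ]
                    assert stack.values[ti, i, j] == pytest.approx(
                        np.mean(vals), abs=1e-10
                    )

    def test_identical_trials_give_zero_anticorrelated_give_two(self, table):
        ep = _random_epochs(np.random.default_rng(4), table, n_per_char=2)
        base = np.random.default_rng(5).normal(size=(4, 1000))
        chars = np.asarray(ep.meta["character_id"])
        ci, cj = table.inconsistent_ids[:2]
        ep.data[chars == ci] = base
        ep.data[chars == cj] = -base
        stack = neural_rdm_timecourse(
            ep, "equal_probability", table, times_ms=np.array([0.0])
        )
        i, j = stack.labels.index(ci), stack.labels.index(cj)
        assert stack.values[0, i, i] == 0.0
        assert stack.values[0, i, j] == pytest.approx(2.0, abs=1e-10)

    def test_trial_order_invariance(self, table):
        rng = np.random.default_rng(6)
        ep = _random_epochs(rng, table)
        perm = rng.permutation(len(ep.meta))
        shuffled = make_epochs(
            ep.data[perm], ep.channel_names,
            roles=list(np.asarray(ep.meta["role"])[perm]),
            categories=list(np.asarray(ep.meta["category"])[perm]),
            characters=list(np.asarray(ep.meta["character_id"])[perm]),
        )
        a = neural_rdm_timecourse(ep, "equal_probability", table,
                                  times_ms=np.array([0.0]))
        b = neural_rdm_timecourse(shuffled, "equal_probability", table,
                                  times_ms=np.array([0.0]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_too_few_trials_reported_by_character(self, table):
        ep = _random_epochs(np.random.default_rng(7), table, n_per_char=1)
        with pytest.raises(RDMError, match="fewer than 2"):
            neural_rdm_timecourse(ep, "equal_probability", table,
                                  times_ms=np.array([0.0]))

    def test_noise_free_effect_matches_predictor_perfectly(self, table, small_session):
        eff = od.EffectSpec("phonological", (200.0, 300.0), 10.0, pattern_seed=3)
        rec = od.simulate_subject(small_session, table, effects=[eff],
                                  noise_sd=0.0, seed=0)
        from oddrsa.preprocess import extract_epochs

        ep = extract_epochs(rec)
        stack = neural_rdm_timecourse(ep, "equal_probability", table,
                                      times_ms=np.array([250.0]))
        model = od.predictor_rdm("phonological", table)
        nv = vectorize_lower_triangle(stack.rdm_at(250.0))
        mv = vectorize_lower_triangle(model)
        # the in-window neural RDM separates between- from within-category
        # pairs perfectly; with a tied binary model vector the tie-corrected
        # Spearman of a perfect separation is sqrt(3)/2
        assert nv[mv == 1].min() > nv[mv == 0].max()
        rho = stats.spearmanr(nv, mv).statistic
        assert rho > 0.86


class TestModelRDMs:
    def test_predictor_between_vs_within_pairs(self, table):
        r = od.predictor_rdm("orthographic", table)
        ior, iph, ise = (table.ids_of(c)[0] for c in ("IOr", "IPh", "ISe"))
        g = lambda a, b: r.values[r.labels.index(a), r.labels.index(b)]
        assert g(ior, iph) == 1.0
        assert g(iph, ise) == 0.0  # both orthographically consistent
        assert vectorize_lower_triangle(r).sum() == 18  # 3 x 6 between pairs

    def test_radical_control_structure(self, table):
        r = od.radical_control_rdm(table)
        v = vectorize_lower_triangle(r)
        assert (v == 0).sum() == 9 and (v == 1).sum() == 27
        np.testing.assert_array_equal(r.values, r.values.T)
        np.testing.assert_array_equal(np.diag(r.values), 0)

    def test_frequency_rdm_log_metric(self, table):
        f = table.frame.copy()
        f["frequency"] = 10.0
        assert np.all(od.frequency_rdm(od.CharacterTable(f)).values == 0)
        f.loc[f["character_id"] == table.inconsistent_ids[0], "frequency"] = 100.0
        r = od.frequency_rdm(od.CharacterTable(f))
        i = r.labels.index(table.inconsistent_ids[0])
        assert r.values[i, 1 - i] == pytest.approx(1.0)  # |log10(100)-log10(10)|

    def test_frequency_rdm_scale_invariant(self, table):
        a = od.frequency_rdm(table)
        f = table.frame.copy()
        f["frequency"] *= 7.5
        b = od.frequency_rdm(od.CharacterTable(f))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_rating_rdm_absolute_differences(self, table):
        f = table.frame.copy()
        scores = {cid: 4.0 for cid in table.character_ids}
        ids = table.inconsistent_ids
        scores[ids[0]], scores[ids[1]], scores[ids[2]] = 2.0, 5.0, 5.0
        f["rating_orth"] = [scores[c] for c in f["character_id"]]
        r = od.rating_rdm("orthographic", od.CharacterTable(f))
        g = lambda a, b: r.values[r.labels.index(a), r.labels.index(b)]
        assert g(ids[0], ids[1]) == 3.0
        assert g(ids[0], ids[2]) == 3.0
        assert g(ids[1], ids[2]) == 0.0

    def test_rating_rdm_missing_ratings_rejected(self, table):
        f = table.frame.drop(columns=["rating_phon"])
        with pytest.raises(RDMError):
            od.rating_rdm("phonological", od.CharacterTable(f))


class TestVectorisation:
    def test_lower_triangle_order_and_roundtrip(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        v = vectorize_lower_triangle(m)
        np.testing.assert_array_equal(v, [1.0, 2.0, 3.0])  # (1,0),(2,0),(2,1)
        np.testing.assert_array_equal(symmetrize_from_lower(v, 3), m)

    def test_nine_by_nine_gives_36(self, table):
        assert len(vectorize_lower_triangle(od.frequency_rdm(table))) == 36

    def test_two_by_two(self):
        assert vectorize_lower_triangle(
            np.array([[0.0, 0.7], [0.7, 0.0]])
        ) == pytest.approx([0.7])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(RDMError):
            RDM(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
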