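"""Ground-truth injection: features, montage, linearity, determinism."""

import numpy as np
import pytest

import oddrsa as od
from oddrsa.preprocess import extract_epochs
from oddrsa.simulate import (
    ROI_LEFT,
    ROI_RIGHT,
    EffectSpec,
    SimulationError,
    character_feature,
    iter_cohort,
)


class TestCharacterFeature:
    def test_binary_consistency_features(self, table):
        ior = table.ids_of("IOr")[0]
        iph = table.ids_of("IPh")[0]
        cc = table.ids_of("CC")[0]
        assert character_feature("orthographic", ior, table) == 1.0
        # IPh characters are orthographically consistent
        assert character_feature("orthographic", iph, table) == 0.0
        assert character_feature("phonological", iph, table) == 1.0
        assert character_feature("semantic", cc, table) == 0.0

    def test_frequency_feature_is_standardised(self, table):
        z = np.array(
            [character_feature("frequency", c, table) for c in table.character_ids]
        )
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12

    def test_unknown_character_raises(self, table):
        with pytest.raises(Exception):
            character_feature("frequency", "nope", table)


class TestMontage:
    def test_default_montage_geometry(self, montage):
        assert len(montage.channel_names) == 61
        assert len(set(montage.channel_names)) == 61
        for ch in ROI_LEFT + ROI_RIGHT:
            assert ch in montage.channel_names
        np.testing.assert_allclose(
            np.linalg.norm(montage.positions, axis=1), 1.0, atol=1e-9
        )


def _epochs(rec):
    return extract_epochs(rec)


class TestSimulateSubject:
    def test_no_effects_no_noise_epochs_identical(self, table, small_session):
        rec = od.simulate_subject(
            small_session, table, effects=[], noise_sd=0.0, seed=0
        )
        ep = _epochs(rec)
        ref = ep.data[0]
        assert ref.max() > 0  # the common evoked waveform is present
        # sub-μV tolerance: with 700-800 ms onset spacing the tail of the
        # previous trial's evoked response bleeds faintly into the baseline
        for k in range(1, ep.data.shape[0]):
            np.testing.assert_allclose(ep.data[k], ref, atol=5e-3)

    def test_single_effect_confined_to_window(self, table, small_session):
        eff = EffectSpec("orthographic", (200.0, 300.0), 10.0, pattern_seed=1)
        rec = od.simulate_subject(
            small_session, table, effects=[eff], noise_sd=0.0, seed=0
        )
        ep = _epochs(rec)
        meta = ep.meta
        ior = ep.data[(meta["category"] == "IOr").to_numpy()][0]
        other = ep.data[(meta["category"] == "IPh").to_numpy()][0]
        diff = ior - other
        t = ep.times_ms
        inside = (t >= 200) & (t < 300)
        assert np.abs(diff[:, inside]).max() > 0.1
        assert np.abs(diff[:, ~inside]).max() < 1e-4

    def test_vmmn_deflection_negative_at_roi_only(self, table, small_session):
        eff = EffectSpec("vmmn", (150.0, 300.0), 2.0, roi_restricted=True)
        rec = od.simulate_subject(
            small_session, table, effects=[eff], noise_sd=0.0, seed=0
        )
        ep = _epochs(rec)
        dev = ep.data[(ep.meta["role"] == "deviant").to_numpy()].mean(axis=0)
        eq = ep.data[(ep.meta["role"] == "equiprobable").to_numpy()].mean(axis=0)
        diff = dev - eq
        t = ep.times_ms
        p7 = ep.channel_names.index("P7")
        cz = ep.channel_names.index("Cz")
        inside = (t >= 150) & (t < 300)
        assert diff[p7, inside].min() < -1.5
        assert np.abs(diff[p7, ~inside]).max() < 5e-3
        assert np.abs(diff[cz, :]).max() < 5e-3

    def test_linearity_of_effects(self, table, small_session):
        a = EffectSpec("orthographic", (150.0, 400.0), 5.0, pattern_seed=1)
        b = EffectSpec("frequency", (150.0, 250.0), 4.0, pattern_seed=2)
        kw = dict(noise_sd=0.0, seed=0)
        both = od.simulate_subject(small_session, table, effects=[a, b], **kw)
        only_a = od.simulate_subject(small_session, table, effects=[a], **kw)
        only_b = od.simulate_subject(small_session, table, effects=[b], **kw)
        none = od.simulate_subject(small_session, table, effects=[], **kw)
        np.testing.assert_allclose(
            both.data,
            only_a.data + only_b.data - none.data,
            atol=1e-3,
        )

    def test_deterministic_given_seed(self, table, small_session):
        r1 = od.simulate_subject(small_session, table, noise_sd=3.0, seed=42)
        r2 = od.simulate_subject(small_session, table, noise_sd=3.0, seed=42)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(SimulationError):
            EffectSpec("semantic", (500.0, 900.0), 1.0)

    def test_events_strictly_increasing(self, table, small_session):
        rec = od.simulate_subject(small_session, table, noise_sd=1.0, seed=0)
        assert (np.diff(rec.events["sample"]) > 0).all()


class TestCohort:
    def test_reproducible_and_sized(self, table):
        kw = dict(
            n_subjects=2, table=table, n_trials_oddball=24, n_trials_equal=24,
            noise_sd=2.0, seed=9,
        )
        c1 = od.simulate_cohort(**kw)
        c2 = od.simulate_cohort(**kw)
        assert len(c1) == 2
        for s1, s2 in zip(c1, c2):
            assert s1.subject_id == s2.subject_id
            np.testing.assert_array_equal(s1.recording.data, s2.recording.data)

    def test_zero_between_subject_sd_shares_amplitudes(self, table):
        # with sd=0 both subjects get the deterministic effect amplitudes:
        # identical designs + identical noise seeds would be needed for equal
        # data, so compare the noise-free signal instead
        effs = [EffectSpec("orthographic", (150.0, 300.0), 5.0, pattern_seed=1)]
        subs = list(
            iter_cohort(
                n_subjects=2, table=table, effects=effs, between_subject_sd=0.0,
                n_trials_oddball=24, n_trials_equal=24, noise_sd=0.0, seed=3,
            )
        )
        peaks = []
        for s in subs:
            ep = extract_epochs(s.recording)
            ior = ep.data[(ep.meta["category"] == "IOr").to_numpy()]
            other = ep.data[(ep.meta["category"] == "ISe").to_numpy()]
            peaks.append(np.abs(ior.mean(0) - other.mean(0)).max())
        assert peaks[0] == pytest.approx(peaks[1], rel=1e-3)
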