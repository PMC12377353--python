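"""Coactivation coefficient and synergy area shares."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from emgcycle import (
    ActivationModel,
    MovementProtocol,
    cc_by_phase,
    coactivation_coefficient,
    generate_trial,
    muscle_synergy,
)
from emgcycle.errors import AlignmentError
from emgcycle.kinematics import PHASE_ORDER, Phase
from emgcycle.signals import EnvelopeSignal, EnvelopeStage


def env(samples, fs=20.0, muscle=""):
    return EnvelopeSignal(
        np.asarray(samples, float), fs=fs, stage=EnvelopeStage.NORMALIZED, muscle=muscle
    )


envelopes = hnp.arrays(
    dtype=float,
    shape=st.integers(min_value=3, max_value=60),
    elements=st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
)


class TestCoactivationCoefficient:
    def test_identical_envelopes_give_100(self):
        a = np.abs(np.sin(np.linspace(0, 3, 50))) + 0.1
        assert coactivation_coefficient(a, a.copy()) == pytest.approx(100.0, abs=1e-9)

    def test_disjoint_supports_give_0(self):
        a = np.concatenate([np.ones(25), np.zeros(25)])
        b = np.concatenate([np.zeros(25), np.ones(25)])
        assert coactivation_coefficient(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_constant_half_ratio_gives_two_thirds(self):
        a, b = np.full(40, 1.0), np.full(40, 0.5)
        assert coactivation_coefficient(a, b) == pytest.approx(200.0 / 3.0, abs=1e-9)

    def test_both_silent_defined_as_zero(self):
        assert coactivation_coefficient(np.zeros(10), np.zeros(10)) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(a=envelopes, b=envelopes)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        assert coactivation_coefficient(a[:n], b[:n]) == pytest.approx(
            coactivation_coefficient(b[:n], a[:n]), abs=1e-9
        )

    @settings(max_examples=50, deadline=None)
    @given(a=envelopes, k=st.floats(min_value=1e-3, max_value=1e3))
    def test_joint_scale_invariance(self, a, k):
        b = np.roll(a, 1)
        assert coactivation_coefficient(k * a, k * b) == pytest.approx(
            coactivation_coefficient(a, b), abs=1e-6
        )

    def test_single_envelope_scaling_is_monotone(self):
        rng = np.random.default_rng(3)
        a = np.abs(rng.standard_normal(80)) + 0.05
        b = np.abs(rng.standard_normal(80)) + 0.05
        ks = [1e-4, 1e-2, 0.5, 1.0]
        ccs = [coactivation_coefficient(a, k * b) for k in ks]
        assert ccs[0] < 1.0  # k -> 0 drives CC toward 0
        assert all(x < y for x, y in zip(ccs[:-1], ccs[1:]))

    def test_length_mismatch_and_negative_inputs_rejected(self):
        with pytest.raises(AlignmentError):
            coactivation_coefficient(np.ones(5), np.ones(6))
        with pytest.raises(ValueError):
            coactivation_coefficient(np.array([-1.0, 1.0]), np.ones(2))

    def test_trapezoid_matches_dense_riemann_on_smooth_envelopes(self):
        # envelopes vanishing at segment ends: trapezoid and Riemann sums
        # coincide, so Eq. 1 agrees with the brute-force oracle to 1e-9
        t = np.linspace(0, 1, 2000)
        a = np.sin(np.pi * t) ** 2
        b = 0.4 * np.sin(np.pi * t) ** 2 + 0.2 * np.sin(2 * np.pi * t) ** 2
        dx = t[1] - t[0]
        riemann = (
            2 * np.sum(np.minimum(a, b)) / (np.sum(a) + np.sum(b)) * 100
        )
        assert coactivation_coefficient(a, b, dx=dx) == pytest.approx(riemann, abs=1e-9)


class TestCcByPhase:
    def trial(self, fracs=(0.2, 0.5, 0.2, 0.2)):
        order = (Phase.ACC_FLEX, Phase.DEC_FLEX, Phase.ACC_EXT, Phase.DEC_EXT)
        model = ActivationModel(
            antagonist_frac=dict(zip(order, fracs)), tonic_triceps=0.0, noise_floor=0.0
        )
        protocol = MovementProtocol(bpm=60, n_cycles=6, cycle_jitter=0.0)
        return generate_trial(protocol, model, seed=0)

    def normalized(self, e):
        peak = e.samples.max()
        return env(e.samples / peak if peak > 0 else e.samples, muscle=e.muscle)

    def test_elevated_flexion_deceleration_ratio_dominates(self):
        trial = self.trial((0.2, 0.5, 0.2, 0.2))
        res = cc_by_phase(
            self.normalized(trial.biceps_envelope),
            self.normalized(trial.triceps_envelope),
            trial.truth_segmentation,
        )
        means = res.phase_means()
        assert means["Dec_Flex"] > max(
            means["Acc_Flex"], means["Acc_Ext"], means["Dec_Ext"]
        )

    def test_silent_triceps_gives_zero_everywhere(self):
        trial = self.trial()
        silent = env(np.zeros_like(trial.triceps_envelope.samples), muscle="triceps")
        res = cc_by_phase(
            self.normalized(trial.biceps_envelope), silent, trial.truth_segmentation
        )
        assert (res.per_phase["cc"] == 0.0).all()
        assert (res.per_cycle["cc"] == 0.0).all()

    def test_concatenated_phase_integrals_reproduce_full_cycle_cc(self):
        # sum-of-integrals convention: phase areas add up to the cycle areas,
        # checked against a brute-force sample-sum oracle
        trial = self.trial((0.3, 0.6, 0.1, 0.4))
        b = self.normalized(trial.biceps_envelope).samples
        t = self.normalized(trial.triceps_envelope).samples
        for cyc in trial.truth_segmentation:
            common = total = 0.0
            for phase in PHASE_ORDER:
                s, e = cyc.spans[phase]
                bs, ts = b[s : e + 1], t[s : e + 1]
                common += np.trapezoid(np.minimum(bs, ts))
                total += np.trapezoid(bs) + np.trapezoid(ts)
            oracle = 2 * common / total * 100
            bs, ts = b[cyc.start : cyc.end + 1], t[cyc.start : cyc.end + 1]
            full = coactivation_coefficient(bs, ts)
            assert full == pytest.approx(oracle, abs=1e-9)

    def test_agonist_labels_follow_movement_direction(self):
        trial = self.trial()
        res = cc_by_phase(
            self.normalized(trial.biceps_envelope),
            self.normalized(trial.triceps_envelope),
            trial.truth_segmentation,
        )
        lab = res.per_phase.drop_duplicates("phase").set_index("phase")["agonist"]
        assert lab["Acc_Flex"] == lab["Dec_Flex"] == "biceps"
        assert lab["Acc_Ext"] == lab["Dec_Ext"] == "triceps"


class TestMuscleSynergy:
    def test_flexion_only_biceps_has_full_flexion_share(self):
        protocol = MovementProtocol(bpm=60, n_cycles=4, cycle_jitter=0.0)
        model = ActivationModel(
            antagonist_frac={p: 0.0 for p in PHASE_ORDER}, tonic_triceps=0.0, noise_floor=0.0
        )
        trial = generate_trial(protocol, model, seed=0)
        res = muscle_synergy(
            trial.biceps_envelope, trial.triceps_envelope, trial.truth_segmentation
        )
        biceps = res.per_cycle[res.per_cycle["muscle"] == "biceps"]
        assert np.allclose(biceps["flexion_pct"], 100.0, atol=1e-9)
        assert np.allclose(biceps["extension_pct"], 0.0, atol=1e-9)

    def test_tonic_only_triceps_share_follows_phase_durations(self):
        # constant envelope: area ratio equals the flexion share of cycle time
        protocol = MovementProtocol(bpm=60, n_cycles=4, cycle_jitter=0.0)
        model = ActivationModel(
            antagonist_frac={p: 0.3 for p in PHASE_ORDER}, tonic_triceps=0.0, noise_floor=0.0
        )
        trial = generate_trial(protocol, model, seed=0)
        tonic = env(np.full_like(trial.triceps_envelope.samples, 0.25), muscle="triceps")
        res = muscle_synergy(trial.biceps_envelope, tonic, trial.truth_segmentation)
        triceps = res.per_cycle[res.per_cycle["muscle"] == "triceps"]
        for _, row in triceps.iterrows():
            cyc = trial.truth_segmentation.cycles[int(row["cycle"])]
            flex_len = sum(
                cyc.spans[p][1] - cyc.spans[p][0] for p in PHASE_ORDER if p.is_flexion
            )
            total_len = cyc.end - cyc.start
            assert row["flexion_pct"] == pytest.approx(100 * flex_len / total_len, abs=0.5)

    def test_shares_sum_to_100_and_mirror_under_muscle_swap(self, jitterfree_trial):
        seg = jitterfree_trial.truth_segmentation
        b, t = jitterfree_trial.biceps_envelope, jitterfree_trial.triceps_envelope
        res = muscle_synergy(b, t, seg)
        active = res.per_cycle.dropna()
        assert np.allclose(active["flexion_pct"] + active["extension_pct"], 100.0, atol=1e-9)
        swapped = muscle_synergy(
            env(t.samples, muscle="biceps"), env(b.samples, muscle="triceps"), seg
        )
        orig_t = res.per_cycle[res.per_cycle["muscle"] == "triceps"]["flexion_pct"]
        swap_b = swapped.per_cycle[swapped.per_cycle["muscle"] == "biceps"]["flexion_pct"]
        assert np.allclose(orig_t.to_numpy(), swap_b.to_numpy())

    def test_silent_muscle_reported_missing(self, jitterfree_trial):
        seg = jitterfree_trial.truth_segmentation
        silent = env(np.zeros_like(jitterfree_trial.biceps_envelope.samples), muscle="triceps")
        with pytest.warns(UserWarning):
            res = muscle_synergy(jitterfree_trial.biceps_envelope, silent, seg)
        triceps = res.per_cycle[res.per_cycle["muscle"] == "triceps"]
        assert triceps["flexion_pct"].isna().all()

    def test_between_muscle_share_complements(self, jitterfree_trial):
        res = muscle_synergy(
            jitterfree_trial.biceps_envelope,
            jitterfree_trial.triceps_envelope,
            jitterfree_trial.truth_segmentation,
        )
        flex = res.between_muscle[res.between_muscle["half"] == "flexion"]
        assert (flex["biceps_pct"] > 50).all()  # biceps dominates its agonist half
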