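import numpy as np
import pytest

from hypnodense import (
    FOUR_STAGE,
    GroupProfile,
    ambiguity_series,
    annotate_transition_continuity,
    cohens_kappa,
    confusion,
    hypnogram_from_hypnodensity,
    load_profile,
    osa_like,
    per_class_scores,
    rbd_like,
    simulate_cohort,
    simulate_hypnodensity,
    simulate_hypnogram,
    simulate_manual,
)
from hypnodense.metrics import extract_bouts


def flat_profile(**kwargs):
    defaults = dict(
        name="flat",
        transition_matrix=np.full((4, 4), 0.25),
        concentration=10.0,
    )
    defaults.update(kwargs)
    return GroupProfile(**defaults)


class TestProfiles:
    def test_row_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GroupProfile(name="bad", transition_matrix=np.eye(4) * 0.9)

    def test_parameter_ranges(self):
        with pytest.raises(ValueError):
            flat_profile(concentration=0)
        with pytest.raises(ValueError):
            flat_profile(rem_leak=1.0)
        with pytest.raises(ValueError):
            flat_profile(manual_noise=-0.1)

    def test_presets_load_by_name_and_yaml(self):
        for name, fn in (("rbd_like", rbd_like), ("osa_like", osa_like)):
            by_name = load_profile(name)
            np.testing.assert_allclose(
                by_name.transition_matrix, fn().transition_matrix
            )
            assert by_name.concentration == fn().concentration

    def test_preset_contrast_direction(self):
        # rbd_like is constructed leakier and smoother than osa_like
        rbd, osa = rbd_like(), osa_like()
        assert rbd.rem_leak > osa.rem_leak
        assert rbd.crossfade_epochs > osa.crossfade_epochs
        assert rbd.concentration < osa.concentration


class TestSimulateHypnogram:
    def test_identity_matrix_constant(self):
        profile = flat_profile(transition_matrix=np.eye(4))
        h = simulate_hypnogram(profile, 100, seed=0)
        assert len(set(h.labels)) == 1
        assert h.labels[0] == "W"  # chain starts in W

    def test_deterministic_per_seed(self):
        profile = rbd_like()
        a = simulate_hypnogram(profile, 300, seed=7)
        b = simulate_hypnogram(profile, 300, seed=7)
        c = simulate_hypnogram(profile, 300, seed=8)
        assert np.array_equal(a.codes, b.codes)
        assert not np.array_equal(a.codes, c.codes)

    def test_geometric_mean_bout_length(self):
        # diagonal 0.95 -> geometric mean run length 1/(1-0.95) = 20 epochs
        tm = np.full((4, 4), 0.05 / 3)
        np.fill_diagonal(tm, 0.95)
        profile = flat_profile(transition_matrix=tm)
        lengths = []
        for s in range(40):
            h = simulate_hypnogram(profile, 5000, seed=s)
            # drop edge bouts: censored run lengths bias the mean
            lengths.extend(b.length_epochs for b in extract_bouts(h)[1:-1])
        assert len(lengths) > 5000
        assert np.mean(lengths) == pytest.approx(20.0, rel=0.05)

    def test_min_epochs(self):
        with pytest.raises(ValueError):
            simulate_hypnogram(flat_profile(), 1, seed=0)


class TestSimulateHypnodensity:
    def test_rows_sum_to_one(self):
        truth = simulate_hypnogram(rbd_like(), 200, seed=1)
        hd = simulate_hypnodensity(truth, rbd_like(), seed=1)
        np.testing.assert_allclose(hd.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_high_concentration_low_ambiguity(self):
        truth = simulate_hypnogram(flat_profile(), 500, seed=2)
        sharp = flat_profile(concentration=5000.0)
        hd = simulate_hypnodensity(truth, sharp, seed=2)
        series = ambiguity_series(hd, hypnogram_from_hypnodensity(hd))
        assert series.values.mean() < 0.05

    def test_ambiguity_decreasing_in_concentration(self):
        truth = simulate_hypnogram(flat_profile(), 5000, seed=3)
        means = []
        for conc in (1, 3, 10, 30, 100):
            hd = simulate_hypnodensity(
                truth, flat_profile(concentration=float(conc)), seed=3
            )
            series = ambiguity_series(hd, hypnogram_from_hypnodensity(hd))
            means.append(series.values.mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_continuity_increasing_in_crossfade(self):
        profile = flat_profile(concentration=20.0)
        truth = simulate_hypnogram(profile, 5000, seed=4)
        means = []
        for c in (0, 1, 2, 3):
            hd = simulate_hypnodensity(
                truth, flat_profile(concentration=20.0, crossfade_epochs=c),
                seed=4,
            )
            staging = hypnogram_from_hypnodensity(hd)
            conts = [
                t.continuity
                for t in annotate_transition_continuity(hd, staging)
            ]
            means.append(np.mean(conts))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_rem_leak_halves_rem_probability(self):
        tm = np.full((4, 4), 0.01 / 3)
        np.fill_diagonal(tm, 0.99)  # long runs, mostly REM after burn-in
        # force REM-rich truth by starting transitions toward R
        truth = simulate_hypnogram(flat_profile(), 20000, seed=5)
        rem_code = FOUR_STAGE.index("R")
        base = simulate_hypnodensity(
            truth, flat_profile(rem_leak=0.0), seed=5
        )
        leaky = simulate_hypnodensity(
            truth, flat_profile(rem_leak=0.5), seed=5
        )
        rem_rows = truth.codes == rem_code
        assert rem_rows.sum() > 2000
        mean_base = base.probs[rem_rows, rem_code].mean()
        mean_leaky = leaky.probs[rem_rows, rem_code].mean()
        assert mean_leaky == pytest.approx(0.5 * mean_base, rel=0.02)

    def test_rem_leak_goes_mostly_to_n12(self):
        truth = simulate_hypnogram(flat_profile(), 20000, seed=6)
        rem_code = FOUR_STAGE.index("R")
        n12_code = FOUR_STAGE.index("N1+N2")
        w_code = FOUR_STAGE.index("W")
        base = simulate_hypnodensity(truth, flat_profile(rem_leak=0.0), seed=6)
        leaky = simulate_hypnodensity(truth, flat_profile(rem_leak=0.6), seed=6)
        rem_rows = truth.codes == rem_code
        gain_n12 = (leaky.probs[rem_rows, n12_code]
                    - base.probs[rem_rows, n12_code]).mean()
        gain_w = (leaky.probs[rem_rows, w_code]
                  - base.probs[rem_rows, w_code]).mean()
        assert gain_n12 == pytest.approx(2 * gain_w, rel=0.02)


class TestSimulateManual:
    def test_zero_noise_identical(self):
        truth = simulate_hypnogram(rbd_like(), 400, seed=7)
        manual = simulate_manual(truth, rbd_like().replace(manual_noise=0.0),
                                 seed=7)
        assert np.array_equal(manual.codes, truth.codes)

    def test_full_noise_never_agrees(self):
        truth = simulate_hypnogram(rbd_like(), 400, seed=8)
        noisy = simulate_manual(
            truth, rbd_like().replace(manual_noise=0.999999), seed=8
        )
        agreement_rate = np.mean(noisy.codes == truth.codes)
        assert agreement_rate < 0.01

    def test_kappa_monotone_in_noise(self):
        profile = rbd_like()
        noise_grid = (0.0, 0.1, 0.3, 0.6)
        kappas = []
        for noise in noise_grid:
            vals = []
            for seed in range(10):
                truth = simulate_hypnogram(profile, 2000, seed=seed)
                manual = simulate_manual(
                    truth, profile.replace(manual_noise=noise), seed=seed
                )
                vals.append(cohens_kappa(confusion(truth, manual)))
            kappas.append(np.mean(vals))
        assert all(a > b for a, b in zip(kappas, kappas[1:]))


class TestSimulateCohort:
    def test_sizes_and_invariants(self, contrast_cohort):
        assert len(contrast_cohort) == 12
        for rec in contrast_cohort.records:
            assert set(rec.methods) == {"manual", "exg", "hrvm"}
            assert rec.hypnodensity("manual") is None
            for m in ("exg", "hrvm"):
                hd = rec.hypnodensity(m)
                assert hd is not None
                np.testing.assert_allclose(hd.probs.sum(axis=1), 1.0, atol=1e-9)
                assert np.array_equal(
                    rec.hypnogram(m).codes,
                    hypnogram_from_hypnodensity(hd).codes,
                )

    def test_deterministic(self):
        profiles = {"a": rbd_like(), "b": osa_like()}
        c1 = simulate_cohort(profiles, 2, 120, seed=5)
        c2 = simulate_cohort(profiles, 2, 120, seed=5)
        for r1, r2 in zip(c1.records, c2.records):
            for m in r1.methods:
                assert np.array_equal(r1.hypnogram(m).codes,
                                      r2.hypnogram(m).codes)

    def test_kappa_and_rem_sensitivity_decrease_with_rem_leak(self):
        # moderate concentration so argmax flips respond gradually to leak
        base = osa_like().replace(crossfade_epochs=0, concentration=4.0)
        leak_grid = (0.0, 0.2, 0.4, 0.6)
        kappas, rem_sens = [], []
        for leak in leak_grid:
            profile = base.replace(rem_leak=leak)
            ks, ss = [], []
            for seed in range(5):
                truth = simulate_hypnogram(profile, 3000, seed=seed)
                hd = simulate_hypnodensity(truth, profile, seed=seed)
                staged = hypnogram_from_hypnodensity(hd)
                cm = confusion(truth, staged)
                ks.append(cohens_kappa(cm))
                ss.append(per_class_scores(cm)["R"]["sensitivity"])
            kappas.append(np.mean(ks))
            rem_sens.append(np.mean(ss))
        assert all(a > b for a, b in zip(kappas, kappas[1:]))
        assert all(a > b for a, b in zip(rem_sens, rem_sens[1:]))

    def test_rem_confusion_dominated_by_n12(self):
        profile = osa_like().replace(rem_leak=0.5, crossfade_epochs=0)
        n12 = FOUR_STAGE.index("N1+N2")
        w = FOUR_STAGE.index("W")
        n3 = FOUR_STAGE.index("N3")
        r = FOUR_STAGE.index("R")
        lost = np.zeros(4)
        for seed in range(5):
            truth = simulate_hypnogram(profile, 3000, seed=seed)
            hd = simulate_hypnodensity(truth, profile, seed=seed)
            cm = confusion(truth, hypnogram_from_hypnodensity(hd))
            lost += cm.counts[r]
        assert lost[n12] > lost[w] > lost[n3]

    def test_group_contrast_directions(self):
        cohort = simulate_cohort(
            {"rbd_like": rbd_like(), "osa_like": osa_like()},
            n_subjects=8, n_epochs=480, seed=11,
        )
        rem_amb = {"rbd_like": [], "osa_like": []}
        cont = {"rbd_like": [], "osa_like": []}
        for rec in cohort.records:
            hd = rec.hypnodensity("exg")
            staging = rec.hypnogram("exg")
            series = ambiguity_series(hd, staging)
            rem_amb[rec.group].extend(series.for_stage("R"))
            cont[rec.group].extend(
                t.continuity
                for t in annotate_transition_continuity(hd, staging)
            )
        assert np.median(rem_amb["rbd_like"]) > np.median(rem_amb["osa_like"])
        assert np.median(cont["rbd_like"]) > np.median(cont["osa_like"])
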