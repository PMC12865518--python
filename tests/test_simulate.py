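"""Synthetic-cohort generator: determinism, calibration, convergence, dependence."""
import io
from dataclasses import replace

import numpy as np
import pytest

import resectability as rs
from resectability.cohort import Assessor
from resectability import study_counts as sc
from resectability.simulate import (
    _simulate_arrays,
    _vector_paired_auc,
    default_sim_config,
    shifted_config,
)


def _csv_bytes(cohort):
    buf = io.StringIO()
    rs.write_cohort(cohort, buf)
    return buf.getvalue()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_csv(self):
        config = default_sim_config(n_patients=80, seed=12)
        assert _csv_bytes(rs.simulate_cohort(config)) == _csv_bytes(rs.simulate_cohort(config))

    def test_different_seed_differs(self):
        a = default_sim_config(n_patients=80, seed=12)
        b = default_sim_config(n_patients=80, seed=13)
        assert _csv_bytes(rs.simulate_cohort(a)) != _csv_bytes(rs.simulate_cohort(b))

    def test_experiment_table_reproducible(self):
        config = default_sim_config(n_patients=100, seed=0, inoperable_fraction=0.0,
                                    mri_missing_fraction=0.0)
        one = rs.experiment_type1_power(config, true_delta_grid=(0.0,), reps=500, seed=5)
        two = rs.experiment_type1_power(config, true_delta_grid=(0.0,), reps=500, seed=5)
        assert one.equals(two)


class TestGeneratedCohorts:
    def test_round_trip_through_reader(self, tmp_path):
        config = default_sim_config(n_patients=60, seed=7)
        cohort = rs.simulate_cohort(config)
        path = tmp_path / "sim.csv"
        rs.write_cohort(cohort, path)
        again = rs.read_cohort(path)  # strict: any invariant breach raises
        assert again.records == cohort.records

    def test_perfect_detection_recovers_truth(self):
        config = default_sim_config(n_patients=400, seed=3, inoperable_fraction=0.0,
                                    mri_missing_fraction=0.0)
        perfect = replace(
            config,
            sensitivity={a: 1.0 for a in config.sensitivity},
            false_call={a: 0.0 for a in config.false_call},
            inter_modality_rho=0.0,
        )
        cohort = rs.simulate_cohort(perfect)
        res = rs.DiagnosticAccuracy.from_cohort(cohort, Assessor.US).fit()
        assert res.metrics.auc == 1.0
        assert res.counts.fp == res.counts.fn == 0

    def test_outcome_structure_matches_config_fractions(self):
        config = default_sim_config(n_patients=5000, seed=21)
        cohort = rs.simulate_cohort(config)
        n = len(cohort)
        inoperable = sum(1 for r in cohort if r.outcome.inoperable)
        mri = sum(1 for r in cohort if r.mri_available)
        assert inoperable / n == pytest.approx(config.inoperable_fraction, abs=0.02)
        assert mri / n == pytest.approx(1 - config.mri_missing_fraction, abs=0.02)


class TestCalibration:
    def test_operating_points_reproduced_in_closed_form(self):
        config = default_sim_config(n_patients=167)
        for assessor, (se, sp) in sc.OPERATING_POINTS.items():
            assert rs.patient_sensitivity(config, assessor) == pytest.approx(se, abs=1e-9)
            assert rs.patient_specificity(config, assessor) == pytest.approx(sp, abs=1e-9)

    def test_large_sample_surgical_any_frequency(self):
        """10^5-patient cohort reproduces the surgical any-criterion margin
        within one percentage point."""
        config = default_sim_config(n_patients=100_000, seed=2)
        arrays = _simulate_arrays(config, np.random.default_rng(2), reps=1,
                                  assessors=[Assessor.SURG_EXPL])
        freq = float(arrays["labels"][Assessor.SURG_EXPL].mean())
        assert freq == pytest.approx(78 / 242, abs=0.01)

    def test_site_marginals_converge_at_binomial_rate(self):
        config = default_sim_config(n_patients=100_000, seed=4)
        arrays = _simulate_arrays(config, np.random.default_rng(4), reps=1,
                                  assessors=[Assessor.SURG_EXPL])
        truth = arrays["truth"][0]
        involved = arrays["involved"][0]
        p = np.asarray(config.site_probs_nonresectable)
        p0 = np.prod(1 - p)
        expected = p / (1 - p0)  # conditioned on >= 1 involved site
        observed = involved[truth].mean(axis=0)
        n1 = int(truth.sum())
        tol = 4 * np.sqrt(expected * (1 - expected) / n1)
        assert np.all(np.abs(observed - expected) <= tol)

    def test_degenerate_single_site_perfect_detection_is_exact(self):
        config = rs.calibrate_from_margins(
            [0.25] + [0.0] * 7,
            {Assessor.SURG_EXPL: (1.0, 1.0), Assessor.US: (1.0, 1.0)},
            prevalence=0.25,
        )
        assert config.site_probs_nonresectable[0] == pytest.approx(1.0, abs=0.01)
        assert rs.patient_sensitivity(config, Assessor.US) == pytest.approx(1.0)

    def test_infeasible_sensitivity_cap_raises(self):
        with pytest.raises(rs.CalibrationError):
            rs.calibrate_from_margins(
                [c / 242 for c in sc.SITE_COUNTS[Assessor.SURG_EXPL]],
                sc.OPERATING_POINTS, any_freq=78 / 242,
                max_site_sensitivity=0.5,
            )

    def test_config_survives_dict_round_trip(self):
        config = default_sim_config(n_patients=50, seed=9)
        assert rs.SimConfig.from_dict(config.to_dict()) == config


class TestDependence:
    def test_rho_shrinks_paired_se(self):
        """Stronger shared-latent correlation between modalities reduces the
        paired AUC standard error (monotone over a rho grid)."""
        mean_ses = []
        for rho in (0.0, 0.45, 0.9):
            config = default_sim_config(
                n_patients=167, seed=0, inoperable_fraction=0.0,
                mri_missing_fraction=0.0, inter_modality_rho=rho)
            arrays = _simulate_arrays(config, np.random.default_rng(17), reps=400,
                                      assessors=[Assessor.US, Assessor.CT])
            la = arrays["labels"][Assessor.US]
            lb = arrays["labels"][Assessor.CT]
            truth = arrays["truth"]
            ses = []
            for k in range(400):
                pairs = rs.PairedPredictions(la[k], lb[k], truth[k])
                ses.append(rs.paired_auc_noninf(pairs).se_diff)
            mean_ses.append(np.mean(ses))
        assert mean_ses[0] > mean_ses[1] > mean_ses[2]

    def test_vectorized_decision_matches_scalar_test(self):
        config = default_sim_config(n_patients=167, seed=0, inoperable_fraction=0.0,
                                    mri_missing_fraction=0.0)
        arrays = _simulate_arrays(config, np.random.default_rng(6), reps=50,
                                  assessors=[Assessor.US, Assessor.CT])
        la = arrays["labels"][Assessor.US]
        lb = arrays["labels"][Assessor.CT]
        truth = arrays["truth"]
        mask = np.ones_like(truth, dtype=bool)
        reject, valid = _vector_paired_auc(la, lb, truth, mask, 0.05, 0.05)
        for k in range(50):
            pairs = rs.PairedPredictions(la[k], lb[k], truth[k])
            res = rs.paired_auc_noninf(pairs, margin=0.05, alpha=0.05)
            assert valid[k]
            assert bool(reject[k]) == (res.conclusion == "noninferior")


class TestShiftedConfig:
    def test_target_auc_difference_is_exact(self):
        config = default_sim_config(n_patients=167)
        for delta in (-0.05, 0.0, 0.05):
            shifted = shifted_config(config, Assessor.US, Assessor.CT, delta)
            auc_a = (rs.patient_sensitivity(shifted, Assessor.US)
                     + rs.patient_specificity(shifted, Assessor.US)) / 2
            auc_b = (rs.patient_sensitivity(shifted, Assessor.CT)
                     + rs.patient_specificity(shifted, Assessor.CT)) / 2
            assert auc_a - auc_b == pytest.approx(delta, abs=1e-9)

    def test_unattainable_shift_rejected(self):
        config = default_sim_config(n_patients=167)
        with pytest.raises(ValueError):
            shifted_config(config, Assessor.US, Assessor.CT, -0.25)
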