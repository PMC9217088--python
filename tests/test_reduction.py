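"""Calibration, blank estimation/correction, N content and batch QC."""

import numpy as np
import pandas as pd
import pytest

from paleotroph import (
    BlankError,
    CalibrationError,
    batch_qc,
    blank_correct,
    estimate_blank,
    fit_calibration,
    n_content,
    reduce_dataset,
    simulate_foodweb,
    simulate_raw_batch,
)
from paleotroph.reduction import BlankEstimate

from conftest import make_config


def _refs(iaea, usgs34):
    rows = []
    for name, vals in (("IAEA-NO3", iaea), ("USGS34", usgs34)):
        cert = 4.7 if name == "IAEA-NO3" else -1.8
        for v in np.atleast_1d(vals):
            rows.append(
                dict(analysis_id=f"r{len(rows)}", batch_id="B1", specimen_id=name,
                     role="nitrate_reference", measured_d15n=v, n_amount=20.0,
                     certified_d15n=cert)
            )
    return pd.DataFrame(rows)


class TestCalibration:
    def test_two_point_example(self):
        line = fit_calibration(_refs(5.0, -1.5))
        assert line.slope == pytest.approx(1.0, abs=1e-12)
        assert line.intercept == pytest.approx(-0.3, abs=1e-12)

    def test_identity_when_measured_equals_certified(self):
        line = fit_calibration(_refs(4.7, -1.8))
        assert line.slope == pytest.approx(1.0, abs=1e-12)
        assert line.intercept == pytest.approx(0.0, abs=1e-12)

    def test_replicates_fix_both_reference_means(self, rng):
        # the fitted line must map each reference's mean measured value
        # exactly onto its certified value
        iaea = 5.1 + rng.normal(0, 0.1, size=3)
        usgs = -1.4 + rng.normal(0, 0.1, size=3)
        line = fit_calibration(_refs(iaea, usgs))
        assert line.apply(iaea.mean()) == pytest.approx(4.7, abs=1e-10)
        assert line.apply(usgs.mean()) == pytest.approx(-1.8, abs=1e-10)
        # equals the unique least-squares line through the two mean points
        slope, intercept = np.polyfit([iaea.mean(), usgs.mean()], [4.7, -1.8], 1)
        assert line.slope == pytest.approx(slope, abs=1e-10)
        assert line.intercept == pytest.approx(intercept, abs=1e-10)

    def test_single_reference_errors(self):
        refs = _refs(5.0, -1.5)
        with pytest.raises(CalibrationError, match="two-point"):
            fit_calibration(refs[refs["specimen_id"] == "IAEA-NO3"])


def _aa(rows):
    return pd.DataFrame(
        [
            dict(analysis_id=f"a{i}", batch_id="B1", specimen_id=name,
                 role="amino_acid_reference", measured_d15n=meas,
                 n_amount=n_tot, certified_d15n=cert)
            for i, (name, cert, meas, n_tot) in enumerate(rows)
        ]
    )


def _blank_rows(nmol):
    return pd.DataFrame(
        [dict(analysis_id="b0", batch_id="B1", specimen_id="blank", role="blank",
              measured_d15n=np.nan, n_amount=nmol)]
    )


class TestBlank:
    def test_single_reference_mass_balance(self):
        # (10*20.0 - 9.6*20.68) / 0.4 = 3.68
        est = estimate_blank(
            _aa([("USGS65", 20.68, 20.0, 10.0)]), _blank_rows(0.4)
        )
        assert est.blank_nmol == pytest.approx(0.4)
        assert est.blank_d15n == pytest.approx(3.68, abs=1e-10)

    def test_unidentifiable_when_no_leverage(self):
        rows = [("USGS65", 20.68, 20.5, 10.0)] * 3
        with pytest.raises(BlankError, match="unidentifiable"):
            estimate_blank(_aa(rows), _blank_rows(0.4))

    def test_zero_misfit_flags_no_detectable_blank(self):
        rows = [("USGS40", -4.5, -4.5, 10.0), ("USGS65", 20.68, 20.68, 25.0)]
        est = estimate_blank(_aa(rows), _blank_rows(0.4))
        assert est.no_detectable_blank
        assert est.blank_nmol == pytest.approx(0.4)
        # blank correction becomes the identity
        assert blank_correct(12.0, 20.0, est) == pytest.approx(12.0)

    def test_recovery_from_generated_batch(self, rng):
        # 8 references, both materials, 5-50 nmol, true blank 6.0 permil
        true_b, nb = 6.0, 0.4
        rows = []
        for cert in (-4.5, 20.68):
            name = "USGS40" if cert < 0 else "USGS65"
            for size in (5.0, 12.0, 25.0, 50.0):
                meas = (size * cert + nb * true_b) / (size + nb) + rng.normal(0, 0.02)
                rows.append((name, cert, meas, size + nb))
        est = estimate_blank(_aa(rows), _blank_rows(nb))
        assert est.blank_d15n == pytest.approx(true_b, abs=0.2)


class TestBlankCorrect:
    def test_worked_example(self):
        est = BlankEstimate("B1", 0.4, 5.0)
        assert blank_correct(10.0, 20.0, est) == pytest.approx(198.0 / 19.6, abs=1e-12)

    def test_zero_blank_is_identity(self):
        assert blank_correct(10.0, 20.0, BlankEstimate("B1", 0.0, 5.0)) == 10.0

    def test_dominating_blank_errors(self):
        with pytest.raises(BlankError, match="dominates"):
            blank_correct(10.0, 0.3, BlankEstimate("B1", 0.4, 5.0))

    def test_forward_mixing_round_trip(self, rng):
        # correcting then re-mixing must reproduce the measurement to 1e-9
        for _ in range(1000):
            nb = rng.uniform(0.0, 1.0)
            nt = nb + rng.uniform(1.0, 50.0)
            db = rng.uniform(-10, 25)
            dm = rng.uniform(-10, 30)
            est = BlankEstimate("B", nb, db)
            ds = blank_correct(dm, nt, est)
            remixed = (ds * (nt - nb) + db * nb) / nt
            assert abs(remixed - dm) < 1e-9

    def test_correction_moves_away_from_blank(self):
        # sample above the blank: more blank N pulls the measurement down,
        # so the corrected value must rise with blank size
        prev = 10.0
        for nb in (0.1, 0.3, 0.6, 1.0):
            cor = blank_correct(10.0, 20.0, BlankEstimate("B", nb, 5.0))
            assert cor > prev
            prev = cor


class TestNContent:
    @pytest.mark.parametrize(
        "tot,blank,mass,expect", [(30.0, 0.0, 4.0, 7.5), (30.4, 0.4, 4.0, 7.5)]
    )
    def test_examples(self, tot, blank, mass, expect):
        assert n_content(tot, blank, mass) == pytest.approx(expect)

    def test_over_subtraction_flagged(self):
        with pytest.raises(BlankError, match="over-subtraction"):
            n_content(0.3, 0.4, 4.0)

    def test_fossil_class_mean_recovered(self):
        cfg = make_config()
        _, teeth = simulate_foodweb(cfg)
        fossil = teeth[teeth["preservation"] == "fossil"]["true_n_content"]
        se = 2.0 / np.sqrt(len(fossil))
        assert abs(fossil.mean() - 4.8) < 2 * se


def _standards(values_by_batch, name="std"):
    rows = []
    for batch, vals in values_by_batch.items():
        for v in vals:
            rows.append(
                dict(analysis_id=f"s{len(rows)}", batch_id=batch, specimen_id=name,
                     role="inhouse_standard", measured_d15n=v, n_amount=25.0,
                     dissolved_mass=3.0)
            )
    return pd.DataFrame(rows)


class TestBatchQC:
    def test_within_batch_sd(self):
        rep = batch_qc(_standards({"B1": [10.0, 10.5, 11.0]}))
        assert rep.per_batch["sd_d15n"].iloc[0] == pytest.approx(0.5)

    def test_identical_batches_have_no_batch_effect(self):
        rep = batch_qc(_standards({"B1": [10.0, 10.5, 11.0], "B2": [10.0, 10.5, 11.0]}))
        s = rep.summary.iloc[0]
        assert s["longterm_sd_d15n"] == pytest.approx(s["avg_within_sd_d15n"], rel=0.2)

    def test_variance_components(self, rng):
        # between-batch 0.6, within 0.37 -> long-term ~= sqrt(0.6^2 + 0.37^2)
        longterms = []
        for _ in range(50):
            batches = {
                f"B{b}": 12.0 + rng.normal(0, 0.6) + rng.normal(0, 0.37, size=3)
                for b in range(8)
            }
            longterms.append(batch_qc(_standards(batches)).summary["longterm_sd_d15n"].iloc[0])
        expect = np.hypot(0.6, 0.37)
        assert abs(np.mean(longterms) - expect) < 0.15 * expect

    def test_single_replicates_warn(self):
        with pytest.warns(UserWarning, match="within-batch SD undefined"):
            rep = batch_qc(_standards({"B1": [10.0], "B2": [10.4]}))
        assert np.isnan(rep.summary["avg_within_sd_d15n"].iloc[0])


class TestFullReduction:
    def test_round_trip_recovers_true_values(self):
        # reduce(simulate_raw_batch(...)) within 3 x meas_sd for >= 99%
        hits = total = 0
        for seed in range(20):
            cfg = make_config(seed=seed)
            _, teeth = simulate_foodweb(cfg)
            raw = simulate_raw_batch(teeth, cfg)
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # blank-fraction QC warnings
                red = reduce_dataset(raw)
            j = teeth.merge(red.samples, on="specimen_id", suffixes=("", "_r"))
            err = np.abs(j["d15n_eb_r"] - j["true_d15n_eb"])
            hits += int((err < 3 * cfg.meas_sd_eb).sum())
            total += len(err)
        assert hits / total >= 0.99

    def test_calibrate_then_blank_correct_is_exact_on_clean_batches(self):
        from conftest import noise_free

        cfg = noise_free(blank_nmol_range=(0.3, 0.5), cal_slope=0.98, cal_intercept=-0.3)
        _, teeth = simulate_foodweb(cfg)
        raw = simulate_raw_batch(teeth, cfg)
        red = reduce_dataset(raw)
        j = teeth.merge(red.samples, on="specimen_id", suffixes=("", "_r"))
        assert np.allclose(j["d15n_eb_r"], j["true_d15n_eb"], atol=1e-8)
        assert np.allclose(j["n_content"], j["true_n_content"], atol=1e-8)
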