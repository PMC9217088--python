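"""Baseline-referenced trophic algebra, Welch tests, screens."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleotroph import (
    FitError,
    SpeciesSpec,
    TDFModel,
    absolute_trophic_level,
    baseline_consistency,
    delta_vs_baseline,
    diagenesis_screen,
    diet_d15n,
    piscivore_baseline,
    reconstruct,
    simulate_foodweb,
    summarize_groups,
    trophic_offset,
    welch_test,
    welch_tests,
)

from conftest import make_config


def teeth_frame(rows):
    df = pd.DataFrame(rows)
    for col, default in (
        ("genus", "G"), ("region", "A"), ("preservation", "fossil"),
        ("n_content", np.nan),
    ):
        if col not in df.columns:
            df[col] = default
    return df


def test_summarize_groups():
    teeth = teeth_frame(
        [dict(specimen_id=f"t{i}", species="sp", epoch="Miocene",
              is_piscivore=False, d15n_eb=v) for i, v in enumerate([10.0, 12.0, 14.0])]
        + [dict(specimen_id="t9", species="solo", epoch="Miocene",
                is_piscivore=False, d15n_eb=20.0)]
    )
    out = summarize_groups(teeth).set_index("species")
    assert out.loc["sp", "n"] == 3
    assert out.loc["sp", "mean_d15n"] == pytest.approx(12.0)
    assert out.loc["sp", "sd_d15n"] == pytest.approx(2.0)
    assert np.isnan(out.loc["solo", "sd_d15n"])


class TestBaseline:
    def test_pooled_piscivore_teeth(self):
        teeth = teeth_frame(
            [dict(specimen_id=f"p{i}", species="pisc", epoch="Eocene",
                  is_piscivore=True, d15n_eb=v) for i, v in enumerate([13.0, 15.0, 17.0])]
        )
        mean, sd, n = piscivore_baseline(teeth, "Eocene")
        assert (mean, sd, n) == (15.0, pytest.approx(2.0), 3)

    def test_missing_piscivores_error_names_epoch(self):
        teeth = teeth_frame(
            [dict(specimen_id="t0", species="sp", epoch="Eocene",
                  is_piscivore=False, d15n_eb=20.0)]
        )
        with pytest.raises(FitError, match="Eocene"):
            piscivore_baseline(teeth, "Eocene")

    def test_single_tooth_baseline_warns(self):
        teeth = teeth_frame(
            [dict(specimen_id="p0", species="pisc", epoch="Eocene",
                  is_piscivore=True, d15n_eb=14.0)]
        )
        with pytest.warns(UserWarning, match="single"):
            mean, sd, n = piscivore_baseline(teeth, "Eocene")
        assert mean == 14.0 and np.isnan(sd) and n == 1


class TestDelta:
    def test_quadrature_propagation(self):
        delta, sd = delta_vs_baseline(20.0, 3.0, 15.0, 4.0)
        assert (delta, sd) == (5.0, pytest.approx(5.0))

    def test_zero_when_group_equals_baseline(self):
        delta, _ = delta_vs_baseline(15.0, 1.0, 15.0, 1.0)
        assert delta == 0.0

    def test_missing_sd_warns_and_returns_delta(self):
        with pytest.warns(UserWarning, match="missing SD"):
            delta, sd = delta_vs_baseline(20.0, np.nan, 15.0, 2.0)
        assert delta == 5.0 and np.isnan(sd)

    def test_monte_carlo_confirms_quadrature(self, rng):
        draws = rng.normal(20, 3, 50_000) - rng.normal(15, 4, 50_000)
        assert abs(draws.std(ddof=1) - 5.0) < 0.05 * 5.0


class TestTrophicAlgebra:
    @pytest.mark.parametrize("tdf,expect", [(5.5, 1.3), (2.3, 3.2)])
    def test_reported_offsets(self, tdf, expect):
        assert round(trophic_offset(7.3, tdf), 1) == expect

    def test_zero_delta(self):
        assert trophic_offset(0.0, 2.5) == 0.0

    def test_nonpositive_tdf_rejected(self):
        with pytest.raises(FitError):
            trophic_offset(7.3, 0.0)

    @pytest.mark.parametrize("tdf,expect", [(5.5, 5.7), (2.3, 7.6)])
    def test_absolute_levels_from_anchor(self, tdf, expect):
        model = TDFModel()
        level = absolute_trophic_level(trophic_offset(7.3, tdf), model)
        assert round(level, 1) == expect

    def test_anchor_identity(self):
        assert absolute_trophic_level(0.0, TDFModel()) == 4.4

    @pytest.mark.parametrize("eb,expect", [(23.0, 18.8), (4.2, 0.0)])
    def test_diet_estimator(self, eb, expect):
        assert diet_d15n(eb, TDFModel()) == pytest.approx(expect)

    @given(st.floats(-10, 10), st.floats(0.5, 6), st.floats(0.1, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_offset_linearity_and_tdf_monotonicity(self, delta, tdf, a):
        assert trophic_offset(a * delta, tdf) == pytest.approx(
            a * trophic_offset(delta, tdf), rel=1e-9, abs=1e-9
        )
        if delta > 0:
            assert trophic_offset(delta, tdf + 0.5) < trophic_offset(delta, tdf)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([10.0, 11.0, 12.0], [10.0, 11.0, 12.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form(self):
        a, b = np.array([20.0, 21.0, 22.0]), np.array([10.0, 11.0, 12.0])
        t, df, p = welch_test(a, b)
        se = np.sqrt(1 / 3 + 1 / 3)  # both sample variances are 1, n = 3
        assert t == pytest.approx(10.0 / se, abs=1e-6)
        assert df == pytest.approx(4.0, abs=1e-6)

    def test_small_groups_skipped_with_reason(self):
        teeth = teeth_frame(
            [dict(specimen_id="a", species="sp", epoch="Miocene",
                  is_piscivore=False, d15n_eb=20.0)]
            + [dict(specimen_id=f"p{i}", species="pisc", epoch="Miocene",
                    is_piscivore=True, d15n_eb=v) for i, v in enumerate([14.0, 15.0])]
        )
        out = welch_tests(teeth, "Miocene")
        assert out.iloc[0]["skipped"] != ""
        assert np.isnan(out.iloc[0]["t"])


class TestReconstruct:
    def test_piscivore_anchoring_and_invariants(self, small_config):
        _, teeth = simulate_foodweb(small_config)
        est = reconstruct(teeth)
        pisc = est[est["is_piscivore"]]
        # piscivore groups sit at the anchor by construction (delta vs a pool
        # containing them is small)
        mid = pisc[pisc["tdf"] == 2.5]
        assert (mid["trophic_level"] - 4.4).abs().max() < 0.5
        # exact identities on every row
        assert np.allclose(est["trophic_offset"], est["delta_vs_baseline"] / est["tdf"])
        assert np.allclose(est["diet_d15n"], est["mean_d15n"] - 1.7 - 2.5)

    def test_full_chain_recovery_unbiased_at_large_n(self):
        cfg = make_config(
            species_list=[
                SpeciesSpec("pisc", "P", "Miocene", 4.4, True, 400),
                SpeciesSpec("meg", "Otodus", "Miocene", 7.3, False, 400),
            ],
            seed=3,
        )
        _, teeth = simulate_foodweb(cfg)
        est = reconstruct(teeth)
        row = est[(est["species"] == "meg") & (est["tdf"] == 2.5)].iloc[0]
        assert abs(row["trophic_level"] - 7.3) < 0.1

    def test_noise_free_diet_round_trip_is_exact(self):
        from conftest import noise_free

        cfg = noise_free()
        eco, teeth = simulate_foodweb(cfg)
        est = reconstruct(teeth)
        truth = eco.species.set_index(["species", "epoch"])
        mid = est[est["tdf"] == 2.5]
        for _, row in mid.iterrows():
            expect = truth.loc[(row["species"], row["epoch"]), "d15n_diet"]
            assert row["diet_d15n"] == pytest.approx(expect, abs=1e-9)


class TestScreens:
    def test_diagenesis_no_flag_without_correlation(self, rng):
        teeth = teeth_frame(
            [dict(specimen_id=f"t{i}", species="meg", genus="Otodus", epoch="Miocene",
                  is_piscivore=False, d15n_eb=v, n_content=c)
             for i, (v, c) in enumerate(zip(rng.normal(22, 2, 40), rng.normal(4.8, 2, 40)))]
        )
        rep = diagenesis_screen(teeth)
        assert not rep["alteration_suspect"]

    def test_diagenesis_flags_loss_with_fractionation(self, rng):
        n_content = rng.uniform(1, 8, 40)
        d15n = 28.0 - 1.5 * n_content + rng.normal(0, 0.5, 40)
        teeth = teeth_frame(
            [dict(specimen_id=f"t{i}", species="meg", genus="Otodus", epoch="Miocene",
                  is_piscivore=False, d15n_eb=v, n_content=c)
             for i, (v, c) in enumerate(zip(d15n, n_content))]
        )
        rep = diagenesis_screen(teeth)
        assert rep["alteration_suspect"]
        meg = [c for c in rep["correlations"] if c["label"] == "megatooth"][0]
        assert meg["r"] < 0 and meg["p"] < 0.05

    def test_modern_n_content_mean_recovered(self, small_config):
        _, teeth = simulate_foodweb(small_config)
        teeth = teeth.rename(columns={"true_n_content": "n_content"})
        rep = diagenesis_screen(teeth)
        modern = rep["n_content"]["modern"]
        se = 1.9 / np.sqrt(modern["n"])
        assert abs(modern["mean"] - 7.4) < 2 * se

    def test_baseline_consistency_single_region(self, small_config):
        _, teeth = simulate_foodweb(small_config)
        rep = baseline_consistency(teeth)
        assert rep["region"] == []
        assert len(rep["epoch"]) > 0  # Carcharias spans Modern and Miocene
        assert not rep["flagged"]

    def test_baseline_consistency_flags_region_shift(self):
        cfg = make_config(
            species_list=[
                SpeciesSpec("pisc", "Carcharias", "Miocene", 4.4, True, 20,
                            regions=("A", "B")),
            ],
            region_shifts={"B": 5.0},
            seed=2,
        )
        _, teeth = simulate_foodweb(cfg)
        rep = baseline_consistency(teeth, threshold=3.0)
        assert rep["flagged"]
        flagged = [e for e in rep["region"] if e["exceeds_threshold"]]
        assert flagged and abs(flagged[0]["mean_diff"]) > 3.0
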