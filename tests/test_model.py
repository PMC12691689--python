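"""End-to-end stepwise inference: recovery, design validation, kcat table."""

import numpy as np
import pandas as pd
import pytest

from alarmokin import (
    CompetitionKineticsModel,
    DesignError,
    NucleotideSpecies,
    ReactionCondition,
    VelocityMeasurement,
    paper_design,
    run_full_inference,
    simulate_velocities,
)
from alarmokin.model import GDP_FLAG, frame_to_measurements, measurements_to_frame

S = NucleotideSpecies


@pytest.fixture(scope="module")
def noise_free(paper):
    return simulate_velocities(paper, paper_design(cv=0.0), seed=0)


class TestNoiseFreeRecovery:
    def test_all_truth_cells_recovered(self, paper, noise_free):
        res = run_full_inference(noise_free)
        assert res.km_donor.value == pytest.approx(82.0, rel=1e-6)
        assert res.vmax_pppGpp.value == pytest.approx(110.0, rel=1e-6)
        assert res.km_acceptor_atp.value == pytest.approx(1400.0, rel=1e-6)
        assert res.vmax_pppApp.value == pytest.approx(114.0, rel=1e-6)
        tab = res.table
        for sp in (S.ADP, S.AMP, S.GMP):
            assert tab.loc[sp.value, "km_uM"] == pytest.approx(
                paper.km_acceptor(sp), rel=1e-6
            )
            assert tab.loc[sp.value, "vmax_uM_per_min"] == pytest.approx(
                paper.vmax(sp), rel=1e-6
            )

    def test_kcat_column_from_quantified_reference(self, noise_free):
        res = run_full_inference(
            noise_free,
            enzyme_conc_nM=0.30,
            reference_rate_uM_per_min=23.0,
            reference_atp_uM=5000.0,
        )
        tab = res.table
        assert res.kcat_reference_per_min == pytest.approx(1.0e5, rel=0.02)
        # kcat scales with Vmax, so ordering must match
        sub = tab.dropna(subset=["kcat_per_min"])
        assert (
            sub.sort_values("vmax_uM_per_min").index
            == sub.sort_values("kcat_per_min").index
        ).all()
        for _, row in sub.dropna(subset=["km_uM"]).iterrows():
            assert row["kcat_over_km_per_min_per_uM"] == pytest.approx(
                row["kcat_per_min"] / row["km_uM"], rel=1e-9
            )

    def test_summary_mentions_constants(self, noise_free):
        res = run_full_inference(noise_free)
        text = res.summary()
        assert "Km,donor" in text and "pppApp" in text


class TestDesignValidation:
    def test_missing_acceptor_titration(self, paper):
        design = paper_design(cv=0.0)
        ms = [
            m
            for m in simulate_velocities(paper, design, seed=0)
            if m.product != "pppApp" or len(m.condition.acceptors_present()) > 1
        ]
        with pytest.raises(DesignError, match="ATP-alone"):
            run_full_inference(ms)

    def test_missing_donor_titration(self, paper):
        ms = [
            m
            for m in simulate_velocities(paper, paper_design(cv=0.0), seed=0)
            if m.product != "pppGpp"
        ]
        with pytest.raises(DesignError, match="donor"):
            run_full_inference(ms)

    def test_mixed_batches_rejected(self, paper, noise_free):
        from dataclasses import replace

        tainted = [
            replace(m, batch="batch2") if i == 0 else m
            for i, m in enumerate(noise_free)
        ]
        with pytest.raises(DesignError, match="batch"):
            run_full_inference(tainted)

    def test_mixed_gtp_in_donor_block_rejected(self, paper, noise_free):
        odd = VelocityMeasurement(
            condition=ReactionCondition({S.ATP: 100.0, S.GTP: 2000.0}),
            product="pppGpp",
            velocity_uM_per_min=5.0,
        )
        with pytest.raises(DesignError, match="GTP"):
            run_full_inference(noise_free + [odd])

    def test_gdp_competition_flagged_never_reported(self, paper, noise_free):
        extra_cond = ReactionCondition({S.ATP: 5000.0, S.GDP: 500.0})
        extra = [
            VelocityMeasurement(condition=extra_cond, product="pppApp",
                                velocity_uM_per_min=50.0),
            VelocityMeasurement(condition=extra_cond, product="ppGpp",
                                velocity_uM_per_min=80.0),
        ]
        res = run_full_inference(noise_free + extra)
        row = res.table.loc["GDP"]
        assert row["flag"] == GDP_FLAG
        assert np.isnan(row["km_uM"]) and np.isnan(row["vmax_uM_per_min"])

    def test_failed_deconvolution_does_not_abort_other_rows(self, paper, noise_free):
        # an impossible pppApp velocity in one competition only poisons that row
        bad_cond = ReactionCondition({S.ATP: 5000.0, S.GDP: 1.0})
        ms = list(noise_free)
        ms += [
            VelocityMeasurement(condition=c, product=p, velocity_uM_per_min=v)
            for c, p, v in [(bad_cond, "pppApp", 50.0), (bad_cond, "ppGpp", 1.0)]
        ]
        res = run_full_inference(ms)
        assert res.table.loc["GMP", "km_uM"] == pytest.approx(
            paper.km_acceptor(S.GMP), rel=1e-6
        )


class TestStochasticRecovery:
    """Bias of the sequential estimator shrinks as replication grows."""

    @pytest.mark.parametrize("n_rep, tol", [(2, 0.60), (8, 0.35), (32, 0.20)])
    def test_errors_shrink_with_replication(self, paper, n_rep, tol):
        # tolerances ~5x the analytic information bound for the worst cell
        ms = simulate_velocities(paper, paper_design(replicates=n_rep, cv=0.10), seed=3)
        res = run_full_inference(ms)
        errs = [
            abs(res.km_donor.value / 82 - 1),
            abs(res.km_acceptor_atp.value / 1400 - 1),
            abs(res.vmax_pppApp.value / 114 - 1),
        ]
        for sp in (S.ADP, S.AMP, S.GMP):
            errs.append(abs(res.table.loc[sp.value, "km_uM"] / paper.km_acceptor(sp) - 1))
        assert max(errs) < tol

    def test_bootstrap_se_is_seeded_and_comparable_to_covariance(self, paper):
        ms = simulate_velocities(paper, paper_design(replicates=4, cv=0.05), seed=5)
        model = CompetitionKineticsModel(ms)
        res_a = model.fit(bootstrap=30, seed=11)
        res_b = model.fit(bootstrap=30, seed=11)
        pd.testing.assert_frame_equal(res_a.bootstrap_se, res_b.bootstrap_se)
        boot = res_a.bootstrap_se.loc["km_donor_uM", "bootstrap_se"]
        assert 0 < boot < 10 * res_a.km_donor.se

    def test_estimates_covered_by_reported_se(self, paper):
        ms = simulate_velocities(paper, paper_design(replicates=4, cv=0.05), seed=5)
        res = run_full_inference(ms)
        assert abs(res.km_donor.value - 82) < 4 * res.km_donor.se
        assert abs(res.vmax_pppApp.value - 114) < 4 * res.vmax_pppApp.se


class TestFrameRoundTrip:
    def test_measurements_to_frame_and_back(self, noise_free):
        df = measurements_to_frame(noise_free)
        back = frame_to_measurements(df)
        assert len(back) == len(noise_free)
        assert back[0].condition.concentrations == noise_free[0].condition.concentrations
        assert [m.velocity_uM_per_min for m in back] == [
            m.velocity_uM_per_min for m in noise_free
        ]

    def test_from_dataframe_fit_matches_direct(self, noise_free):
        df = measurements_to_frame(noise_free)
        res_df = CompetitionKineticsModel.from_dataframe(df).fit()
        res_direct = run_full_inference(noise_free)
        assert res_df.km_donor.value == pytest.approx(res_direct.km_donor.value)
        pd.testing.assert_frame_equal(res_df.table, res_direct.table)
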