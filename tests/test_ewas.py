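import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import betainc

from itac.datamodel import BetaMatrix, MethylationState, ProbeManifest, ValidationError
from itac.ewas import (
    call_state,
    combine_beta,
    ewas,
    export_manhattan_volcano,
    locus_analysis,
    locus_min_smoothed_p,
    qc_samples,
    smooth_pvalues,
)


def _beta(arr, probes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


def _manifest(probes, chroms=None, positions=None, islands=None, genes=None):
    n = len(probes)
    return ProbeManifest(
        pd.DataFrame(
            {
                "chromosome": chroms or ["chr1"] * n,
                "position": positions if positions is not None else np.arange(1, n + 1) * 100,
                "gene": genes or ["GENE"] * n,
                "island_id": islands or ["CpG:1"] * n,
            },
            index=pd.Index(probes, name="id"),
        )
    )


class TestQc:
    def test_uniform_sample_fails(self):
        rng = np.random.default_rng(0)
        beta = _beta(rng.uniform(0, 1, (10000, 1)))
        qc = qc_samples(beta)
        frac = qc["fraction_intermediate"].iloc[0]
        assert abs(frac - 0.5) < 0.02  # uniform mass of (0.25, 0.75)
        assert not qc["pass"].iloc[0]

    def test_all_zero_sample_passes(self):
        beta = _beta(np.zeros((200, 1)))
        qc = qc_samples(beta)
        assert qc["fraction_intermediate"].iloc[0] == 0.0
        assert qc["pass"].iloc[0]

    def test_bimodal_mixture_matches_beta_cdf_oracle(self):
        """fraction_intermediate of a 50/50 Beta(1,10)/Beta(10,1) mixture
        equals the CDF mass of (0.25, 0.75), which is symmetric across the
        two components."""
        rng = np.random.default_rng(1)
        n = 10000
        half = n // 2
        vals = np.concatenate([rng.beta(1, 10, half), rng.beta(10, 1, half)])
        beta = _beta(vals[:, None])
        qc = qc_samples(beta)
        p_low = sps.beta.cdf(0.75, 1, 10) - sps.beta.cdf(0.25, 1, 10)
        p_high = sps.beta.cdf(0.75, 10, 1) - sps.beta.cdf(0.25, 10, 1)
        expected = 0.5 * (p_low + p_high)
        assert expected == pytest.approx(2 * 0.5 * p_low)  # symmetry of the mixture
        sd = np.sqrt(expected * (1 - expected) / n)
        assert abs(qc["fraction_intermediate"].iloc[0] - expected) < 5 * sd
        assert qc["pass"].iloc[0]

    def test_too_few_probes_is_error(self):
        with pytest.raises(ValidationError):
            qc_samples(_beta(np.zeros((50, 1))))


class TestCallState:
    @pytest.mark.parametrize(
        "value,state",
        [
            (0.1, MethylationState.UNMETHYLATED),
            (0.4, MethylationState.HEMIMETHYLATED),
            (0.7, MethylationState.METHYLATED),
            (0.0, MethylationState.UNMETHYLATED),
            (1.0, MethylationState.METHYLATED),
            # boundaries belong to the hemimethylated band
            (0.2, MethylationState.HEMIMETHYLATED),
            (0.6, MethylationState.HEMIMETHYLATED),
        ],
    )
    def test_bands(self, value, state):
        assert call_state(value) is state

    def test_out_of_range_is_error(self):
        with pytest.raises(ValidationError):
            call_state(1.3)
        with pytest.raises(ValidationError):
            call_state(-0.1)

    @given(st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_exhaustive_and_exclusive(self, value):
        state = call_state(value)
        assert state in MethylationState


def _hand_t_p(x, y):
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, p


class TestEwas:
    def test_identical_arms_null(self):
        arr = np.tile([0.1, 0.5, 0.9], (3, 1))
        beta = _beta(np.column_stack([arr, arr]))
        res = ewas(beta, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        np.testing.assert_array_equal(res["t_stat"], 0.0)
        np.testing.assert_array_equal(res["p"], 1.0)
        np.testing.assert_array_equal(res["delta_beta"], 0.0)

    def test_p_matches_hand_t_cdf_oracle(self):
        x = np.array([0.42, 0.38, 0.45, 0.35])
        y = np.array([0.05, 0.07, 0.04, 0.06])
        t_oracle, p_oracle = _hand_t_p(x, y)
        beta = _beta(np.concatenate([x, y])[None, :])
        res = ewas(beta, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert abs(res["t_stat"].iloc[0] - t_oracle) < 1e-12
        assert abs(res["p"].iloc[0] - p_oracle) < 1e-12

    def test_planted_probe_power_monte_carlo(self):
        """Power oracle: tumor Beta(mean .4, sd .05) vs control Beta(mean .05,
        sd .02), n = 4 vs 72, must reach Bonferroni significance (m = 20000)
        in essentially every replicate."""
        rng = np.random.default_rng(2)
        n_rep, m = 1000, 20000
        tum = rng.beta(38.4, 57.6, (n_rep, 4))
        ctl = rng.beta(5.89, 111.9, (n_rep, 72))
        from itac.stats import pooled_ttest

        _, p = pooled_ttest(tum, ctl)
        assert np.mean(p * m < 0.05) > 0.99
        # and the states implied by the generating means are the planted ones
        assert call_state(0.4) is MethylationState.HEMIMETHYLATED
        assert call_state(0.05) is MethylationState.UNMETHYLATED

    def test_states_attached(self):
        beta = _beta([[0.4, 0.42, 0.05, 0.06]])
        res = ewas(beta, ["s0", "s1"], ["s2", "s3"])
        assert res["state_tumor"].iloc[0] == "hemimethylated"
        assert res["state_control"].iloc[0] == "unmethylated"

    def test_bonferroni_invariant(self):
        rng = np.random.default_rng(3)
        beta = _beta(rng.uniform(0, 1, (50, 8)))
        res = ewas(beta, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert (res["p_bonferroni"] >= res["p"]).all()
        np.testing.assert_allclose(res["p_bonferroni"], np.minimum(1, res["p"] * 50))

    def test_missing_samples_rejected(self):
        beta = _beta(np.full((3, 4), 0.5))
        with pytest.raises(ValidationError):
            ewas(beta, ["s0", "nope"], ["s2", "s3"])

    def test_global_null_familywise_error_controlled(self):
        """Under the global null the chance of any Bonferroni hit stays near
        the nominal 0.05 family-wise level (empirical bound + 3 sd)."""
        rng = np.random.default_rng(4)
        n_rep, n_probes = 60, 2000
        hits = 0
        for _ in range(n_rep):
            arr = rng.beta(1, 10, (n_probes, 40))
            beta = _beta(arr)
            res = ewas(beta, [f"s{i}" for i in range(20)], [f"s{i}" for i in range(20, 40)])
            hits += (res["p_bonferroni"] < 0.05).any()
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep <= bound


class TestSmoothing:
    def test_constant_p_unchanged(self):
        probes = [f"p{i}" for i in range(9)]
        res = pd.DataFrame({"p": [0.01] * 9}, index=probes)
        man = _manifest(probes)
        out = smooth_pvalues(res, man, radius=3)
        np.testing.assert_allclose(out["p_smoothed"], 0.01, rtol=1e-12)

    def test_single_probe_chromosome(self):
        res = pd.DataFrame({"p": [0.003]}, index=["p0"])
        out = smooth_pvalues(res, _manifest(["p0"]), radius=3)
        assert out["p_smoothed"].iloc[0] == pytest.approx(0.003, rel=1e-12)

    def test_hand_arithmetic_example(self):
        # p = (1e-8, 1, 1, 1, 1, 1, 1), radius 3: first probe's smoothed score
        # = (8+0+0+0)/4 = 2 -> p_smoothed = 1e-2
        probes = [f"p{i}" for i in range(7)]
        res = pd.DataFrame({"p": [1e-8, 1, 1, 1, 1, 1, 1]}, index=probes)
        out = smooth_pvalues(res, _manifest(probes), radius=3)
        assert out["p_smoothed"].iloc[0] == pytest.approx(1e-2, rel=1e-12)

    def test_windowed_mean_oracle(self):
        rng = np.random.default_rng(5)
        n, radius = 40, 3
        probes = [f"p{i}" for i in range(n)]
        p = rng.uniform(1e-10, 1, n)
        res = pd.DataFrame({"p": p}, index=probes)
        out = smooth_pvalues(res, _manifest(probes), radius=radius)
        scores = -np.log10(p)
        for i in range(n):
            window = scores[max(0, i - radius): min(n, i + radius + 1)]
            expected = 10 ** (-np.mean(window))
            assert out["p_smoothed"].iloc[i] == pytest.approx(expected, rel=1e-12)

    def test_contraction_property(self):
        rng = np.random.default_rng(6)
        n = 100
        probes = [f"p{i}" for i in range(n)]
        p = rng.uniform(1e-12, 1, n)
        res = pd.DataFrame({"p": p}, index=probes)
        out = smooth_pvalues(res, _manifest(probes), radius=3)
        raw_scores = -np.log10(p)
        smoothed_scores = -np.log10(out["p_smoothed"].to_numpy(dtype=float))
        assert smoothed_scores.max() <= raw_scores.max() + 1e-12
        assert smoothed_scores.min() >= raw_scores.min() - 1e-12

    def test_chromosomes_independent(self):
        probes = [f"p{i}" for i in range(6)]
        chroms = ["chr1"] * 3 + ["chr2"] * 3
        p = [1e-6, 1, 1, 1, 1, 1]
        res = pd.DataFrame({"p": p}, index=probes)
        out = smooth_pvalues(res, _manifest(probes, chroms=chroms), radius=3)
        # chr2 probes must be untouched by chr1's strong hit
        np.testing.assert_allclose(out["p_smoothed"].iloc[3:], 1.0, rtol=1e-12)

    def test_probe_without_coordinates_gets_na(self):
        probes = ["p0", "p1"]
        res = pd.DataFrame({"p": [0.5, 0.1, 0.3]}, index=probes + ["lost"])
        out = smooth_pvalues(res, _manifest(probes), radius=1)
        assert np.isnan(out.loc["lost", "p_smoothed"])
        assert not out.loc[probes, "p_smoothed"].isna().any()

    def test_row_order_preserved(self):
        probes = ["pB", "pA", "pC"]
        res = pd.DataFrame({"p": [0.1, 0.2, 0.3]}, index=probes)
        man = _manifest(["pA", "pB", "pC"], positions=[100, 200, 300])
        out = smooth_pvalues(res, man, radius=1)
        assert list(out.index) == probes


class TestLocus:
    def _results(self, tumor_means, control_means, probes):
        return pd.DataFrame(
            {
                "mean_beta_tumor": tumor_means,
                "mean_beta_control": control_means,
                "state_tumor": [call_state(v).value for v in tumor_means],
                "state_control": [call_state(v).value for v in control_means],
            },
            index=probes,
        )

    def test_concordant_hemimethylation(self):
        probes = [f"p{i}" for i in range(4)]
        res = self._results([0.3, 0.4, 0.5, 0.25], [0.05, 0.1, 0.02, 0.15], probes)
        man = _manifest(probes, islands=["CpG:9"] * 4)
        summary = locus_analysis(res, man, "CpG:9")
        assert summary.verdict == "concordant_hemimethylation"
        assert summary.n_hemimethylated_tumor == 4

    def test_one_discordant_probe_is_mixed(self):
        probes = [f"p{i}" for i in range(3)]
        res = self._results([0.3, 0.4, 0.9], [0.05, 0.1, 0.7], probes)
        man = _manifest(probes, islands=["CpG:9"] * 3)
        assert locus_analysis(res, man, "CpG:9").verdict == "mixed"

    def test_no_pattern_is_null(self):
        probes = ["p0", "p1"]
        res = self._results([0.05, 0.9], [0.04, 0.88], probes)
        man = _manifest(probes, islands=["CpG:9"] * 2)
        assert locus_analysis(res, man, "CpG:9").verdict == "null"

    def test_empty_extra_beta_uses_ewas_samples_only(self):
        probes = ["p0"]
        res = self._results([0.3], [0.05], probes)
        man = _manifest(probes, islands=["CpG:9"])
        summary = locus_analysis(res, man, "CpG:9", extra_beta=None)
        assert summary.extra_states is None

    def test_extra_beta_states_reported(self):
        probes = ["p0", "p1"]
        res = self._results([0.3, 0.4], [0.05, 0.06], probes)
        man = _manifest(probes, islands=["CpG:9"] * 2)
        extra = _beta([[0.35, 0.45], [0.5, 0.3]], probes=probes, samples=["x1", "x2"])
        summary = locus_analysis(res, man, "CpG:9", extra_beta=extra)
        assert list(summary.extra_states["state"]) == ["hemimethylated", "hemimethylated"]

    def test_unknown_island_is_error(self):
        res = self._results([0.3], [0.05], ["p0"])
        man = _manifest(["p0"], islands=["CpG:9"])
        with pytest.raises(ValidationError):
            locus_analysis(res, man, "CpG:404")


class TestExports:
    def _results(self):
        probes = ["p0", "p1", "p2"]
        return (
            pd.DataFrame(
                {
                    "delta_beta": [0.3, -0.1, 0.0],
                    "p": [1e-4, 0.2, 0.9],
                    "p_smoothed": [1e-3, np.nan, 0.5],
                },
                index=probes,
            ),
            _manifest(probes, positions=[300, 100, 200]),
        )

    def test_three_probe_fixture_sorted(self):
        res, man = self._results()
        manhattan, volcano = export_manhattan_volcano(res, man)
        assert len(volcano) == 3
        assert list(manhattan["position"]) == sorted(manhattan["position"])

    def test_na_smoothed_omitted_from_manhattan_kept_in_volcano(self):
        res, man = self._results()
        manhattan, volcano = export_manhattan_volcano(res, man)
        assert "p1" not in manhattan.index
        assert "p1" in volcano.index

    def test_neg_log10_columns_recompute(self):
        res, man = self._results()
        manhattan, volcano = export_manhattan_volcano(res, man)
        for probe in manhattan.index:
            assert manhattan.loc[probe, "neg_log10_p_smoothed"] == pytest.approx(
                -np.log10(res.loc[probe, "p_smoothed"]), abs=1e-12
            )
        np.testing.assert_allclose(
            volcano["neg_log10_p"], -np.log10(res["p"]), atol=1e-12
        )


def test_combine_beta_requires_same_probes():
    a = _beta([[0.1], [0.2]], probes=["p0", "p1"])
    b = _beta([[0.3], [0.4]], probes=["p0", "pX"])
    with pytest.raises(ValidationError):
        combine_beta(a, b)


def test_full_meth_pipeline_on_small_scenario(small_methylation):
    tumor, control, manifest, truth = small_methylation
    qc = qc_samples(tumor)
    assert set(qc.index[qc["pass"]]) == set(truth["qc_good_samples"])
    assert set(qc.index[~qc["pass"]]) == set(truth["qc_bad_samples"])
    merged = combine_beta(tumor, control)
    res = ewas(merged, truth["qc_good_samples"], control.sample_ids)
    res = smooth_pvalues(res, manifest, radius=3)
    ranking = locus_min_smoothed_p(res, manifest)
    planted = set(truth["planted_islands"])
    assert set(ranking.index[:2]) == planted
    for island in planted:
        summary = locus_analysis(
            res, manifest, island, extra_beta=BetaMatrix(tumor.beta[truth["qc_bad_samples"]])
        )
        assert summary.verdict == "concordant_hemimethylation"
        assert (summary.extra_states["state"] == "hemimethylated").all()
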