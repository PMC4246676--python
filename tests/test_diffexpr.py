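"""Size factors, dispersions, the conditioned exact NB test, calls, VST."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fluxcord.diffexpr import (
    CountMatrix,
    adjust_bh,
    call_transcripts,
    ddct,
    estimate_dispersions,
    nb_exact_test,
    run_de,
    size_factors,
    vst,
)

ACC = {f"A_{j}": "A" for j in range(3)} | {f"B_{j}": "B" for j in range(3)}
COLS = list(ACC)


def _cm(counts: np.ndarray) -> CountMatrix:
    return CountMatrix(
        counts=pd.DataFrame(
            counts,
            index=[f"t{i}" for i in range(len(counts))],
            columns=COLS[: counts.shape[1]],
        ),
        accessions={c: ACC[c] for c in COLS[: counts.shape[1]]},
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [40], [7]], (1, 4)))
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_doubles_factor(self):
        # hand computation on a 5x4 matrix: column 3 = 2x column 0
        base = np.array(
            [[10, 12, 9, 20], [100, 95, 110, 200], [7, 8, 6, 14],
             [50, 55, 45, 100], [33, 30, 36, 66]]
        )
        sf = size_factors(pd.DataFrame(base))
        assert sf.iloc[3] / sf.iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_single_row_closed_form(self):
        # [[10, 20]]: geometric mean sqrt(200); factors 10/√200, 20/√200
        sf = size_factors(pd.DataFrame([[10, 20]]))
        assert np.allclose(sf, [10 / np.sqrt(200), 20 / np.sqrt(200)])
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_no_all_positive_row_is_an_error(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(pd.DataFrame([[0, 5], [3, 0]]))


class TestDispersions:
    def test_poisson_data_yields_near_zero_alpha(self):
        rng = np.random.default_rng(0)
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 2000))
        counts = pd.DataFrame(
            rng.poisson(mu[:, None], size=(2000, 6)), columns=COLS
        )
        disp = estimate_dispersions(counts, size_factors(counts), ACC)
        assert np.median(disp["alpha_mom"]) <= 0.01

    def test_nb_simulation_recovers_alpha(self):
        rng = np.random.default_rng(1)
        alpha = 0.2
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 2000))
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], size=(2000, 6))
        counts = pd.DataFrame(rng.poisson(lam), columns=COLS)
        disp = estimate_dispersions(counts, size_factors(counts), ACC)
        assert 0.1 <= np.median(disp["alpha"]) <= 0.3

    def test_constant_row_gets_floor(self):
        counts = pd.DataFrame(
            np.vstack([np.full(6, 50), [10, 20, 30, 40, 50, 60]]), columns=COLS
        )
        sf = pd.Series(1.0, index=COLS)
        disp = estimate_dispersions(counts, sf, ACC)
        assert disp.loc[0, "alpha_mom"] == 0.0
        assert disp.loc[0, "alpha"] >= 1e-8


class TestExactTest:
    def test_symmetric_split_has_p_one(self):
        assert nb_exact_test(30, 30, 40.0, 40.0, 0.1, 0.1) == pytest.approx(1.0)

    @pytest.mark.parametrize("k_a,k_b", [(0, 7), (3, 5), (17, 40), (100, 60)])
    def test_zero_dispersion_matches_conditioned_binomial(self, k_a, k_b):
        # the Poisson limit of the conditioned NB test is a two-sided
        # (minimum-likelihood) binomial test on the split
        p_nb = nb_exact_test(k_a, k_b, 50.0, 50.0, 0.0, 0.0)
        p_binom = stats.binomtest(k_a, k_a + k_b, 0.5).pvalue
        assert p_nb == pytest.approx(p_binom, abs=1e-6)

    def test_unequal_means_match_direct_summation(self):
        # brute-force oracle: direct normalized summation over all splits
        k_a, k_b, mu_a, mu_b, al = 40, 10, 20.0, 30.0, 0.05
        r = 1 / al
        total = k_a + k_b
        a = np.arange(total + 1)
        pa = stats.nbinom.pmf(a, r, r / (r + mu_a))
        pb = stats.nbinom.pmf(total - a, r, r / (r + mu_b))
        joint = pa * pb
        expected = joint[joint <= joint[k_a] * (1 + 1e-12)].sum() / joint.sum()
        assert nb_exact_test(k_a, k_b, mu_a, mu_b, al, al) == pytest.approx(
            expected, rel=1e-10
        )

    def test_extreme_split_is_tiny(self):
        assert nb_exact_test(100, 0, 50.0, 50.0, 0.01, 0.01) < 1e-6

    def test_large_totals_use_windowed_sum(self):
        p = nb_exact_test(26000, 25000, 25500.0, 25500.0, 0.001, 0.001)
        assert 0.0 < p <= 1.0

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(1.5, 2, 10, 10, 0.1, 0.1)


class TestBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        # p=(0.01,0.02,0.03,0.04), m=4: p_(i) * 4/i = .04,.04,.04,.04
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones_stay_ones(self):
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.1, np.nan])


class TestCalls:
    @pytest.mark.parametrize(
        "padj,mean_a,mean_b,expected",
        [
            (0.005, 300.0, 100.0, "T"),  # significant and 3-fold up
            (0.005, 150.0, 100.0, "N"),  # fold filter fails at 1.5
            (0.02, 1000.0, 100.0, "N"),  # significance filter fails
            (0.005, 100.0, 300.0, "S"),
            (0.005, 100.0, 0.0, "T"),  # one-zero mean passes the fold filter
        ],
    )
    def test_threshold_rules(self, padj, mean_a, mean_b, expected):
        de = pd.DataFrame(
            {"mean_A": [mean_a], "mean_B": [mean_b], "padj": [padj]}
        )
        assert call_transcripts(de)["call"].iloc[0] == expected


class TestVST:
    def test_zero_maps_to_zero(self):
        assert vst(0.0, 0.1) == 0.0

    def test_derivative_stabilizes_variance(self):
        # g'(μ) = 1/sqrt(μ + αμ²) by finite differences at μ=100, α=0.1
        mu, alpha, h = 100.0, 0.1, 1e-4
        deriv = (vst(mu + h, alpha) - vst(mu - h, alpha)) / (2 * h)
        assert deriv == pytest.approx(1 / np.sqrt(mu + alpha * mu**2), rel=1e-6)

    def test_large_mu_log2_slope(self):
        # doubling μ adds 2/√α·ln√2 in the limit
        alpha, mu = 0.1, 1e6
        gap = vst(2 * mu, alpha) - vst(mu, alpha)
        assert gap == pytest.approx(2 / np.sqrt(alpha) * np.log(np.sqrt(2)),
                                    rel=1e-4)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            vst(10.0, 0.0)


@pytest.mark.parametrize("d,expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
def test_ddct_closed_form(d, expected):
    # ΔΔCt realized via the target Ct in the treated condition
    assert ddct(20.0 + d, 15.0, 20.0, 15.0) == pytest.approx(expected)


def test_ddct_requires_finite_ct():
    with pytest.raises(ValueError):
        ddct(np.inf, 15.0, 20.0, 15.0)


class TestRunDE:
    def test_scaling_one_column_changes_no_call(self):
        rng = np.random.default_rng(3)
        mu = np.exp(rng.uniform(np.log(20), np.log(800), 400))
        fold = np.where(np.arange(400) < 40, 4.0, 1.0)
        counts = np.column_stack(
            [rng.poisson(mu * fold) for _ in range(3)]
            + [rng.poisson(mu) for _ in range(3)]
        )
        cm1 = _cm(counts)
        scaled = counts.copy()
        scaled[:, 0] *= 5  # library-depth change only
        cm2 = _cm(scaled)
        de1 = run_de(cm1, accession_a="A")
        de2 = run_de(cm2, accession_a="A")
        assert (de1["call"] == de2["call"]).all()

    def test_both_zero_rows_are_null(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 100)])
        de = run_de(_cm(counts), accession_a="A")
        assert de.iloc[0]["pvalue"] == 1.0
        assert de.iloc[0]["call"] == "N"

    def test_requires_two_accessions(self):
        cm = CountMatrix(
            counts=pd.DataFrame([[1, 2]], columns=["x", "y"]),
            accessions={"x": "A", "y": "A"},
        )
        with pytest.raises(ValueError, match="two accessions"):
            run_de(cm)

    def test_direction_anchor_flips_calls(self):
        rng = np.random.default_rng(4)
        mu = np.exp(rng.uniform(np.log(50), np.log(500), 250))
        fold = np.where(np.arange(250) < 50, 4.0, 1.0)  # 50 planted, 200 null
        counts = np.column_stack(
            [rng.poisson(mu * fold) for _ in range(3)]
            + [rng.poisson(mu) for _ in range(3)]
        )
        de_a = run_de(_cm(counts), accession_a="A")
        de_b = run_de(_cm(counts), accession_a="B")
        assert (de_a["call"].iloc[:50] == "T").sum() > 40
        assert ((de_a["call"] == "T") == (de_b["call"] == "S")).all()


def test_count_matrix_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    cm = _cm(rng.poisson(100.0, size=(20, 6)))
    path = tmp_path / "counts.tsv"
    cm.to_tsv(path)
    again = CountMatrix.from_tsv(path)
    pd.testing.assert_frame_equal(again.counts, cm.counts)
    assert again.accessions == cm.accessions
    # byte-identical on rewrite
    path2 = tmp_path / "counts2.tsv"
    again.to_tsv(path2)
    assert path.read_bytes() == path2.read_bytes()


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        CountMatrix(
            counts=pd.DataFrame([[-1, 2]], columns=["x", "y"]),
            accessions={"x": "A", "y": "B"},
        )
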