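"""Differential HDX-MS: uptake normalization, significance, EX1/EX2."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokin import hdx
from allokin.hdx import IsotopeEnvelope, PeptideUptake
from allokin.synthetic import PeptideSpec, SyntheticConfig, gen_hdx_dataset

SEQ = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


class TestMaxUptake:
    def test_substrate_peptide(self):
        # the kinase substrate decapeptide: N=10, no prolines
        assert hdx.max_uptake("ALRRFSLHGA") == 8

    def test_prolines_subtract(self):
        assert hdx.max_uptake("APAPAAAAA") == 9 - 2 - 2

    def test_dipeptide_clamped_to_zero(self):
        assert hdx.max_uptake("AG") == 0

    def test_alternative_convention(self):
        assert hdx.max_uptake("ALRRFSLHGA", convention="n-p-1") == 9

    def test_invalid_letter(self):
        with pytest.raises(ValueError, match="invalid residue"):
            hdx.max_uptake("ALRZ")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(SEQ)
    def test_reversal_invariance_and_proline_decrement(self, seq):
        assert hdx.max_uptake(seq) == hdx.max_uptake(seq[::-1])
        if hdx.max_uptake(seq) > 0 and "P" not in seq:
            assert hdx.max_uptake("P" + seq[1:]) == hdx.max_uptake(seq) - 1


class TestPercentDifference:
    @pytest.mark.parametrize("da,db,norm,expected", [
        (4.0, 0.0, 8.0, 50.0),
        (3.0, 3.0, 8.0, 0.0),
        (2.0, 1.0, 4.0, 25.0),
    ])
    def test_examples(self, da, db, norm, expected):
        assert hdx.percent_uptake_difference(da, db, norm) == pytest.approx(expected)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(0, 10), st.floats(0, 10), st.floats(0.1, 20))
    def test_antisymmetry(self, da, db, norm):
        assert hdx.percent_uptake_difference(da, db, norm) == pytest.approx(
            -hdx.percent_uptake_difference(db, da, norm))

    def test_nonpositive_normalizer(self):
        with pytest.raises(ValueError):
            hdx.percent_uptake_difference(1.0, 0.0, 0.0)


def _pair(seq, span, d_a, d_b, exposure=10.0, fd=None):
    return (PeptideUptake(seq, span, "A", exposure, list(d_a), fd_uptake=fd),
            PeptideUptake(seq, span, "B", exposure, list(d_b), fd_uptake=fd))


class TestSignificanceFilter:
    def test_small_difference_fails_threshold_despite_tight_ci(self):
        # ΔD% ≈ 4% on MaxUptake·f_D2O = 7.6 Da with negligible scatter
        pairs = [_pair("ALRRFSLHGA", (1, 10), [3.304, 3.306, 3.305], [3.0, 3.001, 2.999])]
        res = hdx.significance_filter(pairs)
        assert abs(res[0].delta_pct) < 5
        assert not res[0].significant

    def test_large_difference_with_clear_ci_is_significant(self):
        pairs = [_pair("ALRRFSLHGA", (1, 10), [4.0, 4.1, 3.9], [3.0, 3.1, 2.9])]
        res = hdx.significance_filter(pairs)
        assert res[0].delta_pct > 5
        assert res[0].significant

    def test_zero_variance_identical_means_not_significant(self):
        pairs = [_pair("ALRRFSLHGA", (1, 10), [3.0, 3.0], [3.0, 3.0])]
        res = hdx.significance_filter(pairs)
        assert not res[0].significant

    def test_single_replicate_warns_and_uses_threshold_only(self):
        pairs = [_pair("ALRRFSLHGA", (1, 10), [5.0], [3.0])]
        res = hdx.significance_filter(pairs)
        assert "threshold" in res[0].warning
        assert res[0].significant  # 2/7.6 = 26% > 5%

    def test_fd_normalization(self):
        pairs = [_pair("ALRRFSLHGA", (1, 10), [2.0, 2.0], [1.0, 1.0], fd=4.0)]
        res = hdx.significance_filter(pairs, normalizer="fd")
        assert res[0].delta_pct == pytest.approx(25.0)

    def test_null_false_positive_rate_at_nominal_level(self):
        """Type-I error of the pooled-variance CI under no true difference."""
        rng = np.random.default_rng(11)
        alpha, sd, n_rep, n_pept, n_sims = 0.05, 0.15, 3, 20, 60
        fp, total = 0, 0
        for _ in range(n_sims):
            pairs = []
            for i in range(n_pept):
                mu = rng.uniform(2, 6)
                a = rng.normal(mu, sd, n_rep)
                b = rng.normal(mu, sd, n_rep)
                pairs.append(_pair("ALRRFSLHGA", (1, 10), a, b))
            # CI criterion alone (threshold disabled) to measure coverage
            res = hdx.significance_filter(pairs, alpha=alpha, min_delta_pct=0.0)
            fp += sum(r.significant for r in res)
            total += len(res)
        rate = fp / total
        mc_sd = np.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 2 * mc_sd

    def test_pooled_ci_matches_bootstrap_oracle(self):
        """Pooled-variance CI vs brute-force bootstrap percentile interval."""
        rng = np.random.default_rng(3)
        sd, n_rep = 0.2, 10
        pairs = []
        for i in range(12):
            mu = rng.uniform(2, 6)
            pairs.append(_pair("ALRRFSLHGA", (1, 10),
                               rng.normal(mu, sd, n_rep), rng.normal(mu, sd, n_rep)))
        res = hdx.significance_filter(pairs)
        a, b = map(np.asarray, (pairs[0][0].replicates, pairs[0][1].replicates))
        boots = [np.mean(rng.choice(a, n_rep)) - np.mean(rng.choice(b, n_rep))
                 for _ in range(4000)]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        boot_half = (hi - lo) / 2
        assert res[0].ci_halfwidth_da == pytest.approx(boot_half, rel=0.25)


class TestCumulativeDelta:
    EXPOSURES = (3.0, 10.0, 30.0, 90.0)

    def _records(self, uptakes_by_peptide, state):
        out = []
        for (seq, start), per_time in uptakes_by_peptide.items():
            for t, d in zip(self.EXPOSURES, per_time):
                out.append(PeptideUptake(seq, (start, start + len(seq) - 1),
                                         state, t, [d]))
        return out

    def test_identical_states_zero_everywhere(self):
        ups = {("ALRRFSLHGA", 1): [1, 2, 3, 4], ("GHKLMNQRST", 11): [2, 2, 2, 2]}
        res = hdx.cumulative_delta(self._records(ups, "A"), self._records(ups, "B"))
        assert all(v == 0 for _, _, v in res)

    def test_unit_deltas_sum(self):
        a = {("ALRRFSLHGA", 1): [2, 3, 4, 5]}
        b = {("ALRRFSLHGA", 1): [1, 2, 3, 4]}
        res = hdx.cumulative_delta(self._records(a, "A"), self._records(b, "B"))
        assert res[0][2] == pytest.approx(4.0)

    def test_protection_confined_to_one_region(self):
        """Protection applied to one span appears only in that span's bars."""
        cfg = SyntheticConfig(seed=4, noise_sd=0.0, replicate_count=1)
        fast = dict(k_exchange=5.0)     # exchanges fully by 3 min everywhere
        peps = [PeptideSpec("AILKEVFGHR", 1, **fast),
                PeptideSpec("GSTWYQNDEL", 40, **fast),
                PeptideSpec("MKVLHEFAGI", 80, **fast)]
        state_a, _ = gen_hdx_dataset(peps, "EX2", cfg, state="A")
        protected = [PeptideSpec("AILKEVFGHR", 1, **fast),
                     PeptideSpec("GSTWYQNDEL", 40, k_exchange=0.01),  # protected
                     PeptideSpec("MKVLHEFAGI", 80, **fast)]
        state_b, _ = gen_hdx_dataset(protected, "EX2", cfg, state="B")
        res = hdx.cumulative_delta(state_a, state_b)
        spans = {span: v for span, _, v in res}
        assert spans[(40, 49)] > 5.0
        assert abs(spans[(1, 10)]) < 1e-6 and abs(spans[(80, 89)]) < 1e-6
        assert [r[0] for r in res] == sorted(r[0] for r in res)  # N→C order

    def test_exposure_mismatch_raises(self):
        a = self._records({("ALRRFSLHGA", 1): [1, 2, 3, 4]}, "A")
        b = [r for r in self._records({("ALRRFSLHGA", 1): [1, 2, 3, 4]}, "B")
             if r.exposure != 30.0]
        with pytest.raises(ValueError, match="missing"):
            hdx.cumulative_delta(a, b)


def _gaussian_envelope(centers, weights, sigma=1.0, lo=995.0, hi=1030.0, step=0.25):
    m = np.arange(lo, hi, step)
    inten = np.zeros_like(m)
    for c, w in zip(centers, weights):
        inten += w * np.exp(-0.5 * ((m - c) / sigma) ** 2)
    return IsotopeEnvelope(mass=m, intensity=inten)


class TestEnvelopeClassification:
    def test_single_gaussian_is_ex2(self):
        fit = hdx.classify_envelope(_gaussian_envelope([1005.0], [1.0]))
        assert fit.n_components == 1 and fit.label == "EX2"

    def test_balanced_mixture_six_da_apart(self):
        fit = hdx.classify_envelope(_gaussian_envelope([1004.0, 1010.0], [0.5, 0.5]))
        assert fit.n_components == 2 and fit.label == "EX1-like"
        assert fit.fractions[0] == pytest.approx(0.5, abs=0.05)
        assert sum(fit.fractions) == pytest.approx(1.0)
        assert fit.means[1] - fit.means[0] >= 2.0

    def test_minor_component_below_separation_limit_is_parsimonious(self):
        fit = hdx.classify_envelope(_gaussian_envelope([1004.0, 1005.2], [0.95, 0.05]))
        assert fit.n_components == 1

    def test_too_few_channels(self):
        env = IsotopeEnvelope(mass=np.arange(5.0), intensity=np.ones(5))
        with pytest.raises(ValueError, match="8 mass channels"):
            hdx.classify_envelope(env)

    def test_ex2_regime_rarely_misclassified(self):
        """On EX2 synthetic envelopes the classifier stays unimodal."""
        n_one = 0
        seeds = range(20)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            env0 = _gaussian_envelope([1003.0 + 4 * rng.random()], [1.0])
            noisy = env0.intensity * (1 + rng.normal(0, 0.05, env0.intensity.shape))
            env = IsotopeEnvelope(mass=env0.mass, intensity=np.clip(noisy, 0, None))
            n_one += hdx.classify_envelope(env).n_components == 1
        assert n_one >= 0.95 * len(seeds)


class TestEx1Kinetics:
    def test_noiseless_inverse(self):
        t = np.array([3.0, 10.0, 30.0, 90.0])
        f = 1 - np.exp(-0.1 * t)
        k, se = hdx.ex1_unfolding_rate(t, f)
        assert k == pytest.approx(0.100, abs=1e-6)

    def test_noisy_recovery_three_se_coverage(self):
        # with 4 points and df=3 a 3-SE interval covers ~94% of draws;
        # check coverage over an ensemble rather than a single draw
        rng = np.random.default_rng(8)
        t = np.array([3.0, 10.0, 30.0, 90.0])
        hits = 0
        n_sims = 50
        for _ in range(n_sims):
            f = np.clip(1 - np.exp(-0.1 * t) + rng.normal(0, 0.03, 4), 0, 1)
            k, se = hdx.ex1_unfolding_rate(t, f)
            hits += abs(k - 0.1) < 3 * se
        assert hits / n_sims >= 0.80

    def test_unidentifiable_when_saturated(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            hdx.ex1_unfolding_rate([3.0, 10.0, 30.0], [1.0, 1.0, 1.0])

    def test_rate_ratio_fast_vs_slow_excludes_one(self):
        """Faster unfolding in one state: ratio > 1 with CI excluding 1."""
        rng = np.random.default_rng(9)
        t = np.array([3.0, 10.0, 30.0, 90.0])
        f_fast = np.clip(1 - np.exp(-0.2 * t) + rng.normal(0, 0.02, 4), 0, 1)
        f_slow = np.clip(1 - np.exp(-0.02 * t) + rng.normal(0, 0.02, 4), 0, 1)
        kf, sf = hdx.ex1_unfolding_rate(t, f_fast)
        ks, ss = hdx.ex1_unfolding_rate(t, f_slow)
        ratio, (lo, hi) = hdx.ex1_rate_ratio(kf, sf, ks, ss)
        assert ratio > 1 and lo > 1

    def test_fraction_series_handles_unimodal_extremes(self):
        cfg = SyntheticConfig(seed=2, noise_sd=0.0, replicate_count=1)
        pep = PeptideSpec("AILKEVFGHR", 1, k_open=0.1, protected_uptake=0.5)
        _, envs = gen_hdx_dataset([pep], "EX1", cfg)
        d_max = hdx.max_uptake(pep.sequence) * 0.95
        t, f = hdx.ex1_fraction_series(
            list(envs.values()), folded_mass=pep.mono_mass + 0.5,
            unfolded_mass=pep.mono_mass + d_max)
        k, se = hdx.ex1_unfolding_rate(t, f)
        assert f[-1] > 0.95  # 90 min: essentially fully unfolded, not 0
        assert k == pytest.approx(0.1, rel=0.15)


class TestDeuteriumFraction:
    @pytest.mark.parametrize("ratio,expected", [(20, 0.95), (2, 0.5), (1e9, 1.0)])
    def test_values(self, ratio, expected):
        assert hdx.deuterium_fraction(ratio) == pytest.approx(expected, abs=1e-6)

    def test_sub_unity_ratio_rejected(self):
        with pytest.raises(ValueError):
            hdx.deuterium_fraction(0.5)
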