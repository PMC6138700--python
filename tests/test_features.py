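"""Feature annotation, per-subtype regressions, FDR and enrichment tests."""

import numpy as np
import pytest
from scipy import stats

from ervrates.features import (
    FeatureTrack,
    annotate_features,
    collect_subtype_sites,
    denovo_feature_test,
    fdr_select,
    fit_subtype_model,
    signature_enrichment,
)
from ervrates.kmers import MutationSubtype, enumerate_subtypes, subtype_index
from ervrates.rates import estimate_rates
from ervrates.simulate import gen_feature_tracks


def newton_multilogistic(z, x, iters=200):
    """Independent Newton-Raphson ML fit of a multi-feature logistic model."""
    z = np.asarray(z, float)
    design = np.column_stack([np.ones(len(z)), x])
    beta = np.zeros(design.shape[1])
    for _ in range(iters):
        eta = design @ beta
        p = 1 / (1 + np.exp(-eta))
        grad = design.T @ (z - p)
        hess = -(design * (p * (1 - p))[:, None]).T @ design
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.abs(step).max() < 1e-12:
            break
    return beta


def brute_force_bh(pvals, q):
    """Step-up Benjamini-Hochberg from the definition."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, dtype=bool)
    k_max = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= q * rank / m:
            k_max = rank
    for rank, i in enumerate(order, start=1):
        if rank <= k_max:
            reject[i] = True
    return reject


class TestAnnotate:
    def test_half_open_interval_boundary(self, genome):
        track = FeatureTrack(name="island", kind="binary",
                             intervals={"chr1": [(99, 199)]})
        # 1-based pos 100..199 are inside; 200 is one past the half-open end
        x, keep, names = annotate_features(
            [("chr1", 100), ("chr1", 199), ("chr1", 200)], genome, [track])
        assert list(x[:, 0]) == [1.0, 1.0, 0.0]
        assert keep.all() and names == ["island"]

    def test_constant_track_window_mean(self, genome):
        track = FeatureTrack(name="flat", kind="continuous",
                             values={"chr1": [(0, genome.length("chr1"), 2.5)]})
        x, keep, _ = annotate_features([("chr1", 5), ("chr1", 100_000)],
                                       genome, [track])
        assert np.allclose(x, 2.5)

    def test_sawtooth_window_mean_matches_brute_force(self, genome, rng):
        n = genome.length("chr1")
        period = 1000
        runs = [(s, min(s + period, n), float((s // period) % 7))
                for s in range(0, n, period)]
        track = FeatureTrack(name="saw", kind="continuous",
                             values={"chr1": runs})
        dense = np.empty(n)
        for s, e, v in runs:
            dense[s:e] = v
        sites = [("chr1", int(p)) for p in rng.integers(1, n + 1, size=100)]
        x, keep, _ = annotate_features(sites, genome, [track], window_bp=10_000)
        for (chrom, pos), got in zip(sites, x[:, 0]):
            lo = max(0, pos - 1 - 5000)
            hi = min(n, pos + 5000)
            assert got == pytest.approx(dense[lo:hi].mean(), rel=1e-12)

    def test_missing_window_masked(self, genome):
        track = FeatureTrack(name="gappy", kind="continuous",
                             values={"chr1": [(50_000, 60_000, 1.0)]})
        x, keep, _ = annotate_features([("chr1", 55_000), ("chr1", 150_000)],
                                       genome, [track])
        assert keep[0] and not keep[1]


class TestCollectSites:
    def test_consistency_with_motif_counts_and_rates(self, genome, singletons):
        table = estimate_rates(singletons, genome, 7)
        # pick the most populated subtype for a meaningful check
        j = int(np.argmax(table.erv_counts))
        sub = enumerate_subtypes(7)[j]
        sites = collect_subtype_sites(genome, sub, singletons)
        assert len(sites) == table.motif_counts[j]
        assert sum(z for _, _, z in sites) == table.erv_counts[j]

    def test_positions_match_brute_force_motif_scan(self, genome):
        from ervrates.kmers import revcomp

        sub = enumerate_subtypes(7)[subtype_index(7)[
            MutationSubtype("ATACGCA", "T")]]
        sites = collect_subtype_sites(genome, sub, [])
        seq = genome.sequence("chr1")
        expected = []
        for i in range(len(seq) - 6):
            w = seq[i:i + 7]
            if w == "ATACGCA" or w == revcomp("ATACGCA"):
                expected.append(i + 4)
        assert [p for _, p, _ in sites] == expected


class TestFitSubtypeModel:
    def test_all_zero_features_reduce_to_marginal_rate(self, rng):
        sub = enumerate_subtypes(7)[0]
        n = 5000
        z = (rng.random(n) < 0.03).astype(float)
        x = np.zeros((n, 15))
        m = fit_subtype_model(sub, z, x, [f"f{i}" for i in range(15)])
        assert m.fitted
        marginal = z.mean()
        assert 1 / (1 + np.exp(-m.coef[0])) == pytest.approx(marginal,
                                                             abs=1e-9)
        assert np.allclose(m.coef[1:], 0.0)

    def test_min_erv_filter_skips(self, rng):
        sub = enumerate_subtypes(7)[0]
        z = np.zeros(1000)
        z[:5] = 1
        m = fit_subtype_model(sub, z, rng.random((1000, 3)), ["a", "b", "c"])
        assert not m.fitted and "skipped" in m.note

    def test_matches_newton_oracle(self, rng):
        """Full 15-predictor fit agrees with an independent optimizer."""
        sub = enumerate_subtypes(7)[0]
        n = 500
        x = np.column_stack([rng.integers(0, 2, size=(n, 3)).astype(float),
                             rng.uniform(0, 1, size=(n, 2))])
        lin = -3.0 + 0.8 * x[:, 0] - 0.5 * x[:, 3]
        z = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        z[:30] = 1  # ensure enough events
        names = ["b1", "b2", "b3", "c1", "c2"]
        m = fit_subtype_model(sub, z, x, names, continuous=["c1", "c2"])
        assert m.fitted
        xs = x / m.scale
        beta = newton_multilogistic(z, xs)
        assert np.allclose(m.coef, beta, atol=1e-6)

    def test_binary_or2_recovery_within_wald_ci(self):
        """95% Wald CI covers log(2) in >=90/100 replicates at n=50,000.

        One binary feature at odds ratio 2, base rate 0.02 — the power
        setting under which feature effects should be reliably estimable.
        """
        rng = np.random.default_rng(1234)
        sub = enumerate_subtypes(7)[0]
        true_beta = np.log(2.0)
        n = 50_000
        covered = 0
        for _ in range(100):
            f = (rng.random(n) < 0.3).astype(float)
            lin = np.log(0.02 / 0.98) + true_beta * f
            z = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
            m = fit_subtype_model(sub, z, f[:, None], ["f"])
            if not m.fitted:
                continue
            lo = m.coef[1] - 1.96 * m.se[1]
            hi = m.coef[1] + 1.96 * m.se[1]
            covered += lo <= true_beta <= hi
        assert covered >= 90

    def test_collinear_features_flagged(self, rng):
        sub = enumerate_subtypes(7)[0]
        n = 2000
        f = (rng.random(n) < 0.5).astype(float)
        x = np.column_stack([f, f])  # perfectly collinear
        z = (rng.random(n) < 0.05).astype(float)
        m = fit_subtype_model(sub, z, x, ["f1", "f2"])
        assert (not m.fitted) or np.isfinite(m.se[1:]).all()


class TestFDR:
    def test_all_ones_nothing_flagged(self):
        models = [_fake_model(enumerate_subtypes(7)[i], 1.0)
                  for i in range(20)]
        out = fdr_select(models, q=0.05)
        assert not out["significant"].any()

    def test_single_small_p_flagged(self):
        models = [_fake_model(enumerate_subtypes(7)[0], 0.04)]
        out = fdr_select(models, q=0.05)
        assert out["significant"].all()

    def test_matches_brute_force_step_up(self, rng):
        pvals = np.concatenate([rng.uniform(0, 1, 900),
                                rng.uniform(0, 1e-4, 100)])
        rng.shuffle(pvals)
        models = [_fake_model(enumerate_subtypes(7)[i % 24_576], p)
                  for i, p in enumerate(pvals)]
        out = fdr_select(models, q=0.05)
        expect = brute_force_bh(pvals, 0.05)
        assert np.array_equal(out.sort_index()["significant"].to_numpy(),
                              expect)

    def test_null_false_flag_rate_controlled(self):
        """Global-null false-flag proportion stays near/below q over 50 reps."""
        rng = np.random.default_rng(99)
        rates = []
        for _ in range(50):
            pvals = rng.uniform(0, 1, 500)
            rej = brute_force_bh(pvals, 0.05)  # oracle definition
            models = [_fake_model(enumerate_subtypes(7)[i % 24_576], p)
                      for i, p in enumerate(pvals)]
            out = fdr_select(models, q=0.05)
            assert np.array_equal(out["significant"].to_numpy(), rej)
            rates.append(out["significant"].mean())
        mean = float(np.mean(rates))
        se = float(np.std(rates) / np.sqrt(50))
        assert mean <= 0.05 + 2 * se


def _fake_model(sub, p, beta=0.5):
    from ervrates.features import SubtypeEffectModel

    return SubtypeEffectModel(
        subtype=sub, coef_names=["intercept", "f"],
        coef=np.array([-3.0, beta]), se=np.array([0.1, 0.2]),
        p_values=np.array([1e-10, p]), n_sites=1000, n_ervs=50,
        scale=np.ones(1))


class TestEnrichment:
    def test_null_proportion_not_significant(self):
        flagged = [s for s in enumerate_subtypes(7)[:600]]
        k = sum(1 for s in flagged if s.basic_type == "A>C")
        res = signature_enrichment(flagged,
                                   lambda s: s.basic_type == "A>C",
                                   null_p=k / len(flagged))
        assert res.p_two_sided > 0.5

    def test_reported_a_to_g_excess_bound(self):
        """270 of 403 flagged subtypes being A>G beats the 1/6 null decisively."""
        res_p = float(stats.binom.sf(270 - 1, 403, 1 / 6))
        assert res_p < 1.09e-111

    def test_w_flank_excess_bound(self):
        res_p = float(stats.binom.sf(175 - 1, 270, 1 / 4))
        assert res_p < 4.12e-43

    def test_matches_scipy_upper_tail(self):
        flagged = []
        subs = enumerate_subtypes(7)
        flagged = list(subs[:300]) + [s for s in subs
                                      if s.basic_type == "A>G"][:103]
        res = signature_enrichment(flagged,
                                   lambda s: s.basic_type == "A>G",
                                   null_p=1 / 6)
        k = res.k
        assert res.p_upper == pytest.approx(
            float(stats.binom.sf(k - 1, 403, 1 / 6)))

    def test_empty_flag_set_untestable(self):
        res = signature_enrichment([], lambda s: True, null_p=0.5)
        assert not res.testable


class TestDeNovoFeature:
    def test_identical_rates_statistic_near_zero(self, genome):
        track = FeatureTrack(name="t", kind="binary",
                             intervals={"chr1": [(0, 100_000)]})
        dn = [("chr1", p) for p in range(500, 150_000, 500)]
        bg = [("chr1", p + 37) for p in range(500, 150_000, 500)]
        res = denovo_feature_test(dn, bg, track)
        assert res.statistic < 1.0

    def test_twofold_enrichment_detected(self, genome, rng):
        """2x enrichment inside a half-genome track at 2,000 de novos."""
        n = genome.length("chr1")
        track = FeatureTrack(name="t", kind="binary",
                             intervals={"chr1": [(0, n // 2)]})
        inside = rng.integers(1, n // 2, size=4000)
        outside = rng.integers(n // 2 + 1, n, size=4000)
        dn = ([("chr1", int(p)) for p in inside[:1333]]
              + [("chr1", int(p)) for p in outside[:667]])
        bg = ([("chr1", int(p)) for p in inside[1333:1333 + 1500]]
              + [("chr1", int(p)) for p in outside[667:667 + 1500]])
        res = denovo_feature_test(dn, bg, track)
        assert res.direction == 1
        assert res.p_value < 1e-6

    def test_chi2_matches_hand_formula(self):
        track = FeatureTrack(name="t", kind="binary",
                             intervals={"c": [(0, 10)]})
        dn = [("c", 5)] * 30 + [("c", 50)] * 70
        bg = [("c", 5)] * 40 + [("c", 50) ] * 160
        res = denovo_feature_test(dn, bg, track)
        table = np.array([[30, 70], [40, 160]], dtype=float)
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        hand = ((table - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(hand, rel=1e-12)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(hand, 1)))


class TestGeneratedTracks:
    def test_coverage_realized_within_2pct(self):
        from ervrates.simulate import gen_genome

        g = gen_genome(1_000_000, seed=81)
        tracks, depth = gen_feature_tracks(g, seed=82, coverage=0.2)
        binary = [t for t in tracks if t.kind == "binary"]
        assert len(binary) == 11
        for t in binary[:3]:
            covered = sum(e - s for s, e in t.intervals["chr1"])
            assert abs(covered / 1_000_000 - 0.2) <= 0.02

    def test_zero_coverage_empty(self, genome):
        tracks, _ = gen_feature_tracks(genome, seed=83, coverage=0.0)
        assert all(not t.intervals["chr1"]
                   for t in tracks if t.kind == "binary")

    def test_constant_spec_continuous_value_at(self, genome):
        track = FeatureTrack(name="c", kind="continuous",
                             values={"chr1": [(0, genome.length("chr1"), 7.0)]})
        assert track.value_at(genome, "chr1", 12345) == 7.0
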