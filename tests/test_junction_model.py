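import json
import math

import numpy as np
import pytest

from conftest import TRAIN_CFG, planted_junction_genome, random_sequence
from spliceseek._dna import revcomp
from spliceseek.io_formats import Genome
from spliceseek.junction_model import (
    DEFAULT_BPS_PWM,
    FEATURE_NAMES,
    DegenerateFitError,
    JunctionModel,
    ParetoModel,
    detect_signal,
    extract_features,
    fit_logistic,
    fit_pareto,
    genome_background,
    pareto_log_density,
    score_bps,
    score_junction,
    train_model,
)
from spliceseek.simulate import SimConfig, simulate_genome


def _intron_genome(intron_seq, flank=60):
    rng = np.random.default_rng(2)
    left = random_sequence(flank, rng)
    right = random_sequence(flank, rng)
    return Genome({"chr1": left + intron_seq + right}), flank, flank + len(intron_seq)


class TestDetectSignal:
    @pytest.mark.parametrize(
        "first,last,expected",
        [
            ("GT", "AG", ("GT-AG", "+")),
            ("GC", "AG", ("GC-AG", "+")),
            ("AT", "AC", ("AT-AC", "+")),
            ("CT", "AC", ("GT-AG", "-")),
            ("CT", "GC", ("GC-AG", "-")),
            ("GT", "AT", ("AT-AC", "-")),
            ("AA", "TT", ("other", ".")),
        ],
    )
    def test_signal_classes_both_strands(self, first, last, expected):
        intron = first + "CCCCCCCCCCCCCCCCCCCC" + last
        g, d, a = _intron_genome(intron)
        assert detect_signal(g, "chr1", d, a) == expected

    def test_tiny_intron_is_other(self):
        g, d, a = _intron_genome("GTA")
        assert detect_signal(g, "chr1", d, a) == ("other", ".")


class TestPareto:
    def test_mle_recovers_shape_within_5_percent(self):
        rng = np.random.default_rng(0)
        sizes = 60.0 * (1.0 + rng.pareto(1.5, size=10_000))
        model = fit_pareto(sizes)
        assert abs(model.alpha - 1.5) / 1.5 < 0.05
        assert model.xm == pytest.approx(sizes.min())

    def test_matches_scipy_mle_and_logpdf(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        sizes = 60.0 * (1.0 + rng.pareto(2.0, size=5000))
        model = fit_pareto(sizes)
        b, loc, scale = stats.pareto.fit(sizes, floc=0.0, fscale=sizes.min())
        assert model.alpha == pytest.approx(b, rel=1e-3)
        for x in (100.0, 500.0, 5000.0):
            assert pareto_log_density(model, x) == pytest.approx(
                stats.pareto.logpdf(x, model.alpha, scale=model.xm), rel=1e-9
            )

    def test_degenerate_identical_sizes(self):
        with pytest.raises(DegenerateFitError):
            fit_pareto([100.0] * 50)

    def test_too_few_sizes(self):
        with pytest.raises(ValueError, match="at least 30"):
            fit_pareto(list(range(1, 30)))

    def test_log_density_closed_form(self):
        assert pareto_log_density(ParetoModel(1.0, 1.0), 1.0) == pytest.approx(0.0)
        expected = math.log(2) + 2 * math.log(10) - 3 * math.log(100)
        assert pareto_log_density(ParetoModel(2.0, 10.0), 100.0) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(-8.5172, abs=5e-4)

    def test_density_monotone_beyond_scale(self):
        m = ParetoModel(1.5, 60.0)
        xs = np.linspace(60, 5000, 200)
        vals = [pareto_log_density(m, x) for x in xs]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_sub_support_penalty(self):
        m = ParetoModel(1.5, 60.0)
        at_xm = pareto_log_density(m, 60.0)
        assert pareto_log_density(m, 30.0) == pytest.approx(at_xm - 5.0)
        with pytest.raises(ValueError):
            pareto_log_density(m, 0)


class TestScoreBps:
    def test_planted_consensus_reaches_pwm_maximum(self):
        bg = np.full(4, 0.25)
        consensus = "".join("ACGT"[i] for i in DEFAULT_BPS_PWM.argmax(axis=1))
        rng = np.random.default_rng(7)
        intron = list(random_sequence(100, rng))
        intron[100 - 30 : 100 - 23] = list(consensus)  # inside the 18-40 window
        g, d, a = _intron_genome("".join(intron))
        score = score_bps(g, "chr1", d, a, "+", background=bg)
        expected = float(np.log(DEFAULT_BPS_PWM.max(axis=1) / 0.25).sum())
        assert score == pytest.approx(expected)

    def test_all_n_window_floors(self):
        g = Genome({"chr1": "N" * 200})
        assert score_bps(g, "chr1", 20, 180, "+") == -10.0

    def test_strand_flip_invariance(self):
        rng = np.random.default_rng(9)
        seq = random_sequence(400, rng)
        g = Genome({"chr1": seq})
        grc = Genome({"chr1": revcomp(seq)})
        bg = genome_background(g)
        d, a = 100, 300
        n = len(seq)
        fwd = score_bps(g, "chr1", d, a, "+", background=bg)
        rev = score_bps(grc, "chr1", n - a, n - d, "-", background=bg)
        assert fwd == pytest.approx(rev)


class TestFitLogistic:
    def test_separable_threshold_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 3))
        y = (X[:, 1] > 0.3).astype(float)
        b0, b = fit_logistic(X[:1500], y[:1500])
        pred = (b0 + X[1500:] @ b) > 0
        assert (pred == y[1500:]).mean() > 0.95
        assert abs(b[1]) > 3 * max(abs(b[0]), abs(b[2]))

    def test_uninformative_labels_give_null_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 3))
        y = rng.integers(0, 2, size=4000).astype(float)
        b0, b = fit_logistic(X, y)
        assert np.abs(b).max() < 0.15

    def test_coefficient_recovery_within_10_percent(self):
        rng = np.random.default_rng(2)
        beta = np.array([1.2, -0.8, 0.5])
        X = rng.normal(size=(100_000, 3))
        p = 1.0 / (1.0 + np.exp(-(0.3 + X @ beta)))
        y = (rng.random(100_000) < p).astype(float)
        b0, b = fit_logistic(X, y)
        assert np.all(np.abs(b - beta) / np.abs(beta) < 0.10)
        assert abs(b0 - 0.3) < 0.1


def _null_model(beta0=0.0, beta=None):
    n = len(FEATURE_NAMES)
    return JunctionModel(
        organism="test",
        feature_names=list(FEATURE_NAMES),
        beta0=beta0,
        beta=np.zeros(n) if beta is None else beta,
        mu=np.zeros(n),
        sigma=np.ones(n),
        pareto=ParetoModel(1.5, 60.0),
    )


class TestScoreJunction:
    def test_zero_linear_predictor_scores_half(self):
        m = _null_model()
        assert score_junction(m, np.zeros(len(FEATURE_NAMES))) == pytest.approx(0.5)

    def test_saturation_at_extremes(self):
        up = _null_model(beta0=40.0)
        down = _null_model(beta0=-40.0)
        z = np.zeros(len(FEATURE_NAMES))
        assert up.score(z) > 1 - 1e-9
        assert down.score(z) < 1e-9
        assert 0 < down.score(z) and up.score(z) < 1

    def test_strictly_monotone_in_linear_predictor(self):
        beta = np.zeros(len(FEATURE_NAMES))
        beta[0] = 2.0
        m = _null_model(beta=beta)
        z0 = np.zeros(len(FEATURE_NAMES))
        z1 = z0.copy()
        z1[0] = 1.0
        assert m.score(z1) > m.score(z0)


class TestTrainModel:
    def test_round_trip_serialization(self, trained_model, tmp_path):
        path = tmp_path / "model.json"
        trained_model.save(path)
        loaded = JunctionModel.load(path)
        assert loaded.feature_names == trained_model.feature_names
        assert loaded.beta0 == trained_model.beta0
        np.testing.assert_array_equal(loaded.beta, trained_model.beta)
        np.testing.assert_array_equal(loaded.mu, trained_model.mu)
        assert loaded.pareto == trained_model.pareto
        # plain-text, versioned
        payload = json.loads(path.read_text())
        assert payload["format"] == "spliceseek-junction-model"

    def test_rejects_non_model_file(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text("{}")
        with pytest.raises(ValueError):
            JunctionModel.load(p)

    def test_canonical_typical_intron_outscores_huge_noncanonical(
        self, trained_model
    ):
        genome, _, truth = simulate_genome(TRAIN_CFG)
        m = trained_model
        z_good = np.zeros(len(FEATURE_NAMES))
        z_good[FEATURE_NAMES.index("sig_gtag")] = 1.0
        z_good[FEATURE_NAMES.index("pareto_logpdf")] = pareto_log_density(m.pareto, 150)
        z_good[FEATURE_NAMES.index("log_intron_size")] = math.log(150)
        z_good[FEATURE_NAMES.index("bps_score")] = 2.0
        z_good[FEATURE_NAMES.index("anchor_len")] = 18
        z_bad = np.zeros(len(FEATURE_NAMES))
        z_bad[FEATURE_NAMES.index("sig_other")] = 1.0
        z_bad[FEATURE_NAMES.index("pareto_logpdf")] = pareto_log_density(m.pareto, 10**6)
        z_bad[FEATURE_NAMES.index("log_intron_size")] = math.log(10**6)
        z_bad[FEATURE_NAMES.index("bps_score")] = -2.0
        z_bad[FEATURE_NAMES.index("anchor_len")] = 18
        assert m.score(z_good) > m.score(z_bad)
        assert m.score(z_good) > 0.5 > m.score(z_bad)

    def test_coefficient_report_covers_every_feature(self):
        cfg = SimConfig(genome_length=400_000, n_genes=50, seed=19)
        genome, _, truth = simulate_genome(cfg)
        model, report = train_model(genome, truth.junctions, seed=19)
        assert list(report["feature"]) == FEATURE_NAMES
        assert len(report) == len(model.beta)

    def test_training_is_deterministic(self):
        cfg = SimConfig(genome_length=300_000, n_genes=40, seed=23)
        genome, _, truth = simulate_genome(cfg)
        m1, _ = train_model(genome, truth.junctions, seed=5)
        m2, _ = train_model(genome, truth.junctions, seed=5)
        assert m1.beta0 == m2.beta0
        np.testing.assert_array_equal(m1.beta, m2.beta)

    def test_short_intron_organism_penalizes_size_more(self):
        """Trained on annotations with a stronger short-intron preference
        (larger Pareto shape), the model's score drops faster with intron
        size than when trained on a long-intron organism."""
        short_pref = SimConfig(
            genome_length=900_000, n_genes=110, seed=31, intron_alpha=2.5
        )
        long_pref = SimConfig(
            genome_length=1_400_000, n_genes=110, seed=31, intron_alpha=1.1
        )
        models = {}
        for name, cfg in (("short", short_pref), ("long", long_pref)):
            genome, _, truth = simulate_genome(cfg)
            models[name], _ = train_model(
                genome, truth.junctions, seed=31, max_intron=20_000
            )

        def drop(m):
            def f(size):
                z = np.zeros(len(FEATURE_NAMES))
                z[FEATURE_NAMES.index("sig_gtag")] = 1.0
                z[FEATURE_NAMES.index("pareto_logpdf")] = pareto_log_density(
                    m.pareto, size
                )
                z[FEATURE_NAMES.index("log_intron_size")] = math.log(size)
                z[FEATURE_NAMES.index("anchor_len")] = 18
                return m.linear_predictor(z)

            return f(200) - f(4000)

        assert drop(models["short"]) > drop(models["long"])


class TestExtractFeatures:
    def test_one_hot_signal_and_bounded_mismatch_frac(self, trained_model):
        genome, (d, a), _ = planted_junction_genome(seed=4)
        z, sig, strand = extract_features(
            genome, "chr1", d, a, mismatches=1, read_length=50, anchor_len=10,
            pareto=trained_model.pareto,
        )
        assert z[:4].sum() == 1.0
        assert sig == "GT-AG" and strand == "+"
        assert 0 <= z[FEATURE_NAMES.index("mismatch_frac")] <= 1
        assert z[FEATURE_NAMES.index("anchor_len")] == 10
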