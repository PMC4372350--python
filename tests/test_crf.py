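import itertools

import numpy as np
import pytest

from ampcore import crf
from ampcore.crf import (
    LABELS,
    CRFModel,
    TemplateError,
    compile_observations,
    drop_channel,
    load_model,
    load_templates,
    log_partition,
    marginals,
    nll_and_gradient,
    parse_template_line,
    parse_templates,
    path_log_score,
    save_model,
    train,
    viterbi,
)
from conftest import make_random_tracks

TEMPLATES = parse_templates("U1:%x[0,0]\nU2:%x[-1,1]/%x[0,6]\nB\nB2:%x[0,0]")


def random_model(n, rng, tracks=None):
    """A CRF with random weights indexed over one random sequence."""
    if tracks is None:
        tracks = make_random_tracks(n, rng)
    gold = [LABELS[i] for i in rng.integers(0, 2, tracks.length)]
    data, ui, bi = crf._compile_dataset([(tracks, gold)], TEMPLATES, LABELS)
    model = CRFModel(
        labels=LABELS,
        templates=list(TEMPLATES),
        uni_index=ui,
        bi_index=bi,
        w_uni=rng.normal(size=(data.n_uni, 2)),
        w_bi=rng.normal(size=(data.n_bi, 3, 2)),
    )
    return model, tracks, gold


def enumerate_scores(model, tracks):
    return {
        y: path_log_score(model, tracks, list(y))
        for y in itertools.product(LABELS, repeat=tracks.length)
    }


class TestTemplates:
    def test_default_set_counts(self):
        templates = load_templates("default")
        unis = [t for t in templates if t.arity == "unigram"]
        bis = [t for t in templates if t.arity == "bigram"]
        assert len(unis) == 41  # 8 channels x 5 offsets + residue bigram
        assert len(bis) == 1

    def test_parse_terms(self):
        t = parse_template_line("U7:%x[-2,3]/%x[0,0]")
        assert t.terms == ((-2, 3), (0, 0))
        assert t.channels == ("ALIGN", "PRIMARY")

    def test_pure_transition(self):
        t = parse_template_line("B")
        assert t.arity == "bigram" and t.terms == ()

    def test_bad_lines_rejected(self):
        with pytest.raises(TemplateError):
            parse_template_line("X1:%x[0,0]")
        with pytest.raises(TemplateError):
            parse_template_line("U1:%x[0,99]")
        with pytest.raises(TemplateError):
            parse_template_line("U1:garbage")

    def test_drop_channel(self):
        templates = load_templates("default")
        reduced = drop_channel(templates, "PRIMARY")
        assert all("PRIMARY" not in t.channels for t in reduced)
        # 5 PRIMARY unigrams + the residue bigram removed
        assert len(templates) - len(reduced) == 6


class TestCompile:
    def test_single_unigram(self):
        rng = np.random.default_rng(0)
        tracks = make_random_tracks(2, rng)
        primary = tracks.channels["PRIMARY"]
        uni, bi = compile_observations(tracks, parse_templates("U1:%x[0,0]"))
        assert uni == [[f"U1={primary[0]}"], [f"U1={primary[1]}"]]
        assert bi == [[], []]

    def test_boundary_padding_token(self):
        rng = np.random.default_rng(0)
        tracks = make_random_tracks(3, rng)
        uni, _ = compile_observations(tracks, parse_templates("U1:%x[-2,0]"))
        assert uni[0] == ["U1=_B-2_"]
        assert uni[1] == ["U1=_B-1_"]

    def test_fired_feature_count_matches_template_enumeration(self):
        rng = np.random.default_rng(1)
        tracks = make_random_tracks(10, rng)
        templates = load_templates("default")
        uni, bi = compile_observations(tracks, templates)
        n_uni = sum(1 for t in templates if t.arity == "unigram")
        n_bi = sum(1 for t in templates if t.arity == "bigram")
        assert [len(row) for row in uni] == [n_uni] * 10
        assert [len(row) for row in bi] == [n_bi] * 10


class TestScoring:
    def test_zero_weights_score_zero(self):
        rng = np.random.default_rng(2)
        model, tracks, _ = random_model(5, rng)
        model.w_uni[:] = 0.0
        model.w_bi[:] = 0.0
        for y in itertools.product(LABELS, repeat=5):
            assert path_log_score(model, tracks, list(y)) == 0.0

    def test_single_state_feature(self):
        rng = np.random.default_rng(3)
        model, tracks, _ = random_model(1, rng)
        model.w_uni[:] = 0.0
        model.w_bi[:] = 0.0
        # weight 1 on every pattern fired at position 0, CRITICAL column
        model.w_uni[:, 0] = 1.0 / len(model.uni_index)
        assert path_log_score(model, tracks, ["CRITICAL"]) == pytest.approx(1.0)
        assert path_log_score(model, tracks, ["NONCRITICAL"]) == pytest.approx(0.0)

    def test_unknown_label_rejected(self):
        rng = np.random.default_rng(4)
        model, tracks, _ = random_model(3, rng)
        with pytest.raises(ValueError, match="unknown labels"):
            path_log_score(model, tracks, ["CRITICAL", "BAD", "CRITICAL"])


class TestExactInference:
    def test_zero_weight_partition_closed_form(self):
        rng = np.random.default_rng(5)
        for n in (1, 4, 9):
            model, tracks, _ = random_model(n, rng)
            model.w_uni[:] = 0.0
            model.w_bi[:] = 0.0
            assert log_partition(model, tracks) == pytest.approx(n * np.log(2))

    def test_length_one_closed_form(self):
        rng = np.random.default_rng(6)
        model, tracks, _ = random_model(1, rng)
        a = path_log_score(model, tracks, ["CRITICAL"])
        b = path_log_score(model, tracks, ["NONCRITICAL"])
        assert log_partition(model, tracks) == pytest.approx(np.logaddexp(a, b))

    def test_partition_and_viterbi_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(1, 10))
            model, tracks, _ = random_model(n, rng)
            scores = enumerate_scores(model, tracks)
            brute = np.logaddexp.reduce(list(scores.values()))
            assert abs(log_partition(model, tracks) - brute) < 1e-8
            v = viterbi(model, tracks)
            assert path_log_score(model, tracks, v) == pytest.approx(
                max(scores.values())
            )

    def test_conditional_probabilities_normalize(self):
        rng = np.random.default_rng(8)
        model, tracks, _ = random_model(8, rng)
        logz = log_partition(model, tracks)
        total = sum(
            np.exp(s - logz) for s in enumerate_scores(model, tracks).values()
        )
        assert abs(total - 1.0) < 1e-8

    def test_viterbi_tie_breaks_to_first_label(self):
        rng = np.random.default_rng(9)
        model, tracks, _ = random_model(6, rng)
        model.w_uni[:] = 0.0
        model.w_bi[:] = 0.0
        assert viterbi(model, tracks) == ["CRITICAL"] * 6

    def test_viterbi_beats_random_paths(self):
        rng = np.random.default_rng(10)
        model, tracks, _ = random_model(12, rng)
        best = path_log_score(model, tracks, viterbi(model, tracks))
        for _ in range(200):
            y = [LABELS[i] for i in rng.integers(0, 2, 12)]
            assert path_log_score(model, tracks, y) <= best + 1e-12


class TestMarginals:
    def test_uniform_at_zero_weights(self):
        rng = np.random.default_rng(11)
        model, tracks, _ = random_model(5, rng)
        model.w_uni[:] = 0.0
        model.w_bi[:] = 0.0
        assert np.allclose(marginals(model, tracks), 0.5)

    def test_sum_to_one(self):
        rng = np.random.default_rng(12)
        model, tracks, _ = random_model(9, rng)
        m = marginals(model, tracks)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(13)
        model, tracks, _ = random_model(7, rng)
        logz = log_partition(model, tracks)
        expect = np.zeros((7, 2))
        for y, s in enumerate_scores(model, tracks).items():
            p = np.exp(s - logz)
            for i, lab in enumerate(y):
                expect[i, LABELS.index(lab)] += p
        assert np.allclose(marginals(model, tracks), expect, atol=1e-9)


class TestGradient:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(14)
        data = [
            (make_random_tracks(6, rng), [LABELS[i] for i in rng.integers(0, 2, 6)]),
            (make_random_tracks(4, rng), [LABELS[i] for i in rng.integers(0, 2, 4)]),
        ]
        d, ui, bi = crf._compile_dataset(data, TEMPLATES, LABELS)
        x0 = rng.normal(size=d.n_uni * 2 + d.n_bi * 6) * 0.5

        def f(x):
            nll, gu, gb = crf._batched_nll_grad(
                x[: d.n_uni * 2].reshape(d.n_uni, 2),
                x[d.n_uni * 2 :].reshape(d.n_bi, 3, 2),
                d, 2, 10.0,
            )
            return nll, np.concatenate([gu.ravel(), gb.ravel()])

        _, g = f(x0)
        eps = 1e-6
        for j in range(len(x0)):
            xp, xm = x0.copy(), x0.copy()
            xp[j] += eps
            xm[j] -= eps
            num = (f(xp)[0] - f(xm)[0]) / (2 * eps)
            denom = max(1e-8, abs(num) + abs(g[j]))
            assert abs(num - g[j]) / denom < 1e-5

    def test_balanced_single_position_gradient(self):
        # one-position corpus with both labels equally often: at zero
        # weights, expected counts are 0.5 each, so the state gradient is
        # (0.5 - empirical) per fired pattern
        rng = np.random.default_rng(15)
        tracks = make_random_tracks(1, rng)
        data = [(tracks, ["CRITICAL"]), (tracks, ["NONCRITICAL"])]
        tmpl = parse_templates("U1:%x[0,0]")
        d, ui, bi = crf._compile_dataset(data, tmpl, LABELS)
        _, gu, _ = crf._batched_nll_grad(
            np.zeros((d.n_uni, 2)), np.zeros((0, 3, 2)), d, 2, np.inf
        )
        assert np.allclose(gu, [[2 * 0.5 - 1, 2 * 0.5 - 1]])

    def test_nll_api_on_model(self):
        rng = np.random.default_rng(16)
        model, tracks, gold = random_model(5, rng)
        nll, grad = nll_and_gradient(model, [(tracks, gold)])
        assert np.isfinite(nll)
        assert grad.shape == (model.n_weights,)


class TestTraining:
    def test_separable_dataset_fits_perfectly(self):
        # label is a deterministic function of the residue at offset 0
        rng = np.random.default_rng(17)
        data = []
        for _ in range(6):
            tracks = make_random_tracks(12, rng)
            gold = [
                "CRITICAL" if r in "ACDEFGHIK" else "NONCRITICAL"
                for r in tracks.channels["PRIMARY"]
            ]
            data.append((tracks, gold))
        result = train(data, templates=parse_templates("U1:%x[0,0]"),
                       l2_sigma2=1e6, max_iter=200)
        for tracks, gold in data:
            assert viterbi(result.model, tracks) == gold

    def test_optimum_no_worse_than_zero_weights(self):
        rng = np.random.default_rng(18)
        data = [
            (make_random_tracks(8, rng), [LABELS[i] for i in rng.integers(0, 2, 8)])
            for _ in range(4)
        ]
        result = train(data, templates=TEMPLATES, max_iter=100)
        nll0, _ = nll_and_gradient(
            CRFModel(
                labels=LABELS,
                templates=list(TEMPLATES),
                uni_index=result.model.uni_index,
                bi_index=result.model.bi_index,
                w_uni=np.zeros_like(result.model.w_uni),
                w_bi=np.zeros_like(result.model.w_bi),
            ),
            data,
        )
        assert result.final_nll <= nll0 + 1e-9

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            train([], templates=TEMPLATES)
        rng = np.random.default_rng(19)
        data = [(make_random_tracks(3, rng), ["CRITICAL"] * 3)]
        with pytest.raises(TemplateError):
            train(data, templates=[])

    def test_deterministic_and_round_trips(self, tmp_path):
        rng1 = np.random.default_rng(20)
        data1 = [
            (make_random_tracks(10, rng1), [LABELS[i] for i in rng1.integers(0, 2, 10)])
            for _ in range(3)
        ]
        rng2 = np.random.default_rng(20)
        data2 = [
            (make_random_tracks(10, rng2), [LABELS[i] for i in rng2.integers(0, 2, 10)])
            for _ in range(3)
        ]
        r1 = train(data1, templates=TEMPLATES, max_iter=50)
        r2 = train(data2, templates=TEMPLATES, max_iter=50)
        assert np.array_equal(r1.model.w_uni, r2.model.w_uni)
        assert np.array_equal(r1.model.w_bi, r2.model.w_bi)

        p1, p2 = tmp_path / "m1.crf", tmp_path / "m2.crf"
        save_model(r1.model, p1)
        save_model(r2.model, p2)
        assert p1.read_bytes() == p2.read_bytes()
        loaded = load_model(p1)
        assert np.array_equal(loaded.w_uni, r1.model.w_uni)
        assert np.array_equal(loaded.w_bi, r1.model.w_bi)
        save_model(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_convexity_perturbed_starts_agree(self):
        rng = np.random.default_rng(21)
        data = [
            (make_random_tracks(6, rng), [LABELS[i] for i in rng.integers(0, 2, 6)])
            for _ in range(3)
        ]
        objectives = []
        for trial in range(5):
            d, _, _ = crf._compile_dataset(data, TEMPLATES, LABELS)
            size = d.n_uni * 2 + d.n_bi * 6
            init = rng.normal(size=size) * 0.5
            res = train(data, templates=TEMPLATES, max_iter=500, tol=1e-12,
                        init=init)
            objectives.append(res.final_nll)
        assert max(objectives) - min(objectives) < 1e-4
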