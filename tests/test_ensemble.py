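"""Hybrid ensemble: lexicon scoring, weighted fusion, rule-table merge."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from vaxsent.corpus import UsageError
from vaxsent.ensemble import (
    Backends,
    BackendError,
    ClassifierOutput,
    EnsembleConfig,
    KeywordClassifier,
    LexiconScorer,
    Sentiment,
    classify_corpus,
    classify_post,
    combine_lexicons,
    default_rule_table,
    lexicon_polarity,
    merge_rule,
    polarity_to_label,
)
from vaxsent.preprocess import CleanText

from conftest import make_post


def cleaned(*tokens):
    return CleanText(post_id="x", tokens=tokens)


class TestLexiconScorer:
    def test_symmetric_valences_cancel(self):
        scorer = LexiconScorer({"good": 0.8, "bad": -0.8})
        assert scorer(("good", "bad")) == 0.0

    def test_mean_of_in_lexicon_tokens(self):
        scorer = LexiconScorer({"good": 0.8, "great": 0.6})
        assert scorer(("good", "great")) == pytest.approx(0.7)

    def test_no_in_lexicon_tokens_scores_zero(self):
        scorer = LexiconScorer({"good": 0.8})
        assert scorer(("unknown", "words")) == 0.0

    def test_out_of_range_valence_rejected(self):
        with pytest.raises(UsageError):
            LexiconScorer({"good": 1.5})

    def test_backend_contract_violation_detected(self):
        post = make_post(text="whatever")
        with pytest.raises(BackendError):
            lexicon_polarity(lambda toks: 2.0, post, cleaned("whatever"))


class TestCombineLexicons:
    def test_zero_inputs_give_zero(self):
        assert combine_lexicons(0.0, 0.0) == 0.0

    def test_convexity_fixed_point(self):
        assert combine_lexicons(1.0, 1.0) == pytest.approx(1.0)

    def test_default_weights_hand_arithmetic(self):
        assert combine_lexicons(1.0, -1.0, (0.45, 0.55)) == pytest.approx(-0.10)

    def test_invalid_weights_rejected(self):
        with pytest.raises(UsageError):
            combine_lexicons(0.5, 0.5, (0.4, 0.5))
        with pytest.raises(UsageError):
            combine_lexicons(0.5, 0.5, (-0.1, 1.1))

    @given(
        a=st.floats(-1, 1), b=st.floats(-1, 1),
        w=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, a, b, w):
        out = combine_lexicons(a, b, (w, 1.0 - w))
        assert -1.0 <= out <= 1.0

    @given(
        a1=st.floats(-1, 1), a2=st.floats(-1, 1), b=st.floats(-1, 1),
        w=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_first_argument(self, a1, a2, b, w):
        lo, hi = sorted((a1, a2))
        weights = (w, 1.0 - w)
        assert combine_lexicons(lo, b, weights) <= combine_lexicons(hi, b, weights)

    def test_degenerate_weights_reduce_to_lexicon_a(self):
        for a in (-0.7, 0.0, 0.3):
            assert combine_lexicons(a, 0.9, (1.0, 0.0)) == a


class TestPolarityToLabel:
    @pytest.mark.parametrize("tau", [0.0, 0.05, 0.5])
    def test_zero_is_neutral_for_any_band(self, tau):
        assert polarity_to_label(0.0, tau) == Sentiment.NEUTRAL

    def test_clear_positive(self):
        assert polarity_to_label(0.5, 0.05) == Sentiment.POSITIVE

    def test_boundary_is_inclusive_neutral(self):
        assert polarity_to_label(-0.05, 0.05) == Sentiment.NEUTRAL
        assert polarity_to_label(0.05, 0.05) == Sentiment.NEUTRAL

    def test_negative_band_rejected(self):
        with pytest.raises(UsageError):
            polarity_to_label(0.1, -0.01)


class TestMergeRule:
    @pytest.mark.parametrize(
        "lex,clf,expected",
        [
            (Sentiment.POSITIVE, Sentiment.NEGATIVE, Sentiment.POSITIVE),
            (Sentiment.NEUTRAL, Sentiment.NEGATIVE, Sentiment.NEGATIVE),
            (Sentiment.NEGATIVE, Sentiment.POSITIVE, Sentiment.POSITIVE),
        ],
    )
    def test_default_table(self, lex, clf, expected):
        assert merge_rule(lex, clf) == expected

    def test_missing_pair_in_custom_table_rejected(self):
        partial = {(Sentiment.POSITIVE, Sentiment.POSITIVE): Sentiment.POSITIVE}
        with pytest.raises(UsageError):
            EnsembleConfig(rule_table=partial)


class TestEnsembleConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(UsageError):
            EnsembleConfig(lexicon_weights=(0.5, 0.6))

    def test_probability_vector_validation(self):
        with pytest.raises(BackendError):
            ClassifierOutput(Sentiment.POSITIVE, (0.5, 0.5, 0.5))
        with pytest.raises(BackendError):
            ClassifierOutput(Sentiment.POSITIVE, (0.8, 0.1, 0.1))  # argmax mismatch
        out = ClassifierOutput(Sentiment.POSITIVE, (0.1, 0.2, 0.7))
        assert out.probabilities == (0.1, 0.2, 0.7)


GRID_SCORES = (-1.0, -0.5, 0.0, 0.5, 1.0)


class FixedLexicon:
    def __init__(self, value):
        self.value = value

    def __call__(self, tokens):
        return self.value


def test_classify_post_matches_brute_force_on_exhaustive_grid():
    """75-cell oracle: every (lex_a, lex_b, clf) combination must equal an
    independent re-evaluation of weighted-average -> threshold -> table."""
    cfg = EnsembleConfig()
    post = make_post(text="irrelevant")
    ct = cleaned("irrelevant")
    for a, b, clf in itertools.product(GRID_SCORES, GRID_SCORES, (-1, 0, 1)):
        backends = Backends(
            FixedLexicon(a), FixedLexicon(b),
            lambda text, c=clf: ClassifierOutput(Sentiment(c)),
        )
        got = classify_post(post, ct, backends, cfg)

        # independent brute-force evaluation
        combined = 0.45 * a + 0.55 * b
        if combined > 0.05:
            lex_label = 1
        elif combined < -0.05:
            lex_label = -1
        else:
            lex_label = 0
        expected = lex_label if lex_label == 1 else clf

        assert got.error is None
        assert int(got.final) == expected, (a, b, clf)
        assert got.combined == pytest.approx(combined)


def test_echo_classifier_projects_to_lexicon_labels():
    """A classifier that echoes the lexicon label leaves labels unchanged."""
    cfg = EnsembleConfig()
    scorer = LexiconScorer({"good": 0.8, "bad": -0.8})
    posts = [make_post("a", text="good good"), make_post("b", text="bad"),
             make_post("c", text="meh")]
    cleaned_posts = [cleaned(*p.text.split()) for p in posts]
    for post, ct in zip(posts, cleaned_posts):
        lex_label = polarity_to_label(scorer(ct.tokens), cfg.neutral_band)
        backends = Backends(
            scorer, scorer, lambda text, l=lex_label: ClassifierOutput(l)
        )
        got = classify_post(post, ct, backends, cfg)
        assert got.final == lex_label


def test_always_classifier_table_projects_to_classifier_labels():
    table = {
        (lex, clf): clf
        for lex in (Sentiment.NEGATIVE, Sentiment.NEUTRAL, Sentiment.POSITIVE)
        for clf in (Sentiment.NEGATIVE, Sentiment.NEUTRAL, Sentiment.POSITIVE)
    }
    cfg = EnsembleConfig(rule_table=table)
    backends = Backends(
        FixedLexicon(1.0), FixedLexicon(1.0),
        lambda text: ClassifierOutput(Sentiment.NEGATIVE),
    )
    got = classify_post(make_post(text="x"), cleaned("x"), backends, cfg)
    assert got.final == Sentiment.NEGATIVE


def test_backend_failure_labels_post_error_and_continues():
    def crashing(text):
        raise RuntimeError("backend down")

    posts = [make_post("a", text="good"), make_post("b", text="bad")]
    cts = [cleaned("good"), cleaned("bad")]
    scorer = LexiconScorer({"good": 0.8, "bad": -0.8})
    backends = Backends(scorer, scorer, crashing)
    audit, n_errors = classify_corpus(posts, cts, backends)
    assert n_errors == 2
    assert audit["final"].isna().all()
    assert audit["error"].notna().all()


def test_keyword_classifier_majority_sign():
    clf = KeywordClassifier()
    assert clf("great amazing fear").label == Sentiment.POSITIVE
    assert clf("hoax fear great").label == Sentiment.NEGATIVE
    assert clf("nothing here").label == Sentiment.NEUTRAL
    assert clf("great fear").label == Sentiment.NEUTRAL  # tie
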