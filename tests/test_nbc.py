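"""Unit and property tests for the naive Bayesian classifier core."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import lineage, make_classification, make_ts
from ribotax import nbc
from ribotax.taxonomy import RANKS, UNCLASSIFIED

dna_with_ambiguity = st.text(alphabet="ACGTN", min_size=0, max_size=40)


class TestExtractWords:
    @pytest.mark.parametrize(
        "seq,w,expected",
        [
            ("ACGTACGT", 8, ["ACGTACGT"]),
            ("ACGTNACGT", 4, ["ACGT", "ACGT"]),  # windows covering N skipped
            ("ACG", 8, []),  # shorter than the word: empty, not an error
            ("acgt", 4, ["ACGT"]),  # case-normalized
        ],
    )
    def test_examples(self, seq, w, expected):
        assert nbc.extract_words(seq, w) == expected

    def test_sliding_window_count(self):
        words = nbc.extract_words("ACGTACGTACGT", 8)
        assert len(words) == 5
        assert words == oracles.words_bruteforce("ACGTACGTACGT", 8)

    @settings(max_examples=200, derandomize=True)
    @given(seq=dna_with_ambiguity, w=st.integers(min_value=1, max_value=6))
    def test_matches_bruteforce_enumeration(self, seq, w):
        assert nbc.extract_words(seq, w) == oracles.words_bruteforce(seq, w)

    def test_distinct_view_preserves_first_occurrence_order(self):
        assert nbc.distinct_words("ACGTACGTT", 4) == ["ACGT", "CGTA", "GTAC", "TACG", "CGTT"]

    def test_word_codes_agree_with_strings(self):
        seq = "ACGTTGCANTTACGT"
        codes = nbc.word_codes(seq, 4)
        assert [nbc.code_to_word(int(c), 4) for c in codes] == nbc.extract_words(seq, 4)

    def test_invalid_word_size(self):
        with pytest.raises(ValueError):
            nbc.extract_words("ACGT", 0)


class TestTrain:
    def test_pseudocount_formulas_single_sequence(self):
        # one genus, one sequence, word size 8: every present word has
        # prior (1+0.5)/2 and conditional (1+0.75)/2
        ts = make_ts("t", [("s1", "ACGTACGTAC", lineage("G1"))])
        model = nbc.train(ts, 8)
        for word in nbc.distinct_words("ACGTACGTAC", 8):
            assert model.word_prior(word) == pytest.approx(1.5 / 2)
            assert model.cond_prob("G1", word) == pytest.approx((1 + 0.75) / 2)

    def test_prior_counts_documents_not_occurrences(self):
        # two sequences both containing the word: n(w)=2, N=2
        ts = make_ts("t", [("s1", "ACGTACGTA", lineage("G1")),
                           ("s2", "TTACGTACGT", lineage("G2"))])
        model = nbc.train(ts, 8)
        assert model.word_prior("ACGTACGT") == pytest.approx(2.5 / 3)

    def test_absent_word_stays_positive(self):
        # word absent from a 3-sequence genus: P(w|G) = prior / 4 > 0
        entries = [(f"a{i}", "ACGTACGTACGT", lineage("Ga")) for i in range(3)]
        entries += [("b1", "TTTTCCCCTTTTCCCC", lineage("Gb"))]
        model = nbc.train(make_ts("t", entries), 8)
        prior = model.word_prior("TTTTCCCC")
        assert model.cond_prob("Ga", "TTTTCCCC") == pytest.approx(prior / 4)
        assert model.cond_prob("Ga", "TTTTCCCC") > 0

    def test_empty_training_set(self):
        with pytest.raises(ValueError, match="empty training set"):
            nbc.train([], 8)

    def test_missing_taxonomy_names_sequence(self):
        from ribotax import ReferenceSeq

        with pytest.raises(ValueError, match="s99"):
            nbc.train([ReferenceSeq("s99", "ACGTACGT")], 8)


class TestClassify:
    def test_single_genus_always_wins(self):
        ts = make_ts("t", [("s1", "ACGTACGTACGTAC", lineage("Only"))])
        genus, _ = nbc.classify(nbc.train(ts, 4), "TTTTGGGG")
        assert genus == "Only"

    def test_disjoint_word_content_matches_oracle(self):
        refs = [("Ga", "ACACACACACAC"), ("Ga", "ACACACACACGA"),
                ("Gb", "GTGTGTGTGTGT")]
        ts = make_ts("t", [(f"s{i}", seq, lineage(g)) for i, (g, seq) in enumerate(refs)])
        model = nbc.train(ts, 4)
        genus, scores = nbc.classify(model, "ACACACAC")
        expected = oracles.nbc_scores(refs, 4, "ACACACAC")
        assert genus == "Ga"
        for g in expected:
            assert scores[g] == pytest.approx(expected[g], abs=1e-9)

    def test_random_instances_match_bruteforce(self):
        rng = random.Random(20)
        for _ in range(25):
            refs, read = oracles.random_instance(rng)
            ts = make_ts("t", [(f"s{i}", seq, lineage(g))
                               for i, (g, seq) in enumerate(refs)])
            model = nbc.train(ts, 4)
            genus, scores = nbc.classify(model, read)
            expected = oracles.nbc_scores(refs, 4, read)
            assert genus == oracles.nbc_argmax(expected)
            for g in expected:
                assert scores[g] == pytest.approx(expected[g], abs=1e-9)

    def test_tie_break_lexicographic(self):
        # identical training sequences in two genera: identical scores
        ts = make_ts("t", [("s1", "ACGTACGTACGT", lineage("Gb")),
                           ("s2", "ACGTACGTACGT", lineage("Ga"))])
        genus, scores = nbc.classify(nbc.train(ts, 4), "ACGTACGT")
        assert scores["Ga"] == scores["Gb"]
        assert genus == "Ga"

    def test_no_classifiable_words(self):
        ts = make_ts("t", [("s1", "ACGTACGTACGT", lineage("G1"))])
        model = nbc.train(ts, 4)
        with pytest.raises(ValueError, match="no classifiable words"):
            nbc.classify(model, "NNNNN")


class TestBootstrap:
    def _toy(self):
        random.seed(4)
        a = oracles.random_dna(60, random)
        refs = [("Ga", a), ("Ga", oracles.mutate_seq(a, 0.05, random)),
                ("Gb", oracles.mutate_seq(a, 0.2, random)),
                ("Gc", oracles.random_dna(60, random))]
        lineages = {
            "Ga": lineage("Ga", family="FamAB").display_labels,
            "Gb": lineage("Gb", family="FamAB").display_labels,
            "Gc": lineage("Gc").display_labels,
        }
        ts = make_ts("t", [
            ("s1", refs[0][1], lineage("Ga", family="FamAB")),
            ("s2", refs[1][1], lineage("Ga", family="FamAB")),
            ("s3", refs[2][1], lineage("Gb", family="FamAB")),
            ("s4", refs[3][1], lineage("Gc")),
        ])
        return refs, lineages, ts

    def test_isolated_divergent_genus_scores_100_everywhere(self):
        rng = random.Random(7)
        seqs = [oracles.random_dna(120, rng) for _ in range(3)]
        ts = make_ts("t", [(f"s{i}", s, lineage(f"G{i}")) for i, s in enumerate(seqs)])
        model = nbc.train(ts, 8)
        c = nbc.bootstrap_confidence(model, seqs[0], trials=100, seed=5)
        assert all(conf == 100.0 for _, conf in c.per_rank)
        assert c.winning_genus == "G0"

    def test_family_confidence_at_least_genus(self):
        # a read ambiguous between two genera of one family
        rng = random.Random(9)
        anc = oracles.random_dna(80, rng)
        fam = lineage("X", family="SharedFam")
        ts = make_ts("t", [
            ("s1", oracles.mutate_seq(anc, 0.1, rng),
             lineage("Ga", family="SharedFam")),
            ("s2", oracles.mutate_seq(anc, 0.1, rng),
             lineage("Gb", family="SharedFam")),
        ])
        model = nbc.train(ts, 4)
        c = nbc.bootstrap_confidence(model, anc, trials=200, seed=3)
        assert c.confidence("Family") >= c.confidence("Genus")

    def test_matches_large_trial_monte_carlo(self):
        # fixed toy model: package confidences vs an independent pure-python
        # re-simulation with 100,000 trials, within 5 percentage points
        refs, lineages, ts = self._toy()
        read = oracles.mutate_seq(refs[0][1], 0.12, random.Random(11))
        model = nbc.train(ts, 4)
        ours = nbc.bootstrap_confidence(model, read, trials=20000, seed=42)
        winner, confs = oracles.bootstrap_mc(refs, lineages, 4, read, 100_000,
                                             random.Random(12345))
        assert ours.winning_genus == winner
        for r in range(6):
            assert ours.confidence(r) == pytest.approx(confs[r], abs=5.0)

    def test_deterministic_given_seed(self):
        _, _, ts = self._toy()
        model = nbc.train(ts, 4)
        read = ts.refs[0].sequence
        a = nbc.bootstrap_confidence(model, read, trials=100, seed=77, query_id="q")
        b = nbc.bootstrap_confidence(model, read, trials=100, seed=77, query_id="q")
        assert a == b

    def test_invalid_trials(self):
        _, _, ts = self._toy()
        model = nbc.train(ts, 4)
        with pytest.raises(ValueError):
            nbc.bootstrap_confidence(model, "ACGTACGT", trials=0, seed=1)

    def test_ancestor_dominance_on_random_models(self):
        rng = random.Random(31)
        for _ in range(30):
            refs, read = oracles.random_instance(rng)
            ts = make_ts("t", [(f"s{i}", seq, lineage(g))
                               for i, (g, seq) in enumerate(refs)])
            model = nbc.train(ts, 4)
            c = nbc.bootstrap_confidence(model, read, trials=50, seed=rng.randrange(2**31))
            confs = [conf for _, conf in c.per_rank]
            assert all(confs[r] >= confs[r + 1] for r in range(5))


class TestApplyThreshold:
    def test_truncates_from_first_failing_rank(self):
        c = make_classification("q", ["D", "P", "C", "O", "F", "G"],
                                [100, 100, 90, 70, 55, 40])
        out = nbc.apply_threshold(c, 60)
        assert [lab for lab, _ in out.per_rank] == \
            ["D", "P", "C", "O", UNCLASSIFIED, UNCLASSIFIED]
        assert out.threshold_applied == 60

    def test_all_confident_unchanged(self):
        c = make_classification("q", list("DPCOFG"), [100] * 6)
        assert [lab for lab, _ in nbc.apply_threshold(c, 60).per_rank] == list("DPCOFG")

    def test_domain_failure_unclassifies_everything(self):
        c = make_classification("q", list("DPCOFG"), [59, 100, 100, 100, 100, 100])
        out = nbc.apply_threshold(c, 60)
        assert all(lab == UNCLASSIFIED for lab, _ in out.per_rank)
        assert out.is_unclassified

    def test_boundary_is_inclusive_pass(self):
        c = make_classification("q", list("DPCOFG"), [100, 100, 100, 100, 100, 60])
        assert nbc.apply_threshold(c, 60).label("Genus") == "G"
        c = make_classification("q", list("DPCOFG"), [100, 100, 100, 100, 100, 59.999])
        assert nbc.apply_threshold(c, 60).label("Genus") == UNCLASSIFIED

    def test_cutoff_range_checked(self):
        c = make_classification("q", list("DPCOFG"), [100] * 6)
        for bad in (-1, 100.5):
            with pytest.raises(ValueError):
                nbc.apply_threshold(c, bad)

    @settings(max_examples=200, derandomize=True)
    @given(
        confs=st.lists(st.floats(min_value=0, max_value=100), min_size=6, max_size=6),
        cutoff=st.floats(min_value=0, max_value=100),
    )
    def test_prefix_monotone_truncation(self, confs, cutoff):
        c = make_classification("q", list("DPCOFG"), confs)
        out = nbc.apply_threshold(c, cutoff)
        labels = [lab for lab, _ in out.per_rank]
        # once a rank is unclassified every deeper rank is too
        seen = False
        for lab, conf in zip(labels, confs):
            if seen:
                assert lab == UNCLASSIFIED
            if lab == UNCLASSIFIED:
                seen = True
        # and the first unclassified rank is exactly the first sub-cutoff one
        fails = [i for i, conf in enumerate(confs) if conf < cutoff]
        if fails:
            assert labels[fails[0]] == UNCLASSIFIED
            assert all(lab != UNCLASSIFIED for lab in labels[: fails[0]])
        else:
            assert UNCLASSIFIED not in labels
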