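"""Symmetric-delete correction against exhaustive edit-distance oracles."""

from functools import lru_cache

import numpy as np
import pytest

from infodemic import (
    Corrector,
    FrequencyDictionary,
    SpellConfig,
    boost_domain,
    build_index,
    correct,
    damerau_levenshtein,
)
from infodemic.spellfix import (
    ParameterError,
    ValidationError,
    deletion_variants,
)

TOY_WORDS = [
    "cough", "fever", "virus", "mask", "wash", "hands", "soap", "water",
    "covid", "corona", "symptom", "throat", "breath", "doctor", "nurse",
    "home", "stay", "safe", "sick", "test", "swab", "fewer", "couch",
    "tough", "rough", "mark", "cash", "hand", "soup", "later", "cot",
    "cost", "coast", "toast", "most", "mist", "must", "mast", "fast",
    "fist", "list", "lost", "last", "best", "rest", "nest", "vest",
    "west", "jest", "zest",
]


@pytest.fixture
def toy_dict():
    # descending counts so frequency tie-breaks are exercised
    return FrequencyDictionary(
        counts={w: 1000 - 17 * i for i, w in enumerate(TOY_WORDS)})


@pytest.fixture
def toy_corrector(toy_dict):
    return Corrector(toy_dict, SpellConfig(max_edit_distance=2, domain_boost=1.0))


def oracle_osa(a: str, b: str) -> int:
    """Independent memoized-recursion optimal-string-alignment distance."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def oracle_correct(token, dictionary, cfg):
    """Exhaustive search over the whole dictionary with the stated ranking."""
    if token in dictionary:
        return token
    best = None
    for word, count in dictionary.counts.items():
        dist = oracle_osa(token, word)
        if dist > cfg.max_edit_distance:
            continue
        eff = count * cfg.domain_boost if word in cfg.domain_lexicon else count
        key = (dist, -eff, word)
        if best is None or key < best[0]:
            best = (key, word)
    return best[1] if best else token


class TestBoostDomain:
    def test_factor_one_is_identity(self, toy_dict):
        assert boost_domain(toy_dict, {"cough"}, 1.0).counts == toy_dict.counts

    def test_direct_arithmetic(self):
        d = FrequencyDictionary(counts={"cough": 10, "tough": 100})
        boosted = boost_domain(d, {"cough"}, 20)
        assert boosted.counts == {"cough": 200, "tough": 100}

    def test_boost_flips_winner_among_equidistant_candidates(self):
        d = FrequencyDictionary(counts={"cog": 100, "cough": 10})
        cfg = SpellConfig(max_edit_distance=2, domain_boost=1.0)
        idx = build_index(d, 2)
        # "cogh" is distance 1 from both; frequency decides
        assert correct("cogh", idx, d, cfg) == "cog"
        boosted = boost_domain(d, {"cough"}, 20)
        idx_b = build_index(boosted, 2)
        assert correct("cogh", idx_b, boosted, cfg) == "cough"
        assert oracle_correct("cogh", boosted, cfg) == "cough"

    def test_factor_below_one_rejected(self, toy_dict):
        with pytest.raises(ParameterError):
            boost_domain(toy_dict, {"cough"}, 0.5)


class TestBuildIndex:
    def test_single_word_variants(self):
        idx = build_index(FrequencyDictionary(counts={"at": 1}), 1)
        assert set(idx.index) == {"at", "a", "t"}

    def test_collision_maps_to_both_words(self):
        idx = build_index(FrequencyDictionary(counts={"ab": 1, "ba": 1}), 1)
        assert idx.index["a"] == {"ab", "ba"}

    def test_keys_equal_brute_force_enumeration(self, toy_dict):
        def brute_deletes(word, d):
            out = {word}
            if d == 0:
                return out
            for i in range(len(word)):
                out |= brute_deletes(word[:i] + word[i + 1:], d - 1)
            return out

        small = FrequencyDictionary(
            counts={w: c for w, c in list(toy_dict.counts.items())[:20]})
        idx = build_index(small, 2)
        expected_keys = set()
        for w in small.counts:
            expected_keys |= brute_deletes(w, 2)
        assert set(idx.index) == expected_keys
        for variant, origins in idx.index.items():
            assert origins == {w for w in small.counts
                               if variant in brute_deletes(w, 2)}


class TestDamerauLevenshtein:
    @pytest.mark.parametrize("a,b,expected", [
        ("", "abc", 3),
        ("ab", "ba", 1),          # adjacent transposition
        ("kitten", "sitting", 3),
        ("ca", "abc", 3),         # optimal string alignment, not full DL
        ("cough", "cough", 0),
    ])
    def test_spot_values(self, a, b, expected):
        assert damerau_levenshtein(a, b) == expected

    def test_agrees_with_independent_recursion(self):
        rng = np.random.default_rng(11)
        letters = "abcdef"
        for _ in range(200):
            a = "".join(rng.choice(list(letters), size=rng.integers(0, 7)))
            b = "".join(rng.choice(list(letters), size=rng.integers(0, 7)))
            assert damerau_levenshtein(a, b) == oracle_osa(a, b)


class TestCorrect:
    def test_exact_hit_returned_unchanged(self, toy_dict, toy_corrector):
        assert toy_corrector.correct("cough") == "cough"

    def test_transposed_token_recovered(self, toy_dict, toy_corrector):
        assert toy_corrector.correct("cuogh") == "cough"
        cfg = toy_corrector.cfg
        assert oracle_correct("cuogh", toy_dict, cfg) == "cough"

    def test_hopeless_token_returned_unchanged(self, toy_corrector):
        assert toy_corrector.correct("zzzzz") == "zzzzz"

    def test_empty_token_rejected(self, toy_corrector):
        with pytest.raises(ValidationError):
            toy_corrector.correct("")

    def test_fuzz_equivalence_with_exhaustive_oracle(self, toy_dict):
        cfg = SpellConfig(max_edit_distance=2, domain_boost=1.0)
        idx = build_index(toy_dict, 2)
        rng = np.random.default_rng(23)
        letters = "abcdefghijklmnopqrstuvwz"
        for _ in range(300):
            token = "".join(rng.choice(list(letters),
                                       size=rng.integers(1, 9)))
            assert correct(token, idx, toy_dict, cfg) == \
                oracle_correct(token, toy_dict, cfg)

    def test_idempotence(self, toy_corrector):
        rng = np.random.default_rng(31)
        letters = "abcdefghortuvw"
        for _ in range(100):
            token = "".join(rng.choice(list(letters),
                                       size=rng.integers(1, 8)))
            once = toy_corrector.correct(token)
            assert toy_corrector.correct(once) == once

    def test_increasing_boost_never_demotes_domain_candidate(self):
        d = FrequencyDictionary(counts={"cog": 100, "cough": 10, "cosh": 60})
        idx = build_index(d, 2)
        token = "cogh"  # distance 1 from all three candidates
        winners = []
        for boost in (1.0, 2.0, 5.0, 20.0, 100.0):
            cfg = SpellConfig(max_edit_distance=2, domain_boost=boost,
                              domain_lexicon=frozenset({"cough"}))
            winners.append(correct(token, idx, d, cfg))
        # once the domain word wins it keeps winning at higher boosts
        first_win = next((i for i, w in enumerate(winners) if w == "cough"),
                         len(winners))
        assert all(w == "cough" for w in winners[first_win:])

    def test_max_distance_one_excludes_distance_two(self, toy_dict):
        cfg = SpellConfig(max_edit_distance=1)
        idx = build_index(toy_dict, 1)
        # "cugh" is distance 1 from cough? c-u-g-h -> insert o: yes, distance 1
        assert correct("cugh", idx, toy_dict, cfg) == "cough"
        # "cug" is distance 2 from cough, no candidate within 1
        assert correct("cugz", idx, toy_dict, cfg) == "cugz"


class TestValidation:
    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValidationError):
            FrequencyDictionary(counts={"x": 0})

    def test_uppercase_word_rejected(self):
        with pytest.raises(ValidationError):
            FrequencyDictionary(counts={"Covid": 3})

    def test_bad_max_distance_rejected(self, toy_dict):
        with pytest.raises(ParameterError):
            build_index(toy_dict, 3)

    def test_deletion_variants_include_self(self):
        assert deletion_variants("ab", 1) == {"ab", "a", "b"}
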