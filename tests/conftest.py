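import numpy as np
import pytest

import indriflex as ix
from indriflex.simulate import CategoryParams, make_transition_matrix


@pytest.fixture(scope="session")
def small_corpus() -> ix.Corpus:
    """Three groups, one non-dominant each: all nine dyad factor levels occur."""
    cfg = ix.SyntheticConfig(
        n_groups=3,
        songs_per_group=8,
        n_nondominants_per_group=1,
        nondominant_participation=0.6,
        seed=11,
    )
    return ix.generate_corpus(cfg)


@pytest.fixture(scope="session")
def handmade_corpus() -> ix.Corpus:
    """A tiny hand-written corpus with known contents."""
    singers = {
        "fA": ix.SingerMeta("fA", "female", "dominant", "g1"),
        "mA": ix.SingerMeta("mA", "male", "dominant", "g1"),
        "nA": ix.SingerMeta("nA", "unrecorded", "non_dominant", "g1"),
    }
    tok = ix.parse_contribution_string
    contributions = [
        ix.Contribution("s1", "fA", tok("SU|DP3|DP2|DP3")),
        ix.Contribution("s1", "mA", tok("SU|DP2|DP2")),
        ix.Contribution("s2", "fA", tok("DP2|DP3|DP3|DP5|DP4")),
        ix.Contribution("s2", "mA", tok("SU|DP2|DP3")),
        ix.Contribution("s2", "nA", tok("SU|SU|DP2")),
    ]
    return ix.Corpus(singers=singers, contributions=contributions,
                     provenance="handmade")


def brute_force_jaro(a, b):
    """Independent Jaro implementation, straight from the definition.

    Matches are collected by scanning each position of ``a`` for the first
    unused equal token of ``b`` within the window w = floor(max(|a|,|b|)/2)-1;
    transpositions are half the number of positions at which the two matched
    subsequences disagree.  Written without sharing code with the package.
    """
    a, b = list(a), list(b)
    w = max(len(a), len(b)) // 2 - 1
    if w < 0:
        w = 0
    used_b = set()
    pairs = []  # (index in a, index in b)
    for i in range(len(a)):
        for j in range(max(0, i - w), min(len(b), i + w + 1)):
            if j not in used_b and a[i] == b[j]:
                used_b.add(j)
                pairs.append((i, j))
                break
    m = len(pairs)
    if m == 0:
        return 0.0, 0, 0.0
    seq_a = [a[i] for i, _ in sorted(pairs)]
    seq_b = [b[j] for _, j in sorted(pairs, key=lambda p: p[1])]
    t = sum(1 for x, y in zip(seq_a, seq_b) if x != y) / 2.0
    sim = (m / len(a) + m / len(b) + (m - t) / m) / 3.0
    return sim, m, t


@pytest.fixture(scope="session")
def category_params_null():
    """All three categories share one generating matrix (matched generators)."""
    base = make_transition_matrix(6, 1.0, seed=5)
    return {
        cat: CategoryParams(base, mean_length=10.0) for cat in ix.CATEGORIES
    }
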