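"""Jaro similarity over phrase-token sequences and the dyadic dataset.

The Jaro statistic compares two sequences by counting *matches* (equal
tokens within a sliding window of half the longer sequence) and
*transpositions* (matched tokens that appear out of order).  With ``m``
matches and ``t`` transpositions between sequences ``a`` and ``b``::

    sim = (m/|a| + m/|b| + (m - t)/m) / 3        (0 if m == 0)

Following the source convention for these data, the value is stored as a
similarity: 1 means identical sequences, 0 means no matching tokens, and
*lower* values indicate more flexible (more variable) phrase concatenation.
A distance accessor (``1 - sim``) is provided.

Canonically each phrase type is one symbol (token-level matching); a
character-level compatibility mode that compares the raw pipe-delimited text
is available, since generic string-distance tooling applied to such text
would match individual characters and overweight shared label prefixes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import Contribution, Corpus, SingerMeta

__all__ = [
    "JaroResult",
    "jaro_similarity",
    "jaro_distance",
    "pairwise_jaro_matrix",
    "build_dyad_dataset",
    "CATEGORY_FACTOR_LEVELS",
]

#: The nine levels of the dyad factor: distance type (W/B) crossed with the
#: sex/status categories of the two singers.
CATEGORY_FACTOR_LEVELS = (
    "WDF", "WDM", "WND",
    "BDF", "BDM", "BND",
    "B-DF-DM", "B-DF-ND", "B-DM-ND",
)

_CAT_SHORT = {"dominant_female": "DF", "dominant_male": "DM", "non_dominant": "ND"}


@dataclasses.dataclass(frozen=True)
class JaroResult:
    """Similarity plus the match/transposition counts it is built from."""

    similarity: float
    matches: int
    transpositions: float  # half-counts: 0, 0.5, 1, ...

    @property
    def distance(self) -> float:
        return 1.0 - self.similarity


def _as_symbols(seq: Sequence) -> tuple:
    if isinstance(seq, Contribution):
        return tuple(t.value for t in seq.tokens)
    return tuple(getattr(t, "value", t) for t in seq)


def _jaro_core(a: tuple, b: tuple) -> tuple[float, int, float]:
    la, lb = len(a), len(b)
    window = max(max(la, lb) // 2 - 1, 0)
    flagged_b = [False] * lb
    matched_a: list = []
    matched_b_idx: list[int] = []
    for i, ai in enumerate(a):
        lo = i - window if i - window > 0 else 0
        hi = i + window + 1
        if hi > lb:
            hi = lb
        for j in range(lo, hi):
            if not flagged_b[j] and b[j] == ai:
                flagged_b[j] = True
                matched_a.append(ai)
                matched_b_idx.append(j)
                break
    m = len(matched_a)
    if m == 0:
        return 0.0, 0, 0.0
    matched_b = [b[j] for j in sorted(matched_b_idx)]
    half_transpositions = sum(x != y for x, y in zip(matched_a, matched_b))
    t = half_transpositions / 2.0
    sim = (m / la + m / lb + (m - t) / m) / 3.0
    return sim, m, t


def jaro_similarity(
    a: Sequence | Contribution,
    b: Sequence | Contribution,
    winkler_prefix_weight: float = 0.0,
    max_prefix: int = 4,
) -> JaroResult:
    """Jaro similarity between two non-empty token sequences.

    Symmetric in its arguments; 1.0 iff the sequences are identical, 0.0 iff
    no token matches.  ``winkler_prefix_weight`` > 0 enables the
    Jaro-Winkler common-prefix boost (off by default: plain Jaro is the
    canonical statistic here).
    """
    sa, sb = _as_symbols(a), _as_symbols(b)
    if not sa or not sb:
        raise ValueError("jaro_similarity requires non-empty sequences")
    if not 0.0 <= winkler_prefix_weight <= 0.25:
        raise ValueError("winkler_prefix_weight must be in [0, 0.25]")
    sim, m, t = _jaro_core(sa, sb)
    if winkler_prefix_weight > 0.0 and sim > 0.0:
        ell = 0
        for x, y in zip(sa[:max_prefix], sb[:max_prefix]):
            if x != y:
                break
            ell += 1
        sim = sim + ell * winkler_prefix_weight * (1.0 - sim)
    return JaroResult(similarity=sim, matches=m, transpositions=t)


def jaro_distance(a, b, **kwargs) -> float:
    """``1 - jaro_similarity``; 0 for identical sequences."""
    return 1.0 - jaro_similarity(a, b, **kwargs).similarity


def pairwise_jaro_matrix(
    contributions: Sequence[Contribution] | Sequence[Sequence],
    mode: str = "token",
) -> np.ndarray:
    """Dense symmetric matrix of pairwise Jaro similarities.

    ``mode="token"`` (canonical) treats each phrase type as one symbol;
    ``mode="character"`` compares the pipe-delimited text representations
    character by character (compatibility with generic string tooling).
    The diagonal is 1 (complete match).
    """
    if len(contributions) < 2:
        raise ValueError("need at least two contributions")
    if mode == "token":
        # encode as int tuples: cheap equality in the inner loop
        codebook: dict = {}
        seqs = []
        for c in contributions:
            syms = _as_symbols(c)
            seqs.append(tuple(codebook.setdefault(s, len(codebook)) for s in syms))
    elif mode == "character":
        seqs = [
            tuple("|".join(_as_symbols(c)))
            for c in contributions
        ]
    else:
        raise ValueError("mode must be 'token' or 'character'")

    n = len(seqs)
    M = np.ones((n, n), dtype=float)
    for i in range(n):
        si = seqs[i]
        row = M[i]
        for j in range(i + 1, n):
            if si == seqs[j]:
                continue  # row initialized to 1
            sim, _, _ = _jaro_core(si, seqs[j])
            row[j] = sim
            M[j, i] = sim
    return M


def _factor_level(sa: SingerMeta, sb: SingerMeta) -> tuple[str, str]:
    ca, cb = _CAT_SHORT[sa.category], _CAT_SHORT[sb.category]
    if sa.singer_id == sb.singer_id:
        return "within", f"W{ca}"
    if ca == cb:
        return "between", f"B{ca}"
    first, second = sorted((ca, cb), key=("DF", "DM", "ND").index)
    return "between", f"B-{first}-{second}"


def build_dyad_dataset(
    matrix: np.ndarray,
    contributions: Sequence[Contribution],
    singers: dict[str, SingerMeta] | Corpus,
) -> pd.DataFrame:
    """Unfold the pairwise matrix into one row per unordered contribution pair.

    Each of the ``n(n-1)/2`` upper-triangle entries becomes a record holding
    the dyad (unordered singer pair), the distance type (``within`` when both
    contributions come from the same individual, else ``between``), the
    nine-level category factor, the Jaro value ``jd`` and its square root
    ``jd_sqrt`` (the mixed model's response).
    """
    if isinstance(singers, Corpus):
        singers = singers.singers
    n = len(contributions)
    if matrix.shape != (n, n):
        raise ValueError("matrix dimension must equal the number of contributions")
    for c in contributions:
        if c.singer_id not in singers:
            raise KeyError(f"missing singer metadata for {c.singer_id!r}")

    iu, ju = np.triu_indices(n, k=1)
    jd = matrix[iu, ju]
    sid = [c.singer_id for c in contributions]
    meta = {s: singers[s] for s in set(sid)}

    dyad_ids, dist_types, factors, a_list, b_list = [], [], [], [], []
    for i, j in zip(iu, ju):
        sa, sb = meta[sid[i]], meta[sid[j]]
        dtype, level = _factor_level(sa, sb)
        pair = tuple(sorted((sa.singer_id, sb.singer_id)))
        dyad_ids.append("--".join(pair))
        dist_types.append(dtype)
        factors.append(level)
        a_list.append(sid[i])
        b_list.append(sid[j])

    return pd.DataFrame(
        {
            "dyad_id": dyad_ids,
            "singer_a": a_list,
            "singer_b": b_list,
            # contribution indices of the pair: lets the mixed model place a
            # random effect on each contribution (records sharing one are
            # correlated)
            "idx_a": iu,
            "idx_b": ju,
            "distance_type": pd.Categorical(dist_types,
                                            categories=["within", "between"]),
            "category_factor": pd.Categorical(factors,
                                              categories=CATEGORY_FACTOR_LEVELS),
            "jd": jd,
            "jd_sqrt": np.sqrt(jd),
        }
    )
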