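"""Normalized diversity of song contributions and duet covariation.

The normalized diversity (ND) of a contribution is the number of distinct
phrase types it contains divided by its length in tokens: for
``DP2|DP3|DP3|DP5|DP4`` the 4 distinct types over 5 tokens give ND = 0.8.
ND ranges over (0, 1]; it is 1 iff all tokens are distinct and 1/length iff
all tokens are identical.  Because the alphabet has only six types, richness
saturates at 6 and ND is bounded above by 6/length for long contributions —
a combinatorial ceiling inherent to the statistic.

Unlike the Jaro analysis, ND is order-free: permuting the tokens of a
contribution does not change it.  The two statistics therefore capture
different facets of flexibility (composition vs. concatenation).

Duet covariation: within each group, the per-song NDs of the dominant female
and dominant male are paired over the songs in which both sang, and their
rank correlation (Spearman) measures whether the pair modulates diversity
together.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Contribution, Corpus

__all__ = [
    "DiversityRecord",
    "normalized_diversity",
    "diversity_table",
    "pair_duet_diversities",
    "group_covariation",
]

#: Minimum shared songs for a per-group correlation test.
MIN_PAIRS_FOR_TEST = 3


@dataclasses.dataclass(frozen=True)
class DiversityRecord:
    song_id: str
    singer_id: str
    category: str
    richness: int
    length: int
    value: float

    @property
    def log_value(self) -> float:
        return math.log(self.value)


def normalized_diversity(tokens: Sequence | Contribution) -> DiversityRecord:
    """Richness / length of one token sequence.

    Returns a :class:`DiversityRecord`; for bare sequences the identifier and
    category fields are empty strings.
    """
    if isinstance(tokens, Contribution):
        song_id, singer_id, seq = tokens.song_id, tokens.singer_id, tokens.tokens
    else:
        song_id, singer_id, seq = "", "", tuple(tokens)
    if len(seq) == 0:
        raise ValueError("normalized_diversity requires a non-empty sequence")
    richness = len(set(seq))
    length = len(seq)
    return DiversityRecord(
        song_id=song_id,
        singer_id=singer_id,
        category="",
        richness=richness,
        length=length,
        value=richness / length,
    )


def diversity_table(corpus: Corpus) -> pd.DataFrame:
    """One row per contribution: richness, length, ND and log ND.

    The natural-log column ``log_nd`` is the response the diversity mixed
    model uses (the log base is immaterial to inference).
    """
    rows = []
    for c in corpus.contributions:
        rec = normalized_diversity(c.tokens)
        meta = corpus.singers[c.singer_id]
        rows.append(
            {
                "song_id": c.song_id,
                "singer_id": c.singer_id,
                "category": meta.category,
                "group_id": meta.group_id,
                "richness": rec.richness,
                "length": rec.length,
                "nd": rec.value,
                "log_nd": math.log(rec.value),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["song_id", "singer_id", "category", "group_id",
                 "richness", "length", "nd", "log_nd"],
    )


def pair_duet_diversities(table: pd.DataFrame, group_id: str) -> pd.DataFrame:
    """Pair per-song NDs of a group's dominant female and male.

    Only songs in which *both* dominants contributed are paired (songs with
    additional non-dominant singers still count: duets may be part of
    choruses).  Rows are ordered by ``song_id`` for stability.  Raises if the
    group lacks a dominant of either sex.
    """
    g = table[table["group_id"] == group_id]
    f = g[g["category"] == "dominant_female"]
    m = g[g["category"] == "dominant_male"]
    if f.empty or m.empty:
        raise ValueError(
            f"group {group_id!r} lacks a dominant "
            f"{'female' if f.empty else 'male'} contribution"
        )
    merged = pd.merge(
        f[["song_id", "nd"]].rename(columns={"nd": "nd_female"}),
        m[["song_id", "nd"]].rename(columns={"nd": "nd_male"}),
        on="song_id",
        how="inner",
    ).sort_values("song_id", kind="mergesort", ignore_index=True)
    merged.insert(0, "group_id", group_id)
    return merged


@dataclasses.dataclass(frozen=True)
class CovariationResult:
    group_id: str
    n_paired_songs: int
    rho: float  # NaN when untested
    p_value: float  # NaN when untested
    tested: bool


def group_covariation(
    table: pd.DataFrame,
    min_pairs: int = MIN_PAIRS_FOR_TEST,
) -> pd.DataFrame:
    """Per-group Spearman correlation of paired duet diversities.

    Groups with fewer than ``min_pairs`` shared songs are reported untested
    (``rho`` and ``p_value`` NaN, ``tested`` False) rather than dropped.
    Ties are handled by midranks (scipy's Spearman).
    """
    out = []
    for gid in sorted(table["group_id"].unique()):
        sub = table[table["group_id"] == gid]
        cats = set(sub["category"])
        if not {"dominant_female", "dominant_male"} <= cats:
            continue
        pairs = pair_duet_diversities(table, gid)
        n = len(pairs)
        if n >= min_pairs:
            rho, p = stats.spearmanr(pairs["nd_female"], pairs["nd_male"])
            out.append(CovariationResult(gid, n, float(rho), float(p), True))
        else:
            out.append(CovariationResult(gid, n, float("nan"), float("nan"), False))
    return pd.DataFrame([dataclasses.asdict(r) for r in out])
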