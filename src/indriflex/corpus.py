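"""Domain model for indri song corpora.

An indri song is produced jointly by the members of a family group; the slice
of a song emitted by one individual is a *contribution*.  Each contribution is
encoded as an ordered sequence of phrase-type tokens over a closed six-symbol
alphabet: the single unit ``SU`` and the descending phrases ``DP2``-``DP6``
(phrases of 2-6 adjacent notes with descending frequency).  Other annotation
labels that occur in field transcriptions (e.g. long notes, ``LN``) are not
part of the analysis alphabet and are filtered out before any statistic is
computed.

This module defines the in-memory containers (:class:`SingerMeta`,
:class:`Contribution`, :class:`Corpus`) and the readers/writers for the two
ingest formats: Praat TextGrid annotation files (one interval tier per singer)
and a flat CSV of pre-encoded strings such as ``SU|DP3|DP2|DP3``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PhraseToken",
    "ANALYSIS_ALPHABET",
    "SingerMeta",
    "Contribution",
    "Corpus",
    "CorpusError",
    "parse_contribution_string",
    "filter_to_analysis_alphabet",
    "read_corpus_csv",
    "write_corpus_csv",
    "read_textgrid_corpus",
    "read_textgrid",
]


class CorpusError(ValueError):
    """Raised for malformed corpora, labels, or ingest files."""


class PhraseToken(str, enum.Enum):
    """One symbol of the six-letter phrase alphabet."""

    SU = "SU"
    DP2 = "DP2"
    DP3 = "DP3"
    DP4 = "DP4"
    DP5 = "DP5"
    DP6 = "DP6"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The closed analysis alphabet, in canonical order.
ANALYSIS_ALPHABET: tuple[PhraseToken, ...] = tuple(PhraseToken)

_VALID_LABELS = {t.value for t in PhraseToken}

SEXES = ("female", "male", "unrecorded")
STATUSES = ("dominant", "non_dominant")

#: Analysis categories: dominant singers keep their sex, non-dominants are
#: pooled regardless of sex (their sex is typically unrecorded in the field).
CATEGORIES = ("dominant_female", "dominant_male", "non_dominant")


@dataclasses.dataclass(frozen=True)
class SingerMeta:
    """Identity, sex, status and group membership of one singer.

    ``sex`` may be ``"unrecorded"`` only for non-dominants: the analysis pools
    non-dominant males and females into a single category, so their sex is
    never used.
    """

    singer_id: str
    sex: str
    status: str
    group_id: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CorpusError(f"invalid sex {self.sex!r} for singer {self.singer_id!r}")
        if self.status not in STATUSES:
            raise CorpusError(
                f"invalid status {self.status!r} for singer {self.singer_id!r}"
            )
        if self.sex == "unrecorded" and self.status != "non_dominant":
            raise CorpusError(
                f"singer {self.singer_id!r}: sex may be unrecorded only for "
                "non-dominants"
            )

    @property
    def category(self) -> str:
        """Analysis category: dominant_female, dominant_male or non_dominant."""
        if self.status == "non_dominant":
            return "non_dominant"
        return f"dominant_{self.sex}"


@dataclasses.dataclass(frozen=True)
class Contribution:
    """One singer's tokenized output within one song."""

    song_id: str
    singer_id: str
    tokens: tuple[PhraseToken, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise CorpusError(
                f"contribution ({self.song_id}, {self.singer_id}) has no tokens"
            )

    def as_string(self, delimiter: str = "|") -> str:
        return delimiter.join(t.value for t in self.tokens)


def parse_contribution_string(
    raw: str,
    delimiter: str = "|",
    on_unknown: str = "raise",
) -> tuple[PhraseToken, ...]:
    """Parse a delimited phrase string (e.g. ``"SU|DP3|DP2|DP3"``) into tokens.

    Parameters
    ----------
    raw
        Delimited text; must be non-empty after trimming.
    delimiter
        Single-character field separator.
    on_unknown
        ``"raise"`` (default) fails on any label outside the analysis
        alphabet, naming the label and its 1-based position; ``"drop"``
        silently removes such labels.
    """
    if on_unknown not in ("raise", "drop"):
        raise ValueError("on_unknown must be 'raise' or 'drop'")
    raw = raw.strip()
    if not raw:
        raise CorpusError("empty contribution string")
    tokens: list[PhraseToken] = []
    for pos, label in enumerate(raw.split(delimiter), start=1):
        label = label.strip()
        if label in _VALID_LABELS:
            tokens.append(PhraseToken(label))
        elif on_unknown == "raise":
            raise CorpusError(
                f"unknown phrase label {label!r} at position {pos} in {raw!r}"
            )
    return tuple(tokens)


def filter_to_analysis_alphabet(
    contribution: Contribution | Sequence[str | PhraseToken],
) -> Contribution | tuple[PhraseToken, ...] | None:
    """Drop every token outside the six-symbol analysis alphabet.

    Accepts either a :class:`Contribution` or a bare sequence of labels.
    Returns the filtered object, or ``None`` when nothing survives -- an
    empty result marks the contribution as excluded from analysis rather
    than raising.
    """
    if isinstance(contribution, Contribution):
        kept = tuple(t for t in contribution.tokens if t.value in _VALID_LABELS)
        if not kept:
            return None
        return Contribution(contribution.song_id, contribution.singer_id, kept)
    kept = tuple(
        PhraseToken(str(t)) for t in contribution if str(t) in _VALID_LABELS
    )
    return kept or None


@dataclasses.dataclass
class Corpus:
    """A collection of singers and their song contributions.

    Invariants (checked by :meth:`validate`, called on construction): every
    contribution's singer resolves to a :class:`SingerMeta`; each
    ``(song_id, singer_id)`` pair appears at most once; singer ids are unique.
    """

    singers: dict[str, SingerMeta]
    contributions: list[Contribution]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for c in self.contributions:
            if c.singer_id not in self.singers:
                raise CorpusError(
                    f"contribution ({c.song_id}, {c.singer_id}) references an "
                    "unknown singer"
                )
            key = (c.song_id, c.singer_id)
            if key in seen:
                raise CorpusError(f"duplicate (song_id, singer_id) pair {key}")
            seen.add(key)

    # -- convenience ------------------------------------------------------

    @property
    def song_ids(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for c in self.contributions:
            if c.song_id not in seen:
                seen.add(c.song_id)
                out.append(c.song_id)
        return out

    def contributions_of(self, singer_id: str) -> list[Contribution]:
        return [c for c in self.contributions if c.singer_id == singer_id]

    def category_of(self, singer_id: str) -> str:
        return self.singers[singer_id].category

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.contributions:
            s = self.singers[c.singer_id]
            rows.append(
                {
                    "song_id": c.song_id,
                    "singer_id": c.singer_id,
                    "sex": s.sex,
                    "status": s.status,
                    "group_id": s.group_id,
                    "tokens": c.as_string(),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["song_id", "singer_id", "sex", "status", "group_id", "tokens"],
        )

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "singers": [dataclasses.asdict(s) for s in self.singers.values()],
            "contributions": [
                {
                    "song_id": c.song_id,
                    "singer_id": c.singer_id,
                    "tokens": c.as_string(),
                }
                for c in self.contributions
            ],
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# CSV ingest / export
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["song_id", "singer_id", "sex", "status", "group_id", "tokens"]


def write_corpus_csv(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as a flat CSV (one row per contribution)."""
    path = Path(path)
    corpus.to_frame().to_csv(path, index=False)
    return path


def read_corpus_csv(path: str | Path, on_unknown: str = "raise") -> Corpus:
    """Read a corpus CSV written by :func:`write_corpus_csv`.

    Required columns: song_id, singer_id, sex, status, group_id, tokens
    (pipe-delimited).  Round-trips losslessly with :func:`write_corpus_csv`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusError(f"{path}: missing required column(s) {missing}")
    singers: dict[str, SingerMeta] = {}
    contributions: list[Contribution] = []
    for row in df.itertuples(index=False):
        meta = SingerMeta(
            singer_id=row.singer_id,
            sex=row.sex,
            status=row.status,
            group_id=row.group_id,
        )
        prior = singers.get(meta.singer_id)
        if prior is not None and prior != meta:
            raise CorpusError(
                f"{path}: inconsistent metadata for singer {meta.singer_id!r}"
            )
        singers[meta.singer_id] = meta
        contributions.append(
            Contribution(
                song_id=row.song_id,
                singer_id=row.singer_id,
                tokens=parse_contribution_string(row.tokens, on_unknown=on_unknown),
            )
        )
    return Corpus(singers=singers, contributions=contributions, provenance=str(path))


# ---------------------------------------------------------------------------
# Praat TextGrid ingest
# ---------------------------------------------------------------------------
# Praat writes two text dialects.  The "long" form spells out
#   intervals [1]:
#       xmin = 0
#       xmax = 1.5
#       text = "SU"
# while the "short" form lists bare values line by line.  Both are handled by
# scanning tier by tier; only IntervalTier items are read.  Files may be UTF-8
# or UTF-16 (Praat's default on some platforms).


@dataclasses.dataclass(frozen=True)
class TextGridInterval:
    xmin: float
    xmax: float
    text: str


@dataclasses.dataclass(frozen=True)
class TextGridTier:
    name: str
    intervals: tuple[TextGridInterval, ...]


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    if data.startswith(b"\xff\xfe") or data.startswith(b"\xfe\xff"):
        return data.decode("utf-16")
    return data.decode("utf-8")


_QUOTED = re.compile(r'"((?:[^"]|"")*)"')


def _unquote(s: str) -> str:
    return s.replace('""', '"')


def read_textgrid(path: str | Path) -> list[TextGridTier]:
    """Parse a Praat TextGrid (long or short dialect) into interval tiers."""
    path = Path(path)
    text = _read_text(path)
    lines = text.splitlines()
    if not any("TextGrid" in ln for ln in lines[:5]):
        raise CorpusError(f"{path}: not a Praat TextGrid (missing header)")

    # Tokenize into a flat stream of values: quoted strings and bare numbers /
    # keywords.  This treats long and short dialects uniformly, because the
    # long dialect's "key = value" lines reduce to the same value stream.
    stream: list[str] = []
    for lineno, ln in enumerate(lines, start=1):
        ln = ln.strip()
        if not ln:
            continue
        if "=" in ln and not ln.startswith('"'):
            ln = ln.split("=", 1)[1].strip()
        m = _QUOTED.fullmatch(ln)
        if m:
            stream.append('"' + m.group(1) + '"')
            continue
        # bare token (number, size line, or structural noise such as
        # "item [1]:" / "intervals [3]:" which carries no value)
        if re.fullmatch(r"[-+0-9.eE]+", ln):
            stream.append(ln)

    # Walk the stream: after the file header (xmin, xmax, <exists>, size) each
    # tier starts with its class string.
    tiers: list[TextGridTier] = []
    i = 0
    n = len(stream)

    def next_quoted(j: int) -> tuple[str, int]:
        while j < n and not stream[j].startswith('"'):
            j += 1
        if j >= n:
            raise CorpusError(f"{path}: truncated TextGrid")
        return _unquote(stream[j][1:-1]), j + 1

    while i < n:
        if not stream[i].startswith('"'):
            i += 1
            continue
        cls = _unquote(stream[i][1:-1])
        if cls not in ("IntervalTier", "TextTier"):
            i += 1
            continue
        name, i = next_quoted(i + 1)
        try:
            # tier xmin, xmax, count
            xmin = float(stream[i]); xmax = float(stream[i + 1])
            count = int(float(stream[i + 2]))
            i += 3
        except (IndexError, ValueError) as exc:
            raise CorpusError(
                f"{path}: malformed tier header for {name!r}"
            ) from exc
        intervals: list[TextGridInterval] = []
        if cls == "IntervalTier":
            for _ in range(count):
                try:
                    a = float(stream[i]); b = float(stream[i + 1])
                except (IndexError, ValueError) as exc:
                    raise CorpusError(
                        f"{path}: malformed interval in tier {name!r}"
                    ) from exc
                label, i2 = next_quoted(i + 2)
                i = i2
                intervals.append(TextGridInterval(a, b, label))
            tiers.append(TextGridTier(name=name, intervals=tuple(intervals)))
        else:  # TextTier (points): skip count point entries
            for _ in range(count):
                _ = float(stream[i])
                _, i = next_quoted(i + 1)
    return tiers


def read_textgrid_corpus(
    path: str | Path,
    tier_map: Mapping[str, str],
    singers: Mapping[str, SingerMeta],
    song_id: str | None = None,
    on_unknown: str = "drop",
) -> Corpus:
    """Build a corpus from one annotated TextGrid.

    ``tier_map`` maps tier names to singer ids; unmapped tiers are skipped.
    Interval labels are parsed as phrase tokens in time order; empty labels
    (silences) are skipped.  ``song_id`` defaults to the file stem.  Labels
    outside the analysis alphabet are dropped by default (field annotations
    include long notes and other units the analysis excludes).
    """
    path = Path(path)
    if song_id is None:
        song_id = path.stem
    tiers = read_textgrid(path)
    tier_names = {t.name for t in tiers}
    for tname in tier_map:
        if tname not in tier_names:
            raise CorpusError(f"{path}: mapped tier {tname!r} not found")
    contributions: list[Contribution] = []
    used: dict[str, SingerMeta] = {}
    for tier in tiers:
        if tier.name not in tier_map:
            continue
        singer_id = tier_map[tier.name]
        if singer_id not in singers:
            raise CorpusError(f"no SingerMeta provided for singer {singer_id!r}")
        labels = [
            iv.text.strip()
            for iv in sorted(tier.intervals, key=lambda iv: iv.xmin)
            if iv.text.strip()
        ]
        if not labels:
            continue
        tokens: list[PhraseToken] = []
        for pos, label in enumerate(labels, start=1):
            if label in _VALID_LABELS:
                tokens.append(PhraseToken(label))
            elif on_unknown == "raise":
                raise CorpusError(
                    f"{path}, tier {tier.name!r}: unknown label {label!r} at "
                    f"interval {pos}"
                )
        if not tokens:
            continue
        used[singer_id] = singers[singer_id]
        contributions.append(
            Contribution(song_id=song_id, singer_id=singer_id, tokens=tuple(tokens))
        )
    return Corpus(singers=dict(used), contributions=contributions,
                  provenance=str(path))


def merge_corpora(corpora: Iterable[Corpus], provenance: str = "merged") -> Corpus:
    """Merge corpora (e.g. one per TextGrid file) into one.

    Singer metadata must agree across inputs.
    """
    singers: dict[str, SingerMeta] = {}
    contributions: list[Contribution] = []
    for c in corpora:
        for sid, meta in c.singers.items():
            if sid in singers and singers[sid] != meta:
                raise CorpusError(f"conflicting metadata for singer {sid!r}")
            singers[sid] = meta
        contributions.extend(c.contributions)
    return Corpus(singers=singers, contributions=contributions,
                  provenance=provenance)
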