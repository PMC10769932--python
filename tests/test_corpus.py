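import pytest

import indriflex as ix
from indriflex.corpus import merge_corpora


class TestParseContributionString:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("SU|DP3|DP2|DP3", ("SU", "DP3", "DP2", "DP3")),
            ("SU", ("SU",)),
            (" DP2 | DP6 ", ("DP2", "DP6")),
        ],
    )
    def test_valid_strings(self, raw, expected):
        tokens = ix.parse_contribution_string(raw)
        assert tuple(t.value for t in tokens) == expected

    def test_unknown_label_strict_names_position(self):
        with pytest.raises(ix.CorpusError, match="'LN' at position 2"):
            ix.parse_contribution_string("SU|LN")

    def test_unknown_label_drop_policy(self):
        tokens = ix.parse_contribution_string("SU|LN|DP2", on_unknown="drop")
        assert tuple(t.value for t in tokens) == ("SU", "DP2")

    def test_empty_input_rejected(self):
        with pytest.raises(ix.CorpusError):
            ix.parse_contribution_string("   ")


class TestFilterToAnalysisAlphabet:
    def test_clean_sequence_unchanged(self):
        toks = ix.parse_contribution_string("SU|DP3")
        assert ix.filter_to_analysis_alphabet(toks) == toks

    def test_out_of_alphabet_tokens_removed(self):
        kept = ix.filter_to_analysis_alphabet(["SU", "LN", "DP3"])
        assert tuple(t.value for t in kept) == ("SU", "DP3")

    def test_all_out_of_alphabet_flags_exclusion(self):
        assert ix.filter_to_analysis_alphabet(["LN", "LN"]) is None


class TestDomainInvariants:
    def test_six_admissible_tokens(self):
        assert {t.value for t in ix.ANALYSIS_ALPHABET} == {
            "SU", "DP2", "DP3", "DP4", "DP5", "DP6"
        }

    def test_unrecorded_sex_requires_non_dominant(self):
        with pytest.raises(ix.CorpusError):
            ix.SingerMeta("x", "unrecorded", "dominant", "g")

    def test_category_labels(self):
        assert ix.SingerMeta("a", "female", "dominant", "g").category == "dominant_female"
        assert ix.SingerMeta("b", "unrecorded", "non_dominant", "g").category == "non_dominant"

    def test_empty_contribution_rejected(self):
        with pytest.raises(ix.CorpusError):
            ix.Contribution("s", "x", ())

    def test_unresolved_singer_rejected(self):
        toks = ix.parse_contribution_string("SU")
        with pytest.raises(ix.CorpusError, match="unknown singer"):
            ix.Corpus(singers={}, contributions=[ix.Contribution("s", "x", toks)])

    def test_duplicate_song_singer_pair_rejected(self, handmade_corpus):
        dup = handmade_corpus.contributions[0]
        with pytest.raises(ix.CorpusError, match="duplicate"):
            ix.Corpus(
                singers=handmade_corpus.singers,
                contributions=list(handmade_corpus.contributions) + [dup],
            )


class TestCsvRoundTrip:
    def test_round_trip_handmade(self, handmade_corpus, tmp_path):
        p = tmp_path / "corpus.csv"
        ix.write_corpus_csv(handmade_corpus, p)
        back = ix.read_corpus_csv(p)
        assert back.to_frame().equals(handmade_corpus.to_frame())

    def test_round_trip_synthetic(self, small_corpus, tmp_path):
        p = tmp_path / "corpus.csv"
        ix.write_corpus_csv(small_corpus, p)
        back = ix.read_corpus_csv(p)
        assert back.to_frame().equals(small_corpus.to_frame())

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("song_id,singer_id,tokens\ns1,a,SU\n")
        with pytest.raises(ix.CorpusError, match="missing required column"):
            ix.read_corpus_csv(p)

    def test_json_export_contains_everything(self, handmade_corpus):
        import json

        payload = json.loads(handmade_corpus.to_json())
        assert len(payload["singers"]) == 3
        assert payload["contributions"][0]["tokens"] == "SU|DP3|DP2|DP3"


LONG_TEXTGRID = '''File type = "ooTextFile"
Object class = "TextGrid"

xmin = 0
xmax = 10
tiers? <exists>
size = 2
item []:
    item [1]:
        class = "IntervalTier"
        name = "female"
        xmin = 0
        xmax = 10
        intervals: size = 4
        intervals [1]:
            xmin = 0
            xmax = 2
            text = "SU"
        intervals [2]:
            xmin = 2
            xmax = 3
            text = ""
        intervals [3]:
            xmin = 3
            xmax = 5
            text = "DP2"
        intervals [4]:
            xmin = 5
            xmax = 10
            text = "LN"
    item [2]:
        class = "IntervalTier"
        name = "male"
        xmin = 0
        xmax = 10
        intervals: size = 2
        intervals [1]:
            xmin = 0
            xmax = 4
            text = "DP3"
        intervals [2]:
            xmin = 4
            xmax = 10
            text = "DP4"
'''

SHORT_TEXTGRID = '''File type = "ooTextFile"
Object class = "TextGrid"

0
10
<exists>
1
"IntervalTier"
"female"
0
10
3
0
2
"SU"
2
3
""
3
10
"DP2"
'''


@pytest.fixture
def singers():
    return {
        "f1": ix.SingerMeta("f1", "female", "dominant", "g1"),
        "m1": ix.SingerMeta("m1", "male", "dominant", "g1"),
    }


class TestTextGridIngest:
    def test_long_dialect_two_tiers(self, tmp_path, singers):
        p = tmp_path / "song1.TextGrid"
        p.write_text(LONG_TEXTGRID)
        corpus = ix.read_textgrid_corpus(p, {"female": "f1", "male": "m1"}, singers)
        by_singer = {c.singer_id: c for c in corpus.contributions}
        assert by_singer["f1"].as_string() == "SU|DP2"  # silence + LN dropped
        assert by_singer["m1"].as_string() == "DP3|DP4"
        assert all(c.song_id == "song1" for c in corpus.contributions)

    def test_short_dialect(self, tmp_path, singers):
        p = tmp_path / "song2.TextGrid"
        p.write_text(SHORT_TEXTGRID)
        corpus = ix.read_textgrid_corpus(p, {"female": "f1"}, singers)
        assert corpus.contributions[0].as_string() == "SU|DP2"

    def test_utf16_tolerated(self, tmp_path, singers):
        p = tmp_path / "song3.TextGrid"
        p.write_bytes(LONG_TEXTGRID.encode("utf-16"))
        corpus = ix.read_textgrid_corpus(p, {"female": "f1"}, singers)
        assert corpus.contributions[0].as_string() == "SU|DP2"

    def test_unmapped_tier_skipped(self, tmp_path, singers):
        p = tmp_path / "song4.TextGrid"
        p.write_text(LONG_TEXTGRID)
        corpus = ix.read_textgrid_corpus(p, {"female": "f1"}, singers)
        assert {c.singer_id for c in corpus.contributions} == {"f1"}

    def test_missing_mapped_tier_is_error(self, tmp_path, singers):
        p = tmp_path / "song5.TextGrid"
        p.write_text(LONG_TEXTGRID)
        with pytest.raises(ix.CorpusError, match="'chorus' not found"):
            ix.read_textgrid_corpus(p, {"chorus": "f1"}, singers)

    def test_malformed_file_is_parse_error(self, tmp_path, singers):
        p = tmp_path / "bad.TextGrid"
        p.write_text("not a textgrid at all\n")
        with pytest.raises(ix.CorpusError):
            ix.read_textgrid_corpus(p, {}, singers)

    def test_textgrid_and_csv_agree(self, tmp_path, singers):
        """The same annotated content yields identical token sequences."""
        p = tmp_path / "songX.TextGrid"
        p.write_text(LONG_TEXTGRID)
        tg = ix.read_textgrid_corpus(p, {"female": "f1", "male": "m1"}, singers)
        csv_path = tmp_path / "songX.csv"
        ix.write_corpus_csv(tg, csv_path)
        back = ix.read_corpus_csv(csv_path)
        assert [c.as_string() for c in back.contributions] == [
            c.as_string() for c in tg.contributions
        ]

    def test_merge_corpora(self, tmp_path, singers):
        p1, p2 = tmp_path / "a.TextGrid", tmp_path / "b.TextGrid"
        p1.write_text(LONG_TEXTGRID)
        p2.write_text(SHORT_TEXTGRID)
        c1 = ix.read_textgrid_corpus(p1, {"female": "f1", "male": "m1"}, singers)
        c2 = ix.read_textgrid_corpus(p2, {"female": "f1"}, singers)
        merged = merge_corpora([c1, c2])
        assert len(merged.contributions) == 3
        assert {c.song_id for c in merged.contributions} == {"a", "b"}
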