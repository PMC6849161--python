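"""Lexicon loading and entity matching, incl. brute-force oracle equivalence."""

import random

import pytest

from neurolabel import (
    ModifierType,
    ObservationType,
    load_lexicons,
    match_entities,
    pos_tag,
    read_report,
    tokenize,
    zone,
)
from neurolabel.linguistic import lemmatise
from neurolabel.ner import LexiconError, parse_lexicon


@pytest.fixture(scope="module")
def lexicons():
    return load_lexicons()


def _prepared(text):
    doc = tokenize(zone(read_report(text)))
    pos_tag(doc)
    lemmatise(doc)
    return doc


class TestLexiconLoading:
    def test_multiword_atrophy_entry(self):
        entries = parse_lexicon(["inter-cerebral volume loss\tatrophy"])
        (entry,) = entries
        assert entry.etype is ObservationType.ATROPHY
        assert entry.tokens == ("inter-cerebral", "volume", "loss")

    def test_time_old_modifier_entry(self):
        (entry,) = parse_lexicon(["established\ttime:old"])
        assert entry.etype is ModifierType.TIME_OLD

    def test_two_token_observation_entry(self):
        (entry,) = parse_lexicon(["lacunar event\tischaemic stroke"])
        assert entry.etype is ObservationType.ISCHAEMIC_STROKE
        assert len(entry.tokens) == 2

    def test_unknown_type_names_line(self):
        with pytest.raises(LexiconError, match="line 2"):
            parse_lexicon(["# comment", "thing\tnonsense type"])

    def test_category_mismatch_rejected(self):
        with pytest.raises(LexiconError, match="not an observation"):
            parse_lexicon(["old\ttime:old"], category="observation")

    def test_entries_sorted_internally(self):
        a = parse_lexicon(["infarct\tischaemic stroke", "mass\ttumour"])
        b = parse_lexicon(["mass\ttumour", "infarct\tischaemic stroke"])
        assert a == b

    def test_shipped_lexicons_cover_quoted_vocabulary(self, lexicons):
        obs, mods = lexicons
        obs_surfaces = {e.tokens for e in obs}
        assert ("lacunar", "event") in obs_surfaces
        assert ("inter-cerebral", "volume", "loss") in obs_surfaces
        mod_surfaces = {(e.tokens, e.etype) for e in mods}
        for word in ("old", "previous", "established"):
            assert ((word,), ModifierType.TIME_OLD) in mod_surfaces


class TestMatching:
    def test_nested_abbreviation_entities(self, lexicons):
        doc = _prepared("Previous POCI.")
        match_entities(doc, *lexicons)
        poci = [e for e in doc.entities if doc.text_of(e) == "POCI"]
        assert len(poci) == 2
        obs = next(e for e in poci if e.is_observation)
        mod = next(e for e in poci if not e.is_observation)
        assert obs.etype is ObservationType.ISCHAEMIC_STROKE
        assert mod.etype is ModifierType.LOC_CORTICAL
        assert obs.nested_with == mod.entity_id
        assert mod.nested_with == obs.entity_id
        assert (obs.start, obs.end) == (mod.start, mod.end)

    def test_abbreviation_is_literal_not_lemma(self, lexicons):
        doc = _prepared("poci noted.")  # lowercase surface still matches
        match_entities(doc, *lexicons)
        assert any(e.etype is ObservationType.ISCHAEMIC_STROKE
                   for e in doc.entities)

    def test_fig_style_sentence(self, lexicons):
        doc = _prepared("old thalamic infarcts")
        match_entities(doc, *lexicons)
        types = {e.etype for e in doc.entities}
        assert types == {
            ModifierType.TIME_OLD,
            ModifierType.LOC_DEEP,
            ObservationType.ISCHAEMIC_STROKE,
        }

    def test_plural_matches_singular_entry(self, lexicons):
        doc = _prepared("several infarcts and masses")
        match_entities(doc, *lexicons)
        assert {e.etype for e in doc.entities} == {
            ObservationType.ISCHAEMIC_STROKE,
            ObservationType.TUMOUR,
        }

    def test_longest_match_wins(self, lexicons):
        doc = _prepared("subdural haematoma seen")
        match_entities(doc, *lexicons)
        (ent,) = doc.entities
        assert ent.etype is ObservationType.SUBDURAL_HAEMATOMA
        assert doc.text_of(ent) == "subdural haematoma"

    def test_partial_overlap_suppresses_modifier(self, lexicons):
        # "lacunar event" is an observation; the bare "lacunar" modifier
        # match inside it must be suppressed
        doc = _prepared("lacunar event noted")
        match_entities(doc, *lexicons)
        (ent,) = doc.entities
        assert ent.etype is ObservationType.ISCHAEMIC_STROKE

    def test_same_category_entities_never_overlap(self, lexicons):
        doc = _prepared(
            "old subarachnoid haemorrhage and small vessel disease with "
            "subdural haematoma"
        )
        match_entities(doc, *lexicons)
        for cat in (True, False):
            spans = sorted(
                (e.start, e.end) for e in doc.entities
                if e.is_observation is cat
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence
# ---------------------------------------------------------------------------


def _oracle_pass(sent, entries):
    """Independent longest-match selection: enumerate every entry against
    every token run, then pick greedily by (length desc, start asc)."""
    hits = []
    for entry in entries:
        k = len(entry.tokens)
        for start in range(len(sent.tokens) - k + 1):
            window = sent.tokens[start : start + k]
            ok = True
            for etok, tok in zip(entry.tokens, window):
                if entry.mode == "literal":
                    ok = tok.surface.lower() == etok
                else:
                    ok = etok in (tok.lemma, tok.surface.lower())
                if not ok:
                    break
            if ok:
                hits.append((start, start + k, entry))
    hits.sort(key=lambda h: (-(h[1] - h[0]), h[0], h[2].etype.value, h[2].mode))
    used = set()
    spans = set()
    picked = []
    for start, end, entry in hits:
        if used & set(range(start, end)) or (start, end) in spans:
            continue
        used |= set(range(start, end))
        spans.add((start, end))
        picked.append((sent.tokens[start].start, sent.tokens[end - 1].end,
                       entry.etype))
    return picked


def _oracle(doc, obs_entries, mod_entries):
    expected = []
    for sent in doc.sentences:
        obs = _oracle_pass(sent, obs_entries)
        obs_spans = {(s, e) for s, e, _ in obs}
        expected.extend(obs)
        for s, e, etype in _oracle_pass(sent, mod_entries):
            partial = any(os < e and s < oe and (os, oe) != (s, e)
                          for os, oe in obs_spans)
            if partial:
                continue
            expected.append((s, e, etype))
    return sorted(expected, key=lambda x: (x[0], x[1], x[2].value))


_FILLERS = ["the", "with", "and", "seen", "of", "normal", "scan", "shows",
            "in", "no", "region", ","]


def _random_sentence(rng, vocab):
    n = rng.randint(3, 12)
    return " ".join(rng.choice(vocab) for _ in range(n))


def test_matcher_equals_bruteforce_oracle_on_random_sentences(lexicons):
    """Greedy longest-match selection equals exhaustive enumeration on
    1000 random synthetic sentences built from lexicon fragments."""
    obs_entries, mod_entries = lexicons
    vocab = _FILLERS + [
        tok for e in obs_entries for tok in e.tokens
    ] + [tok for e in mod_entries for tok in e.tokens] + [
        "POCI", "infarcts", "masses", "old"
    ]
    rng = random.Random(20260926)
    for _ in range(1000):
        doc = _prepared(_random_sentence(rng, vocab))
        match_entities(doc, obs_entries, mod_entries)
        got = sorted(
            ((e.start, e.end, e.etype) for e in doc.entities),
            key=lambda x: (x[0], x[1], x[2].value),
        )
        assert got == _oracle(doc, obs_entries, mod_entries)
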