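"""Discourse transcript scoring: content word fluency (CWF) and correct
information units (CIU).

CWF is a transcription-less measure: one point every time the speaker
produces an item from a pre-specified checklist, in any inflected form
or via a listed synonym, counting re-use in later phrases but excluding
immediate repetitions and perseverations of the same item.  CIU counting
is annotation-driven: a token counts when it carries none of the
exclusion flags and is not an immediate repetition of the previous
unflagged token.  Relevance/accuracy judgments live in the flags (human
coding or the simulator); the counters themselves are deterministic.

Lemmatization is a deterministic rule table (irregular forms first, then
ordered suffix stripping) rather than a statistical tagger: every match
must be auditable.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Token",
    "Transcript",
    "ChecklistItem",
    "Checklist",
    "CWFResult",
    "normalize_token",
    "score_cwf",
    "count_cius",
    "word_count",
    "response_matrix",
    "read_transcript_tsv",
    "write_transcript_tsv",
    "read_chat_lite",
    "read_checklist",
    "write_checklist",
]

VALID_FLAGS = frozenset({"filler", "unintelligible", "off_topic", "inaccurate", "non_word"})
CIU_EXCLUDE_FLAGS = VALID_FLAGS  # any flag disqualifies a token as a CIU


@dataclass(frozen=True)
class Token:
    position: int
    surface: str
    flags: frozenset = frozenset()
    phrase_id: int = 0

    def __post_init__(self):
        bad = set(self.flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown token flags: {sorted(bad)}")
        object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class Transcript:
    participant_id: str
    tokens: tuple = ()

    def __post_init__(self):
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        toks = tuple(self.tokens)
        pos = [t.position for t in toks]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("token positions must be strictly increasing")
        object.__setattr__(self, "tokens", toks)


@dataclass(frozen=True)
class ChecklistItem:
    item_id: str
    lemma: str
    synonyms: frozenset = frozenset()
    word_class: str = "noun"  # "noun" | "verb"
    length_phonemes: int = 3
    frequency: float = 1.0
    imageability: float = 400.0

    def __post_init__(self):
        if self.word_class not in ("noun", "verb"):
            raise ValueError("word_class must be 'noun' or 'verb'")
        if self.length_phonemes < 1:
            raise ValueError("length_phonemes must be >= 1")
        syns = frozenset(self.synonyms)
        if self.lemma in syns:
            raise ValueError(f"lemma {self.lemma!r} listed among its own synonyms")
        object.__setattr__(self, "synonyms", syns)


@dataclass(frozen=True)
class Checklist:
    items: tuple
    stimulus_name: str = "synthetic"

    def __post_init__(self):
        items = tuple(self.items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        lemmas = [it.lemma for it in items]
        if len(set(lemmas)) != len(lemmas):
            raise ValueError("no two items may share a lemma")
        seen = set()
        for it in items:
            if it.synonyms & seen:
                raise ValueError("synonym sets must be pairwise disjoint across items")
            seen |= it.synonyms
        object.__setattr__(self, "items", items)

    def __len__(self):
        return len(self.items)


@dataclass(frozen=True)
class CWFResult:
    per_item_counts: dict
    total: int
    audit: tuple   # (position, item_id, match_kind in {lemma, inflected, synonym})
    excluded: tuple  # (position, reason in {immediate_repetition, perseveration})


# ---------------------------------------------------------------------------
# Normalization

# Irregular surface -> lemma. Consulted before any suffix rule.
IRREGULAR_FORMS = {
    "children": "child",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "dishes": "dish",
    "took": "take",
    "taken": "take",
    "takes": "take",
    "stole": "steal",
    "stolen": "steal",
    "fell": "fall",
    "fallen": "fall",
    "ran": "run",
    "running": "run",
    "gave": "give",
    "given": "give",
    "stood": "stand",
    "dried": "dry",
    "drying": "dry",
}

# Lemmas ending in -ie whose plural would otherwise trip the -ies rule
# ("cookies" must normalize to "cookie", not "cooky").
IE_LEMMAS = frozenset({"cookie", "pie", "movie", "tie", "auntie", "lassie"})

# Stems that lose a final e before -ing/-ed; restored after stripping.
E_RESTORE = {
    "tak": "take", "mak": "make", "giv": "give", "wobbl": "wobble",
    "stat": "state", "plac": "place", "wav": "wave", "clos": "close",
    "handl": "handle", "toppl": "topple", "rins": "rinse",
}

_PUNCT_RE = re.compile(r"^[^\w]+|[^\w]+$")
_VOWELS = set("aeiou")


def normalize_token(surface: str) -> str:
    """Map an inflected surface form to its lemma.

    Lower-cases, strips edge punctuation, then applies an irregular-form
    table followed by ordered suffix rules (-ies→-y, -es, -s, -ing, -ed,
    with e-restoration and consonant undoubling).  Returns the cleaned
    surface unchanged when no rule applies.
    """
    if not surface:
        raise ValueError("empty surface form")
    w = _PUNCT_RE.sub("", surface.lower())
    if not w:
        raise ValueError(f"surface {surface!r} contains no word characters")
    if w in IRREGULAR_FORMS:
        return IRREGULAR_FORMS[w]
    if w.endswith("s") and not w.endswith("ss") and w[:-1] in IE_LEMMAS:
        return w[:-1]
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("es") and len(w) > 4 and (w[-4:-2] in ("ch", "sh") or w[-3] in "sxz"):
        return w[:-2]
    if w.endswith("s") and not w.endswith("ss") and len(w) > 3:
        return w[:-1]
    for suffix in ("ing", "ed"):
        if w.endswith(suffix) and len(w) > len(suffix) + 2:
            stem = w[: -len(suffix)]
            if stem in E_RESTORE:
                return E_RESTORE[stem]
            if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS | {"l", "s"}:
                return stem[:-1]  # running -> run style undoubling
            return stem
    return w


def _match_index(checklist: Checklist) -> dict:
    """lemma/synonym (normalized) -> (item_id, is_synonym)."""
    index = {}
    for it in checklist.items:
        index[it.lemma] = (it.item_id, False)
        for syn in it.synonyms:
            index[normalize_token(syn)] = (it.item_id, True)
    return index


def score_cwf(transcript: Transcript, checklist: Checklist) -> CWFResult:
    """Score a transcript against a checklist.

    A token scores for an item when its normalized form equals the item's
    lemma or a listed synonym.  Exclusions: within one phrase, a second
    consecutive resolution to the same item (adjacency evaluated after
    skipping filler-flagged tokens only) is an immediate repetition, and
    a third or later one is a perseveration.  Re-use in a later phrase
    always counts.  Unintelligible tokens never match.
    """
    index = _match_index(checklist)
    counts = {it.item_id: 0 for it in checklist.items}
    audit, excluded = [], []
    run_item = None      # item of the current consecutive-resolution run
    run_len = 0
    run_phrase = None
    for tok in transcript.tokens:
        if "filler" in tok.flags:
            continue  # transparent for adjacency
        if tok.flags & {"unintelligible", "non_word"}:
            run_item, run_len = None, 0
            continue
        norm = normalize_token(tok.surface)
        hit = index.get(norm)
        if hit is None:
            run_item, run_len = None, 0
            continue
        item_id, is_syn = hit
        if item_id == run_item and tok.phrase_id == run_phrase:
            run_len += 1
            reason = "immediate_repetition" if run_len == 2 else "perseveration"
            excluded.append((tok.position, reason))
            continue
        run_item, run_len, run_phrase = item_id, 1, tok.phrase_id
        counts[item_id] += 1
        if is_syn:
            kind = "synonym"
        else:
            lemma = next(it.lemma for it in checklist.items if it.item_id == item_id)
            kind = "lemma" if _PUNCT_RE.sub("", tok.surface.lower()) == lemma else "inflected"
        audit.append((tok.position, item_id, kind))
    return CWFResult(per_item_counts=counts, total=sum(counts.values()),
                     audit=tuple(audit), excluded=tuple(excluded))


def count_cius(transcript: Transcript) -> int:
    """Count correct information units from annotation flags.

    A token counts when it carries no exclusion flag and is not an
    immediate repetition (same normalized form) of the preceding
    unflagged token, adjacency evaluated after removing flagged tokens.
    """
    n = 0
    prev_norm = None
    for tok in transcript.tokens:
        if tok.flags & CIU_EXCLUDE_FLAGS:
            continue
        norm = normalize_token(tok.surface)
        if norm != prev_norm:
            n += 1
        prev_norm = norm
    return n


def word_count(transcript: Transcript) -> int:
    """Number of word tokens: everything except unintelligible and
    non-word productions (fillers count as words)."""
    return sum(1 for t in transcript.tokens
               if not (t.flags & {"unintelligible", "non_word"}))


def response_matrix(results, checklist: Checklist, for_irt: bool = False):
    """Persons × items dichotomous production matrix.

    Entry (i, j) is 1 when person i produced item j at least once.  With
    ``for_irt`` set, all-0 and all-1 columns (which carry no information
    for item-response models) are dropped and reported on the returned
    matrix as ``dropped_items``.
    """
    from .irt import ItemResponseMatrix  # local import: irt does not import us

    results = list(results)
    if not results:
        raise ValueError("empty results")
    item_ids = [it.item_id for it in checklist.items]
    data = np.zeros((len(results), len(item_ids)), dtype=int)
    for i, res in enumerate(results):
        extra = set(res.per_item_counts) - set(item_ids)
        if extra:
            raise ValueError(f"result {i} scored against a different checklist: {sorted(extra)}")
        for j, iid in enumerate(item_ids):
            data[i, j] = 1 if res.per_item_counts.get(iid, 0) >= 1 else 0
    dropped = []
    if for_irt:
        keep = []
        for j, iid in enumerate(item_ids):
            s = data[:, j].sum()
            if s == 0 or s == len(results):
                dropped.append(iid)
            else:
                keep.append(j)
        data = data[:, keep]
        item_ids = [item_ids[j] for j in keep]
    persons = [f"p{i:04d}" for i in range(len(results))]
    return ItemResponseMatrix(persons=persons, items=item_ids, data=data,
                              dropped_items=tuple(dropped))


# ---------------------------------------------------------------------------
# I/O

def write_transcript_tsv(transcript: Transcript, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["position", "surface", "flags", "phrase_id"])
        for t in transcript.tokens:
            w.writerow([t.position, t.surface, ";".join(sorted(t.flags)), t.phrase_id])


def read_transcript_tsv(path, participant_id: str | None = None) -> Transcript:
    pid = participant_id or Path(path).stem
    tokens = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            flags = frozenset(f for f in row.get("flags", "").split(";") if f)
            tokens.append(Token(position=int(row["position"]), surface=row["surface"],
                                flags=flags, phrase_id=int(row.get("phrase_id", 0))))
    return Transcript(participant_id=pid, tokens=tuple(tokens))


_REP_RE = re.compile(r"\[x\s*(\d+)\]")


def read_chat_lite(path, participant_id: str | None = None) -> Transcript:
    """Parse a CHAT-lite transcript: one utterance per line; ``&-word`` is
    a filler, ``xxx`` is unintelligible, ``word [x N]`` expands to N
    productions of the word."""
    pid = participant_id or Path(path).stem
    tokens = []
    pos = 0
    with open(path) as fh:
        for phrase_id, line in enumerate(ln for ln in (l.strip() for l in fh) if ln):
            raw = line.split()
            i = 0
            while i < len(raw):
                word = raw[i]
                reps = 1
                if i + 2 < len(raw) and raw[i + 1] == "[x":
                    m = _REP_RE.match(raw[i + 1] + " " + raw[i + 2])
                    if m:
                        reps = int(m.group(1))
                        i += 2
                else:
                    m = _REP_RE.search(word)
                    if m:
                        reps = int(m.group(1))
                        word = _REP_RE.sub("", word).strip()
                flags = frozenset()
                if word.startswith("&-"):
                    flags = frozenset({"filler"})
                    word = word[2:]
                elif word == "xxx":
                    flags = frozenset({"unintelligible"})
                if word:
                    for _ in range(reps):
                        tokens.append(Token(position=pos, surface=word,
                                            flags=flags, phrase_id=phrase_id))
                        pos += 1
                i += 1
    return Transcript(participant_id=pid, tokens=tuple(tokens))


def write_checklist(checklist: Checklist, path) -> None:
    payload = {
        "stimulus_name": checklist.stimulus_name,
        "items": [
            {
                "item_id": it.item_id, "lemma": it.lemma,
                "synonyms": sorted(it.synonyms), "word_class": it.word_class,
                "length_phonemes": it.length_phonemes,
                "frequency": it.frequency, "imageability": it.imageability,
            }
            for it in checklist.items
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_checklist(path) -> Checklist:
    """Read a checklist from JSON ({stimulus_name, items:[...]}) or TSV
    (columns item_id, lemma, synonyms, word_class, length_phonemes,
    frequency, imageability; synonyms semicolon-separated)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        items = tuple(
            ChecklistItem(
                item_id=d["item_id"], lemma=d["lemma"],
                synonyms=frozenset(d.get("synonyms", ())),
                word_class=d.get("word_class", "noun"),
                length_phonemes=int(d.get("length_phonemes", 3)),
                frequency=float(d.get("frequency", 1.0)),
                imageability=float(d.get("imageability", 400.0)),
            )
            for d in payload["items"]
        )
        return Checklist(items=items, stimulus_name=payload.get("stimulus_name", path.stem))
    items = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            items.append(ChecklistItem(
                item_id=row["item_id"], lemma=row["lemma"],
                synonyms=frozenset(s for s in row.get("synonyms", "").split(";") if s),
                word_class=row.get("word_class", "noun"),
                length_phonemes=int(row.get("length_phonemes", 3)),
                frequency=float(row.get("frequency", 1.0)),
                imageability=float(row.get("imageability", 400.0)),
            ))
    return Checklist(items=tuple(items), stimulus_name=path.stem)
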