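"""Lightweight rule-based English lemmatizer.

Concepts in word networks are normalized forms ("take", not "took" or
"taking"), so inflected variants collapse onto one node.  The rules
here are a small irregular-form table plus conservative suffix
stripping; they are not a full morphological analyzer, but they are
deterministic, dependency-free and adequate for collapsing common
verb/noun inflections.
"""

from __future__ import annotations

# Common irregular verb and noun forms -> lemma.
_IRREGULAR: dict[str, str] = {
    "took": "take", "taken": "take", "takes": "take", "taking": "take",
    "went": "go", "gone": "go", "goes": "go", "going": "go",
    "said": "say", "says": "say", "saying": "say",
    "made": "make", "making": "make",
    "gave": "give", "given": "give", "giving": "give",
    "got": "get", "gotten": "get", "getting": "get",
    "knew": "know", "known": "know", "knowing": "know",
    "told": "tell", "telling": "tell",
    "thought": "think", "thinking": "think",
    "felt": "feel", "feeling": "feel",
    "left": "leave", "leaving": "leave",
    "found": "find", "finding": "find",
    "came": "come", "coming": "come",
    "saw": "see", "seen": "see", "seeing": "see",
    "did": "do", "done": "do", "doing": "do",
    "was": "be", "were": "be", "been": "be", "is": "be", "are": "be",
    "am": "be", "being": "be",
    "had": "have", "has": "have", "having": "have",
    "loved": "love", "loves": "love", "loving": "love",
    "wanted": "want", "wants": "want", "wanting": "want",
    "lived": "live", "lives": "live", "living": "live",
    "died": "die", "dies": "die", "dying": "die",
    "children": "child", "men": "man", "women": "woman",
    "people": "person", "wives": "wife",
}

_VOWELS = set("aeiou")


def lemmatize(word: str) -> str:
    """Return the lemma of a lowercased word.

    Irregular forms come from a fixed table; otherwise ``-ies``,
    ``-es``, ``-s``, ``-ing`` and ``-ed`` suffixes are stripped with
    guards that avoid mangling short words ("was", "his", "ring").
    Unknown shapes are returned unchanged.
    """
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    n = len(word)
    if word.endswith("ies") and n > 4:
        return word[:-3] + "y"
    if word.endswith("sses") or word.endswith("shes") or word.endswith("ches"):
        return word[:-2]
    if word.endswith("es") and n > 4 and word[-3] in "sxz":
        return word[:-2]
    if word.endswith("s") and n > 3 and not word.endswith("ss") and not word.endswith("us"):
        return word[:-1]
    if word.endswith("ing") and n > 5:
        stem = word[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2]:  # running -> run
            stem = stem[:-1]
        elif stem[-1] not in _VOWELS and len(stem) > 1 and stem[-2] not in _VOWELS:
            pass
        elif stem[-1] not in _VOWELS and stem + "e" in _IRREGULAR.values():
            stem = stem + "e"
        return stem
    if word.endswith("ed") and n > 4:
        stem = word[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2]:  # stopped -> stop
            stem = stem[:-1]
        elif stem + "e" in _IRREGULAR.values() or stem.endswith(("at", "iv", "us")):
            stem = stem + "e"
        return stem
    return word
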