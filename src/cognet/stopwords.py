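"""Default English function-word list.

Stopwords are *flagged* on tokens, never deleted from the corpus:
co-occurrence construction optionally skips them, while closeness
rankings drop them from the ranking only (they stay in the graph).
The inventory covers determiners, adpositions, conjunctions,
auxiliaries and pronouns; personal pronouns ("i", "you", "s/he", "it")
are deliberately *not* stopwords because they are first-class actors
in subject-verb-object networks.
"""

from __future__ import annotations

DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """
    a an the this that these those some any each every no such
    and or but nor so yet for because although though while if
    unless until when whenever where wherever whether than as
    of in on at by with from to into onto upon about above below
    under over between among through during before after against
    within without along across behind beyond near off out up down
    is am are was were be been being
    do does did done doing
    have has had having
    will would shall should can could may might must
    not n't never
    there here then now just only also too very quite rather
    what which who whom whose why how
    its his her their our your my mine yours ours theirs hers
    them they we us him
    """.split()
)
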