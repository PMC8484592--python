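# Methods

This note documents the models implemented in `cognet`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Corpus model and tokenization

A corpus is an ordered list of documents, each a list of sentences of
tokens. Tokenization is deliberately minimal and fully deterministic:
lowercase, sentence split on terminal punctuation (`.!?`), tokens are
maximal runs of letters/apostrophes. Documents with fewer than
`min_sentences` sentences (default 2) are dropped, since triangle and
frame statistics are meaningless on fragments. Gendered third-person
pronouns merge into a single concept `s/he` at read time, so actor
analyses do not split the "other person" role by gender. A small
rule-based lemmatizer (irregular-form table plus conservative suffix
stripping) collapses inflectional variants; the word type used as a
network node ("concept") is the lemma by default, configurable to the
surface form, because corpus studies differ on this point and nothing
downstream depends on the choice.

Stopwords (determiners, adpositions, conjunctions, auxiliaries —
never personal pronouns, which are first-class actors here) are
*flagged, not removed*: co-occurrence construction drops them before
measuring adjacency (so content words separated only by function words
count as adjacent), while closeness rankings drop them from the
ranking but keep them in the graph, where they legitimately mediate
shortest paths.

Valence annotation maps each concept to {positive, negative, neutral}
from a lexicon; numeric norm scores are thresholded with a documented
neutral band (user-set; scores ≤ low are negative, ≥ high positive).
Out-of-vocabulary words default to neutral — the least-assumption
choice, since neutral words neither create nor break signed triads.

## Networks

**Co-occurrence (CO).** Within each sentence, every pair of distinct
concepts at distance ≤ `window` (default 1, strict adjacency)
increments the pair's edge weight; edges never cross sentences.
Weights are kept but the triad census is purely topological, since
balance is about which associations exist, not how often.

**Subject–verb–object (SVO).** Triples come either from CoNLL-U
dependency annotations (`nsubj`/`obj` dependents sharing a head) or
from the bundled heuristic extractor, which emits one triple per
simple three-token declarative sentence — the pattern the synthetic
generator plants. Each triple adds a 3-clique (s–v, v–o, s–o), which
is the unique pairwise construction under which every participant's
strength equals exactly twice its triple count; that identity is what
makes strength a principled centrality for actor analysis, and it is
tested exactly. Reflexive triples (subject = object) contribute only
the two verb edges and are logged. Negation, auxiliaries and copulas
receive no special treatment.

## Emotional balance

Edge signs are a deterministic function of endpoint valences (rule in
the README). Triads are classified from node valences, which is
equivalent to classifying the induced sign multiset but matches how
the taxonomy is defined; exhaustive enumeration over all 27 valence
assignments confirms the {+,+,−} configuration can never arise, so the
taxonomy is {+,+,+} / {+,−,−} (balanced) vs {−,−,−} (unbalanced), with
≥ 2-neutral triangles excluded. Triad fractions are reported over
classified triads (the DoB denominator convention); a variant over all
triangles is also emitted.

Two null models, each with explicit seeds and a default of 1000
realizations:

* **Configuration null** — connected double-edge-swap rewiring
  (10·|E| attempted swaps per realization, swaps that disconnect the
  graph rejected), valences staying attached to their words. Tested
  against an independently coded long MCMC swap chain on a small
  graph.
* **Label-shuffle null** — uniform permutation of the valence labels
  on the fixed topology. Internally this is vectorized: triangles are
  enumerated once and each permutation only re-indexes a valence code
  array, which makes 1000 realizations cheap even on dense graphs.

z-scores are reported per statistic and omitted (flagged) when a null
is degenerate (sd = 0).

## SVO structure statistics

**Tail exponent.** Discrete power-law MLE: for each candidate cutoff
`xmin` (unique observed values, ≥ 10 tail points, at most 100
candidates), the exponent maximizes the Hurwitz-zeta likelihood and
the cutoff minimizing the KS distance wins. On 5000 planted draws
with γ = 2 the fit recovers the exponent within ±0.1. For
exponential-tailed data the optimal cutoff climbs deep into the tail —
small `n_tail` relative to the sample is the diagnostic of a poor
power law.

**Degeneracy.** D = (N·max_v π(v) − 1)/(N − 2), where
π(v) = (1/N)·Σ_{u∈N(v)} 1/deg(u) is the probability that one uniform
random-walk step from a uniformly random node lands on v. D = 1 iff
the graph is a perfect star (every step lands on the hub) and D = 0 on
any regular graph (uniform landing distribution); both identities are
tested for N up to 50. This statistic is this package's
reconstruction of the star-concentration idea: it satisfies every
stated contract (one-step walk concentration, [0,1] range,
star-uniqueness of the maximum) and is documented as such.

**Shrinkage.** 1 − |GC(G−v)|/|GC(G)| in node counts (a
strength-weighted variant would be possible but node count is the
simplest reading and the default). The null resamples the whole
weighted network from the soft configuration model: independent
Poisson edge weights with mean s_i·s_j/(2W), self-loops included with
mean s_i²/(4W) so that E[strength_i] = s_i holds exactly (the
Chung–Lu convention; loops are irrelevant to connectivity). Per node
the 1st/99th null centiles and a two-sided empirical p-value (with the
+1 continuity correction) are reported.

**Articulation share.** A node u depends on v when u's component
after deleting v holds strictly less than half of the remaining giant
component — the minority fragments hanging off v. This threshold
handles the degenerate star case (every leaf depends on the hub, even
though each post-removal component ties for "largest") while matching
the intuitive reading — fragments cut off from the bulk — on realistic
topologies. Reported overall and restricted to negative-valence
words.

**Clusters.** Girvan–Newman divisive clustering on the unweighted
topology, with a deterministic tie-break (lexicographically smallest
word pair among maximal-betweenness edges) so runs are reproducible.
Per-cluster valence fractions and induced-subgraph degeneracy are
reported.

**Neighborhood valence.** Pooled two-proportion χ² (1 df, no
continuity correction, two-sided p) comparing the fraction of negative
(resp. positive) words among a node's neighbors with the rest of the
network; requires ≥ 5 neighbors and a nonempty comparison group.

## Semantic frames and emotion profiles

Closeness is (n−1)/Σd on the giant component, verified exactly
against a hand-rolled BFS oracle. Ties share the minimum rank
(competition ranking). Rank shifts under the configuration null reuse
the rewiring machinery: shift = mean null rank − observed rank,
positive when the word ranks better than its degree alone explains.

A semantic frame is the radius-1 neighborhood by default (radius
configurable). For the emotion profile, the frame is intersected with
the lexicon universe (out-of-universe words logged and dropped), the
observed richness of each of the 8 Plutchik emotions is counted, and
the null draws equal-size word sets uniformly *without replacement*
from the universe (default 1000 samples). Significance uses the
empirical central (1−α) interval of the null rather than a normal
approximation — safer at small frame sizes — with z-scores reported
alongside for display. Two conventions for degenerate nulls: a frame
equal to the whole universe yields a point-mass null equal to the
observation, so z = 0 by construction; an emotion borne by no lexicon
word yields an undefined z, flagged as such. Marginally each
emotion's null count is hypergeometric, which the tests use as an
independent check of calibration; the implementation itself always
samples.

## Synthetic generator

The generator emulates a small corpus of personal notes: 139
documents of ~120 tokens (6–10 sentences × 12–18 tokens), a vocabulary
of 300 word types (80% noun-like, 20% verb-like), valences i.i.d. from
(0.35 positive, 0.25 negative, 0.40 neutral) — a typical affect-norm
mix — and independent per-word emotion flags at 10% prevalence.
Sentences are token chains in which each word copies its
predecessor's valence class with probability `c` (the
compartmentalization knob); at c = 0 the adjacent same-valence rate
equals Σp_k² as under independence, a tested identity. Planted SVO
triples and self-hub triples are embedded as parseable three-token
sentences. The self token's objects come from a reserved peripheral
noun pool composed so that a fraction `p_self_negative_attach`
(default 0.6) of it is negative — negative words concentrate around
the self rather than in the prose, producing the star-of-negatives
pattern the structure statistics are designed to detect. The
free-association baseline is a preferential-attachment graph over a
valence-independent random word order: heterogeneous degrees,
connected, zero valence assortativity by construction.

**Study conditions.** The compartmentalization experiments (the DoB
grid and the c = 0 calibration) run on a positive-dominant condition:
vocabulary 100, valence mix (0.5, 0.1, 0.4), no planted triples, so
that at c = 0 valence is fully independent of topology. This regime
choice is substantive, not cosmetic: the symmetric valence-copy
process inflates single-valence triangles of *every* class, so with a
balanced valence mix the {−,−,−} class grows alongside {+,+,+} and the
degree of balance *falls* with c. A rising DoB — affective
organization of the kind the balance analysis targets — requires the
positive class to dominate triangle formation, i.e. a lexicon where
negative words are sparse, which is also the affective profile of the
corpora this analysis is designed for. With 20 seeds per grid point
the mean DoB rises strictly along c ∈ {0, 0.3, 0.6, 0.9}, and at c = 0
the observed DoB falls inside the label-shuffle null's ±3 sd band in
every seed.

**What the synthetic experiments do not show.** Generated sentences
are token sequences, not prose: no syntax beyond the planted
three-token pattern, no polysemy, no topical structure, no Zipfian
frequency profile (word frequencies are near-uniform within a valence
class). Passing the recovery tests demonstrates that the machinery
detects the structures it is defined to detect at realistic sizes —
not that real corpora contain them.

## Problem sizes and numerics

Null-model defaults are 1000 realizations; the test suite and the
acceptance script use 200–1000 depending on the cost of one
realization (label shuffles are vectorized and always run at high
counts; configuration rewiring and soft-CM resampling use 100–300
where a realization requires full graph reconstruction). Monte-Carlo
comparisons in tests use 3-standard-error bands. Empirical p-values
use the (1 + count)/(1 + n) correction and are capped at 1. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; fixed seeds give byte-identical pipeline
outputs (no timestamps are written).

## Known limitations

* The heuristic SVO extractor handles only the three-token
  declarative pattern; real text needs CoNLL-U input from an external
  parser.
* The rule lemmatizer is intentionally small; rare irregular forms
  pass through unlemmatized.
* Configuration-model sampling by swap-rejection is approximately,
  not exactly, uniform over connected graphs with fixed degrees; the
  MCMC cross-check bounds the discrepancy on small graphs only.
* The degeneracy statistic is a reconstruction from its stated
  properties, not a transcription of a published formula.
* With valence mixes far from positive-dominance the
  compartmentalization knob lowers rather than raises the degree of
  balance (see Study conditions above); the generator makes no
  attempt to hide this regime dependence.
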