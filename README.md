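# cognet

Cognitive-network analysis of text corpora: build word networks from
documents, sign their edges from word valence, and quantify how the
affective and syntactic structure of a corpus is organized — the kind
of analysis used to study the collective mindset expressed in corpora
of personal narratives (diaries, letters, clinical notes) where the
raw text itself often cannot be shared.

The package is aimed at computational social scientists and
psycholinguists who want the network machinery (and its null models)
as tested, reusable components, exercisable end to end on synthetic
corpora with known planted structure.

## What it computes

**Emotional balance.** From a co-occurrence (CO) network whose nodes
carry a valence class, edge signs follow the rule

    w(a,b) =  0  if both words are neutral
    w(a,b) = -1  if either word is negative
    w(a,b) = +1  if both are positive, or one positive and one neutral

Every triangle is then classified by its node valences — {+,+,+} (no
negative word), {+,−,−} (exactly one), {−,−,−} (two or more), with
triangles containing two or more neutral words excluded — and the
*degree of balance* is the balanced fraction

    DoB = (n_{+++} + n_{+--}) / (n_{+++} + n_{+--} + n_{---}).

Under this signing rule the classic one-negative-edge triangle
{+,+,−} is structurally impossible. Observed censuses are compared
against two Monte-Carlo nulls: a connected degree-preserving
configuration model (double edge swaps) and a uniform shuffle of the
valence labels on the fixed topology.

**Actor structure.** From subject–verb–object triples, each triple
becomes a 3-clique, so node strength s(v) equals twice the number of
triples containing v. The module fits a discrete power law to the
strength tail (maximum likelihood, KS-minimizing cutoff), measures
*star-degeneracy* D = (N·max_v π(v) − 1)/(N − 2) with π(v) the landing
probability of a one-step random walk from a uniform start (D = 1 only
on perfect stars), giant-component *shrinkage* under node deletion
against a strength-preserving soft configuration model, articulation
shares, Girvan–Newman clusters, and pooled two-proportion χ² contrasts
of neighborhood valence.

**Semantic frames.** Closeness-centrality rankings (function words
excluded from the ranking, not the graph), configuration-model rank
shifts, and emotion profiles: how many words in a target's
neighborhood carry each of the 8 Plutchik emotions, z-scored against
equal-size random samples from an emotion lexicon.

**Synthetic corpora.** A generator with a tunable
*compartmentalization* parameter c (the probability that the next
word in a sentence copies the previous word's valence class), a self
token planted as a star hub that preferentially attaches negative
words, embedded ground-truth SVO triples, and a valence-independent
free-association-style baseline network.

## Worked example

```python
from cognet import (SyntheticSpec, generate_lexicons, generate_corpus,
                    annotate_valence, build_cooccurrence,
                    triad_census, label_shuffle_null)

spec = SyntheticSpec(seed=1, compartmentalization=0.6,
                     vocab_size=100, valence_mix=(0.5, 0.1, 0.4),
                     n_self_triples=0, n_planted_triples=0)
valence, emotions = generate_lexicons(spec)
corpus, _ = generate_corpus(spec, valence)
corpus = annotate_valence(corpus, valence)

G = build_cooccurrence(corpus)           # 100 nodes, window-1 adjacency
census = triad_census(G)
null = label_shuffle_null(G, n_realizations=1000, seed=2)["dob"]
print(f"DoB = {census.dob:.3f}")
print(f"label-shuffle null: {null.mean:.3f} +/- {null.sd:.3f}")
```

prints

```
DoB = 0.961
label-shuffle null: 0.957 +/- 0.004
```

i.e. on this compartmentalized synthetic corpus 96.1% of classified
triads are balanced, slightly above what the same topology yields once
the valence labels are shuffled — the same comparison one would make
on a real corpus to ask whether affect is organized beyond what the
valence counts alone imply.

The same analyses run from the shell:

```sh
cognet run-all --out-dir out --seed 1 --n-realizations 200
```

which writes the simulated corpus and lexicons, both networks, the
balance report, the SVO structure report, closeness rankings and
emotion profiles, plus a `manifest.json` recording every output, seed
and parameter. Identical seeds give byte-identical outputs.

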