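# Methods

## Scope and model

`kolminer` discovers likely opinion leaders for a medical topic from news
text in five stages: CRF named-entity extraction, rule-based subject-expert
filtering, name normalization, co-mention network construction, and
centrality ranking.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic test bed does and
does not establish.

## Sequence model

The tagger is a first-order linear-chain CRF over the four IO labels
`(Iperson, Iorg, Iloc, O)` in that fixed order.  For per-token feature
sets x and label sequence y,

    score(y | x) = Σ_t [ W[y_t]·x_t + T[y_{t−1}, y_t] ],
    P(y | x) = exp(score) / Z(x),

with Z from the forward recursion in log space.  Training minimizes the
NLL plus a Gaussian prior (variance 10.0 by default, a common CRF
setting), with L-BFGS-B from zero initialization — deterministic for a
fixed corpus and configuration.  Gradients are expected-minus-empirical
feature counts from forward–backward.  The gradient, the partition
function and Viterbi are all checked against exhaustive enumeration over
all 4^T label sequences for short sentences, and against central finite
differences.

Numerical choices: log-sum-exp with max subtraction everywhere;
Viterbi ties break to the smallest label index (first label wins on an
all-zero model), making decoding reproducible; features unseen in training
are ignored at decode time; a non-finite objective aborts with the
offending sentence.  The IO scheme cannot separate two same-type entities
that abut with no outside token between them — this is asserted in the
tests as expected behavior, not a defect.

Feature families: lowercase token, rule lemma, prefixes/suffixes of
lengths 2–4, character 2/3-grams, shape patterns, POS tag, sentence
section, dictionary membership (person first/last, organization, location
lexicons), and top-5 distributional-thesaurus neighbors; each family is
replicated for context offsets −2..+2 with explicit BOS/EOS markers
instead of padding features.  POS comes from the training corpus columns
at train time and from a small deterministic rule tagger at run time; the
lemmatizer is a handful of suffix rules.  The thesaurus maps each term
above a frequency floor (2) to its cosine-nearest neighbors under
context-co-occurrence vectors (window 2); its exact construction is a
free design choice here, only the paradigmatic-neighbor contract is load
bearing.

## Expert filtering

Rules apply in order, each only removing mentions:

1. **Organization-nested names** — a person mention is dropped if its span
   lies inside an organization mention, or its surface equals a
   whitespace token of an organization mention in the same document.  The
   rule is resolved per document because no global organization registry
   exists at this layer.
2. **Keyword proximity** — 33 scholarly keywords, matched
   case-insensitively on token boundaries ("Dr" never fires inside
   "drive"; multiword keywords match as phrases).  The distance is the
   nearest-boundary gap between the mention span and a keyword span
   (0 on overlap), measured on the raw document, any occurrence counts,
   and the 100-character window is inclusive at exactly 100.
3. **Publication count** — keep persons with ≥ 10 publications, looked up
   by (first, last) name in a static TSV table by default.  A first name
   that is a bare initial falls back, PubMed-style, to the maximum count
   among same-last-name rows starting with that initial, so "J. Doe"
   resolves like "John Doe".  Absent names count 0; a provider *failure*
   (as opposed to a miss) retains the mention with a warning flag, since
   dropping data on infrastructure errors would silently bias the expert
   set.  The threshold applies per mention, before normalization.

## Name normalization

Mentions are clustered by single-link merging within last-name blocks
(blocks whose keys agree within normalized edit distance 0.2 are fused,
so near-miss spellings can still meet).  The pairwise score parses each
surface into (first tokens, last token) after stripping honorifics, and
multiplies last-name edit similarity (zero beyond normalized distance
0.2) by first-name compatibility: 1.0 identical, 0.9 for initial-vs-full
or a missing first name, 0 for two different full first names.  The merge
threshold θ = 0.85 admits exact and initial-form matches but not
different first names; lowering θ can only reduce the cluster count.

Context evidence is the mention's *associated* organization and location:
the nearest org/loc mention in the same sentence (a news attribution
sentence carries the affiliation), falling back to the nearest in the
article.  Early experiments using every org/loc in the article let
background mentions bridge unrelated people.  Shared-token tests ignore
generic institution words (University, Clinic, ...), which carry no
identity signal.  `require_context` has three settings: `True` (evidence
required for every merge), `False` (never), and `"auto"` (waived only for
exact spelled-out full-name matches).  The pipeline default is `True`:
identical names at different institutions must stay distinct people —
that is precisely the polysemy case the org/location evidence exists to
resolve — and `"auto"` would merge them.  The cost of `True` is that two
mentions of one person with no shared context evidence stay separate; in
news text, expert mentions almost always carry an affiliation.

## Co-mention network and ranking

The graph links two individuals iff they co-occur in at least one
article; repeat co-mentions do not weight the edge.  Centralities follow
the classical definitions: degree deg(v)/(n−1); betweenness summed over
unordered pairs, unnormalized; closeness 1/Σd; eigenvector as the
principal eigenvector of the adjacency matrix, max-normalized to 1.
Closeness and eigenvector are undefined across components, so they (and
the degree denominator n, for consistency) are computed per connected
component; `use_global_n` switches degree to the whole-graph n.  The
eigenvector is computed by power iteration on A + I — the identity shift
guarantees convergence on bipartite components, where iterating A itself
oscillates — to an iterate tolerance of 1e-10 (cap 1000 iterations),
with λ as the Rayleigh quotient; the fixed-point residual ‖Ac − λc‖∞
stays below 1e-8.  All rankings sort descending with ties broken by
person id; the candidate list is the union of the five top-20 lists.
Betweenness uses the Brandes accumulation (networkx) and is verified
against exhaustive geodesic enumeration on small graphs.

## Synthetic test bed

The generator emulates the structure the pipeline assumes: templated
news-style articles (roughly 100–400 words, so the 100-character window
is exercised realistically) with gold-annotated Person/Organization/
Location spans; experts placed within the keyword window with counts
≥ 10; non-experts placed behind ≥ 110 characters of keyword-free filler
or given counts < 10; organization-nested traps ("Maylor Clinic" ...
"I visited Maylor"); polysemous twins (identical full names, different
institutions) and initial-form synonyms; and a block structure over
persons so the co-mention graph has planted communities.  Default
conditions: 120 articles, 60 persons (60 % experts, 20 % low-publication,
20 % keyword-distant), 2 polysemy pairs, 30 % initial forms, 12 % trap
articles, 3 blocks with 8 % cross-block mixing, 260 training sentences.
Before returning, the generator verifies offset fidelity and that the
three rules alone reproduce the planted expert flags (separability); it
raises rather than emit an inconsistent corpus.

What passing means — and does not.  The templates are far more regular
than real news: names come from closed pools largely covered by the
lexicons, affiliations always appear in the attribution sentence, and
boilerplate is absent.  Perfect synthetic recovery therefore demonstrates
the correctness of the machinery (offsets, rules, clustering, graph
construction, determinism), not real-corpus accuracy; accuracy on real
news is what the 100-article benchmark arithmetic characterizes, and it
is substantially below the synthetic ceiling.

Problem sizes throughout (120 articles, 260 training sentences, random
oracle graphs of ≤ 8 vertices, 50 random CRF models on sentences of ≤ 5
tokens) are chosen so every oracle can be exhaustive and the whole suite
runs in well under a minute of CRF training; they are the package's own
test conditions, not estimates of production scale.

## Known limitations

* No nickname table and no co-authorship evidence in normalization; the
  evidence types are name form, organization and location only.
* The publication provider ships as a static table; a live bibliographic
  lookup is a pluggable adapter, deliberately outside the test path.
* English-only tokenization with a fixed abbreviation list.
* Boilerplate removal is a light tag-stripping plus link-density
  heuristic, not a full content-extraction system.
* IO labeling merges abutting same-type entities by construction.
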