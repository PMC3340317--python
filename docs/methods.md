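# Methods

This note documents the models and procedures implemented in `semprop`, the
parameter choices that matter, what the synthetic fixtures do and do not
emulate, and the numerical decisions behind the solvers.

## Network model

An SBML file is reduced to typed elements (species, reactions, compartments)
and directed, role-labelled references among them: each reaction refers to
its reactants, products and modifiers, and each species to its compartment.
Rules, events and parameters are ignored — similarity and propagation are
defined over the three element types that carry biological identity in a
reaction network.  Modifier references are kept as their own role so that
enzymes and regulators can contribute information to a reaction.  Annotations
are parsed from both MIRIAM URI dialects (`urn:miriam:resource:id` and
`http(s)://identifiers.org/resource/id`) into (resource, identifier,
qualifier) records; the two dialects normalise to equal values (resource
lower-cased, identifier percent-decoded).  Qualifiers are recorded but not
weighted: "is"-like and "isVersionOf"-like relations are featurised
identically, since there is no principled weighting without a gold standard.

## Features and direct similarity

A concept space is built from all (resource, identifier) pairs seen in the
input models; an optional equivalence table merges cross-resource synonyms
(e.g. a ChEBI and a KEGG entry for the same sugar) into one concept.  Feature
values are binary — 1 per annotated concept — the minimal choice given that
partial-confidence annotations have no agreed encoding; fractional weights
remain representable in the `FeatureMatrix` type.  The direct similarity is
the normalised quadratic form σ = vᵀSv′/√((vᵀSv)(v′ᵀSv′)), 0 whenever either
vector is zero.  S defaults to the identity, i.e. concepts are treated as
logically independent and σ is the cosine; a user-supplied S (white-space
matrix with a concept-key header) is accepted but never derived here.
Denominator products below 1e−15 are treated as zero vectors.  Cross-type
similarities (species vs reaction etc.) are fixed to 0 at the comparison
layer: similarity tables only ever contain same-type pairs.

## Propagation

The transfer matrix R has entries (reaction, species) = α and
(species, reaction) = β for reactant/product references, a symmetric
`modifier_weight` on modifier edges, and a symmetric `compartment_weight` on
compartment-of edges.  Defaults: α = β = 0.5, modifier_weight = 0.5,
compartment_weight = 0.  The benchmark results are insensitive to moderate
changes in these weights; compartment propagation is off by default because a
shared compartment links nearly all species of a model and would blur
rather than sharpen identities.  All entries touching a cofactor species are
zero: a species is a cofactor if any of its annotations appears in the
configured cofactor list, which ships with the common currency metabolites
(ATP, ADP, AMP, NAD(H), NADP(H), water, proton, phosphate, CO₂, O₂) as ChEBI
entries and is user-overridable — cofactors are hubs whose shared presence
says nothing about two reactions being related.

**Feature propagation** solves (I − λR)W = V by sparse LU factorisation
(never an explicit inverse).  **Similarity propagation** solves
(I − λQ)ψ = σ on the pair graph, whose nodes are same-type cross-model pairs
and whose matrix is the Kronecker product of the two transfer matrices
restricted to those nodes.  Excluding cross-type pairs from Q is exact — their
similarity is defined 0 and no Q edge could change that — and shrinks the
pair graph.  The pair graph makes the cost asymmetry explicit: Q has
O(|M|·|N|) nodes versus |M| and |N| for the two R matrices, which is why SP
is the more expensive (and usually slightly better) scheme.

λ is chosen as `lambda_fraction`/r with r the spectral radius of the transfer
matrix, default fraction 0.5 (λ = 1/(2r)); λ·r ≥ 1 raises rather than
returning a divergent solution, and r = 0 (no propagation paths) maps to
λ = 1 by convention since the series then terminates at its first term.
The spectral radius is computed densely below 50 elements, by sparse
largest-magnitude Arnoldi above, with a logged power-iteration fallback.
Both solves equal the truncated propagation series Σₖ(λ·)ᵏ to < 1e−8 at
K = 100 and satisfy their fixed-point equations to < 1e−9 (checked in the
test suite against an independent dense-series oracle).  A `max_steps`
argument exposes the truncated series directly; with λ = 1 and one step on
the one-reaction pair fixture it reproduces the closed form
ψ(x,y) = α²(σ_ap + σ_bq) exactly.  Inferred values are not clipped at 1 —
SP values above 1 are accumulated propagation mass; capping them is a
display decision, not part of the model.  Values whose magnitude falls below
1e−14 after a solve are snapped to 0 to keep solver dust out of downstream
greedy matching.

## Alignment

The greedy aligner keeps one global candidate queue across all model pairs,
ordered by descending ψ with ties broken lexicographically by the
(model_id, element_id) labels of both members, so repeated runs are
bit-identical even when elements carry identical annotations.  Pairs at or
below 1e−12 are never matched (ψ must be genuinely positive).  A merge that
would place two elements of one model in the same tuple is rejected and the
candidate discarded; merging otherwise unions the two tuples, which for three
or more models carries previously matched partners along — transitivity holds
by construction.  The alignment score sums table similarities over all
cross-model pairs inside tuples.  Exact score maximisation is deliberately
out of scope (it is computationally hard); the test suite bounds the greedy
score by a brute-force optimum on small instances and verifies equality for
strictly dominant diagonals.  Precision and recall of an alignment are
computed over matched pairs (tuples expanded to their pairwise closure);
singleton tuples contribute nothing, an empty prediction has precision 1 and
an empty reference recall 1 by convention.

## Annotation prediction

Prediction uses a deliberately restricted propagation: transfer only between
reactions and their reactants/products, weight ½ in both directions, one
propagation step (series truncated at k = 1, λ = 1), cofactor blocking still
active.  This keeps an element's vector local to its direct neighbourhood and
gives the leave-one-out exactness property: the collection entry for
annotation *i* of element *x* is *x*'s propagated vector with component *i*
zeroed, so a query model missing exactly that annotation reproduces the
entry vector bit-for-bit and the hidden concept scores cosine 1.  The query
element's own remaining annotations do contribute to its vector — predictions
improve as more of the model is annotated.  Collection search is an
exhaustive linear scan (corpora here are desk-scale); concepts are
de-duplicated keeping the best score, ranked by (score desc, concept key) for
determinism, and truncated to top-n.  Collection vectors are stored
un-normalised; the cosine normalises at comparison time.

## Synthetic fixtures and what they show

The generators produce the benchmark topologies: a linear chain with only its
endpoints annotated (the minimal case where direct similarity fails and
propagation recovers the full matching), a one-reaction pair with annotated
species and unannotated reactions (the closed-form example), a
phosphorylation-style pair whose two protein states carry identical
annotations but different contexts, and random degree-capped bipartite
species–reaction networks.  The random generator wires every species into at
least one reaction and rejects reactions whose touched-species set duplicates
an earlier one: tiny random graphs otherwise produce twin elements with
identical neighbourhoods, which no neighbourhood-based method can tell apart.
The leave-one-out exactness benchmark uses fully annotated chains for the
same reason — exact recovery is only well-posed when every element has a
distinct neighbourhood signature.

Annotation removal strips whole elements (an element keeps all annotations or
none), drawing the removed set as the prefix of one seeded permutation, so
for a fixed seed the sets are nested across fractions; replicate recall
curves are therefore monotone-coupled, which stabilises the benchmark means
at 25 replicates.  The alignment benchmark (removal → similarity → greedy
matching → precision/recall against the identity alignment) runs a full
factorial over fractions {0, 0.2, 0.4, 0.6, 0.8}, 25 replicates and the three
measures on a 10-species/7-reaction pair — sizes chosen so the whole grid
runs in seconds while leaving room for recall to degrade smoothly.

What passing these benchmarks does **not** show: fixtures have uniform
annotation quality, no annotation errors, no qualifier diversity, no shared
sub-pathways between non-identical models, and no kinetic information.  Real
model pairs differ in granularity (lumped vs elementary reactions), use
inconsistent resources for the same concept (making the equivalence table
load-bearing), and contain genuinely ambiguous elements; precision on such
pairs will be lower than on these fixtures, especially at low annotation
coverage, where propagated guesses outnumber safe matches.

## Known limitations

- Propagation weights are fixed, not learned; there is no gold-standard
  alignment corpus here to fit them on.
- The concept-similarity matrix S is an opaque input; no ontology-based
  similarity is computed.
- SP memory/time grow with the product of model sizes; models with thousands
  of elements per side will want blocking by element type or pre-filtering of
  pair nodes.
- Prediction quality depends on the corpus containing near-isomorphic
  neighbourhoods of the query; a corpus from a different domain yields
  confident-looking but meaningless suggestions (scores are cosines, not
  calibrated probabilities).
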