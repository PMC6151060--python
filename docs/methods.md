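# Methods

## Graph model of metabolism

A metabolic model is reduced to a directed *compound graph*: one node per
compound, and for every reaction an edge from each substrate to each
product (both directions for reversible reactions). Stoichiometry is
deliberately ignored — seed detection is a reachability argument, and edge
multiplicity or coefficients cannot change which compounds are reachable
from which. Self-loop edges (a compound listed on both sides of one
reaction) are dropped and counted in the parse provenance; they cannot
affect SCC membership beyond the node itself.

Two parse choices matter and are both configurable:

- **Compartment stripping** (default on). Model species ids usually carry a
  compartment tag (`glc_D[c]`, `glc_D_c`, or the XML-escaped bracket form).
  Stripping it merges compartment duplicates onto one base id. This is
  required for any cross-organism comparison — the indices match compounds
  by id across models — at the cost of conflating, e.g., cytosolic and
  extracellular pools. With stripping off, each compartment instance is a
  distinct node and seed counts grow accordingly; which convention external
  seed-count tables used is generally not recoverable from the counts
  alone, so both are exposed.
- **Exchange/biomass exclusion** (default on, regex `^(EX_|R_EX_|biomass|R_biomass)`,
  case-insensitive). Exchange pseudo-reactions connect every medium
  compound into the network; retaining them makes most true seeds
  non-seeds. Excluded reaction ids are recorded in provenance. Currency
  metabolites (ATP, water, protons, oxygen) are **retained** by default:
  small cofactors are genuine exogenous requirements in this analysis (an
  optional exclusion list is accepted).

The text dialect for networks is a two-column TSV edge list (`#` comments
allowed), written in lexicographic order so output is byte-stable. Isolated
nodes are not representable in this dialect; round-trip guarantees apply to
the edge set.

## Seed detection

Condense the graph into strongly connected components; the condensation is
a DAG. Members of *source components* (in-degree 0 in the condensation) are
the seeds. Rationale: a compound is synthesizable iff some other compound
reaches it; within an SCC every member reaches every other, so either the
whole component is fed from outside (a source component) or some upstream
component feeds it. Each member of a source component of size *s* gets
confidence 1/*s* — the component needs at least one external member but any
single member suffices — so confidences within a component sum to one and
the total seed weight equals the number of source components. A
`min_confidence` threshold (default 0, i.e. keep everything) can drop large
ambiguous source cycles after assignment.

All weakly connected components are analyzed, not only the giant one;
satellite components would otherwise silently lose their seeds. An isolated
node is its own source component (confidence 1). Everything is ordered
lexicographically, so reports are reproducible byte-for-byte.

## Interaction indices

For focal organism *a* with seed confidences c(x) and partner *b*:

- support(a, h)         = Σ{c(x) : x ∈ nodes(h)} / Σ c(x)
- complementarity(a, b) = Σ{c(x) : x ∈ nodes(b), x ∉ seeds(b)} / Σ c(x)
- competition(a, b)     = Σ{c(x) : x ∈ seeds(b)} / Σ c(x)

All three are asymmetric in the pair and lie in [0, 1]; competition of an
organism with itself is 1, complementarity 0, support against its own
network 1. Because `x ∈ nodes(b)` splits exactly into `x ∈ seeds(b)` and
`x ∈ nodes(b) \ seeds(b)`, weighted complementarity plus weighted
competition equals the weighted fraction of focal seeds present anywhere in
the partner network — asserted exactly in tests. Confidence weighting is
the default; unweighted (count-based) variants are one flag away and
coincide with the weighted ones when every source component is a singleton.
Matrix files state the orientation (`focal=row partner=column`) in a header
comment, and per-pair overlap diagnostics are available because an
all-zeros matrix almost always means a compound-namespace mismatch between
models rather than real ecology.

## Community partition

Membership, not confidence, drives the partition of the seed universe into
core (required by every member), unique (exactly one member), and shared
(at least two but not all). For a single-organism community core takes
precedence and unique is empty, keeping |core|+|unique|+|shared| =
|universe| an identity at every community size. Group summaries apply the
same partition within each taxon label and report cross-group exclusives
(compounds in one group's universe absent from another's).

## Pathway enrichment

Per organism: universe N = union of compounds over that organism's
metabolism-class pathways (a per-organism universe; a global-universe flag
exists). n = seed compounds carrying a KEGG id that fall inside the
universe; seeds without a KEGG id or outside the universe are excluded and
the exclusion counts reported. For each pathway of size K with overlap k,
the upper-tail hypergeometric p is computed via the stable survival
function (scipy); k = 0 returns exactly 1. Raw p values are compared to
0.05 with no multiple-testing correction by default, matching the
convention of reporting raw hypergeometric significance for compound-level
enrichment; a Benjamini–Hochberg helper is provided but off. Community
aggregation averages p over the organisms in which a pathway exists —
organisms lacking the pathway contribute nothing to its mean — and counts
organisms where it is significant.

## Food sourcing

Seed metabolite names are matched into the food table by exact equality
after Unicode NFC normalization, case folding, and whitespace collapse.
No fuzzy matching: chemical nomenclature gaps are a real limitation of
name-based sourcing and are surfaced as an unmatched list rather than
papered over.

Filter cascade, in order, each stage's surviving count recorded:
(1) keep foods containing ≥ 1 matched compound; (2) drop foods whose
matched compounds are all below the limit of quantification; (3) drop
processed foods, alcohol, and not-clearly-defined entries; (4) drop foods
where any growth-factor category (amino acids, vitamins, oligosaccharides,
monosaccharides) has no detected compound. Baby-food rows are a labelled
control class and bypass stages 2–4. The cascade is monotone and
idempotent.

Scoring: per food, each category's value is the mean concentration
(mg/100 g) over its matched *quantified* compounds (0 when none); values
are min-max normalized per category **across the foods that survived the
full cascade** (normalizing after filtering is a deliberate choice — the
alternative cohort is configurable in principle and recorded in the output
header); the prebiotic food score is the weighted sum with default weights
vitamins 10, amino acids 8, oligosaccharides 6, bioactive substances 4,
N-compounds 2, monosaccharides 1, NSN −100. Min–max rather than
divide-by-max reads "normalized to [0, 1]" literally; the two coincide
whenever a category's minimum is 0, which holds for most categories in
practice. Ties in the ranking break lexicographically by food name.
Consequences asserted in tests: ranking is invariant under positive
per-category rescaling, and raising a food's NSN mean (cohort max held)
can never improve its rank.

## Co-mention mining

Terms from named dictionaries (gut microbes with taxonomic level and
pathogen tags; immune-related; infection/disease; chemical-related; plus
excluded-animal filter terms) are matched case-insensitively at word
boundaries, longest match first, so a species name shadows its genus
prefix. A sentence qualifies for a dictionary combination when it holds at
least one match from every dictionary in the combination; *relationship*
mode (exactly two dictionaries) additionally applies a pluggable relation
predicate whose default is plain same-sentence co-occurrence. A
dependency-parse relation classifier is intentionally out of scope; the
predicate interface is the extension point, and the default necessarily
over-extracts relative to a syntactic classifier.

The filter chain runs in fixed order with first-matching-rule attribution:
(1) documents published before 2000; (2) title sentences; (3) sentences
containing an excluded animal term; (4) sentences whose microbial matches
are all pathogen-tagged or genus-level. Species frequencies count
*sentences* containing each canonical species (a double mention counts
once), against the combination's post-filter sentence total.

## Synthetic data

Each generator plants the truth its consumer must recover and records it in
a manifest computed by direct construction or brute-force enumeration —
never by calling the module under test:

- **Networks**: an acyclic component skeleton with an exact number of
  source components; every component expanded to a cycle plus random
  chords (strongly connected by construction); inter-component edges only
  run from lower to higher component index, so the planted components are
  exactly the SCCs and the planted sources exactly the seed components.
- **Communities**: every seed is a singleton source compound feeding a sink
  node, and pair-shared seeds are exclusive to their pair, so pairwise
  overlap counts — hence competition — are hit exactly; complementarity and
  host-support targets are planted from each organism's pair-exclusive
  unique seeds as internal partner/host nodes. Targets that do not resolve
  to integer counts, or exceed the available unique seeds, raise with the
  violated constraint: exact construction was chosen over sampling-to-target
  precisely so recovery tests are equalities, not statistics.
- **Food tables**: 50 foods by default; concentrations log-normal per
  category around scales spanning the orders of magnitude of real
  composition data (vitamins fractions of a mg/100 g, monosaccharides
  hundreds); designated foods violate exactly one cascade stage each, one
  baby-food control passes through; the manifest's ranking is computed with
  inline spreadsheet-style arithmetic.
- **Annotations**: a 200-compound universe, one pathway given elevated seed
  overlap (defaults k = 8 of K = 10 against n = 15), backgrounds sampled
  uniformly; the manifest records (N, K, n, k) per pathway.
- **Corpora**: template sentences with neutral filler around planted
  dictionary terms; per-rule filter victims planted separately; manifest
  counts derived by enumerating the planted structures.

One integer seed drives a named RNG stream per generator
(`SeedSequence([seed, stream_id])`), so adding a generator never perturbs
another's fixtures, and regeneration is byte-identical.

What the generators do **not** emulate: realistic metabolic network
topology (degree distributions, pathway modularity), chemical naming
variance, correlated concentrations across foods, or natural-language
syntax. Passing tests therefore demonstrate algorithmic correctness on the
stated contracts, not performance on real models, databases or literature —
headline numbers from real VMH/AGORA models, FooDB or KEGG depend on
versioned external resources and are out of desk scope.

## Pipeline

Stages run in order (mining → parsing → seeds → partition → matrices →
enrichment → food sourcing); a stage whose inputs are absent from the
config is skipped with a log line. Outputs are written atomically (temp
file + rename), carry no timestamps, and are byte-identical across runs on
identical inputs — the analysis has no randomness; only the synthetic
generators do. A stage failure removes the files written by that run and
raises an error naming the stage. The summary embeds a 16-hex-digit SHA-256
hash of the semantically meaningful configuration. Intermediate caching was
considered and omitted: at the problem sizes the package targets, parsing
is cheap and recomputation keeps the determinism contract trivial to state.

## Numerical and degenerate-input choices

- Hypergeometric tails go through the survival function in scipy's stable
  implementation; exact rational enumeration agrees to ≤ 1e−12 for all
  N ≤ 25 (asserted over the full 44k-case sweep).
- Min–max normalization with max = min maps the whole category to 0 (a
  single-food cohort scores 0 everywhere).
- Empty seed sets are an error for every index (the fraction is undefined);
  an empty network is an error for seed detection; an empty edge-list file
  is a valid empty network.
- Deterministic tie-breaks everywhere: lexicographic ids in reports,
  food-name ties in rankings, sorted components in the condensation.

## Problem sizes in the shipped checks

The automated checks run on 200 random digraphs of up to 60 nodes for the
seed oracle, 100 generator parameterizations, 50 random network pairs for
the index identities, the complete hypergeometric grid to N = 25, 1000 null
replicates for calibration, the 50-food fixture, and a planted corpus of a
few dozen sentences — sizes chosen so the whole suite replays in seconds
while still exhausting each contract's structure.
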