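# Methods

This note records the model the package implements, the choices made where the
design was genuinely open, and what the synthetic test world does and does not
establish.

## Source selection

Selection is triple-pattern-wise and hybrid. For each pattern: a bound
predicate is looked up in the catalogue's inverted predicate index (dataset →
predicates is inverted once per access; the index is definitionally the
inversion of descriptor contents); an unbound predicate makes every dataset a
candidate. Pruning with `ASK { pattern }` runs whenever the subject **or**
object is bound — including when the predicate is a variable, a literal
reading of the algorithm. Accounting: #AR counts ASK requests *issued*
(sequentially, in deterministic dataset order), so with the default cold
behaviour #AR equals the sum of pre-pruning candidate counts over
pruning-eligible patterns; an opt-in cache reproduces warm behaviour and
suppresses repeat requests. SST is wall-clock and reported with separate
index and ASK components, since it is ambiguous whether a published selection
time includes probe network time.

Operational edges: an ASK transport failure either removes the dataset and
records the event (default) or aborts, per policy; an optional pre-selection
availability filter excludes endpoints already known to be down; patterns
whose final relevance set is empty are retained, reported as warnings, and
rewritten into empty-solution blocks rather than silently dropped.

## Rewriting

Exclusive groups are computed per BGP and never span an OPTIONAL or UNION
boundary; the outer operators stay in the outer query. Singleton exclusive
groups still become their own SERVICE block. Non-exclusive patterns become a
UNION of one SERVICE block per relevant source, branch order lexicographic by
dataset IRI. Blocks are emitted in ascending order of the smallest pattern
ordinal they contain; join ordering beyond that is the executing engine's
business. Variables are never renamed and the original prefixes are re-emitted.

A FILTER is pushed inside a SERVICE block only when exactly one
*non-union* block covers all of the filter's variables; otherwise it stays in
the outer query. This is a pure transfer optimization — pushing into a union
branch or a partially-covering block could change semantics, so it is never
attempted.

Mirror choice: with endpoint statuses available, the live mirror with lowest
measured latency wins, ties broken lexicographically by URL; without
statuses, the primary (first-listed) URL.

Equivalence (federated result multiset = evaluation over the union of all
dataset graphs) is asserted and tested for BGP/FILTER/UNION/DISTINCT queries.
OPTIONAL parses, evaluates and rewrites, but cross-source OPTIONAL semantics
are a known federation subtlety, so no equivalence guarantee is claimed
for it.

## Execution and provenance

Instrumentation is a wrapper contract around each service invocation:
pre-call timestamp, post-call timestamp, solution-row count, status
(ok/error/down) — one record per SERVICE block in the plan, not per transport
request. "Rows" rather than "triples": SERVICE returns bindings.
A failing endpoint contributes zero rows plus a `down` record (partial
results) unless strict mode aborts. Records live in a store with an
injectable clock: retention 600 s, and a session's next query evicts its
previous record immediately. Session identity is an explicit caller-supplied
key; there is no HTTP layer in this package.

Availability checks probe each URL with `ASK { }` and mirror the statuses
into an RDF graph using a private `urn:x-endpoint-data:` vocabulary (latency,
up, initialized, last-checked, URL), so health data is itself queryable with
SPARQL. `last_checked` never moves backwards even if the clock does.

## Catalogue

Probing issues ordinary SELECT queries (distinct classes, distinct
predicates, one example resource per class, one sampled subject/object per
predicate), so in-process graphs and remote endpoints are handled
identically. Defaults: 1 example per class, 10 000-row probe pages (a page
arriving full flags the descriptor `partial`), 60 s timeout. Labels are the
URI substring after the last `#`, `:` or `/`. Domain/range classes come from
`rdf:type` of the sampled subject/object *within the same endpoint* — no HTTP
dereferencing, for testability. URI regex patterns anchor the example's fixed
prefix up to the last local-segment delimiter (the scheme colon never counts)
and wildcard the local identifier.

Persistence is VoID/Turtle: multi-valued `void:sparqlEndpoint` (primary
first — the writer and reader preserve document order, which is how mirror
priority survives a round trip), `void:classPartition` /
`void:propertyPartition` blank nodes carrying `void:class`, `void:property`,
`void:exampleResource`, `void:uriRegexPattern`, labels and domains/ranges.
Attaching predicates via property partitions is this package's convention;
VoID does not mandate one. Staleness is surfaced, not solved: descriptors
carry an optional built-at timestamp and nothing auto-refreshes.

## Query characterization

Total vertices are counted query-wide (variables by name, IRIs by string,
blank nodes as scoped variables); join membership and degree are evaluated
within a single BGP, with a term qualifying in several BGPs counted once at
its maximum degree. Whether a repeated *predicate* makes a join vertex is
genuinely underdetermined by the usual definition ("subject, predicate or
object of multiple triple patterns"); the default counts all positions and
`join_positions="so"` restricts to subject/object. R and D are exact
`Fraction`s; the display convention truncates (not rounds) R to three
decimals, matching how such tables are customarily printed (2/7 → 0.285).
OPTIONAL and UNION branches open fresh BGPs; FILTER does not interrupt one.

## The SPARQL subset

Hand-rolled because the environment provides no RDF/SPARQL library.
Supported: SELECT/ASK, PREFIX/BASE, `;`/`,`/`a` sugar, FILTER with logical
connectives, comparisons (numeric and string; `=`/`!=` on terms), arithmetic,
REGEX/BOUND/STR/LANG/DATATYPE/CONTAINS/STRSTARTS/STRENDS/isIRI/isLiteral/
isBlank/LCASE/UCASE/STRLEN, OPTIONAL, UNION, SERVICE, DISTINCT, ORDER BY,
LIMIT, OFFSET. Rejected with positioned errors: property paths, sub-selects,
VALUES, BIND, MINUS, GRAPH, CONSTRUCT/DESCRIBE/updates. Evaluation is bag
semantics; filter errors (unbound variables, type errors) discard the
solution, with three-valued `&&`/`||`. Comparison of literals ignores
language tags; typed numeric literals compare numerically. OPTIONAL filter
scoping follows the simple left-join reading; filters inside an OPTIONAL
referencing only outer variables are not given special top-down treatment.

## Synthetic federation

The generator states a fixed world: ten datasets named after the familiar
life-science sources, one class with 30 typed instances each, `rdf:type` and
`rdfs:label` everywhere, three exclusive predicates per dataset (literal- and
IRI-valued alternating, each present on ~70 % of instances), drug-centred
cross-dataset links, and two shared-literal overlaps (a "title"/"genericName"
pair and a "drug_name"/"genericName" pair), all driven by one seed. Instance
IRIs follow the `prefix:local` convention so URI-pattern derivation is
exercised realistically. Scale is 10²–10³ triples per dataset — large enough
for non-trivial joins, small enough for sub-second tests; real deployments
are orders of magnitude larger and nothing here claims statistical realism of
their class structure.

The worked-example fixture is not seeded: it is the stated construction
(category and compound-id predicates only in the drug dataset, typed pathway
compounds and the enzyme link only in the pathway dataset, the synonym
predicate in exactly two datasets, `rdf:type` in all ten), with stand-in
predicate names where the original query's verbatim text is unavailable; the
meaningful surface is the relevance profile (1,1,1,1,2), not the IRIs.

A green equivalence suite therefore establishes: on disjoint-triple
federations of this shape, selection equals per-graph truth and
select→rewrite→execute equals merged-graph evaluation, exactly. It does not
establish behaviour under endpoint result-set truncation, duplicated triples
across datasets (mirrors of one dataset are handled; row-level duplicates
*within* a dataset are explicitly not deduplicated), network pathologies, or
OPTIONAL across sources.

## Numerical and determinism notes

All counting statistics are integers or exact rationals; the only floats are
wall-clock times. Every stochastic component (topology generation, query
synthesis) is driven by explicit seeds; ASK issue order, UNION branch order
and serialization order are deterministic, so repeated runs are byte-stable.
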