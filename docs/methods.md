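# Methods

This note documents the modelling decisions behind the package: what the
semantic-description formalism assumes, how the fixtures were prepared,
which conventions were genuinely open and how they were settled, and what
the tests do and do not demonstrate.

## The description formalism

A semantic description is an ordered sequence of statements about one
organism. Order is semantically irrelevant to the graph but is preserved
everywhere, because taxonomic descriptions follow a conventional anatomical
narrative (habitus → head → thorax → legs → genitalia → measurements) that
readers expect the rendered text to keep.

**Entity paths.** Anatomical locations are part-of chains of ontology
terms rooted at the organism (`male organism > pronotum > dorsal region`).
The *only* relation implied by path nesting is parthood; every other
anatomical relation (homology, adjacency, coincidence, encircling) is an
explicit relational statement. A path may end in a parenthesised group
naming several sibling parts at once — the antennal-club idiom, "these
three flagellomeres form the club" — which the parser expands into one
statement per leaf so that downstream consumers (renderer, differ,
compiler) only ever see flat paths.

**Statement kinds and their closed sets.** Quality statements attach one
quality term to a path. Comparative statements compare a magnitude
attribute of the subject against a (possibly different) attribute of a
reference path; the comparator set is closed to `larger_than` and
`similar_in_magnitude_relative_to`, and the attribute set to `width`,
`length`, `amount`. These sets are exactly the forms attested in the
fixture descriptions; anything else is a *syntax* error rather than a
vocabulary miss, so dialect drift fails loudly. Measurements carry a
finite positive decimal and a unit term. Presence/absence is deliberately
modelled as ordinary quality terms (`present` / `absent`) at the DSL
layer; whether a graph consumer wants to reify absence differently is a
compiler concern, not a syntax one.

**Metadata and annotations.** Header metadata (catalog number, the
taxonomic-unit role and denotation, parent name usage and taxon
identifiers) is a keyed list on the description, not interleaved with the
phenotype statements: printed treatments set these off as a block before
the clause stream, and the clause-count and diff invariants are stated
over phenotype statements. Free-text sections (sexual dimorphism,
variation) are opaque annotations: they are carried, rendered and
round-tripped but never interpreted.

## The DSL dialect

The source dialect is reconstructed, not copied: published fragments of
this description style show the token shape (`aism-flagellomere_5`), the
part-of chain `>`, and the grouping syntax `( , )`, but no complete
grammar. The dialect here fixes the remaining punctuation — `;`
statement terminator, `:` before qualities, a leading `.` marking
relation tokens, `= value, unit:` for measurements, `#` comments,
`@key value` metadata directives, and optional `{ }` blocks that scope a
shared parent path over inner statements (mirroring how printed
descriptions restate context headers). The packaged `.phs` files use the
flat fully-qualified form; block scoping is exercised by unit tests. The
dialect makes no claim of byte compatibility with any external tool's
file format.

Two renderings exist for every description and both are parsed:

* `to_source` emits the token dialect (the authoritative storage form);
* the natural-language renderer emits one clause per statement using
  registry labels (underscores to spaces, explicit label overrides for
  hyphens and Roman numerals), subject paths joined with `", "`, object
  and reference paths written leaf-first with `of`.

Because the clause grammar is closed and labels resolve uniquely, the
rendered markdown is itself machine-readable; `parse_rendered` inverts it
exactly, and the parse → render → parse fixpoint is asserted over both
packaged descriptions. This is the package's central integrity guarantee:
the human-readable text cannot silently diverge from the semantics.

## Fixture transcription

The two packaged descriptions were transcribed from their published
treatments into flat clause lists (one fully qualified clause per printed
clause), then converted to the token dialect. The published layout nests
clauses under shared context headers; transcription expanded every clause
to its full path. Transcription fidelity was checked mechanically in both
directions (every transcribed clause occurs in the whitespace-normalized
printed block allowing for context scoping; every printed fragment is the
tail of some transcribed clause), and the two species' clause lists were
verified to differ in exactly the places the published diagnosis names:
the anterolateral pronotal angle orientation (lateral vs oblique), the
angle of the paramere's distal dorsal margin (straight vs obtuse), an
extra `dorsal region` nesting level at the gena and clypeus, the body
length (23.0 vs 21.5 mm), and the header catalog-number / taxon-ID
values. Each description is 114 phenotype statements plus 5 metadata
entries and 2 annotations.

The seeded vocabulary (149 terms across AISM / COLAO / PATO / RO / UO
namespaces) contains exactly the terms the two descriptions use, plus the
four relations and the unit. Numeric accessions are recorded where the
source material states them (cuticular spine AISM:0000527, metatibial
spur AISM:0000040, antennal club COLAO:0000267, millimeter UO:0000022);
all other terms carry slug identifiers only. The 25 newly created
anatomical accessions (AISM 0000413–0000437) are minted at run time with
placeholder labels, since no labels for them are published; minting is
collision-checked and range-validated. No ontology release is downloaded
or parsed — the registry is a local, self-contained fixture, which is
what makes the whole package testable offline.

## RDF mapping

The compiler uses instance-based EQ modelling: every distinct canonical
path (including every ancestor prefix) becomes exactly one instance node
— a bijection asserted in tests — typed by its ontology class and chained
to its parent with *part of* (BFO:0000050). Qualities are instance nodes
typed by the quality class and linked from their bearer with *has
quality* (RO:0000086). Relational statements become direct edges whose
predicate IRI comes from the registry prefix table. Comparisons and
measurements are reified as small nodes in the package's own `phs:`
vocabulary namespace (subject, attribute, comparator/value, reference/
unit), since no standard predicate set covers "width larger than length
of". Metadata uses Darwin Core terms where they exist
(`dwc:catalogNumber`, `dwc:parentNameUsageID`, `dwc:taxonID`) and `phs:`
placeholders for the modelling-role and denotation links, whose original
predicate IRIs are not published.

Node IRIs are skolem IRIs derived from canonical paths; blank nodes are
avoided entirely. That choice buys deterministic serialization: the
Turtle / N-Triples / TriG writers emit sorted prefix declarations
followed by lexicographically sorted triples, so equal graphs serialize
byte-identically. Parsing (and the isomorphism oracle used to check
round trips) is delegated to rdflib. Term IRIs follow the OBO pattern
`<prefix base> + <numeric id>` when an accession exists and a slug
otherwise; the slug IRIs are documented placeholders, chosen for
determinism over authenticity.

Nanopublications follow the head / assertion / provenance / pubinfo
quartet with fragment-suffixed graph URIs. The assertion graph states the
scientific name (name, authorship, rank, parent-usage link in Darwin Core
terms) or the taxon–habitat association (RO:0002303 *has habitat*);
provenance attributes the assertion to the creator; pubinfo carries
creator and timestamp. Timestamps are explicit arguments so output is
reproducible; signing and network publication are out of scope.

## Diffing and the diagnosis

Statements are matched by a conservative key: canonical subject path +
statement kind + attribute (plus relation name for relational
statements). Within a key, identical statements cancel; remaining
one-per-side leftovers pair up as changed characters, and anything
unpaired is a one-sided (structural) difference. The conservative key
means a path that exists in only one description — the extra
`dorsal region` level under gena/clypeus — is reported as two structural
differences rather than fuzzily aligned into a change; that reading is
deliberate, because whether that nesting discrepancy is biological or a
transcription artifact of the source files cannot be decided from the
published text, and a differ should not guess. Duplicate keys within one
description are compared positionally after cancellation, so statement
order never affects *which* differences are found. Measurements are
compared numerically into their own bucket; header metadata into another.

The diff is validated two independent ways: against a clause-level
textual alignment of the two transcriptions (difflib-based, written in
the test suite without reference to the differ's internals), and against
the triple-set difference of the two compiled graphs (every differing
triple must be attributable to a diff entry, and every diff entry must
produce differing triples).

## Identification keys and occurrence records

Keys are strictly dichotomous: couplets with exactly two leads, each lead
terminating in a taxon or forwarding to another couplet. Validation
checks root presence, dangling targets, cycles and reachability;
`evaluate` is total over complete choice vectors (asserted exhaustively
on the packaged key, where 3 couplets resolve 4 taxa — the binary-tree
leaf count c+1). Lead texts are opaque: no linking of character states to
description statements is attempted.

Occurrence records keep every field verbatim (coordinates at printed
precision, dates in their label form) with typed accessors layered on
top, and validation only where the standard defines hard ranges
(latitude/longitude bounds, positive integer counts, unique occurrence
IDs). CSV export writes canonical Darwin Core headers and round-trips
losslessly. Date normalization recognizes a closed dialect table —
`MM-YYYY` (full-month interval), `DD-MM-YYYY`, and the `DD/DD-MM-YYYY`
collecting interval; anything else (e.g. a collector's code in the date
field) stays verbatim-only rather than being guessed at.

## Limitations

* The DSL dialect is this package's own; it round-trips the attested
  constructs but is not a byte-level implementation of any external
  format, and constructs not attested in the fixtures (nested groupings,
  n-ary relations, ranges of measurements) are not in the grammar.
* Label-form parsing of rendered text requires labels to be unique within
  the vocabulary; an ambiguous label is rejected at lookup. Uniqueness is
  a property of the fixture vocabulary, not of ontologies in general.
* The `phs:` predicate and slug IRIs are placeholders; interoperating
  with a published triple schema would require a one-page mapping.
* The differ aligns by exact canonical path; it will report a renamed or
  re-nested entity as two structural differences, never as a change.
* Tests demonstrate correctness on the packaged material and on
  synthetic perturbations of it; they cannot certify behaviour on other
  groups' description styles or vocabularies.
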