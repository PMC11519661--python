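# phenograph

Ontology-anchored taxonomic descriptions as data.

Species descriptions in taxonomy are traditionally prose. This package
treats them as structured, computable objects instead: a description is an
ordered list of **entity–quality (EQ) statements**, where each anatomical
entity (an insect anatomy / beetle anatomy term) and each quality (a
phenotype-quality term) comes from a controlled ontology vocabulary. From
that single semantic source the toolchain derives everything a taxonomic
treatment needs:

* a **typed RDF instance graph** (Turtle / N-Triples / TriG) for semantic
  querying,
* a deterministic **natural-language rendering** — one clause per
  statement, in the style journals print ("male organism, pronotum,
  dorsal region: convex;"),
* a **diagnosis**, computed by diffing two species' statement lists,
* **dichotomous identification keys** (validated and executable),
* **Darwin Core occurrence records** with summaries and CSV export,
* **nanopublications** (head / assertion / provenance / pubinfo named
  graphs in TriG) for taxon names and habitat associations.

The package ships a complete worked example: the two Malagasy dung beetle
species *Scarabaeus sakalava* and *Scarabaeus viettei* (Coleoptera,
Scarabaeinae), each transcribed as a 114-statement semantic description,
their type-series occurrence records, and the identification key to all
four Malagasy *Scarabaeus*.

## The model

A description `D` is a sequence of statements over entity paths. An
entity path `e₁ > e₂ > … > eₙ` is a *part-of* chain (pronotum → dorsal
region); statements take one of four shapes:

| statement   | form                        | example clause |
|-------------|-----------------------------|----------------|
| quality     | `E: Q`                      | `male organism, pronotum, dorsal region: convex;` |
| relational  | `E .R E′ [: Q]`             | `…cuticular spine in homology relationship with mesotibial spur;` |
| comparative | `E: a ≷ a′ of E′`           | `pronotum: width larger than length of pronotum;` |
| measurement | `E: a = v, unit: u`         | `male organism, length = 23.0, unit: millimeter;` |

Compilation maps each distinct path to one instance node typed by its
ontology class, chained with *part of* (BFO:0000050); qualities become
instances linked to their bearer by *has quality* (RO:0000086). The
rendering function is injective on this statement algebra, so
`parse ∘ render` is the identity — the human-readable text and the
semantic graph can never drift apart.

The diagnosis of two descriptions is the statement-level diff: statements
matched by (canonical subject path, statement kind, attribute); shared
subjects with different value terms are *changed characters*, subjects
present on one side only are *structural differences*, measurements are
compared numerically.

## Worked example

```python
from phenograph import datasets
from phenograph.diff import diff, summarize_diagnosis

registry = datasets.load_registry()
sakalava = datasets.load_description("sakalava", registry)
viettei = datasets.load_description("viettei", registry)
for line in summarize_diagnosis(diff(sakalava, viettei)):
    print(line)
```

prints

```text
male organism / anterolateral pronotal angle: lateral orientation (a) vs oblique orientation (b);
male organism / parameres / distal region / dorsal margin: straight angle to (a) vs obtuse angle to (b);
only in a: male organism, gena, medial region, granulated cuticle: present;
only in a: male organism, gena, lateral region: wrinkled;
only in a: male organism, clypeus, anterior region: wrinkled;
only in b: male organism, gena, dorsal region, medial region, granulated cuticle: present;
only in b: male organism, gena, dorsal region, lateral region: wrinkled;
only in b: male organism, clypeus, dorsal region, anterior region: wrinkled;
male organism: length 23.0 (a) vs 21.5 (b);
```

— the two diagnostic characters separating the species (the tip of the
anterolateral pronotal angles projecting laterally vs obliquely forward,
and the angle of the paramere's distal dorsal margin), a nesting
difference around the gena/clypeus region, and the body-length difference
(23.0 mm vs 21.5 mm).

The same objects drive the CLI:

```sh
phenograph key run --choices 2,2,1       # -> Scarabaeus sakalava
phenograph render sakalava.phs -o out.md
phenograph compile sakalava.phs --dialect turtle -o sakalava.ttl
phenograph nanopub habitat --taxon "Scarabaeus viettei" --habitat "dry deciduous forest"
```

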