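# comatch

Compact coevolutionary matcher for biomedical ontologies.

Given two OWL ontologies, `comatch` computes profile-based concept
similarities (labels, comments, property information of each class and its
direct subclasses, with synonym-aware word matching) and then evolves three
cooperating compact-EA subswarms — probability-vector populations maximizing
MatchRatio, MatchCoverage and MatchFmeasure respectively — to produce an
equivalence alignment between the two class sets. The subswarms exchange
elites each generation so that the coverage (recall surrogate) and ratio
(precision surrogate) metrics improve jointly.

## Layout

| Module | Role |
| --- | --- |
| `comatch.ontology_io` | OWL loading (RDF/XML, Turtle), concept model, term normalization, concept profiles |
| `comatch.similarity` | n-gram/synonym word similarity, delta-gated profile similarity, pairwise similarity matrix |
| `comatch.encoding` | binary chromosomes, gene-segment/threshold bit lengths, decoding, PV sampling/update/mutation |
| `comatch.evaluation` | alignment filtering, MatchCoverage / MatchRatio / MatchFmeasure, precision/recall/f-measure, OAEI RDF + TSV I/O |
| `comatch.cea` | single-swarm compact EA with local-search crossover |
| `comatch.ccea` | three-subswarm coevolution with elite exchange |
| `comatch.synthetic_fixtures` | generator for ontology pairs with known ground truth (synonym renames, character noise, dropout) |
| `comatch.config` / `comatch.cli` | parameter defaults, TOML overrides, command-line interface |

## CLI

```sh
# generate a synthetic benchmark pair with ground truth
comatch make-fixture --out-dir fixture --n-concepts 50 \
    --synonym-rename-fraction 0.2 --char-noise-fraction 0.1 --seed 1

# match the pair (TSV or OAEI RDF output chosen by extension)
comatch match --source fixture/source.owl --target fixture/target.owl \
    --synonyms fixture/synonyms.tsv --out alignment.rdf \
    --seed 1 --max-generation 3000 --trace trace.csv \
    --reference fixture/reference.rdf

# score an existing alignment
comatch evaluate --alignment alignment.rdf --reference fixture/reference.rdf
```

Algorithm parameters (update rate 0.1, crossover probability 0.6, mutation
probability 0.03, mutation rate 0.05, numerical accuracy 0.01, delta 0.06,
3000 generations) can be overridden with `--config params.toml`; keys match
the fields of `comatch.config.MatcherConfig`.

By default the probability vector moves toward the elite only in
generations where the elite strictly improved; set `pv_update_always = true`
to update it every generation (the literal reading of the published update
rule, which converges much faster and explores less).

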