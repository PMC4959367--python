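# relexkit

Relation extraction toolkit for brat-standoff corpora, built for
variant-curation style relations (cohort–disease, gene–mutation, …). It
provides:

- **corpus I/O** (`relexkit.corpus`) — brat `.txt`/`.ann` reading and
  writing, sentence segmentation with entity-safe boundary merging,
  cross-sentence relation flagging, relation-signature selection, and
  collapsing of fine-grained characteristic subtypes.
- **parse layer** (`relexkit.parse`) — tokens/POS, dependency graphs,
  constituency trees with Collins head finding, entity-to-node anchoring
  with suffix/prefix trimming, and labeled dependency paths. Parsing is a
  pluggable adapter contract; a deterministic rule-based
  `SimpleEnglishAdapter` is included so nothing external is required.
- **feature rules** (`relexkit.features`) — the 19 syntactic, lexical and
  supplementary rules (verb-in-dependency-path with a relation-verb
  lexicon, clause/SBAR features, negation and voice, entity windows,
  nominalization patterns, inter-entity statistics) producing named
  feature vectors.
- **models** (`relexkit.model`) — a MaxEnt (multinomial logistic) model
  trained with L-BFGS; the exact dynamic program for non-overlapping
  ARG/NONE assignment over a parse tree; bottom-up top-k joint semantic
  typing; trigger proposal with iterative trigger/argument optimisation;
  and per-signature relation classifiers over gold entity pairs.
- **baseline** (`relexkit.baseline`) — the semantically constrained
  sentential co-occurrence extractor, plus an optional same-string filter.
- **evaluation** (`relexkit.evaluation`) — exact-span relation matching,
  F-beta, seeded file-permutation k-fold cross-validation with both
  macro-over-folds and pooled-micro aggregation.
- **synthetic corpora** (`relexkit.synth`) — a seeded generator of brat
  corpora with planted relations, lexical triggers, trigger noise,
  distractor entities, cross-sentence relations and same-string multi-type
  annotations, together with an exact oracle.

## CLI

```bash
# generate a synthetic corpus + oracle
relexkit simulate --seed 1 --n-docs 20 --out corpus/

# co-occurrence baseline extractions for one relation signature
relexkit baseline --corpus corpus/ --signature cohort-has-disease \
    --same-string-filter off --out predictions.tsv

# cross-validated evaluation (baseline or trained model)
relexkit evaluate --corpus corpus/ --method model \
    --signature cohort-has-disease --folds 10 --seed 3 --beta 0.5 \
    --report report.tsv

# full experiment from a YAML config
relexkit run --config run.yaml --seed 3
```

Signatures are written `Arg1Type-predicate-Arg2Type` (e.g.
`cohort-has-disease`); `--signature all-studied` selects every signature
attested at least `--min-count` times. The seed is required everywhere
randomness enters; identical config + seed gives byte-identical reports.

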