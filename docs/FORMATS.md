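# File formats

All artifacts are plain text. Lines beginning with `# ` are header
metadata of the form `# key=value`; every numeric artifact records at
least `seed` and `config` (a 16-hex-digit hash of the generating
configuration). Floating-point values are written at full `repr`
precision, so identical configurations give byte-identical files.

## FASTA (input/output)

Standard multi-record FASTA, wrapped at 60 columns on output. Residues
may be lower case on input; only the 20 standard amino acids are
accepted.

## Localization TSV

One annotation per line, no header:

    <protein id> TAB <compartment>

A protein with several lines has multiple annotations (and is dropped by
the benchmark filter when unique localization is required).

## Pair TSV (`pairs.tsv`, `splits.tsv`)

Header row then one pair per line:

    idA TAB idB TAB label TAB split

* `label` — 1 interaction, 0 non-interaction
* `split` — one of `pretrain`, `holdout`, `nr_test`, `external`
  (optional on input; defaults to `pretrain`)

## Fold assignment TSV (`folds.tsv`)

    idA TAB idB TAB label TAB fold

`fold` is an integer in `[0, k)` from the stratified assignment.

## Removal report TSV (`removal_report.tsv`)

One removed hold-out pair per line:

    idA TAB idB TAB test_protein TAB train_protein TAB identity

`test_protein` is the pair member that triggered removal,
`train_protein` the first training protein at or above the identity
threshold, `identity` the alignment identity (4 decimals).

## Feature matrix TSV (`encode` output)

Header metadata (`scheme`, `dimensions`, `scaler`, `seed`, `config`),
then a column header `idA idB label x0 ... x{d-1}` and one row per pair.
`d` is 420 for AC pairs and 686 for CT pairs.

## Model JSON (`train` output)

A single JSON object:

* `model` — `layer_sizes`, `activation`, `seed`, per-layer
  `W_enc`/`b_enc`/`W_dec`/`b_dec`, `W_head`, `b_head` (nested lists)
* `scheme`, `lag_max` — encoding used at training time
* `scaler` — `min` and `range` arrays of the fitted min-max scaler
* `seed`, `config`, `training_accuracy`

Loading a saved model reproduces its predictions bit for bit.

## Metrics CSV (`crossval` output)

Header metadata, then:

    fold,accuracy,sensitivity,specificity,precision

one row per fold, followed by `mean` and `sd` rows. A metric with a
zero denominator in a fold is written as `NA`, never as 0.

## Predictions TSV (`predict` output)

    idA TAB idB TAB probability_interaction TAB label

`probability_interaction` is the softmax probability of class 1; `label`
is the argmax, with an exact 0.5 tie resolved to 0.
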