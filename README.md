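# odcert

Classify death certificates as drug-overdose deaths from their free-text
cause-of-death sections, before ICD-10 coding is available.

## Why

Overdose mortality surveillance identifies cases by the underlying
cause-of-death (UCOD) code — X40–X44, X60–X64, X85, or Y10–Y14 — that
NCHS assigns weeks to months after the death. The certifier's free text
("ACUTE COCAINE TOXICITY", "ACCIDENTAL OVERDOSE") exists from day one.
`odcert` is for epidemiologists in state and local health departments who
want provisional overdose counts in near real time: train a classifier on
last year's already-coded certificates (labels come free from the UCOD),
then score this year's uncoded ones as they arrive.

## Method

Selected free-text sections (immediate cause, "due to" lines, optionally
the "significant conditions contributing" (SCC) section, description of
injury) are merged into one uppercase field, punctuation becomes
whitespace, and features are binary indicators of word uni/bi/trigrams
(stop words removed, n-grams occurring in < 5 documents discarded). On
the feature vector **x** ∈ {0,1}^z three classifiers are supported — a
linear SVM (predict overdose iff **w·x** + b > 0), a random forest, and a
multilayer perceptron — each tuned by 3×-repeated stratified 10-fold
cross-validation maximizing F = 2·PPV·Sens/(PPV+Sens), with iterative
grid refinement around the best hyperparameter values, then refit on the
full training year. A keyword baseline (positive iff the text contains
any of a curated list of overdose words/bigrams, matched on token
boundaries) provides the traditional comparator, and one-tailed pooled
two-proportion z-tests compare the best ML model against it on
sensitivity and PPV. Excluding the SCC section typically improves PPV,
because SCC mentions of a *prior* overdose ("HISTORY OF DRUG OVERDOSE")
describe deaths that were not overdoses.

Real coded certificate data is restricted, so the package includes a
synthetic certificate generator (3% overdose prevalence, terse certifier
templates, SCC confounders, emerging test-year substances) that the test
suite and the reproduction script run end to end. See `docs/methods.md`
for the full model description and its limitations.

## Worked example

Simulate a coded training year and a test year in which a novel substance
(ISOTONITAZENE) starts appearing, then run the comparison:

```sh
odcert simulate --n 5000 --seed 1 --out y1.csv
odcert simulate --n 2000 --seed 2 --novel-drug isotonitazene --out y2.csv
printf 'families: [linear_svm]\n' > svm.yaml
odcert compare --train y1.csv --test y2.csv --config svm.yaml \
    --seed 1 --field-set no_scc
```

Output (~15 s; dropping the config trains the forest and MLP too):

```
Train records: 5000   Test records: 2000
Field set: no_scc

Method      PPV     Sensitivity  F-score
linear_svm  1.0000  0.9870       0.9935
rule_based  1.0000  0.8442       0.9155

Best ML model: linear_svm
Sensitivity, linear_svm vs rule_based: z = 3.1884, one-tailed p = 0.0007153
PPV, linear_svm vs rule_based: z = 0.0000, one-tailed p = 0.5
```

Reading it: of 77 true overdoses in the test year the SVM recovers 76
(sensitivity 0.987) with no false positives (PPV 1.0), while the keyword
list — which predates the novel substance — misses 12 (sensitivity
0.844); the sensitivity gap is significant (p < 0.001) and the PPV gap is
not, the expected pattern when rules fail by omission rather than by
over-firing. The same run with `--field-set all_sections` drops the
SVM's PPV (0.9868 at these seeds): SCC confounders cost precision.

Train/score against your own files with `odcert train` / `odcert
predict` (CSV or TSV with a header; column names mapped in a YAML config;
a UCOD column is only needed for training and evaluation). The shipped
phrase list is a synthetic stand-in — replace it with your
jurisdiction's.

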