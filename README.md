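# herbtox

Chemical-similarity based prediction of toxicity and drug interactions for
multi-compound herbal extracts, with dose-response synergy scoring.

The pipeline takes a table of herbal compounds with oral-bioavailability (OB)
and drug-likeness (DL) scores, screens out the active compounds
(OB ≥ 0.3 and DL ≥ 0.18), scores each against an annotated reference compound
library by combined fingerprint Tanimoto similarity, and transfers per-endpoint
toxicity verdicts from *indicator* compounds — similar compounds whose score
exceeds a calibrated similarity threshold.  The threshold itself is derived
from *first-elusive* and *first-contrast* prediction-similarity scores: the
largest similarity at which a retrieve becomes equivocal, or directly
contradicts, the verdict of the most similar annotated compound.  Predicted
drug interactions are split into single statements, classified into seven
activity categories by a transparent keyword lexicon, and exported as a
Cytoscape-loadable compound–partner network.  A synergy module quantifies
two-drug dose-response data via 4PL curve fitting, the Combination Index
(d1/Dx1 + d2/Dx2), and zero-interaction-potency (ZIP) delta scoring with
most-synergistic-area detection.

## Modules

| module | purpose |
| --- | --- |
| `herbtox.dataset` | compound-table ingestion, ADME screen, duplicate merging, persistence |
| `herbtox.simscreen` | path/circular fingerprints, Tanimoto, combined-score library screening |
| `herbtox.calibration` | first-elusive / first-contrast statistics, threshold derivation |
| `herbtox.prediction` | indicator-verdict aggregation, interaction splitting/classification, network export |
| `herbtox.synergy` | 4PL fitting, Combination Index, ZIP delta + most synergistic area |
| `herbtox.synthdata` | seeded synthetic fixtures for every stage (no downloads needed) |

The default similarity threshold (0.6171, the mean surviving first-contrast
score of the original 20-herb calibration corpus) ships as a documented
constant; the calibration module recomputes thresholds from any retrieve
table.

## CLI

```sh
herbtox make-fixtures --out demo --seed 1          # synthetic demo inputs
herbtox screen --in demo/compounds.csv --ob-min 0.3 --dl-min 0.18 --out active.csv
herbtox screen-lib --dataset active.csv --library demo/library.csv --floor 0.0 --out hits.csv
herbtox calibrate --retrieves demo/retrieves.csv --cutoff 0.3 --out calib/
herbtox predict --hits hits.csv --annotations annotations.csv --threshold 0.6171 --out pred/
herbtox network --edges edges.csv --format sif --out net.sif
herbtox synergy ci --dx1 70.48 --dx2 1.85 --d1 4.726 --d2 1.18
herbtox synergy zip --matrix demo/matrix.csv --out zip/
```

Input formats are plain delimited text throughout; dose-response matrices are
row-dose × col-dose grids whose first row/column are the monotherapy margins
(dose 0 of the partner drug).

## Scope notes

Live retrieval from similarity-search or compound-annotation web services is
out of scope: library screening and annotation ingestion operate on
user-supplied files, and `herbtox.synthdata` generates complete synthetic
stand-ins.  The expert reading of free-text interaction records is replaced by
an editable keyword lexicon (`herbtox.prediction.DEFAULT_LEXICON`); rows no
rule matches are surfaced as unclassified, never dropped.
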