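# simrepo

Similarity-based drug repositioning: predict new drug-disease treatment
associations from the combined similarity of a candidate pair to known
treatment pairs.

## The problem and the approach

Drug repositioning assigns new indications to existing compounds.  Under the
guilt-by-association premise — similar drugs treat similar diseases — a
candidate pair (drug *i*, disease *i′*) can be scored by how close it is to
the known treatment pairs (*j*, *j′*) of a curated gold standard.  `simrepo`
implements this end to end:

1. **Seven similarity kernels.**  Drug-drug: Tanimoto on binary molecular
   fingerprints (S_drChe), Jaccard on side-effect term sets (S_drSE),
   normalized Smith-Waterman over target proteins (S_drTar), and Resnik
   semantic similarity with best-match-average over the GO annotations of
   drug-related genes (S_drGO).  Disease-disease: GO similarity of
   disease-related genes (S_diGO), HPO term similarity (S_diHPO), and a
   precomputed phenotypic similarity matrix (S_diPhe).
2. **12 combined features.**  For each known association and each of the
   4 × 3 kernel combinations, the geometric mean
   F = sqrt(S_dr(i,j) · S_di(i′,j′)); each combination is aggregated over
   the known set by max (default) or mean.
3. **Classification under under-sampling.**  Logistic regression, four SVM
   variants and random forest, trained on gold positives vs 1:2 randomly
   under-sampled negatives, over repeated trials with stratified 10-fold
   cross-validation; metrics: accuracy, AUC, AUPR, sensitivity, specificity,
   precision.
4. **Consensus predictions.**  Non-gold pairs predicted positive in every
   trial are reported as novel indication candidates, ranked by mean
   probability.

A synthetic generator (`simrepo.synthetic`) produces complete,
cluster-structured inputs — fingerprints, side effects, target FASTA, gene
tables, GO/HPO ontologies in OBO format, annotations, a phenotype matrix and
gold/held-out association sets — with controllable noise, so the entire
pipeline is testable without access to licensed databases.  See
`docs/methods.md` for the model, its assumptions and the design choices.

## Worked example

```sh
simrepo simulate --clusters 3 --drugs-per-cluster 3 --diseases-per-cluster 3 \
    --noise 0.0 --seed 11 --out demo/
# wrote 9 drugs, 9 diseases, 22 gold associations to demo/

simrepo cv --data demo/ --algo random-forest --trials 2 --folds 5 --seed 0 --out demo/cv
# mean AUC 0.9669, mean accuracy 0.9313

simrepo predict --data demo/ --algo random-forest --trials 2 --folds 5 \
    --seed 0 --out demo/pred
# 1 consensus novel candidates among 59 queries
```

The cross-validation numbers say the classifier separates held-out gold
positives from sampled negatives almost perfectly on this zero-noise toy
(the AUC is the probability that a random positive outranks a random
negative; it sits below 1 here because a few withheld true associations are
inevitably sampled as negatives).  `demo/pred/predictions.tsv` lists every
queried pair with its mean predicted probability, the number of trials
voting positive (`support`), and `is_novel` — true only for pairs predicted
positive in all trials that are absent from the gold standard.  The single
consensus candidate,

```
drug_id   disease_id  mean_probability  support  is_novel
DR01_01   DI01_01     0.948460          2        True
```

is indeed one of the generator's withheld within-cluster treatment pairs.

The same steps are available as library calls (`simrepo.generate`,
`simrepo.compute_kernels`, `simrepo.cross_validate`,
`simrepo.predict_novel`), and `simrepo run --out dir/` executes the whole
pipeline with a JSON run manifest.

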