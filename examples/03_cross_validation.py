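"""Repeated stratified 5-fold cross-validation with pluggable classifiers.

Runs the full pipeline (per-fold selection + classification) under the
built-in weighted nearest-centroid predictor and under a k-NN plug-in,
then picks the better model by mean MCC — the model-comparison pattern
used when benchmarking feature-selection methods.
"""

from sklearn.neighbors import KNeighborsClassifier

from fscop import (
    FsCopConfig,
    SyntheticSpec,
    best_by_mcc,
    generate,
    repeated_cv,
    sklearn_classifier,
)

# moderate separation so the two classifiers can actually differ
data, _ = generate(SyntheticSpec(effect_size=1.5, seed=3))
config = FsCopConfig()

reports = {
    "centroid": repeated_cv(data, config, folds=5, repeats=5, base_seed=0),
    "knn3": repeated_cv(data, config, folds=5, repeats=5, base_seed=0,
                        classifier=sklearn_classifier(
                            lambda: KNeighborsClassifier(3))),
}

print(f"{'model':>10s}  {'Sn':>6s} {'Sp':>6s} {'Acc':>6s} {'Avc':>6s} {'MCC':>6s}")
for name, rep in reports.items():
    m = rep.means
    print(f"{name:>10s}  {m['sn']:6.3f} {m['sp']:6.3f} {m['acc']:6.3f} "
          f"{m['avc']:6.3f} {m['mcc']:6.3f}")

winner, _ = best_by_mcc(reports)
print(f"\nbest model by mean MCC: {winner}")
# Each row pools the 5 folds of each repeat into one confusion table and
# averages the resulting per-repeat metrics over the 5 repeats.
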