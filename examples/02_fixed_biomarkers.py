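"""Force a known biomarker into the selection and measure the cost.

Emulates the typical use case: a feature the literature says matters
(here deliberately an *uninformative* one, the hardest case) is fixed
via a weight lower bound, so it is guaranteed a place in the final
subset.  We compare cross-validated MCC with and without the
constraint — the point being that honoring prior knowledge should not
wreck the classifier.
"""

from fscop import (
    FsCopConfig,
    SyntheticSpec,
    generate,
    inject_fixed_noise_feature,
    repeated_cv,
)

data, truth = generate(SyntheticSpec(seed=2))
fixed = inject_fixed_noise_feature(data, truth, k=1)
fixed_id = next(iter(fixed))
print(f"forcing uninformative feature {fixed_id!r} into the selection")

plain = repeated_cv(data, FsCopConfig(), folds=5, repeats=5, base_seed=0)
constrained = repeated_cv(data, FsCopConfig(fixed=fixed), folds=5, repeats=5,
                          base_seed=0)

print(f"mean MCC unconstrained:  {plain.means['mcc']:.3f}")
print(f"mean MCC with fixed f.:  {constrained.means['mcc']:.3f}")
freq = constrained.selection_frequency()
print(f"{fixed_id!r} selected in {freq[fixed_id]:.0%} of folds")
# The fixed feature appears in every fold (the bound guarantees it) and
# the MCC drops only slightly: the LP compensates by giving the truly
# informative features enough weight to out-vote the forced noise.
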