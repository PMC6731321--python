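"""Generate a synthetic paclitaxel dataset and recover its parameters.

Simulates 8 replicate wells of 25 nM paclitaxel monotherapy (noiseless, so
the recovery is sharp), then runs the sequential calibration (growth
parameters from the drug-free first day, drug parameters from days 1-4 by
multistart least squares) and prints fitted vs generating values.
"""

from pactmab import (
    GeneratorSpec,
    NoiseModel,
    ParamBounds,
    build_schedule,
    fit_pretreatment,
    fit_single_drug,
    generate_dataset,
)
from pactmab.generate import default_truth

regimen = build_schedule("paclitaxel_only", pac_dose=25.0)
truth = default_truth("paclitaxel_only", pac_dose=25.0)
dataset, _ = generate_dataset(
    GeneratorSpec(truth=truth, regimen=regimen, noise=NoiseModel(scale=0.0), seed=7)
)

control_range = ParamBounds(
    {"k": (0.6, 1.1), "theta": (0.5, 0.9)}, provenance="control-derived"
)
pre = fit_pretreatment(dataset, control_range, seed=0)
print(f"pre-treatment fit: k = {pre.params.k:.3f} (truth {truth.k}), "
      f"theta = {pre.params.theta:.3f} (truth {truth.theta})")

result = fit_single_drug(
    dataset, regimen, "paclitaxel", pre.params.k, pre.params.theta,
    n_starts=20, seed=0,
)
print(f"post-treatment fit (weighted L2 = {result.objective:.2f}, "
      f"CCC = {result.ccc:.3f}):")
for name, value in result.fitted_values().items():
    print(f"  {name:9s} fitted {value:7.3f}   truth {getattr(truth, name):7.3f}")
print(
    "\nOn noiseless data the four drug parameters land on the generating"
    "\nvalues; at experimental noise the magnitude/uptake pair is only"
    "\njointly constrained (see docs/methods.md on identifiability)."
)
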