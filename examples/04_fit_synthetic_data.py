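"""Parameter recovery on a synthetic PK dataset.

Generates noisy plasma/urine observations from a known parameterization,
then refits the RA urinary clearance coefficient from a deliberately
wrong (2x) starting value with Nelder-Mead on the RMSE objective.
"""

from mph_pbpk import scenarios
from mph_pbpk.calibration import fit, generate_synthetic_dataset

pop = scenarios.adult_human("iv")
ds = generate_synthetic_dataset(
    pop, scenarios.single_iv_dose(10.0),
    ["d-MPH", "l-MPH", "urine d-RA", "urine l-RA"],
    sampling_times=(0.5, 1, 2, 3, 4, 6, 8, 12, 16),
    noise_sigma=0.1, n_subjects=5, seed=42)

truth = 0.305  # generating Ku_RAdC, L/h/kg^0.75
res = fit(pop, {"Ku_RAdC": (2 * truth, 0.1, 1.2)}, [ds])
est = res.parameters["Ku_RAdC"]
print(f"true Ku_RAdC      : {truth}")
print(f"start (2x)        : {2 * truth}")
print(f"estimate          : {est:.4f}  ({100 * (est / truth - 1):+.1f}%)")
print(f"RMSE start -> end : {res.start_objective:.3f} -> {res.objective:.3f}")
print(f"converged         : {res.converged} ({res.n_evaluations} evaluations)")
# With 10% multiplicative noise on 5 subjects the estimate lands within a
# few percent of truth; on noiseless data the recovery is exact.
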