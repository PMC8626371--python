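"""Simulate a labelling experiment and recover the turnover rate.

A two-site acetylation model: each site swaps its light acetyl group for
a labelled one with first-order rate k, so the M+0/M+2/M+4 fractions are
(1-f)^2, 2f(1-f), f^2 with f = 1 - exp(-k t).  The simulator contaminates
the true fractions with natural isotopes (forward model) and adds
multiplicative measurement noise; correction plus a linear fit should
recover the initial slope.
"""

import pandas as pd

import skewcor as sc
from skewcor.simulate import SimulationSpec, simulate_timecourse

formula = sc.peptide_formula("KQLATKAAR", ["acetyl", "acetyl"])
model = sc.ResolutionModel(60000, 200)
matrix = sc.build_matrix(formula, ["No label", "2C13", "4C13"], model, charge=2)

spec = SimulationSpec(matrix=matrix, rate=0.014, noise_cv=0.02, seed=42)
data = simulate_timecourse(spec)
print("simulated observed intensities (first rows):")
print(data.head(3).round(0))

result = sc.correct(data.drop(columns="time"), matrix)
corrected = (result.fractions * 100).assign(time=data["time"])

truth = pd.DataFrame(
    {
        "time": spec.times,
        "2C13": [100 * spec.true_fractions(t)[1] for t in spec.times],
    }
)
true_fit = sc.fit_slope(truth, "2C13")
fit = sc.fit_slope(corrected, "2C13")
print(f"\ntrue M+2 slope (noise-free fractions): {true_fit.slope:.3f} %/h")
print(f"recovered from corrected noisy data:   {fit.slope:.3f} ± {fit.stderr:.3f} %/h")
print(
    "\nAgreement within the standard error shows the correction inverts the "
    "natural-abundance contamination without biasing the dynamics."
)
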