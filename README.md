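# ppase-kinetics

Kinetic analysis of membrane-bound inorganic pyrophosphatases (mPPases) —
H⁺-pumping (e.g. the plant vacuolar enzyme AVP1) and Na⁺-pumping (e.g. the
archaeal enzyme MVP) proton/sodium pumps that hydrolyse inorganic
pyrophosphate.  The package is for enzymologists who assay these enzymes in
microsomal membranes and need to go from raw replicate rates to publishable
kinetic parameters.

It provides, as a library and a CLI:

* **Substrate speciation.**  The true substrate is the dimagnesium complex
  Mg₂PPi.  Given the total concentrations of PPi, Mg²⁺, K⁺ and Na⁺ and the
  buffered pH, the speciation solver distributes PPi among its H⁺/Mg²⁺/K⁺/Na⁺
  complexes (stepwise dissociation constants, user-overridable table) and
  returns S = [Mg₂PPi].  PPi is added as the tetrasodium salt, so a basal
  Na⁺ = 4 × PPi is always accounted for.
* **Rate laws.**  The empirical Hill equation
  v = V·Sⁿᴴ/(K₀.₅ⁿᴴ + Sⁿᴴ), and a two-state concerted (MWC-type) allosteric
  model for a homodimer with two catalytic sites, exclusive binding to the
  active R state and substrate-stabilised R:

      v/Vm = Ŷ = (S/K_R)(1+S/K_R) / [ (1+S/K_R)² + L/(1+S/K_R)² ]

  where L = [T]/[R] is the allosteric constant and K_R the substrate
  dissociation constant toward R.  L = 0 collapses to Michaelis–Menten with
  Km = K_R.
* **Weighted fitting.**  Replicates (3–5 per point) are collapsed to mean
  points weighted 1/variance; parameters are estimated by bounded, multi-start
  nonlinear least squares with asymptotic standard errors
  (cov = s²(JᵀWJ)⁻¹, s² = wSSE/(N−p)).  Substrate-inhibited points can be
  truncated before fitting.
* **Salt-sensitivity summaries.**  Percent decrease of Vm versus the
  0-mM-NaCl reference and fold changes, per enzyme and salt level.
* **A synthetic assay generator** reproducing the two standard designs
  (matched Mg = 2 × PPi; fixed MgCl₂ with a PPi titration) with seeded,
  replicate-level Gaussian noise — so the whole pipeline is testable without
  wet-lab data.

## Worked example

Simulate a matched-Mg salt series for an AVP1-like enzyme (allosteric truth
Vm = 0.51 U/mg, L = 17, K_R = 84 µM at 0 mM NaCl), refit it, and summarise
the salt sensitivity:

```python
import numpy as np
from ppase_kinetics import (
    AnalysisConfig, ComplexationConstants, MWCParams, SyntheticConfig,
    matched_design_for_substrate, run_analysis, simulate_assay,
)

constants = ComplexationConstants.default()
design = matched_design_for_substrate(nacl_levels=[0.0, 50.0, 100.0],
                                      constants=constants)
truth = {0.0: MWCParams(0.51, 17, 84),
         50.0: MWCParams(0.40, 50, 64),
         100.0: MWCParams(0.24, 106, 69)}
records = simulate_assay(design, SyntheticConfig(truth=truth, seed=42),
                         enzyme="AVP1", constants=constants)
result = run_analysis(records, AnalysisConfig(models=("mwc",),
                                              constants=constants))
print(result.parameter_table[["nacl_mM", "vm_display", "l_display",
                              "k_r_display"]].to_string(index=False))
print(result.sensitivity[["nacl_mM", "percent_decrease",
                          "percent_decrease_rounded10"]].to_string(index=False))
```

Output (seed 42):

```
 nacl_mM      vm_display  l_display k_r_display
     0.0 0.4803 ± 0.0085 19.2 ± 4.0  75.7 ± 5.8
    50.0   0.380 ± 0.014    74 ± 20  57.3 ± 6.1
   100.0   0.264 ± 0.024    41 ± 22    103 ± 23

 nacl_mM  percent_decrease  percent_decrease_rounded10
    50.0         20.855719                        20.0
   100.0         44.991462                        40.0
```

Read: the fitted maximal rate (estimate ± asymptotic SE) drops from
≈0.48 U/mg to ≈0.26 U/mg across the NaCl series while the allosteric
constant L stays well above its Michaelian limit — sodium displaces the
R⇌T equilibrium toward the inactive T state — and the summary reports a
~21% and ~45% Vm decrease at 50 and 100 mM NaCl for this single noisy
realisation (the median over many seeds recovers the generating values;
see `scripts/acceptance.py`).

The same workflow from the shell:

```sh
ppase-kinetics simulate --config sim.yaml --seed 42 --out records.tsv
ppase-kinetics report --model mwc --in records.tsv --out-dir report/
ppase-kinetics speciate --ppi 0.1 --mg 0.2 --na 0.4   # one speciation point
```

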