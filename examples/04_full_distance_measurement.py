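"""The complete workflow: calibrate, image, select, estimate.

Simulates a bead calibration and a small PICT-style cell dataset with a
20 nm true anchor-prey separation, runs every pipeline stage into a run
directory, and prints the final Rician fit.  Rerunning with the same
configuration reuses the cached stage outputs byte-identically.
"""

import numpy as np

from f2f import EstimationConfig, RunConfig, run_workflow
from f2f.registration import AffineMap

cfg = RunConfig(seed=5, estimation=EstimationConfig(n_boot=50))
distortion = AffineMap.from_arrays(1.001 * np.eye(2), np.array([0.5, -0.3]))

result = run_workflow(cfg, "scratch/example_run", simulate={
    "distortion": distortion,
    "n_fov_beads": 20, "n_fov_cells": 4,
    "n_cells": 10, "pairs_per_cell": 2,
    "true_sep_nm": 20.0, "loc_noise_nm": 7.0,
})

fit = result.fit
n_pass = int(result.pairs[[c for c in result.pairs
                           if c.startswith("pass_")]].all(axis=1).sum())
print(f"registration TRE: {result.tre_nm:.3f} nm (gate: < 1 nm)")
print(f"{len(result.pairs)} linked pairs, {n_pass} pass all filters")
print(f"estimated separation: mu = {fit.mu:.2f} +/- {fit.mu_se:.2f} nm "
      f"(truth 20 nm)")
print(f"localization noise:   sigma = {fit.sigma:.2f} nm")
print(f"outlier rejection trimmed {fit.trim_fraction:.1%} "
      f"({fit.n_total - fit.n_used} of {fit.n_total} distances)")
print(f"stage outputs cached under {result.out_dir}/")
# sigma combines the simulated 7 nm per-channel jitter (sqrt(2)*7 = 9.9 nm)
# with the residual centroiding error; mu recovers the 20 nm truth within
# the 2-5 nm precision envelope of the method.
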