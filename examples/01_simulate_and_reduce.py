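"""Simulate raw measurement batches and reduce them to δ15N_EB values.

Builds a small synthetic food web, turns its teeth into raw per-analysis
records (nitrate/amino-acid references, blanks, standard triplicates,
samples mixed with an oxidation blank), then calibrates and blank-corrects
back to per-specimen values.
"""

import warnings

import numpy as np

from paleotroph import default_config, reduce_dataset, simulate_foodweb, simulate_raw_batch

cfg = default_config(seed=0)
ecology, teeth = simulate_foodweb(cfg)
raw = simulate_raw_batch(teeth, cfg)
print(f"{len(teeth)} teeth -> {len(raw)} raw analyses in {raw['batch_id'].nunique()} batches")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # a few low-N samples trip the blank-fraction QC
    result = reduce_dataset(raw)

joined = teeth.merge(result.samples, on="specimen_id", suffixes=("", "_red"))
err = joined["d15n_eb_red"] - joined["true_d15n_eb"]
print(f"recovery of true d15N_EB: bias {err.mean():+.3f} permil, SD {err.std(ddof=1):.3f} permil")
print(f"  ({np.mean(np.abs(err) < 3 * cfg.meas_sd_eb):.1%} of specimens within 3 analytical SDs)")

qc = result.qc.summary.set_index("standard").loc["enameloid-standard"]
print(
    f"in-house standard: within-batch SD {qc['avg_within_sd_d15n']:.2f} permil, "
    f"long-term SD {qc['longterm_sd_d15n']:.2f} permil"
)
print("The long-term SD exceeds the within-batch SD because each batch's")
print("cleaning step shifts the standard slightly; that batch effect is the")
print("dominant term in the ~0.7 permil whole-method reproducibility.")
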