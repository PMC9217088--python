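"""Ground-truth enameloid-bound δ15N against dentin collagen δ15N.

Thirteen modern sand tiger shark teeth carry both tissues; the Deming
regression (errors-in-variables, SD ratio 3.5 = 0.7/0.2) tests whether the
enameloid-bound signal tracks the established dentin collagen recorder.
"""

from paleotroph import default_config, deming_fit, pearson_test, simulate_foodweb, tissue_offset
from paleotroph.synthetic import extract_tissue_pairs

cfg = default_config(seed=0)
_, teeth = simulate_foodweb(cfg)
pairs = extract_tissue_pairs(teeth, species="Carcharias taurus")
print(f"{len(pairs)} paired modern teeth (generated with slope 1, offset 1.7 permil)")

fit = deming_fit(pairs, error_sd_ratio=3.5, n_bootstrap=10_000, seed=0)
print(
    f"Deming: d15N_EB = {fit.slope:.2f} "
    f"[{fit.slope_ci_95[0]:.2f}, {fit.slope_ci_95[1]:.2f}] x d15N_dentin "
    f"+ {fit.intercept:.1f} [{fit.intercept_ci_95[0]:.1f}, {fit.intercept_ci_95[1]:.1f}] permil"
)
corr = pearson_test(pairs)
print(f"Pearson r = {corr.r:.2f}, t = {corr.t_statistic:.2f}, df = {corr.df}, "
      f"p = {corr.p_two_sided:.4f}")
off = tissue_offset(pairs)
print(f"tissue offset (EB - dentin): {off.mean_offset:.1f} +/- {off.sd_offset:.1f} permil")
print("A slope CI spanning 1 and an offset near the generating 1.7 permil mean")
print("the enameloid-bound nitrogen records the same dietary signal as dentin")
print("collagen, shifted by a fixed tissue offset - the basis for reading")
print("trophic level from fossil teeth.")
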