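"""Scenario presets, parameter rescaling and genome-layout construction.

Builds the reference 4 Mb fragment (high/low/high recombination at 1:2:1 with
doubled coding density in the high regions) after rescaling the
million-diploid population down to N = 1000, and prints what the rescaling
preserves.
"""

import numpy as np

from tepop.genome_model import build_layout, rescale_parameters, scenario_preset

raw = scenario_preset("fig9C")
params = rescale_parameters(raw, lam=1000.0)

print(f"scenario fig9C: insertion bias Q = {raw.te_params.Q}, "
      f"constant transposition = {raw.te_params.constant_mode}")
print(f"unscaled: N_e = {raw.N_e:,}, mu = {raw.mu:g}/bp/gen")
print(f"rescaled: N = {params.N_scaled}, mu = {params.mu_scaled:g}, "
      f"generations = {params.generations_scaled:,}")
print(f"theta = 4*N*mu preserved: {4 * params.N_scaled * params.mu_scaled:g} "
      f"== {4 * raw.N_e * raw.mu:g}")
print(f"2Ns = -100 maps to s = {params.s_of(-100.0)} at the reduced size")

layout = build_layout(params, np.random.default_rng(1))
for r in layout.regions:
    bp = layout.exon_bp_in(r.start, r.end)
    print(f"region [{r.start:>9,}, {r.end:>9,}) {r.klass:>4}  "
          f"rec={r.rec_rate:g}/bp  coding={bp / (r.length / 1e6):,.0f} bp/Mb")
# The coding density always lands in [target, target + one exon): exons are
# placed at random until the per-Mb target is reached.
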