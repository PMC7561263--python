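"""A reduced-scale forward simulation of TE and point-mutation dynamics.

Runs the constant-transposition scenario on a 1 Mb fragment with N = 100
diploids for 2,000 generations (the rescaling keeps every population-scaled
parameter at its full-size value) and summarizes the final population.
"""

import numpy as np

from tepop.forward_sim import run_simulation
from tepop.genome_model import reduced_scale, scenario_preset

params = reduced_scale(
    scenario_preset("fig9A"),
    N_scaled=100,
    fragment_length=1_000_000,
    generations_scaled=2000,
)
res = run_simulation(params, seed=42)
st = res.state

n_te = int((st.is_te == 1).sum())
n_snp = st.n_segregating - n_te
counts = st.counts()
twoN = 2 * st.N
pi = np.sum(2 * counts * (twoN - counts) / (twoN * (twoN - 1))) / 1e6
theta = 4 * params.N_scaled * params.mu_scaled

print(f"after {st.generation:,} generations:")
print(f"  segregating point mutations: {n_snp}")
print(f"  segregating TE insertions:   {n_te}")
print(f"  substitutions (fixed):       {st.n_substitutions}")
print(f"  TE insertion events high/low regions: "
      f"{st.te_draws_high}/{st.te_draws_low} (no bias: Q = 0.5)")
print(f"  nucleotide diversity pi = {pi:.3e} vs neutral theta = {theta:.3e}")
# pi falls below 4*N*mu because deleterious mutations at linked sites remove
# neutral diversity (background selection), most strongly in the low
# recombination interior of the fragment.
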