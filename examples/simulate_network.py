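"""Validate the analytics on explicit random networks.

Generates configuration-model cross-feeding networks and iterates the
presence rules (consumers need ALL requirements; metabolites need ANY
producer) to a fixed point, then compares the persisting fractions with
the generating-function prediction.
"""

from crossfeednet import (
    CommunityEnsemble,
    find_fixed_points,
    generate_network,
    percolate,
)

N = M = 2000
z_c, z_m = 4.5, 4.0  # bistable region: the two initialisations disagree

net = generate_network(N, M, z_c, z_m, seed=1)
fps = find_fixed_points(CommunityEnsemble.poisson(z_c, z_m))

up = percolate(net, init="all_present", seed=1)
down = percolate(net, init="all_absent", seed=1)
print(f"network: N = M = {N}, z_c = {z_c}, z_m = {z_m}")
print(f"from all-present: c_hat = {up.c_hat:.4f}  (analytic high branch "
      f"c* = {fps[-1].c_star:.4f})")
print(f"from all-absent:  c_hat = {down.c_hat:.4f}  (analytic low branch "
      f"c* = {fps[0].c_star:.4f})")
print(
    "\nThe same network supports two self-consistent communities; the "
    "initial state\nselects the branch, matching the analytic bistability."
)
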