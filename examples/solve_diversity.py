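"""Solve for community diversity from network structure alone.

For a random cross-feeding community where consumers require on average
z_c metabolites and each metabolite has on average z_m producers, the
persisting fractions (c*, m*) solve c* = exp(-z_c exp(-z_m c*)).
"""

from crossfeednet import CommunityEnsemble, find_fixed_points

for z_c, z_m in [(2.0, 4.0), (4.5, 4.0), (7.0, 4.0)]:
    ens = CommunityEnsemble.poisson(z_c, z_m)
    print(f"\nz_c = {z_c}, z_m = {z_m}:")
    for fp in find_fixed_points(ens):
        print(
            f"  c* = {fp.c_star:.4f}  m* = {fp.m_star:.4f}  "
            f"g'(c*) = {fp.map_derivative:.3f}  [{fp.stability}]"
        )

print(
    "\nOne root means a unique community state; three roots (stable-"
    "unstable-stable)\nmean the community is bistable: which diversity it "
    "shows depends on its history."
)
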