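"""Extract active-site strings through both routes and apply the gates.

The 2D route reads pocket columns off the MSA; the 3D route maps pocket
positions through each member's pairwise alignment to the reference.  Members
below 30% identity to the reference and sites with more than half their
positions gapped are discarded and logged.
"""

from asclust import FamilySpec, generate_family
from asclust.pipeline import extract_sites_2d, extract_sites_3d
from asclust.synthetic import REFERENCE_ID

fx = generate_family(FamilySpec(seed=1))

sites_2d, discards_2d = extract_sites_2d(fx.msa, fx.pocket, REFERENCE_ID)
sites_3d, discards_3d = extract_sites_3d(
    fx.pairwise, {REFERENCE_ID: fx.pocket},
    {REFERENCE_ID: fx.reference.sequence})

print(f"2D route: {len(sites_2d)} sites kept, {len(discards_2d)} discarded")
print(f"3D route: {len(sites_3d)} sites kept, {len(discards_3d)} discarded")
print(f"example: {sites_2d[0].member_id} -> {sites_2d[0].site}")
print("The site string is the member's residue at each reference pocket")
print("position; '-' marks a pocket position deleted in that member.")
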