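"""Infer carotenoid end products from an organism's enzyme-family complement.

Builds three small enzyme profiles against the shipped pathway registry
and prints what each organism can synthesize. End products are reachable
compounds with no applicable downstream reaction; dead ends are enzymes
present without a reachable substrate (candidate annotation errors or
decayed pathways); "incomplete" marks end products the full registry could
process further.
"""

from carotevol import EnzymeProfile, load_registry, reconstruct_profile

graph = load_registry()

profiles = [
    # canonical bicyclic xanthophyll producer: GGPP -> ... -> zeaxanthin
    EnzymeProfile("zeaxanthin_producer", frozenset({"CrtB", "CrtI:4-step", "CrtY", "CrtZ"}), rhodopsin=True),
    # C30 branch (e.g. staphylococci): FPP -> 4,4'-diapolycopene
    EnzymeProfile("c30_producer", frozenset({"CrtM", "CrtN:4-step"})),
    # cyanobacterial-style desaturation chain missing the CrtH isomerase
    EnzymeProfile("decayed_pathway", frozenset({"CrtB", "CrtP", "CrtQ", "CrtZ"})),
]

for profile in profiles:
    call = reconstruct_profile(profile, graph)
    print(f"{call.organism_id}:")
    print(f"  end products : {sorted(call.end_products)}")
    print(f"  dead ends    : {sorted(call.dead_ends)}")
    print(f"  incomplete   : {sorted(call.incomplete_products)}")
    print(f"  rhodopsin    : {call.rhodopsin}")

# The first organism resolves to zeaxanthin alone; the second stops at the
# C30 carotene; the third stalls at the cis-lycopene intermediate, leaving
# its hydroxylase CrtZ as a dead end - the signature of a gene-loss-decayed
# or mis-annotated pathway.
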