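"""How the hierarchical, edit-tiered read assignment resolves ambiguity.

Categories claim reads in a fixed priority order (rRNA before hairpin before
tRNA ...), so a sequence present verbatim in both an rRNA and a tRNA
reference is booked as rRNA; removing the rRNA decoy flips it to tRNA.
Raising the edit budget (tier 0 = exact, tier 1 = one edit, tiers 2-3 = two /
three substitutions) rescues mutated reads without ever stealing reads from
a lower tier.
"""
import dataclasses

from trfkit import assign_sequences, references_from_dict
from trfkit.synthetic import generate_references, small_scenario

config = dataclasses.replace(small_scenario(seed=4), collision_decoys=True)
refs = generate_references(config)
categories = refs.reference_categories()

planted = refs.genes[0].sequence[:26]
(hit,) = assign_sequences([planted], categories).values()
print(f"read planted in rRNA decoy AND tRNA -> claimed by {hit.category} (tier {hit.edit_tier})")

background = {k: dict(v) for k, v in refs.background.items()}
del background["rRNA"]["rRNA_decoy_tRF"]
background["tRNA"] = {g.gene_id: g.sequence for g in refs.genes}
(hit2,) = assign_sequences([planted], references_from_dict(background)).values()
print(f"after removing the decoy            -> claimed by {hit2.category} "
      f"({hit2.gene_hits[0][0]}:{hit2.gene_hits[0][1]}-{hit2.gene_hits[0][2]})")

mutated = "G" + planted[1:] if planted[0] != "G" else "A" + planted[1:]
for tier in (0, 1):
    (m,) = assign_sequences([mutated], categories, max_tier=tier).values()
    print(f"read with one substitution, max_tier={tier} -> {m.category}"
          + (f" (tier {m.edit_tier})" if m.edit_tier is not None else ""))
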