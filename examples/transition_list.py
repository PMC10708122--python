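"""Scheduled-PRM transition list for a crosslinked pair.

Enumerates the b/y fragment transitions of both peptides (indices >= 3,
fragment charges 1-2, each with and without the crosslink mass) and exports
them as a transition list a PRM scheduler can ingest.
"""

from pathlib import Path

from xlinkprm import CrosslinkPair, generate_transitions, write_transition_list

pair = CrosslinkPair.from_sequences("KESYSVYVYK", "TVTAMDVVYALK", crosslink_mass=12)
target = generate_transitions(pair, charge=4, rt_center=74.9)

print(f"{pair.label} at 4+ -> {len(target.transitions)} transitions")
print(f"RT window: {target.rt_start:.1f}-{target.rt_end:.1f} min "
      "(six minutes around the scheduled retention time)")
for frag in target.transitions[:6]:
    print(f"  {frag.name:<12} m/z {frag.mz:.4f}")
print("  ... (+CM names mark the variants carrying the +12 Da crosslink mass)")

out = Path("scratch_transitions.tsv")
write_transition_list([target], out)
print(f"\nFull list written to {out} "
      "(precursor m/z, fragment m/z, names, RT window per row).")
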