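"""Discovery-stage pre-filters on simulated DDA spectra.

Simulates DDA spectra (crosslink spectra assigned to single conditions plus
background spectra shared by all conditions), then applies the two
pre-search filters: removal of precursors heavier than 8 kDa and
restriction to spectra unique to one tube condition. Finally demonstrates
the candidate confidence filter (matched-fragments / total-length > 1.5).
"""

from xlinkprm import (
    CrosslinkPair,
    SimulationConfig,
    filter_candidates,
    filter_precursor_mass,
    group_unique_spectra,
    simulate_dda_mgf,
)
from xlinkprm.spectra import CandidateRecord

by_group, truth = simulate_dda_mgf(SimulationConfig(seed=11))
print("Simulated DDA spectra per condition (crosslinks + shared background):")
for g, spectra in by_group.items():
    print(f"  {g}: {len(spectra)}")

filtered = {g: filter_precursor_mass(s, max_mass=8000.0) for g, s in by_group.items()}
unique = group_unique_spectra(filtered, mz_tol=0.01, rt_tol=2.0)
print("\nAfter the 8 kDa precursor filter and the condition-uniqueness filter:")
for g, spectra in unique.items():
    expected = truth.unique_titles_by_group[g] - truth.heavy_titles
    status = "matches ground truth" if {s.title for s in spectra} == expected else "MISMATCH"
    print(f"  {g}: {len(spectra)} spectra ({status})")
print("Background spectra are shared across conditions, so they all vanish.")

pair = CrosslinkPair.from_sequences("AGYLEKR", "RIYQFTAASPK", 24)
candidates = [
    CandidateRecord(pair=pair, z=4, n_fragments_matched=n, rt=40.2)
    for n in (34, 27, 20)
]
kept = filter_candidates(candidates, threshold=1.5)
print("\nCandidate confidence filter (ratio = matched fragments / summed length):")
for c in candidates:
    print(f"  {c.n_fragments_matched} fragments -> ratio {c.score_ratio:.3f} "
          f"{'kept' if c in kept else 'removed'}")
print("A ratio of exactly 1.5 is removed: the threshold is strict.")
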