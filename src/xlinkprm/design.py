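"""The blood-collection-tube study layout: 4 tube conditions x 3 donors.

Groups: S (Streck cfDNA tube), F (EDTA + formaldehyde), E (untreated EDTA),
A (EDTA + allantoin). One PBMC sample per (group, donor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

GROUPS = ("S", "F", "E", "A")


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of sample ids to (group, donor)."""

    samples: tuple[tuple[str, str, int], ...]  # (sample_id, group, donor)

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.samples)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(s[1] for s in self.samples))

    def group_of(self, sample_id: str) -> str:
        return self._by_id()[sample_id][0]

    def donor_of(self, sample_id: str) -> int:
        return self._by_id()[sample_id][1]

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s[0] for s in self.samples if s[1] == group)

    def _by_id(self) -> dict[str, tuple[str, int]]:
        return {s[0]: (s[1], s[2]) for s in self.samples}


def default_design(n_donors: int = 3) -> SampleDesign:
    """The complete 4-group x n-donor factorial layout (ids like 'S1')."""
    return SampleDesign(
        samples=tuple(
            (f"{g}{d}", g, d) for g in GROUPS for d in range(1, n_donors + 1)
        )
    )
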