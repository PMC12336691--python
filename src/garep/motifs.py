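"""One-wildcard CDR3 motifs.

A motif generalizes an amino-acid clonotype by freeing exactly one
junction position (written ``x``) while keeping the V and J genes and
the junction length fixed: ``CASSxHGGEQYF + TRBV05-06 + TRBJ02-07``
matches any clonotype of the same V/J and length agreeing at every
non-wildcard position. All member clonotypes of a motif are therefore
pairwise within Hamming distance 2 of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import SequenceKey

WILDCARD = "x"

__all__ = ["WILDCARD", "MotifKey", "matches_motif"]


def matches_motif(pattern: str, junction_aa: str) -> bool:
    """True if ``junction_aa`` fits the wildcard ``pattern`` (same length,
    equal at every non-wildcard position)."""
    if len(junction_aa) != len(pattern):
        return False
    return all(p == WILDCARD or p == a for p, a in zip(pattern, junction_aa))


@dataclass(frozen=True)
class MotifKey:
    """A one-wildcard public motif with its observed member clonotypes."""

    pattern: str
    v_gene: str
    j_gene: str
    members: frozenset[SequenceKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pattern.count(WILDCARD) != 1:
            raise ValueError(f"motif pattern {self.pattern!r} must contain exactly one {WILDCARD!r}")
        for m in self.members:
            if not (
                m.v_gene == self.v_gene
                and m.j_gene == self.j_gene
                and matches_motif(self.pattern, m.junction_aa)
            ):
                raise ValueError(f"member {m} does not match motif {self}")

    def matches(self, key: SequenceKey) -> bool:
        return (
            key.v_gene == self.v_gene
            and key.j_gene == self.j_gene
            and matches_motif(self.pattern, key.junction_aa)
        )

    def __str__(self) -> str:
        return f"{self.pattern}+{self.v_gene}+{self.j_gene}"
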