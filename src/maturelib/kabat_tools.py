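"""Framework-region analytics on Kabat-delimited antibody sequences.

Antibody variable-domain frameworks (FR1-4) are strongly conserved and fall
into Kabat subgroups by sequence similarity.  This module works on
pre-delimited framework segments — V_H FR1 (positions 1-30), FR2 (14), FR3
(32) and FR4 (11), 87 positions in total — and provides percent identity,
subgroup assignment by maximum framework identity, and per-position residue
frequency tables with most-common-amino-acid (MCA) extraction.

Full Kabat numbering of raw sequences (insertion codes such as 52a) is out of
scope; inputs are fixed-length, already-aligned segments, with ``-`` for gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .codon_algebra import AMINO_ACIDS

__all__ = [
    "FR_LENGTHS",
    "TOTAL_FR_POSITIONS",
    "FrameworkSegments",
    "SubgroupProfile",
    "IdentityResult",
    "SubgroupAssignment",
    "FrequencyTable",
    "percent_identity",
    "assign_subgroup",
    "frequency_table",
    "most_common",
]

#: Kabat framework-segment lengths for the heavy-chain variable domain.
FR_LENGTHS = {"fr1": 30, "fr2": 14, "fr3": 32, "fr4": 11}
TOTAL_FR_POSITIONS = sum(FR_LENGTHS.values())  # 87

GAP = "-"
_ALLOWED = AMINO_ACIDS | {GAP}


@dataclass(frozen=True)
class FrameworkSegments:
    """The four framework segments of one V_H, 87 positions in total."""

    fr1: str
    fr2: str
    fr3: str
    fr4: str

    def __post_init__(self) -> None:
        for name, expected in FR_LENGTHS.items():
            seg = getattr(self, name).upper()
            if len(seg) != expected:
                raise ValueError(
                    f"{name} must have exactly {expected} residues, got {len(seg)}"
                )
            bad = set(seg) - _ALLOWED
            if bad:
                raise ValueError(f"{name} contains invalid characters: {sorted(bad)}")
            object.__setattr__(self, name, seg)

    def concatenated(self) -> str:
        return self.fr1 + self.fr2 + self.fr3 + self.fr4


@dataclass(frozen=True)
class SubgroupProfile:
    """A Kabat subgroup's most-common-residue framework consensus."""

    name: str
    segments: FrameworkSegments


@dataclass(frozen=True)
class IdentityResult:
    """Framework identity between two segment sets."""

    matches: int
    total: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.matches, self.total)

    @property
    def percent(self) -> float:
        """Identity rounded to one decimal, e.g. 83/87 -> 95.4."""
        return round(100.0 * self.matches / self.total, 1)


def percent_identity(
    query: FrameworkSegments, reference: FrameworkSegments
) -> IdentityResult:
    """Identical positions over all 87 framework positions.

    The denominator is always 87; gap positions (on either side, including
    gap-vs-gap) count as mismatches.
    """
    q, r = query.concatenated(), reference.concatenated()
    matches = sum(1 for a, b in zip(q, r) if a == b and a != GAP)
    return IdentityResult(matches=matches, total=TOTAL_FR_POSITIONS)


@dataclass(frozen=True)
class SubgroupAssignment:
    """Best-matching subgroup with the full identity ranking."""

    best: SubgroupProfile
    identity: IdentityResult
    ranking: Tuple[Tuple[str, IdentityResult], ...]
    tied: bool


def assign_subgroup(
    query: FrameworkSegments, profiles: Sequence[SubgroupProfile]
) -> SubgroupAssignment:
    """Assign ``query`` to the subgroup of maximum framework identity.

    Ties are broken alphabetically by profile name and flagged.  The ranking
    lists every profile, best first.
    """
    if not profiles:
        raise ValueError("need at least one subgroup profile")
    scored = [(p, percent_identity(query, p.segments)) for p in profiles]
    scored.sort(key=lambda item: (-item[1].matches, item[0].name))
    best, best_identity = scored[0]
    tied = len(scored) > 1 and scored[1][1].matches == best_identity.matches
    ranking = tuple((p.name, ident) for p, ident in scored)
    return SubgroupAssignment(
        best=best, identity=best_identity, ranking=ranking, tied=tied
    )


@dataclass(frozen=True)
class FrequencyTable:
    """Per-position relative residue frequencies over an aligned sequence set.

    Frequencies at each position are normalized by the number of non-gap
    observations there; an all-gap column has an empty distribution and is
    listed in ``all_gap_positions``.
    """

    frequencies: Tuple[Dict[str, float], ...]
    n_sequences: int
    all_gap_positions: Tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.frequencies)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: position (1-based), residue, frequency."""
        rows = [
            {"position": i + 1, "residue": aa, "frequency": f}
            for i, dist in enumerate(self.frequencies)
            for aa, f in sorted(dist.items())
        ]
        return pd.DataFrame(rows, columns=["position", "residue", "frequency"])


def frequency_table(sequences: Iterable[str]) -> FrequencyTable:
    """Column-wise residue frequencies of an equal-length aligned set."""
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have the same length")
    for s in seqs:
        bad = set(s) - _ALLOWED
        if bad:
            raise ValueError(f"invalid characters in input: {sorted(bad)}")
    columns: List[Dict[str, float]] = []
    all_gap: List[int] = []
    for i in range(length):
        counts: Dict[str, int] = {}
        for s in seqs:
            if s[i] != GAP:
                counts[s[i]] = counts.get(s[i], 0) + 1
        total = sum(counts.values())
        if total == 0:
            all_gap.append(i)
            columns.append({})
        else:
            columns.append({aa: c / total for aa, c in counts.items()})
    return FrequencyTable(
        frequencies=tuple(columns),
        n_sequences=len(seqs),
        all_gap_positions=tuple(all_gap),
    )


def most_common(table: FrequencyTable) -> List[Tuple[Optional[str], bool]]:
    """Modal residue per position as (residue, tie_flag) pairs.

    Ties are broken alphabetically and flagged; an all-gap column yields
    ``(None, False)``.
    """
    out: List[Tuple[Optional[str], bool]] = []
    for dist in table.frequencies:
        if not dist:
            out.append((None, False))
            continue
        best = max(dist.values())
        modal = sorted(aa for aa, f in dist.items() if f == best)
        out.append((modal[0], len(modal) > 1))
    return out
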