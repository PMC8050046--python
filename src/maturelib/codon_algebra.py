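"""Exact algebra of IUPAC-degenerate codons.

A degenerate codon is a triplet of IUPAC nucleotide ambiguity codes (e.g.
``NNS``, ``VWA``) that stands for the set of concrete DNA codons obtained by
substituting each symbol with one of its bases.  This module expands such
codons through the standard genetic code into amino-acid profiles and tests
them against target residue sets — the primitive underlying degenerate-primer
library design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Tuple

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "STOP",
    "AMINO_ACIDS",
    "IUPAC_CODES",
    "GENETIC_CODE",
    "AlphabetError",
    "DegenerateCodon",
    "CodonExpansion",
    "EncodingReport",
    "expand_degenerate_codon",
    "translate",
    "encodes_exactly",
]

#: Distinguished stop token; never counted as an amino acid.
STOP = "*"

#: The 20 proteinogenic amino acids, one-letter uppercase.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The 15 IUPAC nucleotide ambiguity codes mapped to their base sets
#: (excludes the non-standard ``X`` alias biopython also carries).
IUPAC_CODES: Dict[str, str] = {
    sym: "".join(sorted(bases))
    for sym, bases in ambiguous_dna_values.items()
    if sym != "X"
}


def _standard_code() -> Dict[str, str]:
    table = unambiguous_dna_by_id[1]  # standard nuclear code
    code = dict(table.forward_table)
    for triplet in table.stop_codons:
        code[triplet] = STOP
    return code


#: The standard genetic code: 64 triplets -> one-letter amino acid or ``*``.
GENETIC_CODE: Dict[str, str] = _standard_code()
assert len(GENETIC_CODE) == 64


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


@dataclass(frozen=True)
class DegenerateCodon:
    """Three IUPAC nucleotide symbols.

    Input is normalized: lowercase is uppercased and RNA ``U`` becomes ``T``.

    >>> DegenerateCodon("nns").symbols
    'NNS'
    """

    symbols: str

    def __post_init__(self) -> None:
        normalized = self.symbols.upper().replace("U", "T")
        if len(normalized) != 3:
            raise AlphabetError(
                f"a codon needs exactly 3 symbols, got {len(normalized)}: "
                f"{self.symbols!r}"
            )
        for pos, sym in enumerate(normalized):
            if sym not in IUPAC_CODES:
                raise AlphabetError(
                    f"invalid IUPAC nucleotide {sym!r} at codon position {pos}"
                )
        object.__setattr__(self, "symbols", normalized)

    @property
    def expansion_size(self) -> int:
        """Number of concrete codons: the product of per-symbol base counts."""
        n = 1
        for sym in self.symbols:
            n *= len(IUPAC_CODES[sym])
        return n

    @property
    def is_concrete(self) -> bool:
        return self.expansion_size == 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbols


@dataclass(frozen=True)
class CodonExpansion:
    """The concrete codons of a degenerate codon plus its residue profile.

    ``residue_profile`` maps each encoded amino acid (and ``*`` for stop) to
    the number of concrete codons encoding it; multiplicities sum to the
    expansion size.
    """

    codon: DegenerateCodon
    codons: FrozenSet[str]
    residue_profile: Dict[str, int] = field(hash=False)

    @property
    def residues(self) -> FrozenSet[str]:
        """Encoded amino acids, stop excluded."""
        return frozenset(aa for aa in self.residue_profile if aa != STOP)

    @property
    def stop_count(self) -> int:
        return self.residue_profile.get(STOP, 0)

    @property
    def stop_free_count(self) -> int:
        """Number of concrete codons not encoding a stop."""
        return len(self.codons) - self.stop_count


def expand_degenerate_codon(codon: DegenerateCodon | str) -> CodonExpansion:
    """Expand a degenerate codon into concrete triplets and a residue profile.

    >>> exp = expand_degenerate_codon("VWA")
    >>> sorted(exp.residues)
    ['E', 'I', 'K', 'L', 'Q', 'V']
    """
    if not isinstance(codon, DegenerateCodon):
        codon = DegenerateCodon(codon)
    concrete = [
        "".join(bases)
        for bases in itertools.product(*(IUPAC_CODES[s] for s in codon.symbols))
    ]
    profile: Dict[str, int] = {}
    for triplet in concrete:
        aa = GENETIC_CODE[triplet]
        profile[aa] = profile.get(aa, 0) + 1
    return CodonExpansion(
        codon=codon, codons=frozenset(concrete), residue_profile=profile
    )


def translate(triplet: str) -> str:
    """Translate one concrete codon through the standard code (``*`` = stop)."""
    key = triplet.upper().replace("U", "T")
    if key not in GENETIC_CODE:
        raise AlphabetError(f"not a concrete DNA codon: {triplet!r}")
    return GENETIC_CODE[key]


@dataclass(frozen=True)
class EncodingReport:
    """Outcome of testing a degenerate codon against a target residue set."""

    exact: bool
    extras: FrozenSet[str]
    missing: FrozenSet[str]
    stop_count: int


def encodes_exactly(
    codon: DegenerateCodon | str, target: FrozenSet[str] | set
) -> EncodingReport:
    """Does ``codon`` encode exactly ``target`` with no stop codons?

    Returns a report listing off-target residues, uncovered targets and the
    stop multiplicity; ``exact`` is true iff extras and missing are empty and
    the stop count is zero.
    """
    target = frozenset(target)
    if not target:
        raise ValueError("target residue set must be non-empty")
    bad = target - AMINO_ACIDS
    if bad:
        raise ValueError(f"not proteinogenic amino acids: {sorted(bad)}")
    expansion = expand_degenerate_codon(codon)
    extras = expansion.residues - target
    missing = target - expansion.residues
    exact = not extras and not missing and expansion.stop_count == 0
    return EncodingReport(
        exact=exact,
        extras=frozenset(extras),
        missing=frozenset(missing),
        stop_count=expansion.stop_count,
    )
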