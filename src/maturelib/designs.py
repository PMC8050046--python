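"""Built-in library designs for the anti-cortisol scFv V_H-FR1 campaign.

Two degenerate mutagenesis oligonucleotides target the N-terminal ten Kabat
positions of the heavy-chain framework region 1 (wild type QVQLQQPGAE):

* **Library A** substitutes positions 1-3, 5-7, 9 and 10 with small predefined
  residue menus (positions 4 and 8 stay fixed at L and G), encoded by one
  degenerate codon per position — 1,536 protein variants, no stop codons.
* **Library B** inserts 1-6 consecutive ``NNS``-randomized residues between
  positions 6 and 7, giving 20^n protein variants per sublibrary; the n=1-3
  products are pooled for transformation (slB-1-3), as are n=4 and 5
  (slB-4/5), while n=6 (slB-6) stands alone.
"""

from __future__ import annotations

from typing import List

from .library_design import (
    DegenerateCodon,
    LibrarySpec,
    PositionSpec,
    spec_from_primer,
)

__all__ = [
    "LIBRARY_A_PRIMER",
    "LIBRARY_A_WINDOW_START",
    "LIBRARY_A_N_CODONS",
    "LIBRARY_B_FIVE_PRIME",
    "LIBRARY_B_THREE_PRIME",
    "WILD_TYPE_FR1_1_10",
    "library_a_spec",
    "library_b_spec",
    "library_b_pool",
    "library_b_primer",
]

#: The degenerate library-A oligo, written 5'->3' as synthesized.  The design
#: window reads in the sense frame of V_H: ten codons starting with SAG right
#: after the NcoI cloning context ``...CCATGGCC``.
LIBRARY_A_PRIMER = (
    "ATTGTTATTACTCGCGGCCCAACCGGCCATGGCC"
    "SAGRTCMAACTGVWASAGYCTGGGSSTGRA"
    "CTTGTGAAGCCTGGGGCTTCAGTGAAA"
)
LIBRARY_A_WINDOW_START = LIBRARY_A_PRIMER.index("CCATGGCC") + len("CCATGGCC")
LIBRARY_A_N_CODONS = 10

#: Constant context of the library-B oligos: six fixed codons QVQLQQ
#: (positions 1-6) precede the (NNS)_n insertion point.
LIBRARY_B_FIVE_PRIME = "ATTGTTATTACTCGCGGCCCAACCGGCCATGGCC"
_LIBRARY_B_FIXED_CODONS = "CAGGTCCAACTGCAGCAG"  # Q V Q L Q Q
LIBRARY_B_THREE_PRIME = "CCTGGGGCTGAACTTGTGAAGC"

#: Wild-type V_H positions 1-10 (Kabat), the parental FR1 decamer.
WILD_TYPE_FR1_1_10 = "QVQLQQPGAE"


def library_a_spec() -> LibrarySpec:
    """The substitution library parsed from the printed degenerate primer."""
    return spec_from_primer(
        name="library-A",
        primer=LIBRARY_A_PRIMER,
        window_start=LIBRARY_A_WINDOW_START,
        n_codons=LIBRARY_A_N_CODONS,
        first_label=1,
    )


def library_b_spec(n_insertions: int) -> LibrarySpec:
    """The (NNS)_n insertion sublibrary, 1 <= n <= 6."""
    if not 1 <= n_insertions <= 6:
        raise ValueError("insertion length must be between 1 and 6")
    fixed = []
    for i in range(6):
        codon = DegenerateCodon(_LIBRARY_B_FIXED_CODONS[3 * i : 3 * i + 3])
        fixed.append(
            PositionSpec(
                kabat_label=i + 1,
                mode="fixed",
                residues=frozenset(WILD_TYPE_FR1_1_10[i]),
                codon=codon,
            )
        )
    block = PositionSpec(
        kabat_label=6,
        mode="insertion_block",
        residues=frozenset(),
        codon=DegenerateCodon("NNS"),
        insertion_length=n_insertions,
    )
    return LibrarySpec(
        name=f"library-B-NNS{n_insertions}",
        positions=tuple(fixed) + (block,),
        five_prime_flank=LIBRARY_B_FIVE_PRIME,
        three_prime_flank=LIBRARY_B_THREE_PRIME,
    )


def library_b_pool(pool: str) -> List[LibrarySpec]:
    """The transformed sublibrary pools: ``slB-1-3``, ``slB-4/5`` or ``slB-6``."""
    pools = {
        "slB-1-3": (1, 2, 3),
        "slB-4/5": (4, 5),
        "slB-6": (6,),
    }
    if pool not in pools:
        raise ValueError(f"unknown pool {pool!r}; choose from {sorted(pools)}")
    return [library_b_spec(n) for n in pools[pool]]


def library_b_primer(n_insertions: int) -> str:
    """The NNS-n oligo string as synthesized (constant context + insertions)."""
    return (
        LIBRARY_B_FIVE_PRIME
        + _LIBRARY_B_FIXED_CODONS
        + "NNS" * n_insertions
        + LIBRARY_B_THREE_PRIME
    )
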