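"""Design and accounting of degenerate-codon mutagenesis libraries.

Two library architectures are supported:

* **substitution** libraries, where selected codons of a framework window are
  replaced by degenerate codons each encoding a small predefined residue set
  (one codon per residue, so protein and DNA diversities coincide and no stop
  codons appear);
* **insertion** libraries, where a block of fully randomized ``NNS`` codons
  (all 20 amino acids + the TAG stop, 32 codons) is inserted between two fixed
  framework positions.

The module parses degenerate primers into per-position residue menus, solves
the inverse problem (the minimal degenerate codon covering a residue set),
computes exact protein/DNA diversities and stop fractions, enumerates variant
proteins, and reassembles primers from specs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

from .codon_algebra import (
    AMINO_ACIDS,
    IUPAC_CODES,
    STOP,
    AlphabetError,
    CodonExpansion,
    DegenerateCodon,
    EncodingReport,
    encodes_exactly,
    expand_degenerate_codon,
)

__all__ = [
    "PositionSpec",
    "LibrarySpec",
    "DiversityReport",
    "CodonDesign",
    "parse_degenerate_window",
    "design_codon_for_set",
    "diversity",
    "pooled_diversity",
    "enumerate_protein_variants",
    "assemble_primer",
    "spec_from_primer",
    "reverse_complement",
    "DEFAULT_ENUMERATION_CAP",
]

DEFAULT_ENUMERATION_CAP = 10**6


@dataclass(frozen=True)
class PositionSpec:
    """One design position: fixed residue, substitution menu, or insertion block.

    ``kabat_label`` is the 1-based framework position; an insertion block
    carries the label of the preceding fixed position (it sits between that
    position and the next one).  ``insertion_length`` counts the randomized
    codons in an insertion block and is ignored otherwise.
    """

    kabat_label: int
    mode: str  # "fixed" | "substitution" | "insertion_block"
    residues: FrozenSet[str]
    codon: DegenerateCodon
    insertion_length: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "substitution", "insertion_block"):
            raise ValueError(f"unknown position mode {self.mode!r}")
        object.__setattr__(self, "residues", frozenset(self.residues))
        expansion = expand_degenerate_codon(self.codon)
        if self.mode == "fixed":
            if len(self.residues) != 1 or not self.codon.is_concrete:
                raise ValueError(
                    f"fixed position {self.kabat_label} needs a single residue "
                    "and a concrete codon"
                )
            if expansion.residues != self.residues:
                raise ValueError(
                    f"codon {self.codon} does not encode fixed residue "
                    f"{set(self.residues)}"
                )
        elif self.mode == "substitution":
            if expansion.residues != self.residues or expansion.stop_count:
                raise ValueError(
                    f"substitution codon {self.codon} must encode exactly "
                    f"{sorted(self.residues)} with zero stops"
                )
        else:  # insertion_block
            if not 1 <= self.insertion_length:
                raise ValueError("insertion_block needs insertion_length >= 1")

    @property
    def expansion(self) -> CodonExpansion:
        return expand_degenerate_codon(self.codon)


@dataclass(frozen=True)
class LibrarySpec:
    """An ordered library design: positions plus concrete flanking sequences."""

    name: str
    positions: Tuple[PositionSpec, ...]
    five_prime_flank: str = ""
    three_prime_flank: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        labels = [p.kabat_label for p in self.positions]
        if any(b < a for a, b in zip(labels, labels[1:])):
            raise ValueError("positions must be in ascending label order")
        n_ins = sum(p.mode == "insertion_block" for p in self.positions)
        if n_ins > 1:
            raise ValueError("at most one insertion block per spec")
        for flank, side in (
            (self.five_prime_flank, "5'"),
            (self.three_prime_flank, "3'"),
        ):
            for ch in flank:
                if ch not in "ACGT":
                    raise AlphabetError(
                        f"{side} flank must be concrete DNA; found {ch!r}"
                    )

    @property
    def insertion_block(self) -> Optional[PositionSpec]:
        for p in self.positions:
            if p.mode == "insertion_block":
                return p
        return None

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "five_prime_flank": self.five_prime_flank,
            "three_prime_flank": self.three_prime_flank,
            "positions": [
                {
                    "kabat_label": p.kabat_label,
                    "mode": p.mode,
                    "residues": "".join(sorted(p.residues)),
                    "codon": p.codon.symbols,
                    "insertion_length": p.insertion_length,
                }
                for p in self.positions
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LibrarySpec":
        positions = tuple(
            PositionSpec(
                kabat_label=int(p["kabat_label"]),
                mode=p["mode"],
                residues=frozenset(p.get("residues", "")),
                codon=DegenerateCodon(p["codon"]),
                insertion_length=int(p.get("insertion_length", 0)),
            )
            for p in data["positions"]
        )
        return cls(
            name=data.get("name", "library"),
            positions=positions,
            five_prime_flank=data.get("five_prime_flank", ""),
            three_prime_flank=data.get("three_prime_flank", ""),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "LibrarySpec":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class DiversityReport:
    """Variant counts for one library (or a pool of sublibraries).

    ``protein_diversity`` counts distinct stop-free protein variants;
    ``nucleotide_diversity`` counts distinct DNA variants (stops included);
    ``stop_fraction`` is the fraction of DNA variants carrying >= 1 stop codon.
    """

    protein_diversity: int
    nucleotide_diversity: int
    stop_fraction: float

    def __post_init__(self) -> None:
        if self.protein_diversity > self.nucleotide_diversity:
            raise ValueError("protein diversity cannot exceed DNA diversity")
        if not 0.0 <= self.stop_fraction < 1.0:
            raise ValueError("stop fraction must lie in [0, 1)")


# ---------------------------------------------------------------------------
# primer parsing / assembly


def parse_degenerate_window(
    primer: str, window_start: int, n_codons: int
) -> List[Tuple[DegenerateCodon, FrozenSet[str]]]:
    """Read ``n_codons`` in frame from ``primer`` starting at a 0-based offset.

    Returns each codon with its expanded residue set (stop excluded).  Raises
    a range error when the window overruns the primer and an alphabet error on
    non-IUPAC characters.
    """
    primer = primer.upper().replace("U", "T")
    end = window_start + 3 * n_codons
    if window_start < 0 or end > len(primer):
        raise IndexError(
            f"codon window [{window_start}:{end}] overruns primer of length "
            f"{len(primer)}"
        )
    out = []
    for i in range(n_codons):
        chunk = primer[window_start + 3 * i : window_start + 3 * i + 3]
        codon = DegenerateCodon(chunk)
        out.append((codon, expand_degenerate_codon(codon).residues))
    return out


def assemble_primer(spec: LibrarySpec) -> str:
    """Concatenate 5' flank, per-position codons in order, and 3' flank.

    Insertion blocks contribute ``insertion_length`` copies of their codon.
    Round-trips with :func:`parse_degenerate_window`.
    """
    parts = [spec.five_prime_flank]
    for p in spec.positions:
        reps = p.insertion_length if p.mode == "insertion_block" else 1
        parts.append(p.codon.symbols * reps)
    parts.append(spec.three_prime_flank)
    return "".join(parts)


_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    seq = sequence.upper().replace("U", "T")
    for ch in seq:
        if ch not in IUPAC_CODES:
            raise AlphabetError(f"invalid IUPAC nucleotide {ch!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def spec_from_primer(
    name: str,
    primer: str,
    window_start: int,
    n_codons: int,
    first_label: int = 1,
) -> LibrarySpec:
    """Build a substitution-library spec from a degenerate primer window.

    Constant codons become fixed singletons; degenerate codons become
    substitution positions.  The sequence outside the window becomes the
    flanks (which must therefore be concrete).
    """
    parsed = parse_degenerate_window(primer, window_start, n_codons)
    positions = []
    for offset, (codon, residues) in enumerate(parsed):
        mode = "fixed" if codon.is_concrete else "substitution"
        positions.append(
            PositionSpec(
                kabat_label=first_label + offset,
                mode=mode,
                residues=residues,
                codon=codon,
            )
        )
    primer = primer.upper().replace("U", "T")
    return LibrarySpec(
        name=name,
        positions=tuple(positions),
        five_prime_flank=primer[:window_start],
        three_prime_flank=primer[window_start + 3 * n_codons :],
    )


# ---------------------------------------------------------------------------
# inverse codon design


@dataclass(frozen=True)
class CodonDesign:
    """Result of the minimal-degenerate-codon search for a residue set."""

    codon: DegenerateCodon
    report: EncodingReport
    n_codons: int

    @property
    def exact(self) -> bool:
        return self.report.exact


def design_codon_for_set(target: Iterable[str]) -> CodonDesign:
    """Search all 15^3 degenerate codons for the best cover of ``target``.

    Every candidate must cover the full target (``NNN`` always does, so a
    cover exists).  Among covers the choice is lexicographic: fewest
    off-target residues, then fewest stop codons, then fewest concrete
    codons, then alphabetical symbols.  The report states whether the winner
    is an exact, stop-free cover.
    """
    target = frozenset(target)
    if not target:
        raise ValueError("target residue set must be non-empty")
    bad = target - AMINO_ACIDS
    if bad:
        raise ValueError(f"not proteinogenic amino acids: {sorted(bad)}")

    best_key = None
    best: Optional[CodonDesign] = None
    for symbols in itertools.product(sorted(IUPAC_CODES), repeat=3):
        codon = DegenerateCodon("".join(symbols))
        expansion = expand_degenerate_codon(codon)
        if not target <= expansion.residues:
            continue
        extras = expansion.residues - target
        key = (
            len(extras),
            expansion.stop_count,
            len(expansion.codons),
            codon.symbols,
        )
        if best_key is None or key < best_key:
            best_key = key
            best = CodonDesign(
                codon=codon,
                report=EncodingReport(
                    exact=not extras and expansion.stop_count == 0,
                    extras=frozenset(extras),
                    missing=frozenset(),
                    stop_count=expansion.stop_count,
                ),
                n_codons=len(expansion.codons),
            )
    assert best is not None  # NNN covers any target
    return best


# ---------------------------------------------------------------------------
# diversity accounting


def _position_factors(p: PositionSpec) -> Tuple[int, int, float]:
    """(protein factor, DNA factor, stop-free DNA fraction) for one position."""
    exp = p.expansion
    if p.mode == "insertion_block":
        n_res = len(exp.residues)
        return (
            n_res**p.insertion_length,
            len(exp.codons)**p.insertion_length,
            (exp.stop_free_count / len(exp.codons)) ** p.insertion_length,
        )
    return len(exp.residues), len(exp.codons), exp.stop_free_count / len(exp.codons)


def diversity(spec: LibrarySpec) -> DiversityReport:
    """Exact protein/DNA diversity and stop fraction of one library spec.

    Protein diversity multiplies per-position counts of distinct stop-free
    residues (an ``NNS`` block of length *n* contributes 20^n); DNA diversity
    multiplies codon-expansion sizes; the stop fraction is computed exactly
    from per-position stop-free fractions.
    """
    protein = 1
    dna = 1
    stop_free = 1.0
    for p in spec.positions:
        f_protein, f_dna, f_free = _position_factors(p)
        protein *= f_protein
        dna *= f_dna
        stop_free *= f_free
    return DiversityReport(
        protein_diversity=protein,
        nucleotide_diversity=dna,
        stop_fraction=1.0 - stop_free,
    )


def pooled_diversity(specs: Sequence[LibrarySpec]) -> DiversityReport:
    """Diversity of an equimolar pool of sublibraries: counts add.

    The pooled stop fraction is the DNA-diversity-weighted mean of the
    sublibrary stop fractions (each DNA variant of the pool is equally
    counted once).
    """
    if not specs:
        raise ValueError("need at least one spec")
    reports = [diversity(s) for s in specs]
    protein = sum(r.protein_diversity for r in reports)
    dna = sum(r.nucleotide_diversity for r in reports)
    stopful = sum(r.stop_fraction * r.nucleotide_diversity for r in reports)
    return DiversityReport(
        protein_diversity=protein,
        nucleotide_diversity=dna,
        stop_fraction=stopful / dna,
    )


# ---------------------------------------------------------------------------
# enumeration


def enumerate_protein_variants(
    spec: LibrarySpec, cap: int = DEFAULT_ENUMERATION_CAP
) -> Iterator[str]:
    """Yield each distinct stop-free protein variant once, lexicographically.

    Refuses (with the computed diversity in the message) when the protein
    diversity exceeds ``cap`` — a guard against accidentally materializing
    10^7-scale insertion libraries.
    """
    report = diversity(spec)
    if report.protein_diversity > cap:
        raise ValueError(
            f"protein diversity {report.protein_diversity} exceeds the "
            f"enumeration cap {cap}"
        )
    menus: List[List[str]] = []
    for p in spec.positions:
        residues = sorted(p.expansion.residues)
        reps = p.insertion_length if p.mode == "insertion_block" else 1
        menus.extend([residues] * reps)
    for combo in itertools.product(*menus):
        yield "".join(combo)


def variant_codon_multiplicities(
    spec: LibrarySpec, cap: int = DEFAULT_ENUMERATION_CAP
) -> Dict[str, int]:
    """Map each stop-free protein variant to its concrete-codon multiplicity.

    A variant's multiplicity is the product over positions of the number of
    concrete codons encoding its residue there; summed over variants this
    gives the stop-free DNA count.
    """
    report = diversity(spec)
    if report.protein_diversity > cap:
        raise ValueError(
            f"protein diversity {report.protein_diversity} exceeds the "
            f"enumeration cap {cap}"
        )
    menus: List[List[Tuple[str, int]]] = []
    for p in spec.positions:
        profile = p.expansion.residue_profile
        items = sorted((aa, m) for aa, m in profile.items() if aa != STOP)
        reps = p.insertion_length if p.mode == "insertion_block" else 1
        menus.extend([items] * reps)
    out: Dict[str, int] = {}
    for combo in itertools.product(*menus):
        seq = "".join(aa for aa, _ in combo)
        out[seq] = math.prod(m for _, m in combo)
    return out
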