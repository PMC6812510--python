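"""In-silico proteolytic digestion.

Trypsin by default: cleavage C-terminal of K/R, suppressed before proline,
up to two missed cleavages, and peptide length limits matching what an MS
search would consider.  ``semi`` specificity additionally emits every N- or
C-terminal truncation of each fully tryptic product, which is how processed
protein N-termini (e.g. signal-peptide cleavage) become searchable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = ["EnzymeConfig", "PeptideProduct", "digest", "cut_sites", "count_tryptic_peptides"]


@dataclass(frozen=True)
class EnzymeConfig:
    cleave_after: str = "KR"
    no_cleave_before_proline: bool = True
    max_missed: int = 2
    min_length: int = 7
    max_length: int = 45
    specificity: str = "full"  # 'full' | 'semi'

    def __post_init__(self):
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")
        if self.specificity not in ("full", "semi"):
            raise ValueError(f"unknown specificity {self.specificity!r}")


@dataclass(frozen=True)
class PeptideProduct:
    sequence: str
    start: int  # 0-based offset in the parent protein
    missed: int  # internal cleavage sites
    nterm_tryptic: bool
    cterm_tryptic: bool

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def semi(self) -> bool:
        return not (self.nterm_tryptic and self.cterm_tryptic)


def cut_sites(sequence: str, enzyme: EnzymeConfig) -> list[int]:
    """Positions i such that the enzyme cuts between residues i and i+1."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in enzyme.cleave_after:
            if enzyme.no_cleave_before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(
    sequence: str,
    enzyme: EnzymeConfig = EnzymeConfig(),
    clip_nterm_met: bool = False,
) -> list[PeptideProduct]:
    """Digest ``sequence``; products are unique by (start, end), sorted.

    ``clip_nterm_met`` additionally emits the protein-N-terminal products
    with the initiator methionine removed (the co-translational processing
    searched by standard engines).
    """
    out: dict[tuple[int, int], PeptideProduct] = {}
    _digest_into(sequence, enzyme, 0, out)
    if clip_nterm_met and sequence[:1] == "M":
        clipped: dict[tuple[int, int], PeptideProduct] = {}
        _digest_into(sequence[1:], enzyme, 1, clipped)
        for key, p in clipped.items():
            if p.start == 1:  # only products exposing the new N-terminus
                out.setdefault(key, p)
    return sorted(out.values(), key=lambda p: (p.start, p.end))


def _digest_into(sequence, enzyme, offset, out):
    n = len(sequence)
    if n == 0:
        return
    sites = cut_sites(sequence, enzyme)
    site_set = set(sites)
    # boundaries where a tryptic terminus can occur
    starts = [0] + [i + 1 for i in sites]
    ends = [i + 1 for i in sites] + [n]

    def internal_missed(s: int, e: int) -> int:
        return sum(1 for i in range(s, e - 1) if i in site_set)

    def add(s: int, e: int, nt: bool, ct: bool):
        length = e - s
        if not (enzyme.min_length <= length <= enzyme.max_length):
            return
        if internal_missed(s, e) > enzyme.max_missed:
            return
        key = (s + offset, e + offset)
        if key not in out:
            out[key] = PeptideProduct(sequence[s:e], s + offset, internal_missed(s, e), nt, ct)

    full_products = []
    for ai, s in enumerate(starts):
        for e in ends:
            if e <= s:
                continue
            if internal_missed(s, e) > enzyme.max_missed:
                continue
            full_products.append((s, e))
            add(s, e, True, True)
    if enzyme.specificity == "semi":
        for s, e in full_products:
            for k in range(s + 1, e):  # N-terminal truncations
                add(k, e, k in {i + 1 for i in sites} or k == 0, True)
            for k in range(s + 1, e):  # C-terminal truncations
                add(s, k, True, k in {i + 1 for i in sites} or k == n)
    return


def count_tryptic_peptides(sequence: str, min_length: int = 6, max_length: int = 30) -> int:
    """Number of fully tryptic zero-missed-cleavage peptides within length bounds.

    This is the iBAQ denominator: the theoretically observable peptides of a
    protein.
    """
    enz = EnzymeConfig(max_missed=0, min_length=min_length, max_length=max_length)
    return sum(1 for p in digest(sequence, enz) if not p.semi)
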