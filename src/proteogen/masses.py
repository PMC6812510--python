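"""Monoisotopic peptide masses, modifications, and b/y fragment ions.

The mass model underlying the search engine: residue monoisotopic masses,
peptide neutral mass (residues + water + modification deltas), and singly-
to multiply-charged b/y fragment ladders as produced by HCD fragmentation.

A modification placement on a peptide is a tuple of :class:`ModPlacement`;
position -1 denotes the peptide/protein N-terminus, otherwise the 0-based
residue index.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "MONO",
    "WATER",
    "PROTON",
    "ModificationSpec",
    "ModPlacement",
    "Fragment",
    "peptide_mass",
    "fragments",
    "mod_placements",
    "STANDARD_FIXED",
    "STANDARD_VARIABLE",
    "PTM_PASS_VARIABLE",
]

# Monoisotopic residue masses (Da), standard 20 amino acids.
MONO: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.0105646863
PROTON = 1.00727646688


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass shift targeting residues (e.g. ``"STY"``) or ``"nterm"``."""

    name: str
    target: str
    delta: float
    fixed: bool = False

    def __post_init__(self):
        if abs(self.delta) >= 600:
            raise ValueError(f"{self.name}: |delta| must be < 600 Da")

    def sites(self, peptide: str, protein_nterm: bool = False) -> list[int]:
        if self.target == "nterm":
            return [-1] if protein_nterm else []
        return [i for i, aa in enumerate(peptide) if aa in self.target]


@dataclass(frozen=True, order=True)
class ModPlacement:
    position: int  # -1 = N-terminus
    name: str
    delta: float


@dataclass(frozen=True)
class Fragment:
    kind: str  # 'b' | 'y'
    index: int
    charge: int
    mz: float


# The modification sets used in the study's search passes.
CARBAMIDOMETHYL_C = ModificationSpec("Carbamidomethyl", "C", 57.02146, fixed=True)
ACETYL_PROTEIN_NTERM = ModificationSpec("Acetyl-Nterm", "nterm", 42.01057)
OXIDATION_M = ModificationSpec("Oxidation", "M", 15.99491)
PHOSPHO_STY = ModificationSpec("Phospho", "STY", 79.96633)
ACETYL_K = ModificationSpec("Acetyl-K", "K", 42.01057)
METHYL_KR = ModificationSpec("Methyl", "KR", 14.01565)
DIMETHYL_KR = ModificationSpec("Dimethyl", "KR", 28.03130)
TRIMETHYL_K = ModificationSpec("Trimethyl", "K", 42.04695)
GG_K = ModificationSpec("GlyGly-K", "K", 114.04293)  # ubiquitylation remnant

STANDARD_FIXED = (CARBAMIDOMETHYL_C,)
STANDARD_VARIABLE = (ACETYL_PROTEIN_NTERM, OXIDATION_M, PHOSPHO_STY)
PTM_PASS_VARIABLE = (ACETYL_K, METHYL_KR, DIMETHYL_KR, TRIMETHYL_K, GG_K)


def _check_peptide(peptide: str) -> None:
    bad = set(peptide) - MONO.keys()
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in {peptide!r}")


def peptide_mass(peptide: str, mods: Sequence[ModPlacement] = ()) -> float:
    """Neutral monoisotopic mass: residue masses + water + modification deltas."""
    _check_peptide(peptide)
    for m in mods:
        if not (-1 <= m.position < len(peptide)):
            raise ValueError(f"mod {m.name} at illegal position {m.position}")
    return sum(MONO[aa] for aa in peptide) + WATER + sum(m.delta for m in mods)


def fragments(
    peptide: str,
    mods: Sequence[ModPlacement] = (),
    max_charge: int = 1,
) -> list[Fragment]:
    """Theoretical b1..b(n-1) and y1..y(n-1) ions at charges 1..max_charge.

    N-terminal and residue mods at positions < k shift b(k); mods at
    positions >= n-k shift y(k).
    """
    _check_peptide(peptide)
    n = len(peptide)
    if n < 2:
        raise ValueError("peptide must have length >= 2")
    delta_at = [0.0] * n
    nterm_delta = 0.0
    for m in mods:
        if m.position == -1:
            nterm_delta += m.delta
        else:
            delta_at[m.position] += m.delta
    # prefix sums of residue+mod masses
    prefix = [0.0]
    for i, aa in enumerate(peptide):
        prefix.append(prefix[-1] + MONO[aa] + delta_at[i])
    total = prefix[-1] + nterm_delta
    out = []
    for k in range(1, n):
        b_neutral = prefix[k] + nterm_delta
        y_neutral = total - (prefix[n - k] + nterm_delta) + WATER
        for z in range(1, max_charge + 1):
            out.append(Fragment("b", k, z, (b_neutral + z * PROTON) / z))
            out.append(Fragment("y", k, z, (y_neutral + z * PROTON) / z))
    return out


def mod_placements(
    peptide: str,
    fixed: Sequence[ModificationSpec],
    variable: Sequence[ModificationSpec],
    max_var: int = 3,
    protein_nterm: bool = False,
    max_site_combinations: int = 64,
) -> Iterator[tuple[ModPlacement, ...]]:
    """Enumerate modification placements: fixed mods always applied, then all
    combinations of up to ``max_var`` variable-mod site assignments.

    Each site takes at most one variable mod.  The enumeration is capped at
    ``max_site_combinations`` placements per peptide to bound the search
    space; the unmodified-but-fixed placement is always yielded first.
    """
    base = []
    for spec in fixed:
        for pos in spec.sites(peptide, protein_nterm):
            base.append(ModPlacement(pos, spec.name, spec.delta))
    base = tuple(sorted(base))
    yield base
    options: list[ModPlacement] = []
    for spec in variable:
        for pos in spec.sites(peptide, protein_nterm):
            options.append(ModPlacement(pos, spec.name, spec.delta))
    emitted = 1
    for r in range(1, max_var + 1):
        for combo in combinations(options, r):
            positions = [m.position for m in combo]
            if len(set(positions)) != len(positions):
                continue  # one mod per site
            yield tuple(sorted(base + combo))
            emitted += 1
            if emitted >= max_site_combinations:
                return
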