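"""Mirror alignment of experimental vs synthetic-peptide spectra.

Greedy nearest-m/z peak pairing within a fragment tolerance, a normalized
spectral-contrast similarity on square-root-transformed intensities, and
b/y-ion annotation of the matched peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .masses import Fragment, ModPlacement, fragments
from .spectra_io import Spectrum

__all__ = ["AlignmentResult", "align_spectra", "annotate_alignment"]


@dataclass
class AlignmentResult:
    pairs: list[tuple[float, float, float]]  # (m/z a, m/z b, delta ppm)
    similarity: float
    unmatched_a: int
    unmatched_b: int
    annotations: list[Optional[str]] = field(default_factory=list)


def align_spectra(a: Spectrum, b: Spectrum, frag_tol: float = 0.02) -> AlignmentResult:
    """Greedily pair peaks of two spectra and score their similarity.

    Candidate pairs within ``frag_tol`` are taken smallest-|delta m/z| first,
    each peak used at most once.  Similarity is the normalized dot product of
    square-root intensities over the union peak set: 1.0 only for identical
    peak sets with proportional intensities, 0.0 for disjoint spectra.  The
    result is symmetric in its inputs.
    """
    if len(a) == 0 or len(b) == 0:
        return AlignmentResult([], 0.0, len(a), len(b))
    cand = []
    j0 = 0
    for i, mza in enumerate(a.mz):
        for j in range(len(b.mz)):
            d = b.mz[j] - mza
            if abs(d) <= frag_tol:
                cand.append((abs(d), i, j))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs_idx = []
    for d, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs_idx.append((i, j))
    pairs_idx.sort()
    sa = np.sqrt(a.intensity)
    sb = np.sqrt(b.intensity)
    dot = sum(sa[i] * sb[j] for i, j in pairs_idx)
    norm = float(np.linalg.norm(sa) * np.linalg.norm(sb))
    sim = float(dot / norm) if norm > 0 else 0.0
    pairs = [
        (float(a.mz[i]), float(b.mz[j]), float((b.mz[j] - a.mz[i]) / a.mz[i] * 1e6))
        for i, j in pairs_idx
    ]
    return AlignmentResult(
        pairs, sim, len(a) - len(pairs), len(b) - len(pairs)
    )


def annotate_alignment(
    result: AlignmentResult,
    peptide: str,
    mods: Sequence[ModPlacement] = (),
    frag_tol: float = 0.02,
    max_charge: int = 1,
) -> AlignmentResult:
    """Label matched peak pairs with b/y ion indices within ``frag_tol`` of
    the peptide's theoretical ladder; unexplained pairs stay unlabeled."""
    theo = fragments(peptide, mods, max_charge)
    labels: list[Optional[str]] = []
    for mza, mzb, _ in result.pairs:
        label = None
        best = frag_tol
        for f in theo:
            d = abs(f.mz - mza)
            if d <= best:
                best = d
                label = f"{f.kind}{f.index}" + (f"({f.charge}+)" if f.charge > 1 else "")
        labels.append(label)
    result.annotations = labels
    return result
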