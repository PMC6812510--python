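"""Self-contained peptide-spectrum matching with target-decoy FDR control.

Replaces a commercial search engine at desk scale: peptides from the target
and reversed-decoy databases are indexed by neutral mass; each spectrum is
scored against candidates within the precursor tolerance with a binomial
fragment-count score; q-values come from target-decoy counting; parsimony
grouping reduces peptides to a minimal protein set; and the iterative
multi-pass strategy re-searches unmatched spectra against PTM-widened and
sample-specific (SAAV / junction / ORF / signal) databases.

The score of a candidate peptide is

    score = -10 * log10 P(X >= k),   X ~ Binomial(N, p)

where N is the number of theoretical b/y fragments, k the number matched
within the fragment tolerance, and p = min(0.99, 2 * tol * n_peaks / range)
the per-fragment chance of a random hit.  Ties break on the matched
intensity fraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .custom_db import ProteinRecord, generate_decoys
from .enzyme import EnzymeConfig, digest
from .masses import (
    ModificationSpec,
    ModPlacement,
    PROTON,
    STANDARD_FIXED,
    STANDARD_VARIABLE,
    PTM_PASS_VARIABLE,
    fragments,
    mod_placements,
    peptide_mass,
)
from .spectra_io import Spectrum

__all__ = [
    "SearchConfig",
    "PeptideMatch",
    "ProteinGroup",
    "PeptideIndex",
    "SearchDatabases",
    "PassResult",
    "score_psm",
    "search_pass",
    "estimate_fdr",
    "group_proteins",
    "iterative_search",
    "missing_protein_evidence",
]


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol_ppm: float = 10.0
    fragment_tol: float = 0.02
    enzyme: EnzymeConfig = EnzymeConfig()
    fixed_mods: tuple[ModificationSpec, ...] = STANDARD_FIXED
    variable_mods: tuple[ModificationSpec, ...] = STANDARD_VARIABLE
    max_var_mods: int = 3
    max_frag_charge: int = 1
    min_matched_fragments: int = 4
    fdr: float = 0.01

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class PeptideMatch:
    spectrum_id: str
    peptide: str
    mods: tuple[ModPlacement, ...]
    proteins: tuple[str, ...]
    missed: int
    score: float
    intensity_frac: float
    is_decoy: bool
    pass_label: str
    semi: bool = False
    q: Optional[float] = None


@dataclass
class ProteinGroup:
    leader: str
    members: tuple[str, ...]
    peptides: tuple[str, ...]
    best_score: float
    is_decoy: bool
    q: Optional[float] = None


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_psm(
    spectrum: Spectrum,
    theo_mz: np.ndarray,
    fragment_tol: float,
) -> tuple[float, float, int]:
    """Binomial-tail score of a theoretical ladder against a spectrum.

    Returns (score, matched-intensity fraction, matched count); an empty
    spectrum or zero matches scores 0.
    """
    n_theo = len(theo_mz)
    if len(spectrum) == 0 or n_theo == 0:
        return 0.0, 0.0, 0
    mz = spectrum.mz
    idx = np.searchsorted(mz, theo_mz)
    left = np.clip(idx - 1, 0, len(mz) - 1)
    right = np.clip(idx, 0, len(mz) - 1)
    dist = np.minimum(np.abs(mz[left] - theo_mz), np.abs(mz[right] - theo_mz))
    hit = dist <= fragment_tol
    k = int(np.count_nonzero(hit))
    if k == 0:
        return 0.0, 0.0, 0
    mz_range = float(mz[-1] - mz[0])
    if mz_range <= 0:
        mz_range = 1.0
    p = min(0.99, 2.0 * fragment_tol * len(mz) / mz_range)
    tail = max(float(stats.binom.sf(k - 1, n_theo, p)), 1e-300)
    score = -10.0 * np.log10(tail)
    # intensity fraction of peaks matched by any theoretical fragment
    matched_peaks = set()
    for t, h in zip(theo_mz, hit):
        if not h:
            continue
        i = np.searchsorted(mz, t)
        for j in (i - 1, i):
            if 0 <= j < len(mz) and abs(mz[j] - t) <= fragment_tol:
                matched_peaks.add(j)
    total = float(spectrum.intensity.sum())
    frac = float(spectrum.intensity[sorted(matched_peaks)].sum() / total) if total > 0 else 0.0
    return float(score), frac, k


# ---------------------------------------------------------------------------
# Peptide index
# ---------------------------------------------------------------------------

class PeptideIndex:
    """Mass-sorted index of (peptide, modification placement) candidates.

    Peptides are produced by digesting every record (decoys included) with
    the configured enzyme; initiator-Met-clipped N-terminal products are
    added for protein entries; modification placements are enumerated per
    peptide.  ``exclude_peptides`` removes sequences (typically the
    reference digest) so custom-database passes cannot rediscover wild-type
    peptides.
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        cfg: SearchConfig,
        exclude_peptides: Optional[set[str]] = None,
        add_decoys: bool = True,
    ):
        if add_decoys:
            targets = [r for r in records if r.origin != "decoy"]
            records = list(records) + generate_decoys(targets)
        self.records = records
        exclude = exclude_peptides or set()
        # (sequence, at_protein_nterm) -> links / flags
        peptides: dict[tuple[str, bool], dict] = {}
        for rec in records:
            for p in digest(rec.sequence, cfg.enzyme, clip_nterm_met=True):
                if p.sequence in exclude:
                    continue
                at_nterm = p.start <= 1
                key = (p.sequence, at_nterm)
                info = peptides.setdefault(
                    key, {"links": [], "missed": p.missed, "semi": p.semi, "decoy": True}
                )
                info["links"].append((rec.accession, p.start))
                info["semi"] = info["semi"] and p.semi
                if rec.origin != "decoy":
                    info["decoy"] = False
        entries = []
        for (seq, at_nterm), info in peptides.items():
            for mods in mod_placements(
                seq, cfg.fixed_mods, cfg.variable_mods, cfg.max_var_mods, protein_nterm=at_nterm
            ):
                entries.append(
                    (
                        peptide_mass(seq, mods),
                        seq,
                        mods,
                        tuple(acc for acc, _ in info["links"]),
                        info["missed"],
                        info["decoy"],
                        info["semi"],
                    )
                )
        entries.sort(key=lambda e: e[0])
        self._entries = entries
        self._masses = np.array([e[0] for e in entries])
        self._frag_cache: dict = {}
        self._cfg = cfg

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def target_peptides(self) -> set[str]:
        return {seq for _, seq, _, _, _, decoy, _ in self._entries if not decoy}

    def candidates(self, neutral_mass: float, tol_ppm: float):
        tol = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self._masses, neutral_mass - tol, side="left")
        hi = np.searchsorted(self._masses, neutral_mass + tol, side="right")
        return self._entries[lo:hi]

    def theo_mz(self, peptide: str, mods: tuple[ModPlacement, ...]) -> np.ndarray:
        key = (peptide, mods)
        cached = self._frag_cache.get(key)
        if cached is None:
            frags = fragments(peptide, mods, self._cfg.max_frag_charge)
            cached = np.sort(np.array([f.mz for f in frags]))
            self._frag_cache[key] = cached
        return cached


# ---------------------------------------------------------------------------
# Search + FDR
# ---------------------------------------------------------------------------

def estimate_fdr(matches: list[PeptideMatch]) -> list[PeptideMatch]:
    """Assign target-decoy q-values: FDR(t) = #decoy(>=t) / #target(>=t),
    q = the minimum FDR over all thresholds at or below the match's score."""
    if not matches:
        return matches
    order = sorted(
        range(len(matches)),
        key=lambda i: (matches[i].score, matches[i].intensity_frac),
        reverse=True,
    )
    n_t = n_d = 0
    fdrs = []
    for i in order:
        if matches[i].is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append(n_d / max(n_t, 1))
    qs = [0.0] * len(order)
    running = 1.0
    for rank in range(len(order) - 1, -1, -1):
        running = min(running, fdrs[rank])
        qs[rank] = running
    for rank, i in enumerate(order):
        matches[i].q = min(qs[rank], 1.0)
    return matches


@dataclass
class PassResult:
    pass_label: str
    matches: list[PeptideMatch]  # best PSM per spectrum, q-values assigned
    accepted: list[PeptideMatch]  # targets with q <= fdr
    unmatched: list[Spectrum]


def search_pass(
    spectra: Sequence[Spectrum],
    index: PeptideIndex,
    cfg: SearchConfig,
    pass_label: str,
) -> PassResult:
    """Best target/decoy match per spectrum, q-values, and the unmatched set
    (spectra without a target match at q <= cfg.fdr)."""
    matches: list[PeptideMatch] = []
    matched_ids: dict[str, PeptideMatch] = {}
    for s in spectra:
        best = None
        for mass, seq, mods, prots, missed, decoy, semi in index.candidates(
            s.neutral_mass, cfg.precursor_tol_ppm
        ):
            score, frac, k = score_psm(s, index.theo_mz(seq, mods), cfg.fragment_tol)
            if score <= 0 or k < cfg.min_matched_fragments:
                continue
            cand = (score, frac, seq, mods, prots, missed, decoy, semi)
            if best is None or cand[:2] > best[:2]:
                best = cand
        if best is not None:
            m = PeptideMatch(
                spectrum_id=s.spectrum_id,
                peptide=best[2],
                mods=best[3],
                proteins=best[4],
                missed=best[5],
                score=best[0],
                intensity_frac=best[1],
                is_decoy=best[6],
                pass_label=pass_label,
                semi=best[7],
            )
            matches.append(m)
            matched_ids[s.spectrum_id] = m
    estimate_fdr(matches)
    accepted = [m for m in matches if not m.is_decoy and m.q is not None and m.q <= cfg.fdr]
    accepted_ids = {m.spectrum_id for m in accepted}
    unmatched = [s for s in spectra if s.spectrum_id not in accepted_ids]
    return PassResult(pass_label, matches, accepted, unmatched)


# ---------------------------------------------------------------------------
# Parsimony protein grouping
# ---------------------------------------------------------------------------

def _exact_min_cover(prot2pep: dict[str, frozenset], universe: set) -> Optional[list[str]]:
    """Smallest protein set covering all peptides; ties resolved toward the
    cover containing proteins with more peptides, then lexicographically."""
    prots = sorted(prot2pep)
    for size in range(1, len(prots) + 1):
        best = None
        for combo in itertools.combinations(prots, size):
            covered = set().union(*(prot2pep[p] for p in combo))
            if covered >= universe:
                rank = (tuple(sorted((-len(prot2pep[p]), p) for p in combo)))
                if best is None or rank < best[0]:
                    best = (rank, list(combo))
        if best is not None:
            return best[1]
    return None


def group_proteins(
    matches: Sequence[PeptideMatch],
    fdr: float = 0.01,
    exact_limit: int = 15,
) -> list[ProteinGroup]:
    """Parsimony grouping of confident peptides into a minimal protein set.

    Small instances (<= ``exact_limit`` distinct proteins per connected
    component after subset-merging) are solved as exact minimum set cover;
    larger ones by the standard greedy cover.  Proteins whose peptide sets
    are subsets of a chosen protein's set join its group.  Protein-level
    q-values come from target-decoy counting on group best scores.
    """
    # peptide-level confident matches: targets at q <= fdr plus decoys above
    # the weakest accepted target score (they carry the protein-level FDR).
    targets = [m for m in matches if not m.is_decoy and m.q is not None and m.q <= fdr]
    if not targets:
        return []
    min_score = min(m.score for m in targets)
    decoys = [m for m in matches if m.is_decoy and m.score >= min_score]
    use = targets + decoys

    pep_best: dict[str, float] = {}
    pep2prot: dict[str, set[str]] = {}
    for m in use:
        pep_best[m.peptide] = max(pep_best.get(m.peptide, 0.0), m.score)
        pep2prot.setdefault(m.peptide, set()).update(m.proteins)
    prot2pep: dict[str, frozenset] = {}
    for pep, prots in pep2prot.items():
        for p in prots:
            prot2pep.setdefault(p, set()).add(pep)  # type: ignore[arg-type]
    prot2pep = {p: frozenset(s) for p, s in prot2pep.items()}
    universe = set(pep2prot)

    chosen: list[str]
    if len(prot2pep) <= exact_limit:
        chosen = _exact_min_cover(prot2pep, universe) or []
    else:
        chosen = []
        uncovered = set(universe)
        while uncovered:
            leader = min(
                prot2pep,
                key=lambda p: (-len(prot2pep[p] & uncovered), -len(prot2pep[p]), p),
            )
            if not prot2pep[leader] & uncovered:
                break
            chosen.append(leader)
            uncovered -= prot2pep[leader]

    # order leaders by explanatory power for deterministic output
    chosen = sorted(chosen, key=lambda p: (-len(prot2pep[p]), p))
    grouped: set[str] = set()
    groups: list[ProteinGroup] = []
    assigned_peps: set[str] = set()
    for leader in chosen:
        members = sorted(
            p
            for p in prot2pep
            if p not in grouped and prot2pep[p] <= prot2pep[leader]
        )
        grouped.update(members)
        peps = tuple(sorted(prot2pep[leader]))
        groups.append(
            ProteinGroup(
                leader=leader,
                members=tuple(members),
                peptides=peps,
                best_score=max(pep_best[p] for p in peps),
                is_decoy=leader.startswith("DECOY_"),
            )
        )
        assigned_peps.update(peps)
    # protein-level q by picket-fence counting on group best scores
    order = sorted(range(len(groups)), key=lambda i: groups[i].best_score, reverse=True)
    n_t = n_d = 0
    fdrs = []
    for i in order:
        if groups[i].is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdrs.append(n_d / max(n_t, 1))
    qs = [0.0] * len(order)
    run = 1.0
    for rank in range(len(order) - 1, -1, -1):
        run = min(run, fdrs[rank])
        qs[rank] = run
    for rank, i in enumerate(order):
        groups[i].q = min(qs[rank], 1.0)
    return groups


# ---------------------------------------------------------------------------
# Missing-protein evidence
# ---------------------------------------------------------------------------

def missing_protein_evidence(
    protein_seq: str,
    unique_peptides: Iterable[str],
    min_len: int = 9,
) -> str:
    """HPP-style protein-evidence call from uniquely mapping peptides.

    ``PE1_eligible``: at least two unique peptides of >= ``min_len`` residues
    whose mapped intervals are non-nested (neither contains the other);
    ``single_peptide``: exactly one such peptide, or several but all nested;
    ``none`` otherwise.
    """
    intervals = []
    for pep in set(unique_peptides):
        if len(pep) < min_len:
            continue
        pos = protein_seq.find(pep)
        if pos < 0:
            continue
        intervals.append((pos, pos + len(pep)))
    if not intervals:
        return "none"
    for (s1, e1), (s2, e2) in itertools.combinations(intervals, 2):
        nested = (s1 <= s2 and e2 <= e1) or (s2 <= s1 and e1 <= e2)
        if not nested:
            return "PE1_eligible"
    return "single_peptide"


# ---------------------------------------------------------------------------
# Iterative multi-pass search
# ---------------------------------------------------------------------------

@dataclass
class SearchDatabases:
    reference: list[ProteinRecord]
    saav: list[ProteinRecord] = field(default_factory=list)
    junction: list[ProteinRecord] = field(default_factory=list)
    orf: list[ProteinRecord] = field(default_factory=list)
    signal: list[ProteinRecord] = field(default_factory=list)


def iterative_search(
    spectra: Sequence[Spectrum],
    dbs: SearchDatabases,
    cfg: SearchConfig,
) -> dict[str, PassResult]:
    """The multi-pass strategy: reference search first, then unmatched
    spectra against the PTM-widened reference, then the proteogenomic
    (SAAV/junction/ORF) databases, then the semi-tryptic signal-peptide
    database.  Each pass is FDR-controlled independently; custom passes
    exclude peptides already present in the reference digest so a wild-type
    peptide can never surface as a variant identification.
    """
    results: dict[str, PassResult] = {}
    ref_index = PeptideIndex(dbs.reference, cfg)
    ref_peptides = ref_index.target_peptides
    res1 = search_pass(spectra, ref_index, cfg, "reference")
    results["reference"] = res1
    current = res1.unmatched

    if current:
        ptm_cfg = replace(cfg, variable_mods=PTM_PASS_VARIABLE)
        ptm_index = PeptideIndex(dbs.reference, ptm_cfg)
        res2 = search_pass(current, ptm_index, ptm_cfg, "ptm")
        results["ptm"] = res2
        current = res2.unmatched

    custom = list(dbs.saav) + list(dbs.junction) + list(dbs.orf)
    if custom and current:
        idx = PeptideIndex(custom, cfg, exclude_peptides=ref_peptides)
        res3 = search_pass(current, idx, cfg, "proteogenomic")
        # relabel by database origin of the best protein link
        origin_of = {r.accession: r.origin for r in custom}
        for m in res3.matches:
            if not m.is_decoy:
                m.pass_label = origin_of.get(m.proteins[0], "proteogenomic")
        results["proteogenomic"] = res3
        current = res3.unmatched

    if dbs.signal and current:
        semi_cfg = replace(
            cfg,
            enzyme=replace(cfg.enzyme, specificity="semi"),
            variable_mods=STANDARD_VARIABLE,
        )
        idx = PeptideIndex(dbs.signal, semi_cfg, exclude_peptides=ref_peptides)
        res4 = search_pass(current, idx, semi_cfg, "signal")
        results["signal"] = res4
    return results
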