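"""Transcriptome-proteome integration.

Downstream interpretation of confident peptide identifications: allelic
expression classes of variant (SAAV) peptides, protein N-terminus and
translation-initiation-site classification with near-cognate TIS scanning,
signal-peptide cleavage offsets, junction-supported proteoforms, iBAQ
protein quantification, mRNA-protein correlation and tissue enrichment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .custom_db import ProteinRecord, SAAVRecord
from .enzyme import EnzymeConfig, count_tryptic_peptides, digest
from .search_engine import PeptideMatch, ProteinGroup
from .sequence_models import (
    GenomeSequence,
    JunctionClass,
    SpliceJunction,
    TranscriptModel,
    classify_junction,
    spliced_sequence,
    translate,
)

__all__ = [
    "AlleleEvidence",
    "NTermCall",
    "CleavageCall",
    "ProteinQuant",
    "ProteoformCall",
    "classify_allelic_expression",
    "evaluate_allelic_evidence",
    "classify_nterm",
    "scan_near_cognate_tis",
    "upstream_inframe_region",
    "classify_cleavage",
    "flag_dual_cleavage",
    "compute_ibaq",
    "correlate_mrna_protein",
    "call_enriched_genes",
    "detect_junction_proteoforms",
    "detect_intron_retention",
]

NEAR_COGNATE = ("CTG", "GTG", "TTG", "ACG", "ATA", "ATT", "ATC", "AAG", "AGG")
START_CODONS = ("ATG",) + NEAR_COGNATE


# ---------------------------------------------------------------------------
# Allelic expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleEvidence:
    saav: SAAVRecord
    genotype: str  # het | hom_alt
    ref_detected: bool
    alt_detected: bool
    klass: str
    conflict: bool
    observable: bool = True


def classify_allelic_expression(
    genotype: str, ref_detected: bool, alt_detected: bool
) -> tuple[str, bool]:
    """Map (mRNA genotype, peptide evidence) to an allelic-expression class.

    Returns (class, conflict): a homozygous-alt variant with a detected
    reference peptide is flagged as a possible misassignment, never dropped.
    """
    if genotype not in ("het", "hom_alt"):
        raise ValueError(f"genotype {genotype!r}")
    conflict = genotype == "hom_alt" and ref_detected
    if ref_detected and alt_detected:
        return "het_both", conflict
    if alt_detected:
        return ("hom_alt_only" if genotype == "hom_alt" else "het_alt_only"), conflict
    if ref_detected:
        return "ref_only", conflict
    return "undetected", conflict


def _site_detected(
    protein_seq: str, position: int, peptides: set[str], enzyme: EnzymeConfig
) -> tuple[bool, bool]:
    """(observable, detected) for the residue at 1-based ``position``.

    Observable: some fully tryptic peptide within length bounds covers the
    site.  Detected: one of the given peptide sequences covers it.
    """
    observable = detected = False
    for p in digest(protein_seq, enzyme):
        if p.semi:
            continue
        if p.start < position <= p.end:
            observable = True
            if p.sequence in peptides:
                detected = True
    return observable, detected


def evaluate_allelic_evidence(
    saavs: Sequence[SAAVRecord],
    saav_records: Sequence[ProteinRecord],
    ref_proteins: Mapping[str, str],
    accepted: Sequence[PeptideMatch],
    enzyme: EnzymeConfig = EnzymeConfig(),
) -> list[AlleleEvidence]:
    """Pair each SAAV's mRNA genotype with reference/alternate peptide
    detection among the accepted identifications."""
    peptides = {m.peptide for m in accepted}
    by_acc = {r.accession: r for r in saav_records}
    out = []
    for saav in saavs:
        ref_seq = ref_proteins.get(saav.protein_id)
        if ref_seq is None:
            continue
        acc = f"{saav.protein_id}|SAAV|{saav.label}"
        rec = by_acc.get(acc)
        alt_seq = rec.sequence if rec else (
            ref_seq[: saav.position - 1] + saav.alt_aa + ref_seq[saav.position :]
        )
        obs_r, det_r = _site_detected(ref_seq, saav.position, peptides, enzyme)
        obs_a, det_a = _site_detected(alt_seq, saav.position, peptides, enzyme)
        klass, conflict = classify_allelic_expression(saav.variant.genotype, det_r, det_a)
        out.append(
            AlleleEvidence(
                saav, saav.variant.genotype, det_r, det_a, klass, conflict,
                observable=obs_r and obs_a,
            )
        )
    return out


# ---------------------------------------------------------------------------
# N-termini and translation initiation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NTermCall:
    peptide: str
    protein_id: str
    klass: str  # annotated_acetyl | annotated_free | met_cleaved | upstream_inframe | extension
    offset_codons: int  # 0 = annotated TIS; negative = upstream
    tis_codon: Optional[str] = None
    tis_offset: Optional[int] = None


def upstream_inframe_region(tx: TranscriptModel, g: GenomeSequence) -> tuple[str, int]:
    """In-frame, stop-free 5'-UTR segment directly upstream of the CDS.

    Returns (nucleotide sequence whose length is a codon multiple, number of
    codons).  The segment ends immediately before the annotated start codon
    and is truncated after the nearest in-frame stop.
    """
    if not tx.cds:
        return "", 0
    seq = spliced_sequence(tx, g)
    # transcript coordinate of the CDS start
    cds_positions = sorted(tx.cds)
    if tx.strand == "+":
        cds_start_genomic = cds_positions[0][0]
    else:
        cds_start_genomic = cds_positions[-1][1]
    offset = 0
    found = False
    for s, e in tx.exons:  # transcript order
        lo, hi = min(s, e), max(s, e)
        if lo <= cds_start_genomic <= hi:
            offset += (cds_start_genomic - s) if tx.strand == "+" else (e - cds_start_genomic)
            found = True
            break
        offset += hi - lo + 1
    if not found:
        return "", 0
    n_codons = offset // 3
    region = seq[offset - 3 * n_codons : offset]
    aa = translate(region, 0, "keep")
    # keep only the stop-free suffix adjacent to the CDS
    stop = aa.rfind("*")
    if stop >= 0:
        region = region[3 * (stop + 1) :]
        n_codons = n_codons - (stop + 1)
    return region, n_codons


def scan_near_cognate_tis(
    utr_inframe: str, peptide_codon_offset: int
) -> Optional[tuple[str, int]]:
    """Nearest canonical or near-cognate start codon upstream of a peptide.

    ``utr_inframe`` is the in-frame UTR sequence ending right before the
    annotated start codon (codon at offset -1 is its last three bases);
    ``peptide_codon_offset`` (<= 0) is the peptide's first codon relative to
    the annotated TIS.  Scans codons strictly upstream of the peptide start
    toward the UTR 5' end; an intervening in-frame stop aborts the scan.
    Returns (codon, offset) or None.
    """
    n_up = len(utr_inframe) // 3
    for off in range(peptide_codon_offset - 1, -n_up - 1, -1):
        codon = utr_inframe[(off + n_up) * 3 : (off + n_up) * 3 + 3]
        if len(codon) < 3:
            break
        if codon in ("TAA", "TAG", "TGA"):
            return None
        if codon in START_CODONS:
            return codon, off
    return None


def classify_nterm(
    peptide: str,
    acetylated: bool,
    protein_seq: str,
    utr_inframe: str = "",
    protein_id: str = "",
) -> Optional[NTermCall]:
    """Classify a peptide relative to a protein's annotated N-terminus.

    The protein is extended upstream by the in-frame stop-free translation
    of its 5'-UTR; a peptide mapping internally (beyond residue 2) is not an
    N-terminal observation and returns None.
    """
    upstream_aa = translate(utr_inframe, 0, "keep") if utr_inframe else ""
    n_up = len(upstream_aa)
    extended = upstream_aa + protein_seq
    pos = extended.find(peptide)
    if pos < 0:
        return None
    offset = pos - n_up
    end = pos + len(peptide)
    tis: Optional[tuple[str, int]] = None
    if offset == 0:
        klass = "annotated_acetyl" if acetylated else "annotated_free"
    elif offset == 1 and protein_seq[:1] == "M":
        klass = "met_cleaved"
    elif offset < 0:
        klass = "upstream_inframe" if end <= n_up else "extension"
        tis = scan_near_cognate_tis(utr_inframe, offset)
    else:
        return None
    return NTermCall(
        peptide,
        protein_id,
        klass,
        offset,
        tis_codon=tis[0] if tis else None,
        tis_offset=tis[1] if tis else None,
    )


# ---------------------------------------------------------------------------
# Signal-peptide cleavage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageCall:
    protein_id: str
    observed_start: int  # 1-based first residue of the observed mature N-terminus
    annotated_end: int  # 1-based last residue of the annotated signal peptide
    offset: int
    klass: str  # annotated | alternate | unrelated


def classify_cleavage(
    observed_start: int,
    annotated_end: int,
    window: int = 5,
    protein_id: str = "",
) -> CleavageCall:
    """Compare an observed mature N-terminus with the annotated cleavage site.

    Offset = observed - annotated mature start; 0 is the annotated site,
    within ``window`` residues an alternate site, beyond it unrelated.
    """
    offset = observed_start - (annotated_end + 1)
    if offset == 0:
        klass = "annotated"
    elif abs(offset) <= window:
        klass = "alternate"
    else:
        klass = "unrelated"
    return CleavageCall(protein_id, observed_start, annotated_end, offset, klass)


def flag_dual_cleavage(calls: Iterable[CleavageCall]) -> set[str]:
    """Proteins observed with both the annotated and an alternate site."""
    ann, alt = set(), set()
    for c in calls:
        if c.klass == "annotated":
            ann.add(c.protein_id)
        elif c.klass == "alternate":
            alt.add(c.protein_id)
    return ann & alt


# ---------------------------------------------------------------------------
# Quantification and correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinQuant:
    group_id: str
    ibaq: Optional[float]
    summed_intensity: float
    theoretical_peptides: int


def compute_ibaq(
    psms: pd.DataFrame,
    groups: Sequence[ProteinGroup],
    protein_seqs: Mapping[str, str],
    min_peptide: int = 6,
    max_peptide: int = 30,
) -> list[ProteinQuant]:
    """iBAQ per protein group.

    ``psms`` columns: run, peptide, intensity.  Each run is scaled to equal
    total signal (mean of run totals), intensities are summed over the
    group's peptides, and divided by the number of fully tryptic peptides of
    length ``min_peptide``..``max_peptide`` of the group's lead protein.
    """
    psms = psms.copy()
    totals = psms.groupby("run")["intensity"].sum()
    target = float(totals.mean())
    psms["norm"] = psms.apply(
        lambda r: r["intensity"] * target / totals[r["run"]], axis=1
    )
    by_pep = psms.groupby("peptide")["norm"].sum()
    out = []
    for grp in groups:
        if grp.is_decoy:
            continue
        summed = float(sum(by_pep.get(p, 0.0) for p in grp.peptides))
        seq = protein_seqs.get(grp.leader, "")
        n_theo = count_tryptic_peptides(seq, min_peptide, max_peptide) if seq else 0
        ibaq = summed / n_theo if n_theo > 0 else None
        out.append(ProteinQuant(grp.leader, ibaq, summed, n_theo))
    return out


def correlate_mrna_protein(
    expr: Mapping[str, float], quants: Mapping[str, float]
) -> tuple[float, pd.DataFrame]:
    """Pearson r of log2 FPKM vs log2 iBAQ over genes with both > 0."""
    rows = [
        (g, expr[g], quants[g])
        for g in sorted(set(expr) & set(quants))
        if expr[g] > 0 and quants[g] > 0
    ]
    if len(rows) < 3:
        raise ValueError("fewer than 3 paired observations")
    df = pd.DataFrame(rows, columns=["gene", "fpkm", "ibaq"])
    df["log2_fpkm"] = np.log2(df["fpkm"])
    df["log2_ibaq"] = np.log2(df["ibaq"])
    r, _ = stats.pearsonr(df["log2_fpkm"], df["log2_ibaq"])
    return float(r), df


def call_enriched_genes(
    matrix: pd.DataFrame,
    target: str,
    fold: float = 5.0,
    min_expr: float = 1.0,
) -> set[str]:
    """Genes enriched in ``target``: expression >= min_expr and >= fold times
    the maximum across all other tissues (HPA-style enrichment)."""
    if target not in matrix.columns:
        raise ValueError(f"target column {target!r} missing")
    others = matrix.drop(columns=[target])
    if others.shape[1] == 0:
        raise ValueError("need at least one non-target tissue")
    tgt = matrix[target]
    other_max = others.max(axis=1)
    mask = (tgt >= min_expr) & (tgt >= fold * other_max)
    return set(matrix.index[mask])


# ---------------------------------------------------------------------------
# Junction proteoforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteoformCall:
    peptide: str
    event: str  # alt_donor | alt_acceptor | intron_retention | exon_extension
    junction: Optional[SpliceJunction] = None
    extension_bp: Optional[int] = None
    gene_id: str = ""
    ambiguous: bool = False


def detect_junction_proteoforms(
    junction_matches: Sequence[PeptideMatch],
    entries_by_accession: Mapping[str, SpliceJunction],
    reference_junctions: Sequence[SpliceJunction],
) -> list[ProteoformCall]:
    """Interpret confident junction-pass peptides as splice proteoforms.

    A novel donor with a known acceptor is an alternate donor (the exon-
    extension distance in bp is measured against the annotated junction
    sharing the acceptor); symmetrically for alternate acceptors; a junction
    novel at both ends is an exon extension event.  Annotated junctions
    yield no novel-proteoform call.  Peptides mapping to more than one
    junction are flagged ambiguous.
    """
    ref = list(reference_junctions)
    out = []
    for m in junction_matches:
        juncs = {
            entries_by_accession[a].key: entries_by_accession[a]
            for a in m.proteins
            if a in entries_by_accession
        }
        if not juncs:
            continue
        ambiguous = len(juncs) > 1
        j = next(iter(juncs.values()))
        if j.junction_known:
            continue
        if j.donor_known and j.acceptor_known:
            event, ext = "exon_extension", None  # novel pairing of known sites
        elif j.acceptor_known and not j.donor_known:
            event = "alt_donor"
            shared = [
                r for r in ref
                if r.contig == j.contig and r.strand == j.strand
                and r.acceptor_pos == j.acceptor_pos
            ]
            ext = None
            if shared:
                best = min(shared, key=lambda r: abs(j.donor_pos - r.donor_pos))
                ext = (j.donor_pos - best.donor_pos) * (1 if j.strand == "+" else -1)
        elif j.donor_known and not j.acceptor_known:
            event = "alt_acceptor"
            shared = [
                r for r in ref
                if r.contig == j.contig and r.strand == j.strand
                and r.donor_pos == j.donor_pos
            ]
            ext = None
            if shared:
                best = min(shared, key=lambda r: abs(j.acceptor_pos - r.acceptor_pos))
                ext = (best.acceptor_pos - j.acceptor_pos) * (1 if j.strand == "+" else -1)
        else:
            event, ext = "exon_extension", None
        out.append(ProteoformCall(m.peptide, event, j, ext, ambiguous=ambiguous))
    return out


def detect_intron_retention(
    orf_matches: Sequence[PeptideMatch],
    orf_records: Mapping[str, ProteinRecord],
    assembled_txs: Mapping[str, TranscriptModel],
    reference_junctions: Sequence[SpliceJunction],
) -> list[ProteoformCall]:
    """Intron-retention proteoforms: ORF-pass peptides whose genomic span
    lies wholly within an annotated intron of the same contig/strand."""
    out = []
    for m in orf_matches:
        for acc in m.proteins:
            rec = orf_records.get(acc)
            if rec is None or rec.origin != "orf":
                continue
            tx = assembled_txs.get(rec.get("transcript"))
            if tx is None:
                continue
            frame = int(rec.get("frame", "0"))
            seg_off = int(rec.get("aa_offset", "0"))
            seq_pos = rec.sequence.find(m.peptide)
            if seq_pos < 0:
                continue
            # transcript nt range of the peptide
            nt_start = frame + 3 * (seg_off + seq_pos)
            nt_end = nt_start + 3 * len(m.peptide)
            genomic = _transcript_range_to_genomic(tx, nt_start, nt_end)
            for rj in reference_junctions:
                if rj.contig != tx.contig or rj.strand != tx.strand:
                    continue
                if all(rj.start <= s and e <= rj.end for s, e in genomic):
                    out.append(
                        ProteoformCall(m.peptide, "intron_retention", rj, gene_id=tx.gene_id)
                    )
                    break
            else:
                continue
            break
    return out


def _transcript_range_to_genomic(
    tx: TranscriptModel, nt_start: int, nt_end: int
) -> list[tuple[int, int]]:
    """Genomic blocks (1-based inclusive) of transcript offsets [nt_start, nt_end)."""
    positions = []
    for s, e in tx.exons:
        if tx.strand == "+":
            positions.extend(range(s, e + 1))
        else:
            positions.extend(range(e, s - 1, -1))
    wanted = positions[nt_start:nt_end]
    if not wanted:
        return []
    blocks = []
    lo = hi = wanted[0]
    for p in wanted[1:]:
        if abs(p - hi) == 1:
            hi = p
        else:
            blocks.append((min(lo, hi), max(lo, hi)))
            lo = hi = p
    blocks.append((min(lo, hi), max(lo, hi)))
    return blocks
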