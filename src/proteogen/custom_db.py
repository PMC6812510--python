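"""Sample-specific search-database construction.

Builds the custom protein databases that let an MS/MS search see what a
reference database cannot: single-amino-acid-variant (SAAV) proteins from
non-synonymous SNVs in expressed genes, peptides spanning novel exon-exon
junctions (90-nt exonic flanks translated in three frames), three-frame ORFs
of assembled transcripts, N-terminal regions of signal-peptide proteins for
the semi-tryptic pass, and reversed decoys for target-decoy FDR estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .enzyme import EnzymeConfig, digest
from .sequence_models import (
    GenomeSequence,
    JunctionClass,
    SpliceJunction,
    TranscriptModel,
    cds_sequence,
    classify_junction,
    translate,
    translate_codon,
)

__all__ = [
    "VariantRecord",
    "SAAVRecord",
    "ProteinRecord",
    "JunctionPeptideEntry",
    "SignalAnnotation",
    "Consequence",
    "ReferenceMismatchError",
    "call_consequence",
    "translate_cds",
    "build_reference_db",
    "build_saav_db",
    "build_junction_db",
    "build_orf_db",
    "build_signal_db",
    "generate_decoys",
    "write_fasta",
    "read_fasta_records",
    "read_vcf",
    "read_expression_table",
    "read_signal_table",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ReferenceMismatchError(ValueError):
    """VCF ref allele disagrees with the genome."""


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    genotype: str  # 'het' | 'hom_alt'
    source_id: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("single-nucleotide variants only")
        if self.genotype not in ("het", "hom_alt"):
            raise ValueError(f"genotype {self.genotype!r}")


@dataclass(frozen=True)
class SAAVRecord:
    protein_id: str
    position: int  # 1-based residue
    ref_aa: str
    alt_aa: str
    variant: VariantRecord

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa == alt_aa")

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    origin: str  # reference | saav | junction | orf | signal | decoy
    meta: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if "X" in self.sequence or "*" in self.sequence:
            raise ValueError(f"{self.accession}: sequence contains X/*")

    def get(self, key: str, default: str = "") -> str:
        return dict(self.meta).get(key, default)


@dataclass(frozen=True)
class JunctionPeptideEntry:
    junction: SpliceJunction
    frame: int
    peptide: str
    boundary_offset: int  # residues 5' of the junction within the peptide
    index: int = 0  # uniquifies peptides of one junction
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self):
        if not (1 <= self.boundary_offset <= len(self.peptide) - 1):
            raise ValueError("peptide does not span the junction")

    @property
    def accession(self) -> str:
        j = self.junction
        return (f"JUNC|{j.contig}:{j.start}-{j.end}({j.strand})"
                f"|F{self.frame}|off{self.boundary_offset}|p{self.index}")


@dataclass(frozen=True)
class SignalAnnotation:
    protein_id: str
    signal_end: int  # 1-based last residue of the signal peptide

    def __post_init__(self):
        if not (5 <= self.signal_end <= 60):
            raise ValueError(f"signal_end {self.signal_end} outside sanity bounds [5, 60]")


@dataclass(frozen=True)
class Consequence:
    kind: str  # missense | synonymous | stop_gain | stop_loss | noncoding
    saav: Optional[SAAVRecord] = None


# ---------------------------------------------------------------------------
# Variant consequence calling
# ---------------------------------------------------------------------------

def _cds_positions(tx: TranscriptModel) -> list[int]:
    """Genomic positions of CDS bases in transcript (5'->3') order."""
    blocks = sorted(tx.cds)
    if tx.strand == "+":
        return [p for s, e in blocks for p in range(s, e + 1)]
    return [p for s, e in reversed(blocks) for p in range(e, s - 1, -1)]


def translate_cds(tx: TranscriptModel, g: GenomeSequence) -> str:
    """Protein of a CDS-complete transcript (stop excluded)."""
    return translate(cds_sequence(tx, g), 0, "truncate_at_stop")


def call_consequence(
    v: VariantRecord, tx: TranscriptModel, g: GenomeSequence
) -> Consequence:
    """Locate the variant in the spliced CDS and call its coding consequence.

    Strand-aware: on minus-strand transcripts the alt allele is complemented
    before substitution.  A variant outside the CDS (intron/UTR) is
    ``noncoding``; a ref-allele mismatch against the genome is a hard error.
    """
    if not tx.cds_complete:
        raise ValueError(f"{tx.transcript_id}: CDS absent or incomplete")
    if g.base(v.contig, v.position) != v.ref:
        raise ReferenceMismatchError(
            f"{v.contig}:{v.position} genome={g.base(v.contig, v.position)} vcf_ref={v.ref}"
        )
    if v.contig != tx.contig:
        return Consequence("noncoding")
    positions = _cds_positions(tx)
    try:
        idx = positions.index(v.position)
    except ValueError:
        return Consequence("noncoding")
    cds = cds_sequence(tx, g)
    codon_i, offset = divmod(idx, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_base = v.alt if tx.strand == "+" else v.alt.translate(_COMPLEMENT)
    mutated = codon[:offset] + alt_base + codon[offset + 1 :]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(mutated)
    if ref_aa == alt_aa:
        return Consequence("synonymous")
    if alt_aa == "*":
        return Consequence("stop_gain")
    if ref_aa == "*":
        return Consequence("stop_loss")
    return Consequence(
        "missense",
        SAAVRecord(tx.transcript_id, codon_i + 1, ref_aa, alt_aa, v),
    )


# ---------------------------------------------------------------------------
# Database builders
# ---------------------------------------------------------------------------

def build_reference_db(txs: Iterable[TranscriptModel], g: GenomeSequence) -> list[ProteinRecord]:
    """Translate every CDS-complete transcript into a reference protein entry."""
    out = []
    for tx in txs:
        if not tx.cds_complete:
            continue
        prot = translate_cds(tx, g)
        if not prot or "X" in prot:
            continue
        out.append(
            ProteinRecord(tx.transcript_id, prot, "reference", (("gene", tx.gene_id),))
        )
    return out


def build_saav_db(
    variants: Iterable[VariantRecord],
    txs: Iterable[TranscriptModel],
    g: GenomeSequence,
    expression: Mapping[str, float],
    fpkm_min: float = 0.1,
) -> tuple[list[ProteinRecord], list[SAAVRecord]]:
    """SAAV protein database: one full-length substituted protein per
    (transcript, missense variant) in an expressed gene (FPKM >= fpkm_min).
    """
    records, saavs = [], []
    tx_list = [t for t in txs if t.cds_complete]
    by_contig: dict[str, list[TranscriptModel]] = {}
    for t in tx_list:
        by_contig.setdefault(t.contig, []).append(t)
    for v in variants:
        for tx in by_contig.get(v.contig, []):
            s, e = tx.span
            if not (s <= v.position <= e):
                continue
            if expression.get(tx.gene_id, 0.0) < fpkm_min:
                continue
            cons = call_consequence(v, tx, g)
            if cons.kind != "missense":
                continue
            saav = cons.saav
            prot = translate_cds(tx, g)
            if saav.position > len(prot):
                continue  # variant in the stop codon
            mutated = prot[: saav.position - 1] + saav.alt_aa + prot[saav.position :]
            acc = f"{tx.transcript_id}|SAAV|{saav.label}"
            records.append(
                ProteinRecord(
                    acc,
                    mutated,
                    "saav",
                    (
                        ("gene", tx.gene_id),
                        ("protein", tx.transcript_id),
                        ("saav", saav.label),
                        ("genotype", v.genotype),
                        ("variant", f"{v.contig}:{v.position}{v.ref}>{v.alt}"),
                    ),
                )
            )
            saavs.append(saav)
    return records, saavs


def _exonic_flank(
    j: SpliceJunction,
    g: GenomeSequence,
    txs: Optional[Sequence[TranscriptModel]],
    flank_nt: int,
    side: str,
) -> tuple[str, bool]:
    """Up-to-``flank_nt`` exonic sequence adjacent to the intron, clipped at
    the flanking exon's far boundary (and at the contig edge).  Returns
    (sequence, truncated?).
    """
    if side == "left":
        end = j.start - 1
        start = max(1, end - flank_nt + 1)
    else:
        start = j.end + 1
        end = min(g.length(j.contig), start + flank_nt - 1)
    if txs:
        for tx in txs:
            if tx.contig != j.contig or tx.strand != j.strand:
                continue
            for es, ee in tx.exons_genomic:
                if side == "left" and ee == j.start - 1:
                    start = max(start, es)
                elif side == "right" and es == j.end + 1:
                    end = min(end, ee)
    seq = g.fetch(j.contig, start, end) if start <= end else ""
    return seq, len(seq) < flank_nt


def build_junction_db(
    junctions: Iterable[SpliceJunction],
    g: GenomeSequence,
    flank_nt: int = 90,
    enzyme: EnzymeConfig = EnzymeConfig(),
    txs: Optional[Sequence[TranscriptModel]] = None,
    novel_only: bool = True,
) -> tuple[list[JunctionPeptideEntry], list[ProteinRecord]]:
    """Junction-peptide database.

    For each stranded (non-annotated, unless ``novel_only=False``) junction:
    take up to ``flank_nt`` exonic nt on each side of the intron, concatenate
    in transcript orientation, translate in all three frames (novel junctions
    may fall outside any annotated CDS, so the frame cannot be inferred),
    digest, and keep only peptides genuinely spanning the boundary — at least
    one complete residue encoded on each side.  Frames with a stop codon
    across the boundary contribute nothing for that reading.
    """
    entries: list[JunctionPeptideEntry] = []
    records: list[ProteinRecord] = []
    seen: set[tuple] = set()
    for j in junctions:
        if j.strand not in "+-":
            continue  # translation frame undefined without strand
        if novel_only and j.junction_known is not None:
            if classify_junction(j) is JunctionClass.ANNOTATED:
                continue
        left, trunc_l = _exonic_flank(j, g, txs, flank_nt, "left")
        right, trunc_r = _exonic_flank(j, g, txs, flank_nt, "right")
        if not left or not right:
            continue
        if j.strand == "+":
            seq5, seq3 = left, right
            trunc5, trunc3 = trunc_l, trunc_r
        else:
            seq5 = str(Seq(right).reverse_complement())
            seq3 = str(Seq(left).reverse_complement())
            trunc5, trunc3 = trunc_r, trunc_l
        concat = seq5 + seq3
        boundary = len(seq5)
        for frame in (0, 1, 2):
            aa = translate(concat, frame, "keep")
            # walk stop-free segments with their aa offsets
            seg_start = 0
            for seg_end in [i for i, c in enumerate(aa) if c == "*"] + [len(aa)]:
                segment = aa[seg_start:seg_end]
                off0 = seg_start
                seg_start = seg_end + 1
                if "X" in segment or len(segment) < enzyme.min_length:
                    continue
                for p in digest(segment, enzyme):
                    if p.semi:
                        continue
                    nt_start = frame + 3 * (off0 + p.start)
                    nt_end = nt_start + 3 * len(p.sequence)
                    # at least one complete residue each side of the boundary
                    if not (nt_start + 3 <= boundary <= nt_end - 3):
                        continue
                    bo = -(-(boundary - nt_start) // 3)  # ceil: straddling codon counts left
                    key = (j.key, frame, p.sequence, bo)
                    if key in seen:
                        continue
                    seen.add(key)
                    n_for_j = sum(1 for k in seen if k[0] == j.key)
                    entry = JunctionPeptideEntry(
                        j, frame, p.sequence, bo, n_for_j, trunc5, trunc3
                    )
                    entries.append(entry)
                    records.append(
                        ProteinRecord(
                            entry.accession,
                            p.sequence,
                            "junction",
                            (
                                ("junction", f"{j.contig}:{j.start}-{j.end}"),
                                ("strand", j.strand),
                                ("frame", str(frame)),
                                ("boundary_offset", str(bo)),
                            ),
                        )
                    )
    return entries, records


def build_orf_db(
    txs: Iterable[TranscriptModel],
    g: GenomeSequence,
    min_orf_aa: int = 7,
) -> list[ProteinRecord]:
    """Three-forward-frame ORF database of (assembled) transcripts.

    Transcripts are stranded, so only the three forward frames of the spliced
    sequence are read; each frame is split at stops and segments of at least
    ``min_orf_aa`` residues are kept with (transcript, frame, offset)
    provenance.
    """
    from .sequence_models import spliced_sequence

    out = []
    for tx in txs:
        seq = spliced_sequence(tx, g)
        for frame in (0, 1, 2):
            aa = translate(seq, frame, "keep")
            start = 0
            for end in [i for i, c in enumerate(aa) if c == "*"] + [len(aa)]:
                segment = aa[start:end]
                off = start
                start = end + 1
                if len(segment) < min_orf_aa or "X" in segment:
                    continue
                acc = f"{tx.transcript_id}|ORF|F{frame}|{off}"
                out.append(
                    ProteinRecord(
                        acc,
                        segment,
                        "orf",
                        (
                            ("transcript", tx.transcript_id),
                            ("gene", tx.gene_id),
                            ("frame", str(frame)),
                            ("aa_offset", str(off)),
                        ),
                    )
                )
    return out


def build_signal_db(
    proteins: Mapping[str, str],
    signals: Iterable[SignalAnnotation],
    window_aa: int = 60,
) -> list[ProteinRecord]:
    """N-terminal regions (signal peptide + ``window_aa`` mature residues) of
    signal-annotated proteins, for the semi-tryptic cleavage-site search."""
    out = []
    for ann in signals:
        seq = proteins.get(ann.protein_id)
        if seq is None:
            warnings.warn(f"signal annotation for unknown protein {ann.protein_id}")
            continue
        if len(seq) <= ann.signal_end:
            warnings.warn(f"{ann.protein_id}: shorter than its signal peptide")
            continue
        region = seq[: ann.signal_end + window_aa]
        out.append(
            ProteinRecord(
                f"{ann.protein_id}|SIGNAL|end{ann.signal_end}",
                region,
                "signal",
                (("protein", ann.protein_id), ("signal_end", str(ann.signal_end))),
            )
        )
    return out


def generate_decoys(db: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target, accession-prefixed DECOY_."""
    if not db:
        raise ValueError("target database is empty")
    out = []
    for rec in db:
        if rec.origin == "decoy" or rec.accession.startswith("DECOY_"):
            raise ValueError(f"refusing to build a decoy of decoy {rec.accession}")
        out.append(ProteinRecord("DECOY_" + rec.accession, rec.sequence[::-1], "decoy"))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            meta = " ".join(f"{k}={v}" for k, v in rec.meta)
            header = f">{rec.accession} origin={rec.origin}" + (f" {meta}" if meta else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_fasta_records(path: str | Path) -> list[ProteinRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split()[1:]
        kv = dict(f.split("=", 1) for f in fields if "=" in f)
        origin = kv.pop("origin", "reference")
        out.append(ProteinRecord(rec.id, str(rec.seq), origin, tuple(sorted(kv.items()))))
    return out


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read SNVs with sample genotype from a VCF (v4.x) file.

    Multi-allelic rows are decomposed; indels and MNVs are skipped with a
    warning.  Genotype of the first sample is used: both alleles equal to
    the alt index -> hom_alt, one -> het.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            contig, pos, vid, ref, alts = f[0], int(f[1]), f[2], f[3], f[4].split(",")
            gt_alleles: list[str] = []
            if len(f) >= 10:
                fmt = f[8].split(":")
                sample = f[9].split(":")
                if "GT" in fmt:
                    gt = sample[fmt.index("GT")]
                    gt_alleles = gt.replace("|", "/").split("/")
            for ai, alt in enumerate(alts, start=1):
                if len(ref) != 1 or len(alt) != 1 or alt in (".", "*"):
                    warnings.warn(f"skipping non-SNV {contig}:{pos} {ref}>{alt}")
                    continue
                if gt_alleles:
                    hits = gt_alleles.count(str(ai))
                    if hits == 0:
                        continue
                    genotype = "hom_alt" if hits == len(gt_alleles) else "het"
                else:
                    genotype = "het"
                out.append(VariantRecord(contig, pos, ref, alt, genotype, vid))
    return out


def read_expression_table(path: str | Path) -> dict[str, float]:
    """gene_id -> FPKM from a two-column TSV (header optional)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or parts[0].lower() in ("gene_id", "gene"):
                continue
            out[parts[0]] = float(parts[1])
    return out


def read_signal_table(path: str | Path) -> list[SignalAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or parts[0].lower() in ("protein_id", "protein"):
                continue
            out.append(SignalAnnotation(parts[0], int(parts[1])))
    return out
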