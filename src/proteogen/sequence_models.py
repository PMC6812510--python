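"""Genome, transcript and splice-junction models.

This module is the coordinate backbone of the pipeline: it reads a genome
FASTA and a GENCODE-style GTF, reconstructs spliced transcript and CDS
sequences (strand-aware, 1-based inclusive genomic coordinates), translates
nucleotide sequence in any frame, and enumerates/classifies exon-exon splice
junctions against a reference annotation.

Coordinate conventions
----------------------
* GTF and all in-memory coordinates are 1-based inclusive.
* Junction BED I/O is 0-based half-open (converters are exact).
* A :class:`SpliceJunction` stores the *intron* span: ``start`` is the first
  intronic base, ``end`` the last.
* Exons of a :class:`TranscriptModel` are kept in transcript (5'->3') order;
  for minus-strand transcripts that is descending genomic order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "SpliceJunction",
    "JunctionClass",
    "read_genome_fasta",
    "read_gtf",
    "write_gtf",
    "spliced_sequence",
    "cds_sequence",
    "translate",
    "enumerate_junctions",
    "annotate_junctions",
    "classify_junction",
    "infer_junction_strand",
    "read_junction_bed",
    "write_junction_classes",
]

_IUPAC_NT = set("ACGTNRYSWKMBDHV")
_AMBIGUOUS = set("RYSWKMBDHV")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"


class GenomeError(ValueError):
    pass


class GtfError(ValueError):
    pass


class GenomeSequence:
    """Uppercase DNA per contig with bounds-checked 1-based slicing."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise GenomeError("genome has no contigs")
        clean: dict[str, str] = {}
        for cid, seq in contigs.items():
            s = seq.upper()
            if not s:
                raise GenomeError(f"contig {cid!r} is empty")
            bad = set(s) - _IUPAC_NT
            if bad:
                raise GenomeError(f"contig {cid!r} has non-IUPAC characters: {sorted(bad)}")
            # ambiguity codes other than N carry no codon information here
            if set(s) & _AMBIGUOUS:
                s = "".join("N" if c in _AMBIGUOUS else c for c in s)
            clean[cid] = s
        self.contigs: dict[str, str] = clean

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end]`` (1-based inclusive)."""
        if contig not in self.contigs:
            raise GenomeError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if not (1 <= start <= end <= len(seq)):
            raise GenomeError(
                f"coordinates {contig}:{start}-{end} outside [1, {len(seq)}]"
            )
        return seq[start - 1 : end]

    def base(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos)


def read_genome_fasta(path: str | Path) -> GenomeSequence:
    """Load a genome FASTA; the header token before whitespace is the contig id."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GenomeError(f"duplicate contig id {rec.id!r}")
        contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise GenomeError(f"no FASTA records in {path}")
    return GenomeSequence(contigs)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript.

    ``exons`` and ``cds`` are tuples of (start, end), 1-based inclusive,
    ordered 5'->3' in transcript orientation.  ``source`` distinguishes
    reference annotation from RNA-seq-assembled models.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[tuple[int, int], ...]] = None
    source: str = "reference"

    def __post_init__(self):
        if self.strand not in "+-":
            raise GtfError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise GtfError(f"{self.transcript_id}: no exons")
        gen = self.exons_genomic
        for (s1, e1), (s2, e2) in zip(gen, gen[1:]):
            if s2 <= e1:
                raise GtfError(f"{self.transcript_id}: overlapping exons")
        if self.cds:
            for cs, ce in self.cds:
                if not any(s <= cs and ce <= e for s, e in self.exons):
                    raise GtfError(f"{self.transcript_id}: CDS outside exon union")

    @property
    def exons_genomic(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.exons))

    @property
    def span(self) -> tuple[int, int]:
        gen = self.exons_genomic
        return gen[0][0], gen[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        if not self.cds:
            return 0
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def cds_complete(self) -> bool:
        """True when a CDS is present and its spliced length is a codon multiple."""
        return bool(self.cds) and self.cds_length % 3 == 0


def _order_for_strand(blocks: Iterable[tuple[int, int]], strand: str):
    return tuple(sorted(blocks, reverse=(strand == "-")))


def read_gtf(path: str | Path, source: str = "reference") -> list[TranscriptModel]:
    """Parse exon (and CDS) features of a GTF into transcript models.

    Exons are grouped per ``transcript_id`` and returned sorted 5'->3' by
    strand.  Raises :class:`GtfError` on exons lacking a transcript_id or on
    inconsistent strand/contig within one transcript.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cdss: dict[str, list] = {}
    genes: dict[str, str] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError:
            raise GtfError(f"{feat.featuretype} at {feat.seqid}:{feat.start} lacks transcript_id")
        gid = feat.attributes.get("gene_id", [tid])[0]
        key = (feat.seqid, feat.strand)
        if tid in meta and meta[tid] != key:
            raise GtfError(f"{tid}: inconsistent contig/strand across features")
        meta[tid] = key
        genes[tid] = gid
        bucket = exons if feat.featuretype == "exon" else cdss
        bucket.setdefault(tid, []).append((feat.start, feat.end))
    out = []
    for tid, ex in exons.items():
        contig, strand = meta[tid]
        cds = cdss.get(tid)
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=genes[tid],
                contig=contig,
                strand=strand,
                exons=_order_for_strand(ex, strand),
                cds=_order_for_strand(cds, strand) if cds else None,
                source=source,
            )
        )
    return out


def write_gtf(txs: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in txs:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            s, e = tx.span
            fh.write(
                f"{tx.contig}\tproteogen\ttranscript\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for s_, e_ in tx.exons_genomic:
                fh.write(
                    f"{tx.contig}\tproteogen\texon\t{s_}\t{e_}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            if tx.cds:
                for s_, e_ in sorted(tx.cds):
                    fh.write(
                        f"{tx.contig}\tproteogen\tCDS\t{s_}\t{e_}\t.\t{tx.strand}\t0\t{attrs}\n"
                    )


def _splice(blocks: Sequence[tuple[int, int]], strand: str, contig: str, g: GenomeSequence) -> str:
    parts = [g.fetch(contig, s, e) for s, e in sorted(blocks)]
    seq = "".join(parts)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def spliced_sequence(tx: TranscriptModel, g: GenomeSequence) -> str:
    """Exon sequences concatenated 5'->3' (reverse-complemented on minus strand)."""
    return _splice(tx.exons_genomic, tx.strand, tx.contig, g)


def cds_sequence(tx: TranscriptModel, g: GenomeSequence) -> str:
    if not tx.cds:
        raise GtfError(f"{tx.transcript_id}: no CDS")
    return _splice(tx.cds, tx.strand, tx.contig, g)


def translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return _CODON_TO_AA[codon]


def translate(dna: str, frame: int = 0, stop_policy: str = "truncate_at_stop"):
    """Translate ``dna`` in ``frame`` (0/1/2) with the standard genetic code.

    Codons containing N translate to 'X'.  ``truncate_at_stop`` returns the
    protein string up to (excluding) the first stop; ``split_at_stops``
    returns the list of stop-free segments (possibly empty strings dropped);
    ``keep`` returns the raw string with '*' for stops.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"invalid frame {frame!r}")
    dna = dna.upper()
    aas = []
    for i in range(frame, len(dna) - 2, 3):
        aas.append(translate_codon(dna[i : i + 3]))
    raw = "".join(aas)
    if stop_policy == "keep":
        return raw
    if stop_policy == "truncate_at_stop":
        return raw.split("*", 1)[0]
    if stop_policy == "split_at_stops":
        return [seg for seg in raw.split("*") if seg]
    raise ValueError(f"unknown stop_policy {stop_policy!r}")


# ---------------------------------------------------------------------------
# Splice junctions
# ---------------------------------------------------------------------------

class JunctionClass(enum.Enum):
    ANNOTATED = "annotated"
    PARTIAL_NOVEL = "partial_novel"
    COMPLETE_NOVEL = "complete_novel"
    NOVEL_PAIRING = "novel_pairing"


@dataclass(frozen=True)
class SpliceJunction:
    """One intron: ``start``/``end`` are its first/last base (1-based inclusive).

    Donor/acceptor flags are filled by :func:`annotate_junctions`; until then
    they are ``None``.  The donor is the boundary at the 5' end of the intron
    in transcript orientation (genomic start on '+', genomic end on '-').
    """

    contig: str
    start: int
    end: int
    strand: str
    donor_known: Optional[bool] = None
    acceptor_known: Optional[bool] = None
    junction_known: Optional[bool] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"intron start {self.start} !< end {self.end}")
        if self.junction_known and not (self.donor_known and self.acceptor_known):
            raise ValueError("junction_known requires donor_known and acceptor_known")

    @property
    def donor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_pos(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def key(self) -> tuple:
        return (self.contig, self.strand, self.start, self.end)


def enumerate_junctions(txs: Iterable[TranscriptModel]) -> list[SpliceJunction]:
    """One junction per adjacent exon pair; single-exon transcripts contribute none."""
    seen = set()
    out = []
    for tx in txs:
        gen = tx.exons_genomic
        for (s1, e1), (s2, e2) in zip(gen, gen[1:]):
            j = SpliceJunction(tx.contig, e1 + 1, s2 - 1, tx.strand)
            if j.key not in seen:
                seen.add(j.key)
                out.append(j)
    return out


def annotate_junctions(
    junctions: Iterable[SpliceJunction],
    reference: Iterable[SpliceJunction],
) -> list[SpliceJunction]:
    """Fill donor/acceptor/junction-known flags against the reference set."""
    ref = list(reference)
    ref_j = {j.key for j in ref}
    ref_donor = {(j.contig, j.strand, j.donor_pos) for j in ref}
    ref_acceptor = {(j.contig, j.strand, j.acceptor_pos) for j in ref}
    out = []
    for j in junctions:
        jk = j.key in ref_j
        dk = (j.contig, j.strand, j.donor_pos) in ref_donor
        ak = (j.contig, j.strand, j.acceptor_pos) in ref_acceptor
        out.append(replace(j, donor_known=dk, acceptor_known=ak, junction_known=jk))
    return out


def classify_junction(j: SpliceJunction) -> JunctionClass:
    """Classify a flag-annotated junction.

    annotated: the exact intron is annotated; partial_novel: exactly one of
    donor/acceptor is novel; complete_novel: both novel; novel_pairing: both
    sites known but never annotated as a pair.
    """
    if j.donor_known is None or j.acceptor_known is None or j.junction_known is None:
        raise ValueError("junction flags not populated")
    if j.junction_known and not (j.donor_known and j.acceptor_known):
        raise ValueError("inconsistent flags")
    if j.junction_known:
        return JunctionClass.ANNOTATED
    if j.donor_known and j.acceptor_known:
        return JunctionClass.NOVEL_PAIRING
    if j.donor_known or j.acceptor_known:
        return JunctionClass.PARTIAL_NOVEL
    return JunctionClass.COMPLETE_NOVEL


def infer_junction_strand(g: GenomeSequence, contig: str, start: int, end: int) -> str:
    """Infer strand from splice dinucleotides (GT-AG forward, CT-AC reverse).

    Returns '.' when neither motif matches; such junctions are excluded from
    peptide database construction because the translation frame is undefined.
    """
    first2 = g.fetch(contig, start, start + 1)
    last2 = g.fetch(contig, end - 1, end)
    if first2 == "GT" and last2 == "AG":
        return "+"
    if first2 == "CT" and last2 == "AC":
        return "-"
    return "."


def read_junction_bed(path: str | Path, g: Optional[GenomeSequence] = None) -> list[SpliceJunction]:
    """Read a BED6 junction table whose blocks are introns (0-based half-open).

    Strand '.' is resolved from splice-site dinucleotides when a genome is
    given; junctions that stay unstranded are returned with strand '.'.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            contig, b_start, b_end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) > 5 else "."
            start, end = b_start + 1, b_end  # 0-based half-open -> 1-based inclusive
            if strand == "." and g is not None:
                strand = infer_junction_strand(g, contig, start, end)
            out.append(SpliceJunction(contig, start, end, strand))
    return out


def write_junction_classes(junctions: Iterable[SpliceJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tintron_start\tintron_end\tstrand\tclass\n")
        for j in junctions:
            fh.write(
                f"{j.contig}\t{j.start}\t{j.end}\t{j.strand}\t{classify_junction(j).value}\n"
            )
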