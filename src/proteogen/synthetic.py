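"""Self-consistent synthetic study generator.

Builds a toy genome with multi-exon genes (GT-AG introns), reference and
RNA-seq-"assembled" transcript models, planted novel splice events
(alternate-donor junctions, intron retention), 5'-UTR near-cognate
translation-initiation sites, signal peptides with planted cleavage
offsets, coding SNVs with controlled consequence and zygosity, a gene
expression table plus a multi-tissue matrix with planted enriched genes,
and MS/MS spectra (b/y ladders with dropout, jitter and noise) for planted
reference, SAAV, junction, PTM, N-terminal and signal-cleaved peptides —
together with a ground-truth manifest covering every spectrum and variant.

Every artifact derives from one master seed via labeled sub-streams, so a
given (config, seed) pair reproduces every output byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .custom_db import (
    ProteinRecord,
    SignalAnnotation,
    VariantRecord,
    build_junction_db,
    build_reference_db,
)
from .enzyme import EnzymeConfig, digest
from .masses import (
    ACETYL_K,
    ACETYL_PROTEIN_NTERM,
    CARBAMIDOMETHYL_C,
    DIMETHYL_KR,
    GG_K,
    METHYL_KR,
    TRIMETHYL_K,
    ModPlacement,
    PROTON,
    fragments,
    peptide_mass,
)
from .sequence_models import (
    GenomeSequence,
    SpliceJunction,
    TranscriptModel,
    annotate_junctions,
    enumerate_junctions,
    write_gtf,
)
from .spectra_io import Spectrum, write_mgf

__all__ = ["SimConfig", "SimulatedStudy", "simulate_study"]

_STOPS = ("TAA", "TAG", "TGA")

# codons for "safe" filler amino acids: never K/R, never a canonical or
# near-cognate start codon, never a stop
_SAFE_CODONS = {
    "G": "GGC", "A": "GCC", "S": "TCC", "P": "CCC", "V": "GTC",
    "T": "ACC", "L": "CTC", "N": "AAC", "D": "GAC", "Q": "CAA",
    "E": "GAA", "H": "CAC", "F": "TTC", "Y": "TAC", "W": "TGG",
    "C": "TGC", "I": "ATC", "M": "ATG",
}
_CODON_CHOICES = {
    "G": ["GGT", "GGC", "GGA", "GGG"], "A": ["GCT", "GCC", "GCA", "GCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "C": ["TGT", "TGC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "N": ["AAT", "AAC"], "D": ["GAT", "GAC"],
    "Q": ["CAA", "CAG"], "K": ["AAA", "AAG"], "E": ["GAA", "GAG"],
    "M": ["ATG"], "H": ["CAT", "CAC"], "F": ["TTT", "TTC"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "Y": ["TAT", "TAC"], "W": ["TGG"],
}
_SAFE_AA = "GASVTLNDQEHFY"  # filler residues (no K/R/M/C/W/I, no P: never blocks cleavage)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs of the synthetic generator.

    Defaults describe a small but complete study: 20 multi-exon genes on one
    contig, a fifth carrying a novel alternate-donor junction, planted coding
    SNVs at a 70:30 missense:synonymous ratio and 1:1 het:hom zygosity,
    log-normal expression with ~15% of genes below the FPKM detectability
    cutoff, and spectra as charge-2 precursors over charge-1 b/y ladders.
    """

    seed: int = 17
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 4)
    mean_cds_codons: int = 120
    frac_novel_junction: float = 0.2
    frac_intron_retention: float = 0.1
    frac_upstream_tis: float = 0.2
    frac_signal_peptide: float = 0.2
    frac_minus_strand: float = 0.25
    n_variants: int = 24
    het_fraction: float = 0.5
    missense_fraction: float = 0.7
    frac_silent_genes: float = 0.15
    n_ptm_peptides: int = 3  # per PTM type
    n_acetyl_nterm: int = 3
    n_met_cleaved: int = 3
    n_reference_peptides: Optional[int] = None  # None = all fully tryptic 0-missed
    peak_dropout: float = 0.0
    noise_peaks: int = 0
    n_noise_spectra: int = 30
    mz_jitter: bool = True
    intensity_sigma: float = 0.5
    abundance_sigma: float = 1.0
    n_tissues: int = 8
    n_enriched_genes: int = 3
    enrichment_fold: float = 5.0
    fragment_tol: float = 0.02
    alt_donor_extension_nt: int = 24
    gene_spacer_nt: int = 300

    def rng(self, label: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, zlib.crc32(label.encode()) & 0x7FFFFFFF])


@dataclass
class GeneTruth:
    gene_id: str
    transcript_id: str
    strand: str
    protein: str
    fpkm: float = 0.0
    abundance: float = 0.0
    enriched: bool = False
    signal_end: Optional[int] = None
    cleavage_offsets: list[int] = field(default_factory=list)
    upstream_kind: Optional[str] = None  # upstream_inframe | extension
    upstream_peptide: Optional[str] = None
    tis_codon: Optional[str] = None
    tis_offset: Optional[int] = None
    novel_junction: Optional[tuple] = None  # junction key
    alt_donor_extension: Optional[int] = None
    retention_peptide: Optional[str] = None
    retention_intron: Optional[tuple] = None


@dataclass
class SimulatedStudy:
    cfg: SimConfig
    genome: GenomeSequence
    ref_txs: list[TranscriptModel]
    assembled_txs: list[TranscriptModel]
    novel_junctions: list[SpliceJunction]
    variants: list[VariantRecord]
    variant_truth: pd.DataFrame
    expression: dict[str, float]
    tissue_matrix: pd.DataFrame
    enriched_genes: set[str]
    signals: list[SignalAnnotation]
    genes: list[GeneTruth]
    spectra: list[Spectrum]
    manifest: pd.DataFrame

    @property
    def reference_proteins(self) -> list[ProteinRecord]:
        return build_reference_db(self.ref_txs, self.genome)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every artifact in the formats the pipeline consumes."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {k: out / v for k, v in {
            "genome": "genome.fa", "gtf": "reference.gtf",
            "assembled_gtf": "assembled.gtf", "junctions": "novel_junctions.bed",
            "vcf": "variants.vcf", "expression": "expression.tsv",
            "tissues": "tissue_matrix.tsv", "signals": "signal_peptides.tsv",
            "mgf": "spectra.mgf", "manifest": "manifest.tsv",
            "manifest_json": "manifest.json",
        }.items()}
        with open(paths["genome"], "w") as fh:
            for cid, seq in self.genome.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_gtf(self.ref_txs, paths["gtf"])
        write_gtf(self.assembled_txs, paths["assembled_gtf"])
        with open(paths["junctions"], "w") as fh:
            for j in self.novel_junctions:
                fh.write(f"{j.contig}\t{j.start - 1}\t{j.end}\tnovel\t0\t{j.strand}\n")
        self._write_vcf(paths["vcf"])
        with open(paths["expression"], "w") as fh:
            fh.write("gene_id\tfpkm\n")
            for g, v in sorted(self.expression.items()):
                fh.write(f"{g}\t{v:.6g}\n")
        self.tissue_matrix.to_csv(paths["tissues"], sep="\t", float_format="%.6g")
        with open(paths["signals"], "w") as fh:
            fh.write("protein_id\tsignal_end\n")
            for s in self.signals:
                fh.write(f"{s.protein_id}\t{s.signal_end}\n")
        write_mgf(self.spectra, paths["mgf"])
        self.manifest.to_csv(paths["manifest"], sep="\t", index=False)
        with open(paths["manifest_json"], "w") as fh:
            json.dump(self.manifest.to_dict(orient="records"), fh, indent=1, default=str)
        return paths

    def _write_vcf(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for cid, seq in self.genome.contigs.items():
                fh.write(f"##contig=<ID={cid},length={len(seq)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
            for v in sorted(self.variants, key=lambda x: (x.contig, x.position)):
                gt = "0/1" if v.genotype == "het" else "1/1"
                fh.write(
                    f"{v.contig}\t{v.position}\t{v.source_id}\t{v.ref}\t{v.alt}"
                    f"\t100\tPASS\t.\tGT\t{gt}\n"
                )


# ---------------------------------------------------------------------------
# Gene construction (transcript-orientation local coordinates, then placed)
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    aas = "ACDEFGHILMNPQSTVWY"
    body = []
    for _ in range(n_aa - 1):
        if rng.random() < 0.12:
            body.append("K" if rng.random() < 0.5 else "R")
        else:
            body.append(aas[rng.integers(len(aas))])
    return "M" + "".join(body)


def _backtranslate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODON_CHOICES[aa][rng.integers(len(_CODON_CHOICES[aa]))] for aa in protein
    )


def _safe_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_SAFE_CODONS[_SAFE_AA[rng.integers(len(_SAFE_AA))]] for _ in range(n))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _plain_intron(rng: np.random.Generator) -> str:
    length = int(rng.integers(60, 91))
    return "GT" + _random_dna(rng, length - 4) + "AG"


def _alt_donor_intron(rng: np.random.Generator, ext: int) -> str:
    """Intron whose position-``ext`` suffix is itself a valid GT..AG intron."""
    inner = "GT" + _random_dna(rng, int(rng.integers(50, 71))) + "AG"
    return "GT" + _random_dna(rng, ext - 2) + inner


def _retention_intron(rng: np.random.Generator) -> tuple[str, str]:
    """In-frame stop-free intron carrying a fully tryptic 9-mer; returns
    (intron nt, planted intronic peptide)."""
    s_aas = [_SAFE_AA[rng.integers(len(_SAFE_AA))] for _ in range(8)]
    codons = (
        ["GTG"]
        + [_SAFE_CODONS[_SAFE_AA[rng.integers(len(_SAFE_AA))]] for _ in range(5)]
        + ["AAA"]
        + [_SAFE_CODONS[a] for a in s_aas]
        + ["AAG"]
        + [_SAFE_CODONS[_SAFE_AA[rng.integers(len(_SAFE_AA))]] for _ in range(2)]
        + ["CAG"]
    )
    intron = "".join(codons)
    assert intron.startswith("GT") and intron.endswith("AG")
    peptide = "".join(s_aas) + "K"
    return intron, peptide


@dataclass
class _GeneLayout:
    gene_seq: str  # genomic sequence in transcript orientation
    exons_local: list[tuple[int, int]]  # 1-based within gene
    cds_local: list[tuple[int, int]]
    novel_exons_local: Optional[list[tuple[int, int]]] = None
    retained_exons_local: Optional[list[tuple[int, int]]] = None
    novel_junction_local: Optional[tuple[int, int]] = None
    retention_intron_local: Optional[tuple[int, int]] = None
    utr5_len: int = 0
    cds_nt: str = ""


def _build_gene_layout(
    rng: np.random.Generator,
    cfg: SimConfig,
    protein: str,
    utr5: str,
    flags: dict,
) -> tuple[_GeneLayout, dict]:
    cds = _backtranslate(rng, protein) + "TAA"
    utr3 = _random_dna(rng, int(rng.integers(15, 40)))
    u, c = len(utr5), len(cds)
    tx = utr5 + cds + utr3
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    n_introns = n_exons - 1
    truth: dict = {}
    # codon-aligned insertion points inside the CDS, well apart
    usable = list(range(u + 30, u + c - 30, 3))
    rng.shuffle(usable)
    points: list[int] = []
    for p in usable:
        if all(abs(p - q) >= 60 for q in points):
            points.append(p)
        if len(points) == n_introns:
            break
    points.sort()
    introns: list[tuple[int, str]] = []
    special_idx = rng.integers(len(points)) if points else None
    ret_peptide = None
    for i, p in enumerate(points):
        if flags.get("novel_junction") and i == special_idx:
            introns.append((p, _alt_donor_intron(rng, cfg.alt_donor_extension_nt)))
        elif flags.get("intron_retention") and i == special_idx:
            intron, ret_peptide = _retention_intron(rng)
            introns.append((p, intron))
        else:
            introns.append((p, _plain_intron(rng)))
    # assemble genomic gene sequence and local exon coordinates
    gene_parts, exons_local = [], []
    cursor_tx, cursor_local = 0, 0
    intron_local_spans = []
    for p, iseq in introns:
        exon_seq = tx[cursor_tx:p]
        gene_parts.append(exon_seq)
        exons_local.append((cursor_local + 1, cursor_local + len(exon_seq)))
        cursor_local += len(exon_seq)
        intron_local_spans.append((cursor_local + 1, cursor_local + len(iseq)))
        gene_parts.append(iseq)
        cursor_local += len(iseq)
        cursor_tx = p
    gene_parts.append(tx[cursor_tx:])
    exons_local.append((cursor_local + 1, cursor_local + len(tx) - cursor_tx))
    gene_seq = "".join(gene_parts)

    def to_local_blocks(t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Map transcript range [t_start, t_end] (1-based) to local blocks."""
        blocks = []
        shift = 0
        bounds = [0] + [p for p, _ in introns] + [len(tx)]
        for k in range(len(bounds) - 1):
            seg_s, seg_e = bounds[k] + 1, bounds[k + 1]
            if k > 0:
                shift += len(introns[k - 1][1])
            lo, hi = max(t_start, seg_s), min(t_end, seg_e)
            if lo <= hi:
                blocks.append((lo + shift, hi + shift))
        return blocks

    cds_local = to_local_blocks(u + 1, u + c)
    layout = _GeneLayout(gene_seq, exons_local, cds_local, utr5_len=u, cds_nt=cds)
    if flags.get("novel_junction") and points:
        a, b = intron_local_spans[special_idx]
        ext = cfg.alt_donor_extension_nt
        novel = [list(e) for e in exons_local]
        novel[special_idx][1] += ext
        layout.novel_exons_local = [tuple(e) for e in novel]
        layout.novel_junction_local = (a + ext, b)
        truth["alt_donor_extension"] = ext
    if flags.get("intron_retention") and points:
        a, b = intron_local_spans[special_idx]
        merged = [list(e) for e in exons_local]
        merged[special_idx] = [merged[special_idx][0], merged[special_idx + 1][1]]
        del merged[special_idx + 1]
        layout.retained_exons_local = [tuple(e) for e in merged]
        layout.retention_intron_local = (a, b)
        truth["retention_peptide"] = ret_peptide
    return layout, truth


def _upstream_utr5(rng: np.random.Generator, kind: str) -> tuple[str, dict]:
    """5'-UTR with a planted near-cognate TIS and tryptic upstream peptide."""
    lead = _random_dna(rng, int(rng.integers(0, 3)))
    if kind == "upstream_inframe":
        s_aas = [_SAFE_AA[rng.integers(len(_SAFE_AA))] for _ in range(8)]
        codons = ["TAA", "CTG", _safe_codons(rng, 1), "AAA"] + [
            _SAFE_CODONS[a] for a in s_aas
        ] + ["AAA", _safe_codons(rng, 1), _safe_codons(rng, 1)]
        peptide = "".join(s_aas) + "K"
        truth = {"upstream_kind": kind, "tis_codon": "CTG", "tis_offset": -14,
                 "upstream_peptide": peptide, "peptide_offset": -11}
    else:  # extension
        c_aas = [_SAFE_AA[rng.integers(len(_SAFE_AA))] for _ in range(3)]
        codons = ["TAA", "GTG", _safe_codons(rng, 1), _safe_codons(rng, 1), "AAA"] + [
            _SAFE_CODONS[a] for a in c_aas
        ]
        truth = {"upstream_kind": kind, "tis_codon": "GTG", "tis_offset": -7,
                 "upstream_prefix": "".join(c_aas), "peptide_offset": -3}
    return lead + "".join(codons), truth


def _signal_protein(rng: np.random.Generator, n_aa: int) -> tuple[str, int]:
    """Protein starting with a K/R-free signal peptide ending in A, whose
    mature region has its first K at mature position 13."""
    sig_len = int(rng.integers(16, 26))
    sig = "M" + "".join(
        _SAFE_AA[rng.integers(len(_SAFE_AA))] for _ in range(sig_len - 2)
    ) + "A"
    mature12 = "".join(_SAFE_AA[rng.integers(len(_SAFE_AA))] for _ in range(12))
    rest = "A" + _random_protein(rng, max(20, n_aa - sig_len - 13))[2:]
    return sig + mature12 + "K" + rest, sig_len


# ---------------------------------------------------------------------------
# Stage simulators
# ---------------------------------------------------------------------------

def simulate_genome_annotation(cfg: SimConfig):
    """Genome FASTA + reference/assembled transcript models + novel junctions."""
    rng = cfg.rng("genome")
    n = cfg.n_genes
    counts = {
        "novel_junction": max(1, round(cfg.frac_novel_junction * n)),
        "intron_retention": max(1, round(cfg.frac_intron_retention * n)),
        "upstream": max(2, round(cfg.frac_upstream_tis * n)),
        "signal": max(2, round(cfg.frac_signal_peptide * n)),
    }
    roles: list[dict] = [dict() for _ in range(n)]
    pool = list(range(n))
    rng.shuffle(pool)
    it = iter(pool)
    # one special role per gene; tiny configs simply carry fewer events
    for role, count in (("novel_junction", counts["novel_junction"]),
                        ("intron_retention", counts["intron_retention"]),
                        ("upstream", counts["upstream"]),
                        ("signal", counts["signal"])):
        for k in range(count):
            gi = next(it, None)
            if gi is None:
                break
            if role == "upstream":
                roles[gi]["upstream"] = (
                    "upstream_inframe" if k % 2 == 0 else "extension"
                )
            else:
                roles[gi][role] = True

    genes: list[GeneTruth] = []
    ref_txs: list[TranscriptModel] = []
    assembled: list[TranscriptModel] = []
    novel_local: list[tuple[str, tuple[int, int], str]] = []
    chrom_parts: list[str] = []
    cursor = 0
    contig = "chr1"
    for gi in range(n):
        flags = roles[gi]
        gid, tid = f"G{gi:03d}", f"T{gi:03d}"
        strand = "-" if rng.random() < cfg.frac_minus_strand else "+"
        n_aa = max(60, int(rng.normal(cfg.mean_cds_codons, 20)))
        truth_extra: dict = {}
        if flags.get("signal"):
            protein, sig_len = _signal_protein(rng, n_aa)
        else:
            protein, sig_len = _random_protein(rng, n_aa), None
        if flags.get("upstream"):
            kind = flags["upstream"]
            utr5, up_truth = _upstream_utr5(rng, kind)
            truth_extra.update(up_truth)
        else:
            utr5 = _random_dna(rng, int(rng.integers(9, 30)))
        layout, ltruth = _build_gene_layout(rng, cfg, protein, utr5, flags)
        truth_extra.update(ltruth)
        spacer = _random_dna(rng, cfg.gene_spacer_nt)
        chrom_parts.append(spacer)
        cursor += len(spacer)
        gstart = cursor  # 0-based start of gene block
        Lg = len(layout.gene_seq)
        if strand == "+":
            chrom_parts.append(layout.gene_seq)
            def g(p: int) -> int:
                return gstart + p
        else:
            comp = str.maketrans("ACGTN", "TGCAN")
            chrom_parts.append(layout.gene_seq.translate(comp)[::-1])
            def g(p: int) -> int:
                return gstart + Lg - p + 1
        cursor += Lg

        def map_blocks(blocks):
            out = []
            for a, b in blocks:
                x, y = g(a), g(b)
                out.append((min(x, y), max(x, y)))
            # transcript order: ascending for +, descending for -
            return tuple(sorted(out, reverse=(strand == "-")))

        ref_txs.append(
            TranscriptModel(tid, gid, contig, strand,
                            map_blocks(layout.exons_local),
                            map_blocks(layout.cds_local), "reference")
        )
        if layout.novel_exons_local:
            assembled.append(
                TranscriptModel(f"{tid}.nov", gid, contig, strand,
                                map_blocks(layout.novel_exons_local), None, "assembled")
            )
            a, b = layout.novel_junction_local
            x, y = g(a), g(b)
            novel_local.append((contig, (min(x, y), max(x, y)), strand))
        if layout.retained_exons_local:
            assembled.append(
                TranscriptModel(f"{tid}.ret", gid, contig, strand,
                                map_blocks(layout.retained_exons_local), None, "assembled")
            )
            a, b = layout.retention_intron_local
            x, y = g(a), g(b)
            truth_extra["retention_intron"] = (contig, min(x, y), max(x, y), strand)
        if flags.get("upstream"):
            assembled.append(
                TranscriptModel(f"{tid}.asm", gid, contig, strand,
                                map_blocks(layout.exons_local), None, "assembled")
            )
        gt = GeneTruth(gid, tid, strand, protein)
        gt.signal_end = sig_len
        for k, v in truth_extra.items():
            if hasattr(gt, k):
                setattr(gt, k, v)
        gt._extra = truth_extra  # type: ignore[attr-defined]
        genes.append(gt)
    chrom_parts.append(_random_dna(rng, cfg.gene_spacer_nt))
    genome = GenomeSequence({contig: "".join(chrom_parts)})
    ref_junctions = enumerate_junctions(ref_txs)
    novel = annotate_junctions(
        [SpliceJunction(c, s, e, st) for c, (s, e), st in novel_local], ref_junctions
    )
    for gt in genes:
        if gt.alt_donor_extension is not None:
            for j, (c, (s, e), st) in zip(novel, novel_local):
                pass
    # attach novel junction keys to their genes
    ni = 0
    for gt in genes:
        if gt.alt_donor_extension is not None:
            gt.novel_junction = novel[ni].key
            ni += 1
    return genome, ref_txs, assembled, novel, genes


def simulate_expression(cfg: SimConfig, genes: Sequence[GeneTruth]):
    rng = cfg.rng("expression")
    n_silent = round(cfg.frac_silent_genes * len(genes))
    # silent genes are drawn from the role-free pool so every planted event
    # (junction, retention, upstream TIS, signal) sits in an expressed gene
    plain = [i for i, g in enumerate(genes)
             if not (g.signal_end or g.upstream_kind or g.novel_junction
                     or g.retention_peptide)]
    n_silent = min(n_silent, len(plain))
    silent_idx = set(rng.choice(plain, size=n_silent, replace=False).tolist())
    expression: dict[str, float] = {}
    for i, gt in enumerate(genes):
        if i in silent_idx:
            fpkm = float(rng.uniform(0.0, 0.09))
        else:
            fpkm = float(np.exp(rng.normal(3.0, 1.2)))
        gt.fpkm = expression[gt.gene_id] = fpkm
        gt.abundance = fpkm * float(np.exp(rng.normal(0.0, cfg.abundance_sigma)))

    tissues = ["HUVEC"] + [f"tissue_{i}" for i in range(1, cfg.n_tissues)]
    expressed = [i for i in range(len(genes)) if i not in silent_idx]
    enr_idx = set(
        rng.choice(expressed, size=min(cfg.n_enriched_genes, len(expressed)),
                   replace=False).tolist()
    )
    rows = []
    for i, gt in enumerate(genes):
        others = np.exp(rng.normal(1.0, 1.0, size=cfg.n_tissues - 1))
        if i in enr_idx:
            target = cfg.enrichment_fold * float(others.max()) * float(rng.uniform(1.2, 2.0))
            gt.enriched = True
        else:
            target = float(np.exp(rng.normal(1.0, 1.0)))
            # guarantee non-enrichment at the planted fold
            if target >= cfg.enrichment_fold * others.max():
                others[0] = target / (cfg.enrichment_fold * 0.8)
        rows.append([target] + list(others))
    matrix = pd.DataFrame(rows, index=[g.gene_id for g in genes], columns=tissues)
    matrix.index.name = "gene_id"
    enriched = {genes[i].gene_id for i in enr_idx}
    return expression, matrix, enriched


def simulate_variants(
    cfg: SimConfig,
    genes: Sequence[GeneTruth],
    ref_txs: Sequence[TranscriptModel],
    genome: GenomeSequence,
):
    """Codon-aware SNV placement realizing the missense:synonymous ratio.

    Missense variants never create/destroy K/R or stops (so digestion
    context is preserved and the variant peptide stays observable).
    """
    from .masses import MONO
    from .sequence_models import translate_codon

    # substitutions isobaric with a searched modification (methyl, dimethyl,
    # acetyl/trimethyl, oxidation, GlyGly, carbamidomethyl, phospho) cannot be
    # distinguished from a modified reference peptide by precursor mass
    mod_deltas = (57.02146, 42.01057, 15.99491, 79.96633,
                  14.01565, 28.03130, 42.04695, 114.04293)

    def _ambiguous_sub(ref_aa: str, alt_aa: str) -> bool:
        # 0.06 Da covers the 10 ppm precursor window up to the 5 kDa search
        # limit, so a substitution this close to a mod delta could match a
        # modified reference peptide instead
        d = abs(MONO[alt_aa] - MONO[ref_aa])
        return any(abs(d - md) < 0.06 for md in mod_deltas) or d < 0.06

    rng = cfg.rng("variants")
    tx_by_gene = {t.gene_id: t for t in ref_txs}
    n_mis = round(cfg.missense_fraction * cfg.n_variants)
    wanted = ["missense"] * n_mis + ["synonymous"] * (cfg.n_variants - n_mis)
    order = rng.permutation(len(genes))
    variants: list[VariantRecord] = []
    truth_rows = []
    used: dict[str, list[int]] = {}
    gene_cycle = [genes[i] for i in order]
    gi = 0
    comp = str.maketrans("ACGTN", "TGCAN")
    for vi, kind in enumerate(wanted):
        placed = False
        for _attempt in range(len(gene_cycle) * 4):
            gt = gene_cycle[gi % len(gene_cycle)]
            gi += 1
            tx = tx_by_gene[gt.gene_id]
            prot = gt.protein
            n_codons = len(prot)
            lo = (gt.signal_end or 0) + 14
            codon_candidates = [
                k for k in range(max(5, lo), n_codons - 3)
                if all(abs(k - u) >= 12 for u in used.get(gt.gene_id, []))
            ]
            if not codon_candidates:
                continue
            k = int(codon_candidates[rng.integers(len(codon_candidates))])
            cds_nt = _cds_nt_of(tx, genome)
            codon = cds_nt[3 * k : 3 * k + 3]
            choices = []
            for w in range(3):
                for alt in "ACGT":
                    if alt == codon[w]:
                        continue
                    mut = codon[:w] + alt + codon[w + 1 :]
                    ref_aa, alt_aa = translate_codon(codon), translate_codon(mut)
                    if kind == "synonymous" and ref_aa == alt_aa:
                        choices.append((w, alt, ref_aa, alt_aa))
                    elif kind == "missense":
                        if (
                            ref_aa != alt_aa
                            and alt_aa not in "KR*" and ref_aa not in "KR*"
                            and not _ambiguous_sub(ref_aa, alt_aa)
                        ):
                            choices.append((w, alt, ref_aa, alt_aa))
            if not choices:
                continue
            w, alt, ref_aa, alt_aa = choices[rng.integers(len(choices))]
            cds_idx = 3 * k + w
            gpos = _cds_positions_of(tx)[cds_idx]
            ref_nt_t = codon[w]
            if tx.strand == "-":
                ref_g, alt_g = ref_nt_t.translate(comp), alt.translate(comp)
            else:
                ref_g, alt_g = ref_nt_t, alt
            assert genome.base(tx.contig, gpos) == ref_g
            genotype = "het" if rng.random() < cfg.het_fraction else "hom_alt"
            v = VariantRecord(tx.contig, gpos, ref_g, alt_g, genotype, f"v{vi}")
            variants.append(v)
            used.setdefault(gt.gene_id, []).append(k)
            truth_rows.append({
                "variant_id": v.source_id, "gene_id": gt.gene_id,
                "transcript_id": tx.transcript_id, "contig": tx.contig,
                "position": gpos, "ref": ref_g, "alt": alt_g,
                "genotype": genotype, "consequence": kind,
                "protein_position": k + 1, "ref_aa": ref_aa, "alt_aa": alt_aa,
                "expressed": gt.fpkm >= 0.1,
            })
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place all requested variants")
    return variants, pd.DataFrame(truth_rows)


def _cds_positions_of(tx: TranscriptModel) -> list[int]:
    blocks = sorted(tx.cds)
    if tx.strand == "+":
        return [p for s, e in blocks for p in range(s, e + 1)]
    return [p for s, e in reversed(blocks) for p in range(e, s - 1, -1)]


def _cds_nt_of(tx: TranscriptModel, genome: GenomeSequence) -> str:
    from .sequence_models import cds_sequence

    return cds_sequence(tx, genome)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _fixed_mods(peptide: str) -> tuple[ModPlacement, ...]:
    return tuple(
        ModPlacement(i, CARBAMIDOMETHYL_C.name, CARBAMIDOMETHYL_C.delta)
        for i, aa in enumerate(peptide) if aa == "C"
    )


def _make_spectrum(
    rng: np.random.Generator,
    sid: str,
    peptide: str,
    mods: tuple[ModPlacement, ...],
    cfg: SimConfig,
    abundance: float,
) -> Spectrum:
    frags = fragments(peptide, mods, max_charge=1)
    mz = np.array(sorted(f.mz for f in frags))
    if cfg.peak_dropout > 0:
        keep = rng.random(len(mz)) >= cfg.peak_dropout
        if keep.sum() < 4:
            keep[:4] = True
        mz = mz[keep]
    if cfg.mz_jitter:
        jit = rng.normal(0.0, cfg.fragment_tol / 8.0, size=len(mz))
        mz = mz + np.clip(jit, -cfg.fragment_tol / 2, cfg.fragment_tol / 2)
    if cfg.intensity_sigma > 0:
        inten = abundance * np.exp(rng.normal(0.0, cfg.intensity_sigma, size=len(mz)))
    else:
        inten = np.full(len(mz), abundance)
    if cfg.noise_peaks > 0:
        noise_mz = rng.uniform(120.0, float(mz.max()) + 120.0, size=cfg.noise_peaks)
        noise_in = abundance * np.exp(rng.normal(-1.5, 0.5, size=cfg.noise_peaks))
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_in])
    mass = peptide_mass(peptide, mods)
    return Spectrum(sid, (mass + 2 * PROTON) / 2, 2, mz, inten)


def _mods_str(mods: tuple[ModPlacement, ...]) -> str:
    return ";".join(f"{m.name}@{m.position}" for m in sorted(mods)) or "-"


def simulate_spectra(cfg: SimConfig, study_parts: dict) -> tuple[list[Spectrum], pd.DataFrame]:
    """Spectra + manifest for planted reference/variant/junction/PTM/N-term/
    signal peptides plus pure-noise spectra."""
    rng = cfg.rng("spectra")
    genes: list[GeneTruth] = study_parts["genes"]
    genome: GenomeSequence = study_parts["genome"]
    ref_txs = study_parts["ref_txs"]
    novel = study_parts["novel_junctions"]
    variant_truth: pd.DataFrame = study_parts["variant_truth"]
    enzyme = EnzymeConfig()
    plan: list[tuple[str, str, tuple[ModPlacement, ...], dict]] = []

    proteins = {g.transcript_id: g.protein for g in genes}
    abundances = {g.transcript_id: g.abundance for g in genes}
    gene_of = {g.transcript_id: g for g in genes}

    # --- SAAV peptides (planned first: variant sites constrain which
    # reference-allele peptides exist in the sample) --------------------------
    alt_expected = []
    saav_plan = []
    ref_excluded: set[tuple[str, str]] = set()
    for row in variant_truth.to_dict(orient="records"):
        if row["consequence"] != "missense" or not row["expressed"]:
            continue
        prot = proteins[row["transcript_id"]]
        pos = row["protein_position"]
        mutated = prot[: pos - 1] + row["alt_aa"] + prot[pos:]
        alt_pep = next(
            (p for p in digest(mutated, EnzymeConfig(max_missed=0))
             if not p.semi and p.start < pos <= p.end), None
        )
        ref_pep = next(
            (p for p in digest(prot, EnzymeConfig(max_missed=0))
             if not p.semi and p.start < pos <= p.end), None
        )
        if alt_pep is None:
            continue
        if ref_pep is not None:
            # the reference-allele peptide is only present when the sample
            # actually expresses the reference allele (and is detected)
            ref_excluded.add((row["transcript_id"], ref_pep.sequence))
        detect_ref = row["genotype"] == "het" and rng.random() < 0.5 and ref_pep is not None
        saav_plan.append(("saav", alt_pep.sequence, _fixed_mods(alt_pep.sequence),
                          {"protein": row["transcript_id"], "variant_id": row["variant_id"],
                           "saav": f"{row['ref_aa']}{pos}{row['alt_aa']}",
                           "genotype": row["genotype"]}))
        expected = "hom_alt_only" if row["genotype"] == "hom_alt" else (
            "het_both" if detect_ref else "het_alt_only")
        alt_expected.append((row["variant_id"], expected))
        if detect_ref:
            saav_plan.append(("saav_ref", ref_pep.sequence, _fixed_mods(ref_pep.sequence),
                              {"protein": row["transcript_id"],
                               "variant_id": row["variant_id"],
                               "genotype": row["genotype"]}))

    # --- reference peptides -------------------------------------------------
    candidates = []
    for tid, prot in proteins.items():
        if gene_of[tid].fpkm < 0.1:
            continue
        for p in digest(prot, EnzymeConfig(max_missed=0)):
            if not p.semi and "X" not in p.sequence and (tid, p.sequence) not in ref_excluded:
                candidates.append((tid, p))
    if cfg.n_reference_peptides is None:
        chosen = candidates
    else:
        weights = np.array([abundances[t] for t, _ in candidates])
        idx = rng.choice(len(candidates), size=min(cfg.n_reference_peptides, len(candidates)),
                         replace=False, p=weights / weights.sum())
        chosen = [candidates[i] for i in sorted(idx)]
    for tid, p in chosen:
        plan.append(("reference", p.sequence, _fixed_mods(p.sequence),
                     {"protein": tid, "gene": gene_of[tid].gene_id}))

    # --- PTM-bearing peptides (second-pass search targets) -------------------
    ptm_specs = [ACETYL_K, METHYL_KR, DIMETHYL_KR, TRIMETHYL_K, GG_K]
    var_sites: dict[str, set[int]] = {}
    for row in variant_truth.to_dict(orient="records"):
        if row["consequence"] == "missense":
            var_sites.setdefault(row["transcript_id"], set()).add(row["protein_position"])
    with_internal_k = [
        (tid, p) for tid, prot in proteins.items() if gene_of[tid].fpkm >= 0.1
        for p in digest(prot, EnzymeConfig(max_missed=2))
        if not p.semi and p.missed >= 1 and p.start > 1 and "K" in p.sequence[:-1]
        and not any(p.start < pos <= p.end for pos in var_sites.get(tid, ()))
    ]
    rng.shuffle(with_internal_k)
    ki = 0
    for spec in ptm_specs:
        for _ in range(cfg.n_ptm_peptides):
            if ki >= len(with_internal_k):
                break
            tid, p = with_internal_k[ki]
            ki += 1
            sites = [i for i, aa in enumerate(p.sequence[:-1]) if aa in spec.target]
            if not sites:
                continue
            pos = sites[0]
            mods = tuple(sorted(_fixed_mods(p.sequence) + (ModPlacement(pos, spec.name, spec.delta),)))
            plan.append(("ptm", p.sequence, mods,
                         {"protein": tid, "ptm": spec.name, "site": pos}))

    # --- SAAV peptides (planned above) ---------------------------------------
    plan.extend(saav_plan)

    # --- junction-spanning peptides (same flank clipping as the search DB) ---
    entries, _recs = build_junction_db(
        novel, genome, enzyme=enzyme, txs=study_parts.get("assembled_txs"),
        novel_only=True,
    )
    by_j: dict[tuple, list] = {}
    for e in entries:
        by_j.setdefault(e.junction.key, []).append(e)
    for gt in genes:
        if gt.novel_junction and gt.novel_junction in by_j and gt.fpkm >= 0.1:
            e = max(by_j[gt.novel_junction], key=lambda x: (len(x.peptide), x.peptide))
            plan.append(("junction", e.peptide, _fixed_mods(e.peptide),
                         {"gene": gt.gene_id, "junction": str(gt.novel_junction),
                          "frame": e.frame, "event": "alt_donor",
                          "extension": gt.alt_donor_extension}))

    # --- intron-retention peptides -------------------------------------------
    for gt in genes:
        if gt.retention_peptide and gt.fpkm >= 0.1:
            plan.append(("retention", gt.retention_peptide,
                         _fixed_mods(gt.retention_peptide),
                         {"gene": gt.gene_id, "event": "intron_retention"}))

    # --- upstream-TIS peptides -----------------------------------------------
    tx_by_id = {t.transcript_id: t for t in ref_txs}
    for gt in genes:
        if not gt.upstream_kind or gt.fpkm < 0.1:
            continue
        if gt.upstream_kind == "upstream_inframe":
            pep = gt.upstream_peptide
        else:
            extra = gt._extra.get("upstream_prefix", "")  # type: ignore[attr-defined]
            prot = gt.protein
            # end at a cleavage site giving a searchable peptide: length >= 7,
            # <= 45, and at most 2 internal missed cleavages
            cut_sites = [i for i, aa in enumerate(prot)
                         if aa in "KR" and prot[i + 1 : i + 2] != "P"]
            end = next(
                (i for i in cut_sites
                 if len(extra) + i + 1 >= 7
                 and len(extra) + i + 1 <= 45
                 and sum(1 for c in cut_sites if c < i) <= 2),
                None,
            )
            if end is None:
                continue
            pep = extra + prot[: end + 1]
            gt.upstream_peptide = pep
        plan.append(("upstream", pep, _fixed_mods(pep),
                     {"gene": gt.gene_id, "kind": gt.upstream_kind,
                      "tis_codon": gt.tis_codon, "tis_offset": gt.tis_offset}))

    # --- protein N-terminal peptides (acetyl / Met-cleaved) ------------------
    plain = [g for g in genes
             if g.fpkm >= 0.1 and not g.signal_end and not g.upstream_kind]
    rng.shuffle(plain)
    pi = 0
    for klass, count in (("annotated_acetyl", cfg.n_acetyl_nterm),
                         ("met_cleaved", cfg.n_met_cleaved)):
        taken = 0
        while taken < count and pi < len(plain):
            gt = plain[pi]
            pi += 1
            prot = gt.protein
            first = next((p for p in digest(prot, EnzymeConfig(max_missed=0))
                          if p.start == 0 and not p.semi), None)
            if first is None:
                continue
            if klass == "annotated_acetyl":
                pep = first.sequence
                mods = tuple(sorted(_fixed_mods(pep) + (
                    ModPlacement(-1, ACETYL_PROTEIN_NTERM.name, ACETYL_PROTEIN_NTERM.delta),)))
            else:
                pep = first.sequence[1:]
                if len(pep) < 7:
                    continue
                mods = _fixed_mods(pep)
            plan.append(("nterm", pep, mods,
                         {"gene": gt.gene_id, "protein": gt.transcript_id,
                          "nterm_class": klass}))
            taken += 1

    # --- signal-cleaved semi-tryptic N-termini -------------------------------
    sig_genes = [g for g in genes if g.signal_end and g.fpkm >= 0.1]
    for si, gt in enumerate(sig_genes):
        if si == 0:
            offsets = [-9]  # out-of-window control: classed unrelated
        elif si % 3 == 0:
            offsets = [0, int(rng.integers(1, 6))]  # dual-site protein
        elif si % 3 == 1:
            offsets = [0]
        else:
            off = 0
            while off == 0:
                off = int(rng.integers(-5, 6))
            offsets = [off]
        prot, send = gt.protein, gt.signal_end
        first_k = prot.index("K", send)
        for off in offsets:
            start = send + off  # 0-based first mature residue observed
            pep = prot[start : first_k + 1]
            if len(pep) < 7 or len(pep) > 45:
                continue
            gt.cleavage_offsets.append(off)
            plan.append(("signal", pep, _fixed_mods(pep),
                         {"gene": gt.gene_id, "protein": gt.transcript_id,
                          "signal_end": send, "offset": off}))

    # --- emit spectra ---------------------------------------------------------
    spectra: list[Spectrum] = []
    rows = []
    for i, (origin, pep, mods, detail) in enumerate(plan):
        mass = peptide_mass(pep, mods)
        if not (500.0 <= mass <= 5000.0):
            continue
        tid = detail.get("protein") or detail.get("gene") or ""
        abundance = abundances.get(tid, None)
        if abundance is None:
            g = next((x for x in genes if x.gene_id == detail.get("gene")), None)
            abundance = g.abundance if g else 10.0
        sid = f"sim.{i:05d}.{origin}"
        spectra.append(_make_spectrum(rng, sid, pep, mods, cfg, max(abundance, 1e-3)))
        rows.append({"spectrum_id": sid, "origin": origin, "peptide": pep,
                     "mods": _mods_str(mods), **{k: str(v) for k, v in detail.items()}})
    for i in range(cfg.n_noise_spectra):
        n_peaks = int(rng.integers(30, 60))
        mz = np.sort(rng.uniform(150.0, 1500.0, size=n_peaks))
        inten = np.exp(rng.normal(2.0, 1.0, size=n_peaks))
        sid = f"sim.noise.{i:04d}"
        spectra.append(Spectrum(sid, float(rng.uniform(400.0, 1000.0)), 2, mz, inten))
        rows.append({"spectrum_id": sid, "origin": "noise", "peptide": "-", "mods": "-"})
    manifest = pd.DataFrame(rows).fillna("")
    manifest.attrs["allelic_expected"] = dict(alt_expected)
    return spectra, manifest


def simulate_study(cfg: SimConfig = SimConfig()) -> SimulatedStudy:
    """Run every stage of the generator and assemble the ground truth."""
    genome, ref_txs, assembled, novel, genes = simulate_genome_annotation(cfg)
    expression, matrix, enriched = simulate_expression(cfg, genes)
    variants, variant_truth = simulate_variants(cfg, genes, ref_txs, genome)
    spectra, manifest = simulate_spectra(cfg, {
        "genes": genes, "genome": genome, "ref_txs": ref_txs,
        "assembled_txs": assembled, "novel_junctions": novel,
        "variant_truth": variant_truth,
    })
    signals = [
        SignalAnnotation(g.transcript_id, g.signal_end)
        for g in genes if g.signal_end
    ]
    return SimulatedStudy(
        cfg=cfg, genome=genome, ref_txs=ref_txs, assembled_txs=assembled,
        novel_junctions=novel, variants=variants, variant_truth=variant_truth,
        expression=expression, tissue_matrix=matrix, enriched_genes=enriched,
        signals=signals, genes=genes, spectra=spectra, manifest=manifest,
    )
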