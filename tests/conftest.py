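"""Shared fixtures: a hand-built two-exon toy gene (both strands) and a
session-scoped synthetic study with its full multi-pass search results."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from proteogen.custom_db import (
    build_junction_db,
    build_orf_db,
    build_saav_db,
    build_signal_db,
)
from proteogen.search_engine import SearchConfig, SearchDatabases, iterative_search
from proteogen.sequence_models import GenomeSequence, TranscriptModel
from proteogen.synthetic import SimConfig, simulate_study

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# 20 codons (60 nt): ATG + 18 sense codons + TAA
TOY_CDS = (
    "ATG" "GCT" "GAC" "GAA" "GGG" "CAT" "AAA" "TTT" "CTG" "ATG"
    "CCG" "CAA" "TCT" "GTG" "TGG" "TAC" "GTT" "GAT" "CGA" "TAA"
)
TOY_INTRON = "GT" + "CCCCTTTTAACCGGTTAA" + "AG"
_SPLIT = 27  # exon1 carries the first 27 CDS nt


@dataclass
class ToyGene:
    genome: GenomeSequence
    tx: TranscriptModel
    cds: str

    def genomic_pos(self, cds_index: int) -> int:
        """Genomic position (1-based) of 0-based CDS index, strand-aware."""
        ex = self.tx.cds  # transcript order
        if cds_index < _SPLIT:
            s, e = ex[0]
            return s + cds_index if self.tx.strand == "+" else e - cds_index
        s, e = ex[1]
        off = cds_index - _SPLIT
        return s + off if self.tx.strand == "+" else e - off


def make_toy_gene(strand: str) -> ToyGene:
    pad = "ACGTAC" * 5
    gene = TOY_CDS[:_SPLIT] + TOY_INTRON + TOY_CDS[_SPLIT:]
    if strand == "-":
        gene = revcomp(gene)
    seq = pad + gene + pad
    g0 = len(pad)  # 0-based gene start
    L = len(gene)
    if strand == "+":
        e1 = (g0 + 1, g0 + _SPLIT)
        e2 = (g0 + _SPLIT + len(TOY_INTRON) + 1, g0 + L)
        exons = (e1, e2)
    else:
        # mirror: local interval [a,b] (1-based in transcript orientation)
        def m(a, b):
            return (g0 + L - b + 1, g0 + L - a + 1)

        exons = (m(1, _SPLIT), m(_SPLIT + len(TOY_INTRON) + 1, L))
    tx = TranscriptModel("TOY_T1", "TOY_G1", "chrT", strand, exons, exons, "reference")
    return ToyGene(GenomeSequence({"chrT": seq}), tx, TOY_CDS)


@pytest.fixture(scope="session")
def toy_plus() -> ToyGene:
    return make_toy_gene("+")


@pytest.fixture(scope="session")
def toy_minus() -> ToyGene:
    return make_toy_gene("-")


STUDY_CFG = SimConfig(seed=11, n_genes=12, n_variants=12, n_noise_spectra=10)


@pytest.fixture(scope="session")
def study():
    return simulate_study(STUDY_CFG)


@pytest.fixture(scope="session")
def study_dbs(study):
    ref = study.reference_proteins
    saav_recs, saavs = build_saav_db(
        study.variants, study.ref_txs, study.genome, study.expression
    )
    entries, jrecs = build_junction_db(
        study.novel_junctions, study.genome, txs=study.assembled_txs
    )
    orf = build_orf_db(study.assembled_txs, study.genome)
    sig = build_signal_db({r.accession: r.sequence for r in ref}, study.signals)
    dbs = SearchDatabases(ref, saav_recs, jrecs, orf, sig)
    return dbs, saavs, entries


@pytest.fixture(scope="session")
def search_results(study, study_dbs):
    dbs, _, _ = study_dbs
    return iterative_search(study.spectra, dbs, SearchConfig())


@pytest.fixture(scope="session")
def accepted_by_spectrum(search_results):
    out = {}
    for res in search_results.values():
        for m in res.accepted:
            out[m.spectrum_id] = m
    return out
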