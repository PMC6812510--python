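"""Custom database builders: consequence calling (exhaustive oracle on both
strands), SAAV proteins, junction-spanning peptides, ORFs, signal regions,
decoys."""

import numpy as np
import pytest
from Bio.Seq import Seq

from proteogen.custom_db import (
    ProteinRecord,
    ReferenceMismatchError,
    SignalAnnotation,
    VariantRecord,
    build_junction_db,
    build_orf_db,
    build_saav_db,
    build_signal_db,
    call_consequence,
    generate_decoys,
    read_fasta_records,
    read_vcf,
    translate_cds,
    write_fasta,
)
from proteogen.enzyme import EnzymeConfig, digest
from proteogen.sequence_models import (
    GenomeSequence,
    SpliceJunction,
    TranscriptModel,
    annotate_junctions,
    translate,
)

from conftest import TOY_CDS, revcomp


def oracle_consequence(cds: str, idx: int, alt_tx: str) -> tuple[str, int]:
    """Independent oracle: mutate the spliced CDS and re-translate fully."""
    mutated = cds[:idx] + alt_tx + cds[idx + 1 :]
    ref_aa = str(Seq(cds).translate())
    alt_aa = str(Seq(mutated).translate())
    if ref_aa == alt_aa:
        return "synonymous", -1
    codon = idx // 3
    r, a = ref_aa[codon], alt_aa[codon]
    if a == "*":
        return "stop_gain", codon
    if r == "*":
        return "stop_loss", codon
    return "missense", codon


class TestConsequenceCaller:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_snv_agreement_with_mutate_and_translate(self, strand, request):
        toy = request.getfixturevalue("toy_plus" if strand == "+" else "toy_minus")
        comp = str.maketrans("ACGT", "TGCA")
        for idx in range(len(TOY_CDS)):
            ref_tx = TOY_CDS[idx]
            gpos = toy.genomic_pos(idx)
            for alt_tx in "ACGT":
                if alt_tx == ref_tx:
                    continue
                ref_g = ref_tx if strand == "+" else ref_tx.translate(comp)
                alt_g = alt_tx if strand == "+" else alt_tx.translate(comp)
                v = VariantRecord("chrT", gpos, ref_g, alt_g, "het", "v")
                got = call_consequence(v, toy.tx, toy.genome)
                kind, codon = oracle_consequence(TOY_CDS, idx, alt_tx)
                assert got.kind == kind, (idx, alt_tx, strand)
                if kind == "missense":
                    assert got.saav.position == codon + 1
                    assert got.saav.ref_aa == str(Seq(TOY_CDS).translate())[codon]

    def test_wobble_synonymous(self, toy_plus):
        # codon 4 is GGG (Gly); third-position G->A stays Gly
        idx = 4 * 3 + 2
        v = VariantRecord("chrT", toy_plus.genomic_pos(idx), "G", "A", "het")
        assert call_consequence(v, toy_plus.tx, toy_plus.genome).kind == "synonymous"

    def test_intronic_variant_is_noncoding(self, toy_plus):
        s, e = sorted(toy_plus.tx.exons)[0]
        pos = e + 3  # inside the intron
        ref = toy_plus.genome.base("chrT", pos)
        alt = "A" if ref != "A" else "C"
        v = VariantRecord("chrT", pos, ref, alt, "het")
        assert call_consequence(v, toy_plus.tx, toy_plus.genome).kind == "noncoding"

    def test_reference_mismatch_is_hard_error(self, toy_plus):
        pos = toy_plus.genomic_pos(5)
        ref = toy_plus.genome.base("chrT", pos)
        wrong = "A" if ref != "A" else "C"
        v = VariantRecord("chrT", pos, wrong, "G" if wrong != "G" else "T", "het")
        with pytest.raises(ReferenceMismatchError):
            call_consequence(v, toy_plus.tx, toy_plus.genome)

    def test_planted_variant_consequences_match_manifest(self, study):
        tx_by_gene = {t.gene_id: t for t in study.ref_txs}
        for row in study.variant_truth.to_dict(orient="records"):
            v = VariantRecord(row["contig"], row["position"], row["ref"],
                              row["alt"], row["genotype"])
            got = call_consequence(v, tx_by_gene[row["gene_id"]], study.genome)
            assert got.kind == row["consequence"]
            if got.kind == "missense":
                assert got.saav.label == (
                    f"{row['ref_aa']}{row['protein_position']}{row['alt_aa']}"
                )


class TestSaavDb:
    def test_hamming_distance_exactly_one(self, study, study_dbs):
        dbs, saavs, _ = study_dbs
        ref = {r.accession: r.sequence for r in dbs.reference}
        assert dbs.saav, "no SAAV entries built"
        for rec, saav in zip(dbs.saav, saavs):
            wild = ref[saav.protein_id]
            mut = rec.sequence
            assert len(wild) == len(mut)
            diffs = [i for i, (a, b) in enumerate(zip(wild, mut)) if a != b]
            assert diffs == [saav.position - 1]
            assert mut[saav.position - 1] == saav.alt_aa

    def test_synonymous_and_silent_genes_excluded(self, toy_plus):
        tx = toy_plus.tx
        # synonymous variant -> nothing
        idx = 4 * 3 + 2
        v_syn = VariantRecord("chrT", toy_plus.genomic_pos(idx), "G", "A", "het")
        recs, saavs = build_saav_db([v_syn], [tx], toy_plus.genome, {"TOY_G1": 5.0})
        assert recs == [] and saavs == []
        # missense in an unexpressed gene -> nothing
        idx2 = 5 * 3  # CAT His codon, first base
        v_mis = VariantRecord("chrT", toy_plus.genomic_pos(idx2), "C", "G", "het")
        recs, _ = build_saav_db([v_mis], [tx], toy_plus.genome, {"TOY_G1": 0.0})
        assert recs == []
        recs, _ = build_saav_db([v_mis], [tx], toy_plus.genome, {"TOY_G1": 0.09})
        assert recs == []
        recs, _ = build_saav_db([v_mis], [tx], toy_plus.genome, {"TOY_G1": 0.1})
        assert len(recs) == 1


def _hand_junction_setup():
    """A designed 180-nt junction context: 90-nt exonic flank each side."""
    rng = np.random.default_rng(99)
    left_aa = "K" + "GAV" * 8 + "TDNER"  # 30 codons, tryptic sites at K1/R30
    right_aa = "LSEPHYK" + "M" + "QQQQQQQQQQQQQQQQQQQQQK"  # 30 codons
    from proteogen.synthetic import _SAFE_CODONS  # deterministic codons

    def bt(aa):
        table = dict(_SAFE_CODONS)
        table.update({"K": "AAA", "R": "AGA", "M": "ATG"})
        return "".join(table[c] for c in aa)

    left, right = bt(left_aa), bt(right_aa)
    assert len(left) == len(right) == 90
    genome = GenomeSequence({"cj": "C" * 10 + left + "GT" + "A" * 56 + "AG" + right + "C" * 10})
    j = SpliceJunction("cj", 101, 160, "+", donor_known=False,
                       acceptor_known=False, junction_known=False)
    return genome, j, left, right


class TestJunctionDb:
    def test_every_entry_spans_its_junction(self, study_dbs):
        _, _, entries = study_dbs
        assert entries
        for e in entries:
            assert 1 <= e.boundary_offset <= len(e.peptide) - 1

    def test_hand_worked_example_exact_peptide_set(self):
        genome, j, left, right = _hand_junction_setup()
        entries, _ = build_junction_db([j], genome, flank_nt=90, novel_only=False)
        got = {(e.frame, e.peptide, e.boundary_offset) for e in entries}
        # independent oracle: translate each frame of the concatenation and
        # enumerate tryptic peptides crossing the boundary
        expected = set()
        concat = left + right
        for frame in (0, 1, 2):
            aa = translate(concat, frame, "keep")
            for seg, off in _segments(aa):
                for p in digest(seg, EnzymeConfig()):
                    if p.semi:
                        continue
                    nt_s = frame + 3 * (off + p.start)
                    nt_e = nt_s + 3 * len(p.sequence)
                    if nt_s + 3 <= 90 <= nt_e - 3:
                        bo = -(-(90 - nt_s) // 3)
                        expected.add((frame, p.sequence, bo))
        assert got == expected
        # frozen spot check: the in-frame missed-cleavage peptide crossing
        # the boundary ends with the right-flank tryptic stretch
        frame0 = {p for f, p, _ in got if f == 0}
        assert frame0 and any(p.endswith("LSEPHYK") for p in frame0)

    def test_truncated_flank_flagged(self):
        genome, j, left, right = _hand_junction_setup()
        # clip the left flank to a 30-nt exon via an explicit transcript model
        s, e = 81, 100  # 20-nt left exon ending at the donor
        tx = TranscriptModel("a", "g", "cj", "+",
                             ((s, 100), (161, 250)), None, "assembled")
        entries, _ = build_junction_db([j], genome, flank_nt=90, txs=[tx],
                                       novel_only=False)
        assert entries and all(e_.truncated_left for e_ in entries)

    def test_stop_across_boundary_drops_frame(self):
        # frame 0 reads TA|A across the boundary -> a stop straddles the
        # junction, so frame 0 contributes no spanning peptide
        left = "GCT" * 9 + "TA"  # 29 nt, frame-0 codon 10 completed by the A
        right = "A" + "GCT" * 10
        genome = GenomeSequence(
            {"c": "AAAA" + left + "GT" + "C" * 26 + "AG" + right + "AAAA"}
        )
        j_start = 4 + len(left) + 1
        j = SpliceJunction("c", j_start, j_start + 29, "+",
                           donor_known=False, acceptor_known=False,
                           junction_known=False)
        entries, _ = build_junction_db([j], genome, flank_nt=29, novel_only=False)
        assert all(e.frame != 0 for e in entries)


def _segments(aa: str):
    start = 0
    for end in [i for i, c in enumerate(aa) if c == "*"] + [len(aa)]:
        if end > start:
            yield aa[start:end], start
        start = end + 1


class TestOrfDb:
    def test_short_segment_dropped(self):
        g = GenomeSequence({"c": "ATGAAATAA"})
        tx = TranscriptModel("t", "g", "c", "+", ((1, 9),), None, "assembled")
        recs = build_orf_db([tx], g, min_orf_aa=7)
        assert all("F0" not in r.accession for r in recs)

    def test_segment_count_matches_stop_split_oracle(self, study):
        rng = np.random.default_rng(5)
        recs = build_orf_db(study.assembled_txs, study.genome, min_orf_aa=7)
        from proteogen.sequence_models import spliced_sequence

        for tx in study.assembled_txs:
            seq = spliced_sequence(tx, study.genome)
            expected = 0
            for frame in (0, 1, 2):
                aa = translate(seq, frame, "keep")
                expected += sum(
                    1 for seg in aa.split("*") if len(seg) >= 7 and "X" not in seg
                )
            got = sum(1 for r in recs if r.get("transcript") == tx.transcript_id)
            assert got == expected

    def test_provenance_recorded(self, study):
        recs = build_orf_db(study.assembled_txs, study.genome)
        for r in recs[:10]:
            assert r.origin == "orf"
            assert r.get("frame") in {"0", "1", "2"}


class TestSignalDb:
    def test_window_and_short_protein(self):
        prots = {"P1": "M" + "A" * 100, "P2": "M" + "A" * 30}
        recs = build_signal_db(prots, [SignalAnnotation("P1", 20),
                                       SignalAnnotation("P2", 20)], window_aa=60)
        assert len(recs[0].sequence) == 80
        assert len(recs[1].sequence) == 31  # shorter than window: full protein

    def test_missing_protein_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            recs = build_signal_db({}, [SignalAnnotation("nope", 20)])
        assert recs == []

    def test_entry_count_matches_annotations(self, study, study_dbs):
        dbs, _, _ = study_dbs
        present = sum(
            1 for s in study.signals
            if any(r.accession == s.protein_id for r in dbs.reference)
        )
        assert len(dbs.signal) == present


class TestDecoys:
    def test_reversal_and_prefix(self):
        rec = ProteinRecord("P1", "PEPTIDER", "reference")
        (d,) = generate_decoys([rec])
        assert d.sequence == "REDITPEP"
        assert d.accession == "DECOY_P1"

    def test_decoy_of_decoy_forbidden(self):
        d = ProteinRecord("DECOY_P1", "AAA", "decoy")
        with pytest.raises(ValueError):
            generate_decoys([d])

    def test_composition_preserved_and_counts_match(self, study_dbs):
        dbs, _, _ = study_dbs
        decoys = generate_decoys(dbs.reference)
        assert len(decoys) == len(dbs.reference)
        for t, d in zip(dbs.reference, decoys):
            assert sorted(t.sequence) == sorted(d.sequence)

    def test_no_accession_collisions_across_origins(self, study_dbs):
        dbs, _, _ = study_dbs
        accs = [r.accession for db in
                (dbs.reference, dbs.saav, dbs.junction, dbs.orf, dbs.signal)
                for r in db]
        assert len(accs) == len(set(accs))


class TestIo:
    def test_fasta_roundtrip_with_metadata(self, tmp_path, study_dbs):
        dbs, _, _ = study_dbs
        p = tmp_path / "db.fa"
        write_fasta(dbs.saav, p)
        back = read_fasta_records(p)
        assert [(r.accession, r.sequence, r.origin) for r in back] == [
            (r.accession, r.sequence, r.origin) for r in dbs.saav
        ]

    def test_vcf_genotypes_and_snv_filter(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS\n"
            "c\t10\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\n"
            "c\t20\tv2\tC\tT\t.\tPASS\t.\tGT\t1/1\n"
            "c\t30\tv3\tG\tGA\t.\tPASS\t.\tGT\t0/1\n"  # indel: skipped
            "c\t40\tv4\tT\tA,C\t.\tPASS\t.\tGT\t1/2\n"  # multi-allelic
        )
        with pytest.warns(UserWarning):
            vars_ = read_vcf(p)
        by_id = {}
        for v in vars_:
            by_id.setdefault(v.source_id, []).append(v)
        assert by_id["v1"][0].genotype == "het"
        assert by_id["v2"][0].genotype == "hom_alt"
        assert "v3" not in by_id
        assert {v.alt for v in by_id["v4"]} == {"A", "C"}
        assert all(v.genotype == "het" for v in by_id["v4"])
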