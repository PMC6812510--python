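"""Downstream integration: allelic classes, N-termini/TIS, cleavage sites,
iBAQ, mRNA-protein correlation, tissue enrichment, junction proteoforms."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteogen.integrate import (
    NEAR_COGNATE,
    START_CODONS,
    call_enriched_genes,
    classify_allelic_expression,
    classify_cleavage,
    classify_nterm,
    compute_ibaq,
    correlate_mrna_protein,
    detect_junction_proteoforms,
    evaluate_allelic_evidence,
    flag_dual_cleavage,
    scan_near_cognate_tis,
    upstream_inframe_region,
)
from proteogen.search_engine import ProteinGroup


class TestAllelicClassifier:
    TRUTH = {
        ("het", True, True): "het_both",
        ("het", True, False): "ref_only",
        ("het", False, True): "het_alt_only",
        ("het", False, False): "undetected",
        ("hom_alt", True, True): "het_both",
        ("hom_alt", True, False): "ref_only",
        ("hom_alt", False, True): "hom_alt_only",
        ("hom_alt", False, False): "undetected",
    }

    def test_exhaustive_2x2x2_truth_table(self):
        for (gt, ref, alt), expected in self.TRUTH.items():
            klass, conflict = classify_allelic_expression(gt, ref, alt)
            assert klass == expected
            # conflicts flagged, never silently dropped
            assert conflict == (gt == "hom_alt" and ref)

    def test_totality_and_determinism(self):
        space = list(itertools.product(("het", "hom_alt"), (True, False), (True, False)))
        first = [classify_allelic_expression(*args) for args in space]
        second = [classify_allelic_expression(*args) for args in space]
        assert first == second and len(first) == 8

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            classify_allelic_expression("missing", True, True)

    def test_planted_classes_recovered_on_study(self, study, study_dbs,
                                                accepted_by_spectrum):
        dbs, saavs, _ = study_dbs
        ref = {r.accession: r.sequence for r in dbs.reference}
        accepted = list(accepted_by_spectrum.values())
        evidence = evaluate_allelic_evidence(saavs, dbs.saav, ref, accepted)
        expected = study.manifest.attrs["allelic_expected"]
        by_variant = {
            (e.saav.protein_id, e.saav.label): e.klass for e in evidence
        }
        vt = study.variant_truth.set_index("variant_id")
        checked = 0
        for vid, exp_class in expected.items():
            row = vt.loc[vid]
            key = (row["transcript_id"],
                   f"{row['ref_aa']}{row['protein_position']}{row['alt_aa']}")
            assert by_variant.get(key) == exp_class, (vid, exp_class)
            checked += 1
        assert checked >= 3


class TestNTerm:
    PROT = "MAGHIKWNDESTPLCVFYQR" + "ADKHGWINSETPVLCK"

    def test_annotated_acetyl_and_free(self):
        c = classify_nterm("MAGHIK", True, self.PROT)
        assert c.klass == "annotated_acetyl" and c.offset_codons == 0
        c2 = classify_nterm("MAGHIK", False, self.PROT)
        assert c2.klass == "annotated_free"

    def test_met_cleaved(self):
        c = classify_nterm("AGHIK", False, self.PROT)
        assert c.klass == "met_cleaved" and c.offset_codons == 1

    def test_internal_peptide_is_not_an_nterm_call(self):
        assert classify_nterm("WNDESTPLCVFYQR", False, self.PROT) is None

    def test_upstream_and_extension_classes(self):
        # UTR: stop, CTG, K, 8 residues, K, 2 fillers (in-frame codons)
        utr = "TAA" + "CTG" + "AAA" + "GGCGCCTCCGTCACCGACGAAGGC" + "AAA" + "GGCGCC"
        upstream_pep = "GASVTDEGK"  # wholly within the UTR translation
        c = classify_nterm(upstream_pep, False, self.PROT, utr_inframe=utr)
        assert c.klass == "upstream_inframe"
        assert c.offset_codons < 0
        assert c.tis_codon == "CTG"
        crossing = "GAMAGHIK"  # last two UTR codons + Met + protein
        c2 = classify_nterm("GA" + "MAGHIK", False, self.PROT, utr_inframe=utr)
        assert c2.klass == "extension" and c2.offset_codons == -2

    def test_planted_study_events_recovered(self, study, accepted_by_spectrum):
        ref_prot = {g.transcript_id: g.protein for g in study.genes}
        tx_by_id = {t.transcript_id: t for t in study.ref_txs}
        man = study.manifest
        for row in man[man.origin.isin(["upstream", "nterm"])].to_dict("records"):
            m = accepted_by_spectrum[row["spectrum_id"]]
            gene = row.get("gene", "")
            gt = next(g for g in study.genes if g.gene_id == gene)
            utr, _ = upstream_inframe_region(tx_by_id[gt.transcript_id], study.genome)
            acetyl = "Acetyl-Nterm" in row["mods"]
            call = classify_nterm(m.peptide, acetyl, ref_prot[gt.transcript_id],
                                  utr, gt.transcript_id)
            assert call is not None, row
            if row["origin"] == "upstream":
                assert call.klass == row["kind"]
                assert call.tis_codon == row["tis_codon"]
                assert str(call.tis_offset) == str(row["tis_offset"])
            else:
                assert call.klass == row["nterm_class"]


class TestNearCognateScan:
    def test_canonical_atg_found(self):
        utr = "GGC" * 5 + "ATG" + "GGC" * 3  # ATG three codons upstream of peptide
        assert scan_near_cognate_tis(utr, 0) == ("ATG", -4)

    def test_acg_only_candidate(self):
        utr = "TAA" + "ACG" + "GGC" * 5
        assert scan_near_cognate_tis(utr, -2) == ("ACG", -6)

    def test_intervening_stop_aborts(self):
        utr = "ATG" + "TAA" + "GGC" * 4
        assert scan_near_cognate_tis(utr, 0) is None

    def test_random_utrs_match_regex_oracle(self):
        rng = np.random.default_rng(31)
        starts = set(START_CODONS)
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(1000):
            n_codons = int(rng.integers(2, 30))
            utr = "".join("ACGT"[i] for i in rng.integers(4, size=3 * n_codons))
            pep_off = -int(rng.integers(0, n_codons // 2 + 1))
            got = scan_near_cognate_tis(utr, pep_off)
            # oracle: explicit codon walk upstream
            expected = None
            for off in range(pep_off - 1, -n_codons - 1, -1):
                codon = utr[(off + n_codons) * 3 : (off + n_codons) * 3 + 3]
                if codon in stops:
                    break
                if codon in starts:
                    expected = (codon, off)
                    break
            assert got == expected


class TestCleavage:
    @pytest.mark.parametrize("offset,klass", [
        (0, "annotated"), (3, "alternate"), (-3, "alternate"),
        (5, "alternate"), (-5, "alternate"), (9, "unrelated"), (-9, "unrelated"),
    ])
    def test_offset_windows(self, offset, klass):
        ann_end = 20
        call = classify_cleavage(ann_end + 1 + offset, ann_end, window=5, protein_id="P")
        assert call.offset == offset and call.klass == klass

    def test_dual_site_flagging(self):
        calls = [classify_cleavage(21, 20, protein_id="P1"),
                 classify_cleavage(24, 20, protein_id="P1"),
                 classify_cleavage(21, 20, protein_id="P2")]
        assert flag_dual_cleavage(calls) == {"P1"}

    def test_planted_offsets_recovered_exactly(self, study, accepted_by_spectrum):
        man = study.manifest
        prot = {g.transcript_id: g.protein for g in study.genes}
        recovered = []
        for row in man[man.origin == "signal"].to_dict("records"):
            m = accepted_by_spectrum[row["spectrum_id"]]
            pid = row["protein"]
            pos = prot[pid].find(m.peptide)
            call = classify_cleavage(pos + 1, int(row["signal_end"]), protein_id=pid)
            assert call.offset == int(row["offset"])
            expected = ("annotated" if call.offset == 0
                        else "alternate" if abs(call.offset) <= 5 else "unrelated")
            assert call.klass == expected
            recovered.append(call)
        assert recovered
        # the cleavage classes partition the observed N-termini
        assert all(c.klass in {"annotated", "alternate", "unrelated"}
                   for c in recovered)


class TestQuantification:
    def test_single_peptide_ibaq(self):
        psms = pd.DataFrame({"run": ["r1"], "peptide": ["AAAAAAK"],
                             "intensity": [300.0]})
        grp = ProteinGroup("P", ("P",), ("AAAAAAK",), 50.0, False, 0.0)
        seq = "M" + "AAAAAAK" + "GGGGGGGGK"
        (q,) = compute_ibaq(psms, [grp], {"P": seq})
        # theoretical 6-30 aa fully tryptic peptides of seq: MAAAAAAK? no:
        # M|AAAAAAK boundaries -> MAAAAAAK (8), GGGGGGGGK (9) => 2
        assert q.theoretical_peptides == 2
        assert q.ibaq == pytest.approx(150.0)

    def test_scale_equivariance(self):
        psms = pd.DataFrame({"run": ["r1", "r1"], "peptide": ["AAAAAAK", "CCCCCCK"],
                             "intensity": [100.0, 50.0]})
        grp = ProteinGroup("P", ("P",), ("AAAAAAK", "CCCCCCK"), 50.0, False, 0.0)
        seqs = {"P": "AAAAAAKCCCCCCK"}
        (q1,) = compute_ibaq(psms, [grp], seqs)
        psms2 = psms.assign(intensity=psms.intensity * 2)
        (q2,) = compute_ibaq(psms2, [grp], seqs)
        assert q2.ibaq == pytest.approx(2 * q1.ibaq)

    def test_run_normalization_equalizes_totals(self):
        psms = pd.DataFrame({
            "run": ["r1", "r2"], "peptide": ["AAAAAAK", "AAAAAAK"],
            "intensity": [100.0, 400.0],
        })
        grp = ProteinGroup("P", ("P",), ("AAAAAAK",), 50.0, False, 0.0)
        (q,) = compute_ibaq(psms, [grp], {"P": "AAAAAAK"})
        # each run scaled to the mean total (250): 250 + 250
        assert q.summed_intensity == pytest.approx(500.0)

    def test_zero_theoretical_peptides_reported_missing(self):
        psms = pd.DataFrame({"run": ["r1"], "peptide": ["AAAAAAK"],
                             "intensity": [10.0]})
        grp = ProteinGroup("P", ("P",), ("AAAAAAK",), 50.0, False, 0.0)
        (q,) = compute_ibaq(psms, [grp], {"P": "AAK"})
        assert q.ibaq is None


class TestCorrelation:
    def test_proportional_coupling_gives_r_one(self):
        expr = {f"g{i}": float(i + 1) for i in range(20)}
        quants = {g: 3.5 * v for g, v in expr.items()}
        r, df = correlate_mrna_protein(expr, quants)
        assert r == pytest.approx(1.0)
        assert len(df) == 20

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(8)
        expr = {f"g{i}": float(np.exp(rng.normal(0, 1))) for i in range(1000)}
        quants = {f"g{i}": float(np.exp(rng.normal(0, 1))) for i in range(1000)}
        r, _ = correlate_mrna_protein(expr, quants)
        assert abs(r) < 0.1

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(9)
        expr = {f"g{i}": float(np.exp(rng.normal(0, 1))) for i in range(50)}
        quants = {g: v * float(np.exp(rng.normal(0, 0.3))) for g, v in expr.items()}
        r1, _ = correlate_mrna_protein(expr, quants)
        r2, _ = correlate_mrna_protein(
            {g: 7.0 * v for g, v in expr.items()},
            {g: 0.01 * v for g, v in quants.items()},
        )
        assert r1 == pytest.approx(r2)

    def test_too_few_pairs_undefined(self):
        with pytest.raises(ValueError):
            correlate_mrna_protein({"a": 1.0}, {"a": 2.0})


class TestEnrichment:
    def _matrix(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.uniform(1, 3, size=(20, 6)),
                         index=[f"g{i}" for i in range(20)],
                         columns=["target"] + [f"t{i}" for i in range(5)])
        return m

    def test_exclusive_expression_is_enriched(self):
        m = self._matrix()
        m.loc["g0"] = 0.0
        m.loc["g0", "target"] = 50.0
        assert "g0" in call_enriched_genes(m, "target")

    def test_uniform_expression_not_enriched(self):
        m = pd.DataFrame(np.ones((5, 4)),
                         index=list("abcde"), columns=["target", "x", "y", "z"])
        assert call_enriched_genes(m, "target") == set()

    def test_planted_enrichment_recovered_exactly(self, study):
        got = call_enriched_genes(study.tissue_matrix, "HUVEC",
                                  study.cfg.enrichment_fold, 1.0)
        assert got == study.enriched_genes

    def test_invariance_to_column_order_and_rescale(self, study):
        m = study.tissue_matrix
        shuffled = m[list(m.columns[::-1])]
        assert call_enriched_genes(shuffled, "HUVEC", 5.0, 1.0) == \
            call_enriched_genes(m, "HUVEC", 5.0, 1.0)
        # global rescaling (min_expr scaled accordingly)
        assert call_enriched_genes(m * 10.0, "HUVEC", 5.0, 10.0) == \
            call_enriched_genes(m, "HUVEC", 5.0, 1.0)

    def test_single_column_matrix_rejected(self):
        m = pd.DataFrame({"target": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            call_enriched_genes(m, "target")


class TestProteoforms:
    def test_planted_alt_donor_with_extension(self, study, study_dbs,
                                              accepted_by_spectrum, search_results):
        from proteogen.sequence_models import enumerate_junctions

        _, _, entries = study_dbs
        by_acc = {e.accession: e.junction for e in entries}
        ref_j = enumerate_junctions(study.ref_txs)
        j_matches = [m for m in accepted_by_spectrum.values()
                     if m.pass_label == "junction"]
        calls = detect_junction_proteoforms(j_matches, by_acc, ref_j)
        assert calls
        ext = study.cfg.alt_donor_extension_nt
        for c in calls:
            assert c.event == "alt_donor"
            assert c.extension_bp == ext

    def test_annotated_junction_yields_no_call(self, study, study_dbs):
        from proteogen.search_engine import PeptideMatch
        from proteogen.sequence_models import SpliceJunction, enumerate_junctions

        ref_j = enumerate_junctions(study.ref_txs)
        j = ref_j[0]
        known = SpliceJunction(j.contig, j.start, j.end, j.strand, True, True, True)
        m = PeptideMatch("s", "AAAAAAK", (), ("JX",), 0, 50.0, 0.0, False,
                         "junction", q=0.0)
        assert detect_junction_proteoforms([m], {"JX": known}, ref_j) == []

    def test_planted_intron_retention(self, study, accepted_by_spectrum):
        from proteogen.custom_db import build_orf_db
        from proteogen.integrate import detect_intron_retention
        from proteogen.sequence_models import annotate_junctions, enumerate_junctions

        orf_records = {r.accession: r
                       for r in build_orf_db(study.assembled_txs, study.genome)}
        asm = {t.transcript_id: t for t in study.assembled_txs}
        ref_j = enumerate_junctions(study.ref_txs)
        ref_ann = annotate_junctions(ref_j, ref_j)
        orf_matches = [m for m in accepted_by_spectrum.values()
                       if m.pass_label == "orf"]
        calls = detect_intron_retention(orf_matches, orf_records, asm, ref_ann)
        planted = {g.retention_peptide for g in study.genes
                   if g.retention_peptide and g.fpkm >= 0.1}
        assert planted
        got = {c.peptide for c in calls if c.event == "intron_retention"}
        assert planted <= got
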