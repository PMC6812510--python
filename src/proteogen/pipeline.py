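"""End-to-end pipeline: simulate -> build-db -> search -> integrate.

Each stage reads its inputs from and writes its outputs to a run directory,
is skipped when its outputs already exist (resumable), and every number in
the final summary is recomputable from the stage TSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import custom_db as cdb
from . import integrate as integ
from .enzyme import EnzymeConfig
from .masses import ModPlacement
from .search_engine import (
    PeptideMatch,
    ProteinGroup,
    SearchConfig,
    SearchDatabases,
    group_proteins,
    iterative_search,
)
from .sequence_models import (
    SpliceJunction,
    annotate_junctions,
    classify_junction,
    enumerate_junctions,
    read_genome_fasta,
    read_gtf,
    read_junction_bed,
    write_junction_classes,
)
from .spectra_io import read_mgf, write_mgf
from .synthetic import SimConfig, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 17
    fpkm_min: float = 0.1
    fdr: float = 0.01
    flank_nt: int = 90
    cleavage_window: int = 5
    enrichment_fold: float = 5.0
    enrichment_min_expr: float = 1.0
    precursor_tol_ppm: float = 10.0
    fragment_tol: float = 0.02
    enable_custom_passes: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            precursor_tol_ppm=self.precursor_tol_ppm,
            fragment_tol=self.fragment_tol,
            fdr=self.fdr,
        )


def _mods_str(mods) -> str:
    return ";".join(f"{m.name}@{m.position}:{m.delta:.5f}" for m in sorted(mods)) or "-"


def _stage_done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


# ---------------------------------------------------------------------------

def stage_simulate(run: Path, cfg: PipelineConfig) -> None:
    sim_dir = run / "sim"
    if _stage_done([sim_dir / "spectra.mgf", sim_dir / "manifest.tsv"]):
        return
    study = simulate_study(cfg.sim)
    study.write(sim_dir)


def stage_build_db(run: Path, cfg: PipelineConfig) -> None:
    db_dir = run / "db"
    outputs = [db_dir / f for f in
               ("reference.fa", "saav.fa", "junction_peptides.fa", "orf.fa",
                "signal.fa", "saav_map.tsv", "junction_entries.tsv",
                "junction_classes.tsv")]
    if _stage_done(outputs):
        return
    db_dir.mkdir(parents=True, exist_ok=True)
    sim = run / "sim"
    genome = read_genome_fasta(sim / "genome.fa")
    ref_txs = read_gtf(sim / "reference.gtf", source="reference")
    asm_txs = read_gtf(sim / "assembled.gtf", source="assembled")
    expression = cdb.read_expression_table(sim / "expression.tsv")
    variants = cdb.read_vcf(sim / "variants.vcf")
    signals = cdb.read_signal_table(sim / "signal_peptides.tsv")

    reference = cdb.build_reference_db(ref_txs, genome)
    cdb.write_fasta(reference, db_dir / "reference.fa")

    saav_recs, saavs = cdb.build_saav_db(variants, ref_txs, genome, expression, cfg.fpkm_min)
    cdb.write_fasta(saav_recs, db_dir / "saav.fa")
    with open(db_dir / "saav_map.tsv", "w") as fh:
        fh.write("accession\tprotein_id\tposition\tref_aa\talt_aa\tgenotype\t"
                 "contig\tvariant_pos\tref\talt\n")
        for rec, s in zip(saav_recs, saavs):
            v = s.variant
            fh.write(f"{rec.accession}\t{s.protein_id}\t{s.position}\t{s.ref_aa}\t"
                     f"{s.alt_aa}\t{v.genotype}\t{v.contig}\t{v.position}\t{v.ref}\t{v.alt}\n")

    ref_junctions = enumerate_junctions(ref_txs)
    novel = annotate_junctions(read_junction_bed(sim / "novel_junctions.bed", genome),
                               ref_junctions)
    all_j = annotate_junctions(enumerate_junctions(ref_txs + asm_txs), ref_junctions)
    write_junction_classes(all_j + [j for j in novel if j.key not in
                                    {x.key for x in all_j}],
                           db_dir / "junction_classes.tsv")
    entries, jrecs = cdb.build_junction_db(novel, genome, cfg.flank_nt, txs=asm_txs)
    cdb.write_fasta(jrecs, db_dir / "junction_peptides.fa")
    with open(db_dir / "junction_entries.tsv", "w") as fh:
        fh.write("accession\tcontig\tintron_start\tintron_end\tstrand\tframe\t"
                 "boundary_offset\tdonor_known\tacceptor_known\tjunction_known\n")
        for e in entries:
            j = e.junction
            fh.write(f"{e.accession}\t{j.contig}\t{j.start}\t{j.end}\t{j.strand}\t"
                     f"{e.frame}\t{e.boundary_offset}\t{j.donor_known}\t"
                     f"{j.acceptor_known}\t{j.junction_known}\n")

    orf = cdb.build_orf_db(asm_txs, genome)
    cdb.write_fasta(orf, db_dir / "orf.fa")
    ref_seqs = {r.accession: r.sequence for r in reference}
    signal_db = cdb.build_signal_db(ref_seqs, signals)
    cdb.write_fasta(signal_db, db_dir / "signal.fa")


def stage_search(run: Path, cfg: PipelineConfig) -> None:
    search_dir = run / "search"
    outputs = [search_dir / "psms.tsv", search_dir / "protein_groups.tsv"]
    if _stage_done(outputs):
        return
    search_dir.mkdir(parents=True, exist_ok=True)
    db_dir = run / "db"
    spectra = read_mgf(run / "sim" / "spectra.mgf")
    dbs = SearchDatabases(
        reference=cdb.read_fasta_records(db_dir / "reference.fa"),
        saav=cdb.read_fasta_records(db_dir / "saav.fa") if cfg.enable_custom_passes else [],
        junction=cdb.read_fasta_records(db_dir / "junction_peptides.fa")
        if cfg.enable_custom_passes else [],
        orf=cdb.read_fasta_records(db_dir / "orf.fa") if cfg.enable_custom_passes else [],
        signal=cdb.read_fasta_records(db_dir / "signal.fa")
        if cfg.enable_custom_passes else [],
    )
    results = iterative_search(spectra, dbs, cfg.search_config())
    intensity = {s.spectrum_id: float(s.intensity.sum()) for s in spectra}
    rows = []
    all_matches: list[PeptideMatch] = []
    for label, res in results.items():
        all_matches.extend(res.matches)
        for m in res.accepted:
            rows.append({
                "spectrum_id": m.spectrum_id, "peptide": m.peptide,
                "mods": _mods_str(m.mods), "score": round(m.score, 4),
                "q": round(m.q, 6), "pass": m.pass_label,
                "proteins": ";".join(m.proteins), "missed": m.missed,
                "semi": m.semi, "intensity": intensity.get(m.spectrum_id, 0.0),
            })
        write_mgf(res.unmatched, search_dir / f"unmatched_{label}.mgf")
    pd.DataFrame(rows).to_csv(search_dir / "psms.tsv", sep="\t", index=False)
    groups = group_proteins(all_matches, cfg.fdr)
    with open(search_dir / "protein_groups.tsv", "w") as fh:
        fh.write("leader\tmembers\tn_peptides\tbest_score\tq\tpeptides\n")
        for g in groups:
            if g.is_decoy:
                continue
            fh.write(f"{g.leader}\t{';'.join(g.members)}\t{len(g.peptides)}\t"
                     f"{g.best_score:.4f}\t{g.q:.6f}\t{';'.join(g.peptides)}\n")


def _load_psms(run: Path) -> pd.DataFrame:
    df = pd.read_csv(run / "search" / "psms.tsv", sep="\t")
    if df.empty:
        df = pd.DataFrame(columns=["spectrum_id", "peptide", "mods", "score", "q",
                                   "pass", "proteins", "missed", "semi", "intensity"])
    return df


def _matches_from_df(df: pd.DataFrame) -> list[PeptideMatch]:
    out = []
    for r in df.to_dict(orient="records"):
        mods = []
        if isinstance(r["mods"], str) and r["mods"] != "-":
            for tok in r["mods"].split(";"):
                name_pos, delta = tok.rsplit(":", 1)
                name, pos = name_pos.rsplit("@", 1)
                mods.append(ModPlacement(int(pos), name, float(delta)))
        out.append(PeptideMatch(
            spectrum_id=r["spectrum_id"], peptide=r["peptide"],
            mods=tuple(sorted(mods)),
            proteins=tuple(str(r["proteins"]).split(";")), missed=int(r["missed"]),
            score=float(r["score"]), intensity_frac=0.0, is_decoy=False,
            pass_label=str(r["pass"]), semi=bool(r["semi"]), q=float(r["q"]),
        ))
    return out


def stage_integrate(run: Path, cfg: PipelineConfig) -> None:
    out_dir = run / "integrate"
    outputs = [out_dir / f for f in
               ("allelic.tsv", "nterm.tsv", "cleavage.tsv", "proteoforms.tsv",
                "ibaq.tsv", "correlation.tsv", "enrichment.tsv")]
    if _stage_done(outputs):
        return
    out_dir.mkdir(parents=True, exist_ok=True)
    sim, db_dir = run / "sim", run / "db"
    genome = read_genome_fasta(sim / "genome.fa")
    ref_txs = read_gtf(sim / "reference.gtf", source="reference")
    asm_txs = read_gtf(sim / "assembled.gtf", source="assembled")
    expression = cdb.read_expression_table(sim / "expression.tsv")
    reference = cdb.read_fasta_records(db_dir / "reference.fa")
    ref_seqs = {r.accession: r.sequence for r in reference}
    psms = _load_psms(run)
    matches = _matches_from_df(psms)
    accepted = [m for m in matches]

    # --- allelic expression --------------------------------------------------
    saav_map = pd.read_csv(db_dir / "saav_map.tsv", sep="\t")
    saavs, saav_recs = [], cdb.read_fasta_records(db_dir / "saav.fa")
    for r in saav_map.itertuples(index=False):
        v = cdb.VariantRecord(r.contig, int(r.variant_pos), r.ref, r.alt, r.genotype)
        saavs.append(cdb.SAAVRecord(r.protein_id, int(r.position), r.ref_aa, r.alt_aa, v))
    allelic = integ.evaluate_allelic_evidence(saavs, saav_recs, ref_seqs, accepted)
    with open(out_dir / "allelic.tsv", "w") as fh:
        fh.write("protein_id\tsaav\tgenotype\tref_detected\talt_detected\t"
                 "class\tconflict\tobservable\n")
        for a in allelic:
            fh.write(f"{a.saav.protein_id}\t{a.saav.label}\t{a.genotype}\t"
                     f"{a.ref_detected}\t{a.alt_detected}\t{a.klass}\t"
                     f"{a.conflict}\t{a.observable}\n")

    # --- N-termini -----------------------------------------------------------
    tx_by_id = {t.transcript_id: t for t in ref_txs}
    utr_cache = {
        tid: integ.upstream_inframe_region(tx, genome)[0]
        for tid, tx in tx_by_id.items()
    }
    nterm_calls = []
    for m in accepted:
        if m.pass_label not in ("reference", "orf", "ptm"):
            continue
        acetyl = any(mm.position == -1 and mm.name.startswith("Acetyl") for mm in m.mods)
        cand_tids = set()
        for acc in m.proteins:
            tid = acc.split("|", 1)[0].replace("DECOY_", "")
            if tid in tx_by_id:
                cand_tids.add(tid)
        if not cand_tids:
            cand_tids = set(tx_by_id)
        for tid in sorted(cand_tids):
            if tid not in ref_seqs:
                continue
            call = integ.classify_nterm(m.peptide, acetyl, ref_seqs[tid],
                                        utr_cache.get(tid, ""), tid)
            if call is not None:
                nterm_calls.append(call)
                break
    with open(out_dir / "nterm.tsv", "w") as fh:
        fh.write("peptide\tprotein_id\tclass\toffset_codons\ttis_codon\ttis_offset\n")
        for c in nterm_calls:
            fh.write(f"{c.peptide}\t{c.protein_id}\t{c.klass}\t{c.offset_codons}\t"
                     f"{c.tis_codon or '-'}\t{'' if c.tis_offset is None else c.tis_offset}\n")

    # --- signal cleavage -----------------------------------------------------
    cleavage_calls = []
    for m in accepted:
        if m.pass_label != "signal":
            continue
        for acc in m.proteins:
            if "|SIGNAL|" not in acc:
                continue
            pid, _, endtag = acc.partition("|SIGNAL|end")
            seq = ref_seqs.get(pid, "")
            pos = seq.find(m.peptide)
            if pos < 0:
                continue
            cleavage_calls.append(
                integ.classify_cleavage(pos + 1, int(endtag), cfg.cleavage_window, pid)
            )
            break
    dual = integ.flag_dual_cleavage(cleavage_calls)
    with open(out_dir / "cleavage.tsv", "w") as fh:
        fh.write("protein_id\tobserved_start\tannotated_end\toffset\tclass\tdual_site\n")
        for c in cleavage_calls:
            fh.write(f"{c.protein_id}\t{c.observed_start}\t{c.annotated_end}\t"
                     f"{c.offset}\t{c.klass}\t{c.protein_id in dual}\n")

    # --- junction proteoforms ------------------------------------------------
    jent = pd.read_csv(db_dir / "junction_entries.tsv", sep="\t")
    entries_by_acc = {}
    for r in jent.itertuples(index=False):
        entries_by_acc[r.accession] = SpliceJunction(
            r.contig, int(r.intron_start), int(r.intron_end), r.strand,
            bool(r.donor_known), bool(r.acceptor_known), bool(r.junction_known),
        )
    ref_junctions = enumerate_junctions(ref_txs)
    j_matches = [m for m in accepted if m.pass_label == "junction"]
    calls = integ.detect_junction_proteoforms(j_matches, entries_by_acc, ref_junctions)
    orf_matches = [m for m in accepted if m.pass_label == "orf"]
    orf_records = {r.accession: r for r in cdb.read_fasta_records(db_dir / "orf.fa")}
    asm_by_id = {t.transcript_id: t for t in asm_txs}
    ref_ann = annotate_junctions(ref_junctions, ref_junctions)
    calls += integ.detect_intron_retention(orf_matches, orf_records, asm_by_id, ref_ann)
    with open(out_dir / "proteoforms.tsv", "w") as fh:
        fh.write("peptide\tevent\tcontig\tintron_start\tintron_end\tstrand\t"
                 "extension_bp\tgene_id\tambiguous\n")
        for c in calls:
            j = c.junction
            fh.write(f"{c.peptide}\t{c.event}\t{j.contig if j else ''}\t"
                     f"{j.start if j else ''}\t{j.end if j else ''}\t"
                     f"{j.strand if j else ''}\t"
                     f"{'' if c.extension_bp is None else c.extension_bp}\t"
                     f"{c.gene_id}\t{c.ambiguous}\n")

    # --- iBAQ + correlation --------------------------------------------------
    groups_df = pd.read_csv(run / "search" / "protein_groups.tsv", sep="\t")
    groups = [
        ProteinGroup(r.leader, tuple(str(r.members).split(";")),
                     tuple(str(r.peptides).split(";")), float(r.best_score),
                     False, float(r.q))
        for r in groups_df.itertuples(index=False)
    ]
    psm_int = psms.rename(columns={"intensity": "intensity"})
    psm_int = psm_int.assign(run="run1")[["run", "peptide", "intensity"]]
    all_seqs = dict(ref_seqs)
    for fa in ("saav.fa", "junction_peptides.fa", "orf.fa", "signal.fa"):
        for r in cdb.read_fasta_records(db_dir / fa):
            all_seqs.setdefault(r.accession, r.sequence)
    quants = integ.compute_ibaq(psm_int, groups, all_seqs) if groups else []
    with open(out_dir / "ibaq.tsv", "w") as fh:
        fh.write("group\tibaq\tsummed_intensity\ttheoretical_peptides\n")
        for q in quants:
            fh.write(f"{q.group_id}\t{'' if q.ibaq is None else f'{q.ibaq:.6g}'}\t"
                     f"{q.summed_intensity:.6g}\t{q.theoretical_peptides}\n")
    gene_of = {t.transcript_id: t.gene_id for t in ref_txs}
    gene_ibaq = {}
    for q in quants:
        g = gene_of.get(q.group_id.split("|", 1)[0])
        if g and q.ibaq:
            gene_ibaq[g] = gene_ibaq.get(g, 0.0) + q.ibaq
    try:
        r_val, scatter = integ.correlate_mrna_protein(expression, gene_ibaq)
    except ValueError:
        r_val, scatter = float("nan"), pd.DataFrame(
            columns=["gene", "fpkm", "ibaq", "log2_fpkm", "log2_ibaq"])
    scatter.to_csv(out_dir / "correlation.tsv", sep="\t", index=False)

    # --- tissue enrichment ---------------------------------------------------
    matrix = pd.read_csv(sim / "tissue_matrix.tsv", sep="\t", index_col=0)
    enriched = integ.call_enriched_genes(matrix, matrix.columns[0],
                                         cfg.enrichment_fold, cfg.enrichment_min_expr)
    with open(out_dir / "enrichment.tsv", "w") as fh:
        fh.write("gene_id\tenriched\n")
        for g in matrix.index:
            fh.write(f"{g}\t{g in enriched}\n")

    summary = {
        "expressed_genes": int(sum(1 for v in expression.values() if v >= cfg.fpkm_min)),
        "psms_per_pass": psms.groupby("pass").size().to_dict() if len(psms) else {},
        "protein_groups": int(len(groups)),
        "saav_peptides": int((psms["pass"] == "saav").sum()) if len(psms) else 0,
        "nterm_classes": pd.Series([c.klass for c in nterm_calls]).value_counts().to_dict(),
        "cleavage_classes": pd.Series([c.klass for c in cleavage_calls]).value_counts().to_dict(),
        "dual_cleavage_proteins": sorted(dual),
        "proteoforms": pd.Series([c.event for c in calls]).value_counts().to_dict(),
        "allelic_classes": pd.Series([a.klass for a in allelic]).value_counts().to_dict(),
        "mrna_protein_pearson_r": None if pd.isna(r_val) else round(r_val, 4),
        "enriched_genes": sorted(enriched),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


def run_pipeline(run_dir: str | Path, cfg: Optional[PipelineConfig] = None) -> dict:
    """Execute all stages in dependency order; returns the summary dict."""
    cfg = cfg or PipelineConfig()
    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    for stage in (stage_simulate, stage_build_db, stage_search, stage_integrate):
        try:
            stage(run, cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage.__name__} failed: {exc}") from exc
    with open(run / "integrate" / "summary.json") as fh:
        return json.load(fh)
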