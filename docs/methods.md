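# Methods

This note documents the models, parameters and design choices behind
`proteogen`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and sequence conventions

GTF and all in-memory genomic coordinates are 1-based inclusive; junction
BED I/O is 0-based half-open, converted exactly. A `SpliceJunction` stores
the intron span (first and last intronic base). Exons of a transcript are
kept in 5′→3′ transcript order; minus-strand sequences are
reverse-complemented after concatenating exons in genomic order. Codons
containing `N` translate to `X`; database entries containing `X` are
dropped because they cannot be scored against a mass ladder. Ambiguity
codes other than `N` in input FASTA are normalized to `N`.

## Junction classes

A junction is compared to the reference annotation by three flags: the
exact intron annotated, the donor site annotated, the acceptor site
annotated. This yields four classes: `annotated`, `partial_novel` (exactly
one novel site), `complete_novel` (both novel), and `novel_pairing` (both
sites known but never paired). The last class is our own addition: the
two-site-known case is not covered by the usual two-way novel/partial
distinction, and folding it into either would misstate the evidence.
Junctions without strand are resolved by GT–AG/CT–AC dinucleotides; if
neither motif matches they are excluded from peptide-database construction,
since a translation frame is undefined without strand.

## Custom databases

**SAAV.** The consequence caller maps a VCF SNV through the spliced CDS
(strand-aware; the alt allele is complemented on minus-strand transcripts)
and re-translates the affected codon. Only missense variants in genes at
FPKM ≥ 0.1 produce entries, one full-length substituted protein per
(transcript, variant). Full-length entries keep missed-cleavage context
correct; single-variant entries (no haplotype combinations) keep peptide
provenance unambiguous. Multi-allelic VCF rows are decomposed; indels and
MNVs are rejected with a warning.

**Junction peptides.** Up to 90 nt of exonic flank per side (clipped at the
flanking exon boundary when a transcript model supplies one, and flagged
truncated), concatenated in transcript orientation and translated in all
three frames — frames are enumerated rather than inferred from CDS phase
because novel junctions may lie outside any annotated CDS. Each stop-free
segment is digested; a peptide is kept only if at least one complete
residue is encoded on each side of the boundary. The boundary offset counts
residues whose codon starts 5′ of the junction, so a codon split by the
junction is counted on the 5′ side; the offset is therefore always in
[1, len−1]. Whether a flank should instead extend across further upstream
junctions is not defined by the input formats we accept; we clip and flag.

**ORFs.** Assembled transcripts are translated in the three forward frames
only (stranded library chemistry makes the antisense frames meaningless),
split at stops, and segments of ≥ 7 aa (the minimum searchable peptide) are
kept with (transcript, frame, offset) provenance.

**Signal regions.** Signal peptide plus 60 mature residues per annotated
protein, searched semi-tryptically. Sanity bounds on annotated signal ends
are 5–60 aa.

**Decoys.** Full-sequence reversal, one per target, `DECOY_`-prefixed.
Reversal preserves amino-acid composition and length distribution;
decoy-of-decoy construction is refused.

## Search engine

Digestion: trypsin, cleavage C-terminal of K/R, suppressed before proline,
≤ 2 missed cleavages, peptide length 7–45. Semi specificity additionally
emits every N- or C-terminal truncation of each fully tryptic product.
Initiator-Met-clipped N-terminal products are indexed for protein entries,
matching how co-translational Met excision is usually handled.

Masses are monoisotopic; fragment ions are the b/y series (HCD-style, no
neutral losses) at charge 1 by default. Fixed carbamidomethyl-C; first-pass
variable mods acetyl-protein-N-term, oxidation-M, phospho-STY; the PTM pass
swaps the variable set for acetyl-K, mono/di/tri-methyl-K/R and GlyGly-K
(ubiquitylation remnant, +114.04293 Da — the modeled mass is our
assumption, as a remnant mass is the only searchable signature). Variable
mods are capped at 3 per peptide and placement enumeration at 64 per
peptide to bound the search space.

Scoring is a binomial-tail count statistic (see README for the formula).
It is deliberately simple and fully reproducible; commercial engine scores
are proprietary, so correctness is established by ground-truth recovery and
FDR behavior rather than score equality. A PSM additionally requires at
least 4 matched fragments: with a very small per-fragment match probability
the binomial tail otherwise rewards 2–3 chance coincidences from the
widened PTM search space enough to pass. Precursor tolerance 10 ppm,
fragment tolerance 0.02 Da, acceptance at q ≤ 0.01 per pass.

Passes run as a chain — reference → PTM → proteogenomic (SAAV + junction +
ORF) → semi-tryptic signal — each re-searching the previous pass's
unmatched spectra and each FDR-controlled independently (whether the
original multi-engine workflow pooled passes is not observable from its
outputs; per-pass control is our choice and is the conservative one for
the small custom databases). Custom passes exclude peptides present in the
reference digest, so a wild-type peptide can never be reported as a
variant/junction identification on the strength of a shared sequence.

Parsimony grouping solves minimum set cover exactly for components of ≤ 15
proteins (ties broken toward proteins explaining more peptides, then
lexicographically) and falls back to the standard greedy cover above that;
proteins whose peptide sets are subsets of a leader join its group.
Protein-level q-values come from target/decoy counting on group best
scores. Missing-protein evidence follows the two-unique-non-nested-peptides
rule with a 9-aa minimum.

## Integration layer

**Allelic classes.** The classifier is a total function of (mRNA genotype,
reference peptide detected, alternate peptide detected); a homozygous-alt
variant with reference-peptide evidence is flagged as a conflict rather
than dropped. A variant is "observable" only if both allelic forms have a
fully tryptic peptide of ≥ 7 aa covering the site.

**N-termini and TIS.** Each protein is extended upstream by the in-frame,
stop-free translation of its 5′-UTR. A peptide at residue 1 is
`annotated_acetyl`/`annotated_free` by its N-terminal acetylation state; at
residue 2 with an initiator Met, `met_cleaved`; wholly within the UTR
translation, `upstream_inframe`; starting in the UTR and reading through
residue 1, `extension`. Offsets are in codons relative to the annotated
start (0 = annotated ATG, upstream negative). The near-cognate scan walks
in-frame codons strictly upstream of the peptide start toward the UTR 5′
end, stops at an in-frame stop, and returns the nearest member of
{ATG} ∪ {CTG, GTG, TTG, ACG, ATA, ATT, ATC, AAG, AGG} (the one-substitution
neighbors of ATG); the set is configurable.

**Cleavage sites.** Offset = observed mature start − annotated mature
start; 0 is `annotated`, 1 ≤ |offset| ≤ 5 `alternate`, beyond `unrelated`;
proteins with both annotated and alternate calls are flagged dual-site.

**iBAQ.** Each run's PSM intensities are scaled to equal total signal,
summed over a group's peptides, and divided by the count of fully tryptic
6–30 aa peptides of the group leader. A zero denominator is reported as
missing rather than zero. mRNA–protein coupling is Pearson's r over
log₂ FPKM vs log₂ iBAQ for genes positive in both.

**Tissue enrichment.** A gene is enriched in the target tissue if its
expression is ≥ 1 and ≥ 5× the maximum over all other tissues (HPA-style
convention; both constants configurable, and a median- or mean-summarized
matrix is accepted as supplied).

**Junction proteoforms.** A confident junction-pass peptide with a novel
donor and known acceptor is an alternate donor; the exon-extension distance
in bp is measured against the annotated junction sharing the acceptor
(symmetrically for alternate acceptors). Junctions novel at both ends are
reported as exon extensions. Intron retention is called from ORF-pass
peptides whose genomic span lies wholly within an annotated intron.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes: a
~20-gene, single-contig genome with 2–4 exons per gene and GT–AG introns;
log-normal expression with ~15% of genes below the FPKM 0.1 cutoff
(silence is drawn only from genes without planted events, so every planted
subject is observable); codon-aware SNVs realizing a 70:30
missense:synonymous ratio at 1:1 het:hom zygosity; an eight-tissue matrix
with three planted ≥5-fold enriched genes; and charge-2 precursors over
charge-1 b/y ladders with configurable peak dropout, Gaussian m/z jitter
clipped to half the fragment tolerance (so planted identifications remain
recoverable by construction), log-normal intensities proportional to
protein abundance, and uniform noise peaks plus pure-noise spectra. Each
artifact draws from its own labeled RNG stream derived from the master
seed, so regenerating one artifact never shifts another, and a (config,
seed) pair reproduces every output byte.

Planted events: alternate-donor junctions extending an exon 24 bp into the
intron (the intron is built so its 24-bp-shifted suffix is itself GT..AG);
intron-retention isoforms whose retained intron is in-frame, stop-free and
carries a fully tryptic 9-mer; 5′-UTRs with a near-cognate TIS and either a
wholly-upstream or a start-crossing tryptic peptide; K/R-free signal
peptides with cleavage offsets planted across −9..+5 including dual-site
proteins; PTM-bearing peptides for each modification type; and
heterozygous/homozygous variant peptides with the reference-allele peptide
emitted only when the reference allele is meant to be detected.

Two realism concessions are deliberate. Missense substitutions whose mass
shift coincides with a searched modification (e.g. G→A vs methylation,
A→S vs oxidation, I↔L) are excluded from planting: such variants are
genuinely indistinguishable from modified reference peptides at the
precursor level, so they cannot serve as ground truth. And retained introns
/ planted UTR segments are shorter and more structured than real ones.
Consequently, passing tests show the machinery is correct under the stated
noise model; they do not show robustness to co-eluting chimeric spectra,
isotope-envelope errors, retention-time effects, or the mass-coincidence
ambiguities real searches must arbitrate.

## Numerical choices and degenerate inputs

Binomial survival values are floored at 1e-300 before the log. The
per-fragment match probability is capped at 0.99. Empty spectra or zero
matched fragments score 0. An empty database leaves every spectrum
unmatched; zero targets yield an empty FDR result; fewer than three
mRNA–protein pairs make the correlation undefined (an error, not a number).
Peptide m/z matching uses binary search on the sorted peak list; greedy
spectral alignment prefers the smallest |Δm/z| and uses each peak once.

## Problem sizes

The default test and acceptance runs use 20-gene studies (~150 spectra)
for end-to-end checks, a 260-gene reference-only study (~2350 spectra,
15% dropout, 5 noise peaks) for FDR estimation, and a 30-gene noise-free
study for quantification fidelity. These sizes give stable statistics for
every reported quantity while keeping a full run in seconds.

## Known limitations

No Percolator-style rescoring (q-values are raw target–decoy counts); no
deisotoping or precursor mass correction; fragment charge > 1 is off by
default; phospho neutral losses are not modeled; no indel/frameshift or
haplotype-aware proteoforms; protein inference ignores razor-peptide
weighting; iBAQ is not calibrated to absolute copy numbers. The
`novel_pairing` junction class and the exact-cover parsimony for small
instances are this package's own conventions, documented above.
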