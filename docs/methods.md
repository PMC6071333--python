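# Methods

This note documents the models and procedures implemented in `rumencaz`,
the parameters that matter, the numerical and design choices made where the
conventions of the field leave room, and what the synthetic-data tests do
and do not demonstrate.

## Scope and inputs

The package operates strictly downstream of assembly: gene calling, HMM and
similarity searches, binning and bin QC are consumed as tabular inputs, not
executed. Coordinates are 1-based inclusive throughout (GFF3 convention for
genes, HMMER convention for protein alignments). Malformed rows in tabular
inputs are skipped and counted rather than fatal, so large real-world
tables degrade gracefully; the rejection counts are returned and logged.
Marker gene symbols (ackA, pta, mmdA, lcdA, pduP, pduQ, buk, but) are taken
from the `gene=` attribute of the supplied annotation — no homology search
is performed to call them, since that is the annotation pipeline's job
upstream.

## CAZyme annotation cascade

Domain hits carry a model-coverage statistic, `(hmm_end − hmm_start + 1) /
hmm_length`, i.e. coverage of the HMM profile rather than of the query
protein — the dbCAN post-processing convention, which is the context in
which these thresholds are normally quoted.

1. **Filtering.** A hit is retained iff coverage ≥ 0.30 and its e-value
   passes a length-dependent gate: ≤ 1e−5 for alignments strictly longer
   than 80 residues, ≤ 1e−3 for alignments of 80 residues or fewer.
   "Longer than 80" is read literally, so 80 falls in the lenient regime.
   All four thresholds are exposed as parameters.
2. **Overlap resolution.** Per protein, hits are sorted by e-value
   (ascending), then bit score (descending), then family id, and accepted
   greedily iff they share no residue with a previously accepted hit.
   Resolution is interval-based rather than winner-takes-protein because
   multi-domain CAZymes (e.g. GH + CBM, GH + dockerin fusions) are real and
   must survive; a per-protein "best hit only" rule could not produce them.
   The procedure is idempotent and invariant to input row order.
3. **Classification.** Each annotated protein gets one *primary class* —
   the class of its lowest-e-value retained hit (ties: higher bit score,
   then the fixed order GH < PL < CE < CBM < GT < AA < cellulosome < SLH <
   Sus) — so that per-class percentages sum to 100 over proteins. The full
   multi-domain inventory is kept alongside; family-level counts are per
   sequence per family.

GH substrate categories default to: cellulases {GH5, GH9, GH44, GH45, GH48,
GH74}; endohemicellulases {GH8, GH10, GH11, GH12, GH26, GH28, GH53};
debranching {GH51, GH54, GH67, GH78}; oligosaccharide-degrading {GH1, GH2,
GH3, GH29, GH35, GH38, GH39, GH42, GH43, GH94}. The map is user-overridable
(categories must be disjoint GH sets); GH1 is included in the default
oligosaccharide set alongside GH94 because both appear in practice in this
grouping and the categories are a reporting convention, not a claim about
enzymology. A protein's category follows its best-e-value GH family.

Scaffoldin candidates are called by two routes whose union is reported with
mode labels: a template-similarity score ≥ 700 against known scaffoldins
(scores consumed, not computed), and ≥ 2 cohesin domains on one protein.
Tandem cohesins are counted without a spacing rule — any two cohesin hits
on one protein qualify — because cohesin repeats in scaffoldins are not
constrained to fixed spacing.

## Census and densities

The census counts proteins by primary class; GH density is GH-protein
count per Mbp of assembled sequence, with the assembled size supplied
explicitly (the package does not recompute assembly statistics). Densities
and percentages display at one decimal; internal values are unrounded. When
a minimum contig length is applied (1 kb is the convention for
cross-metagenome comparisons), genes on shorter contigs are removed first
and the percentage denominator is named in the report header, because
published "%GH" figures are ambiguous about their denominator.

## Enrichment statistics

Each family is tested with a two-sided Fisher's exact test (scipy) on
`[[k_A, N_A−k_A], [k_B, N_B−k_B]]`. The margins default to the number of
predicted ORFs per metagenome; a CAZyme-gene margin is available, since the
choice is not standardized and materially affects odds ratios. The odds
ratio uses the sample convention `a·d/(b·c)` with 0/0 → 1 and x/0 → ∞.
Multiple testing uses Benjamini–Hochberg step-up (statsmodels `fdr_bh`) —
the standard reading of an unqualified "FDR" correction — with tiers
`***` q < 0.001, `**` q < 0.01, `*` q < 0.05. Tests verify the p-values
against a rational-arithmetic hypergeometric enumeration and the q-values
against the hand-applied step-up formula, and calibrate the q < 0.05 call
rate on paired null profiles (same multinomial, two draws): over 200
replicates of 30 families at depth 1500 the observed rate is ~0.2 %, far
inside the nominal 5 % band, as expected for a discrete test under the
full null.

## PUL detection

A locus is anchored on a SusC–SusD tandem gene pair: a SusC gene and a SusD
gene (SusD-like, SusD-like_2 and SusD-like_3 count as SusD) separated by at
most `pair_gap` intervening genes (default 0, i.e. adjacent), paired
greedily left to right with each gene in at most one pair. The locus is
extended outward from the pair, recruiting CAZyme genes (GH/CE/PL/CBM/Sus)
and keeping interior genes between recruits (counted as unknown-function
members); extension in a direction stops after `window` consecutive
non-CAZyme genes. `window` defaults to 5 — consistent with the gene density
of characterized PULs — and is exposed as a flag because results depend on
it; no published definition of "nearby" exists to defer to. Loci on one
contig whose member ranks come within `merge_gap` (default 2) genes are
merged into multi-pair loci; merging is the default reading of tandem
susC-susD-susC-susD arrangements, with `--no-merge` giving pair-level
counting. Strand is ignored for pairing and extension (no strand rule is
established for PULs) and reported per member. Member count is monotone
non-decreasing in `window`, and locus count monotone non-increasing in
`merge_gap`; both properties are asserted in tests.

## Bin profiling and abundance

QC gating retains bins strictly more than 50 % complete and strictly less
than 10 % contaminated by default; the completeness flag accommodates
stricter reporting conventions (e.g. > 70 %). Relative abundance from
read-mapping counts has no single standard normalization; two modes are
provided. `raw` is the mapped-read fraction; `per_bp` (default) rescales
each bin's fraction by (mean bin size / bin size), so equally covered bins
of different sizes score equally. The absolute scale of size-normalized
abundance is not comparable across studies and is treated as a relative
measure only.

## VFA pathway screening

Pathway presence is pure marker logic: acetate requires both ackA and pta;
propionate routes are diagnosed by mmdA (succinate), lcdA (acrylate) and
pduP or pduQ (propanediol); the two butyrate routes by buk and but.
Matching is by exact, case-insensitive gene-symbol token — important for
"but", which would otherwise substring-match English text. Presence logic
is monotone: adding genes never revokes a call.

## LCA taxonomy

Similarity hits arrive pre-filtered (e ≤ 1e−3, ≤ 20 per protein) with
lineages embedded in the table, keeping the package self-contained (no
taxonomy database is downloaded). Hits within a bit-score band of the best
hit (top-percent filter, default 10 %) are retained, then the protein is
assigned the deepest rank at which all retained lineages agree.
`top_percent=100` gives the naive LCA over all hits. Raising the band can
only widen the retained set, so assignments get shallower or stay put —
asserted as a property. The exact parameterization of the original
MEGAN-style analyses is generally unreported, so the defaults here are
explicit flags, not claims about any particular prior run.

## Synthetic data

The generator plants, per configured bin: a family-frequency profile
(Poisson counts per family), SusC–SusD locus templates (ordered family
strings; unknown tokens such as "susE" become unknown-function locus
members), marker-gene inventories, tandem-cohesin proteins and GH+dockerin
fusions. The default configuration emulates the structure of a
fibre-adherent rumen community: Bacteroidetes-like bins rich in GH2/GH3/
GH43 with PULs and a but-dominant butyrate route, Firmicutes-like bins rich
in GH5/GH9/GH13 with cellulosome components and a buk-dominant route, and a
Fibrobacteres-like bin with cellulases and hemicellulases but no dockerin
or cohesin. Contigs hold 14–30 genes (4–8 contigs per bin), proteins
250–500 aa.

Three constructions make planted truth exactly recoverable, and they are
deliberate idealizations: true hits are drawn to always pass the filter
(e ≤ 1e−8, coverage ≥ 0.5); decoy hits are drawn to always fail it
(e ≥ 1e−2, half additionally with coverage < 0.3); and planted loci are
separated from background CAZyme genes by a buffer of 7 non-CAZyme genes,
wider than the 5-gene extension window. Domains planted on one protein
occupy disjoint fixed slots of the alignment coordinate space so overlap
resolution keeps them all. Similarity hits for a protein all carry its
bin's source lineage within the retained score band, plus an occasional
off-taxon hit placed below the band. Protein residues are random
placeholders; no stage reads them.

Consequently, passing the recovery suites shows that the pipeline's logic
is faithful — filtering, overlap resolution, locus extension, marker logic
and LCA do exactly what they claim on inputs whose truth is known — but
not that the thresholds are well-tuned for real data, where true and false
hits overlap in score, loci abut other CAZyme genes, and lineages disagree
within the score band. Threshold calibration on real data is upstream
validation that synthetic tests cannot replace. All randomness flows from a
single seeded generator; identical seeds give byte-identical output files.

## Problem sizes used in the checked runs

The test suite and the acceptance script run the synthetic pipeline at the
default scale (~750 genes, ~220 planted CAZyme proteins, 6 planted PULs per
dataset; 20 seeds for recovery statistics), the null calibration at 200
replicates × 30 families × depth 1500, and the Fisher oracle comparisons
on 2×2 tables with margins up to 2000 — sizes chosen so the entire suite
completes in well under a minute on one CPU while keeping the binomial
error of the calibration small.

## Known limitations

* Query coverage is interpreted as HMM-model coverage; tools that report
  query-protein coverage will need their tables converted.
* The enrichment margins (ORFs vs CAZyme genes) change odds ratios; both
  are defensible and the choice is surfaced rather than hidden.
* Abundance normalization is relative; absolute percentages are not
  comparable across normalization modes or studies.
* Pathway calls are presence/absence of annotation tokens; missing
  annotations (incomplete bins) read as absent pathways.
* The LCA ignores hit counts per taxon (no min-support rule); a single
  aberrant high-scoring lineage can lift an assignment to a shallow rank.
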