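# rumencaz

Downstream functional profiling of rumen (and other gut) metagenome
assemblies, centred on the carbohydrate-active enzyme (CAZyme) repertoire.
The package consumes post-assembly products — contig FASTA, GFF3 gene calls,
HMMER3-style domain-hit tables, similarity hits with taxonomic lineages, bin
membership/QC tables and read-count tables — and produces:

* **per-protein CAZyme annotations** from HMM domain hits, via a
  dbCAN-style filtering cascade (model coverage ≥ 30 %; e ≤ 1e−5 for
  alignments longer than 80 residues, e ≤ 1e−3 otherwise) followed by
  greedy per-protein overlap resolution that keeps multi-domain proteins
  intact, with substrate categorization of glycoside hydrolases
  (cellulases, endohemicellulases, debranching, oligosaccharide-degrading)
  and cellulosome-component flags (dockerin, cohesin, SLH, tandem-cohesin
  scaffoldin candidates, score-based scaffoldin calls at a 700 cutoff);
* **genome-wide censuses** — per-class/per-family counts, GHs per Mbp of
  assembled DNA, fraction-of-ORF percentages;
* **cross-metagenome enrichment statistics** — a two-sided Fisher's exact
  test per family on `[[k_A, N_A−k_A], [k_B, N_B−k_B]]` with
  Benjamini–Hochberg FDR correction and `ns/*/**/***` significance tiers;
* **polysaccharide utilization locus (PUL) detection** — tandem SusC–SusD
  gene pairs extended to nearby CAZyme genes, merged into multi-pair loci,
  summarized per genome bin;
* **per-bin profiles** — completeness/contamination QC gating (> 50 %
  complete, < 10 % contaminated), size-normalized relative abundance,
  bin × substrate-category capability matrices, cellulosome screening;
* **VFA pathway calls** — acetate (ackA + pta), propionate via succinate
  (mmdA), acrylate (lcdA) or propanediol (pduP/pduQ), butyrate via
  butyrate kinase (buk) or butyryl-CoA:acetate CoA-transferase (but);
* **LCA taxonomy** — MEGAN-style bit-score top-percent filtering followed
  by lowest-common-ancestor assignment, with per-category taxon breakdowns.

A first-class synthetic-data generator (`rumencaz.simulate`) emits the
complete input file set with planted ground truth, so every stage is
testable without downloads.

## Worked example

```python
import rumencaz as rc
from rumencaz.classify import annotate
from rumencaz.census import census
from rumencaz.puls import detect_puls, summarize_puls

dataset, truth = rc.generate(rc.default_config(seed=1))
anns = annotate(dataset.domain_hits, dataset.genes)
total_bp = sum(c.length_bp for c in dataset.contigs.values())
c = census(anns, dataset.genes, assembled_bp=total_bp)
print(f"{c.n_cazyme_proteins} CAZyme proteins among {c.n_orfs_total} ORFs "
      f"({c.pct_cazyme_of_orfs:.1f}%), {c.gh_per_mbp:.1f} GHs/Mbp")
puls = detect_puls(dataset.genes, anns, bin_map=dataset.bin_map)
s = summarize_puls(puls)
print(f"{len(puls)} PULs; per bin min={s.min_puls:.0f} "
      f"max={s.max_puls:.0f} mean={s.mean_puls:.1f}")
```

prints

```
216 CAZyme proteins among 742 ORFs (29.1%), 177.6 GHs/Mbp
6 PULs; per bin min=1 max=3 mean=2.0
```

i.e. the classifier recovered all 216 planted CAZyme proteins among the 742
synthetic gene calls, and the PUL detector found exactly the six planted
SusC–SusD loci. (The synthetic community is deliberately CAZyme-dense, so
its 177.6 GHs/Mbp is far above the ~10–25 GHs/Mbp typical of real
fibre-degrading metagenomes.) Enrichment between two profiles works the
same way:

```python
from rumencaz.compare import compare_profiles
for r in compare_profiles({"GH5": (180, 90), "GH13": (60, 130)}, 20000, 20000):
    print(r.family_id, f"OR={r.odds_ratio:.2f} q={r.q_value:.3g} {r.tier} {r.direction}")
```

```
GH13 OR=0.46 q=3.91e-07 *** under_in_a
GH5 OR=2.01 q=8.32e-08 *** over_in_a
```

The same operations are available from the shell via the `rumencaz`
command (`annotate`, `census`, `compare`, `puls`, `bins`, `vfa`,
`taxonomy`, `simulate`); `rumencaz simulate --seed 3 --outdir demo/`
writes a full synthetic input set plus `ground_truth.json`.

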