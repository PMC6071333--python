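"""Seeded synthetic metagenome datasets with planted ground truth.

The generator emits the full file set the pipeline consumes — contig FASTA,
GFF3 gene calls, HMM domain-hit tables, bin membership/QC tables,
taxonomy-annotated similarity hits and read-count tables — together with a
record of everything that was planted, so each stage can be checked for
exact recovery.

The default configuration mirrors, at desk scale, the statistical structure
of a fibre-adherent rumen community: Bacteroidetes-like bins rich in
oligosaccharide-degrading families (GH2/GH3/GH43) and carrying SusC-SusD
anchored polysaccharide utilization loci with a butyryl-CoA:acetate
CoA-transferase (but) butyrate route; Firmicutes-like bins rich in
cellulases (GH5/GH9) and starch-active GH13 with dockerin/cohesin
cellulosome components and a butyrate-kinase (buk) route; and a
Fibrobacteres-like bin holding cellulases and hemicellulases but no
cellulosome domains.  Protein residues are random placeholders — no stage
reads them — only the tabular and statistical structure is emulated.

All randomness flows from one seed through a single generator instance, so
repeated runs are reproducible bit-for-bit.  Planted loci are isolated from
background CAZyme genes by a buffer of non-CAZyme genes wider than the
detector's extension window, and decoy (noise) domain hits are constructed
to fail the filtering thresholds, so at the default settings the planted
truth is exactly recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import io as annotation_io
from .families import FAMILY_CATALOG, family_class
from .model import (
    BinQcRecord,
    ContigRecord,
    DomainHit,
    GeneRecord,
    SimilarityHit,
)

# ---------------------------------------------------------------------------
# Configuration

#: A small ranked taxonomy used to label similarity hits.
DEFAULT_TAXONOMY_FIXTURE: Dict[str, Tuple[Tuple[str, str], ...]] = {
    "Prevotella ruminicola": (
        ("superkingdom", "Bacteria"),
        ("phylum", "Bacteroidetes"),
        ("class", "Bacteroidia"),
        ("order", "Bacteroidales"),
        ("family", "Prevotellaceae"),
        ("genus", "Prevotella"),
        ("species", "Prevotella ruminicola"),
    ),
    "Bacteroides cellulosilyticus": (
        ("superkingdom", "Bacteria"),
        ("phylum", "Bacteroidetes"),
        ("class", "Bacteroidia"),
        ("order", "Bacteroidales"),
        ("family", "Bacteroidaceae"),
        ("genus", "Bacteroides"),
        ("species", "Bacteroides cellulosilyticus"),
    ),
    "Ruminococcus flavefaciens": (
        ("superkingdom", "Bacteria"),
        ("phylum", "Firmicutes"),
        ("class", "Clostridia"),
        ("order", "Clostridiales"),
        ("family", "Ruminococcaceae"),
        ("genus", "Ruminococcus"),
        ("species", "Ruminococcus flavefaciens"),
    ),
    "Butyrivibrio fibrisolvens": (
        ("superkingdom", "Bacteria"),
        ("phylum", "Firmicutes"),
        ("class", "Clostridia"),
        ("order", "Clostridiales"),
        ("family", "Lachnospiraceae"),
        ("genus", "Butyrivibrio"),
        ("species", "Butyrivibrio fibrisolvens"),
    ),
    "Fibrobacter succinogenes": (
        ("superkingdom", "Bacteria"),
        ("phylum", "Fibrobacteres"),
        ("class", "Fibrobacteria"),
        ("order", "Fibrobacterales"),
        ("family", "Fibrobacteraceae"),
        ("genus", "Fibrobacter"),
        ("species", "Fibrobacter succinogenes"),
    ),
    "Treponema bryantii": (
        ("superkingdom", "Bacteria"),
        ("phylum", "Spirochaetes"),
        ("class", "Spirochaetia"),
        ("order", "Spirochaetales"),
        ("family", "Spirochaetaceae"),
        ("genus", "Treponema"),
        ("species", "Treponema bryantii"),
    ),
}


@dataclass
class NoiseModel:
    """Decoy domain-hit noise.

    Decoys are emitted per protein at ``decoy_rate`` with e-values drawn
    from ``decoy_evalue_range`` (above every filtering threshold); a
    fraction of them additionally get sub-threshold model coverage.
    """

    decoy_rate: float = 0.0
    decoy_evalue_range: Tuple[float, float] = (1e-2, 5.0)
    decoy_low_coverage_fraction: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.decoy_rate <= 1.0):
            raise ValueError("decoy_rate must lie in [0,1]")
        if not (0.0 <= self.decoy_low_coverage_fraction <= 1.0):
            raise ValueError("decoy_low_coverage_fraction must lie in [0,1]")


@dataclass
class BinTemplate:
    """What to plant in one synthetic genome bin."""

    bin_id: str
    phylum: str
    source_taxon: str
    family_profile: Dict[str, float] = field(default_factory=dict)
    pul_templates: List[List[str]] = field(default_factory=list)
    markers: Tuple[str, ...] = ()
    tandem_cohesins: Tuple[int, ...] = ()
    gh_dockerin_fusions: int = 0


@dataclass
class SimulationConfig:
    seed: int = 0
    bins: List[BinTemplate] = field(default_factory=list)
    genes_per_contig: Tuple[int, int] = (14, 30)
    contigs_per_bin: Tuple[int, int] = (4, 8)
    noise: NoiseModel = field(default_factory=NoiseModel)
    taxonomy_fixture: Dict[str, Tuple[Tuple[str, str], ...]] = field(
        default_factory=lambda: dict(DEFAULT_TAXONOMY_FIXTURE)
    )
    protein_aa_range: Tuple[int, int] = (250, 500)
    locus_buffer_genes: int = 7
    n_unbinned_contigs: int = 2
    off_taxon_hit_rate: float = 0.3


def default_config(seed: int = 0, noise: Optional[NoiseModel] = None) -> SimulationConfig:
    """Study-structured default: three Bacteroidetes-like bins with PULs,
    two Firmicutes-like bins with cellulosome components, one
    Fibrobacteres-like bin without them."""
    bins = [
        BinTemplate(
            bin_id="bac_1",
            phylum="Bacteroidetes",
            source_taxon="Prevotella ruminicola",
            family_profile={
                "GH2": 6, "GH3": 6, "GH43": 8, "GH28": 3, "GH10": 2,
                "GH51": 2, "GH78": 3, "GH5": 1, "GH9": 1,
                "CE1": 2, "CE10": 2, "GT2": 3, "CBM6": 1, "SLH": 1,
            },
            pul_templates=[
                ["susC", "susD", "GH10", "GH43", "CE6"],
                ["GH2", "susC", "susD", "GH43"],
                ["susC", "susD", "susC", "susD", "susE",
                 "CE6", "GH10", "GH43", "GH67", "GH5"],
            ],
            markers=("acka", "pta", "mmda", "but"),
        ),
        BinTemplate(
            bin_id="bac_2",
            phylum="Bacteroidetes",
            source_taxon="Bacteroides cellulosilyticus",
            family_profile={
                "GH2": 5, "GH3": 5, "GH43": 6, "GH28": 2, "GH26": 2,
                "GH35": 2, "GH51": 1, "GH78": 2, "CE1": 2, "GT4": 2, "CBM32": 1,
            },
            pul_templates=[
                ["susC", "susD", "GH5", "GH26"],
                ["PL1", "GH105", "susC", "susD", "CE8", "GH28"],
            ],
            markers=("acka", "pta", "mmda", "but", "buk"),
        ),
        BinTemplate(
            bin_id="bac_3",
            phylum="Bacteroidetes",
            source_taxon="Prevotella ruminicola",
            family_profile={
                "GH2": 4, "GH3": 4, "GH43": 5, "GH29": 2, "GH35": 1,
                "GH78": 1, "CE1": 1, "GT2": 2,
            },
            pul_templates=[["susC", "susD", "GH2", "GH16", "CBM44"]],
            markers=("acka", "pta", "mmda", "but"),
        ),
        BinTemplate(
            bin_id="firm_1",
            phylum="Firmicutes",
            source_taxon="Ruminococcus flavefaciens",
            family_profile={
                "GH5": 5, "GH9": 4, "GH13": 6, "GH43": 3, "GH1": 2, "GH3": 2,
                "GH10": 2, "CE4": 2, "GT2": 2, "dockerin": 6, "cohesin": 1,
                "SLH": 1,
            },
            tandem_cohesins=(3, 2),
            gh_dockerin_fusions=2,
            markers=("acka", "pta", "mmda", "buk"),
        ),
        BinTemplate(
            bin_id="firm_2",
            phylum="Firmicutes",
            source_taxon="Butyrivibrio fibrisolvens",
            family_profile={
                "GH5": 4, "GH9": 2, "GH13": 5, "GH2": 2, "GH43": 2,
                "CE1": 1, "GT2": 2, "dockerin": 3,
            },
            markers=("acka", "pta", "buk"),
        ),
        BinTemplate(
            bin_id="fib_1",
            phylum="Fibrobacteres",
            source_taxon="Fibrobacter succinogenes",
            family_profile={
                "GH5": 4, "GH9": 3, "GH45": 2, "GH74": 2, "GH8": 2,
                "GH10": 3, "GH11": 2, "GH26": 2, "GH53": 2,
                "CE1": 1, "CBM6": 2, "PL1": 1,
            },
            markers=("acka", "pta", "mmda"),
        ),
    ]
    cfg = SimulationConfig(seed=seed, bins=bins)
    if noise is not None:
        cfg.noise = noise
    return cfg


# ---------------------------------------------------------------------------
# Ground truth and dataset containers


@dataclass
class GroundTruth:
    families_by_protein: Dict[str, List[str]] = field(default_factory=dict)
    primary_class_by_protein: Dict[str, str] = field(default_factory=dict)
    pul_loci: List[dict] = field(default_factory=list)
    markers_by_bin: Dict[str, List[str]] = field(default_factory=dict)
    pathway_truth: Dict[str, Dict[str, bool]] = field(default_factory=dict)
    taxon_by_protein: Dict[str, str] = field(default_factory=dict)
    class_counts_by_bin: Dict[str, Dict[str, int]] = field(default_factory=dict)
    family_counts_by_bin: Dict[str, Dict[str, int]] = field(default_factory=dict)
    overall_class_counts: Dict[str, int] = field(default_factory=dict)
    overall_family_counts: Dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    contigs: Dict[str, ContigRecord]
    sequences: Dict[str, str]
    genes: List[GeneRecord]
    domain_hits: List[DomainHit]
    bin_map: Dict[str, str]
    bin_qc: List[BinQcRecord]
    similarity_hits: List[SimilarityHit]
    read_counts: Dict[str, int]
    total_reads: int


# ---------------------------------------------------------------------------
# Generation

_PATHWAY_RULES = {
    "acetate": ("all", ("acka", "pta")),
    "propionate_succinate": ("all", ("mmda",)),
    "propionate_acrylate": ("all", ("lcda",)),
    "propionate_propanediol": ("any", ("pdup", "pduq")),
    "butyrate_buk": ("all", ("buk",)),
    "butyrate_but": ("all", ("but",)),
}

_TOKEN_ALIASES = {"susc": "SusC", "susd": "SusD"}


def _template_families(template: Sequence[str]) -> List[Optional[str]]:
    """Map template tokens to catalog families (None = unknown-function)."""
    out: List[Optional[str]] = []
    for token in template:
        fam = _TOKEN_ALIASES.get(token.lower(), token)
        out.append(fam if fam in FAMILY_CATALOG else None)
    return out


def _validate(config: SimulationConfig) -> None:
    max_genes = config.genes_per_contig[1]
    for bt in config.bins:
        if bt.source_taxon not in config.taxonomy_fixture:
            raise ValueError(
                f"bin {bt.bin_id}: source taxon {bt.source_taxon!r} "
                "missing from the taxonomy fixture"
            )
        for fam in bt.family_profile:
            if fam not in FAMILY_CATALOG:
                raise ValueError(f"bin {bt.bin_id}: unknown family {fam!r}")
        for template in bt.pul_templates:
            needed = len(template) + 2 * config.locus_buffer_genes
            if needed > max_genes:
                raise ValueError(
                    f"bin {bt.bin_id}: locus template of {len(template)} genes "
                    f"plus flanking buffer does not fit on a contig of at most "
                    f"{max_genes} genes"
                )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _emit_true_hit(
    rng: np.random.Generator,
    protein_id: str,
    family: str,
    ali_start: int,
    ali_end: int,
) -> DomainHit:
    alen = ali_end - ali_start + 1
    hmm_length = max(alen, int(round(alen / rng.uniform(0.5, 0.95))))
    e_value = float(10 ** rng.uniform(-30.0, -8.0))
    return DomainHit(
        protein_id=protein_id,
        family_id=family,
        e_value=e_value,
        bit_score=float(np.round(rng.uniform(80.0, 600.0), 1)),
        ali_start=ali_start,
        ali_end=ali_end,
        model_coverage=alen / hmm_length,
        hmm_start=1,
        hmm_end=alen,
        hmm_length=hmm_length,
    )


def generate(
    config: SimulationConfig, outdir: Optional[str] = None
) -> Tuple[SyntheticDataset, GroundTruth]:
    """Generate a complete synthetic dataset plus its ground truth.

    When ``outdir`` is given the standard file set is written there:
    contigs.fasta, genes.gff, domain_hits.tsv, bin_map.tsv, bin_qc.tsv,
    similarity_hits.tsv, read_counts.tsv and ground_truth.json.
    Configuration problems (e.g. a locus template that cannot fit on a
    contig) raise before any file is written.
    """
    _validate(config)
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    contigs: Dict[str, ContigRecord] = {}
    sequences: Dict[str, str] = {}
    genes: List[GeneRecord] = []
    domain_hits: List[DomainHit] = []
    bin_map: Dict[str, str] = {}
    bin_qc: List[BinQcRecord] = []
    similarity_hits: List[SimilarityHit] = []
    read_counts: Dict[str, int] = {}
    catalog = sorted(FAMILY_CATALOG)
    leaves = sorted(config.taxonomy_fixture)

    # protein -> list of planted families, in interval order
    planted: Dict[str, List[str]] = {}

    def _build_contig(contig_id: str, n_genes: int) -> List[GeneRecord]:
        pos = int(rng.integers(50, 300))
        contig_genes = []
        for gidx in range(n_genes):
            aa = int(rng.integers(*config.protein_aa_range))
            length = 3 * (aa + 1)
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneRecord(
                gene_id=f"{contig_id}_g{gidx + 1:03d}",
                contig_id=contig_id,
                start=pos,
                end=pos + length - 1,
                strand=strand,
                rank_on_contig=gidx,
                protein_length_aa=aa,
                gene_symbols=frozenset(),
                is_full_length=True,
            )
            contig_genes.append(g)
            pos += length + int(rng.integers(20, 200))
        return contig_genes

    def _finish_contig(contig_id: str, contig_genes: List[GeneRecord], bin_id):
        length = contig_genes[-1].end + int(rng.integers(50, 300))
        seq = _random_sequence(rng, length)
        gc = (seq.count("G") + seq.count("C")) / length
        contigs[contig_id] = ContigRecord(
            contig_id=contig_id,
            length_bp=length,
            gc_fraction=gc,
            bin_id=bin_id if bin_id else "unassigned",
        )
        sequences[contig_id] = seq
        if bin_id:
            bin_map[contig_id] = bin_id

    # Each protein is partitioned into 8 fixed slots so that domains planted
    # in separate calls never overlap (overlap resolution must keep them all).
    _N_SLOTS = 8

    def _plant(gene: GeneRecord, families: Sequence[str]) -> None:
        planted.setdefault(gene.gene_id, [])
        existing = len(planted[gene.gene_id])
        if existing + len(families) > _N_SLOTS:
            raise ValueError(
                f"more than {_N_SLOTS} domains requested on {gene.gene_id}"
            )
        seg = gene.protein_length_aa // _N_SLOTS
        for i, fam in enumerate(families, start=existing):
            lo = i * seg + 1
            hi = (i + 1) * seg
            domain_hits.append(
                _emit_true_hit(rng, gene.gene_id, fam, lo, max(lo, hi))
            )
            planted[gene.gene_id].append(fam)

    def _add_symbols(gene: GeneRecord, symbols: Sequence[str]) -> GeneRecord:
        updated = GeneRecord(
            gene_id=gene.gene_id,
            contig_id=gene.contig_id,
            start=gene.start,
            end=gene.end,
            strand=gene.strand,
            rank_on_contig=gene.rank_on_contig,
            protein_length_aa=gene.protein_length_aa,
            gene_symbols=frozenset(set(gene.gene_symbols) | set(symbols)),
            is_full_length=gene.is_full_length,
        )
        return updated

    for bt in config.bins:
        n_contigs = int(rng.integers(*config.contigs_per_bin, endpoint=True))
        n_contigs = max(n_contigs, len(bt.pul_templates))
        bin_genes: List[List[GeneRecord]] = []
        for cidx in range(n_contigs):
            contig_id = f"{bt.bin_id}_c{cidx + 1:02d}"
            n_genes = int(rng.integers(*config.genes_per_contig, endpoint=True))
            if cidx < len(bt.pul_templates):
                needed = (
                    len(bt.pul_templates[cidx]) + 2 * config.locus_buffer_genes
                )
                n_genes = max(n_genes, needed)
            bin_genes.append(_build_contig(contig_id, n_genes))

        reserved: Dict[str, set] = {}  # contig idx -> reserved gene indices
        # --- planted PULs, one per leading contig
        for tidx, template in enumerate(bt.pul_templates):
            contig_genes = bin_genes[tidx]
            fams = _template_families(template)
            buf = config.locus_buffer_genes
            start = int(
                rng.integers(buf, len(contig_genes) - len(template) - buf + 1)
            )
            locus_gene_ids = []
            locus_families = []
            for offset, fam in enumerate(fams):
                gene = contig_genes[start + offset]
                if fam is not None:
                    _plant(gene, [fam])
                    locus_families.append(fam)
                locus_gene_ids.append((gene.gene_id, fam))
            reserved[tidx] = set(
                range(max(0, start - buf), min(len(contig_genes), start + len(template) + buf))
            )
            # detected locus spans first..last domain-bearing gene
            with_dom = [i for i, (_, fam) in enumerate(locus_gene_ids) if fam]
            member_ids = [
                gid for gid, _ in locus_gene_ids[with_dom[0] : with_dom[-1] + 1]
            ]
            n_pairs = min(
                sum(1 for f in locus_families if f == "SusC"),
                sum(1 for f in locus_families if f and f.startswith("SusD")),
            )
            truth.pul_loci.append(
                {
                    "bin_id": bt.bin_id,
                    "contig_id": contig_genes[0].contig_id,
                    "gene_ids": member_ids,
                    "families": sorted(locus_families),
                    "n_sus_pairs": n_pairs,
                }
            )

        # --- background family profile on unreserved genes
        eligible: List[Tuple[int, int]] = []
        for cidx, contig_genes in enumerate(bin_genes):
            for gidx in range(len(contig_genes)):
                if gidx not in reserved.get(cidx, set()):
                    eligible.append((cidx, gidx))
        order = rng.permutation(len(eligible))
        cursor = 0
        gh_gene_slots: List[Tuple[int, int]] = []

        def _take() -> Optional[Tuple[int, int]]:
            nonlocal cursor
            if cursor >= len(order):
                return None
            slot = eligible[order[cursor]]
            cursor += 1
            return slot

        for fam in sorted(bt.family_profile):
            k = int(rng.poisson(bt.family_profile[fam]))
            for _ in range(k):
                slot = _take()
                if slot is None:
                    break
                _plant(bin_genes[slot[0]][slot[1]], [fam])
                if family_class(fam) == "GH":
                    gh_gene_slots.append(slot)

        for n_coh in bt.tandem_cohesins:
            slot = _take()
            if slot is None:
                break
            _plant(bin_genes[slot[0]][slot[1]], ["cohesin"] * n_coh)

        for _ in range(bt.gh_dockerin_fusions):
            if gh_gene_slots:
                idx = int(rng.integers(len(gh_gene_slots)))
                slot = gh_gene_slots.pop(idx)
            else:
                slot = _take()
                if slot is None:
                    break
                _plant(bin_genes[slot[0]][slot[1]], ["GH5"])
            _plant(bin_genes[slot[0]][slot[1]], ["dockerin"])

        # --- pathway marker symbols on arbitrary genes
        for marker in bt.markers:
            cidx = int(rng.integers(len(bin_genes)))
            gidx = int(rng.integers(len(bin_genes[cidx])))
            bin_genes[cidx][gidx] = _add_symbols(bin_genes[cidx][gidx], [marker])
        truth.markers_by_bin[bt.bin_id] = sorted(bt.markers)
        truth.pathway_truth[bt.bin_id] = {
            pathway: (any if mode == "any" else all)(
                m in bt.markers for m in markers
            )
            for pathway, (mode, markers) in _PATHWAY_RULES.items()
        }

        # --- similarity hits for planted CAZyme proteins
        lineage = config.taxonomy_fixture[bt.source_taxon]
        species = lineage[-1][1]
        for contig_genes in bin_genes:
            for gene in contig_genes:
                if gene.gene_id not in planted:
                    continue
                n_hits = int(rng.integers(3, 9))
                best = rng.uniform(200.0, 800.0)
                for hidx in range(n_hits):
                    similarity_hits.append(
                        SimilarityHit(
                            protein_id=gene.gene_id,
                            subject_id=f"{gene.gene_id}_s{hidx + 1}",
                            bit_score=float(
                                np.round(best * rng.uniform(0.92, 1.0), 2)
                            ),
                            e_value=float(10 ** rng.uniform(-50.0, -10.0)),
                            lineage=lineage,
                        )
                    )
                if rng.random() < config.off_taxon_hit_rate:
                    other = leaves[int(rng.integers(len(leaves)))]
                    if other != bt.source_taxon:
                        similarity_hits.append(
                            SimilarityHit(
                                protein_id=gene.gene_id,
                                subject_id=f"{gene.gene_id}_off",
                                bit_score=float(
                                    np.round(best * rng.uniform(0.5, 0.8), 2)
                                ),
                                e_value=float(10 ** rng.uniform(-20.0, -4.0)),
                                lineage=config.taxonomy_fixture[other],
                            )
                        )
                truth.taxon_by_protein[gene.gene_id] = species

        # --- finalize contigs, QC and reads
        for cidx, contig_genes in enumerate(bin_genes):
            _finish_contig(contig_genes[0].contig_id, contig_genes, bt.bin_id)
            genes.extend(contig_genes)
        size_bp = sum(
            contigs[f"{bt.bin_id}_c{c + 1:02d}"].length_bp for c in range(n_contigs)
        )
        gc_percent = 100.0 * float(
            np.mean(
                [
                    contigs[f"{bt.bin_id}_c{c + 1:02d}"].gc_fraction
                    for c in range(n_contigs)
                ]
            )
        )
        bin_qc.append(
            BinQcRecord(
                bin_id=bt.bin_id,
                size_bp=size_bp,
                gc_percent=round(gc_percent, 2),
                n_contigs=n_contigs,
                completeness=round(float(rng.uniform(75.0, 99.5)), 2),
                contamination=round(float(rng.uniform(0.0, 8.0)), 2),
                strain_heterogeneity=round(float(rng.uniform(0.0, 50.0)), 2),
                taxonomy_label=bt.phylum,
            )
        )
        read_counts[bt.bin_id] = int(size_bp * rng.uniform(0.05, 0.2))

    # --- unbinned background contigs
    for uidx in range(config.n_unbinned_contigs):
        contig_id = f"unbinned_c{uidx + 1:02d}"
        n_genes = int(rng.integers(*config.genes_per_contig, endpoint=True))
        contig_genes = _build_contig(contig_id, n_genes)
        for fam in ("GH13", "GT2"):
            gidx = int(rng.integers(len(contig_genes)))
            gene = contig_genes[gidx]
            if gene.gene_id not in planted:
                _plant(gene, [fam])
        _finish_contig(contig_id, contig_genes, None)
        genes.extend(contig_genes)

    # --- decoy hits, constructed to fail the filtering cascade
    if config.noise.decoy_rate > 0:
        lo_e, hi_e = config.noise.decoy_evalue_range
        for gene in genes:
            if rng.random() >= config.noise.decoy_rate:
                continue
            fam = catalog[int(rng.integers(len(catalog)))]
            aa = gene.protein_length_aa
            alen = int(rng.integers(30, max(31, aa // 2)))
            start = int(rng.integers(1, max(2, aa - alen)))
            low_cov = rng.random() < config.noise.decoy_low_coverage_fraction
            hmm_length = alen * 8 if low_cov else max(alen, int(alen / 0.8))
            domain_hits.append(
                DomainHit(
                    protein_id=gene.gene_id,
                    family_id=fam,
                    e_value=float(rng.uniform(lo_e, hi_e)),
                    bit_score=float(np.round(rng.uniform(5.0, 25.0), 1)),
                    ali_start=start,
                    ali_end=start + alen - 1,
                    model_coverage=alen / hmm_length,
                    hmm_start=1,
                    hmm_end=alen,
                    hmm_length=hmm_length,
                )
            )

    # --- ground-truth tallies
    gene_bin = {g.gene_id: bin_map.get(g.contig_id, "unassigned") for g in genes}
    hit_key: Dict[str, Tuple[float, float, str]] = {}
    for h in domain_hits:
        if h.protein_id not in planted:
            continue
        if h.e_value > 1e-5:  # decoys never define the primary class
            continue
        key = (h.e_value, -h.bit_score, h.family_id)
        if h.protein_id not in hit_key or key < hit_key[h.protein_id]:
            hit_key[h.protein_id] = key
    for pid in sorted(planted):
        fams = planted[pid]
        truth.families_by_protein[pid] = sorted(fams)
        primary = family_class(hit_key[pid][2])
        truth.primary_class_by_protein[pid] = primary
        b = gene_bin[pid]
        truth.class_counts_by_bin.setdefault(b, {})
        truth.class_counts_by_bin[b][primary] = (
            truth.class_counts_by_bin[b].get(primary, 0) + 1
        )
        truth.overall_class_counts[primary] = (
            truth.overall_class_counts.get(primary, 0) + 1
        )
        truth.family_counts_by_bin.setdefault(b, {})
        for fam in sorted(set(fams)):
            truth.family_counts_by_bin[b][fam] = (
                truth.family_counts_by_bin[b].get(fam, 0) + 1
            )
            truth.overall_family_counts[fam] = (
                truth.overall_family_counts.get(fam, 0) + 1
            )

    total_reads = int(sum(read_counts.values()) * rng.uniform(1.2, 1.6))
    dataset = SyntheticDataset(
        contigs=contigs,
        sequences=sequences,
        genes=genes,
        domain_hits=domain_hits,
        bin_map=bin_map,
        bin_qc=bin_qc,
        similarity_hits=similarity_hits,
        read_counts=read_counts,
        total_reads=total_reads,
    )
    if outdir is not None:
        write_dataset(dataset, truth, outdir)
    return dataset, truth


def write_dataset(dataset: SyntheticDataset, truth: GroundTruth, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "contigs.fasta", "w") as fh:
        for contig_id in dataset.contigs:
            fh.write(f">{contig_id}\n")
            seq = dataset.sequences[contig_id]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    annotation_io.write_gene_calls(dataset.genes, out / "genes.gff")
    annotation_io.write_domain_hits(dataset.domain_hits, out / "domain_hits.tsv")
    annotation_io.write_bin_map(dataset.bin_map, out / "bin_map.tsv")
    annotation_io.write_bin_qc(dataset.bin_qc, out / "bin_qc.tsv")
    annotation_io.write_similarity_hits(
        dataset.similarity_hits, out / "similarity_hits.tsv"
    )
    annotation_io.write_read_counts(
        dataset.read_counts, dataset.total_reads, out / "read_counts.tsv"
    )
    truth.to_json(out / "ground_truth.json")


def null_profile_pair(
    seed_or_rng,
    m_families: int,
    depth_a: int,
    depth_b: int,
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Two family-count profiles drawn from one shared multinomial.

    Both draws use the same Dirichlet(1)-distributed proportions, so every
    per-family difference is sampling noise; used to calibrate the
    false-discovery behaviour of the profile comparison.
    """
    if m_families < 1:
        raise ValueError("m_families must be >= 1")
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("profile depths must be positive")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    props = rng.dirichlet(np.ones(m_families))
    counts_a = rng.multinomial(depth_a, props)
    counts_b = rng.multinomial(depth_b, props)
    names = [f"FAM{i + 1:04d}" for i in range(m_families)]
    return (
        dict(zip(names, counts_a.tolist())),
        dict(zip(names, counts_b.tolist())),
    )
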