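"""Readers and writers for the tabular and sequence inputs of the pipeline.

All coordinates are 1-based inclusive (GFF3 convention for genes, HMMER
convention for protein alignments).  Malformed rows in tabular inputs are
skipped and counted rather than fatal, so large real-world tables degrade
gracefully; every reader that can reject rows returns the number rejected
alongside the parsed records, and logs a warning per rejection.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import gc_fraction
from gffutils.feature import feature_from_line

from .families import FAMILY_CATALOG
from .model import (
    UNASSIGNED,
    BinQcRecord,
    ContigRecord,
    DomainHit,
    GeneRecord,
    SimilarityHit,
    gene_sort_key,
)

logger = logging.getLogger(__name__)

DOMAIN_HIT_COLUMNS = [
    "protein_id",
    "family_id",
    "e_value",
    "bit_score",
    "ali_start",
    "ali_end",
    "hmm_start",
    "hmm_end",
    "hmm_length",
]

SIMILARITY_HIT_COLUMNS = ["protein_id", "subject_id", "bit_score", "e_value", "lineage"]

BIN_QC_COLUMNS = [
    "bin_id",
    "size_bp",
    "gc_percent",
    "n_contigs",
    "completeness",
    "contamination",
    "strain_heterogeneity",
    "taxonomy_label",
]


def read_contigs(
    fasta_path, bin_map: Mapping[str, str] | None = None
) -> Dict[str, ContigRecord]:
    """Read contigs from FASTA; only id, length and GC are retained."""
    bin_map = bin_map or {}
    contigs: Dict[str, ContigRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r}")
        contigs[rec.id] = ContigRecord(
            contig_id=rec.id,
            length_bp=len(rec.seq),
            gc_fraction=gc_fraction(rec.seq) if len(rec.seq) else None,
            bin_id=bin_map.get(rec.id, UNASSIGNED),
        )
    return contigs


def _protein_length(start: int, end: int) -> int:
    # CDS length includes the stop codon; minimum 1 aa.
    return max(1, (end - start + 1) // 3 - 1)


def read_gene_calls(
    gff_path, contigs: Mapping[str, ContigRecord]
) -> Tuple[List[GeneRecord], int]:
    """Parse CDS features from a GFF3 file into gene records.

    Gene symbols come from the ``gene=`` attribute (split on commas and
    semicolons, lowercased); a gene is full length unless it carries a
    ``partial`` attribute other than ``00``.  Records with end < start are
    rejected and counted.  A CDS on a contig absent from ``contigs`` is an
    error, as is one extending past the contig end.

    Returns ``(genes, n_rejected)`` with ``rank_on_contig`` assigned per
    contig in (start, end, gene_id) order.
    """
    raw: List[GeneRecord] = []
    n_rejected = 0
    auto_id = 0
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed line
                logger.warning("rejected unparseable GFF line: %s", exc)
                n_rejected += 1
                continue
            if feat.featuretype != "CDS":
                continue
            if feat.end < feat.start:
                logger.warning(
                    "rejected CDS with end < start on %s (%d..%d)",
                    feat.seqid,
                    feat.start,
                    feat.end,
                )
                n_rejected += 1
                continue
            if feat.seqid not in contigs:
                raise ValueError(f"gene call references unknown contig {feat.seqid!r}")
            if feat.end > contigs[feat.seqid].length_bp:
                logger.warning(
                    "rejected CDS extending past end of contig %s", feat.seqid
                )
                n_rejected += 1
                continue
            attrs = feat.attributes
            gene_id = attrs["ID"][0] if "ID" in attrs else None
            if gene_id is None:
                auto_id += 1
                gene_id = f"{feat.seqid}_cds{auto_id}"
            symbols = set()
            for val in attrs.get("gene", []):
                for token in val.replace(";", ",").split(","):
                    token = token.strip().lower()
                    if token:
                        symbols.add(token)
            partial = attrs.get("partial", ["00"])[0]
            raw.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    rank_on_contig=0,
                    protein_length_aa=_protein_length(feat.start, feat.end),
                    gene_symbols=frozenset(symbols),
                    is_full_length=(partial == "00"),
                )
            )
    return assign_ranks(raw), n_rejected


def assign_ranks(genes: Iterable[GeneRecord]) -> List[GeneRecord]:
    """Re-assign ``rank_on_contig`` deterministically per contig."""
    by_contig: Dict[str, List[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_contig[g.contig_id].append(g)
    out: List[GeneRecord] = []
    for contig_id in sorted(by_contig):
        ordered = sorted(by_contig[contig_id], key=gene_sort_key)
        for rank, g in enumerate(ordered):
            out.append(
                GeneRecord(
                    gene_id=g.gene_id,
                    contig_id=g.contig_id,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    rank_on_contig=rank,
                    protein_length_aa=g.protein_length_aa,
                    gene_symbols=g.gene_symbols,
                    is_full_length=g.is_full_length,
                )
            )
    return out


def _read_table(path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a TSV with '#' metadata lines and an optional header row."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str, skip_blank_lines=True
    )
    if df.empty:
        return pd.DataFrame(columns=columns)
    first = [str(v) for v in df.iloc[0].tolist()]
    if first[: len(columns)] == list(columns) or first[0] == columns[0]:
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, : len(columns)]
    df.columns = list(columns)[: df.shape[1]]
    return df


def read_domain_hits(path) -> Tuple[List[DomainHit], int]:
    """Read an HMMER3 per-domain hit table (fixed column subset).

    ``model_coverage`` is computed as ``(hmm_end - hmm_start + 1) /
    hmm_length``.  Rows with non-numeric fields or a family identifier
    outside the catalog are rejected and counted.  An empty file yields an
    empty table.
    """
    try:
        df = _read_table(path, DOMAIN_HIT_COLUMNS)
    except pd.errors.EmptyDataError:
        return [], 0
    hits: List[DomainHit] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            family_id = str(row.family_id)
            if family_id not in FAMILY_CATALOG:
                raise ValueError(f"unknown family {family_id!r}")
            hmm_start = int(row.hmm_start)
            hmm_end = int(row.hmm_end)
            hmm_length = int(row.hmm_length)
            if hmm_length <= 0 or hmm_end < hmm_start:
                raise ValueError("invalid HMM coordinates")
            hits.append(
                DomainHit(
                    protein_id=str(row.protein_id),
                    family_id=family_id,
                    e_value=float(row.e_value),
                    bit_score=float(row.bit_score),
                    ali_start=int(row.ali_start),
                    ali_end=int(row.ali_end),
                    model_coverage=(hmm_end - hmm_start + 1) / hmm_length,
                    hmm_start=hmm_start,
                    hmm_end=hmm_end,
                    hmm_length=hmm_length,
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejected domain-hit row: %s", exc)
            n_rejected += 1
    return hits, n_rejected


def write_domain_hits(hits: Iterable[DomainHit], path, hmm_length: int = 1000) -> None:
    """Write hits in the tabular layout `read_domain_hits` consumes.

    Hits that carry HMM coordinates are written verbatim; otherwise the HMM
    span is reconstructed from ``model_coverage`` against a nominal model
    length.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(DOMAIN_HIT_COLUMNS) + "\n")
        for h in hits:
            if h.hmm_end is not None and h.hmm_length is not None:
                hstart, hend, hlen = h.hmm_start, h.hmm_end, h.hmm_length
            else:
                hstart, hend, hlen = 1, round(h.model_coverage * hmm_length), hmm_length
            fh.write(
                "\t".join(
                    [
                        h.protein_id,
                        h.family_id,
                        str(h.e_value),
                        str(h.bit_score),
                        str(h.ali_start),
                        str(h.ali_end),
                        str(hstart),
                        str(hend),
                        str(hlen),
                    ]
                )
                + "\n"
            )


def parse_lineage(text: str) -> Tuple[Tuple[str, str], ...]:
    """Parse ``rank:name`` tokens separated by semicolons."""
    pairs = []
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        rank, _, name = token.partition(":")
        pairs.append((rank.strip(), name.strip()))
    return tuple(pairs)


def format_lineage(lineage: Sequence[Tuple[str, str]]) -> str:
    return ";".join(f"{rank}:{name}" for rank, name in lineage)


def read_similarity_hits(
    path, max_targets: int = 20
) -> Tuple[Dict[str, List[SimilarityHit]], int]:
    """Read per-protein similarity hits with lineages, keyed by protein.

    At most ``max_targets`` hits are stored per protein (best bit score
    first); malformed rows are rejected and counted.
    """
    df = _read_table(path, SIMILARITY_HIT_COLUMNS)
    by_protein: Dict[str, List[SimilarityHit]] = defaultdict(list)
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            hit = SimilarityHit(
                protein_id=str(row.protein_id),
                subject_id=str(row.subject_id),
                bit_score=float(row.bit_score),
                e_value=float(row.e_value),
                lineage=parse_lineage(row.lineage),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejected similarity-hit row: %s", exc)
            n_rejected += 1
            continue
        by_protein[hit.protein_id].append(hit)
    for pid, hits in by_protein.items():
        hits.sort(key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
        del hits[max_targets:]
    return dict(by_protein), n_rejected


def write_similarity_hits(hits: Iterable[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SIMILARITY_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.protein_id,
                        h.subject_id,
                        str(h.bit_score),
                        str(h.e_value),
                        format_lineage(h.lineage),
                    ]
                )
                + "\n"
            )


def read_bin_map(path) -> Dict[str, str]:
    """Read contig_id -> bin_id membership table."""
    df = _read_table(path, ["contig_id", "bin_id"])
    return {str(r.contig_id): str(r.bin_id) for r in df.itertuples(index=False)}


def write_bin_map(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tbin_id\n")
        for contig_id, bin_id in mapping.items():
            fh.write(f"{contig_id}\t{bin_id}\n")


def read_bin_qc(path) -> List[BinQcRecord]:
    df = _read_table(path, BIN_QC_COLUMNS)
    records = []
    for r in df.itertuples(index=False):
        records.append(
            BinQcRecord(
                bin_id=str(r.bin_id),
                size_bp=int(r.size_bp),
                gc_percent=float(r.gc_percent),
                n_contigs=int(r.n_contigs),
                completeness=float(r.completeness),
                contamination=float(r.contamination),
                strain_heterogeneity=float(r.strain_heterogeneity),
                taxonomy_label=str(r.taxonomy_label),
            )
        )
    return records


def write_bin_qc(records: Iterable[BinQcRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BIN_QC_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.bin_id,
                        str(r.size_bp),
                        str(r.gc_percent),
                        str(r.n_contigs),
                        str(r.completeness),
                        str(r.contamination),
                        str(r.strain_heterogeneity),
                        r.taxonomy_label,
                    ]
                )
                + "\n"
            )


def read_read_counts(path) -> Tuple[Dict[str, int], int]:
    """Read per-bin mapped-read counts.

    Returns ``(counts, total_reads)``.  The library size is carried in a
    ``# total_reads=N`` metadata line; if absent, the sum of mapped counts
    is used.
    """
    total_reads = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "total_reads" in line:
                total_reads = int(line.split("=", 1)[1].strip())
    df = _read_table(path, ["bin_id", "mapped_reads"])
    counts = {str(r.bin_id): int(r.mapped_reads) for r in df.itertuples(index=False)}
    if total_reads is None:
        total_reads = sum(counts.values())
    return counts, total_reads


def write_read_counts(counts: Mapping[str, int], total_reads: int, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_reads={total_reads}\n")
        fh.write("bin_id\tmapped_reads\n")
        for bin_id, n in counts.items():
            fh.write(f"{bin_id}\t{n}\n")


def write_gene_calls(genes: Iterable[GeneRecord], path) -> None:
    """Write gene records as GFF3 CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.gene_symbols:
                attrs.append("gene=" + ",".join(sorted(g.gene_symbols)))
            attrs.append("partial=00" if g.is_full_length else "partial=10")
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "rumencaz",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
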