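import pytest

from rumencaz.model import CazymeAnnotation, DomainHit, GeneRecord
from rumencaz.simulate import NoiseModel, default_config, generate


def make_hit(
    protein_id="p1",
    family_id="GH5",
    e_value=1e-10,
    bit_score=100.0,
    ali_start=1,
    ali_end=150,
    model_coverage=0.9,
):
    return DomainHit(
        protein_id=protein_id,
        family_id=family_id,
        e_value=e_value,
        bit_score=bit_score,
        ali_start=ali_start,
        ali_end=ali_end,
        model_coverage=model_coverage,
    )


def make_contig_genes(contig_id, families, start_gene_index=0):
    """Lay out one gene per entry of ``families`` (family id or None) on a
    contig, returning (genes, annotations).  Annotation e-values decrease
    with position so ordering is deterministic."""
    genes, anns = [], []
    pos = 100
    for i, fam in enumerate(families):
        gid = f"{contig_id}_g{start_gene_index + i:03d}"
        genes.append(
            GeneRecord(
                gene_id=gid,
                contig_id=contig_id,
                start=pos,
                end=pos + 899,
                strand="+",
                rank_on_contig=start_gene_index + i,
                protein_length_aa=299,
            )
        )
        pos += 1000
        if fam is not None:
            fams = fam if isinstance(fam, list) else [fam]
            hits = [
                make_hit(gid, f, e_value=10 ** -(20 + j), ali_start=1 + 100 * j,
                         ali_end=90 + 100 * j)
                for j, f in enumerate(fams)
            ]
            anns.append(
                CazymeAnnotation(
                    protein_id=gid,
                    retained_hits=hits,
                    families=list(fams),
                    primary_class="none",
                )
            )
    return genes, anns


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free synthetic dataset under the default study structure."""
    return generate(default_config(seed=11))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same structure with decoy hits that must be filtered away."""
    cfg = default_config(seed=11, noise=NoiseModel(decoy_rate=0.2))
    return generate(cfg)
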