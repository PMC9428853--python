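import pytest

from glycofunnel.model import GlycoSite, ProteinRecord
from glycofunnel.pipeline import run_pipeline
from glycofunnel.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic cohort: 50 proteins x 3 sites, 10 decoys per QC
    class, 100 planted variants."""
    return generate_bundle(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return run_pipeline(
        proteome=bundle.proteome,
        site_tables=[bundle.site_rows],
        gene_disease=None,
        ortholog_sources=[
            {r.accession: r for r in recs}
            for recs in bundle.orthologs.values()
            if recs
        ],
        disorder_profiles=bundle.disorder,
        functional_regions=bundle.functional_regions,
    )


@pytest.fixture
def toy_protein():
    # S at position 172 flanked by P171/P173, matching the classic
    # beta-tubulin loop arrangement around its O-GlcNAc site
    seq = ["A"] * 200
    seq[170], seq[171], seq[172] = "P", "S", "P"
    return ProteinRecord(
        accession="TOY1",
        gene_symbol="TOY1",
        sequence="".join(seq),
        localization_terms=frozenset({"cytoplasm"}),
        id_dd_flag=True,
    )


@pytest.fixture
def toy_site():
    return GlycoSite(
        protein_accession="TOY1",
        position=172,
        residue="S",
        evidence_peptide="PSP",
        peptide_site_offset=2,
        source_studies=("study01",),
    )
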