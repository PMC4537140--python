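import pandas as pd
import pytest

import palmitome as pt


def small_config(seed: int = 7, **overrides) -> pt.SimulationConfig:
    defaults = dict(
        seed=seed,
        n_genes=300,
        n_background=1500,
        n_studies=15,
        planted_terms=((30, 4.0),),
        n_decoy_terms=10,
        decoy_term_size=20,
        disease_term_size=25,
        n_decoy_disease_terms=5,
        synaptic_list_size=120,
        background_holdout=10,
    )
    defaults.update(overrides)
    return pt.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim():
    """One small synthetic study suite shared across tests."""
    return pt.simulate(small_config())


@pytest.fixture(scope="session")
def sim_dir(sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    pt.write_simulation(sim, out)
    return out


@pytest.fixture()
def tiny_db():
    """Hand-built mapping database with reviewed/unreviewed duplicates."""
    frame = pd.DataFrame(
        [
            # entry_name, symbol, synonyms, full_name, entrez, reviewed, ensembl, refseq, gi
            ("SODC_HUMAN", "SOD1", "ALS1|HEL-S-44", "Superoxide dismutase [Cu-Zn]", 6647, True,
             "ENSG00000142168", "NP_000445", "4507149"),
            ("SODC_MOUSE", "Sod1", "Als1", "Superoxide dismutase [Cu-Zn]", 20655, True,
             "ENSMUSG00000022982", "NP_035564", "45597447"),
            ("Q99999_HUMAN", "SOD1", "", "Superoxide dismutase [Cu-Zn]", 6647, False, "", "", ""),
            ("NPC1_HUMAN", "NPC1", "", "NPC intracellular cholesterol transporter 1", 4864, True,
             "ENSG00000141458", "NP_000262", "255652944"),
            ("LGI1_RAT", "Lgi1", "Epr1", "Leucine-rich glioma-inactivated protein 1", 65127, True,
             "ENSRNOG00000019822", "NP_001100960", "157821697"),
            ("X11111_HUMAN", "ORPHAN1", "", "Unreviewed-only protein", 999, False, "", "", ""),
        ],
        columns=[
            "entry_name", "gene_symbol", "synonyms", "full_name", "entrez_id",
            "reviewed", "ensembl_gene", "refseq_accession", "ncbi_gi",
        ],
    )
    return pt.MappingDatabase(frame)
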