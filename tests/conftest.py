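import pandas as pd
import pytest

from denitscape.synthetic_data import SimulationConfig


GENOME_TSV = """\
genome_id\tassembly_type\tcompleteness\tcontamination\tgunc_pass\tphylum\tgenome_size\thas_nirK\thas_nirS\thas_nor\thas_nosZ\tnosZ_clade\tis_anammox\tis_archaeal_nitrifier
G1\tisolate\t95.0\t1.2\tTrue\tPseudomonadota\t5000000\tTrue\tFalse\tTrue\tTrue\tI\tFalse\tFalse
G2\tmag\t85.5\t3.0\tTrue\tBacteroidota\t3800000\tFalse\tFalse\tFalse\tTrue\tII\tFalse\tFalse
G3\tsag\t80.0\t5.0\tTrue\tActinomycetota\t4100000\tTrue\tFalse\tTrue\tFalse\tnone\tFalse\tFalse
"""


@pytest.fixture
def genome_tsv(tmp_path):
    path = tmp_path / "genomes.tsv"
    path.write_text(GENOME_TSV)
    return path


@pytest.fixture
def small_config():
    return SimulationConfig(seed=7, n_genomes=300, n_samples=20)


@pytest.fixture
def placement_frame():
    return pd.DataFrame(
        [
            {"read_id": "r1", "gene_family": "nosZ", "clade": "nosZ_II", "mass": 0.97},
            {"read_id": "r1", "gene_family": "nosZ", "clade": "nosZ_I", "mass": 0.03},
            {"read_id": "r2", "gene_family": "nosZ", "clade": "nosZ_I", "mass": 0.99},
            {"read_id": "r2", "gene_family": "nosZ", "clade": "outgroup", "mass": 0.01},
            {"read_id": "r3", "gene_family": "nirK", "clade": "NirK_2", "mass": 1.0},
            {"read_id": "r4", "gene_family": "nirK", "clade": "NirK_1a", "mass": 0.96},
            {"read_id": "r4", "gene_family": "nirK", "clade": "NirK_3", "mass": 0.04},
            {"read_id": "r5", "gene_family": "nirS", "clade": "nirS", "mass": 0.90},
            {"read_id": "r5", "gene_family": "nirS", "clade": "NirS_1h", "mass": 0.10},
        ]
    )
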