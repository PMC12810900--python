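import numpy as np
import pandas as pd
import pytest

from metaconsensus.profiles import TaxonProfile

METAPHLAN_TABLE = """\
#mpa_vJan21_test
clade_name\tsampleA\tsampleB
k__Bacteria\t100.0\t100.0
k__Bacteria|p__Firmicutes\t60.0\t55.0
k__Bacteria|p__Bacteroidota\t40.0\t45.0
k__Bacteria|p__Firmicutes|g__Blautia\t60.0\t55.0
k__Bacteria|p__Firmicutes|g__Blautia|s__Blautia_wexlerae\t60.0\t40.0
k__Bacteria|p__Bacteroidota|g__Bacteroides|s__Bacteroides_fragilis\t40.0\t60.0
"""

METAPHLAN_WITH_SGB = """\
clade_name\tsampleA
k__Bacteria|s__Blautia_wexlerae\t50.0
k__Bacteria|s__GGB9342_SGB14341\t30.0
k__Bacteria|s__Bacteroides_fragilis\t20.0
"""

BRACKEN_S1 = """\
name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads\tadded_reads\tnew_est_reads\tfraction_total_reads
Blautia wexlerae\t1796616\tS\t900\t100\t1000\t0.58
Bacteroides fragilis\t817\tS\t350\t50\t400\t0.40
"""

BRACKEN_S2 = """\
name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads\tadded_reads\tnew_est_reads\tfraction_total_reads
Blautia wexlerae\t1796616\tS\t500\t0\t500\t0.70
Faecalibacterium prausnitzii\t853\tS\t200\t100\t300\t0.28
"""


@pytest.fixture
def metaphlan_file(tmp_path):
    path = tmp_path / "merged_abundance.tsv"
    path.write_text(METAPHLAN_TABLE)
    return path


@pytest.fixture
def bracken_files(tmp_path):
    p1 = tmp_path / "s1.bracken"
    p2 = tmp_path / "s2.bracken"
    p1.write_text(BRACKEN_S1)
    p2.write_text(BRACKEN_S2)
    return [p1, p2]


def make_profile(matrix, taxa=None, samples=None, label="test", level="species",
                 taxids=None):
    matrix = np.asarray(matrix, dtype=float)
    taxa = taxa or [f"taxon_{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"S{j}" for j in range(matrix.shape[1])]
    data = pd.DataFrame(matrix, index=taxa, columns=samples)
    return TaxonProfile(classifier_label=label, level=level, data=data,
                        taxids=taxids or {})


@pytest.fixture
def simple_pair():
    """Two 4-sample profiles sharing 2 of 3 taxa each."""
    a = make_profile(
        [[0.5, 0.6, 0.4, 0.5], [0.3, 0.2, 0.4, 0.3], [0.2, 0.2, 0.2, 0.2]],
        taxa=["Blautia wexlerae", "Bacteroides fragilis", "Roseburia hominis"],
        label="marker",
    )
    b = make_profile(
        [[0.45, 0.55, 0.5, 0.4], [0.35, 0.25, 0.3, 0.4], [0.2, 0.2, 0.2, 0.2]],
        taxa=["Blautia_wexlerae", "Bacteroides_fragilis", "Dialister invisus"],
        label="kmer",
    )
    return a, b
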