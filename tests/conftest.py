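import numpy as np
import pytest

import nanoqstr as nq

# The 10 exposure rows printed in the study's dataset excerpt: one plain
# ZnO ENM over six doses (hormetic rise then crash) and one Na-doped ZnO
# ENM over four doses.
TABLE1_CSV = """\
ENM_ID,Core,Doping,Surface_Coating,Diameter_nm,Concentration_ug_mL,Cell_Viability_pct
ENM-01,ZnO,ND,NSC,68.90,0.01,100.00
ENM-01,ZnO,ND,NSC,68.90,1.56,104.79
ENM-01,ZnO,ND,NSC,68.90,3.13,109.64
ENM-01,ZnO,ND,NSC,68.90,6.25,112.06
ENM-01,ZnO,ND,NSC,68.90,12.50,120.16
ENM-01,ZnO,ND,NSC,68.90,25.00,47.35
ENM-02,ZnO,Na (1.5%),NSC,5.50,0.01,100.00
ENM-02,ZnO,Na (1.5%),NSC,5.50,6.25,94.61
ENM-02,ZnO,Na (1.5%),NSC,5.50,12.50,93.56
ENM-02,ZnO,Na (1.5%),NSC,5.50,25.00,93.57
"""


@pytest.fixture
def table1_csv(tmp_path):
    path = tmp_path / "table1.csv"
    path.write_text(TABLE1_CSV, encoding="utf-8")
    return path


@pytest.fixture
def table1_dataset(table1_csv):
    return nq.read_dataset(table1_csv)


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale synthetic exposure table (377 rows, 16 ENMs)."""
    return nq.generate_dataset(nq.study_config(seed=0))


@pytest.fixture(scope="session")
def modelling_dataset(study_dataset):
    """The sub-200-nm modelling subset (333 rows, 11 ENMs)."""
    return nq.filter_by_diameter(study_dataset).dataset


@pytest.fixture(scope="session")
def modelling_features(modelling_dataset):
    matrix, encoder = nq.build_feature_matrix(modelling_dataset)
    return matrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """A tiny descriptor matrix for filter/transform unit tests."""
    import pandas as pd
    from nanoqstr.descriptors import DescriptorMatrix

    frame = pd.DataFrame(
        {
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [2.0, 4.0, 6.0, 8.0],   # = 2*a, perfectly correlated
            "c": [5.0, 5.0, 5.0, 5.0],   # constant
            "d": [0.0, 1.0, 0.0, 1.0],
        }
    )
    return DescriptorMatrix(
        frame=frame, provenance={"a": "raw", "b": "raw", "c": "raw", "d": "onehot"}
    )
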