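import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracle.py

import ipsipanel as ip

TABLE_CSV = """\
ID,Gender,Race,Age,Income,L_1,X_1,Y_1,L_2,X_2,Y_2,L_3,X_3,Y_3
8,1,1,1,1,1.12,1,1.40,0.26,1,1.40,-1.37,1,1.20
16,0,0,0,1,0.46,1,1.00,1.51,1,1.20,0.38,1,1.00
24,1,1,0,1,-1.21,0,1.00,0.76,0,1.60,-1.12,1,3.40
32,0,0,0,1,-0.54,1,1.00,-0.74,1,1.40,0.30,1,1.80
40,0,1,1,1,0.04,1,1.40,0.76,1,3.20,-0.37,1,1.60
48,1,1,0,0,0.54,1,3.20,-1.24,1,1.20,0.63,1,3.20
"""

STUDENT_SCHEMA = {
    "id": "ID", "T": 3,
    "C": ["Gender", "Race", "Age", "Income"],
    "L": "L", "X": "X", "Y": "Y",
}


@pytest.fixture
def student_csv(tmp_path):
    path = tmp_path / "students.csv"
    path.write_text(TABLE_CSV)
    return path


@pytest.fixture
def student_schema():
    return dict(STUDENT_SCHEMA)


@pytest.fixture
def student_panel(student_csv, student_schema):
    return ip.load_panel(student_csv, student_schema)


@pytest.fixture(scope="session")
def discrete_cfg():
    return ip.discrete_config(n=3000, seed=7)


@pytest.fixture(scope="session")
def discrete_panel(discrete_cfg):
    return ip.generate_panel(discrete_cfg)


@pytest.fixture(scope="session")
def discrete_fits(discrete_panel):
    ps = [ip.fit_propensity(discrete_panel, t) for t in (1, 2)]
    system = ip.fit_outcome_system(discrete_panel)
    return ps, system


def make_panel_with_pi(pi_values, seed=0):
    """Tiny synthetic fit object with prescribed fitted propensities."""
    from ipsipanel.design import LinearDesign
    pi = np.asarray(pi_values, dtype=float)
    return ip.PropensityFit(t=1, design=LinearDesign([]), coef=np.zeros(1),
                            se=np.zeros(1), fitted_pi=pi)
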