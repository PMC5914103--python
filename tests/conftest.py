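import numpy as np
import pytest

from rotimb import SyntheticSpec, gen_gaussian


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def imbalanced_ds():
    """20 abnormal / 200 normal, 6 features, moderately overlapping classes."""
    return gen_gaussian(SyntheticSpec(20, 200, 6, separation=2.0, seed=7))


@pytest.fixture
def small_ds():
    """15 abnormal / 60 normal, 4 features — quick to fit."""
    return gen_gaussian(SyntheticSpec(15, 60, 4, separation=2.0, seed=3))


@pytest.fixture
def csv_file(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "x1,x2,outcome\n"
        "1.0,2.0,pos\n"
        "2.0,1.0,neg\n"
        "3.5,0.5,neg\n"
        "0.5,3.0,pos\n"
    )
    return path


@pytest.fixture
def arff_file(tmp_path):
    path = tmp_path / "toy.arff"
    path.write_text(
        "@relation toy\n"
        "@attribute x1 numeric\n"
        "@attribute x2 numeric\n"
        "@attribute class {pos,neg}\n"
        "@data\n"
        "1.0,2.0,pos\n"
        "2.0,1.0,neg\n"
        "3.0,0.0,neg\n"
    )
    return path


@pytest.fixture
def arff_nominal_file(tmp_path):
    path = tmp_path / "nominal.arff"
    path.write_text(
        "@relation nom\n"
        "@attribute x1 numeric\n"
        "@attribute color {red,green,blue}\n"
        "@attribute class {pos,neg}\n"
        "@data\n"
        "1.0,red,pos\n"
        "?,green,neg\n"
        "3.0,?,neg\n"
        "4.0,blue,pos\n"
    )
    return path
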