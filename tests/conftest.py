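import numpy as np
import pytest

from lipidtraffic.signal_sheet import FeatureRecord, SampleMeta, SignalSheet
from lipidtraffic.traffic import CompartmentNetwork


def feat(fid, mz=500.0, rt=5.0, annotation="", lipid_class=""):
    return FeatureRecord(fid, mz, rt, annotation, lipid_class)


def analytical(sid, compartment="liver", phenotype="F", replicate=1):
    return SampleMeta(sid, "analytical", compartment, phenotype, replicate=replicate)


def blank(sid, replicate=1):
    return SampleMeta(sid, "blank", replicate=replicate)


def qc(sid, stock="stock1", level=1.0, replicate=1):
    return SampleMeta(sid, "qc", qc_stock=stock, qc_level=level, replicate=replicate)


def make_sheet(features, samples, matrix):
    return SignalSheet(list(features), list(samples), np.asarray(matrix, dtype=float))


@pytest.fixture
def path_network():
    """Three-compartment path L - S - B: (L,B) is the only non-adjacent pair."""
    return CompartmentNetwork.from_edges(["L", "S", "B"], [("L", "S"), ("S", "B")])


@pytest.fixture
def tiny_sheet():
    """3 features x 4 samples: two analytical compartments, one blank, one QC."""
    features = [feat("f1", 500.0, 2.0), feat("f2", 600.0, 3.0), feat("f3", 700.0, 4.0)]
    samples = [
        analytical("a1", "liver"),
        analytical("a2", "brain"),
        blank("b1"),
        qc("q1"),
    ]
    matrix = [
        [100.0, 200.0, 1.0, 50.0],
        [200.0, 0.0, 2.0, 60.0],
        [300.0, 400.0, 3.0, 70.0],
    ]
    return make_sheet(features, samples, matrix)
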