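import numpy as np
import pandas as pd
import pytest

from protasca.io import SampleDesign, SpectralCountTable

TIME_POINTS = (21, 23, 25, 27, 29, 31)
TEMPS = (23.0, 29.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def tiny_counts():
    """3 proteins x 2 samples with lengths, hand-checkable."""
    counts = pd.DataFrame(
        {"s1": [10, 20, 40], "s2": [5, 0, 5]},
        index=pd.Index(["pA", "pB", "pC"], name="protein_id"))
    lengths = pd.Series([100, 200, 400], index=counts.index)
    return SpectralCountTable(counts=counts, lengths=lengths)


def make_biological_design():
    """6 time x 2 temperature, one (averaged) sample per cell."""
    rows = []
    for t in TIME_POINTS:
        for g in TEMPS:
            rows.append({"sample_id": f"T{t}_{int(g)}C", "time_dpf": t,
                         "temperature_c": g, "replicate_id": "avg"})
    return SampleDesign(pd.DataFrame(rows))


def make_replicate_design():
    """6 x 2 with technical duplicates (24 runs)."""
    rows = []
    for t in TIME_POINTS:
        for g in TEMPS:
            for rep in ("A", "B"):
                rows.append({"sample_id": f"T{t}_{int(g)}C_{rep}",
                             "time_dpf": t, "temperature_c": g,
                             "replicate_id": rep})
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def bio_design():
    return make_biological_design()


@pytest.fixture
def replicate_design():
    return make_replicate_design()


SMALL_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: branch A
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: branch B
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000004
name: leaf under A (chain of two ancestors)
namespace: biological_process
is_a: GO:0000002 ! branch A

[Term]
id: GO:0000005
name: leaf under both branches
namespace: biological_process
is_a: GO:0000002 ! branch A
relationship: part_of GO:0000003 ! branch B

[Term]
id: GO:0000007
name: gone
namespace: biological_process
is_obsolete: true

[Term]
id: GO:0000008
name: binding
namespace: molecular_function
"""


@pytest.fixture
def small_obo(tmp_path):
    p = tmp_path / "small.obo"
    p.write_text(SMALL_OBO)
    return p


def write_annotations(tmp_path, mapping):
    lines = ["protein_id\tgo_terms"]
    for pid, terms in mapping.items():
        lines.append(f"{pid}\t{';'.join(terms)}")
    p = tmp_path / "annotations.tsv"
    p.write_text("\n".join(lines) + "\n")
    return p
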