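import numpy as np
import pandas as pd
import pytest

from lcmsvar.datamodel import ExpressionMatrix, SampleMetadata
from lcmsvar.simulate import SimulationDesign, generate


def make_matrix(values, scale_tag="raw", feature_ids=None, sample_ids=None, protein_ids=None):
    """Build an ExpressionMatrix from a plain 2-D array."""
    arr = np.asarray(values, dtype=float)
    features = feature_ids or [f"F{i}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"S{j}" for j in range(arr.shape[1])]
    frame = pd.DataFrame(arr, index=features, columns=samples)
    prot = None if protein_ids is None else pd.Series(protein_ids, index=frame.index)
    return ExpressionMatrix(values=frame, scale_tag=scale_tag, protein_ids=prot)


def make_metadata(sample_ids, categorical=None, continuous=None, norm_imp_group=None):
    """Build SampleMetadata from per-variable value lists."""
    cols = {}
    cols.update(categorical or {})
    cols.update(continuous or {})
    table = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample"))
    group = None
    if norm_imp_group is not None:
        group = pd.Series(norm_imp_group, index=table.index)
    return SampleMetadata(
        table=table,
        categorical_vars=list((categorical or {}).keys()),
        continuous_vars=list((continuous or {}).keys()),
        norm_imp_group=group,
    )


@pytest.fixture(scope="session")
def demo_data():
    """One draw of the default demonstration design (1000 peptides, 36 samples)."""
    return generate(SimulationDesign(seed=11))


@pytest.fixture(scope="session")
def demo_fixture_dir(demo_data, tmp_path_factory):
    from lcmsvar.simulate import write_fixture

    outdir = tmp_path_factory.mktemp("demo_fixture")
    return write_fixture(demo_data, outdir)
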