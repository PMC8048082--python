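import numpy as np
import pandas as pd
import pytest

from mtqsarx.dataset import (DatasetSchema, MTQSARDataset, SyntheticSpec,
                             generate_synthetic)


@pytest.fixture
def tiny_schema():
    return DatasetSchema(
        id_col="id", response_col="class",
        condition_cols=("c1", "c2"),
        descriptor_cols=("D1", "D2", "D3"),
    )


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "tiny.csv"
    path.write_text(
        "id,class,c1,c2,D1,D2,D3\n"
        "a,1,x,u,0.1,1.0,5\n"
        "b,-1,x,v,0.2,2.0,4\n"
        "c,1,y,u,0.3,3.0,3\n"
        "d,-1,y,v,0.4,4.0,2\n"
        "e,1,x,u,0.5,5.0,1\n"
    )
    return path


@pytest.fixture
def synthetic_ds():
    spec = SyntheticSpec(n_rows=300, n_descriptors=5,
                         condition_cardinalities=(3, 2),
                         active_fraction=0.6, effect_size=1.5,
                         noise_sd=1.0, seed=7)
    return generate_synthetic(spec)


def make_dataset(descriptors, response, conditions, ids=None, p_user=None,
                 set_tag=None):
    """Hand-rolled dataset builder for oracle fixtures."""
    desc = pd.DataFrame(descriptors)
    n = len(desc)
    ids = ids or [f"r{i}" for i in range(n)]
    desc.index = ids
    cond = pd.DataFrame(conditions, index=ids).astype(str)
    return MTQSARDataset(
        ids=ids,
        response=pd.Series(list(response), index=ids),
        conditions=cond,
        descriptors=desc.astype(float),
        p_user=None if p_user is None else pd.Series(list(p_user), index=ids, dtype=float),
        set_tag=None if set_tag is None else pd.Series(list(set_tag), index=ids),
    )
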