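import numpy as np
import pandas as pd
import pytest

from lncforge.matrix import ExpressionMatrix
from lncforge.simulate import SimulationConfig, write_bundle


def make_matrix(values, flags=None, n_g1=None):
    """Small ExpressionMatrix from a 2-D array; first half of columns group1."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    n_g1 = n_g1 if n_g1 is not None else n_samples // 2
    probes = [f"P{i+1:03d}" for i in range(n_probes)]
    samples = [f"S{j+1:02d}" for j in range(n_samples)]
    groups = pd.Series(
        ["group1"] * n_g1 + ["group2"] * (n_samples - n_g1),
        index=samples, name="group",
    )
    fl = None
    if flags is not None:
        fl = pd.DataFrame(np.asarray(flags, dtype=object), index=probes,
                          columns=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        groups=groups, flags=fl,
    )


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One seeded synthetic input bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle") / "b"
    config = SimulationConfig(seed=7)
    gt = write_bundle(config, outdir)
    return {"dir": outdir, "config": config, "truth": gt}
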