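import numpy as np
import pandas as pd
import pytest

from egwas_meta import ExperimentMatrix, PlatformSpec, SimulationConfig, generate_collection


def make_matrix(control_rows, case_rows, probe_ids=None, **kwargs):
    """Build an ExperimentMatrix from per-probe (control values, case values)."""
    values = np.hstack([np.asarray(control_rows, dtype=float), np.asarray(case_rows, dtype=float)])
    n_ctrl = np.asarray(control_rows).shape[1]
    n_case = np.asarray(case_rows).shape[1]
    groups = np.array(["control"] * n_ctrl + ["case"] * n_case, dtype=object)
    if probe_ids is None:
        probe_ids = [f"probe{i + 1}" for i in range(values.shape[0])]
    return ExperimentMatrix(probe_ids=probe_ids, values=values, groups=groups, **kwargs)


@pytest.fixture
def null_matrix_3v3():
    """Pure-noise 3 vs 3 experiment, 200 probes."""
    rng = np.random.default_rng(7)
    values = rng.normal(8.0, 0.5, size=(200, 6))
    return ExperimentMatrix(
        probe_ids=[f"p{i}" for i in range(200)],
        values=values,
        groups=np.array(["control"] * 3 + ["case"] * 3, dtype=object),
    )


@pytest.fixture
def small_collection():
    """4 experiments on 2 platforms, 100 genes, 5 planted at strong effect."""
    config = SimulationConfig(
        n_experiments=4,
        platforms=[
            PlatformSpec(n_probes=120, fraction_multiprobe_genes=0.1, fraction_unannotated_probes=0.05),
            PlatformSpec(n_probes=110, fraction_multiprobe_genes=0.0, fraction_unannotated_probes=0.0),
        ],
        n_genes=100,
        n_planted=5,
        effect_log2fc=2.0,
        sigma_within=0.5,
        n_per_group=3,
        seed=11,
    )
    return generate_collection(config), config


@pytest.fixture
def toy_annotations():
    def table(platform, rows):
        return pd.DataFrame(
            [(platform, p, s, sp, ch, pos) for (p, s, sp, ch, pos) in rows],
            columns=["platform", "probe", "symbol", "species", "chromosome", "position"],
        )

    mouse = table(
        "M1",
        [
            ("m1", "Clec4e", "mouse", "6", 123000),
            ("m2", "Il6", "mouse", "5", 30000000),
            ("m3", "Actb", "mouse", "5", 142000000),
            ("m4", "", "mouse", None, None),
        ],
    )
    human = table(
        "H1",
        [
            ("h1", "CLEC4E", "human", "12", 8600000),
            ("h2", "IL6", "human", "7", 22700000),
            ("h3", "PAI1", "human", "7", 101100000),
        ],
    )
    return [mouse, human]
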