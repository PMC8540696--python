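import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gencore as gc
from gencore.types import CandidateGEN, ExpressionMatrix, Node

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """Tiny, fast simulated world used across unit tests."""
    return gc.SimulationConfig(
        n_receptor=4, n_protein=12, n_tf=5, n_mirna=4, n_lncrna=4,
        n_samples=60, noise_sd=0.02, decoy_rate=0.5, basal_shift=1.5,
        epi_fraction=0.25, seed=11,
    )


@pytest.fixture
def small_gt(small_config):
    return gc.generate_ground_truth(small_config)


def make_regulatory_problem(seed, n=50, k_true=2, k_noise=2, noise_sd=0.05,
                            with_mirna=False):
    """One gene-model regression with known true regulators plus noise decoys."""
    rng = np.random.default_rng(seed)
    regs = [f"tf{j}" for j in range(k_true + k_noise)]
    kinds = ["TF"] * len(regs)
    if with_mirna:
        regs.append("mi0")
        kinds.append("miRNA")
    nodes = [Node("g", "receptor")] + [Node(r, kd) for r, kd in zip(regs, kinds)]
    gen = CandidateGEN(nodes, reg_edges=[(r, "g") for r in regs])
    X = {r: rng.lognormal(0, 0.5, n) for r in regs}
    theta_true = {}
    y = np.full(n, 1.0)
    for j in range(k_true):
        a = rng.uniform(0.3, 1.0) * (1 if rng.random() < 0.5 else -1)
        theta_true[regs[j]] = a
        y = y + a * X[regs[j]]
    if with_mirna:
        d = rng.uniform(0.3, 1.0)
        theta_true["mi0"] = -d
        y = y - d * X["mi0"]
    y = y + rng.normal(0, noise_sd, n)
    expr = ExpressionMatrix(
        ["g"] + regs, [f"s{i}" for i in range(n)],
        np.vstack([y] + [X[r] for r in regs]),
    )
    problem = gc.build_gene_regression("g", gen, expr, expr.sample_ids)
    return problem, theta_true
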