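import numpy as np
import pytest

from bnts.learn import LearnConfig, learn
from bnts.pkn import PKN
from bnts.synthetic import (
    SimConfig,
    default_perturbations,
    generate_pkn,
    sample_true_bn,
    simulate,
)
from bnts.timeseries import PerturbationDataset, normalize, qc_repair


@pytest.fixture(scope="session")
def noise_free_study():
    """Zero-noise default-shape study: truth, data and learned family."""
    cfg = SimConfig(seed=1, noise_sd=0.0)
    pkn = generate_pkn(cfg)
    truth = sample_true_bn(pkn, cfg)
    perts = default_perturbations(pkn, cfg.n_perturbations, cfg.seed)
    dataset, hidden = simulate(truth, pkn, perts, cfg)
    clean, report = qc_repair(dataset)
    norm = normalize(clean)
    output = learn(pkn, norm, LearnConfig(max_models=5))
    return {
        "cfg": cfg,
        "pkn": pkn,
        "truth": truth,
        "hidden": hidden,
        "raw": dataset,
        "norm": norm,
        "output": output,
    }


@pytest.fixture()
def tiny_pkn():
    """One stimulus activating one readout."""
    return PKN(
        frozenset({"s", "r"}),
        frozenset({("s", "r", 1)}),
        {"s": "stimulus", "r": "readout"},
    )


@pytest.fixture()
def tiny_dataset():
    """s=1 perturbation; r rises 0.1 -> 0.9 over two timepoints."""
    return PerturbationDataset(
        ("r",), (0, 5), ({"s": 1},), (np.array([[0.1], [0.9]]),), ("s",), ()
    )


@pytest.fixture()
def fp_gap_instance():
    """Frozen instance where the over-approximation admits an unreachable pair.

    For f_a = a AND b, f_b = NOT a the pair x=(1,0) -> y=(1,1) is
    support-consistent (widen a, then b, condition (c) on a) yet exactly
    unreachable: the only trajectory is (1,0) -> (0,0) -> (0,1), a fixpoint.
    """
    pkn = PKN(
        frozenset({"a", "b"}),
        frozenset({("a", "a", 1), ("b", "a", 1), ("a", "b", -1)}),
        {"a": "readout", "b": "readout"},
    )
    dataset = PerturbationDataset(
        ("a", "b"),
        (0, 5),
        ({},),
        (np.array([[0.9, 0.1], [0.9, 0.9]]),),
        (),
        (),
    )
    return pkn, dataset
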