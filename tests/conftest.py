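"""Shared fixtures.

The expensive Langevin runs (30-mer thermostat run, 100-mer ideal chain,
harmonic dimer) and the surrogate training run are session-scoped so the
physics tests and the acceptance checks share one computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from idrpipe import ensembles, forcefield, libdesign, simulate, surrogate


@pytest.fixture(scope="session")
def params():
    return forcefield.builtin_parameter_set()


@pytest.fixture(scope="session")
def chain30_traj(params):
    """Desk-preset production run of a designed 30-mer (full nonbonded)."""
    seq = libdesign.design_by_composition({"K": 0.1, "E": 0.1, "Y": 0.1}, 30,
                                          seed=42, record_id="chain30")
    coords = simulate.build_initial_coil(seq, params, seed=1)
    coords = simulate.minimize(coords, seq, params)
    cfg = simulate.desk_config(seed=3)
    return simulate.run_langevin(coords, seq, params, cfg)


@pytest.fixture(scope="session")
def ideal100_traj(params):
    """Desk-preset run of a 100-mer with nonbonded terms zeroed (ideal chain)."""
    seq = libdesign.design_by_composition({}, 100, seed=7, record_id="ideal100")
    coords = simulate.build_initial_coil(seq, params, seed=2)
    cfg = simulate.desk_config(seed=5, nonbonded=False)
    return simulate.run_langevin(coords, seq, params, cfg)


@pytest.fixture(scope="session")
def dimer_traj(params):
    """Desk-length run of a two-bead (G-S) harmonic dimer."""
    from idrpipe.seqfeatures import SequenceRecord

    seq = SequenceRecord("dimer", "GS")
    coords = np.array([[0.0, 0.0, 0.0], [params.bond.r0, 0.0, 0.0]])
    cfg = simulate.desk_config(seed=11)
    return simulate.run_langevin(coords, seq, params, cfg)


@pytest.fixture(scope="session")
def surrogate_run():
    """Train the recurrent regressor on a closed-form composition label
    (label = 10 + 30 * tyrosine fraction over designed 50-mers) and
    evaluate on the held-out test partition."""
    rng = np.random.default_rng(0)
    data = []
    for i in range(500):
        fy = rng.uniform(0, 0.5)
        rec = libdesign.design_by_composition({"Y": fy}, 50, seed=1000 + i,
                                              record_id=f"s{i}")
        data.append((rec.seq, 10.0 + 30.0 * rec.seq.count("Y") / 50.0))
    cfg = surrogate.TrainingConfig(learning_rate=0.01, hidden_layers=1,
                                   hidden_dim=16, batch_size=16, seed=0)
    parts = surrogate.split_and_fold(data, seed=0)
    trainval = [data[i] for i in np.concatenate([parts["train"], parts["val"]])]
    test = [data[i] for i in parts["test"]]
    model = surrogate.train_regressor(trainval, cfg, epochs=150)
    r2, rmse, _ = surrogate.evaluate(model, test)
    return {"model": model, "test": test, "r2": r2, "rmse": rmse,
            "parts": parts, "n": len(data)}
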