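import numpy as np
import pytest

from mrmediate import MRInput, SimulationConfig, simulate_summary_stats


def make_mr_input(bx, by, sy, sx=None, ids=None) -> MRInput:
    bx = np.asarray(bx, dtype=float)
    return MRInput(
        variant_ids=ids or [f"v{i}" for i in range(len(bx))],
        bx=bx,
        sx=np.zeros_like(bx) if sx is None else np.asarray(sx, dtype=float),
        by=np.asarray(by, dtype=float),
        sy=np.asarray(sy, dtype=float))


@pytest.fixture(scope="session")
def strong_sim():
    """One strong-effect simulation shared across estimator tests."""
    cfg = SimulationConfig(n_variants=30, instrument_h2=0.2,
                           theta_xy_direct=0.3, seed=42)
    exposure, mediator, outcome, truth = simulate_summary_stats(cfg)
    return cfg, exposure, mediator, outcome, truth


@pytest.fixture
def strong_mr_input(strong_sim):
    _, exposure, _, outcome, truth = strong_sim
    e = exposure.set_index("variant_id").loc[truth.variant_id]
    o = outcome.set_index("variant_id").loc[truth.variant_id]
    return MRInput(variant_ids=list(truth.variant_id),
                   bx=e["beta"].to_numpy(), sx=e["se"].to_numpy(),
                   by=o["beta"].to_numpy(), sy=o["se"].to_numpy())
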