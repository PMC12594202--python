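import numpy as np
import pytest

from stngpe.engine import default_model


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def healthy_run(model):
    """Tuned healthy-state network run shared by the acceptance checks.

    Scale-1/5 network (50 STN / 150 GPe), plasticity off, 10-s warm-up and a
    60-s measurement window, as the firing-rate and spectral constraints
    prescribe.
    """
    from stngpe.engine import NetworkConfig, measure_rates

    cfg = NetworkConfig(scale_factor=5.0, seed=101,
                        synaptic_plasticity=False,
                        structural_plasticity=False)
    stn_rate, gpe_rate, net, res = measure_rates(cfg, model,
                                                 duration_ms=60_000.0,
                                                 warmup_ms=10_000.0)
    return {"stn_rate": stn_rate, "gpe_rate": gpe_rate, "net": net,
            "res": res, "duration_ms": 60_000.0}
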