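"""Configuration files, state snapshots, exports and run manifests.

Parameter files are YAML (or JSON) trees with one block per section
(``stn``, ``gpe``, ``transmitters``, ``plasticity``, ``structural``,
``weights``, ``network``); unknown keys are rejected and the assembled model
re-validates every invariant.  Each block may carry a ``provenance`` mapping
(parameter name -> free-text source tag) which is preserved and echoed into
run manifests.  State snapshots go to HDF5; synapse tables and spike rasters
to CSV.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .engine import ModelParams, Network, NetworkConfig, default_model
from .neurons import GatingSpec, NeuronParams
from .plasticity import PlasticityParams
from .structural import StructuralParams
from .synapses import TransmitterParams

__all__ = [
    "load_config",
    "dump_default_config",
    "RunManifest",
    "save_snapshot",
    "export_spikes_csv",
    "export_synapses_csv",
    "make_fixtures",
]

_SECTIONS = ("stn", "gpe", "transmitters", "plasticity", "structural",
             "weights", "network", "g_nmda_ca_frac", "provenance")
_NEURON_KEYS = {"population", "C", "g_Na", "g_K", "g_T", "g_CaK", "g_A",
                "g_L", "g_leak", "E_Na", "E_K", "E_leak", "I_bias", "ca_out",
                "temperature", "k_ca", "k_conv", "ca_floor", "gating"}


def _check_keys(block: dict, allowed, where: str) -> None:
    unknown = set(block) - set(allowed) - {"provenance"}
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section "
                         f"{where!r}; allowed: {sorted(allowed)}")


def _neuron_from_block(pop: str, block: dict) -> NeuronParams:
    _check_keys(block, _NEURON_KEYS, pop)
    kw = {k: v for k, v in block.items()
          if k not in ("population", "gating", "provenance")}
    gating = tuple(GatingSpec(**g) for g in block.get("gating", ()))
    return NeuronParams(pop.upper() if pop == "stn" else "GPe",
                        gating=gating, **kw)


def load_config(path) -> tuple[ModelParams, NetworkConfig, dict]:
    """Load and validate a parameter file; missing sections use defaults.

    Returns (model, network config, provenance).  Every invariant of the
    underlying parameter dataclasses is re-checked on assembly; unknown keys
    raise a descriptive error.
    """
    path = Path(path)
    with open(path) as fh:
        tree = yaml.safe_load(fh) or {}
    if not isinstance(tree, dict):
        raise ValueError(f"config root must be a mapping, got {type(tree)}")
    _check_keys(tree, _SECTIONS, "<root>")
    base = default_model()
    kw = {}
    if "stn" in tree:
        kw["stn"] = _neuron_from_block("stn", tree["stn"])
    if "gpe" in tree:
        kw["gpe"] = _neuron_from_block("gpe", tree["gpe"])
    if "transmitters" in tree:
        kw["transmitters"] = {
            name: TransmitterParams(transmitter=name, **blk)
            for name, blk in tree["transmitters"].items()}
    if "plasticity" in tree:
        _check_keys(tree["plasticity"],
                    PlasticityParams.__dataclass_fields__, "plasticity")
        kw["plasticity"] = PlasticityParams(**{
            k: v for k, v in tree["plasticity"].items() if k != "provenance"})
    if "structural" in tree:
        _check_keys(tree["structural"],
                    StructuralParams.__dataclass_fields__, "structural")
        kw["structural"] = StructuralParams(**{
            k: v for k, v in tree["structural"].items() if k != "provenance"})
    if "weights" in tree:
        _check_keys(tree["weights"], ("CS", "GS", "SG", "GG", "MS"), "weights")
        kw["weights"] = {**base.weights,
                         **{k: v for k, v in tree["weights"].items()
                            if k != "provenance"}}
    if "g_nmda_ca_frac" in tree:
        kw["g_nmda_ca_frac"] = float(tree["g_nmda_ca_frac"])
    model = replace(base, **kw) if kw else base
    net_kw = dict(tree.get("network", {}))
    net_kw.pop("provenance", None)
    _check_keys(net_kw, NetworkConfig.__dataclass_fields__, "network")
    cfg = NetworkConfig(**net_kw)
    provenance = tree.get("provenance", {})
    for sec in _SECTIONS:
        if isinstance(tree.get(sec), dict) and "provenance" in tree[sec]:
            provenance[sec] = tree[sec]["provenance"]
    return model, cfg, provenance


def _model_tree(model: ModelParams, cfg: NetworkConfig) -> dict:
    tree = {
        "stn": {k: v for k, v in asdict(model.stn).items() if k != "gating"},
        "gpe": {k: v for k, v in asdict(model.gpe).items() if k != "gating"},
        "transmitters": {n: {k: v for k, v in asdict(t).items()
                             if k != "transmitter"}
                         for n, t in model.transmitters.items()},
        "plasticity": asdict(model.plasticity),
        "structural": asdict(model.structural),
        "weights": dict(model.weights),
        "g_nmda_ca_frac": model.g_nmda_ca_frac,
        "network": asdict(cfg),
    }
    tree["stn"].pop("population", None)
    tree["gpe"].pop("population", None)
    return tree


def dump_default_config(path, model: ModelParams | None = None,
                        cfg: NetworkConfig | None = None) -> None:
    """Write the resolved default parameter tree (with provenance tags)."""
    model = model if model is not None else default_model()
    cfg = cfg if cfg is not None else NetworkConfig()
    tree = _model_tree(model, cfg)
    tree["provenance"] = {
        "stn": "source-model kinetics; conductances/bias calibrated to "
               "pacemaking and rebound-burst constraints",
        "gpe": "reduced channel set; calibrated to 30-Hz firing and "
               "iMSN-silencing constraints",
        "transmitters": "receptor-typical kinetics; NMDA activation rate "
                        "calibrated to the 0.25 NMDA:AMPA ratio",
        "plasticity": "main-text structure; thresholds/rates calibrated to "
                      "the stimulation and rebound protocol outcomes",
        "structural": "main-text values (tau_z 1800 s model-fitting value; "
                      "3600 s alternative printed value is configurable); "
                      "calcium targets from the disabled-plasticity "
                      "calibration run",
        "weights": "calibrated to firing-rate/rebound/silencing/beta "
                   "constraints",
    }
    with open(path, "w") as fh:
        yaml.safe_dump(tree, fh, sort_keys=False)


class RunManifest:
    """Reproducibility record of one run: resolved config, seed, outputs."""

    def __init__(self, model: ModelParams, cfg: NetworkConfig,
                 provenance: dict | None = None):
        self.tree = _model_tree(model, cfg)
        self.provenance = provenance or {}
        self.outputs: dict[str, str] = {}
        self.sim_span_ms: list[float] = [0.0, 0.0]

    def add_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.tree, "provenance": self.provenance,
                       "outputs": self.outputs,
                       "sim_span_ms": self.sim_span_ms}, fh, indent=1,
                      default=float)

    @classmethod
    def load(cls, path) -> tuple[ModelParams, NetworkConfig, dict]:
        """Rebuild (model, cfg) from a saved manifest via the config loader."""
        with open(path) as fh:
            blob = json.load(fh)
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".yaml",
                                         delete=False) as tmp:
            yaml.safe_dump(blob["config"], tmp)
            name = tmp.name
        try:
            return load_config(name)
        finally:
            Path(name).unlink()


def save_snapshot(net: Network, path) -> None:
    """Full simulation state to HDF5 (neurons, synapses, elements)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("neurons")
        for name in ("pop", "V", "gates", "ca_soma", "ca_seg", "ca_L",
                     "bias", "last_spike"):
            g.create_dataset(name, data=getattr(net, name))
        s = f.create_group("synapses")
        for name in ("pre", "post", "seg", "type_code", "rho", "s",
                     "fpre_until"):
            s.create_dataset(name, data=getattr(net.table, name))
        e = f.create_group("elements")
        e.create_dataset("z_exc", data=net.elements.z_exc)
        e.create_dataset("z_inh", data=net.elements.z_inh)
        f.attrs["t_ms"] = net.t_ms
        f.attrs["n_stn"] = net.n_stn
        f.attrs["n_gpe"] = net.n_gpe


def export_spikes_csv(result, path) -> None:
    """Spike raster as two-column CSV (neuron_id, spike_time_ms)."""
    import pandas as pd

    pd.DataFrame({"neuron_id": result.spike_neuron,
                  "spike_time_ms": result.spike_t_ms}).to_csv(path,
                                                              index=False)


def export_synapses_csv(net: Network, path) -> None:
    """Synapse table as edge-list CSV with a JSON element-state sidecar."""
    from .connectivity import edge_list_frame

    edge_list_frame(net.table).to_csv(path, index=False)
    sidecar = Path(str(path) + ".elements.json")
    with open(sidecar, "w") as fh:
        json.dump({"z_exc": net.elements.z_exc.tolist(),
                   "z_inh": net.elements.z_inh.tolist()}, fh)


def export_efficacy_h5(path, t_ms, rho_by_type: dict) -> None:
    """Efficacy time series per synapse type as HDF5 datasets.

    ``rho_by_type`` maps a type label (CS/GS/SG/GG) to an array of shape
    (n_synapses, n_times).
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t_ms", data=np.asarray(t_ms))
        for name, arr in rho_by_type.items():
            f.create_dataset(name, data=np.asarray(arr))


def export_trains_csv(trains, path) -> None:
    """Afferent spike trains as two-column CSV (generator_id, spike_time_ms)."""
    import pandas as pd

    pd.DataFrame({
        "generator_id": np.concatenate(
            [np.full(t.size, i, dtype=np.int64) for i, t in enumerate(trains)]
        ) if trains else np.zeros(0, dtype=np.int64),
        "spike_time_ms": (np.concatenate(trains) * 1e3) if trains else np.zeros(0),
    }).to_csv(path, index=False)


def export_trains_h5(trains, path) -> None:
    """Afferent spike trains as HDF5 ragged arrays (one dataset per generator)."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, t in enumerate(trains):
            f.create_dataset(f"gen{i:05d}", data=np.asarray(t))


def make_fixtures(kind: str, seed: int = 0):
    """Deterministic small test inputs shared across the test suite.

    Kinds: ``single_stn``, ``single_gpe``, ``two_synapse_segment``,
    ``micro_network`` (5 STN + 15 GPe), ``spike_sinusoid`` (20-Hz-modulated
    inhomogeneous-Poisson raster).
    """
    from .engine import build_network, single_stn_setup

    if kind == "single_stn":
        return single_stn_setup(default_model(), n_cs=0, n_gs=0, seed=seed)
    if kind == "single_gpe":
        cfg = NetworkConfig(n_stn=1, n_gpe=1, n_ctx=1, n_msn=1, in_degree=0,
                            seed=seed, synaptic_plasticity=False,
                            structural_plasticity=False)
        net = build_network(cfg, default_model())
        net.V[:] = -60.0
        return net
    if kind == "two_synapse_segment":
        # one excitatory (CS) and one inhibitory (GS) synapse on segment 0
        net = single_stn_setup(default_model(), n_cs=1, n_gs=1, seed=seed)
        net.table.seg[:] = 0
        net._refresh_synapse_arrays()
        return net
    if kind == "micro_network":
        cfg = NetworkConfig(n_stn=5, n_gpe=15, n_ctx=50, n_msn=150,
                            in_degree=5, seed=seed,
                            synaptic_plasticity=False,
                            structural_plasticity=False)
        return build_network(cfg, default_model())
    if kind == "spike_sinusoid":
        rng = np.random.default_rng(seed)
        duration_s, n_neurons, base = 120.0, 50, 20.0
        t = np.arange(0.0, duration_s, 1e-3)
        rate = base * (1.0 + 0.8 * np.sin(2 * np.pi * 20.0 * t))
        spikes = []
        for i in range(n_neurons):
            mask = rng.uniform(size=t.size) < rate * 1e-3
            spikes.append(t[mask] * 1e3)
        return spikes, n_neurons, duration_s * 1e3
    raise ValueError(f"unknown fixture kind {kind!r}")
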