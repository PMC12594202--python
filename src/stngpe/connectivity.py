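"""Array-based synapse table and wiring rules for the STN-GPe circuit.

The simulation state of all synapses is kept as a struct-of-arrays
(:class:`SynapseTable`) so the integrator kernels can run over contiguous
memory; a :func:`to_networkx` export provides the directed-multigraph view
for analysis.  Populations: STN and GPe neurons are simulated; CTX and iMSN
afferents are spike generators.

Synapse types and their wiring:

====  =============  ============  =========
type  presynaptic    postsynaptic  sign
====  =============  ============  =========
CS    CTX generator  STN           excitatory
GS    GPe            STN           inhibitory
SG    STN            GPe           excitatory
GG    GPe (no self)  GPe           inhibitory
MS    iMSN generator GPe           inhibitory (non-plastic, fixed edge set)
====  =============  ============  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseTable",
    "TYPE_NAMES",
    "TYPE_CODES",
    "EXC_TYPE_CODES",
    "PRE_KIND",
    "POST_POP",
    "indegree_stats",
    "to_networkx",
    "edge_list_frame",
]

TYPE_NAMES = ("CS", "GS", "SG", "GG", "MS")
TYPE_CODES = {n: i for i, n in enumerate(TYPE_NAMES)}
EXC_TYPE_CODES = (0, 2)  # CS, SG

#: presynaptic source kind per type code: 0=STN, 1=GPe, 2=CTX, 3=MSN
PRE_KIND = np.array([2, 1, 0, 1, 3], dtype=np.int8)
#: postsynaptic population per type code: 0=STN, 1=GPe
POST_POP = np.array([0, 0, 1, 1, 1], dtype=np.int8)

N_GATE_COLS = 6  # exc: AMPA (0..2) + NMDA (3..5); inh: GABAa (0..2)


@dataclass
class SynapseTable:
    """Struct-of-arrays container for all synapses of one network.

    ``post`` is the global neuron index (STN neurons first, then GPe);
    ``pre`` is the index within the presynaptic source population implied by
    the synapse type.  ``s`` holds the gating components and ``fpre_until``
    the expiry time (ms) of the active release pulse.
    """

    pre: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    post: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    seg: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    type_code: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))
    rho: np.ndarray = field(default_factory=lambda: np.zeros(0))
    s: np.ndarray = field(default_factory=lambda: np.zeros((0, N_GATE_COLS)))
    fpre_until: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return self.pre.size

    @property
    def excitatory(self) -> np.ndarray:
        return np.isin(self.type_code, EXC_TYPE_CODES)

    @property
    def plastic(self) -> np.ndarray:
        return self.type_code != TYPE_CODES["MS"]

    def validate(self, n_stn: int, n_gpe: int, n_ctx: int, n_msn: int) -> None:
        """Check endpoint consistency against population sizes."""
        tc = self.type_code
        pre_max = np.array([n_ctx, n_gpe, n_stn, n_gpe, n_msn])[tc]
        if np.any(self.pre < 0) or np.any(self.pre >= pre_max):
            raise ValueError("presynaptic index out of range for its population")
        post_lo = np.where(POST_POP[tc] == 0, 0, n_stn)
        post_hi = np.where(POST_POP[tc] == 0, n_stn, n_stn + n_gpe)
        if np.any(self.post < post_lo) or np.any(self.post >= post_hi):
            raise ValueError("postsynaptic index inconsistent with synapse type")
        gg = tc == TYPE_CODES["GG"]
        if np.any(self.pre[gg] + n_stn == self.post[gg]):
            raise ValueError("GG self-loop")
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise ValueError("rho out of [0, 1]")
        if np.any((self.seg < 0) | (self.seg > 2)):
            raise ValueError("segment out of {0, 1, 2}")

    def append(self, pre, post, seg, type_code, rho) -> None:
        k = len(pre)
        self.pre = np.concatenate([self.pre, np.asarray(pre, dtype=np.int64)])
        self.post = np.concatenate([self.post, np.asarray(post, dtype=np.int64)])
        self.seg = np.concatenate([self.seg, np.asarray(seg, dtype=np.int8)])
        self.type_code = np.concatenate(
            [self.type_code, np.asarray(type_code, dtype=np.int8)])
        self.rho = np.concatenate([self.rho, np.asarray(rho, dtype=float)])
        self.s = np.concatenate([self.s, np.zeros((k, N_GATE_COLS))])
        # finite "never" sentinel (kernel runs with fastmath, which assumes
        # finite floats)
        self.fpre_until = np.concatenate([self.fpre_until, np.full(k, -1e30)])

    def remove(self, rows: np.ndarray) -> None:
        keep = np.ones(len(self), dtype=bool)
        keep[np.asarray(rows, dtype=np.int64)] = False
        for name in ("pre", "post", "seg", "type_code", "rho", "fpre_until"):
            setattr(self, name, getattr(self, name)[keep])
        self.s = self.s[keep]

    def copy(self) -> "SynapseTable":
        return SynapseTable(self.pre.copy(), self.post.copy(), self.seg.copy(),
                            self.type_code.copy(), self.rho.copy(),
                            self.s.copy(), self.fpre_until.copy())

    def state_hash(self) -> str:
        """Stable digest of the wiring (pre, post, seg, type), order-independent."""
        import hashlib

        key = np.stack([self.pre, self.post, self.seg.astype(np.int64),
                        self.type_code.astype(np.int64)])
        order = np.lexsort(key)
        return hashlib.sha256(key[:, order].tobytes()).hexdigest()


def indegree_stats(table: SynapseTable, n_stn: int, n_gpe: int,
                   reference: dict | None = None) -> dict:
    """Mean in-degree per synapse type, optionally with % change vs reference.

    The mean is over all neurons of the postsynaptic population of each type
    (including neurons with zero incoming edges of that type).
    """
    if len(table) == 0:
        raise ValueError("empty synapse table")
    out = {}
    for name, code in TYPE_CODES.items():
        n_post = n_stn if POST_POP[code] == 0 else n_gpe
        count = int(np.sum(table.type_code == code))
        mean = count / n_post
        entry = {"mean": mean}
        if reference is not None:
            ref = reference[name]["mean"]
            entry["pct_change"] = 100.0 * (mean - ref) / ref if ref else np.nan
        out[name] = entry
    return out


def edge_list_frame(table: SynapseTable):
    """Edge list as a pandas DataFrame (pre_id, post_id, type, segment, rho)."""
    import pandas as pd

    return pd.DataFrame({
        "pre_id": table.pre,
        "post_id": table.post,
        "type": [TYPE_NAMES[c] for c in table.type_code],
        "segment": table.seg.astype(int),
        "rho": table.rho,
    })


def to_networkx(table: SynapseTable, n_stn: int, n_gpe: int):
    """Directed multigraph over neurons and afferent generators.

    Node labels: ``("STN", i)``, ``("GPe", i)``, ``("CTX", i)``, ``("MSN", i)``.
    """
    import networkx as nx

    g = nx.MultiDiGraph()
    kind_names = ("STN", "GPe", "CTX", "MSN")
    for row in range(len(table)):
        tc = int(table.type_code[row])
        pre_kind = kind_names[PRE_KIND[tc]]
        post = int(table.post[row])
        post_node = ("STN", post) if post < n_stn else ("GPe", post - n_stn)
        g.add_edge((pre_kind, int(table.pre[row])), post_node,
                   type=TYPE_NAMES[tc], segment=int(table.seg[row]),
                   rho=float(table.rho[row]))
    return g
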