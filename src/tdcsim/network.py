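"""Structural connectome container and whole-network time stepping.

The standard study couples 78 neural masses, one per cortical region of
the AAL (automated anatomical labeling) parcellation, through a symmetric
non-negative weight matrix derived from diffusion imaging.  Coupling is
always excitatory and reciprocal: the excitatory pulse density of one
mass drives the excitatory synaptic filter of its neighbors, scaled by
the global coupling strength ``S``.

The reference diffusion matrix is not redistributable, so the module
ships a seeded synthetic generator producing binary connectomes with a
heavy-tailed (hub-bearing) degree distribution, plus a CSV loader for any
user-supplied matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .neural_mass import NeuralMassParameters, NeuralMassState, mass_step, pulse_density

__all__ = [
    "StructuralNetwork",
    "NetworkState",
    "aal78_labels",
    "load_connectome",
    "save_connectome",
    "generate_synthetic_connectome",
    "network_step",
    "node_degree",
]

_SYMMETRY_TOL = 1e-9


def aal78_labels() -> list[str]:
    """The 78 cortical AAL region names (left/right interleaved)."""
    text = resources.files("tdcsim.data").joinpath("aal78_labels.txt").read_text()
    return text.split()


@dataclass
class StructuralNetwork:
    """Symmetric weighted coupling over labeled regions.

    ``weights`` is mutable under degeneration; ``S`` is the global
    coupling strength multiplying every connection (default 1).
    """

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)
    S: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {w.shape}")
        bad = np.argwhere(np.isnan(w))
        if bad.size:
            raise ValueError(f"NaN weight at row {bad[0][0]}, column {bad[0][1]}")
        bad = np.argwhere(w < 0)
        if bad.size:
            raise ValueError(f"negative weight at row {bad[0][0]}, column {bad[0][1]}")
        asym = np.abs(w - w.T)
        bad = np.argwhere(asym > _SYMMETRY_TOL)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"coupling must be reciprocal: weights[{i},{j}] != weights[{j},{i}]"
            )
        w = 0.5 * (w + w.T)
        bad = np.flatnonzero(np.abs(np.diag(w)) > _SYMMETRY_TOL)
        if bad.size:
            raise ValueError(f"self-coupling not allowed (diagonal entry at {bad[0]})")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if not self.labels:
            n = w.shape[0]
            self.labels = aal78_labels() if n == 78 else [f"region_{i}" for i in range(n)]
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def effective_weights(self) -> np.ndarray:
        return self.S * self.weights

    def total_weight(self) -> float:
        """Sum of coupling weights over unordered pairs."""
        return float(self.weights.sum() / 2.0)

    def copy(self) -> "StructuralNetwork":
        return StructuralNetwork(self.weights.copy(), list(self.labels), self.S)


@dataclass
class NetworkState:
    """Per-mass dynamic states plus the pulse densities seen by neighbors."""

    masses: list[NeuralMassState]
    E: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "NetworkState":
        return cls([NeuralMassState() for _ in range(n)], np.zeros(n))


def load_connectome(path: str | Path, S: float = 1.0) -> StructuralNetwork:
    """Read a square CSV weight matrix, optionally headed by region labels."""
    path = Path(path)
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = first.iloc[0].map(lambda v: isinstance(v, str)).any()
    if has_header:
        df = pd.read_csv(path)
        labels = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, header=None)
        labels = []
    try:
        w = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric connectome entry in {path}: {exc}") from exc
    return StructuralNetwork(w, labels=labels, S=S)


def save_connectome(net: StructuralNetwork, path: str | Path) -> None:
    pd.DataFrame(net.weights, columns=net.labels).to_csv(path, index=False)


def generate_synthetic_connectome(
    n: int,
    mean_degree: float = 5.0,
    hub_fraction: float = 0.15,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
    S: float = 1.0,
) -> StructuralNetwork:
    """Seeded binary connectome with a minority of hub regions.

    Edges are sampled from an expected-degree (Chung-Lu style) model in
    which a ``hub_fraction`` of nodes carry a boosted propensity, yielding
    a heavy-tailed degree distribution; ``hub_fraction = 0`` reduces to an
    Erdos-Renyi-like graph.  Disconnected components, if any, are joined
    by single seeded edges so the returned graph is always connected.
    Hub-propensity nodes are the first ``round(hub_fraction * n)`` indices,
    which lets callers co-locate hubs with a spatial layout.
    """
    if not 0 < mean_degree < n:
        raise ValueError("mean_degree must be in (0, n)")
    if not 0 <= hub_fraction <= 1:
        raise ValueError("hub_fraction must be a proportion")
    rng = np.random.default_rng(seed)
    n_hubs = int(round(hub_fraction * n))
    prop = np.ones(n)
    prop[:n_hubs] = 4.0
    outer = np.outer(prop, prop).astype(float)
    np.fill_diagonal(outer, 0.0)
    # scale so the expected number of edges matches mean_degree * n / 2
    p = outer * (mean_degree * n) / outer.sum()
    if p.max() > 1.0:
        p = np.clip(p, 0.0, 1.0)
    tri = np.triu(rng.random((n, n)) < p, k=1)
    w = (tri | tri.T).astype(float)

    # join components (rare at the default density)
    comp = _components(w)
    while len(comp) > 1:
        a = rng.choice(list(comp[0]))
        b = rng.choice(list(comp[1]))
        w[a, b] = w[b, a] = 1.0
        comp = _components(w)
    return StructuralNetwork(w, labels=list(labels) if labels else [], S=S)


def _components(w: np.ndarray) -> list[set[int]]:
    n = w.shape[0]
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], {start}
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(w[u]):
                if v not in comp:
                    comp.add(int(v))
                    stack.append(int(v))
        seen |= comp
        comps.append(comp)
    return comps


def node_degree(net: StructuralNetwork) -> np.ndarray:
    """Binary degree: number of nonzero neighbors per region."""
    return (net.weights > 0).sum(axis=1).astype(int)


def network_step(
    state: NetworkState,
    net: StructuralNetwork,
    per_mass_params: Sequence[NeuralMassParameters],
    noise_draws: np.ndarray,
    dt: float,
) -> NetworkState:
    """Advance every mass one step with same-step excitatory coupling.

    Each mass ``i`` receives ``Ej(t) = S * sum_j weights[i, j] * E_j(t)``
    into its excitatory synaptic filter, where ``E_j(t)`` is the pulse
    density each mass emits this step.  This is the readable reference
    path; long simulations use the vectorized integrator, which the test
    suite holds to exact agreement with this function.
    """
    n = net.n
    if len(state.masses) != n or len(per_mass_params) != n or len(noise_draws) != n:
        raise ValueError("state, parameter and noise sizes must match the network")
    E_now = np.array(
        [
            pulse_density(
                m.filter_state[0, 0] - p.C2 * m.filter_state[1, 0],
                p.Vd1,
                p.sigmoid_steepness[0],
                p.dmax,
            )
            for m, p in zip(state.masses, per_mass_params)
        ]
    )
    ext = net.effective_weights() @ E_now
    new_masses = [
        mass_step(m, p, float(ext[i]), float(noise_draws[i]), dt)
        for i, (m, p) in enumerate(zip(state.masses, per_mass_params))
    ]
    return NetworkState(new_masses, np.array([m.E for m in new_masses]))
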