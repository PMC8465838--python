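"""Spatially embedded random network construction.

Neurons are point cells placed uniformly at random on the unit square.
Directed synaptic projections are drawn independently per ordered pair with
a Gaussian distance kernel ``p(d) = exp(-d^2 / sigma_r^2)``, which gives a
mildly sparse, distance-dependent connectivity similar to dissociated
cultures grown on plates.  A fixed fraction of cells is labelled inhibitory;
the signed adjacency (+1 excitatory source, -1 inhibitory source) is the
ground truth against which inferred connectivity is scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NetworkTopology",
    "place_neurons",
    "build_connectivity",
    "assign_types",
    "make_topology",
]

EXCITATORY = 0
INHIBITORY = 1


@dataclass
class NetworkTopology:
    """Structural ground truth of one modelled network.

    Attributes
    ----------
    positions : (n, 2) float array
        Cell coordinates on the unit square (non-dimensional units).
    adjacency : (n, n) bool array
        ``adjacency[i, j]`` is True when cell ``j`` projects to cell ``i``
        (rows index targets, columns sources).  No self-connections.
    labels : (n,) int array
        Per-cell class: 0 excitatory, 1 inhibitory.
    sigma_r : float
        Width of the Gaussian connection kernel.
    """

    positions: np.ndarray
    adjacency: np.ndarray
    labels: np.ndarray
    sigma_r: float
    seed: int | None = None
    label_seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def inhibitory_mask(self) -> np.ndarray:
        return self.labels == INHIBITORY

    def signed_adjacency(self) -> np.ndarray:
        """Dense signed view: +1 excitatory link, -1 inhibitory link, 0 none."""
        sign = np.where(self.inhibitory_mask, -1, 1)  # per source column
        return self.adjacency.astype(int) * sign[np.newaxis, :]

    def component_adjacency(self, component: str) -> np.ndarray:
        """Boolean truth matrix for one synapse class.

        ``component='E'`` marks entries with a structural excitatory link
        j -> i; everything else (absent links *and* inhibitory links) is a
        negative.  Symmetrically for ``'I'``.
        """
        if component not in ("E", "I"):
            raise ValueError(f"component must be 'E' or 'I', got {component!r}")
        want_inhib = component == "I"
        src_is_class = self.inhibitory_mask == want_inhib
        return self.adjacency & src_is_class[np.newaxis, :]

    def with_labels(self, labels: np.ndarray, label_seed: int | None = None) -> "NetworkTopology":
        """Same positions and adjacency, different E/I sorting."""
        return NetworkTopology(
            positions=self.positions,
            adjacency=self.adjacency,
            labels=np.asarray(labels),
            sigma_r=self.sigma_r,
            seed=self.seed,
            label_seed=label_seed,
        )

    # -- serialization ----------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n = self.n_neurons
        pd.DataFrame(
            {"neuron_id": np.arange(n), "x": self.positions[:, 0], "y": self.positions[:, 1]}
        ).to_csv(outdir / "positions.csv", index=False)
        pd.DataFrame(
            {
                "neuron_id": np.arange(n),
                "type": np.where(self.inhibitory_mask, "inhibitory", "excitatory"),
            }
        ).to_csv(outdir / "labels.csv", index=False)
        np.savetxt(outdir / "adjacency.txt", self.adjacency.astype(int), fmt="%d")
        np.savetxt(outdir / "signed_adjacency.txt", self.signed_adjacency(), fmt="%d")

    @classmethod
    def load(cls, outdir: str | Path, sigma_r: float = np.nan) -> "NetworkTopology":
        outdir = Path(outdir)
        pos = pd.read_csv(outdir / "positions.csv")[["x", "y"]].to_numpy()
        lab = pd.read_csv(outdir / "labels.csv")["type"].to_numpy()
        adjacency = np.loadtxt(outdir / "adjacency.txt").astype(bool)
        labels = np.where(lab == "inhibitory", INHIBITORY, EXCITATORY)
        return cls(positions=pos, adjacency=adjacency, labels=labels, sigma_r=sigma_r)


def place_neurons(n: int, seed: int) -> np.ndarray:
    """Place ``n`` cells i.i.d. uniformly on the unit square."""
    if n < 2:
        raise ValueError(f"need at least 2 neurons, got {n}")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n, 2))


def build_connectivity(positions: np.ndarray, sigma_r: float, seed: int) -> np.ndarray:
    """Draw directed links with probability exp(-d_ij^2 / sigma_r^2).

    Each ordered pair (i != j) is an independent Bernoulli draw; reciprocal
    links are independent and the diagonal is excluded (no autapses).
    """
    if sigma_r <= 0:
        raise ValueError(f"sigma_r must be positive, got {sigma_r}")
    positions = np.asarray(positions, dtype=float)
    rng = np.random.default_rng(seed)
    diff = positions[:, np.newaxis, :] - positions[np.newaxis, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    prob = np.exp(-d2 / sigma_r**2)
    adjacency = rng.uniform(size=prob.shape) < prob
    np.fill_diagonal(adjacency, False)
    return adjacency


def assign_types(n: int, fraction_inhibitory: float, seed: int) -> np.ndarray:
    """Label exactly round(n * fraction_inhibitory) cells inhibitory.

    The inhibitory subset is drawn uniformly without replacement, so two
    seeds give different sortings with identical class counts.
    """
    if not 0.0 <= fraction_inhibitory <= 1.0:
        raise ValueError(f"fraction_inhibitory must be in [0, 1], got {fraction_inhibitory}")
    n_inhib = int(round(n * fraction_inhibitory))
    rng = np.random.default_rng(seed)
    labels = np.full(n, EXCITATORY, dtype=np.int64)
    labels[rng.choice(n, size=n_inhib, replace=False)] = INHIBITORY
    return labels


def make_topology(
    n: int = 100,
    sigma_r: float = 0.3,
    fraction_inhibitory: float = 0.2,
    topology_seed: int = 0,
    label_seed: int = 0,
) -> NetworkTopology:
    """Build positions, adjacency and labels in one call."""
    positions = place_neurons(n, topology_seed)
    adjacency = build_connectivity(positions, sigma_r, topology_seed)
    labels = assign_types(n, fraction_inhibitory, label_seed)
    return NetworkTopology(
        positions=positions,
        adjacency=adjacency,
        labels=labels,
        sigma_r=sigma_r,
        seed=topology_seed,
        label_seed=label_seed,
    )
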