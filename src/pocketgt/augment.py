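"""Label balancing and training-time graph augmentation.

Candidate sets from geometric detectors are heavily imbalanced (typically
<10% true pockets).  Training therefore (a) oversamples the positive class
each epoch until it matches the negative count, and (b) perturbs every
sampled graph with structured noise so repeated positives are never seen
twice identically: Gaussian positional noise on the Calpha coordinates
(sigma_pos, default 0.5 A), bootstrap node resampling that drops/duplicates
nodes (round((1 - sigma_node) * N) draws with replacement, sigma_node
default 0.03), and multiplicative Gaussian noise on SASA values (sigma_sasa,
default 0.3).  Edges are rebuilt from the noised coordinates so distance
features stay consistent.  Validation and test data are never augmented or
balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import BalancingError
from .graphs import DEFAULT_EDGE_CUTOFF, PocketGraph, build_edges


@dataclass(frozen=True)
class AugmentConfig:
    """Noise strengths and balancing switch (defaults are the tuned values)."""

    sigma_pos: float = 0.5
    sigma_node: float = 0.03
    sigma_sasa: float = 0.3
    balance: bool = True
    enabled: bool = True

    def __post_init__(self):
        if self.sigma_pos < 0 or self.sigma_sasa < 0:
            raise ValueError("noise strengths must be non-negative")
        if not (0.0 <= self.sigma_node < 1.0):
            raise ValueError("sigma_node must lie in [0, 1)")


def balance_labels(labels, rng: np.random.Generator) -> np.ndarray:
    """Epoch index multiset with positives oversampled to the negative count.

    Returns every false-label index once plus ``n_false`` uniform draws
    (with replacement) from the true-label indices; total size is
    ``2 * n_false``.
    """
    labels = np.asarray([bool(l) for l in labels])
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise BalancingError("balancing requires at least one sample of each label")
    drawn = rng.choice(pos_idx, size=len(neg_idx), replace=True)
    return np.concatenate([neg_idx, drawn])


def positional_noise(coords: np.ndarray, sigma_pos: float, rng: np.random.Generator) -> np.ndarray:
    """Add iid N(0, sigma_pos^2) noise per coordinate component (copy)."""
    coords = np.asarray(coords, dtype=float)
    if sigma_pos == 0.0:
        return coords.copy()
    return coords + sigma_pos * rng.standard_normal(coords.shape)


def _resample_indices(n: int, sigma_node: float, rng: np.random.Generator) -> np.ndarray:
    m = int(round((1.0 - sigma_node) * n))
    if m < 1:
        warnings.warn("node resampling produced an empty draw; clamped to 1 node")
        m = 1
    return rng.integers(0, n, size=m)


def node_resample(
    g: PocketGraph,
    sigma_node: float,
    rng: np.random.Generator,
    cutoff: float = DEFAULT_EDGE_CUTOFF,
) -> PocketGraph:
    """Bootstrap the node set: round((1 - sigma_node) * N) draws with replacement.

    Duplicated draws become distinct nodes; edges are rebuilt from the
    resampled coordinates under the usual distance cutoff (self-pairs by new
    index excluded).
    """
    if g.n_nodes < 2:
        raise ValueError("node resampling needs at least 2 nodes")
    idx = _resample_indices(g.n_nodes, sigma_node, rng)
    coords = g.node_coords[idx]
    return replace(
        g,
        node_aa=g.node_aa[idx],
        node_sasa=g.node_sasa[idx],
        node_coords=coords,
        edges=build_edges(coords, cutoff),
        node_residue_keys=tuple(g.node_residue_keys[i] for i in idx),
    )


def sasa_noise(sasa_values: np.ndarray, sigma_sasa: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative noise ``s * (1 + sigma_sasa * eps)``, floored at 0."""
    sasa_values = np.asarray(sasa_values, dtype=float)
    if sigma_sasa == 0.0:
        return sasa_values.copy()
    noised = sasa_values * (1.0 + sigma_sasa * rng.standard_normal(sasa_values.shape))
    return np.maximum(noised, 0.0)


def augment_pocket(
    g: PocketGraph,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    resample: bool = True,
    cutoff: float = DEFAULT_EDGE_CUTOFF,
) -> PocketGraph:
    """Apply node resampling, positional noise and SASA noise; rebuild edges.

    The label and residue-key metadata are preserved.  ``resample=False``
    skips the bootstrap (used to verify the identity composition at zero
    noise).
    """
    if resample and g.n_nodes >= 2:
        idx = _resample_indices(g.n_nodes, cfg.sigma_node, rng)
    else:
        idx = np.arange(g.n_nodes)
    coords = positional_noise(g.node_coords[idx], cfg.sigma_pos, rng)
    sasa = sasa_noise(g.node_sasa[idx], cfg.sigma_sasa, rng)
    return replace(
        g,
        node_aa=g.node_aa[idx],
        node_sasa=sasa,
        node_coords=coords,
        edges=build_edges(coords, cutoff),
        node_residue_keys=tuple(g.node_residue_keys[i] for i in idx),
    )
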