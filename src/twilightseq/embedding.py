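"""Dissimilarity-to-distance transform and simulated-annealing layout.

Raw dissimilarities are empirical tail probabilities, not metric distances.
For display they are passed through the monotone map

    d(diss) = 1 / (-ln(c * diss)),   c = 0.990049833749168 = exp(-0.01),

which sends the largest possible dissimilarity (1) to 100 and pulls apart
near-zero values on a log scale while preserving order. Coordinates in 2D or
3D are then sought whose Euclidean distances approximate the transformed
dissimilarities, by simulated annealing of the squared-residual stress

    stress(X) = sum_{i<j} (||x_i - x_j|| - d_ij)^2 .
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Tuple

import numpy as np

TRANSFORM_CONSTANT = 0.990049833749168
DISS_FLOOR = 1e-6  # safety net; upstream Z fallback should prevent exact zeros


def transform(diss: float) -> float:
    """Display distance for a raw dissimilarity in (0, 1].

    Natural logarithm with c = exp(-0.01), so transform(1) = 100 exactly.
    """
    if not (0.0 < diss <= 1.0):
        raise ValueError(f"dissimilarity {diss} outside (0, 1]")
    return 1.0 / (-math.log(TRANSFORM_CONSTANT * diss))


def inverse_transform(distance: float) -> float:
    """Raw dissimilarity whose transform equals ``distance`` (0 < d < 100... ]."""
    if distance <= 0:
        raise ValueError("display distance must be positive")
    diss = math.exp(-1.0 / distance) / TRANSFORM_CONSTANT
    if diss > 1.0:
        raise ValueError(f"distance {distance} exceeds the transform's range (max 100)")
    return diss


@dataclass
class EmbeddingLayout:
    """Per-sequence coordinates plus the final stress value."""

    coordinates: Dict[str, np.ndarray]
    stress: float
    dimensions: int
    seed: int
    transform_constant: float = TRANSFORM_CONSTANT

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.coordinates[a] - self.coordinates[b]))

    def to_frame(self):
        import pandas as pd

        cols = ["x", "y", "z"][: self.dimensions]
        return pd.DataFrame(
            [[name, *coord] for name, coord in sorted(self.coordinates.items())],
            columns=["id", *cols],
        )


def _target_matrix(ids, dissimilarities: Mapping[FrozenSet[str] | Tuple[str, str], float],
                   ) -> np.ndarray:
    lookup = {frozenset(k): v for k, v in dissimilarities.items()}
    n = len(ids)
    T = np.full((n, n), transform(1.0))
    np.fill_diagonal(T, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            diss = lookup.get(frozenset((ids[i], ids[j])))
            if diss is not None:
                T[i, j] = T[j, i] = transform(max(diss, DISS_FLOOR))
    return T


def _stress(X: np.ndarray, T: np.ndarray) -> float:
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    iu = np.triu_indices(len(X), k=1)
    return float(((D[iu] - T[iu]) ** 2).sum())


def layout(dissimilarities: Mapping, dimensions: int = 2, seed: int = 0,
           n_sweeps: int = 600, moves_per_sweep: int | None = None,
           t0_fraction: float = 0.05, cooling: float = 0.95,
           quench_sweeps: int = 200) -> EmbeddingLayout:
    """Simulated-annealing placement matching transformed dissimilarities.

    Pairs missing from the map are assigned the maximum transformed distance
    (that of dissimilarity 1). The schedule is geometric (T_{k+1} = 0.95 T_k)
    with Gaussian single-point perturbations whose scale shrinks with the
    temperature, followed by zero-temperature quench sweeps during which the
    stress is non-increasing.
    """
    ids = sorted({x for k in dissimilarities for x in k})
    n = len(ids)
    if n < 3:
        raise ValueError("layout needs at least 3 nodes")
    if dimensions not in (2, 3):
        raise ValueError("layout supports 2 or 3 dimensions")
    T = _target_matrix(ids, dissimilarities)
    scale = float(T[np.triu_indices(n, k=1)].mean())
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=scale / 2.0, size=(n, dimensions))

    stress = _stress(X, T)
    temp = max(stress, 1e-12) * t0_fraction / n
    if moves_per_sweep is None:
        moves_per_sweep = 10 * n

    def point_residual(i: int, Xi: np.ndarray) -> float:
        d = np.linalg.norm(X - Xi, axis=1)
        d[i] = T[i, i]
        return float(((d - T[i]) ** 2).sum())

    total_sweeps = n_sweeps + quench_sweeps
    for sweep in range(total_sweeps):
        quenching = sweep >= n_sweeps
        # perturbation scale decays geometrically from scale/2 to ~1e-4 scale
        sigma = 0.5 * scale * (2e-4) ** (sweep / max(total_sweeps - 1, 1))
        for _ in range(moves_per_sweep):
            i = int(rng.integers(n))
            proposal = X[i] + rng.normal(scale=sigma, size=dimensions)
            delta = point_residual(i, proposal) - point_residual(i, X[i])
            if delta < 0 or (not quenching and temp > 0
                             and rng.random() < math.exp(min(-delta / temp, 0.0))):
                X[i] = proposal
                stress += delta
        if not quenching:
            temp *= cooling
    stress = _stress(X, T)  # recompute to shed accumulated float drift
    return EmbeddingLayout(
        coordinates={name: X[k].copy() for k, name in enumerate(ids)},
        stress=stress, dimensions=dimensions, seed=seed,
    )


def write_coordinates(lay: EmbeddingLayout, path) -> None:
    lay.to_frame().to_csv(path, sep="\t", index=False)


def plot_layout(lay: EmbeddingLayout, path, links=()) -> None:
    """Optional SVG scatter of a 2D layout; lines drawn only for given links."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for pair in links:
        a, b = tuple(pair)
        xs = [lay.coordinates[a][0], lay.coordinates[b][0]]
        ys = [lay.coordinates[a][1], lay.coordinates[b][1]]
        ax.plot(xs, ys, color="black", lw=0.8, zorder=1)
    for name, coord in lay.coordinates.items():
        ax.scatter(coord[0], coord[1], s=25, zorder=2)
        ax.annotate(name, coord[:2], fontsize=7)
    ax.set_aspect("equal")
    fig.savefig(path, format="svg")
    plt.close(fig)
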