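"""Gaussian expansion of interatomic distances.

A scalar distance d is encoded as the vector of responses of a uniform
grid of Gaussians, exp(-(d - mu_k)^2 / (2 sigma^2)) with centers
mu_k = mu_min + k * delta_mu up to mu_max.  This spreads a single scalar
across many dimensions so the downstream tensor layer can treat different
distance regimes with independent weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GaussianGrid", "gaussian_expand", "expand_all"]


@dataclass(frozen=True)
class GaussianGrid:
    """Uniform grid of Gaussian basis functions on the distance axis.

    Parameters
    ----------
    mu_min, mu_max : float
        Center of the first Gaussian and upper bound for centers (A).
        Centers run mu_min, mu_min + delta_mu, ... while <= mu_max.
    delta_mu : float
        Gap between adjacent centers (A).
    sigma : float
        Width of each Gaussian, read as a standard deviation (A).
    gamma : float, optional
        Alternative exponent parameterization exp(-gamma (d - mu)^2);
        defaults to 1/(2 sigma^2), which reproduces the sigma form.
    """

    mu_min: float = -1.0
    mu_max: float = 10.0
    delta_mu: float = 0.2
    sigma: float = 0.2
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.delta_mu <= 0:
            raise ValueError("delta_mu must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.mu_max < self.mu_min:
            raise ValueError("mu_max must be >= mu_min")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    @property
    def centers(self) -> np.ndarray:
        # 1e-9 guard so e.g. (10 - (-1)) / 0.2 counts as 55 steps despite
        # the binary representation of 0.2 landing a hair under 55.0
        n = int(np.floor((self.mu_max - self.mu_min) / self.delta_mu + 1e-9)) + 1
        return self.mu_min + self.delta_mu * np.arange(n)

    @property
    def n_features(self) -> int:
        return self.centers.size

    @property
    def exponent(self) -> float:
        return self.gamma if self.gamma is not None else 1.0 / (2.0 * self.sigma**2)


def gaussian_expand(d: float, grid: GaussianGrid) -> np.ndarray:
    """Expand one distance (A) into its Gaussian feature vector."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return np.exp(-grid.exponent * (d - grid.centers) ** 2)


def expand_all(D: np.ndarray, grid: GaussianGrid) -> np.ndarray:
    """Expand a full distance matrix into an (N, N, G) feature tensor.

    The diagonal is present (expansion of d = 0) but interaction sums never
    consume it; symmetry in (i, j) is inherited from D.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"D must be square, got shape {D.shape}")
    return np.exp(-grid.exponent * (D[..., None] - grid.centers) ** 2)
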