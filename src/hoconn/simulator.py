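"""Benchmark network simulator and generic Gaussian data generation.

The seven-node benchmark is a linear structural-equation network: three
independent unit-variance sources X1, X4, X5 feed a common child X2; X2
drives X3 through a chain; X3 is a common driver of X6 and X7. Every node
receives an independent standard-Gaussian innovation. Because the system
is linear, the exact population covariance is available in closed form and
serves as the oracle for all estimator tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_core import TimeSeriesSet, ValidationError, get_logger, spawn_rng

__all__ = [
    "SimulationConfig",
    "NODE_LABELS",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_EDGE_MAP",
    "simulate_benchmark_network",
    "analytic_covariance",
    "gaussian_draws",
    "simulate_gaussian",
]

_log = get_logger(__name__)

NODE_LABELS: tuple[str, ...] = ("X1", "X2", "X3", "X4", "X5", "X6", "X7")

#: the six directed couplings of the benchmark network
_EDGES = frozenset({("X1", "X2"), ("X4", "X2"), ("X5", "X2"),
                    ("X2", "X3"), ("X3", "X6"), ("X3", "X7")})

DEFAULT_COEFFICIENTS: tuple[float, ...] = (0.99, 0.99, 1.0, 0.95, 0.95, 1.0)

#: default assignment of the six weights to directed edges. The three
#: source->child edges take the {0.99, 0.99, 1} group; the chain edge
#: X2->X3 takes weight 1 and the two driver edges X3->X6, X3->X7 take 0.95,
#: which keeps the population MI of all five strongly coupled pairs above
#: 0.5 nats. The assignment is configurable.
DEFAULT_EDGE_MAP: dict[int, tuple[str, str]] = {
    1: ("X1", "X2"),
    2: ("X4", "X2"),
    3: ("X5", "X2"),
    4: ("X3", "X6"),
    5: ("X3", "X7"),
    6: ("X2", "X3"),
}


@dataclass
class SimulationConfig:
    """Parameters of the seven-node benchmark network.

    ``coefficients[i]`` is the weight of the directed edge
    ``edge_map[i + 1]``; all weights must lie in (0, 1.5]. Innovations are
    zero-mean unit-variance Gaussians.
    """

    coefficients: tuple[float, ...] = DEFAULT_COEFFICIENTS
    n_samples: int = 500
    seed: int = 0
    edge_map: dict[int, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_MAP))

    def __post_init__(self) -> None:
        self.coefficients = tuple(float(a) for a in self.coefficients)
        if len(self.coefficients) != 6:
            raise ValidationError("exactly six coupling coefficients required")
        # zero is allowed so the fully decoupled network remains expressible
        if any(not 0.0 <= a <= 1.5 for a in self.coefficients):
            raise ValidationError("coefficients must lie in [0, 1.5]")
        if self.n_samples < 8:
            raise ValidationError("n_samples must be >= 8")
        edges = {tuple(e) for e in self.edge_map.values()}
        if set(self.edge_map) != {1, 2, 3, 4, 5, 6} or edges != set(_EDGES):
            raise ValidationError(
                f"edge_map must cover exactly the six edges {sorted(_EDGES)}")


def _structural_matrix(cfg: SimulationConfig) -> np.ndarray:
    """B with B[child, parent] = weight, node order X1..X7."""
    pos = {label: i for i, label in enumerate(NODE_LABELS)}
    b = np.zeros((7, 7))
    for param, (src, dst) in cfg.edge_map.items():
        b[pos[dst], pos[src]] = cfg.coefficients[param - 1]
    return b


def analytic_covariance(cfg: SimulationConfig) -> np.ndarray:
    """Exact population covariance implied by the structural equations.

    With X = B X + U and Cov(U) = I, the covariance is
    (I - B)^-1 (I - B)^-T; always positive definite.
    """
    ib_inv = np.linalg.inv(np.eye(7) - _structural_matrix(cfg))
    return ib_inv @ ib_inv.T


def simulate_benchmark_network(cfg: SimulationConfig) -> TimeSeriesSet:
    """Draw ``n_samples`` realizations of the seven-node benchmark network."""
    rng = spawn_rng(cfg.seed, "benchmark-network")
    _log.debug("simulate benchmark network: seed=%d, M=%d", cfg.seed, cfg.n_samples)
    innovations = rng.standard_normal((cfg.n_samples, 7))
    ib_inv = np.linalg.inv(np.eye(7) - _structural_matrix(cfg))
    data = innovations @ ib_inv.T
    return TimeSeriesSet(
        data=data, labels=NODE_LABELS,
        meta={"seed": cfg.seed, "coefficients": cfg.coefficients,
              "edge_map": {k: list(v) for k, v in cfg.edge_map.items()}})


def gaussian_draws(cov: np.ndarray, n_samples: int, seed: int) -> np.ndarray:
    """Raw zero-mean Gaussian draws, shape (n_samples, q); accepts q = 1."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    q = cov.shape[0]
    if cov.shape != (q, q) or not np.allclose(cov, cov.T):
        raise ValidationError("covariance must be a symmetric square matrix")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValidationError("covariance is not positive definite") from None
    rng = spawn_rng(seed, "gaussian-draws")
    return rng.standard_normal((n_samples, q)) @ chol.T


def simulate_gaussian(cov: np.ndarray, n_samples: int, seed: int,
                      labels: tuple[str, ...] | None = None,
                      rsn_map: Mapping[str, str] | None = None) -> TimeSeriesSet:
    """Zero-mean Gaussian draws with a given positive-definite covariance."""
    data = gaussian_draws(cov, n_samples, seed)
    q = data.shape[1]
    if labels is None:
        labels = tuple(f"S{i + 1}" for i in range(q))
    ts = TimeSeriesSet(data=data, labels=labels, meta={"seed": seed})
    if rsn_map is not None:
        from .io_core import bind_rsn_map
        ts = bind_rsn_map(ts, rsn_map)
    return ts
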