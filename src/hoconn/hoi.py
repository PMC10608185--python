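"""High-order interaction measures and multiplet handling.

The central quantity is the O-information of a group of N >= 2 variables:
zero for every pair, positive for redundancy-dominated groups, negative for
synergy-dominated ones. It is computed directly from Gaussian entropies of
the group covariance,

    Omega = (N - 2) H(S) + sum_j [H(S_j) - H(S minus j)],

which is the unrolled form of the add-one-variable recursion
``Omega(S) = Omega(S minus j) + Delta(S minus j; S_j)``; the recursion and
the increment formula

    Delta = (2 - N) I(S minus j; S_j) + sum_{m != j} I(S minus {m,j}; S_j)

are kept as tested identities rather than as the computational path.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gaussian_info import mi_from_covariance, mutual_information, sample_covariance, _logdet_pd
from .io_core import (
    InsufficientSamplesError,
    Multiplet,
    SamplingInfeasibleError,
    TimeSeriesSet,
    ValidationError,
    get_logger,
    spawn_rng,
)

__all__ = [
    "OIResult",
    "OIIncrement",
    "o_information",
    "o_information_from_covariance",
    "oi_increment",
    "enumerate_multiplets",
    "sample_multiplet_hierarchy",
    "read_multiplets",
    "write_multiplets",
]

_log = get_logger(__name__)


def _character(value: float) -> str:
    if value > 0.0:
        return "redundant"
    if value < 0.0:
        return "synergistic"
    return "balanced"


@dataclass
class OIResult:
    """O-information of one multiplet, in nats, with optional CI/significance."""

    multiplet: Multiplet
    order: int
    value: float
    character: str
    ci: tuple[float, float] | None = None
    significant: bool | None = None


@dataclass
class OIIncrement:
    """Change in O-information from adding ``target`` to the rest of the multiplet."""

    multiplet: Multiplet
    target: int
    value: float
    significant: bool | None = None


# ---------------------------------------------------------------------------
# O-information
# ---------------------------------------------------------------------------

def o_information_from_covariance(cov: np.ndarray) -> float:
    """O-information (nats) of jointly Gaussian variables with covariance ``cov``.

    The ``(2 pi e)`` entropy constants cancel, leaving a pure
    log-determinant combination. Returns exactly 0.0 for two variables.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n = cov.shape[0]
    if n < 2:
        raise ValidationError("O-information needs at least 2 variables")
    if n == 2:
        return 0.0
    ld_full = _logdet_pd(cov, what="multiplet covariance")
    total = (n - 2) * ld_full
    for j in range(n):
        keep = [i for i in range(n) if i != j]
        total += math.log(cov[j, j])
        total -= _logdet_pd(cov[np.ix_(keep, keep)], what="sub-multiplet covariance")
    return 0.5 * total


def _oi_from_cov_batch(covs: np.ndarray) -> np.ndarray:
    """Vectorized O-information over a stack of covariances ``(B, N, N)``.

    Replicates whose (sub)covariances are not positive definite come back
    as NaN instead of raising, so bootstrap loops can skip them.
    """
    covs = np.asarray(covs, dtype=float)
    b, n, _ = covs.shape
    if n == 2:
        return np.zeros(b)
    sign, ld_full = np.linalg.slogdet(covs)
    bad = sign <= 0
    total = (n - 2) * ld_full
    with np.errstate(invalid="ignore", divide="ignore"):
        for j in range(n):
            keep = [i for i in range(n) if i != j]
            total += np.log(covs[:, j, j])
            s, ld = np.linalg.slogdet(covs[:, keep][:, :, keep])
            bad |= s <= 0
            total -= ld
    total = 0.5 * total
    total[bad | ~np.isfinite(total)] = np.nan
    return total


def o_information(ts: TimeSeriesSet, m) -> OIResult:
    """O-information of a multiplet estimated from data.

    Exactly 0.0 for pairs; for N >= 3 the value is independent of any
    peel-off ordering because it is evaluated in closed form.
    """
    m = _as_group(m, ts)
    if m.order == 2:
        return OIResult(multiplet=m, order=2, value=0.0, character="balanced")
    if ts.n_samples <= m.order:
        raise InsufficientSamplesError(
            f"need M > N: M={ts.n_samples}, N={m.order}")
    cov = sample_covariance(ts, m)
    value = o_information_from_covariance(cov)
    return OIResult(multiplet=m, order=m.order, value=value,
                    character=_character(value))


def oi_increment(ts: TimeSeriesSet, m, target: int) -> OIIncrement:
    """Increment of O-information brought by ``target`` to the rest of ``m``.

    Evaluated term by term as a weighted sum of mutual informations; for
    N = 3 this is the interaction information of the triplet. Satisfies
    ``o_information(m) == o_information(m without target) + increment``.
    """
    m = _as_group(m, ts)
    target = int(target)
    if target not in m:
        raise ValidationError(f"target {target} not in multiplet {m.indices}")
    n = m.order
    if n < 3:
        raise ValidationError("OI increments are defined for multiplets of order >= 3")
    rest = m.without(target)
    tgt = Multiplet((target,))
    value = (2 - n) * mutual_information(ts, rest, tgt).value
    for other in rest:
        value += mutual_information(ts, rest.without(other), tgt).value
    return OIIncrement(multiplet=m, target=target, value=value)


def oi_increment_from_covariance(cov: np.ndarray, pos: int) -> float:
    """Population OI increment for the variable at position ``pos`` of ``cov``."""
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if n < 3:
        raise ValidationError("OI increments need at least 3 variables")
    rest = [i for i in range(n) if i != pos]

    def _mi(sources: list[int]) -> float:
        order = sources + [pos]
        sub = cov[np.ix_(order, order)]
        return mi_from_covariance(sub, len(sources))

    value = (2 - n) * _mi(rest)
    for other in rest:
        value += _mi([i for i in rest if i != other])
    return value


def _as_group(m, ts: TimeSeriesSet) -> Multiplet:
    mult = m if isinstance(m, Multiplet) else Multiplet(tuple(m))
    if mult.order < 2:
        raise ValidationError("joint analysis needs a multiplet of order >= 2")
    if mult.indices[-1] >= ts.n_channels:
        raise ValidationError(
            f"multiplet {mult.indices} out of range for Q={ts.n_channels}")
    return mult


# ---------------------------------------------------------------------------
# multiplet enumeration and sampling
# ---------------------------------------------------------------------------

def enumerate_multiplets(q: int, n: int) -> list[Multiplet]:
    """All C(q, n) canonical multiplets of order ``n``, lexicographic order."""
    if n < 2:
        raise ValidationError("multiplet order must be >= 2")
    if n > q:
        raise ValidationError(f"order {n} exceeds channel count {q}")
    return [Multiplet(c) for c in combinations(range(q), n)]


def sample_multiplet_hierarchy(
    ts: TimeSeriesSet,
    counts_per_order: Mapping[int, int],
    seed: int,
) -> dict[int, list[Multiplet]]:
    """Random multiplet hierarchy constrained by the channel network map.

    Order-3 multiplets are drawn (without replacement) from triplets whose
    three channels lie in pairwise-distinct networks. Each order-(N+1)
    multiplet extends a randomly chosen sampled order-N multiplet with a
    channel from a network not yet represented in it; when no unrepresented
    network has channels left, the extension falls back to any unused
    channel (logged). Deterministic for a fixed seed; parentage is logged.
    """
    if ts.rsn_map is None:
        raise ValidationError("multiplet hierarchy sampling needs an rsn_map")
    orders = sorted(int(o) for o in counts_per_order)
    if not orders or orders[0] != 3 or orders != list(range(3, 3 + len(orders))):
        raise ValidationError(
            "counts_per_order must cover consecutive orders starting at 3")
    rng = spawn_rng(seed, "multiplet-hierarchy")
    nets = [ts.rsn_map[l] for l in ts.labels]

    cross = [Multiplet(c) for c in combinations(range(ts.n_channels), 3)
             if len({nets[i] for i in c}) == 3]
    want3 = int(counts_per_order[3])
    if want3 > len(cross):
        raise SamplingInfeasibleError(
            f"requested {want3} distinct-network triplets but only "
            f"{len(cross)} exist")
    picked = rng.choice(len(cross), size=want3, replace=False)
    hierarchy: dict[int, list[Multiplet]] = {3: [cross[i] for i in sorted(picked)]}

    for order in orders[1:]:
        want = int(counts_per_order[order])
        parents = hierarchy[order - 1]
        chosen: list[Multiplet] = []
        seen: set[tuple[int, ...]] = set()
        attempts = 0
        max_attempts = 1000 * max(want, 1) + 1000
        while len(chosen) < want:
            attempts += 1
            if attempts > max_attempts:
                raise SamplingInfeasibleError(
                    f"could not draw {want} distinct multiplets of order {order}")
            parent = parents[rng.integers(len(parents))]
            represented = {nets[i] for i in parent}
            fresh = [i for i in range(ts.n_channels)
                     if i not in parent and nets[i] not in represented]
            if not fresh:
                fresh = [i for i in range(ts.n_channels) if i not in parent]
                if not fresh:
                    continue
                _log.debug("order-%d extension of %s falls back to represented "
                           "networks (all networks in use)", order, parent.indices)
            extension = int(fresh[rng.integers(len(fresh))])
            candidate = Multiplet(parent.indices + (extension,))
            if candidate.indices in seen:
                continue
            seen.add(candidate.indices)
            chosen.append(candidate)
            _log.debug("order-%d multiplet %s extends root %s with channel %d",
                       order, candidate.indices, parent.indices, extension)
        hierarchy[order] = chosen
    _log.info("sampled multiplet hierarchy (seed=%d): %s", seed,
              {o: len(ms) for o, ms in hierarchy.items()})
    return hierarchy


# ---------------------------------------------------------------------------
# multiplet list JSON
# ---------------------------------------------------------------------------

def write_multiplets(path: str | Path,
                     hierarchy: Mapping[int, Sequence[Multiplet]],
                     labels: Sequence[str]) -> None:
    """Write a multiplet hierarchy as a JSON array of {order, channels} objects."""
    records = [
        {"order": int(order), "channels": list(m.labelled(labels))}
        for order in sorted(hierarchy)
        for m in hierarchy[order]
    ]
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_multiplets(path: str | Path,
                    labels: Sequence[str]) -> dict[int, list[Multiplet]]:
    """Read a multiplet JSON file, resolving channel labels against ``labels``."""
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise ValidationError(f"{path}: multiplet file must hold a JSON array")
    index = {l: i for i, l in enumerate(labels)}
    hierarchy: dict[int, list[Multiplet]] = {}
    for rec in records:
        channels = rec["channels"]
        missing = [c for c in channels if c not in index]
        if missing:
            raise ValidationError(f"{path}: unknown channel labels {missing}")
        m = Multiplet(tuple(index[c] for c in channels))
        order = int(rec.get("order", m.order))
        if order != m.order:
            raise ValidationError(
                f"{path}: declared order {order} != channel count {m.order}")
        hierarchy.setdefault(order, []).append(m)
    return hierarchy
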