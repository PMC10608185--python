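"""Statistical validation engines: iAAFT surrogates and block bootstrap.

Two independent resampling schemes back the significance machinery:

* **iAAFT surrogates** destroy cross-channel coupling while preserving each
  channel's amplitude distribution exactly and its power spectrum to within
  a tolerance; the (1 - alpha) percentile of the surrogate MI distribution
  gives a per-pair significance threshold.
* **Block bootstrap** resamples the k = floor(M/L) non-overlapping blocks
  of length L with replacement, applying the same block draw to every
  channel so coupling is preserved; the resulting measure distributions
  give percentile confidence intervals, a zero-in-CI significance rule for
  the O-information, and the inputs of unpaired Student t-tests for
  order-to-order increments and between-condition differences.

All percentile computations go through :func:`percentile` (linear
interpolation between order statistics) so every consumer shares one rule.
Randomness derives from a master seed via per-(operation, measure,
replicate) child streams, making ensembles bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .gaussian_info import MIEstimate, mutual_information
from .hoi import _oi_from_cov_batch, oi_increment_from_covariance
from .io_core import (
    DegenerateChannelError,
    HoconnError,
    Multiplet,
    ResamplingConfig,
    TimeSeriesSet,
    ValidationError,
    as_multiplet,
    get_logger,
    spawn_rng,
)

__all__ = [
    "SurrogateEnsemble",
    "BootstrapEnsemble",
    "MeasureSpec",
    "ConditionDecision",
    "percentile",
    "iaaft_surrogate",
    "mi_significance",
    "block_bootstrap",
    "bootstrap_distribution",
    "oi_zero_significance",
    "increment_significance",
    "condition_difference",
]

_log = get_logger(__name__)


def percentile(values: np.ndarray, q: float) -> float:
    """The q-th percentile (0..100) with linear interpolation between order stats."""
    return float(np.percentile(np.asarray(values, dtype=float), q, method="linear"))


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class SurrogateEnsemble:
    """Surrogate MI values, the derived threshold and the significance decision."""

    measure_values: np.ndarray
    threshold: float
    decision: bool


@dataclass
class BootstrapEnsemble:
    """Bootstrap values of one measure with its percentile confidence interval."""

    measure_values: np.ndarray
    ci: tuple[float, float]
    measure_id: str
    n_skipped: int = 0


@dataclass(frozen=True)
class MeasureSpec:
    """Identifies the measure a bootstrap distribution describes."""

    kind: Literal["mi", "oi", "doi"]
    x: Multiplet | None = None
    y: Multiplet | None = None
    multiplet: Multiplet | None = None
    target: int | None = None

    @classmethod
    def mi(cls, x, y) -> "MeasureSpec":
        return cls(kind="mi", x=as_multiplet(x), y=as_multiplet(y))

    @classmethod
    def oi(cls, m) -> "MeasureSpec":
        return cls(kind="oi", multiplet=as_multiplet(m))

    @classmethod
    def doi(cls, m, target: int) -> "MeasureSpec":
        m = as_multiplet(m)
        if target not in m:
            raise ValidationError(f"target {target} not in multiplet {m.indices}")
        return cls(kind="doi", multiplet=m, target=int(target))

    @property
    def measure_id(self) -> str:
        if self.kind == "mi":
            return f"mi:{self.x.key()}|{self.y.key()}"
        if self.kind == "oi":
            return f"oi:{self.multiplet.key()}"
        return f"doi:{self.multiplet.key()}>{self.target}"


@dataclass
class ConditionDecision:
    """Outcome of a between-condition comparison for one measure."""

    measure_id: str
    delta: float
    decision: Literal["higher", "lower", "no difference"]
    p_value: float


# ---------------------------------------------------------------------------
# iAAFT surrogates
# ---------------------------------------------------------------------------

def _iaaft_batch(series: np.ndarray, n_surr: int, rng: np.random.Generator,
                 max_iter: int, tol: float) -> np.ndarray:
    """Generate ``n_surr`` iAAFT surrogates of a single channel, vectorized.

    Each surrogate starts from an independent random permutation of the
    original values, then alternates a spectrum-adjustment step (impose the
    original Fourier amplitudes, keep current phases) with an amplitude-
    adjustment step (rank-remap onto the original sorted values). A
    surrogate is converged when its rank permutation stabilizes or its
    relative amplitude-spectrum error drops below ``tol``.
    """
    x = np.asarray(series, dtype=float)
    m = x.size
    if m < 8:
        raise ValidationError(f"iAAFT needs at least 8 samples, got {m}")
    if np.ptp(x) == 0.0:
        raise DegenerateChannelError("cannot build surrogates of a constant series")
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    target_norm = np.linalg.norm(target_amp)

    # independent random starting permutations
    perm = np.argsort(rng.random((n_surr, m)), axis=1)
    surr = x[perm]
    prev_order = np.full((n_surr, m), -1, dtype=np.int64)
    active = np.arange(n_surr)
    for _ in range(max_iter):
        spec = np.fft.rfft(surr[active], axis=1)
        amp = np.abs(spec)
        err = np.linalg.norm(amp - target_amp, axis=1) / target_norm
        phases = np.angle(spec)
        candidate = np.fft.irfft(target_amp * np.exp(1j * phases), n=m, axis=1)
        # rank-remap candidate onto the original amplitude distribution
        order = np.argsort(candidate, axis=1)
        remapped = np.empty_like(candidate)
        np.put_along_axis(remapped, order, sorted_x[None, :], axis=1)
        stable = np.all(order == prev_order[active], axis=1)
        surr[active] = remapped
        prev_order[active] = order
        keep = ~(stable | (err < tol))
        active = active[keep]
        if active.size == 0:
            break
    return surr


def iaaft_surrogate(series: np.ndarray, seed: int,
                    max_iter: int = 100, tol: float = 1e-4) -> np.ndarray:
    """One iAAFT surrogate of a single channel.

    The surrogate's sorted values equal the original's sorted values
    exactly; its periodogram matches the original's within ``tol`` relative
    error or until ``max_iter`` iterations are spent.
    """
    rng = spawn_rng(seed, "iaaft")
    return _iaaft_batch(series, 1, rng, max_iter, tol)[0]


def _scalar_mi_batch(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Regression MI for rows of paired scalar series (vectorized Eq. form)."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    var_x = np.sum(xc * xc, axis=1)
    var_y = np.sum(yc * yc, axis=1)
    cov = np.sum(xc * yc, axis=1)
    resid = var_x - cov * cov / var_y
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 0.5 * (np.log(var_x) - np.log(resid))
    return vals


def mi_significance(ts: TimeSeriesSet, i, j, cfg: ResamplingConfig) -> MIEstimate:
    """Surrogate-data significance test of the MI between channels ``i`` and ``j``.

    ``n_surrogates`` independent surrogate *pairs* are generated (each
    channel phase-randomized independently), the MI is recomputed on every
    pair, and the threshold is the 100(1 - alpha) percentile of that
    distribution. The original MI is significant when it exceeds the
    threshold strictly.
    """
    i = ts.index(i) if isinstance(i, str) else int(i)
    j = ts.index(j) if isinstance(j, str) else int(j)
    if i == j:
        raise ValidationError("cannot test a channel against itself")
    est = mutual_information(ts, (i,), (j,))
    rng = spawn_rng(cfg.seed, "mi-surrogate", i, j)
    _log.debug("mi_significance pair (%d,%d): master seed %d", i, j, cfg.seed)
    xs = _iaaft_batch(ts.data[:, i], cfg.n_surrogates, rng,
                      cfg.iaaft_max_iter, cfg.iaaft_tol)
    ys = _iaaft_batch(ts.data[:, j], cfg.n_surrogates, rng,
                      cfg.iaaft_max_iter, cfg.iaaft_tol)
    surrogate_mi = _scalar_mi_batch(xs, ys)
    threshold = percentile(surrogate_mi, 100.0 * (1.0 - cfg.alpha))
    est.threshold = threshold
    est.significant = bool(est.value > threshold)
    est.meta["surrogates"] = SurrogateEnsemble(
        measure_values=surrogate_mi, threshold=threshold,
        decision=est.significant)
    return est


# ---------------------------------------------------------------------------
# block bootstrap
# ---------------------------------------------------------------------------

def _block_pool(m: int, length: int) -> int:
    """Number of usable non-overlapping blocks; remainder samples are dropped."""
    if length > m:
        raise ValidationError(f"block length {length} exceeds series length {m}")
    return m // length


def _bootstrap_rows(m: int, length: int, n_rep: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Row indices of ``n_rep`` bootstrap pseudo-series, shape (n_rep, k*L).

    Blocks are the k = floor(M/L) contiguous non-overlapping segments
    starting at 0, L, 2L, ...; k of them are drawn *with replacement* per
    replicate, and the same draw is applied to all channels by the caller.
    """
    k = _block_pool(m, length)
    picks = rng.integers(0, k, size=(n_rep, k))
    offsets = np.arange(length)
    return (picks[:, :, None] * length + offsets[None, None, :]).reshape(n_rep, k * length)


def block_bootstrap(ts: TimeSeriesSet, cfg: ResamplingConfig,
                    seed: int | None = None) -> TimeSeriesSet:
    """One bootstrap pseudo-realization of all channels jointly.

    The same randomly chosen block sequence is applied to every channel,
    preserving cross-channel coupling. With ``block_length == M`` the
    output is identical to the input.
    """
    rng = spawn_rng(cfg.seed if seed is None else seed, "block-bootstrap")
    rows = _bootstrap_rows(ts.n_samples, cfg.block_length, 1, rng)[0]
    return ts.with_data(ts.data[rows], bootstrap=True)


def _measure_values(ts: TimeSeriesSet, measure: MeasureSpec,
                    rows: np.ndarray) -> np.ndarray:
    """Evaluate a measure on every bootstrap replicate (NaN where singular)."""
    n_rep = rows.shape[0]
    if measure.kind == "mi" and measure.x.order == 1 and measure.y.order == 1:
        xs = ts.data[:, measure.x.indices[0]][rows]
        ys = ts.data[:, measure.y.indices[0]][rows]
        return _scalar_mi_batch(xs, ys)
    if measure.kind == "oi":
        cols = list(measure.multiplet)
        block = ts.data[:, cols][rows]                       # (B, M', N)
        centered = block - block.mean(axis=1, keepdims=True)
        covs = np.einsum("bmi,bmj->bij", centered, centered) / (rows.shape[1] - 1)
        return _oi_from_cov_batch(covs)
    values = np.empty(n_rep)
    for b in range(n_rep):
        boot = ts.with_data(ts.data[rows[b]], bootstrap=True)
        try:
            if measure.kind == "mi":
                values[b] = mutual_information(boot, measure.x, measure.y).value
            else:  # doi
                from .hoi import oi_increment
                values[b] = oi_increment(boot, measure.multiplet,
                                         measure.target).value
        except HoconnError:
            values[b] = np.nan
    return values


def bootstrap_distribution(ts: TimeSeriesSet, measure: MeasureSpec,
                           cfg: ResamplingConfig) -> BootstrapEnsemble:
    """Block-bootstrap distribution of one measure with its percentile CI.

    Singular replicates are skipped and logged; more than 10% skipped
    raises a distribution-failure error. Reproducible under a fixed seed.
    """
    rng = spawn_rng(cfg.seed, "bootstrap", measure.measure_id)
    _log.debug("bootstrap %s: seed %d, Nb=%d, L=%d", measure.measure_id,
               cfg.seed, cfg.n_bootstrap, cfg.block_length)
    rows = _bootstrap_rows(ts.n_samples, cfg.block_length, cfg.n_bootstrap, rng)
    values = _measure_values(ts, measure, rows)
    good = np.isfinite(values)
    n_skipped = int(np.sum(~good))
    if n_skipped:
        _log.warning("bootstrap %s: skipped %d singular replicates",
                     measure.measure_id, n_skipped)
    if n_skipped > 0.1 * cfg.n_bootstrap:
        raise HoconnError(
            f"bootstrap distribution failure for {measure.measure_id}: "
            f"{n_skipped}/{cfg.n_bootstrap} replicates singular")
    values = values[good]
    lo = percentile(values, 100.0 * cfg.alpha / 2.0)
    hi = percentile(values, 100.0 * (1.0 - cfg.alpha / 2.0))
    return BootstrapEnsemble(measure_values=values, ci=(lo, hi),
                             measure_id=measure.measure_id, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# significance rules
# ---------------------------------------------------------------------------

def oi_zero_significance(ens: BootstrapEnsemble, alpha: float) -> bool:
    """Zero-in-CI rule: NOT significant iff 0 lies strictly inside the
    (100*alpha/2, 100*(1-alpha/2)) percentile interval of the ensemble."""
    if ens.measure_values.size == 0:
        raise ValidationError("empty bootstrap ensemble")
    lo = percentile(ens.measure_values, 100.0 * alpha / 2.0)
    hi = percentile(ens.measure_values, 100.0 * (1.0 - alpha / 2.0))
    if lo == 0.0 and hi == 0.0:
        # degenerate all-zero distribution (e.g. the OI of a pair)
        return False
    return not (lo < 0.0 < hi)


def _unpaired_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Classical (equal-variance) unpaired Student t-test p-value.

    Degenerate zero-variance ensembles with equal means yield p = 1 by
    convention (logged).
    """
    res = stats.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p):
        _log.warning("t-test undefined (zero variance both sides); p set to 1")
        return 1.0
    return p


def increment_significance(ens_high: BootstrapEnsemble,
                           ens_root: BootstrapEnsemble,
                           alpha: float) -> bool:
    """Is the OI increment from root (order N-1) to multiplet (order N)
    significant? Unpaired Student t-test between the two bootstrap
    distributions at level ``alpha``."""
    p = _unpaired_t_pvalue(ens_high.measure_values, ens_root.measure_values)
    return bool(p < alpha)


def condition_difference(ens_a: BootstrapEnsemble, ens_b: BootstrapEnsemble,
                         alpha: float) -> ConditionDecision:
    """Signed between-condition decision for one shared measure.

    ``delta = mean(b) - mean(a)``; the decision is "higher"/"lower" when
    the unpaired Student t-test rejects at ``alpha``, else "no difference".
    """
    if ens_a.measure_id != ens_b.measure_id:
        raise ValidationError(
            f"measure mismatch: {ens_a.measure_id} vs {ens_b.measure_id}")
    delta = float(np.mean(ens_b.measure_values) - np.mean(ens_a.measure_values))
    p = _unpaired_t_pvalue(ens_a.measure_values, ens_b.measure_values)
    if p < alpha:
        decision = "higher" if delta > 0 else "lower"
    else:
        decision = "no difference"
    return ConditionDecision(measure_id=ens_a.measure_id, delta=delta,
                             decision=decision, p_value=p)
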