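"""Shared data model, file I/O, configuration and logging.

All other modules build on the three core types defined here:

* :class:`TimeSeriesSet` -- an ``M x Q`` matrix of synchronous channel
  recordings with unique channel labels and an optional grouping of
  channels into named networks.
* :class:`Multiplet` -- a canonical (sorted, duplicate-free) group of
  channel indices analysed jointly.
* :class:`ResamplingConfig` -- the knobs of the statistical-validation
  engines (surrogate count, bootstrap count, block length, significance
  level, seeds).

Time series travel as delimited text with a header row of labels; network
maps as two-column CSV; configuration as JSON or YAML.
"""

from __future__ import annotations

import csv
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HoconnError",
    "ValidationError",
    "FormatError",
    "ParseError",
    "DegenerateChannelError",
    "InsufficientSamplesError",
    "SingularityError",
    "InfiniteInformationError",
    "SamplingInfeasibleError",
    "TimeSeriesSet",
    "Multiplet",
    "ResamplingConfig",
    "as_multiplet",
    "read_timeseries",
    "write_timeseries",
    "read_rsn_map",
    "standardize",
    "load_config",
    "spawn_rng",
    "get_logger",
    "configure_logging",
]


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class HoconnError(Exception):
    """Base class for all package errors."""


class ValidationError(HoconnError):
    """Input violates a documented precondition or invariant."""


class FormatError(HoconnError):
    """Structurally malformed file (ragged rows, wrong column count)."""


class ParseError(HoconnError):
    """A cell of a data file could not be interpreted as a number."""


class DegenerateChannelError(ValidationError):
    """A channel is constant (zero variance) where variability is required."""


class InsufficientSamplesError(ValidationError):
    """Fewer time points than the operation needs."""


class SingularityError(HoconnError):
    """A covariance matrix is singular or numerically indefinite."""


class InfiniteInformationError(SingularityError):
    """Residual covariance singular: deterministic linear dependence."""


class SamplingInfeasibleError(HoconnError):
    """Requested multiplet counts cannot be realised for this channel/network layout."""


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------

_LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def get_logger(name: str = "hoconn") -> logging.Logger:
    return logging.getLogger(name)


def configure_logging(verbosity: int = 1, logfile: str | None = None) -> None:
    """Attach a timestamped handler; verbosity 0=WARNING, 1=INFO, >=2=DEBUG."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    root = get_logger()
    root.setLevel(level)
    handler: logging.Handler
    handler = logging.FileHandler(logfile) if logfile else logging.StreamHandler()
    handler.setFormatter(logging.Formatter(_LOG_FORMAT))
    root.addHandler(handler)


_log = get_logger(__name__)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def spawn_rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic child generator derived from a master ``seed``.

    ``tags`` (operation name, pair/multiplet id, replicate index, ...) are
    hashed into a spawn key so that every stochastic unit of work gets an
    independent, reproducible stream.
    """
    key = tuple(zlib.crc32(str(t).encode("utf-8")) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesSet:
    """An observed realization of Q channels over M synchronous time points.

    Parameters
    ----------
    data
        Real matrix of shape ``(M, Q)``; one column per channel.
    labels
        Q unique channel identifiers, in column order.
    rsn_map
        Optional mapping ``label -> network name``; when present it must
        cover every label exactly once.
    meta
        Free-form provenance (condition tag, seed, source file).
    """

    data: np.ndarray
    labels: tuple[str, ...]
    rsn_map: dict[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(str(l) for l in self.labels)
        if self.data.ndim != 2:
            raise ValidationError("time-series data must be a 2-D matrix")
        m, q = self.data.shape
        if m < 2:
            raise ValidationError(f"need at least 2 time points, got M={m}")
        if q < 2:
            raise ValidationError(f"need at least 2 channels, got Q={q}")
        if len(self.labels) != q:
            raise ValidationError(
                f"{len(self.labels)} labels for {q} data columns")
        if len(set(self.labels)) != q:
            raise ValidationError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"non-finite value at row {bad[0] + 1}, "
                f"column '{self.labels[bad[1]]}' (missing values are rejected)")
        if self.rsn_map is not None:
            missing = [l for l in self.labels if l not in self.rsn_map]
            if missing:
                raise ValidationError(
                    f"rsn_map lacks network names for labels: {missing}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown channel label '{label}'") from None

    def channel(self, i: int | str) -> np.ndarray:
        if isinstance(i, str):
            i = self.index(i)
        return self.data[:, i]

    def with_data(self, data: np.ndarray, **meta) -> "TimeSeriesSet":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return TimeSeriesSet(data=data, labels=self.labels,
                             rsn_map=None if self.rsn_map is None else dict(self.rsn_map),
                             meta=new_meta)

    def networks(self) -> dict[str, list[int]]:
        """Channel indices grouped by network, in first-appearance order."""
        if self.rsn_map is None:
            raise ValidationError("no rsn_map attached to this TimeSeriesSet")
        groups: dict[str, list[int]] = {}
        for i, label in enumerate(self.labels):
            groups.setdefault(self.rsn_map[label], []).append(i)
        return groups


@dataclass(frozen=True)
class Multiplet:
    """A canonical group of distinct channel indices analysed jointly.

    Indices are stored sorted increasing. Groups of size one are allowed so
    that single channels can take the role of a regression block; joint
    high-order analyses require size >= 2 and enforce it at the call site.
    """

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        if len(idx) == 0:
            raise ValidationError("a multiplet needs at least one index")
        if len(set(idx)) != len(idx):
            raise ValidationError(f"duplicate channel indices in multiplet {idx}")
        if any(i < 0 for i in idx):
            raise ValidationError("channel indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    @property
    def order(self) -> int:
        return len(self.indices)

    def __contains__(self, j: int) -> bool:
        return int(j) in self.indices

    def __iter__(self):
        return iter(self.indices)

    def without(self, j: int) -> "Multiplet":
        """The multiplet with channel ``j`` removed."""
        if j not in self:
            raise ValidationError(f"channel {j} not in multiplet {self.indices}")
        return Multiplet(tuple(i for i in self.indices if i != j))

    def labelled(self, labels: Sequence[str]) -> tuple[str, ...]:
        return tuple(labels[i] for i in self.indices)

    def key(self) -> str:
        return "-".join(str(i) for i in self.indices)


def as_multiplet(spec: "Multiplet | int | Iterable[int]") -> Multiplet:
    """Coerce an int, an index iterable or a Multiplet into a Multiplet."""
    if isinstance(spec, Multiplet):
        return spec
    if isinstance(spec, (int, np.integer)):
        return Multiplet((int(spec),))
    return Multiplet(tuple(spec))


@dataclass
class ResamplingConfig:
    """Controls of the surrogate and bootstrap validation engines."""

    n_surrogates: int = 300
    n_bootstrap: int = 300
    block_length: int = 50
    alpha: float = 0.05
    seed: int = 0
    iaaft_max_iter: int = 100
    iaaft_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValidationError("n_surrogates must be >= 1")
        if self.n_bootstrap < 2:
            raise ValidationError("n_bootstrap must be >= 2")
        if self.block_length < 1:
            raise ValidationError("block_length must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie strictly between 0 and 1")
        if self.iaaft_max_iter < 1:
            raise ValidationError("iaaft_max_iter must be >= 1")
        if self.iaaft_tol <= 0:
            raise ValidationError("iaaft_tol must be positive")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path, delimiter: str = ",") -> TimeSeriesSet:
    """Read a delimited text file with a header row of channel labels.

    Every data row holds one time point; column order is preserved.
    Ragged rows raise :class:`FormatError`; non-numeric (or missing) cells
    raise :class:`ParseError` naming the offending row and column;
    duplicate labels raise :class:`ValidationError`.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
    if not first.strip():
        raise ValidationError(f"{path}: empty file")
    labels = [c.strip() for c in next(csv.reader([first], delimiter=delimiter))]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"{path}: duplicate channel labels {dupes}")
    try:
        frame = pd.read_csv(path, sep=delimiter, header=0, skip_blank_lines=True,
                            float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed table ({exc})") from exc
    if frame.shape[1] != len(labels):
        raise FormatError(f"{path}: inconsistent column count")
    if frame.shape[0] < 2:
        raise ValidationError(
            f"{path}: need at least 2 data rows, found {frame.shape[0]}")
    columns = []
    for pos in range(frame.shape[1]):
        converted = pd.to_numeric(frame.iloc[:, pos], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric or missing value in column "
                f"'{labels[pos]}' at data row {bad[0] + 1}")
        columns.append(converted.to_numpy(dtype=float))
    data = np.column_stack(columns)
    return TimeSeriesSet(data=data, labels=tuple(labels),
                         meta={"source": str(path)})


def write_timeseries(ts: TimeSeriesSet, path: str | Path,
                     delimiter: str = ",") -> None:
    """Write a TimeSeriesSet as delimited text at full double precision."""
    path = Path(path)
    header = delimiter.join(ts.labels)
    np.savetxt(path, ts.data, fmt="%.17g", delimiter=delimiter,
               header=header, comments="")


def read_rsn_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``label,network`` CSV into a mapping.

    A first row of exactly ``label,network`` is treated as a header.
    Duplicate labels and empty files are rejected.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    if rows and [c.strip().lower() for c in rows[0]] == ["label", "network"]:
        rows = rows[1:]
    if not rows:
        raise ValidationError(f"{path}: empty network map")
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 2:
            raise FormatError(
                f"{path}: expected two columns at row {lineno}, got {len(row)}")
        label, network = row[0].strip(), row[1].strip()
        if not label or not network:
            raise ValidationError(f"{path}: blank label or network at row {lineno}")
        if label in mapping:
            raise ValidationError(f"{path}: duplicated label '{label}'")
        mapping[label] = network
    return mapping


def bind_rsn_map(ts: TimeSeriesSet, rsn_map: Mapping[str, str]) -> TimeSeriesSet:
    """Attach a network map to a TimeSeriesSet, validating label coverage."""
    missing = [l for l in ts.labels if l not in rsn_map]
    if missing:
        raise ValidationError(f"network map lacks labels: {missing}")
    return TimeSeriesSet(data=ts.data, labels=ts.labels,
                         rsn_map={l: rsn_map[l] for l in ts.labels},
                         meta=dict(ts.meta))


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(ts: TimeSeriesSet) -> TimeSeriesSet:
    """Remove each channel's mean and scale to unit sample standard deviation.

    The unbiased (M-1) denominator is used, matching the covariance
    convention of the information estimators. Constant channels raise
    :class:`DegenerateChannelError` naming the label. Idempotent within
    numerical tolerance.
    """
    mean = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise DegenerateChannelError(
            f"constant channel(s): {[ts.labels[i] for i in dead]}")
    out = ts.with_data((ts.data - mean) / sd, standardized=True)
    return out


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a JSON (``.json``) or YAML (anything else) configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        loaded = json.loads(text)
    else:
        loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return loaded


def resampling_config_from_dict(cfg: Mapping) -> ResamplingConfig:
    known = {f for f in ResamplingConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in cfg.items() if k in known}
    return ResamplingConfig(**kwargs)
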