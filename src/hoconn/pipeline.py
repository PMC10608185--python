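"""Full single-subject analysis: pairwise network, high-order multiplets,
validation, densities, and between-condition comparison.

``run_pairwise`` tests every channel pair with the surrogate-data engine
and reports the MI matrix, significance mask and global/local densities.
``run_hoi`` attaches bootstrap confidence intervals and significance to the
O-information of each analysed multiplet and to every per-target increment.
``compare_conditions`` matches the bootstrap ensembles of two conditions
measure by measure with unpaired t-tests. Reports serialize to plain CSV
and JSON at full double precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hoi import OIIncrement, OIResult, o_information, oi_increment
from .io_core import (
    Multiplet,
    ResamplingConfig,
    TimeSeriesSet,
    ValidationError,
    get_logger,
)
from .resampling import (
    BootstrapEnsemble,
    ConditionDecision,
    MeasureSpec,
    bootstrap_distribution,
    condition_difference,
    increment_significance,
    mi_significance,
    oi_zero_significance,
)

__all__ = [
    "ConnectivityReport",
    "HOIReport",
    "ComparisonReport",
    "DensityReport",
    "run_pairwise",
    "run_hoi",
    "compare_conditions",
    "compute_densities",
    "write_connectivity_report",
    "write_hoi_report",
    "write_comparison_report",
    "write_density_report",
]

_log = get_logger(__name__)


# ---------------------------------------------------------------------------
# report types
# ---------------------------------------------------------------------------

@dataclass
class DensityReport:
    """Global and per-network-block percentages of significant links."""

    global_density: float
    local: pd.DataFrame | None = None        # % significant, NaN when undefined
    local_counts: pd.DataFrame | None = None  # significant pairs per block
    local_pairs: pd.DataFrame | None = None   # total pairs per block


@dataclass
class ConnectivityReport:
    """Pairwise MI network with significance mask and densities."""

    labels: tuple[str, ...]
    mi_matrix: np.ndarray
    significance_mask: np.ndarray
    densities: DensityReport
    thresholds: np.ndarray | None = None
    ensembles: dict[str, BootstrapEnsemble] = field(default_factory=dict)

    @property
    def global_density(self) -> float:
        return self.densities.global_density


@dataclass
class HOIReport:
    """O-information results, per-target increments and significance rates."""

    oi_results: dict[int, list[OIResult]]
    increments: dict[int, list[OIIncrement]]
    significance_rate: dict[int, float]
    ensembles: dict[str, BootstrapEnsemble] = field(default_factory=dict)


@dataclass
class ComparisonReport:
    """Signed between-condition decisions, one per shared measure.

    Sign convention: delta = condition_b - condition_a.
    """

    decisions: list[ConditionDecision]


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def compute_densities(mask: np.ndarray,
                      labels: Sequence[str] | None = None,
                      rsn_map: Mapping[str, str] | None = None) -> DensityReport:
    """Percentage of significant links globally and per network block.

    ``local[g, h]`` covers all pairs with one channel in network ``g`` and
    one in ``h`` (within-network blocks use C(n, 2) pairs); within-network
    cells for single-channel networks are undefined (NaN).
    """
    mask = np.asarray(mask, dtype=bool)
    q = mask.shape[0]
    if mask.shape != (q, q) or not np.array_equal(mask, mask.T):
        raise ValidationError("significance mask must be a symmetric square matrix")
    iu = np.triu_indices(q, k=1)
    n_pairs = q * (q - 1) // 2
    n_sig = int(mask[iu].sum())
    global_density = 100.0 * n_sig / n_pairs
    if rsn_map is None:
        return DensityReport(global_density=global_density)
    if labels is None:
        raise ValidationError("labels are required to compute local densities")
    groups: dict[str, list[int]] = {}
    for i, label in enumerate(labels):
        groups.setdefault(rsn_map[label], []).append(i)
    names = list(groups)
    counts = pd.DataFrame(np.nan, index=names, columns=names)
    totals = pd.DataFrame(np.nan, index=names, columns=names)
    local = pd.DataFrame(np.nan, index=names, columns=names)
    for gi, g in enumerate(names):
        for h in names[gi:]:
            ia, ib = groups[g], groups[h]
            if g == h:
                total = len(ia) * (len(ia) - 1) // 2
                sig = int(mask[np.ix_(ia, ia)][np.triu_indices(len(ia), k=1)].sum())
            else:
                total = len(ia) * len(ib)
                sig = int(mask[np.ix_(ia, ib)].sum())
            counts.loc[g, h] = counts.loc[h, g] = sig
            totals.loc[g, h] = totals.loc[h, g] = total
            if total > 0:
                local.loc[g, h] = local.loc[h, g] = 100.0 * sig / total
    return DensityReport(global_density=global_density, local=local,
                         local_counts=counts, local_pairs=totals)


# ---------------------------------------------------------------------------
# pairwise analysis
# ---------------------------------------------------------------------------

def run_pairwise(ts: TimeSeriesSet, cfg: ResamplingConfig,
                 collect_bootstrap: bool = False) -> ConnectivityReport:
    """Surrogate-validated MI network over all channel pairs.

    When ``collect_bootstrap`` is set, a block-bootstrap MI ensemble is also
    computed per pair, enabling between-condition comparison.
    """
    q = ts.n_channels
    mi = np.full((q, q), np.nan)
    mask = np.zeros((q, q), dtype=bool)
    thresholds = np.full((q, q), np.nan)
    ensembles: dict[str, BootstrapEnsemble] = {}
    for i in range(q):
        for j in range(i + 1, q):
            est = mi_significance(ts, i, j, cfg)
            mi[i, j] = mi[j, i] = est.value
            mask[i, j] = mask[j, i] = bool(est.significant)
            thresholds[i, j] = thresholds[j, i] = est.threshold
            if collect_bootstrap:
                spec = MeasureSpec.mi(i, j)
                ensembles[spec.measure_id] = bootstrap_distribution(ts, spec, cfg)
    densities = compute_densities(mask, labels=ts.labels, rsn_map=ts.rsn_map)
    _log.info("pairwise analysis: %d/%d significant links (global density %.1f%%)",
              int(mask[np.triu_indices(q, k=1)].sum()), q * (q - 1) // 2,
              densities.global_density)
    return ConnectivityReport(labels=ts.labels, mi_matrix=mi,
                              significance_mask=mask, densities=densities,
                              thresholds=thresholds, ensembles=ensembles)


# ---------------------------------------------------------------------------
# high-order analysis
# ---------------------------------------------------------------------------

def run_hoi(ts: TimeSeriesSet,
            multiplets: Mapping[int, Sequence[Multiplet]],
            cfg: ResamplingConfig) -> HOIReport:
    """O-information and increments for an order-keyed multiplet collection.

    Every multiplet receives a bootstrap CI and the zero-in-CI significance
    decision. Every (multiplet, target) increment is tested with the
    unpaired t-test between the multiplet's and its root's OI bootstrap
    distributions for N >= 4; at N = 3 the root OI is identically zero, so
    the increment inherits the triplet's zero-in-CI decision.
    """
    oi_results: dict[int, list[OIResult]] = {}
    increments: dict[int, list[OIIncrement]] = {}
    rates: dict[int, float] = {}
    ensembles: dict[str, BootstrapEnsemble] = {}

    def _oi_ensemble(m: Multiplet) -> BootstrapEnsemble:
        spec = MeasureSpec.oi(m)
        if spec.measure_id not in ensembles:
            ensembles[spec.measure_id] = bootstrap_distribution(ts, spec, cfg)
        return ensembles[spec.measure_id]

    for order in sorted(multiplets):
        results: list[OIResult] = []
        incs: list[OIIncrement] = []
        for m in multiplets[order]:
            res = o_information(ts, m)
            ens = _oi_ensemble(m)
            res.ci = ens.ci
            res.significant = oi_zero_significance(ens, cfg.alpha)
            results.append(res)
            if order < 3:
                continue
            for target in m:
                inc = oi_increment(ts, m, target)
                if order == 3:
                    inc.significant = res.significant
                else:
                    root_ens = _oi_ensemble(m.without(target))
                    inc.significant = increment_significance(ens, root_ens,
                                                             cfg.alpha)
                incs.append(inc)
        oi_results[order] = results
        increments[order] = incs
        n_sig = sum(1 for r in results if r.significant)
        rates[order] = 100.0 * n_sig / len(results) if results else math.nan
        _log.info("order %d: %d multiplets, significance rate %.1f%%",
                  order, len(results), rates[order])
    return HOIReport(oi_results=oi_results, increments=increments,
                     significance_rate=rates, ensembles=ensembles)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def compare_conditions(report_a, report_b, cfg: ResamplingConfig) -> ComparisonReport:
    """Between-condition decisions for every measure shared by both reports.

    ``report_a``/``report_b`` are :class:`ConnectivityReport` or
    :class:`HOIReport` instances of the same kind carrying bootstrap
    ensembles; delta = condition_b - condition_a. Mismatched measure sets
    raise an argument error.
    """
    ens_a, ens_b = report_a.ensembles, report_b.ensembles
    if set(ens_a) != set(ens_b):
        only_a = sorted(set(ens_a) - set(ens_b))
        only_b = sorted(set(ens_b) - set(ens_a))
        raise ValidationError(
            f"conditions do not share the same measures (a-only: {only_a}, "
            f"b-only: {only_b})")
    decisions = [condition_difference(ens_a[mid], ens_b[mid], cfg.alpha)
                 for mid in sorted(ens_a)]
    return ComparisonReport(decisions=decisions)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return "%.17g" % x


def write_connectivity_report(report: ConnectivityReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = list(report.labels)
    pd.DataFrame(report.mi_matrix, index=labels, columns=labels).to_csv(
        out / "mi_matrix.csv", float_format="%.17g")
    pd.DataFrame(report.significance_mask.astype(int), index=labels,
                 columns=labels).to_csv(out / "mi_mask.csv")
    write_density_report(report.densities, out / "densities.json")


def write_density_report(densities: DensityReport, path: str | Path) -> None:
    payload: dict = {"global_density": densities.global_density}
    if densities.local is not None:
        local = densities.local
        payload["networks"] = list(local.index)
        payload["local_density"] = [
            [None if pd.isna(v) else float(v) for v in row]
            for row in local.to_numpy()
        ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def write_hoi_report(report: HOIReport, out_dir: str | Path,
                     labels: Sequence[str]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    oi_rows = []
    for order in sorted(report.oi_results):
        for res in report.oi_results[order]:
            oi_rows.append({
                "multiplet_id": res.multiplet.key(),
                "order": order,
                "channels": " ".join(res.multiplet.labelled(labels)),
                "OI": _fmt(res.value),
                "ci_low": "" if res.ci is None else _fmt(res.ci[0]),
                "ci_high": "" if res.ci is None else _fmt(res.ci[1]),
                "character": res.character,
                "significant": res.significant,
            })
    pd.DataFrame(oi_rows).to_csv(out / "oi_table.csv", index=False)
    doi_rows = []
    for order in sorted(report.increments):
        for inc in report.increments[order]:
            doi_rows.append({
                "multiplet_id": inc.multiplet.key(),
                "order": order,
                "target": labels[inc.target],
                "dOI": _fmt(inc.value),
                "significant": inc.significant,
            })
    pd.DataFrame(doi_rows).to_csv(out / "doi_table.csv", index=False)
    rates = {str(o): report.significance_rate[o] for o in sorted(report.significance_rate)}
    (out / "significance_rates.json").write_text(json.dumps(rates, indent=1) + "\n")


def write_comparison_report(report: ComparisonReport, path: str | Path) -> None:
    rows = [{
        "measure_id": d.measure_id,
        "delta": _fmt(d.delta),
        "decision": d.decision,
        "p_value": _fmt(d.p_value),
    } for d in report.decisions]
    frame = pd.DataFrame(rows, columns=["measure_id", "delta", "decision", "p_value"])
    with open(path, "w") as fh:
        fh.write("# delta = condition_b - condition_a\n")
        frame.to_csv(fh, index=False)
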