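"""Assemble directed, strength-weighted interaction networks per month.

For each calendar-month window and each unordered city pair the full
framework runs once (swap symmetry of the lag scan makes the reverse
computation redundant): lag-scanned cross-correlation, the two significance
gates, the lag-sign direction candidate, and Granger confirmation.  Pairs
surviving all stages become directed edges whose strength is the pair's
P_max and whose lag is |T_delay|.

Multiple testing across the pairs of a window is "none" by default (the
plain formulation); Benjamini-Hochberg adjustment of the Fisher-gate
p-values is available because hundreds of simultaneous pairs at alpha=0.05
inflate false edges.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ExportError, InsufficientOverlapError, \
    InsufficientSitesError
from .granger import DirectionDecision, confirm_direction
from .ingest import SiteSeries, SiteTable, window as slice_window
from .lagcorr import LagCorrelationResult, LagGrid, lag_correlation

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "source", "target", "year", "month", "strength", "lag_hours",
    "p_r", "p_fisher", "granger_p", "bidirectional",
]


@dataclass
class AnalysisConfig:
    """Every tunable of the pairwise pipeline, serialised into all outputs."""

    tau_min: int = -168
    tau_max: int = 168
    step: int = 1
    min_overlap: int = 30
    alpha: float = 0.05
    max_lag: int = 24
    criterion: str = "aic"
    lag_order: int | None = None   # only with criterion="fixed"
    difference: bool = False
    completeness_min: float = 0.75
    multiplicity: str = "none"
    exclude_boundary: bool = True
    use_effective_n: bool = False

    def __post_init__(self):
        if self.multiplicity not in ("none", "benjamini-hochberg"):
            raise ConfigurationError(
                f"unknown multiplicity method {self.multiplicity!r}"
            )

    def grid(self) -> LagGrid:
        return LagGrid(self.tau_min, self.tau_max, self.step)

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class InteractionEdge:
    source: str
    target: str
    year: int
    month: int
    strength: float     # the pair's P_max
    lag_hours: int      # |T_delay|, >= 1 for any directed edge
    p_r: float
    p_fisher: float
    granger_p: float
    bidirectional: bool

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in EDGE_COLUMNS}


@dataclass
class InteractionNetwork:
    window: tuple[int, int]
    nodes: list[str]
    edges: list[InteractionEdge]
    config: dict
    diagnostics: dict = field(default_factory=dict)
    pair_results: dict = field(default_factory=dict)    # {(c1, c2): LagCorrelationResult}
    decisions: dict = field(default_factory=dict)       # {(c1, c2): DirectionDecision}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_row() for e in self.edges], columns=EDGE_COLUMNS)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(window=self.window, **{"config": self.config})
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, strength=e.strength, lag_hours=e.lag_hours,
                       p_r=e.p_r, p_fisher=e.p_fisher, granger_p=e.granger_p,
                       bidirectional=e.bidirectional)
        return g


def adjust_multiplicity(
    p_values,
    method: str = "none",
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Gate a vector of Fisher-test p-values, optionally BH-adjusted.

    Returns (adjusted p-values, reject mask).  Method "none" leaves the
    p-values untouched and gates at the raw alpha, reproducing the plain
    formulation; "benjamini-hochberg" applies the step-up FDR adjustment.
    NaN entries (pairs without a defined Fisher test) never pass.
    """
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        with np.errstate(invalid="ignore"):
            return p, (p < alpha) & np.isfinite(p)
    if method == "benjamini-hochberg":
        finite = np.isfinite(p)
        adjusted = np.full_like(p, np.nan)
        reject = np.zeros(len(p), dtype=bool)
        if finite.any():
            rej, adj, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
            adjusted[finite] = adj
            reject[finite] = rej
        return adjusted, reject
    raise ConfigurationError(f"unknown multiplicity method {method!r}")


def build_network(
    series_by_city: Mapping[str, SiteSeries],
    year: int,
    month: int,
    config: AnalysisConfig | None = None,
) -> InteractionNetwork:
    """Run the full two-step framework over all city pairs in one window.

    Stages per unordered pair: lag correlation -> t-gate on P_max ->
    (multiplicity-adjusted) Fisher gate -> direction candidate from the sign
    of T_delay -> Granger confirmation in the candidate direction.  Pairs
    with T_delay = 0 or (by default) on the grid boundary yield no edge.
    """
    config = config or AnalysisConfig()
    grid = config.grid()

    windows: dict[str, SiteSeries] = {}
    skipped: dict[str, str] = {}
    for city in sorted(series_by_city):
        try:
            w = slice_window(series_by_city[city], year, month, config.completeness_min)
        except ValueError:
            skipped[city] = "window outside series span"
            continue
        if not w.usable:
            skipped[city] = f"completeness {w.completeness:.2f} < {config.completeness_min}"
            continue
        windows[city] = w
    if len(windows) < 2:
        raise InsufficientSitesError(
            f"window {year}-{month:02d}: {len(windows)} usable cities "
            f"(skipped: {skipped})"
        )
    logger.info("window %d-%02d: %d usable cities, %d skipped",
                year, month, len(windows), len(skipped))

    pair_results: dict[tuple[str, str], LagCorrelationResult] = {}
    for c1, c2 in itertools.combinations(sorted(windows), 2):
        try:
            pair_results[(c1, c2)] = lag_correlation(
                windows[c1], windows[c2], grid,
                min_overlap=config.min_overlap, alpha=config.alpha,
                use_effective_n=config.use_effective_n,
            )
        except InsufficientOverlapError:
            logger.warning("pair (%s, %s): insufficient overlap, skipped", c1, c2)

    # t-gate, boundary policy, then the (optionally adjusted) Fisher gate
    candidates = []
    for pair, res in pair_results.items():
        if not res.r_test.significant:
            continue
        if res.t_delay == 0:
            continue  # significant at lag zero: association without direction
        if config.exclude_boundary and res.boundary:
            continue
        candidates.append(pair)
    fisher_p = [pair_results[p].p_fisher for p in candidates]
    _, passed = adjust_multiplicity(fisher_p, config.multiplicity, config.alpha)

    edges: list[InteractionEdge] = []
    decisions: dict = {}
    anomalies: list[tuple[str, str]] = []
    n_confirm_attempted = 0
    for pair, ok in zip(candidates, passed):
        if not ok:
            continue
        res = pair_results[pair]
        n_confirm_attempted += 1
        decision: DirectionDecision = confirm_direction(
            res, windows[pair[0]], windows[pair[1]],
            max_lag=config.max_lag, alpha=config.alpha,
            criterion=config.criterion, lag_order=config.lag_order,
            difference=config.difference,
        )
        decisions[pair] = decision
        if decision.reverse_only_anomaly:
            anomalies.append(pair)
            logger.warning("pair %s: reverse-only Granger rejection, no edge", pair)
        if decision.confirmed:
            edges.append(InteractionEdge(
                source=decision.source,
                target=decision.target,
                year=year, month=month,
                strength=res.p_max,
                lag_hours=abs(res.t_delay),
                p_r=res.p_r,
                p_fisher=res.p_fisher,
                granger_p=decision.forward.p_value,
                bidirectional=decision.bidirectional,
            ))

    edges.sort(key=lambda e: (e.source, e.target))
    diagnostics = {
        "n_cities": len(windows),
        "n_skipped_cities": len(skipped),
        "skipped_cities": skipped,
        "n_pairs_scanned": len(pair_results),
        "n_direction_candidates": len(candidates),
        "n_fisher_passed": int(np.sum(passed)) if len(candidates) else 0,
        "n_granger_confirmed": len(edges),
        "reverse_only_anomalies": [list(p) for p in anomalies],
    }
    logger.info("window %d-%02d: %s", year, month,
                {k: v for k, v in diagnostics.items() if isinstance(v, int)})
    return InteractionNetwork(
        window=(year, month),
        nodes=sorted(windows),
        edges=edges,
        config=config.as_dict(),
        diagnostics=diagnostics,
        pair_results=pair_results,
        decisions=decisions,
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def pairwise_to_frames(network: InteractionNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format profile table and per-pair summary for all scanned pairs."""
    long_rows = []
    summary_rows = []
    for (c1, c2), res in sorted(network.pair_results.items()):
        for tau, p_tau, n_tau in zip(res.tau_grid, res.profile, res.n_overlap):
            long_rows.append({"city_1": c1, "city_2": c2, "tau": int(tau),
                              "P_tau": p_tau, "n_tau": int(n_tau)})
        summary_rows.append({
            "city_1": c1, "city_2": c2, "P_max": res.p_max, "T_delay": res.t_delay,
            "p_r": res.p_r, "p_fisher": res.p_fisher,
            "significant": res.significant, "boundary": res.boundary,
        })
    return pd.DataFrame(long_rows), pd.DataFrame(summary_rows)


def granger_report_frame(network: InteractionNetwork) -> pd.DataFrame:
    """Per-pair Granger outcomes (both directions summarised by candidate)."""
    rows = []
    for (c1, c2), d in sorted(network.decisions.items()):
        rows.append({
            "source": d.source, "target": d.target,
            "p_order": d.forward.lag_order,
            "F": d.forward.f_stat, "p_value": d.forward.p_value,
            "decision": "confirmed" if d.confirmed else "not-confirmed",
            "bidirectional_flag": d.bidirectional,
            "reverse_only_anomaly": d.reverse_only_anomaly,
            "stationarity_treatment": d.forward.stationarity,
        })
    return pd.DataFrame(rows, columns=[
        "source", "target", "p_order", "F", "p_value", "decision",
        "bidirectional_flag", "reverse_only_anomaly", "stationarity_treatment"])


def export_network(
    network: InteractionNetwork,
    site_table: SiteTable | None,
    path,
    fmt: str = "csv",
) -> Path:
    """Write the edge list as CSV, or as GeoJSON LineStrings via site coords."""
    path = Path(path)
    if fmt == "csv":
        network.to_frame().to_csv(path, index=False)
        return path
    if fmt == "geojson":
        if site_table is None:
            raise ExportError("GeoJSON export requires a site table")
        features = []
        for e in network.edges:
            for city in (e.source, e.target):
                if city not in site_table:
                    raise ExportError(f"city {city!r} missing from site table")
            src = site_table.lookup(e.source)
            tgt = site_table.lookup(e.target)
            features.append({
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [float(src["lon"]), float(src["lat"])],
                        [float(tgt["lon"]), float(tgt["lat"])],
                    ],
                },
                "properties": e.as_row(),
            })
        doc = {"type": "FeatureCollection", "features": features}
        path.write_text(json.dumps(doc, indent=2))
        return path
    raise ConfigurationError(f"unknown export format {fmt!r}")


def read_edge_csv(path) -> list[InteractionEdge]:
    """Read back an edge-list CSV written by :func:`export_network`."""
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        InteractionEdge(
            source=str(r.source), target=str(r.target), year=int(r.year),
            month=int(r.month), strength=float(r.strength),
            lag_hours=int(r.lag_hours), p_r=float(r.p_r),
            p_fisher=float(r.p_fisher), granger_p=float(r.granger_p),
            bidirectional=bool(r.bidirectional),
        )
        for r in df.itertuples()
    ]


def window_summary(network: InteractionNetwork) -> dict:
    """JSON-serialisable per-window summary (counts + config snapshot)."""
    return {
        "window": {"year": network.window[0], "month": network.window[1]},
        "nodes": network.nodes,
        "n_edges": len(network.edges),
        "edges": [e.as_row() for e in network.edges],
        "diagnostics": network.diagnostics,
        "config": network.config,
    }
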