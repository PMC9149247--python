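"""Synthetic multi-city advection scenarios with known ground truth.

The statistical framework needs, for validation, multi-city hourly series in
which the true pairwise transport lags and directions are known.  This
module generates them from a deliberately minimal physical picture: cities
on a plane, a per-calendar-month wind (direction and speed), source cities
emitting a positive autocorrelated AR(1) signal, straight-line advection
with exponential distance decay, and per-city AR(1) measurement noise.  A
city j downwind of source s receives the source signal delayed by the travel
time (along-wind distance / speed) and attenuated by exp(-decay * distance).

On top of the clean signal the generator injects the pathologies real
station feeds exhibit — missing hours, implausible zeros, extreme outliers
(> 1,000 µg/m³) and duplicated records — so the full ingest/QC pipeline can
run unmodified on simulated data, and QC removal can be checked record for
record against the injection log.

The ground truth is geometric: an ordered pair (i, j) is
"downwind-connected" in a window when j lies downwind of i (positive
along-wind separation), within a cross-wind corridor, with an integer travel
lag inside the scan range.  This is not a dispersion model; it exists to
test the statistics, not to imitate a chemical transport model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .ingest import SiteSeries, SiteTable, StationRecord, _tz

# planar km -> lon/lat anchor (roughly the Yellow Sea region)
_ANCHOR_LAT = 35.0
_ANCHOR_LON = 120.0
_KM_PER_DEG_LAT = 111.0


@dataclass(frozen=True)
class SyntheticSite:
    city_id: str
    x_km: float
    y_km: float
    tz_offset_hours: int = 8
    country: str = "SIM"

    @property
    def lat(self) -> float:
        return _ANCHOR_LAT + self.y_km / _KM_PER_DEG_LAT

    @property
    def lon(self) -> float:
        return _ANCHOR_LON + self.x_km / (_KM_PER_DEG_LAT * math.cos(math.radians(_ANCHOR_LAT)))


@dataclass(frozen=True)
class WindSpell:
    """Wind for one calendar month: compass bearing the air moves TOWARD."""

    year: int
    month: int
    direction_deg: float
    speed_kmh: float

    def unit_vector(self) -> np.ndarray:
        th = math.radians(self.direction_deg)
        return np.array([math.sin(th), math.cos(th)])  # (east, north)


@dataclass
class SyntheticScenario:
    """Full configuration of a simulated study.

    Emission is an AR(1) process with marginal mean ``emission_mean`` and
    standard deviation ``emission_sd`` (µg/m³); per-city noise is AR(1) with
    marginal sd ``noise_sd``.  With ``decay_per_km = 0`` the signal-to-noise
    ratio at every receiving city is emission_sd / noise_sd.
    """

    sites: Sequence[SyntheticSite]
    sources: Sequence[str]
    wind: Sequence[WindSpell]
    emission_mean: float = 60.0
    emission_sd: float = 20.0
    emission_ar1: float = 0.95
    noise_sd: float = 10.0
    noise_ar1: float = 0.5
    background: float = 15.0
    decay_per_km: float = 0.0
    corridor_km: float = 50.0
    max_truth_lag_h: int = 168
    missing_frac: float = 0.02
    outlier_frac: float = 0.005
    zero_frac: float = 0.005
    duplicate_frac: float = 0.005
    stations_per_city: int = 1
    value_floor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.sites or not self.wind:
            raise ConfigurationError("scenario needs at least one site and one wind spell")
        ids = [s.city_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate city_id in scenario sites")
        unknown = set(self.sources) - set(ids)
        if unknown:
            raise ConfigurationError(f"source cities not in site list: {sorted(unknown)}")
        for spell in self.wind:
            if spell.speed_kmh <= 0:
                raise ConfigurationError("wind speed must be positive")
        if self.decay_per_km < 0:
            raise ConfigurationError("decay rate must be >= 0")
        for name in ("missing_frac", "outlier_frac", "zero_frac", "duplicate_frac"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1)")

    def site_table(self) -> SiteTable:
        return SiteTable(pd.DataFrame(
            {
                "city_id": [s.city_id for s in self.sites],
                "lat": [s.lat for s in self.sites],
                "lon": [s.lon for s in self.sites],
                "tz_offset_hours": [s.tz_offset_hours for s in self.sites],
                "country": [s.country for s in self.sites],
            }
        ))

    def to_yaml(self, path) -> None:
        doc = {
            "sites": [asdict(s) for s in self.sites],
            "sources": list(self.sources),
            "wind": [asdict(w) for w in self.wind],
        }
        for k, v in asdict(self).items():
            if k not in ("sites", "sources", "wind"):
                doc[k] = v
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        doc = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
        doc["sites"] = [SyntheticSite(**s) for s in doc["sites"]]
        doc["wind"] = [WindSpell(**w) for w in doc["wind"]]
        return cls(**doc)


@dataclass
class TruthMatrix:
    """Per window and ordered pair: true transport lag and connectivity.

    Columns: year, month, source, target, lag_hours (int, rounded to the
    measurement grid), lag_hours_exact (sub-hour truth, for documentation),
    connected (bool).
    """

    frame: pd.DataFrame

    def for_window(self, year: int, month: int) -> pd.DataFrame:
        m = (self.frame["year"] == year) & (self.frame["month"] == month)
        return self.frame[m].reset_index(drop=True)

    def cities(self) -> set[str]:
        return set(self.frame["source"]) | set(self.frame["target"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TruthMatrix":
        return cls(pd.read_csv(path))


@dataclass
class RecoveryMetrics:
    direction_accuracy: float
    lag_mae_hours: float
    false_edge_count: int
    n_true_pairs: int
    n_matched: int
    lag_within_tolerance: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationResult:
    scenario: SyntheticScenario
    records: list[StationRecord]
    truth: TruthMatrix
    clean: dict            # {(year, month): {city_id: SiteSeries}}
    injections: dict       # {(year, month): {city_id: {class: sorted hour lists}}}

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": [r.station_id for r in self.records],
                "city_id": [r.city_id for r in self.records],
                "timestamp": [r.timestamp.isoformat() for r in self.records],
                "value": [r.value for r in self.records],
            }
        )

    def write_records(self, path) -> None:
        """CSV in exactly the ingest dialect, so the pipeline runs unmodified."""
        self.records_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Geometry and truth
# ---------------------------------------------------------------------------

def _month_hours(year: int, month: int) -> int:
    start = pd.Timestamp(year=year, month=month, day=1)
    return int(((start + pd.offsets.MonthBegin(1)) - start) / pd.Timedelta(hours=1))


def _pair_geometry(si: SyntheticSite, sj: SyntheticSite, spell: WindSpell):
    d = np.array([sj.x_km - si.x_km, sj.y_km - si.y_km])
    w = spell.unit_vector()
    along = float(d @ w)
    perp = float(np.linalg.norm(d - along * w))
    return along, perp


def build_truth(scenario: SyntheticScenario) -> TruthMatrix:
    rows = []
    for spell in scenario.wind:
        for si in scenario.sites:
            for sj in scenario.sites:
                if si.city_id == sj.city_id:
                    continue
                along, perp = _pair_geometry(si, sj, spell)
                lag_exact = along / spell.speed_kmh if along > 0 else float("nan")
                lag_int = int(round(lag_exact)) if along > 0 else 0
                connected = (
                    along > 0
                    and perp <= scenario.corridor_km
                    and 1 <= lag_int <= scenario.max_truth_lag_h
                )
                rows.append(
                    {
                        "year": spell.year,
                        "month": spell.month,
                        "source": si.city_id,
                        "target": sj.city_id,
                        "lag_hours": lag_int if connected else 0,
                        "lag_hours_exact": lag_exact if connected else float("nan"),
                        "connected": connected,
                    }
                )
    return TruthMatrix(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, phi: float, marginal_sd: float) -> np.ndarray:
    """Stationary zero-mean AR(1) with the given marginal standard deviation."""
    innov_sd = marginal_sd * math.sqrt(max(1.0 - phi * phi, 1e-12))
    e = np.empty(n)
    e[0] = rng.normal(0.0, marginal_sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + shocks[t - 1]
    return e


def simulate(scenario: SyntheticScenario, seed: int | None = None) -> SimulationResult:
    """Generate station records, clean per-window series and the truth matrix.

    Deterministic for a fixed seed (``seed`` overrides ``scenario.seed``).
    Pathologies are injected after signal construction: outlier/zero hours
    replace the clean value (QC later turns them into gaps), missing hours
    drop the record entirely, duplicate records are exact copies.
    """
    root = np.random.default_rng(scenario.seed if seed is None else seed)
    truth = build_truth(scenario)
    sites = {s.city_id: s for s in scenario.sites}

    records: list[StationRecord] = []
    clean: dict = {}
    injections: dict = {}

    for spell in scenario.wind:
        h = _month_hours(spell.year, spell.month)
        pad = scenario.max_truth_lag_h + 8
        rng_window = np.random.default_rng(root.integers(2**31))
        emissions = {
            s: scenario.emission_mean
            + _ar1(rng_window, h + pad, scenario.emission_ar1, scenario.emission_sd)
            for s in scenario.sources
        }
        clean[(spell.year, spell.month)] = {}
        injections[(spell.year, spell.month)] = {}

        for site in scenario.sites:
            cid = site.city_id
            rng_city = np.random.default_rng(root.integers(2**31))
            values = np.full(h, scenario.background, dtype=float)
            for s in scenario.sources:
                if s == cid:
                    values += emissions[s][pad:]
                    continue
                along, perp = _pair_geometry(sites[s], site, spell)
                lag = int(round(along / spell.speed_kmh)) if along > 0 else 0
                if (along > 0 and perp <= scenario.corridor_km
                        and 1 <= lag <= scenario.max_truth_lag_h):
                    dist = math.hypot(site.x_km - sites[s].x_km, site.y_km - sites[s].y_km)
                    atten = math.exp(-scenario.decay_per_km * dist)
                    values += atten * emissions[s][pad - lag: pad - lag + h]
            values += _ar1(rng_city, h, scenario.noise_ar1, scenario.noise_sd)
            values = np.maximum(values, scenario.value_floor)

            start = pd.Timestamp(
                year=spell.year, month=spell.month, day=1, tz=_tz(site.tz_offset_hours)
            )
            clean[(spell.year, spell.month)][cid] = SiteSeries(
                city_id=cid, tz_offset_hours=site.tz_offset_hours,
                start=start, values=values.copy(),
            )

            # pathology injection: disjoint hour sets for missing/outlier/zero
            n_bad = {
                "missing": int(round(scenario.missing_frac * h)),
                "outlier": int(round(scenario.outlier_frac * h)),
                "zero": int(round(scenario.zero_frac * h)),
            }
            bad_hours = rng_city.choice(h, size=sum(n_bad.values()), replace=False)
            sets = {}
            k = 0
            for cls in ("missing", "outlier", "zero"):
                sets[cls] = sorted(int(t) for t in bad_hours[k: k + n_bad[cls]])
                k += n_bad[cls]

            observed = values.copy()
            for t in sets["outlier"]:
                observed[t] = 1000.5 + float(rng_city.exponential(500.0))
            for t in sets["zero"]:
                observed[t] = 0.0

            kept_hours = sorted(set(range(h)) - set(sets["missing"]))
            n_dup = int(round(scenario.duplicate_frac * h))
            dup_hours = sorted(
                int(t) for t in rng_city.choice(kept_hours, size=min(n_dup, len(kept_hours)),
                                                replace=False)
            )
            sets["duplicate"] = dup_hours
            injections[(spell.year, spell.month)][cid] = sets

            for k_station in range(scenario.stations_per_city):
                sid = f"{cid}-s{k_station + 1}"
                for t in kept_hours:
                    ts = start + pd.Timedelta(hours=t)
                    records.append(StationRecord(sid, cid, ts, float(observed[t])))
                for t in dup_hours:
                    ts = start + pd.Timedelta(hours=t)
                    records.append(StationRecord(sid, cid, ts, float(observed[t])))

    return SimulationResult(scenario, records, truth, clean, injections)


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(network, truth: TruthMatrix, lag_tolerance: float = 1.0) -> RecoveryMetrics:
    """Score a recovered window network against the simulator's ground truth.

    direction_accuracy: fraction of downwind-connected ordered pairs whose
    recovered edge exists with the matching direction (a missing edge counts
    as a miss).  lag_mae_hours: mean |recovered lag - true lag| over matched
    edges.  false_edge_count: recovered edges on pairs that are not
    downwind-connected in that window.
    """
    year, month = network.window
    tw = truth.for_window(year, month)
    if tw.empty:
        raise ValueError(f"truth matrix has no window {year}-{month:02d}")
    net_cities = set(network.nodes)
    if net_cities.isdisjoint(truth.cities()):
        raise ValueError("network and truth matrix share no cities")

    true_pairs = {
        (r.source, r.target): int(r.lag_hours)
        for r in tw.itertuples()
        if r.connected
    }
    edges = {(e.source, e.target): e for e in network.edges}

    n_true = len(true_pairs)
    lag_errors = [abs(edges[p].lag_hours - lag) for p, lag in true_pairs.items() if p in edges]
    n_matched = len(lag_errors)
    false_edges = [p for p in edges if p not in true_pairs]

    return RecoveryMetrics(
        direction_accuracy=(n_matched / n_true) if n_true else float("nan"),
        lag_mae_hours=float(np.mean(lag_errors)) if lag_errors else 0.0,
        false_edge_count=len(false_edges),
        n_true_pairs=n_true,
        n_matched=n_matched,
        lag_within_tolerance=(
            float(np.mean([e <= lag_tolerance for e in lag_errors])) if lag_errors else 0.0
        ),
    )


# ---------------------------------------------------------------------------
# Packaged scenarios
# ---------------------------------------------------------------------------

def chain_scenario(
    positions_km: Sequence[float] = (0.0, 75.0, 125.0, 175.0, 225.0),
    speed_kmh: float = 12.5,
    months: Sequence[tuple[int, int, float]] = ((2018, 1, 90.0),),
    seed: int = 0,
    sources: Sequence[str] | None = None,
    **overrides,
) -> SyntheticScenario:
    """Cities in a west-east chain with the wind blowing along the axis.

    ``months`` is a sequence of (year, month, wind bearing toward).  With the
    default geometry and 12.5 km/h wind, the source-to-city travel lags are
    exactly 6, 10, 14 and 18 h and the remaining downwind pairs fall between
    4 and 12 h — all well inside the scan grid.
    """
    sites = [SyntheticSite(f"C{i + 1}", x_km=float(x), y_km=0.0)
             for i, x in enumerate(positions_km)]
    wind = [WindSpell(y, m, d, speed_kmh) for (y, m, d) in months]
    return SyntheticScenario(
        sites=sites,
        sources=list(sources) if sources is not None else [sites[0].city_id],
        wind=wind, seed=seed, **overrides,
    )


def benchmark_chain(seed: int = 0) -> SyntheticScenario:
    """The packaged 5-city benchmark: SNR 2, lags 6-18 h, one January month."""
    return chain_scenario(seed=seed)


def reversal_scenario(seed: int = 0) -> SyntheticScenario:
    """Two-window chain with the wind reversing between January and July.

    Sources sit at both ends of the chain so that whichever end is upwind in
    a window emits the advected signal for that window.
    """
    return chain_scenario(
        months=((2018, 1, 90.0), (2018, 7, 270.0)),
        sources=["C1", "C5"],
        seed=seed,
    )
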