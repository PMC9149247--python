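from datetime import timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from driftnet import SiteSeries, benchmark_chain, qc_filter, simulate

TZ8 = timezone(timedelta(hours=8))
TZ9 = timezone(timedelta(hours=9))
JAN = pd.Timestamp("2018-01-01", tz=TZ8)


def make_series(values, city="A", tz_offset=8, start=None) -> SiteSeries:
    start = start if start is not None else pd.Timestamp(
        "2018-01-01", tz=timezone(timedelta(hours=tz_offset)))
    return SiteSeries(city_id=city, tz_offset_hours=tz_offset,
                      start=start, values=np.asarray(values, dtype=float))


def ar1(rng: np.random.Generator, n: int, phi: float, sd: float = 1.0,
        mean: float = 0.0) -> np.ndarray:
    """Stationary AR(1) with marginal sd; independent oracle-grade generator."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + shocks[t - 1]
    return e + mean


@pytest.fixture(scope="session")
def benchmark_sim():
    """One simulated 5-city benchmark month, QC'd, shared across tests."""
    sim = simulate(benchmark_chain(seed=0))
    kept, report = qc_filter(sim.records)
    cities = sorted({r.city_id for r in kept})
    from driftnet import average_stations
    series = {c: average_stations(kept, c) for c in cities}
    return sim, kept, report, series
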