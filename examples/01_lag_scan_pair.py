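"""Lag-scanned cross-correlation for one city pair.

Simulates two cities 600 km apart under a steady 50 km/h wind (true travel
time 12 h), then scans the Pearson correlation P(tau) over +/-168 h.  The
peak location T_delay gives the temporal order (negative = the first city
leads), and two tests gate significance: a t-test that P_max is nonzero and
a Fisher r-to-z test that P_max beats the zero-lag correlation P(0).
"""

import driftnet as dn
from driftnet.synthetic import SyntheticSite, WindSpell

scenario = dn.SyntheticScenario(
    sites=[SyntheticSite("upwind", 0.0, 0.0), SyntheticSite("downwind", 600.0, 0.0)],
    sources=["upwind"],
    wind=[WindSpell(2018, 1, 90.0, 50.0)],  # blowing east at 50 km/h
    seed=42,
)
sim = dn.simulate(scenario)
kept, _ = dn.qc_filter(sim.records)
series = {c: dn.average_stations(kept, c) for c in ("upwind", "downwind")}

res = dn.lag_correlation(series["upwind"], series["downwind"])

print(f"P_max   = {res.p_max:.3f}   (interaction strength)")
print(f"T_delay = {res.t_delay:+d} h  (negative: upwind city leads)")
print(f"P(0)    = {res.p_zero:.3f}   (correlation with no lag)")
print(f"t-test p = {res.p_r:.2e}, Fisher p = {res.p_fisher:.2e}")
print(f"significant pair: {res.significant}")
print()
print("The peak at -12 h matches the 600 km / 50 km/h travel time: the")
print("downwind series is best aligned when the upwind series is shifted")
print("12 h later, so the candidate direction is upwind -> downwind.")
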