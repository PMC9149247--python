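"""Full monthly interaction network on the packaged 5-city benchmark.

Five cities in a chain, one upwind source, true travel lags 6-18 h, SNR 2,
plus realistic pathologies (missing hours, zeros, >1000 ug/m3 outliers,
duplicates).  The pipeline runs QC -> lag scan -> gates -> Granger per pair
and the result is scored against the simulator's ground truth.
"""

import driftnet as dn

sim = dn.simulate(dn.benchmark_chain(seed=0))
kept, report = dn.qc_filter(sim.records)
print(f"QC: kept {report.retained}/{report.n_input} records "
      f"(zeros {report.zeros}, outliers {report.outliers}, "
      f"duplicates {report.duplicates})")

series = {c: dn.average_stations(kept, c) for c in sorted({r.city_id for r in kept})}
net = dn.build_network(series, 2018, 1)

print(f"\nJanuary network: {len(net.edges)} directed edges over {len(net.nodes)} cities")
for e in net.edges:
    print(f"  {e.source} -> {e.target}: strength {e.strength:.2f}, "
          f"lag {e.lag_hours:2d} h, Granger p = {e.granger_p:.1e}")

m = dn.evaluate_recovery(net, sim.truth)
print(f"\nvs ground truth: direction accuracy {m.direction_accuracy:.2f}, "
      f"lag MAE {m.lag_mae_hours:.2f} h, false edges {m.false_edge_count}")
print()
print("Every downwind-connected pair is recovered with the exact geometric")
print("travel lag; strengths sit near 0.8, the theoretical correlation of")
print("two noisy copies of a shared signal at SNR 2.")
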