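"""End-to-end orchestration: QC -> windows -> pairwise -> Granger -> exports.

This layer does no computation of its own; it binds the library modules
behind one serialisable :class:`RunConfig` so a whole analysis is
reproducible from a YAML file and a seed.  Every run embeds its resolved
configuration in the outputs it writes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import ingest
from .errors import ConfigurationError, DriftnetError
from .network import AnalysisConfig, build_network, export_network, \
    granger_report_frame, pairwise_to_frames, window_summary

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, outputs, analysis tunables and the seed for one pipeline run."""

    records_csv: str
    sites_csv: str | None = None
    out_dir: str = "driftnet-out"
    windows: Sequence[Sequence[int]] = ()      # [(year, month), ...]
    target_tz_offset_hours: int = 8
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    write_geojson: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown run config keys: {sorted(unknown)}")
        if "analysis" in doc:
            doc["analysis"] = AnalysisConfig.from_dict(doc["analysis"])
        return cls(**doc)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["windows"] = [list(w) for w in self.windows]
        return d


def prepare_series(
    records_csv,
    format_spec: ingest.FormatSpec = ingest.DEFAULT_FORMAT,
    target_tz_offset_hours: int = 8,
) -> tuple[dict[str, ingest.SiteSeries], ingest.QCReport, ingest.ParseResult]:
    """Parse, QC, station-average and timezone-align a raw records file."""
    parsed = ingest.load_station_records(records_csv, format_spec)
    logger.info("parsed %d records (%d rejected rows)", len(parsed), parsed.n_rejected)
    kept, report = ingest.qc_filter(parsed.records)
    logger.info("QC retained %d of %d records", report.retained, report.n_input)
    series = {}
    for city in sorted({r.city_id for r in kept}):
        s = ingest.average_stations(kept, city, qc_log=report.as_dict()["removed"])
        series[city] = ingest.align_timezone(s, target_tz_offset_hours)
    return series, report, parsed


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Artifacts per window: edge-list CSV, per-window summary JSON, the full
    lag-profile CSV, per-pair summary CSV, per-pair Granger report CSV and
    optional GeoJSON.  Plus the QC report and the per-city series CSV.
    Raises (with the stage name in the message) on any stage failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    site_table = ingest.SiteTable.from_csv(config.sites_csv) if config.sites_csv else None

    try:
        series, qc_report, parsed = prepare_series(
            config.records_csv, target_tz_offset_hours=config.target_tz_offset_hours
        )
    except DriftnetError as exc:
        raise type(exc)(f"[stage ingest/qc] {exc}") from exc

    qc_report.to_json(out / "qc_report.json")
    ingest.series_to_csv(series, out / "series.csv")

    summaries = []
    for year, month in config.windows:
        tag = f"{year}-{month:02d}"
        try:
            net = build_network(series, int(year), int(month), config.analysis)
        except DriftnetError as exc:
            raise type(exc)(f"[stage network {tag}] {exc}") from exc
        export_network(net, site_table, out / f"edges_{tag}.csv", "csv")
        if config.write_geojson:
            export_network(net, site_table, out / f"edges_{tag}.geojson", "geojson")
        profiles, pair_summary = pairwise_to_frames(net)
        profiles.to_csv(out / f"profiles_{tag}.csv", index=False)
        pair_summary.to_csv(out / f"pairwise_{tag}.csv", index=False)
        granger_report_frame(net).to_csv(out / f"granger_{tag}.csv", index=False)
        summary = window_summary(net)
        (out / f"summary_{tag}.json").write_text(json.dumps(summary, indent=2))
        summaries.append(summary)

    run_summary = {
        "config": config.as_dict(),
        "n_cities": len(series),
        "qc": qc_report.as_dict(),
        "rejected_rows": parsed.n_rejected,
        "windows": summaries,
    }
    (out / "run_summary.json").write_text(json.dumps(run_summary, indent=2))
    return run_summary
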