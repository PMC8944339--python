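"""End-to-end audit pipeline: ingest -> clean -> gaps -> bias -> report.

The pipeline consumes the six inputs (GenBank flat file, BOLD-style table,
occurrence table, gazetteer, province geometries, institution map plus a
foreign-place list), applies the cleaning and filtering rules under one or
both country-NA modes, and bundles every analysis table into an AuditReport
that can be written as a directory of comma-delimited tables with a JSON
run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bias, clean, gaps, ingest
from .fixtures import Corpus
from .gazetteer import Gazetteer
from .geometry import ProvinceGeometries

ANALYSIS_RANKS = gaps.IDENTIFICATION_RANKS
TREND_AXES = ("collection_year", "submission_year")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """Paths and knobs for a pipeline run (YAML-serializable)."""

    genbank: str
    bold: str
    occurrences: str
    gazetteer: str
    geometries: str
    institutions: str
    foreign_places: str
    out: str | None = None
    mode: str = "include_na_country"  # include_na_country|exclude_na_country|both
    smoothing_span: float = 0.75
    quantiles_on: str = "transformed"  # transformed | raw
    seed: int = 0

    def modes(self) -> list[str]:
        if self.mode == "both":
            return list(clean.FILTER_MODES)
        if self.mode not in clean.FILTER_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        return [self.mode]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        payload = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AuditReport:
    """All analysis tables computed under one country-NA mode."""

    mode: str
    completeness: gaps.CompletenessReport
    issues: pd.DataFrame
    identification: dict[str, pd.DataFrame]
    taxon_bias: dict[str, pd.DataFrame]
    province_bias: pd.DataFrame
    contributors: pd.DataFrame
    contributor_split: pd.DataFrame
    trends: dict[str, pd.DataFrame]
    region_matrix: pd.DataFrame
    filter_log: clean.FilterLog
    residues: dict[str, int]
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            f"completeness_{self.mode}": self.completeness.to_frame(),
            f"fig1b_issues_{self.mode}": self.issues,
            f"fig4_provinces_{self.mode}": self.province_bias,
            f"fig5_countries_{self.mode}": self.contributors,
            f"fig5_contrib_split_{self.mode}": self.contributor_split,
            f"fig6_matrix_{self.mode}": self.region_matrix.reset_index(),
            f"filter_log_{self.mode}": self.filter_log.to_frame(),
            f"residues_{self.mode}": pd.DataFrame(
                sorted(self.residues.items()), columns=["residue", "count"]
            ),
        }
        for rank, df in self.identification.items():
            out[f"fig2_rank_{rank}_{self.mode}"] = df
        for rank, df in self.taxon_bias.items():
            out[f"fig3_rank_{rank}_{self.mode}"] = df
        for axis, df in self.trends.items():
            out[f"fig5_trend_{axis}_{self.mode}"] = df
        return out


@dataclass
class AuditInputs:
    """Parsed inputs shared by every mode of a run."""

    genbank_text: str
    bold: pd.DataFrame
    occurrences: pd.DataFrame
    gazetteer: Gazetteer
    geometries: ProvinceGeometries
    institution_map: dict[str, tuple[str, str | None]]
    foreign_places: list[str]

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "AuditInputs":
        return cls(
            genbank_text=corpus.genbank_text,
            bold=corpus.bold,
            occurrences=corpus.occurrences,
            gazetteer=corpus.gazetteer,
            geometries=corpus.geometries,
            institution_map=ingest.read_institution_map(corpus.institution_map),
            foreign_places=list(corpus.foreign_places),
        )

    @classmethod
    def from_paths(cls, config: PipelineConfig) -> "AuditInputs":
        return cls(
            genbank_text=Path(config.genbank).read_text(),
            bold=pd.read_csv(
                config.bold, sep="\t", dtype=str, keep_default_na=False
            ),
            occurrences=pd.read_csv(
                config.occurrences, sep="\t", dtype=str, keep_default_na=False
            ),
            gazetteer=Gazetteer.read_csv(config.gazetteer),
            geometries=ProvinceGeometries.from_geojson(config.geometries),
            institution_map=ingest.read_institution_map(config.institutions),
            foreign_places=pd.read_csv(config.foreign_places)["place"].tolist(),
        )


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate with stage name, keep traceback
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def prepare_barcode_table(inputs: AuditInputs) -> pd.DataFrame:
    """Ingest and clean the barcode sources (mode-independent steps)."""
    gb_records = _stage("parse_genbank")(ingest.parse_genbank, inputs.genbank_text)
    bold_records = _stage("read_bold")(
        ingest.read_bold, inputs.bold, inputs.institution_map
    )
    barcode = _stage("harmonize")(ingest.harmonize, gb_records, bold_records)
    barcode["marker"] = barcode["marker_raw"].map(clean.standardize_marker)
    barcode["species"] = barcode["species"].map(clean.mark_unidentified)
    barcode = _stage("resolve_localities")(
        clean.resolve_records, barcode, inputs.gazetteer
    )
    barcode = _stage("flag_country_mismatch")(
        clean.flag_country_mismatches,
        barcode,
        inputs.gazetteer,
        inputs.foreign_places,
    )
    barcode = _stage("attribute_contributors")(
        ingest.attribute_contributors, barcode, inputs.institution_map
    )
    return barcode


def prepare_occurrence_table(
    inputs: AuditInputs,
) -> tuple[pd.DataFrame, int]:
    occ_records = _stage("read_occurrences")(
        ingest.read_occurrences, inputs.occurrences
    )
    occ = ingest.occurrences_to_frame(occ_records)
    return clean.filter_occurrences(occ)


def run_audit(
    inputs: AuditInputs,
    mode: str,
    smoothing_span: float = 0.75,
    quantiles_on: str = "transformed",
    _prepared: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> AuditReport:
    """Run every analysis for one country-NA mode."""
    if _prepared is not None:
        barcode, occ = _prepared
        n_homo_occ = 0
    else:
        barcode = prepare_barcode_table(inputs)
        occ, n_homo_occ = prepare_occurrence_table(inputs)
    tax_table = _stage("derive_taxonomy")(clean.derive_taxonomy_table, occ)
    barcode, filter_log = _stage("apply_filters")(
        clean.apply_filters, barcode, mode
    )
    barcode, n_filled, n_incomplete = _stage("backfill_taxonomy")(
        clean.backfill_taxonomy, barcode, tax_table
    )

    comp = _stage("completeness")(gaps.completeness, barcode, mode)
    issues = _stage("issue_frequencies")(gaps.issue_frequencies, barcode)
    identification = {
        rank: _stage("identification")(
            gaps.identification_vs_barcoding, barcode, occ, rank
        )
        for rank in ANALYSIS_RANKS
    }

    flag_cols = {
        "transformed": ("log_barcode", "log_occurrence"),
        "raw": ("n_barcode", "n_occurrence"),
    }[quantiles_on]
    taxon_bias = {}
    for rank in ANALYSIS_RANKS:
        points = bias.add_log_columns(
            bias.taxon_counts(barcode, occ, rank)
        )
        if len(points):
            points, _ = bias.percentile_flags(points, flag_cols)
        taxon_bias[rank] = points

    province_points, prov_residue = _stage("province_counts")(
        bias.province_counts, barcode, occ, inputs.geometries
    )
    province_points = bias.add_log_columns(province_points)
    if len(province_points):
        province_points, _ = bias.percentile_flags(province_points, flag_cols)

    contributors, split = _stage("contributors")(
        bias.contributor_counts, barcode
    )
    trends = {
        axis: _stage("temporal_trends")(
            bias.temporal_trends, barcode, axis, smoothing_span
        )
        for axis in TREND_AXES
    }

    barcode = bias.assign_regions(
        barcode, inputs.gazetteer, inputs.institution_map, inputs.geometries
    )
    region_order = inputs.gazetteer.names("region")
    matrix, region_residue = _stage("region_matrix")(
        bias.region_matrix, barcode, region_order
    )

    residues = dict(prov_residue.counts)
    residues.update(region_residue.counts)
    residues["occurrence_homo_removed"] = n_homo_occ
    metadata = {
        "mode": mode,
        "n_records_analyzed": int(len(barcode)),
        "n_taxonomy_backfilled": int(n_filled),
        "n_taxonomy_still_incomplete": int(n_incomplete),
        "taxonomy_conflicts_dropped": len(tax_table.conflicts),
        "smoothing_span": smoothing_span,
        "quantiles_on": quantiles_on,
        "quantile_definition": "linear interpolation on transformed values"
        if quantiles_on == "transformed"
        else "linear interpolation on raw counts",
    }
    return AuditReport(
        mode=mode,
        completeness=comp,
        issues=issues,
        identification=identification,
        taxon_bias=taxon_bias,
        province_bias=province_points,
        contributors=contributors,
        contributor_split=split,
        trends=trends,
        region_matrix=matrix,
        filter_log=filter_log,
        residues=residues,
        metadata=metadata,
    )


def run_pipeline(
    config: PipelineConfig, inputs: AuditInputs | None = None
) -> dict[str, AuditReport]:
    """Run the configured pipeline, returning one report per mode.

    When ``config.out`` is set, every table is written as CSV together with
    a machine-readable run manifest.
    """
    if inputs is None:
        inputs = _stage("load_inputs")(AuditInputs.from_paths, config)
    barcode = prepare_barcode_table(inputs)
    occ, n_homo_occ = prepare_occurrence_table(inputs)
    reports = {}
    for mode in config.modes():
        report = run_audit(
            inputs,
            mode,
            smoothing_span=config.smoothing_span,
            quantiles_on=config.quantiles_on,
            _prepared=(barcode.copy(), occ),
        )
        report.residues["occurrence_homo_removed"] = n_homo_occ
        reports[mode] = report
    if config.out:
        write_reports(reports, config, Path(config.out))
    return reports


def write_reports(
    reports: dict[str, AuditReport], config: PipelineConfig, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    table_names = []
    for report in reports.values():
        for name, table in report.tables().items():
            table.to_csv(outdir / f"{name}.csv", index=False)
            table_names.append(name)
    manifest = {
        "seed": config.seed,
        "modes": list(reports),
        "config_digest": config.digest(),
        "tables": sorted(table_names),
        "metadata": {mode: r.metadata for mode, r in reports.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
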