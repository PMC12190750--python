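"""End-to-end orchestration: filter -> per-line fits -> meta -> shrinkage
-> enrichment, with TSV outputs and a reproducibility manifest.

Stages communicate through pandas frames in memory and are written to
disk as TSVs so every intermediate is inspectable.  The output is a pure
function of (inputs, configuration): no stage draws random numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import enrich_gene_sets, read_gene_sets
from .io_formats import (
    MOD_CODES,
    SITE_KEY_COLUMNS,
    SiteCountTable,
    build_count_tables,
    read_gene_map,
    read_sample_sheet,
)
from .ivt_filter import FilterConfig, apply_ivt_filter, summarize_sites
from .meta_infer import call_dms
from .shrinkage import shrink_dms_table
from .site_model import SiteModelConfig, test_sites_per_line

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; every threshold of the standard rule
    set is a field with that rule's value as default."""

    sample_sheet: str = ""
    mod_codes: tuple[str, ...] = MOD_CODES
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha_influence: float = 0.05
    alpha_het: float = 0.05
    q_threshold: float = 0.05
    both_lines_only: bool = False
    bh_scope: str = "per_mod"
    shrinkage_penalty_null: float = 10.0
    gene_map: str | None = None
    gene_sets: str | None = None
    output_dir: str = "dmscall_out"

    def __post_init__(self) -> None:
        for name in ("alpha_influence", "alpha_het", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        unknown = set(self.mod_codes) - set(MOD_CODES)
        if unknown:
            raise ValueError(f"unknown mod codes: {sorted(unknown)}")


def analyze_tables(
    native: dict[str, SiteCountTable],
    ivt: dict[str, SiteCountTable],
    sample_sheet: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """Run the statistical stages on in-memory count tables.

    Returns a dict with keys ``dms`` (the combined DMS table),
    ``filter_reports``, ``fits`` (per-line long table) and optionally
    ``enrichment``.
    """
    reports = []
    all_fits = []
    lines = sorted(
        sample_sheet.loc[sample_sheet["material"] == "native", "cell_line"].unique()
    )
    if not ivt:
        logger.warning(
            "no IVT samples available; filtering on coverage and native "
            "proportion only"
        )
    site_cfg = SiteModelConfig(
        min_mean_reads=cfg.filter.min_mean_reads,
        min_prop=cfg.filter.min_native_prop,
        prop_mode=cfg.filter.prop_mode,
        alpha_influence=cfg.alpha_influence,
    )
    for mod_code in cfg.mod_codes:
        if mod_code not in native:
            continue
        table = native[mod_code]
        native_ids = sample_sheet.loc[
            sample_sheet["material"] == "native", "sample_id"
        ].tolist()
        native_summary = summarize_sites(
            table, [s for s in native_ids if s in table.samples]
        )
        ivt_table = ivt.get(mod_code)
        ivt_summary = summarize_sites(ivt_table) if ivt_table is not None else None
        retained, report = apply_ivt_filter(native_summary, ivt_summary, cfg.filter)
        reports.append(report.to_dict())
        logger.info(
            "mod %s: %d/%d sites pass filter",
            mod_code,
            report.n_pass,
            report.n_input_sites,
        )
        keep_index = pd.MultiIndex.from_frame(table.sites[SITE_KEY_COLUMNS])
        keep_mask = keep_index.isin(
            pd.MultiIndex.from_frame(retained[SITE_KEY_COLUMNS])
        )
        filtered = table.subset_sites(keep_mask)
        for line in lines:
            fits = test_sites_per_line(filtered, sample_sheet, line, site_cfg)
            all_fits.append(fits)

    out: dict = {"filter_reports": pd.DataFrame(reports)}
    if all_fits:
        fits = pd.concat(all_fits, ignore_index=True)
        dms = call_dms(
            fits,
            alpha_het=cfg.alpha_het,
            q_threshold=cfg.q_threshold,
            both_lines_only=cfg.both_lines_only,
            bh_scope=cfg.bh_scope,
        )
        if not dms.empty:
            dms = shrink_dms_table(dms, penalty_null=cfg.shrinkage_penalty_null)
        out["fits"] = fits
        out["dms"] = dms
    else:
        out["fits"] = pd.DataFrame()
        out["dms"] = pd.DataFrame()

    if cfg.gene_map and cfg.gene_sets and not out["dms"].empty:
        gene_map = read_gene_map(cfg.gene_map)
        gene_sets = read_gene_sets(cfg.gene_sets)
        out["enrichment"] = enrich_gene_sets(out["dms"], gene_map, gene_sets)
    return out


def run_dms_pipeline(cfg: RunConfig) -> dict:
    """File-based entry point: read the sheet and bedMethyl inputs, run
    every stage, write TSV outputs plus a run manifest, and return the
    in-memory results."""
    sheet = read_sample_sheet(cfg.sample_sheet)
    tables = build_count_tables(sheet, cfg.mod_codes)
    native = {m: t["native"] for m, t in tables.items() if "native" in t}
    ivt = {m: t["IVT"] for m, t in tables.items() if "IVT" in t}
    results = analyze_tables(native, ivt, sheet, cfg)

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results["filter_reports"].to_csv(
        outdir / "filter_report.tsv", sep="\t", index=False
    )
    results["fits"].to_csv(outdir / "site_fits.tsv", sep="\t", index=False)
    results["dms"].to_csv(outdir / "dms.tsv", sep="\t", index=False)
    if "enrichment" in results:
        results["enrichment"].to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
    manifest = {
        "dmscall_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": _jsonable(asdict(cfg)),
        "n_samples": int(len(sheet)),
        "n_dms": int(results["dms"]["is_dms"].sum())
        if not results["dms"].empty
        else 0,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
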