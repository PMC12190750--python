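"""False-positive site filtering against an IVT (modification-free) control.

In vitro transcribed (IVT) RNA carries no modifications, so any apparent
modification signal in IVT samples is a calling artifact.  A site is kept
for differential testing only if, in the native samples, it has at least
``min_mean_reads`` mean coverage and at least ``min_native_prop`` modified
proportion, and its IVT modified proportion (when the site is covered in
any IVT sample) is strictly below ``max_ivt_prop``.

Boundary semantics follow the rule set literally: ">=" for the native
coverage and proportion thresholds, strict "<" for the IVT proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SITE_KEY_COLUMNS, SiteCountTable


@dataclass
class FilterConfig:
    """Thresholds for the IVT/coverage filter.

    Defaults are the standard rule set: >=20 mean reads across native
    replicates, >=5% native modification proportion, <5% IVT proportion.
    ``prop_mode`` selects how the per-site proportion is aggregated across
    replicates: "pooled" (sum of modified / sum of total counts,
    depth-weighted — the default) or "mean" (unweighted mean of
    per-replicate proportions over covered replicates).
    """

    min_mean_reads: float = 20.0
    min_native_prop: float = 0.05
    max_ivt_prop: float = 0.05
    prop_mode: str = "pooled"
    require_ivt_coverage: float = 0.0  # strict mode: min IVT mean reads to trust the rule

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_native_prop <= 1.0:
            raise ValueError("min_native_prop must be in [0, 1]")
        if not 0.0 <= self.max_ivt_prop <= 1.0:
            raise ValueError("max_ivt_prop must be in [0, 1]")
        if self.prop_mode not in ("pooled", "mean"):
            raise ValueError("prop_mode must be 'pooled' or 'mean'")


@dataclass
class FilterReport:
    """Per-modification accounting of the filter.

    A site failing several rules is counted against the first failing rule
    in the order coverage -> native proportion -> IVT proportion, so
    ``n_pass + n_fail_coverage + n_fail_native_prop + n_fail_ivt_prop ==
    n_input_sites``.
    """

    mod_code: str
    n_input_sites: int = 0
    n_pass: int = 0
    n_fail_coverage: int = 0
    n_fail_native_prop: int = 0
    n_fail_ivt_prop: int = 0

    def to_dict(self) -> dict:
        return {
            "mod_code": self.mod_code,
            "n_input_sites": self.n_input_sites,
            "n_pass": self.n_pass,
            "n_fail_coverage": self.n_fail_coverage,
            "n_fail_native_prop": self.n_fail_native_prop,
            "n_fail_ivt_prop": self.n_fail_ivt_prop,
        }


def summarize_sites(
    table: SiteCountTable, replicate_set: list[str] | None = None
) -> pd.DataFrame:
    """Per-site coverage and proportion summaries over a replicate set.

    Returns a frame aligned with ``table.sites`` with columns
    ``mean_total_reads`` (mean of modified+canonical over ALL listed
    replicates; zero-coverage replicates contribute 0), ``pooled_prop``
    (summed modified / summed total, 0 with ``undefined_prop=True`` when no
    replicate has coverage) and ``mean_prop`` (mean of per-replicate
    proportions over covered replicates).
    """
    if replicate_set is not None:
        if len(replicate_set) == 0:
            raise ValueError("replicate_set must be nonempty")
        table = table.subset_samples(replicate_set)
    n_mod = table.n_mod
    n_tot = table.n_total
    mean_total = n_tot.mean(axis=1)
    tot_sum = n_tot.sum(axis=1)
    covered = tot_sum > 0
    pooled = np.zeros(table.n_sites)
    np.divide(n_mod.sum(axis=1), tot_sum, out=pooled, where=covered)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_rep = np.where(n_tot > 0, n_mod / np.maximum(n_tot, 1), np.nan)
    n_covered_reps = (n_tot > 0).sum(axis=1)
    mean_prop = np.zeros(table.n_sites)
    has_rep = n_covered_reps > 0
    mean_prop[has_rep] = np.nanmean(per_rep[has_rep], axis=1)
    out = table.sites.copy()
    out["mean_total_reads"] = mean_total
    out["pooled_prop"] = pooled
    out["mean_prop"] = mean_prop
    out["undefined_prop"] = ~covered
    return out


def _prop(summary: pd.DataFrame, mode: str) -> np.ndarray:
    return summary["pooled_prop" if mode == "pooled" else "mean_prop"].to_numpy()


def apply_ivt_filter(
    native_summary: pd.DataFrame,
    ivt_summary: pd.DataFrame | None,
    cfg: FilterConfig | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the coverage / native-proportion / IVT-proportion rules.

    Parameters
    ----------
    native_summary, ivt_summary
        Outputs of :func:`summarize_sites` over the native and IVT sample
        groups.  ``ivt_summary`` may be ``None`` (no IVT control available);
        the IVT rule is then vacuously passed.  Sites absent from the IVT
        summary, or whose IVT coverage has not reached
        ``cfg.require_ivt_coverage`` mean reads, likewise pass the IVT rule:
        an unobserved site cannot be tested against the control.

    Returns
    -------
    (retained, report)
        ``retained`` is the subset of ``native_summary`` rows that pass, in
        input order; ``report`` counts failures against the first failing
        rule (coverage -> native prop -> IVT prop).
    """
    if cfg is None:
        cfg = FilterConfig()
    mod_code = (
        str(native_summary["mod_code"].iloc[0]) if len(native_summary) else ""
    )
    ok_cov = native_summary["mean_total_reads"].to_numpy() >= cfg.min_mean_reads
    ok_nat = _prop(native_summary, cfg.prop_mode) >= cfg.min_native_prop

    if ivt_summary is None or ivt_summary.empty:
        ok_ivt = np.ones(len(native_summary), dtype=bool)
    else:
        ivt = ivt_summary.set_index(SITE_KEY_COLUMNS)
        key_index = pd.MultiIndex.from_frame(native_summary[SITE_KEY_COLUMNS])
        ivt_prop = (
            ivt["pooled_prop" if cfg.prop_mode == "pooled" else "mean_prop"]
            .reindex(key_index)
            .to_numpy()
        )
        ivt_reads = ivt["mean_total_reads"].reindex(key_index).to_numpy()
        observed = np.isfinite(ivt_reads) & (ivt_reads > 0)
        if cfg.require_ivt_coverage > 0:
            observed &= ivt_reads >= cfg.require_ivt_coverage
        ok_ivt = ~observed | (np.nan_to_num(ivt_prop) < cfg.max_ivt_prop)

    retained_mask = ok_cov & ok_nat & ok_ivt
    report = FilterReport(
        mod_code=mod_code,
        n_input_sites=len(native_summary),
        n_pass=int(retained_mask.sum()),
        n_fail_coverage=int((~ok_cov).sum()),
        n_fail_native_prop=int((ok_cov & ~ok_nat).sum()),
        n_fail_ivt_prop=int((ok_cov & ok_nat & ~ok_ivt).sum()),
    )
    return native_summary.loc[retained_mask].reset_index(drop=True), report


def artifact_rates(n_qualifying: int, n_removed_by_ivt: int) -> float:
    """Fraction of sites removed by the IVT rule among sites that already
    passed the coverage and native-proportion rules."""
    if n_removed_by_ivt > n_qualifying:
        raise ValueError("removed count exceeds qualifying count")
    if n_qualifying == 0:
        return 0.0
    return n_removed_by_ivt / n_qualifying
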