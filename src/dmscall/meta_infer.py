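"""Inverse-variance fixed-effects meta-analysis across cell lines, Cochran's
Q heterogeneity filtering, and Benjamini-Hochberg FDR control.

Per-line (beta, SE) pairs for a site are pooled with weights w_i = 1/SE_i^2:

    beta_meta = sum(w_i b_i) / sum(w_i),   se_meta = 1 / sqrt(sum(w_i))

Cochran's Q = sum(w_i (b_i - beta_meta)^2) is chi-square with k-1 degrees
of freedom under homogeneity; sites with Q P-value below ``alpha_het`` are
flagged heterogeneous and excluded before FDR correction, so the discovery
set only contains effects shared across lines.  The machinery is generic:
any per-feature (estimate, SE) table can be pooled with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SITE_KEY_COLUMNS


@dataclass
class MetaFit:
    """Fixed-effects pooled result for one feature."""

    beta_meta: float
    se_meta: float
    z: float
    p: float
    Q: float
    p_Q: float
    k: int
    heterogeneous: bool


def fixed_effects_meta(
    betas, ses, alpha_het: float = 0.05
) -> MetaFit:
    """Inverse-variance fixed-effects pooling of (beta, se) pairs.

    With a single study the pooled result equals the input and p_Q := 1.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no estimates to combine")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have equal length")
    if not np.all(np.isfinite(s)) or (s <= 0).any():
        raise ValueError("standard errors must be finite and positive")
    if not np.all(np.isfinite(b)):
        raise ValueError("estimates must be finite")
    w = 1.0 / (s * s)
    wsum = w.sum()
    beta_meta = float((w * b).sum() / wsum)
    se_meta = float(1.0 / np.sqrt(wsum))
    z = beta_meta / se_meta
    p = float(2.0 * stats.norm.sf(abs(z)))
    k = int(b.size)
    if k == 1:
        Q, p_Q = 0.0, 1.0
    else:
        Q = float((w * (b - beta_meta) ** 2).sum())
        p_Q = float(stats.chi2.sf(Q, k - 1))
    return MetaFit(
        beta_meta=beta_meta,
        se_meta=se_meta,
        z=float(z),
        p=p,
        Q=Q,
        p_Q=p_Q,
        k=k,
        heterogeneous=bool(k >= 2 and p_Q < alpha_het),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN inputs propagate as NaN and do not count toward the number of
    tests.  Output satisfies q >= p, q <= 1, and preserves the input
    ordering (monotone in p).
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def heterogeneity_filter(
    records: pd.DataFrame, alpha_het: float = 0.05
) -> pd.DataFrame:
    """Set the ``heterogeneous`` flag (p_Q < alpha_het, only where k >= 2).

    Flagged sites are retained in the table but excluded from DMS calling.
    """
    out = records.copy()
    out["heterogeneous"] = (out["k"] >= 2) & (out["p_Q"] < alpha_het)
    return out


def meta_analyze_table(
    fits: pd.DataFrame,
    key_columns: list[str],
    alpha_het: float = 0.05,
    min_k: int = 1,
) -> pd.DataFrame:
    """Vectorised fixed-effects meta-analysis of a long per-study table.

    ``fits`` needs columns ``key_columns`` + [beta1, se1]; one row per
    (feature, study).  Features with fewer than ``min_k`` usable studies
    are dropped (``min_k=2`` restricts to features tested in every line of
    a two-line design).
    """
    w = 1.0 / (fits["se1"] ** 2)
    tmp = fits.assign(_w=w, _wb=w * fits["beta1"])
    agg = tmp.groupby(key_columns, sort=True).agg(
        k=("_w", "size"), wsum=("_w", "sum"), wbsum=("_wb", "sum")
    )
    agg["beta_meta"] = agg["wbsum"] / agg["wsum"]
    agg["se_meta"] = 1.0 / np.sqrt(agg["wsum"])
    # Q via sum w b^2 - (sum w b)^2 / sum w
    wb2 = tmp.assign(_wb2=tmp["_w"] * tmp["beta1"] ** 2).groupby(
        key_columns, sort=True
    )["_wb2"].sum()
    Q = np.maximum(wb2 - agg["wbsum"] ** 2 / agg["wsum"], 0.0)
    agg["Q"] = np.where(agg["k"] >= 2, Q, 0.0)
    agg["p_Q"] = np.where(
        agg["k"] >= 2, stats.chi2.sf(agg["Q"], np.maximum(agg["k"] - 1, 1)), 1.0
    )
    agg["z"] = agg["beta_meta"] / agg["se_meta"]
    agg["p"] = 2.0 * stats.norm.sf(np.abs(agg["z"]))
    agg = agg.drop(columns=["wsum", "wbsum"]).reset_index()
    agg = agg[agg["k"] >= min_k]
    return heterogeneity_filter(agg, alpha_het=alpha_het)


def call_dms(
    per_line_fits: list[pd.DataFrame] | pd.DataFrame,
    alpha_het: float = 0.05,
    q_threshold: float = 0.05,
    both_lines_only: bool = False,
    bh_scope: str = "per_mod",
) -> pd.DataFrame:
    """Meta-analyze per-line site fits and call differentially modified sites.

    Only fits that are tested, converged and not pruned contribute.  Sites
    flagged heterogeneous (Cochran's Q P < ``alpha_het``, k >= 2) are
    excluded before BH correction — they do not count toward the number of
    tests — and can never be DMS.  BH runs within each modification code by
    default (``bh_scope="per_mod"``) or over all codes at once ("global").

    ``both_lines_only=True`` restricts to sites tested in at least two
    lines; the default also carries single-line sites (a one-study meta
    equals the study itself).

    Returns one row per meta-analyzed site: key columns, mod_code, k,
    beta_meta, se_meta, z, p, Q, p_Q, heterogeneous, q_value, is_dms, and a
    ``shrunken_beta`` column initialised to NaN for the shrinkage stage.
    """
    if bh_scope not in ("per_mod", "global"):
        raise ValueError("bh_scope must be 'per_mod' or 'global'")
    if isinstance(per_line_fits, list):
        fits = pd.concat(per_line_fits, ignore_index=True)
    else:
        fits = per_line_fits
    usable = (
        fits["tested"]
        & fits["converged"]
        & ~fits["pruned"]
        & np.isfinite(fits["beta1"])
        & np.isfinite(fits["se1"])
        & (fits["se1"] > 0)
    )
    fits = fits.loc[usable]
    meta = meta_analyze_table(
        fits,
        key_columns=SITE_KEY_COLUMNS,
        alpha_het=alpha_het,
        min_k=2 if both_lines_only else 1,
    )
    if meta.empty:
        meta["q_value"] = pd.Series(dtype=float)
        meta["is_dms"] = pd.Series(dtype=bool)
        meta["shrunken_beta"] = pd.Series(dtype=float)
        return meta

    q = np.full(len(meta), np.nan)
    keep = ~meta["heterogeneous"].to_numpy()
    if bh_scope == "global":
        q[keep] = bh_adjust(meta.loc[keep, "p"].to_numpy())
    else:
        for mod in meta["mod_code"].unique():
            mask = keep & (meta["mod_code"] == mod).to_numpy()
            q[mask] = bh_adjust(meta.loc[mask, "p"].to_numpy())
    meta["q_value"] = q
    meta["is_dms"] = keep & (q < q_threshold)
    meta["shrunken_beta"] = np.nan
    return meta.reset_index(drop=True)
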