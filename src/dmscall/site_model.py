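"""Per-site binomial regression of modification counts on condition.

For each site within one cell line the model is a logit-link binomial GLM

    cbind(n_mod, n_canonical) ~ condition

with an intercept and a single indicator for the high-glucose condition.
``beta1`` is the log-odds condition effect (positive = higher modification
in the high condition).  Fitting is by iteratively reweighted least
squares (IRLS); for this saturated two-group design the MLE coincides
with the pooled group log-odds,

    beta1 = log[(M1/C1) / (M0/C0)],   se1 = sqrt(1/M1 + 1/C1 + 1/M0 + 1/C0)

with M/C the pooled modified/canonical counts per condition, which serves
as an independent closed-form cross-check.

Influence diagnostics follow the classical GLM recipe: leverage h_i from
the weighted hat matrix at convergence, Pearson residuals r_i, and Cook's
distance D_i = r_i^2 h_i / (phi * p * (1 - h_i)^2) with dispersion phi = 1
and p = 2 coefficients.  Each D_i is referred to an F(p, n - p)
distribution; a site whose minimum Cook's P-value falls below
``alpha_influence`` is flagged as outlier-driven and pruned from the
downstream meta-analysis (the site is dropped, not the sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import SITE_KEY_COLUMNS, SiteCountTable

logger = logging.getLogger(__name__)

N_COEF = 2  # intercept + condition indicator


@dataclass
class GlmFit:
    """Result of one per-site binomial GLM fit."""

    beta0: float
    beta1: float
    se1: float
    wald_z: float
    p: float
    converged: bool
    n_samples: int
    leverages: np.ndarray
    cooks_d: np.ndarray
    cooks_p: np.ndarray


def _check_counts(n_mod: np.ndarray, n_can: np.ndarray) -> None:
    if (n_mod < 0).any() or (n_can < 0).any():
        raise ValueError("counts must be non-negative")


def fit_glm_batch(
    n_mod: np.ndarray,
    n_canonical: np.ndarray,
    condition: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> dict[str, np.ndarray]:
    """Vectorised IRLS over many sites sharing one design.

    Parameters
    ----------
    n_mod, n_canonical
        (n_sites, n_samples) count matrices.
    condition
        (n_samples,) 0/1 indicator (1 = high condition).

    Returns
    -------
    dict of per-site arrays: beta0, beta1, se1, z, p, converged, testable,
    separated, n_iter, plus per-(site, sample) mu, leverage, cooks_d,
    cooks_p, and n_eff (samples with coverage).  Sites that are not
    testable (a condition with zero total coverage) or separated (a pooled
    margin of zero) are left NaN and flagged.
    """
    n_mod = np.atleast_2d(np.asarray(n_mod, dtype=float))
    n_can = np.atleast_2d(np.asarray(n_canonical, dtype=float))
    _check_counts(n_mod, n_can)
    c = np.asarray(condition, dtype=float)
    if set(np.unique(c)) - {0.0, 1.0}:
        raise ValueError("condition must be coded 0/1")
    S, N = n_mod.shape
    n = n_mod + n_can

    M1 = n_mod @ c
    C1 = n_can @ c
    M0 = n_mod @ (1 - c)
    C0 = n_can @ (1 - c)
    testable = (M1 + C1 > 0) & (M0 + C0 > 0)
    separated = testable & ((M1 == 0) | (C1 == 0) | (M0 == 0) | (C0 == 0))
    fit_mask = testable & ~separated

    beta0 = np.full(S, np.nan)
    beta1 = np.full(S, np.nan)
    se1 = np.full(S, np.nan)
    converged = np.zeros(S, dtype=bool)
    n_iter = np.zeros(S, dtype=int)
    mu_out = np.full((S, N), np.nan)
    lev = np.full((S, N), np.nan)
    cooks_d = np.full((S, N), np.nan)
    cooks_p = np.full((S, N), np.nan)
    n_eff = (n > 0).sum(axis=1)

    idx = np.flatnonzero(fit_mask)
    if idx.size:
        m = n_mod[idx]
        nn = n[idx]
        y = np.where(nn > 0, m / np.maximum(nn, 1.0), 0.0)
        # start at the empirical group log-odds of the adjusted proportions
        b0 = special.logit((m.sum(1) + 0.5) / (nn.sum(1) + 1.0))
        b1 = np.zeros_like(b0)
        active = np.ones(idx.size, dtype=bool)
        it_count = np.zeros(idx.size, dtype=int)
        for _ in range(max_iter):
            if not active.any():
                break
            eta = b0[:, None] + b1[:, None] * c[None, :]
            mu = special.expit(eta)
            v = mu * (1.0 - mu)
            w = nn * v
            z = eta + (y - mu) / v
            S00 = w.sum(1)
            S01 = w @ c
            S11 = (w * c * c).sum(1)
            T0 = (w * z).sum(1)
            T1 = (w * z * c).sum(1)
            det = S00 * S11 - S01 * S01
            nb0 = (S11 * T0 - S01 * T1) / det
            nb1 = (S00 * T1 - S01 * T0) / det
            step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
            b0 = np.where(active, nb0, b0)
            b1 = np.where(active, nb1, b1)
            it_count += active
            active = active & (step >= tol)
        conv = ~active

        eta = b0[:, None] + b1[:, None] * c[None, :]
        mu = special.expit(eta)
        v = mu * (1.0 - mu)
        w = nn * v
        S00 = w.sum(1)
        S01 = w @ c
        S11 = (w * c * c).sum(1)
        det = S00 * S11 - S01 * S01
        se = np.sqrt(S00 / det)

        # leverage: h_i = w_i * x_i' (X'WX)^-1 x_i for x_i = (1, c_i)
        quad = (
            S11[:, None]
            - 2.0 * c[None, :] * S01[:, None]
            + (c * c)[None, :] * S00[:, None]
        ) / det[:, None]
        h = w * quad
        r = (y - mu) * np.sqrt(np.where(nn > 0, nn, 0.0) / v)
        with np.errstate(divide="ignore", invalid="ignore"):
            # h -> 1 in saturated designs (n == p); D is then undefined
            d = r * r * h / (N_COEF * (1.0 - h) ** 2)

        beta0[idx] = b0
        beta1[idx] = b1
        se1[idx] = se
        converged[idx] = conv
        n_iter[idx] = it_count
        mu_out[idx] = mu
        lev[idx] = h
        cooks_d[idx] = d
        df2 = n_eff[idx] - N_COEF
        ok_df = df2 > 0
        cp = np.full_like(d, np.nan)
        if ok_df.any():
            cp[ok_df] = stats.f.sf(d[ok_df], N_COEF, df2[ok_df, None])
        cooks_p[idx] = cp
        # zero-coverage samples carry no influence
        zero = nn == 0
        lev[idx] = np.where(zero, 0.0, lev[idx])
        cooks_d[idx] = np.where(zero, 0.0, cooks_d[idx])
        cooks_p[idx] = np.where(zero & np.isfinite(cooks_p[idx]), 1.0, cooks_p[idx])

    z_stat = beta1 / se1
    p = np.where(np.isfinite(z_stat), 2.0 * stats.norm.sf(np.abs(z_stat)), np.nan)
    return {
        "beta0": beta0,
        "beta1": beta1,
        "se1": se1,
        "z": z_stat,
        "p": p,
        "converged": converged,
        "testable": testable,
        "separated": separated,
        "n_iter": n_iter,
        "mu": mu_out,
        "leverage": lev,
        "cooks_d": cooks_d,
        "cooks_p": cooks_p,
        "n_eff": n_eff,
    }


def fit_site_glm(
    n_mod,
    n_canonical,
    condition,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GlmFit:
    """Fit the binomial GLM for a single site (see module docstring).

    ``condition`` may be 0/1 or the strings "low"/"high".  Raises if a
    condition level has zero total coverage (site not testable); a site
    with quasi-complete separation (a pooled modified or canonical margin
    of zero) returns ``converged=False`` with NaN estimates.
    """
    cond = np.asarray(condition)
    if cond.dtype.kind in "UO":
        cond = (cond == "high").astype(float)
    res = fit_glm_batch(
        np.asarray(n_mod)[None, :],
        np.asarray(n_canonical)[None, :],
        cond,
        tol=tol,
        max_iter=max_iter,
    )
    if not res["testable"][0]:
        raise ValueError("a condition has zero total coverage; site not testable")
    return GlmFit(
        beta0=float(res["beta0"][0]),
        beta1=float(res["beta1"][0]),
        se1=float(res["se1"][0]),
        wald_z=float(res["z"][0]),
        p=float(res["p"][0]),
        converged=bool(res["converged"][0]),
        n_samples=int(res["n_eff"][0]),
        leverages=res["leverage"][0],
        cooks_d=res["cooks_d"][0],
        cooks_p=res["cooks_p"][0],
    )


def glm_cooks(
    n_mod, n_canonical, condition, mu: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cook's distances and their F-distribution P-values at a fitted mean.

    Exposed separately so diagnostics can be recomputed at any fitted
    ``mu``; :func:`fit_site_glm` already returns them at convergence.
    """
    cond = np.asarray(condition)
    if cond.dtype.kind in "UO":
        cond = (cond == "high").astype(float)
    nn = np.asarray(n_mod, dtype=float) + np.asarray(n_canonical, dtype=float)
    y = np.where(nn > 0, np.asarray(n_mod, dtype=float) / np.maximum(nn, 1.0), 0.0)
    v = mu * (1.0 - mu)
    w = nn * v
    S00 = w.sum()
    S01 = w @ cond
    S11 = (w * cond * cond).sum()
    det = S00 * S11 - S01 * S01
    h = w * (S11 - 2.0 * cond * S01 + cond * cond * S00) / det
    r = (y - mu) * np.sqrt(np.where(nn > 0, nn, 0.0) / v)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r * r * h / (N_COEF * (1.0 - h) ** 2)
    n_eff = int((nn > 0).sum())
    if n_eff <= N_COEF:
        logger.warning(
            "Cook's P undefined with %d covered samples and %d coefficients",
            n_eff,
            N_COEF,
        )
        p = np.full_like(d, np.nan)
    else:
        p = stats.f.sf(d, N_COEF, n_eff - N_COEF)
    d = np.where(nn == 0, 0.0, d)
    p = np.where((nn == 0) & np.isfinite(p), 1.0, p)
    return d, p


@dataclass
class SiteModelConfig:
    """Eligibility and pruning settings for per-line site testing."""

    min_mean_reads: float = 20.0
    min_prop: float = 0.05
    prop_mode: str = "pooled"
    alpha_influence: float = 0.05


def test_sites_per_line(
    table: SiteCountTable,
    sample_sheet: pd.DataFrame,
    cell_line: str,
    cfg: SiteModelConfig | None = None,
) -> pd.DataFrame:
    """Fit every eligible site of one cell line's native samples.

    Eligibility (mean total reads >= ``min_mean_reads`` and modification
    proportion >= ``min_prop``) is re-applied within the line.  Returns one
    row per input site with fit results and flags: ``tested`` (eligible and
    both conditions covered), ``converged``, ``pruned`` (minimum Cook's
    P-value below ``alpha_influence``), ``min_cooks_p``.  Pruned or
    unconverged sites keep their row — pruning removes a site from the
    downstream meta-analysis, not from the record.
    """
    if cfg is None:
        cfg = SiteModelConfig()
    sel = sample_sheet[
        (sample_sheet["cell_line"] == cell_line)
        & (sample_sheet["material"] == "native")
    ]
    if sel.empty:
        raise ValueError(f"no native samples for cell line {cell_line!r}")
    sub = table.subset_samples(sel["sample_id"].tolist())
    cond = (sel["condition"] == "high").to_numpy(dtype=float)
    if cond.sum() == 0 or cond.sum() == len(cond):
        raise ValueError(f"cell line {cell_line!r} lacks one of the conditions")

    n_tot = sub.n_total
    mean_reads = n_tot.mean(axis=1)
    tot = n_tot.sum(axis=1)
    with np.errstate(invalid="ignore"):
        if cfg.prop_mode == "pooled":
            prop = np.where(tot > 0, sub.n_mod.sum(axis=1) / np.maximum(tot, 1), 0.0)
        else:
            per = np.where(n_tot > 0, sub.n_mod / np.maximum(n_tot, 1), np.nan)
            prop = np.where(
                (n_tot > 0).any(axis=1), np.nanmean(per, axis=1), 0.0
            )
    eligible = (mean_reads >= cfg.min_mean_reads) & (prop >= cfg.min_prop)

    res = fit_glm_batch(sub.n_mod, sub.n_canonical, cond)
    tested = eligible & res["testable"]

    with np.errstate(invalid="ignore"):
        min_cooks_p = np.nanmin(
            np.where(np.isfinite(res["cooks_p"]), res["cooks_p"], np.inf), axis=1
        )
    min_cooks_p = np.where(np.isfinite(min_cooks_p), min_cooks_p, np.nan)
    prunable = np.isfinite(min_cooks_p)
    pruned = tested & res["converged"] & prunable & (min_cooks_p < cfg.alpha_influence)

    out = table.sites.copy()
    out["mod_code"] = table.mod_code
    out["cell_line"] = cell_line
    out["beta0"] = np.where(tested, res["beta0"], np.nan)
    out["beta1"] = np.where(tested, res["beta1"], np.nan)
    out["se1"] = np.where(tested, res["se1"], np.nan)
    out["z"] = np.where(tested, res["z"], np.nan)
    out["p"] = np.where(tested, res["p"], np.nan)
    out["tested"] = tested
    out["converged"] = res["converged"] & tested
    out["separated"] = res["separated"]
    out["pruned"] = pruned
    out["min_cooks_p"] = np.where(tested, min_cooks_p, np.nan)
    out["n_samples"] = res["n_eff"]
    out["mean_total_reads"] = mean_reads
    return out


def pooled_logodds_oracle(
    n_mod, n_canonical, condition
) -> tuple[float, float]:
    """Closed-form pooled log-odds estimate and SE for the two-group design.

    This is the textbook 2x2-table estimator that the IRLS fit must agree
    with on non-separated tables; kept in the package as a fast path for
    sanity checks.
    """
    m = np.asarray(n_mod, dtype=float)
    cn = np.asarray(n_canonical, dtype=float)
    c = np.asarray(condition, dtype=float)
    M1, C1 = m @ c, cn @ c
    M0, C0 = m @ (1 - c), cn @ (1 - c)
    if min(M1, C1, M0, C0) <= 0:
        raise ValueError("separated table: a pooled margin is zero")
    beta1 = np.log((M1 / C1) / (M0 / C0))
    se1 = np.sqrt(1 / M1 + 1 / C1 + 1 / M0 + 1 / C0)
    return float(beta1), float(se1)
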