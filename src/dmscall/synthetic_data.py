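"""Synthetic bedMethyl experiments with known ground truth.

The generator emulates the count-level statistical structure the pipeline
assumes: two cell lines (3 and 4 replicates per condition, mirroring the
EndoC-BH1/EndoC-BH3 design), two glucose conditions, per-site binomial
modification counts with negative-binomial coverage, matched IVT
(modification-free) samples, a subset of sites with a true condition
effect on the log-odds scale, a subset with line-specific (heterogeneous)
effects, a subset of IVT artifact sites (false positives with substantial
IVT signal), and optionally injected outlier replicates whose conditions
are swapped.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
stream seeded from ``SimConfig.seed``, so outputs are byte-identical
across runs and platforms for a given numpy major version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .io_formats import (
    SAMPLE_SHEET_COLUMNS,
    SITE_KEY_COLUMNS,
    SiteCountTable,
    SiteKey,
    SiteRecord,
    validate_sample_sheet,
    write_bedmethyl,
)


@dataclass
class SimConfig:
    """Study-design and effect-structure parameters of the simulator.

    Defaults reproduce the statistical conditions the pipeline is meant
    for: replicate structure (3, 4) per condition across two lines,
    negative-binomial coverage with mean 60 and size 5, baseline
    modification proportions from Beta(2, 8) truncated to >= 0.05, a 1%
    mean basecalling error floor (Beta(1, 99)) at unmodified/IVT
    positions, 10% true differentially modified sites with |delta logit| =
    1.5, 2% line-heterogeneous sites and 5% IVT artifact sites whose
    artifact proportion is drawn from Beta(2, 8).
    """

    seed: int = 0
    n_sites: int = 1000
    mod_codes: tuple[str, ...] = ("a",)
    cell_lines: dict[str, int] = field(
        default_factory=lambda: {"lineA": 3, "lineB": 4}
    )  # replicates per condition
    depth_mean: float = 60.0
    depth_dispersion: float | None = 5.0  # neg-binomial size; None = constant depth
    baseline_alpha: float = 2.0
    baseline_beta: float = 8.0
    baseline_min: float = 0.05
    error_floor_alpha: float = 1.0
    error_floor_beta: float = 99.0
    error_floor_max: float = 0.0125  # clean-site miscall rate stays below the filter threshold
    frac_dms: float = 0.1
    effect_size: float = 1.5  # |delta logit| for fixed-effect mode
    effect_sd: float = 0.0  # >0 switches to delta ~ N(0, effect_sd^2)
    frac_line_heterogeneous: float = 0.02
    frac_ivt_artifact: float = 0.05
    artifact_alpha: float = 2.0
    artifact_beta: float = 8.0
    ivt_replicates_per_line: int = 2
    outlier_rate: float = 0.0  # per (line, replicate) probability
    outlier_replicates: dict[str, tuple[int, ...]] | None = None  # deterministic injection
    sites_per_transcript: int = 3

    def __post_init__(self) -> None:
        for name in ("frac_dms", "frac_line_heterogeneous", "frac_ivt_artifact"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for line, reps in self.cell_lines.items():
            if reps < 2:
                raise ValueError(
                    f"cell line {line!r} needs >=2 replicates per condition"
                )
        unknown = set(self.mod_codes) - {"a", "m", "17596", "17802"}
        if unknown:
            raise ValueError(f"unknown mod codes: {sorted(unknown)}")


@dataclass
class SimResult:
    """In-memory simulated experiment: sheet, truth and count tables."""

    config: SimConfig
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame
    native: dict[str, SiteCountTable]
    ivt: dict[str, SiteCountTable]


def _draw_depth(rng: np.random.Generator, size, mean: float, disp: float | None):
    if disp is None:
        return np.full(size, int(round(mean)), dtype=np.int64)
    # negative binomial parameterised by mean and size (overdispersion)
    p = disp / (disp + mean)
    return rng.negative_binomial(disp, p, size=size)


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Generate a full experiment (native + IVT samples) with truth table.

    For each site, line, condition and replicate: coverage n ~
    NegBin(depth_mean, depth_dispersion) and modified count ~ Binomial(n,
    p) with logit(p) = logit(baseline) + delta_line * 1[high].  Artifact
    sites use their artifact proportion in both native conditions (no
    effect) and in IVT samples; clean sites' IVT proportion is the error
    floor.  Outlier replicates swap the two conditions' success
    probabilities.
    """
    rng = np.random.default_rng(cfg.seed)
    lines = list(cfg.cell_lines)

    # ---- sample sheet -----------------------------------------------------
    rows = []
    for line in lines:
        for rep in range(1, cfg.cell_lines[line] + 1):
            for cond in ("low", "high"):
                rows.append(
                    {
                        "sample_id": f"{line}_{cond}_native_rep{rep}",
                        "cell_line": line,
                        "condition": cond,
                        "material": "native",
                        "replicate": rep,
                        "path": "",
                    }
                )
        for rep in range(1, cfg.ivt_replicates_per_line + 1):
            cond = "low" if rep % 2 == 1 else "high"
            rows.append(
                {
                    "sample_id": f"{line}_{cond}_IVT_rep{rep}",
                    "cell_line": line,
                    "condition": cond,
                    "material": "IVT",
                    "replicate": rep,
                    "path": "",
                }
            )
    sheet = pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)

    native_tables: dict[str, SiteCountTable] = {}
    ivt_tables: dict[str, SiteCountTable] = {}
    truth_frames = []
    for mod_code in cfg.mod_codes:
        S = cfg.n_sites

        # ---- site identities ---------------------------------------------
        tx_idx = np.arange(S) // cfg.sites_per_transcript
        offset = np.arange(S) % cfg.sites_per_transcript
        refs = np.array([f"tx{i:06d}" for i in tx_idx])
        starts = 100 + 37 * offset
        sites = pd.DataFrame(
            {
                "reference": refs,
                "start": starts,
                "end": starts + 1,
                "strand": "+",
                "mod_code": mod_code,
            }
        )

        # ---- truth --------------------------------------------------------
        is_artifact = rng.random(S) < cfg.frac_ivt_artifact
        is_dms = ~is_artifact & (rng.random(S) < cfg.frac_dms)
        is_het = ~is_artifact & (rng.random(S) < cfg.frac_line_heterogeneous)

        baseline = rng.beta(cfg.baseline_alpha, cfg.baseline_beta, size=S)
        # truncate to the detectable range by redrawing
        low = baseline < cfg.baseline_min
        while low.any():
            baseline[low] = rng.beta(
                cfg.baseline_alpha, cfg.baseline_beta, size=int(low.sum())
            )
            low = baseline < cfg.baseline_min
        artifact_prop = rng.beta(cfg.artifact_alpha, cfg.artifact_beta, size=S)
        error_floor = rng.beta(
            cfg.error_floor_alpha, cfg.error_floor_beta, size=S
        )
        # basecaller miscalls at clean sites are rare and, unlike artifact
        # sites, stay well below the filter threshold: redraw tail values
        high = error_floor >= cfg.error_floor_max
        while high.any():
            error_floor[high] = rng.beta(
                cfg.error_floor_alpha, cfg.error_floor_beta, size=int(high.sum())
            )
            high = error_floor >= cfg.error_floor_max
        # keep the error floor strictly positive for binomial draws
        error_floor = np.clip(error_floor, 1e-6, None)

        def draw_delta(size):
            if cfg.effect_sd > 0:
                return rng.normal(0.0, cfg.effect_sd, size=size)
            return cfg.effect_size * rng.choice([-1.0, 1.0], size=size)

        delta = {line: np.zeros(S) for line in lines}
        shared = draw_delta(S)
        for line in lines:
            d = np.zeros(S)
            d[is_dms & ~is_het] = shared[is_dms & ~is_het]
            # heterogeneous sites: independent per-line effect (may be a DMS
            # in one line and null or opposite in the other)
            d[is_het] = draw_delta(int(is_het.sum()))
            delta[line] = d
        any_effect = np.zeros(S, dtype=bool)
        for line in lines:
            any_effect |= delta[line] != 0.0

        # native site proportion by line x condition
        native_p = {}
        for line in lines:
            base_logit = special.logit(baseline)
            for cond_idx, cond in enumerate(("low", "high")):
                p = special.expit(base_logit + delta[line] * cond_idx)
                p = np.where(is_artifact, artifact_prop, p)
                native_p[(line, cond)] = p

        # ---- outlier replicates ------------------------------------------
        outlier_samples: list[str] = []
        outlier_reps: dict[str, set[int]] = {line: set() for line in lines}
        for line in lines:
            if cfg.outlier_replicates is not None:
                chosen = set(cfg.outlier_replicates.get(line, ()))
            else:
                chosen = {
                    rep
                    for rep in range(1, cfg.cell_lines[line] + 1)
                    if rng.random() < cfg.outlier_rate
                }
            outlier_reps[line] = chosen
            outlier_samples.extend(
                f"{line}_{cond}_native_rep{rep}"
                for rep in sorted(chosen)
                for cond in ("low", "high")
            )

        # ---- counts -------------------------------------------------------
        native_samples = sheet.loc[sheet["material"] == "native"]
        n_mod_cols, n_can_cols, col_ids = [], [], []
        for row in native_samples.itertuples(index=False):
            cond = row.condition
            if row.replicate in outlier_reps[row.cell_line]:
                cond = "high" if cond == "low" else "low"  # swapped conditions
            p = native_p[(row.cell_line, cond)]
            n = _draw_depth(rng, S, cfg.depth_mean, cfg.depth_dispersion)
            m = rng.binomial(n, p)
            n_mod_cols.append(m)
            n_can_cols.append(n - m)
            col_ids.append(row.sample_id)
        native_tables[mod_code] = SiteCountTable(
            mod_code=mod_code,
            sites=sites,
            samples=col_ids,
            n_mod=np.column_stack(n_mod_cols).astype(np.int64),
            n_canonical=np.column_stack(n_can_cols).astype(np.int64),
        )

        ivt_p = np.where(is_artifact, artifact_prop, error_floor)
        ivt_samples = sheet.loc[sheet["material"] == "IVT"]
        n_mod_cols, n_can_cols, col_ids = [], [], []
        for row in ivt_samples.itertuples(index=False):
            n = _draw_depth(rng, S, cfg.depth_mean, cfg.depth_dispersion)
            m = rng.binomial(n, ivt_p)
            n_mod_cols.append(m)
            n_can_cols.append(n - m)
            col_ids.append(row.sample_id)
        ivt_tables[mod_code] = SiteCountTable(
            mod_code=mod_code,
            sites=sites,
            samples=col_ids,
            n_mod=np.column_stack(n_mod_cols).astype(np.int64),
            n_canonical=np.column_stack(n_can_cols).astype(np.int64),
        )

        truth = sites.copy()
        truth["true_baseline_prop"] = np.where(is_artifact, artifact_prop, baseline)
        for line in lines:
            truth[f"true_delta_{line}"] = delta[line]
        truth["true_delta_mean"] = np.mean([delta[line] for line in lines], axis=0)
        truth["is_dms"] = any_effect
        truth["is_artifact"] = is_artifact
        truth["is_heterogeneous"] = is_het
        truth["ivt_prop"] = ivt_p
        truth["outlier_samples"] = ";".join(sorted(outlier_samples))
        truth_frames.append(truth)

    return SimResult(
        config=cfg,
        sample_sheet=sheet,
        truth=pd.concat(truth_frames, ignore_index=True),
        native=native_tables,
        ivt=ivt_tables,
    )


def table_to_records(table: SiteCountTable, sample_id: str) -> list[SiteRecord]:
    """Extract one sample's covered sites as bedMethyl records."""
    j = table.samples.index(sample_id)
    m = table.n_mod[:, j]
    cn = table.n_canonical[:, j]
    covered = (m + cn) > 0
    keys = table.sites.loc[covered]
    recs = []
    for key_row, mi, ci in zip(
        keys.itertuples(index=False), m[covered], cn[covered]
    ):
        recs.append(
            SiteRecord(
                key=SiteKey(*key_row),
                sample_id=sample_id,
                n_valid=int(mi + ci),
                n_mod=int(mi),
                n_canonical=int(ci),
                n_other=0,
            )
        )
    return recs


def write_experiment(sim: SimResult, outdir) -> pd.DataFrame:
    """Materialise a simulated experiment: one bedMethyl file per sample,
    ``samples.tsv`` and ``truth.tsv``.  Returns the sheet with paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet = sim.sample_sheet.copy()
    paths = []
    for row in sheet.itertuples(index=False):
        tables = sim.native if row.material == "native" else sim.ivt
        recs: list[SiteRecord] = []
        for mod_code in sorted(tables):
            if row.sample_id in tables[mod_code].samples:
                recs.extend(table_to_records(tables[mod_code], row.sample_id))
        path = outdir / f"{row.sample_id}.bed"
        write_bedmethyl(recs, path)
        paths.append(str(path))
    sheet["path"] = paths
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    validate_sample_sheet(sheet)
    return sheet


def make_gene_map(references, transcripts_per_gene: int = 2) -> pd.DataFrame:
    """Synthetic transcript->gene map grouping consecutive transcripts."""
    refs = sorted(set(references))
    rows = [
        {
            "transcript_id": tx,
            "gene_id": f"gene{i // transcripts_per_gene:05d}",
            "gene_name": f"GENE{i // transcripts_per_gene:05d}",
        }
        for i, tx in enumerate(refs)
    ]
    return pd.DataFrame(rows)


def truth_eval(dms: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Compare a DMS table with simulator ground truth.

    Heterogeneous truth sites are excluded from the power denominator (the
    pipeline removes them by design); artifact and null sites called DMS
    count as false discoveries.  ``power`` is computed over true DMS sites
    that entered the table (passed filters); ``rmse``/``correlation``
    compare ``beta_meta`` (and ``shrunken_beta``) with the true mean
    log-odds effect.
    """
    merged = dms.merge(truth, on=SITE_KEY_COLUMNS, how="inner", validate="1:1")
    if merged.empty:
        raise ValueError("DMS table and truth share no site keys")
    called = merged["is_dms_x"].to_numpy(dtype=bool)
    true_dms = merged["is_dms_y"].to_numpy(dtype=bool)
    het = merged["is_heterogeneous"].to_numpy(dtype=bool)
    n_called = int(called.sum())
    fdp = float((called & ~true_dms).sum() / n_called) if n_called else 0.0
    power_denom = true_dms & ~het
    power = (
        float((called & power_denom).sum() / power_denom.sum())
        if power_denom.any()
        else float("nan")
    )
    eff = merged.loc[power_denom]
    metrics = {
        "n_tested": int(len(merged)),
        "n_called": n_called,
        "fdp": fdp,
        "power": power,
    }
    if len(eff) >= 2:
        tr = eff["true_delta_mean"].to_numpy()
        raw = eff["beta_meta"].to_numpy()
        metrics["effect_correlation"] = float(np.corrcoef(tr, raw)[0, 1])
        metrics["effect_rmse_raw"] = float(np.sqrt(np.mean((raw - tr) ** 2)))
        if "shrunken_beta" in eff and np.isfinite(eff["shrunken_beta"]).all():
            sh = eff["shrunken_beta"].to_numpy()
            metrics["effect_correlation_shrunk"] = float(
                np.corrcoef(tr, sh)[0, 1]
            )
            metrics["effect_rmse_shrunk"] = float(np.sqrt(np.mean((sh - tr) ** 2)))
    # estimation error over every tested site (nulls included)
    tr_all = merged["true_delta_mean"].to_numpy()
    raw_all = merged["beta_meta"].to_numpy()
    metrics["rmse_all_raw"] = float(np.sqrt(np.mean((raw_all - tr_all) ** 2)))
    if "shrunken_beta" in merged and np.isfinite(merged["shrunken_beta"]).all():
        sh_all = merged["shrunken_beta"].to_numpy()
        metrics["rmse_all_shrunk"] = float(np.sqrt(np.mean((sh_all - tr_all) ** 2)))
    return metrics
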