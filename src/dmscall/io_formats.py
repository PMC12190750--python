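"""Reading and writing of modkit-style bedMethyl files and sample sheets.

bedMethyl is a tab-separated BED-derived format with one row per reference
position, strand and modification code, carrying per-position read counts.
The modkit pileup dialect has 18 columns::

    chrom start end mod_code score strand thickStart thickEnd color
    n_valid percent n_mod n_canonical n_other_mod n_delete n_fail n_diff n_nocall

Coordinates are 0-based half-open and every row spans exactly one
nucleotide (``end == start + 1``).  ``percent`` is on a 0-100 scale in the
file; internally proportions are stored as fractions in [0, 1] and are
always recomputed from the count columns when those are present — counts
are the primary data, the percent column is advisory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Modification codes understood by the pipeline, as emitted by modkit:
#: "a" = N6-methyladenosine (m6A), "m" = 5-methylcytosine (m5C),
#: "17596" = inosine, "17802" = pseudouridine (ChEBI identifiers for the
#: latter two).
MOD_CODES = ("a", "m", "17596", "17802")
MOD_NAMES = {"a": "m6A", "m": "m5C", "17596": "inosine", "17802": "pseudouridine"}

SITE_KEY_COLUMNS = ["reference", "start", "end", "strand", "mod_code"]


class SiteKey(NamedTuple):
    """Identity of one modification site: a single nucleotide on one
    strand of one reference sequence, for one modification code."""

    reference: str
    start: int
    end: int
    strand: str
    mod_code: str


@dataclass
class SiteRecord:
    """One bedMethyl row: counts for one site in one sample.

    ``n_valid`` is the valid coverage and always equals
    ``n_mod + n_canonical + n_other`` (other = reads called as a different
    modification at the same base).  ``percent_modified`` is the fraction
    ``n_mod / n_valid`` (0.0 when the site has no valid coverage).
    """

    key: SiteKey
    sample_id: str
    n_valid: int
    n_mod: int
    n_canonical: int
    n_other: int = 0

    @property
    def percent_modified(self) -> float:
        if self.n_valid == 0:
            return 0.0
        return self.n_mod / self.n_valid


class BedmethylParseError(ValueError):
    """Raised for malformed bedMethyl rows; message names the line number."""


def _parse_int(text: str, what: str, path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise BedmethylParseError(
            f"{path}:{lineno}: non-integer {what}: {text!r}"
        ) from None


def read_bedmethyl(
    path,
    allowed_mod_codes: Iterable[str] | None = MOD_CODES,
    sample_id: str = "",
    stats: dict | None = None,
) -> list[SiteRecord]:
    """Parse a bedMethyl file into :class:`SiteRecord` objects.

    Parameters
    ----------
    path
        Tab-separated bedMethyl file (>= 11 columns; modkit writes 18).
    allowed_mod_codes
        Rows whose modification code is not in this set are skipped and
        counted (``stats["skipped_mod_code"]``).  ``None`` keeps all codes.
    sample_id
        Stored on every returned record.
    stats
        Optional dict that receives parse counters: ``n_rows``,
        ``skipped_mod_code`` and ``reconstructed_counts`` (rows whose count
        columns were missing and had to be rebuilt from the percent column).

    Raises
    ------
    BedmethylParseError
        On malformed rows (non-integer counts, width != 1, unknown strand,
        count columns inconsistent with ``n_valid``), naming the line.
    """
    allowed = None if allowed_mod_codes is None else set(allowed_mod_codes)
    counters = {"n_rows": 0, "skipped_mod_code": 0, "reconstructed_counts": 0}
    records: list[SiteRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise BedmethylParseError(
                    f"{path}:{lineno}: expected >=11 tab-separated columns, "
                    f"got {len(fields)}"
                )
            counters["n_rows"] += 1
            mod_code = fields[3]
            if allowed is not None and mod_code not in allowed:
                counters["skipped_mod_code"] += 1
                continue
            start = _parse_int(fields[1], "start", path, lineno)
            end = _parse_int(fields[2], "end", path, lineno)
            if end != start + 1:
                raise BedmethylParseError(
                    f"{path}:{lineno}: expected single-nucleotide interval "
                    f"(end == start + 1), got [{start}, {end})"
                )
            strand = fields[5]
            if strand not in ("+", "-"):
                raise BedmethylParseError(
                    f"{path}:{lineno}: unknown strand {strand!r}"
                )
            n_valid = _parse_int(fields[9], "n_valid", path, lineno)
            if len(fields) >= 13:
                n_mod = _parse_int(fields[11], "n_mod", path, lineno)
                n_canonical = _parse_int(fields[12], "n_canonical", path, lineno)
                n_other = (
                    _parse_int(fields[13], "n_other", path, lineno)
                    if len(fields) >= 14
                    else 0
                )
                if n_mod + n_canonical + n_other != n_valid:
                    raise BedmethylParseError(
                        f"{path}:{lineno}: n_mod + n_canonical + n_other "
                        f"({n_mod}+{n_canonical}+{n_other}) != n_valid ({n_valid})"
                    )
            else:
                # Count columns absent: rebuild from the percent column.
                try:
                    percent = float(fields[10])
                except ValueError:
                    raise BedmethylParseError(
                        f"{path}:{lineno}: non-numeric percent: {fields[10]!r}"
                    ) from None
                n_mod = int(round(percent / 100.0 * n_valid))
                n_canonical = n_valid - n_mod
                n_other = 0
                counters["reconstructed_counts"] += 1
                logger.warning(
                    "%s:%d: count columns missing; reconstructed n_mod=%d "
                    "from percent column",
                    path,
                    lineno,
                    n_mod,
                )
            records.append(
                SiteRecord(
                    key=SiteKey(fields[0], start, end, strand, mod_code),
                    sample_id=sample_id,
                    n_valid=n_valid,
                    n_mod=n_mod,
                    n_canonical=n_canonical,
                    n_other=n_other,
                )
            )
    if stats is not None:
        stats.update(counters)
    return records


def write_bedmethyl(records: Sequence[SiteRecord], path) -> None:
    """Write records as 18-column modkit-dialect bedMethyl.

    The percent column is written to two decimals from the counts (0.00
    for zero-coverage records); ``read_bedmethyl(write_bedmethyl(R))``
    reproduces every integer field of ``R`` exactly.
    """
    with open(path, "w") as fh:
        for rec in records:
            k = rec.key
            percent = 100.0 * rec.percent_modified
            fh.write(
                "\t".join(
                    [
                        k.reference,
                        str(k.start),
                        str(k.end),
                        k.mod_code,
                        str(min(rec.n_valid, 1000)),
                        k.strand,
                        str(k.start),
                        str(k.end),
                        "255,0,0",
                        str(rec.n_valid),
                        f"{percent:.2f}",
                        str(rec.n_mod),
                        str(rec.n_canonical),
                        str(rec.n_other),
                        "0",
                        "0",
                        "0",
                        "0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# sample sheets

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "cell_line",
    "condition",
    "material",
    "replicate",
    "path",
]

CONDITIONS = ("low", "high")
MATERIALS = ("native", "IVT")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a tab-separated sample sheet.

    Required columns: sample_id, cell_line, condition (low|high),
    material (native|IVT), replicate, path.
    """
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str})
    return validate_sample_sheet(sheet)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in sample sheet: {dupes}")
    bad_cond = set(sheet["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition values: {sorted(bad_cond)}")
    bad_mat = set(sheet["material"]) - set(MATERIALS)
    if bad_mat:
        raise ValueError(f"unknown material values: {sorted(bad_mat)}")
    return sheet


def read_gene_map(path) -> pd.DataFrame:
    """Read a transcript-to-gene map TSV (transcript_id, gene_id[, gene_name])."""
    gm = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("transcript_id", "gene_id"):
        if col not in gm.columns:
            raise ValueError(f"gene map missing column {col!r}")
    return gm


# ---------------------------------------------------------------------------
# count tables


@dataclass
class SiteCountTable:
    """Dense per-(site, sample) modified/canonical count matrices for one
    modification code.

    Sites absent from a sample are encoded as (0, 0) — "not covered".
    """

    mod_code: str
    sites: pd.DataFrame  # columns SITE_KEY_COLUMNS, one row per site
    samples: list[str]
    n_mod: np.ndarray  # (n_sites, n_samples) int64
    n_canonical: np.ndarray  # (n_sites, n_samples) int64

    def __post_init__(self) -> None:
        if self.n_mod.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count matrix shape does not match sites/samples")
        if self.n_canonical.shape != self.n_mod.shape:
            raise ValueError("n_mod and n_canonical shapes differ")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_total(self) -> np.ndarray:
        return self.n_mod + self.n_canonical

    def site_keys(self) -> list[SiteKey]:
        return [SiteKey(*row) for row in self.sites.itertuples(index=False)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "SiteCountTable":
        """Restrict to the given samples (order preserved as given)."""
        idx = [self.samples.index(s) for s in sample_ids]
        return SiteCountTable(
            mod_code=self.mod_code,
            sites=self.sites,
            samples=list(sample_ids),
            n_mod=self.n_mod[:, idx],
            n_canonical=self.n_canonical[:, idx],
        )

    def subset_sites(self, mask: np.ndarray) -> "SiteCountTable":
        return SiteCountTable(
            mod_code=self.mod_code,
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=self.samples,
            n_mod=self.n_mod[np.asarray(mask)],
            n_canonical=self.n_canonical[np.asarray(mask)],
        )


def records_to_frame(records: Iterable[SiteRecord]) -> pd.DataFrame:
    rows = [
        (
            r.key.reference,
            r.key.start,
            r.key.end,
            r.key.strand,
            r.key.mod_code,
            r.sample_id,
            r.n_valid,
            r.n_mod,
            r.n_canonical,
            r.n_other,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=SITE_KEY_COLUMNS
        + ["sample_id", "n_valid", "n_mod", "n_canonical", "n_other"],
    )


def frame_to_count_tables(
    frame: pd.DataFrame, samples: Sequence[str]
) -> dict[str, SiteCountTable]:
    """Pivot a long record frame into one dense table per modification code.

    Every site observed in at least one of ``samples`` appears; missing
    (site, sample) cells are filled with (0, 0).  Duplicate (site, sample)
    rows are ambiguous and raise.
    """
    samples = list(samples)
    tables: dict[str, SiteCountTable] = {}
    frame = frame[frame["sample_id"].isin(samples)]
    for mod_code, sub in frame.groupby("mod_code", sort=True):
        dup = sub.duplicated(subset=SITE_KEY_COLUMNS + ["sample_id"])
        if dup.any():
            first = sub.loc[dup].iloc[0]
            raise ValueError(
                "duplicate counts for site "
                f"{tuple(first[c] for c in SITE_KEY_COLUMNS)} in sample "
                f"{first['sample_id']!r}"
            )
        wide_mod = (
            sub.pivot(index=SITE_KEY_COLUMNS, columns="sample_id", values="n_mod")
            .reindex(columns=samples)
            .fillna(0)
        )
        wide_can = (
            sub.pivot(
                index=SITE_KEY_COLUMNS, columns="sample_id", values="n_canonical"
            )
            .reindex(columns=samples)
            .fillna(0)
        )
        sites = wide_mod.index.to_frame(index=False)
        tables[str(mod_code)] = SiteCountTable(
            mod_code=str(mod_code),
            sites=sites,
            samples=samples,
            n_mod=wide_mod.to_numpy(dtype=np.int64),
            n_canonical=wide_can.to_numpy(dtype=np.int64),
        )
    return tables


def build_count_tables(
    sample_sheet: pd.DataFrame,
    allowed_mod_codes: Iterable[str] = MOD_CODES,
) -> dict[str, dict[str, SiteCountTable]]:
    """Read every file in the sheet and assemble count tables.

    Returns ``{mod_code: {"native": table, "IVT": table}}``; a material with
    no samples in the sheet is absent from the inner dict.
    """
    validate_sample_sheet(sample_sheet)
    out: dict[str, dict[str, SiteCountTable]] = {}
    for material, msheet in sample_sheet.groupby("material"):
        records: list[SiteRecord] = []
        for row in msheet.itertuples(index=False):
            records.extend(
                read_bedmethyl(
                    row.path, allowed_mod_codes, sample_id=row.sample_id
                )
            )
        frame = records_to_frame(records)
        if frame.empty:
            continue
        tables = frame_to_count_tables(frame, msheet["sample_id"].tolist())
        for mod_code, table in tables.items():
            out.setdefault(mod_code, {})[str(material)] = table
    return out
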