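"""Reading, validating and summarising IBD segment tables.

Tables are tab-separated with a header row; ``#``-prefixed lines are comments.
Column names in a file are mapped onto the standard schema through a *dialect*
(standard name -> file column name), so output of different IBD callers can be
consumed by remapping the header only.

Standard segment schema: ``iid1, iid2, chrom, start_cM, end_cM, length_cM,
n_snps``. Pairs are canonicalized so that ``iid1 <= iid2`` lexicographically;
the pair is unordered throughout.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: standard column -> default file column (ancIBD-style layout)
DEFAULT_DIALECT: dict[str, str] = {
    "iid1": "iid1",
    "iid2": "iid2",
    "chrom": "ch",
    "start_cM": "start_cm",
    "end_cM": "end_cm",
    "length_cM": "length_cm",
    "n_snps": "n_snps",
}

SEGMENT_COLUMNS = list(DEFAULT_DIALECT)

#: closed macroregion vocabulary for individual metadata
REGIONS = ("C.Basin", "C.Asia", "E.E.Steppe", "other")

#: tolerance for agreement of stated length with end - start (cM)
LENGTH_ATOL_CM = 1e-6


class DataFormatError(ValueError):
    """Table-level problem: unreadable input or missing required column."""


class RecordError(ValueError):
    """Row-level problem; message lists offending line numbers."""


@dataclass(frozen=True)
class IBDSegment:
    """One shared haplotype tract between two individuals (genetic-map coords)."""

    iid1: str
    iid2: str
    chrom: int
    start_cM: float
    end_cM: float
    length_cM: float
    n_snps: int | None = None

    def __post_init__(self) -> None:
        if self.iid1 == self.iid2:
            raise ValueError(f"segment relates an individual to itself: {self.iid1}")
        if self.iid1 > self.iid2:
            raise ValueError("pair not canonicalized (iid1 must sort before iid2)")
        if not 1 <= int(self.chrom) <= 22:
            raise ValueError(f"chrom must be an autosome index 1-22, got {self.chrom}")
        if not self.end_cM > self.start_cM:
            raise ValueError(
                f"end_cM ({self.end_cM}) must exceed start_cM ({self.start_cM})"
            )
        if not self.length_cM > 0:
            raise ValueError("length_cM must be > 0")
        if self.n_snps is not None and self.n_snps < 0:
            raise ValueError("n_snps must be nonnegative")


@dataclass(frozen=True)
class IndividualMeta:
    """Per-individual metadata used by filters and network labelling."""

    iid: str
    group: str
    region: str
    date_CE: float
    n_snps_covered: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not in {REGIONS}")
        if not np.isfinite(self.date_CE):
            raise ValueError("date_CE must be finite")


def _read_text_lines(source) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    return Path(source).read_text(encoding="utf-8").splitlines()


def _parse_table(source) -> tuple[pd.DataFrame, np.ndarray]:
    """Parse a commented TSV, returning the frame and original line numbers (1-based)."""
    lines = _read_text_lines(source)
    kept: list[str] = []
    linenos: list[int] = []
    for i, line in enumerate(lines, start=1):
        if line.startswith("#") or not line.strip():
            continue
        kept.append(line)
        linenos.append(i)
    if not kept:
        raise DataFormatError("no header row found (empty input)")
    frame = pd.read_csv(_io.StringIO("\n".join(kept)), sep="\t", dtype=str)
    return frame, np.asarray(linenos[1:], dtype=int)  # drop the header's line


def _resolve_columns(
    frame: pd.DataFrame, dialect: Mapping[str, str], required: Sequence[str]
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for std in required:
        col = dialect.get(std, std)
        if col not in frame.columns:
            raise DataFormatError(f"missing required column {col!r} (for {std!r})")
        resolved[std] = col
    return resolved


def read_ibd_table(source, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate an IBD segment table.

    Parameters
    ----------
    source
        Path or open text stream of a tab-separated table with header.
    dialect
        Mapping of standard column names to the file's column names;
        defaults to the ancIBD-style :data:`DEFAULT_DIALECT`. ``n_snps``
        and ``length_cM`` are optional in the file: a missing ``n_snps``
        column yields NA counts, a missing ``length_cM`` is recomputed
        from the coordinates.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`SEGMENT_COLUMNS`; pairs canonicalized; all
        rows validated against the segment invariants.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    frame, linenos = _parse_table(source)
    required = ["iid1", "iid2", "chrom", "start_cM", "end_cM"]
    cols = _resolve_columns(frame, dialect, required)

    out = pd.DataFrame(index=frame.index)
    out["iid1"] = frame[cols["iid1"]].astype(str)
    out["iid2"] = frame[cols["iid2"]].astype(str)

    errors: list[str] = []

    def _numeric(std: str, optional: bool = False) -> pd.Series:
        col = dialect.get(std, std)
        if col not in frame.columns:
            if optional:
                return pd.Series(np.nan, index=frame.index)
            raise DataFormatError(f"missing required column {col!r} (for {std!r})")
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() & frame[col].notna()
        for pos in np.flatnonzero(bad.to_numpy()):
            errors.append(
                f"line {linenos[pos]}: non-numeric value {frame[col].iloc[pos]!r} in {col!r}"
            )
        return vals

    out["chrom"] = _numeric("chrom")
    out["start_cM"] = _numeric("start_cM")
    out["end_cM"] = _numeric("end_cM")
    out["length_cM"] = _numeric("length_cM", optional=True)
    out["n_snps"] = _numeric("n_snps", optional=True)
    if errors:
        raise RecordError("; ".join(errors))

    # coordinate invariants, reported with original line numbers
    bad_order = (out["end_cM"] <= out["start_cM"]).to_numpy()
    for pos in np.flatnonzero(bad_order):
        errors.append(
            f"line {linenos[pos]}: end_cM ({out['end_cM'].iloc[pos]}) <= "
            f"start_cM ({out['start_cM'].iloc[pos]})"
        )
    bad_chrom = (~out["chrom"].isin(range(1, 23))).to_numpy()
    for pos in np.flatnonzero(bad_chrom):
        errors.append(f"line {linenos[pos]}: chrom {out['chrom'].iloc[pos]} not in 1..22")
    self_pair = (out["iid1"] == out["iid2"]).to_numpy()
    for pos in np.flatnonzero(self_pair):
        errors.append(f"line {linenos[pos]}: iid1 == iid2 ({out['iid1'].iloc[pos]!r})")
    if errors:
        raise RecordError("; ".join(errors))

    out["chrom"] = out["chrom"].astype(int)

    # stated length must agree with the coordinates; the stated value wins
    recomputed = out["end_cM"] - out["start_cM"]
    stated = out["length_cM"]
    missing_len = stated.isna()
    out.loc[missing_len, "length_cM"] = recomputed[missing_len]
    mismatch = (~missing_len) & ((stated - recomputed).abs() > LENGTH_ATOL_CM)
    if mismatch.any():
        for pos in np.flatnonzero(mismatch.to_numpy()):
            logger.warning(
                "line %d: stated length %.6f cM disagrees with end-start %.6f cM; "
                "keeping stated value",
                linenos[pos],
                stated.iloc[pos],
                recomputed.iloc[pos],
            )
    return canonicalize_pairs(out).reset_index(drop=True)


def canonicalize_pairs(segments: pd.DataFrame) -> pd.DataFrame:
    """Order each unordered pair so iid1 sorts lexicographically before iid2."""
    out = segments.copy()
    swap = (out["iid1"] > out["iid2"]).to_numpy()
    if swap.any():
        a = out.loc[swap, "iid1"].to_numpy()
        out.loc[swap, "iid1"] = out.loc[swap, "iid2"].to_numpy()
        out.loc[swap, "iid2"] = a
    return out


def write_ibd_table(
    segments: pd.DataFrame, sink, dialect: Mapping[str, str] | None = None
) -> None:
    """Write a segment table in the TSV dialect accepted by :func:`read_ibd_table`."""
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    out = segments[SEGMENT_COLUMNS].rename(columns=dialect)
    if hasattr(sink, "write"):
        out.to_csv(sink, sep="\t", index=False)
    else:
        out.to_csv(Path(sink), sep="\t", index=False)


def to_records(segments: pd.DataFrame) -> list[IBDSegment]:
    """Validated dataclass view of a segment frame."""
    recs = []
    for row in segments.itertuples(index=False):
        n = None if pd.isna(row.n_snps) else int(row.n_snps)
        recs.append(
            IBDSegment(
                iid1=row.iid1,
                iid2=row.iid2,
                chrom=int(row.chrom),
                start_cM=float(row.start_cM),
                end_cM=float(row.end_cM),
                length_cM=float(row.length_cM),
                n_snps=n,
            )
        )
    return recs


def from_records(records: Sequence[IBDSegment]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            (r.iid1, r.iid2, r.chrom, r.start_cM, r.end_cM, r.length_cM,
             np.nan if r.n_snps is None else r.n_snps)
            for r in records
        ],
        columns=SEGMENT_COLUMNS,
    )
    return frame


def read_metadata(source) -> pd.DataFrame:
    """Read an individual metadata table (iid, group, region, date_CE, n_snps_covered)."""
    frame, linenos = _parse_table(source)
    required = ["iid", "group", "region", "date_CE", "n_snps_covered"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataFormatError(f"metadata missing column(s): {missing}")
    out = pd.DataFrame(
        {
            "iid": frame["iid"].astype(str),
            "group": frame["group"].astype(str),
            "region": frame["region"].astype(str),
            "date_CE": pd.to_numeric(frame["date_CE"], errors="coerce"),
            "n_snps_covered": pd.to_numeric(frame["n_snps_covered"], errors="coerce"),
        }
    )
    errors = []
    for pos in np.flatnonzero((~out["region"].isin(REGIONS)).to_numpy()):
        errors.append(f"line {linenos[pos]}: region {out['region'].iloc[pos]!r} not in {REGIONS}")
    for pos in np.flatnonzero((~np.isfinite(out["date_CE"])).to_numpy()):
        errors.append(f"line {linenos[pos]}: non-finite date_CE")
    if errors:
        raise RecordError("; ".join(errors))
    out["n_snps_covered"] = out["n_snps_covered"].astype(int)
    if out["iid"].duplicated().any():
        dups = sorted(out.loc[out["iid"].duplicated(), "iid"].unique())
        raise RecordError(f"duplicate individual IDs: {dups}")
    return out.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, sink) -> None:
    meta.to_csv(sink, sep="\t", index=False)


def filter_segments(
    segments: pd.DataFrame,
    min_len_cM: float = 8.0,
    min_snps_per_cM: float = 220.0,
) -> pd.DataFrame:
    """Segment-level quality filter.

    Retains segments strictly longer than ``min_len_cM`` whose SNP density
    strictly exceeds ``min_snps_per_cM``. Segments without a SNP count pass
    the density test only when the density threshold is 0. Both thresholds
    follow the caller's published false-positive guidance (defaults 8 cM
    and 220 SNPs/cM).
    """
    if min_len_cM < 0 or min_snps_per_cM < 0:
        raise ValueError("thresholds must be >= 0")
    if segments.empty:
        return segments.copy()
    keep = segments["length_cM"] > min_len_cM
    if min_snps_per_cM > 0:
        density = segments["n_snps"] / segments["length_cM"]
        keep &= density > min_snps_per_cM  # NaN density -> False
    return segments.loc[keep].reset_index(drop=True)


def filter_individuals(
    meta: pd.DataFrame,
    segments: pd.DataFrame,
    min_snps: int = 450_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-coverage individuals and every segment touching them.

    Individuals are retained only with strictly more than ``min_snps``
    genome-wide SNPs (default 450k). Segments referencing an ID absent
    from the metadata raise :class:`RecordError`.
    """
    if not segments.empty:
        known = set(meta["iid"])
        seg_iids = set(segments["iid1"]) | set(segments["iid2"])
        unknown = sorted(seg_iids - known)
        if unknown:
            raise RecordError(f"segment(s) reference unknown individual(s): {unknown}")
    kept_meta = meta.loc[meta["n_snps_covered"] > min_snps].reset_index(drop=True)
    if segments.empty:
        return kept_meta, segments.copy()
    kept = set(kept_meta["iid"])
    mask = segments["iid1"].isin(kept) & segments["iid2"].isin(kept)
    return kept_meta, segments.loc[mask].reset_index(drop=True)


PAIR_SUMMARY_COLUMNS = [
    "iid1", "iid2", "sum_cM", "n_segments", "max_cM", "n_8_12", "n_ge12", "n_ge20",
]


def pair_summaries(segments: pd.DataFrame, min_len_cM: float = 8.0) -> pd.DataFrame:
    """Aggregate retained segments into per-pair summaries.

    Applies a non-strict length floor (``length_cM >= min_len_cM``, default
    8 cM — the floor used for network construction) and returns one row per
    unordered pair with at least one retained segment: total cM, segment
    count, longest segment, and counts in the 8-12 / >=12 / >=20 cM classes.
    """
    if segments.empty:
        return pd.DataFrame(columns=PAIR_SUMMARY_COLUMNS)
    seg = segments.loc[segments["length_cM"] >= min_len_cM]
    if seg.empty:
        return pd.DataFrame(columns=PAIR_SUMMARY_COLUMNS)
    ln = seg["length_cM"]
    seg = seg.assign(
        _in_8_12=((ln >= 8.0) & (ln < 12.0)).astype(int),
        _ge12=(ln >= 12.0).astype(int),
        _ge20=(ln >= 20.0).astype(int),
    )
    grouped = seg.groupby(["iid1", "iid2"], sort=True)
    out = grouped.agg(
        sum_cM=("length_cM", "sum"),
        n_segments=("length_cM", "size"),
        max_cM=("length_cM", "max"),
        n_8_12=("_in_8_12", "sum"),
        n_ge12=("_ge12", "sum"),
        n_ge20=("_ge20", "sum"),
    ).reset_index()
    return out[PAIR_SUMMARY_COLUMNS]
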