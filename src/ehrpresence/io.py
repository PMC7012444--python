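"""Readers, writers, validation and pipeline orchestration.

All tables are comma-separated text with a header row and ISO-8601 dates.
Open registration ends are encoded as an empty field and materialized to
the global censor date (by default the latest extract date across
practices) at load time.  Row-level problems — malformed dates, end
before start — are rejected and logged with a reason code, never silently
dropped; a missing required column is fatal.

``run_pipeline`` executes coverage then presence, persisting the
monthly-rates intermediate and reusing it when a content hash of the
inputs and the rate-relevant parameters is unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .coverage import compute_all_coverage
from .model import Parameters
from .presence import build_presence

log = logging.getLogger("ehrpresence")

SCHEMAS = {
    "events": ["person_id", "practice_id", "event_date"],
    "registrations": ["person_id", "practice_id", "start", "end"],
    "practice_meta": ["practice_id", "in_sail", "extract_date"],
    "exclusions": ["person_id", "start", "end"],
}
_DATE_COLS = {
    "events": ["event_date"],
    "registrations": ["start", "end"],
    "practice_meta": ["extract_date"],
    "exclusions": ["start", "end"],
}
_OPTIONAL_EMPTY = {  # columns where an empty value is legitimate
    ("registrations", "end"),
    ("practice_meta", "extract_date"),
}


@dataclass
class Dataset:
    """Validated, typed input tables plus the materialized censor date."""

    events: pd.DataFrame
    registrations: pd.DataFrame
    practice_meta: pd.DataFrame
    exclusions: Optional[pd.DataFrame]
    censor: date
    rejects: pd.DataFrame


def _load_one(path: str | Path, table: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate one table; returns (valid rows, rejects)."""
    cols = SCHEMAS[table]
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df[cols].copy()
    reject_reason = pd.Series("", index=df.index)
    for col in _DATE_COLS[table]:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.str.strip() != "")
        if (table, col) not in _OPTIONAL_EMPTY:
            bad |= raw.isna() | (raw.fillna("").str.strip() == "")
        reject_reason[bad & (reject_reason == "")] = f"bad_date:{col}"
        df[col] = parsed
    if table in ("registrations", "exclusions"):
        inverted = df["start"].notna() & df["end"].notna() & (df["end"] < df["start"])
        reject_reason[inverted & (reject_reason == "")] = "end_before_start"
    if table == "practice_meta":
        df["in_sail"] = df["in_sail"].str.strip().isin(["1", "true", "True", "TRUE"])
        no_extract = df["in_sail"] & df["extract_date"].isna()
        reject_reason[no_extract & (reject_reason == "")] = "missing_extract_date"
    bad_mask = reject_reason != ""
    rejects = df[bad_mask].copy()
    rejects["table"] = table
    rejects["reason"] = reject_reason[bad_mask]
    if bad_mask.any():
        log.warning("%s: rejected %d row(s)", path, int(bad_mask.sum()))
    return df[~bad_mask].reset_index(drop=True), rejects


def load_tables(
    events_path: str | Path,
    registrations_path: str | Path,
    practice_meta_path: str | Path,
    exclusions_path: Optional[str | Path] = None,
    censor: Optional[date] = None,
) -> Dataset:
    """Load and validate all input tables; materialize open ends.

    The censor date defaults to the latest extract date in the practice
    metadata; open-ended registrations are set to end there.
    """
    events, rej_e = _load_one(events_path, "events")
    registrations, rej_r = _load_one(registrations_path, "registrations")
    practice_meta, rej_p = _load_one(practice_meta_path, "practice_meta")
    rejects = [rej_e, rej_r, rej_p]
    exclusions = None
    if exclusions_path is not None:
        exclusions, rej_x = _load_one(exclusions_path, "exclusions")
        rejects.append(rej_x)
    if censor is None:
        extracts = practice_meta["extract_date"].dropna()
        if extracts.empty:
            raise ValueError("no extract dates available to derive a censor date")
        censor = extracts.max().date()
    registrations = registrations.copy()
    registrations["end"] = registrations["end"].fillna(pd.Timestamp(censor))
    return Dataset(
        events=events,
        registrations=registrations,
        practice_meta=practice_meta,
        exclusions=exclusions,
        censor=censor,
        rejects=pd.concat(rejects, ignore_index=True),
    )


def _format_dates(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        elif out[col].dtype == object and len(out) and isinstance(
            out[col].dropna().iloc[0] if out[col].notna().any() else None, date
        ):
            out[col] = out[col].map(lambda d: d.isoformat() if pd.notna(d) else "")
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV with ISO dates; booleans as 1/0, None empty."""
    out = _format_dates(df)
    if "sail_data" in out.columns:
        out["sail_data"] = out["sail_data"].map(
            lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(int(bool(v)))
        )
    if "in_sail" in out.columns:
        out["in_sail"] = out["in_sail"].astype(int)
    out.to_csv(path, index=False)


def read_presence(path: str | Path) -> pd.DataFrame:
    """Read a presence table written by :func:`write_table`."""
    df = pd.read_csv(path, dtype={"person_id": str, "practice_id": str})
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
    df["sail_data"] = df["sail_data"].map(
        lambda v: None if pd.isna(v) else bool(int(v))
    ).astype(object)
    return df


def _content_hash(paths: list[Path], extra: dict) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    h.update(json.dumps(extra, sort_keys=True, default=str).encode())
    return h.hexdigest()


def run_pipeline(
    events_path: str | Path,
    registrations_path: str | Path,
    practice_meta_path: str | Path,
    out_dir: str | Path,
    params: Optional[Parameters] = None,
    exclusions_path: Optional[str | Path] = None,
    censor: Optional[date] = None,
) -> dict:
    """Coverage then presence, with a cached monthly-rates intermediate.

    Outputs written to ``out_dir``: ``monthly_rates.csv``,
    ``coverage.csv``, ``presence.csv``, ``conflicts.csv``,
    ``rejects.csv`` and ``run_metadata.json``.  The monthly-rates stage is
    skipped when the input content hash matches the previous run.
    """
    params = params or Parameters()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = load_tables(
        events_path, registrations_path, practice_meta_path, exclusions_path, censor
    )
    rate_inputs_hash = _content_hash(
        [Path(events_path), Path(registrations_path), Path(practice_meta_path)],
        {"min_registered": params.min_registered, "censor": ds.censor},
    )
    cache_meta_path = out / "cache_meta.json"
    monthly_path = out / "monthly_rates.csv"
    reuse = False
    if cache_meta_path.exists() and monthly_path.exists():
        cached = json.loads(cache_meta_path.read_text())
        reuse = cached.get("rate_inputs_hash") == rate_inputs_hash

    warnings_: list[str] = []
    if reuse:
        log.info("monthly-rates intermediate unchanged; reusing %s", monthly_path)
        monthly = pd.read_csv(monthly_path)
        from .coverage import (
            choose_reference_year,
            infer_end_date,
            infer_start_date,
            normalize_rates,
        )
        from .model import NoReferenceYear, ZeroReferenceRate

        coverage_rows = []
        contributing = ds.practice_meta[ds.practice_meta["in_sail"]].sort_values(
            "practice_id"
        )
        for row in contributing.itertuples():
            pid = row.practice_id
            sub = monthly[monthly["practice_id"] == pid]
            none_row = {
                "practice_id": pid,
                "data_start": None,
                "data_end": None,
                "reference_year": None,
            }
            try:
                ref_year = choose_reference_year(ds.registrations, pid, params)
                sub = normalize_rates(sub, ref_year)
                start = infer_start_date(sub, params)
                end = infer_end_date(sub, pd.Timestamp(row.extract_date).date(), params)
                if start is None or end is None or start > end:
                    start = end = None
                coverage_rows.append(
                    {
                        "practice_id": pid,
                        "data_start": start,
                        "data_end": end,
                        "reference_year": ref_year,
                    }
                )
            except (NoReferenceYear, ZeroReferenceRate) as exc:
                warnings_.append(f"practice {pid}: {exc}")
                coverage_rows.append(none_row)
        coverage = pd.DataFrame(
            coverage_rows,
            columns=["practice_id", "data_start", "data_end", "reference_year"],
        )
    else:
        coverage, monthly, warnings_ = compute_all_coverage(
            ds.events, ds.registrations, ds.practice_meta, params
        )
        write_table(monthly, monthly_path)
        cache_meta_path.write_text(json.dumps({"rate_inputs_hash": rate_inputs_hash}))

    presence, conflicts = build_presence(
        ds.registrations,
        coverage,
        ds.exclusions,
        ds.practice_meta,
        params,
        ds.censor,
    )
    write_table(coverage, out / "coverage.csv")
    write_table(presence, out / "presence.csv")
    conflicts.to_csv(out / "conflicts.csv", index=False)
    ds.rejects.pipe(_format_dates).to_csv(out / "rejects.csv", index=False)
    metadata = {
        "package_version": __version__,
        "parameters": params.to_dict(),
        "censor_date": ds.censor.isoformat(),
        "rate_inputs_hash": rate_inputs_hash,
        "monthly_rates_reused": reuse,
        "n_rejected_rows": int(len(ds.rejects)),
        "warnings": warnings_,
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    return {
        "coverage": coverage,
        "presence": presence,
        "conflicts": conflicts,
        "monthly_rates": monthly,
        "metadata": metadata,
    }
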