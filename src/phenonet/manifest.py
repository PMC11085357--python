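"""Dataset manifests: one CSV row per image with label, growth day and split.

The on-disk format is a CSV with header ``path,label,day,split``.  ``day`` is
an integer growth day for plant time-series images and empty for organelle
images; ``split`` is one of ``train``, ``validation`` or ``unassigned``.
Unknown extra columns are preserved on round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

REQUIRED_COLUMNS = ["path", "label", "day", "split"]
VALID_SPLITS = {"train", "validation", "unassigned"}


@dataclass
class ManifestRecord:
    path: str
    label: str
    day: Optional[int] = None
    split: str = "unassigned"


class ManifestError(ValueError):
    """Raised for malformed manifest files or rows."""


def _validate(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{source}: missing manifest column(s): {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        if not isinstance(row.path, str) or not row.path:
            raise ManifestError(f"{source}:{i}: empty image path")
        if not isinstance(row.label, str) or not row.label:
            raise ManifestError(f"{source}:{i}: empty label")
        if row.split not in VALID_SPLITS:
            raise ManifestError(f"{source}:{i}: bad split {row.split!r}")
    days = df["day"]
    if days.notna().any() and days.notna().sum() != len(df):
        bad = int(days.isna().idxmax()) + 2
        raise ManifestError(
            f"{source}:{bad}: day must be set for every row of a time-series "
            "manifest (and empty for every row of an organelle manifest)"
        )
    return df


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a manifest CSV.

    Raises :class:`ManifestError` (with a line number) on malformed rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"path": str, "label": str, "split": str})
    if "day" in df.columns:
        df["day"] = df["day"].astype("Int64")
    df = _validate(df, source=str(path))
    return df


def write_manifest(records, path) -> None:
    """Write records (DataFrame or iterable of ManifestRecord) as CSV."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    if "day" in df.columns:
        df["day"] = df["day"].astype("Int64")
    _validate(df)
    # keep the canonical columns first, preserve any extras
    extras = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    df[REQUIRED_COLUMNS + extras].to_csv(path, index=False)


def is_timeseries(manifest: pd.DataFrame) -> bool:
    return bool(manifest["day"].notna().all()) and len(manifest) > 0
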