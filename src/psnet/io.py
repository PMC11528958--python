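"""Reading and writing visit tables, networks and reports.

Visit tables are UTF-8 delimited text (tab by default) with a header row
and the columns of :data:`psnet.cohort.VISIT_COLUMNS`; list-valued code
columns use semicolons between codes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from psnet.cohort import VISIT_COLUMNS
from psnet.errors import DataError

_MAX_BAD_ROWS_SHOWN = 20


def read_visits(path, sep: str = "\t") -> pd.DataFrame:
    """Schema-validated read of a visit table.

    Raises :class:`DataError` naming missing columns, or listing the row
    numbers (at most 20 shown) of rows with unparseable dates or empty
    identifiers.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[list(VISIT_COLUMNS)]

    bad: list[tuple[int, str]] = []
    parsed = pd.to_datetime(df["visit_date"], format="%Y-%m-%d", errors="coerce")
    for idx in df.index[parsed.isna()]:
        bad.append((int(idx) + 2, "unparseable visit_date"))  # +2: header + 1-based
    for idx in df.index[df["patient_id"].str.strip() == ""]:
        bad.append((int(idx) + 2, "empty patient_id"))
    if bad:
        shown = ", ".join(f"row {r}: {why}" for r, why in bad[:_MAX_BAD_ROWS_SHOWN])
        more = f" (+{len(bad) - _MAX_BAD_ROWS_SHOWN} more)" if len(bad) > _MAX_BAD_ROWS_SHOWN else ""
        raise DataError(f"{path}: {len(bad)} malformed row(s): {shown}{more}")

    df["mh_service_flag"] = df["mh_service_flag"].str.lower().isin(("true", "1", "t", "yes"))
    return df


def write_visits(visits: pd.DataFrame, path, sep: str = "\t") -> None:
    out = visits.copy()
    out["mh_service_flag"] = out["mh_service_flag"].map(lambda b: "true" if b else "false")
    out.to_csv(path, sep=sep, index=False)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def hash_tree(paths: list[Path], root: Path) -> dict[str, str]:
    return {str(p.relative_to(root)): sha256_file(p) for p in sorted(paths)}
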