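"""Cohort file reading/validation and JSON result serialization.

Cohort files are delimited text (comma by default, tab accepted) with the
header contract::

    id, sex, pgs_dep ... pgs_scz, pgs_hand, pgs_cat,
    ace_mal ... ace_sep, int, ext

ACE entries are 0, 1 or empty (missing); polygenic scores and outcomes are
standardized continuous values.  Loaded scores are re-standardized with a
warning when their mean or SD drifts noticeably from (0, 1).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import (
    ACE_LABELS,
    CONTROL_LABELS,
    OUTCOME_LABELS,
    PGS_LABELS,
    Cohort,
)

__all__ = ["load_cohort", "write_cohort", "write_results"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    ("id", "sex") + PGS_LABELS + CONTROL_LABELS + ACE_LABELS + OUTCOME_LABELS
)


def write_cohort(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write a cohort as delimited text; missing ACE entries become empty
    fields."""
    cohort.frame.to_csv(path, sep=sep, index=False, na_rep="")


def load_cohort(path: str | Path, sep: str | None = None) -> Cohort:
    """Read and validate a cohort table.

    The delimiter is sniffed from the header line unless given.  Raises on
    missing columns, non-binary ACE values (with the offending row) and
    all-missing columns.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if sep is None:
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")

    for col in ACE_LABELS:
        vals = frame[col]
        if vals.isna().all():
            raise ValueError(f"ACE column {col!r} is entirely missing")
        bad = vals.dropna()[~vals.dropna().isin([0, 1])]
        if len(bad):
            row = int(bad.index[0])
            raise ValueError(
                f"ACE column {col!r} contains non-binary value {bad.iloc[0]!r} "
                f"at row {row}"
            )
    sexvals = frame["sex"].dropna()
    if not sexvals.isin([0, 1]).all():
        raise ValueError("sex column must be binary 0/1")

    for col in PGS_LABELS + CONTROL_LABELS + OUTCOME_LABELS:
        x = frame[col].to_numpy(dtype=float)
        if np.isnan(x).all():
            raise ValueError(f"column {col!r} is entirely missing")
        mean, sd = float(np.nanmean(x)), float(np.nanstd(x))
        if not sd > 0:
            raise ValueError(f"column {col!r} is constant")
        if abs(mean) > 0.05 or abs(sd - 1.0) > 0.05:
            logger.warning(
                "column %r has mean %.3f, sd %.3f; re-standardizing", col, mean, sd
            )
            frame[col] = (x - mean) / sd
    return Cohort(frame=frame)


def _jsonify(obj):
    if is_dataclass(obj) and hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):  # NaN -> null
        return None
    return obj


def write_results(
    results, path: str | Path, seed: int | None = None, config: dict | None = None
) -> dict:
    """Serialize results to JSON with run metadata and stable key order.

    The payload records the package version, the seed, and a hash of the
    configuration so identical runs produce byte-identical files.
    """
    from . import __version__

    config = _jsonify(config or {})
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload = {
        "meta": {
            "package": "pgsace",
            "version": __version__,
            "seed": seed,
            "config": config,
            "config_hash": cfg_hash,
        },
        "results": _jsonify(results),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
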