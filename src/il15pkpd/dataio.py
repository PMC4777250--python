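"""Event-record CSV dialect and plain-text configuration files.

The dataset format follows the naming conventions of nonlinear mixed-effects
tools (ID, TIME, AMT, DV) so practitioners can eyeball it:

    ID,ARM,TIME,AMT,ROUTE,DVTYPE,DV,BLQ

* dose rows: AMT set (ug/kg), ROUTE in {IV, SC}, DVTYPE=DOSE, DV empty;
* observation rows: DVTYPE in {PK, PD}, DV set (ug/mL or 10^3 cells/uL)
  unless BLQ=1, AMT and ROUTE empty.

Units are fixed by the dialect (day, ug/kg, ug/mL, 10^3 cells/uL) and are
asserted, never inferred.  Reading is strict: malformed rows are reported
with their line numbers.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .study import StudyDataset

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "read_config", "write_config", "validate_records"]

COLUMNS = ["ID", "ARM", "TIME", "AMT", "ROUTE", "DVTYPE", "DV", "BLQ"]
_DVTYPES = {"DOSE", "PK", "PD"}
_ROUTES = {"IV", "SC", ""}


class DatasetFormatError(ValueError):
    """Raised on malformed event-record files; message carries line numbers."""


def validate_records(records: pd.DataFrame, max_errors: int = 20) -> None:
    """Validate an in-memory event-record table; raise listing bad lines.

    Line numbers refer to the CSV representation (header = line 1).
    """
    unknown = [c for c in records.columns if c not in COLUMNS]
    missing = [c for c in COLUMNS if c not in records.columns]
    if unknown or missing:
        raise DatasetFormatError(
            f"bad header: unknown columns {unknown}, missing columns {missing}"
        )
    errors: list[str] = []

    def complain(idx: int, msg: str) -> None:
        errors.append(f"line {idx + 2}: {msg}")

    for idx, row in enumerate(records.itertuples(index=False)):
        dvtype = row.DVTYPE
        if dvtype not in _DVTYPES:
            complain(idx, f"DVTYPE must be one of {sorted(_DVTYPES)}, got {dvtype!r}")
            continue
        if dvtype == "DOSE":
            if not np.isfinite(row.AMT) or row.AMT <= 0:
                complain(idx, f"dose row needs AMT > 0, got {row.AMT!r}")
            if row.ROUTE not in ("IV", "SC"):
                complain(idx, f"dose row needs ROUTE IV or SC, got {row.ROUTE!r}")
            if np.isfinite(row.DV):
                complain(idx, "dose row must not carry a DV value")
            if np.isfinite(row.TIME) and row.TIME < 0:
                complain(idx, f"dose time must be >= 0, got {row.TIME}")
        else:
            if np.isfinite(row.AMT):
                complain(idx, "observation row must not carry AMT")
            if int(row.BLQ) not in (0, 1):
                complain(idx, f"BLQ must be 0 or 1, got {row.BLQ!r}")
            if int(row.BLQ) == 0 and not np.isfinite(row.DV):
                complain(idx, "observation row needs DV unless BLQ=1")
            if int(row.BLQ) == 0 and np.isfinite(row.DV) and row.DV < 0:
                complain(idx, f"DV must be >= 0, got {row.DV}")
        if len(errors) >= max_errors:
            break
    # per-subject monotone non-decreasing times (as sorted on write)
    for sid, grp in records.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            errors.append(f"subject {sid!r}: times are not sorted")
    if errors:
        raise DatasetFormatError("; ".join(errors[:max_errors]))


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write a dataset in the event-record CSV dialect (lossless round-trip).

    Provenance (seed, design label, LLOQ, true parameters of simulated
    subjects) goes to a YAML sidecar ``<path>.meta``.
    """
    path = Path(path)
    frame = dataset.records[COLUMNS].copy()
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "design_label": dataset.design_label,
        "seed": dataset.seed,
        "lloq": dataset.lloq,
        "n_truncated_pd": dataset.n_truncated_pd,
    }
    if dataset.true_parameters is not None:
        meta["true_parameters"] = dataset.true_parameters.to_dict(orient="records")
    with open(str(path) + ".meta", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_dataset(path: str | Path) -> StudyDataset:
    """Read and validate an event-record CSV (plus optional ``.meta`` sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = pd.read_csv(
        path,
        dtype={"ID": str, "ARM": str, "ROUTE": str, "DVTYPE": str},
        keep_default_na=True,
    )
    for col in ("ROUTE", "ARM"):
        if col in records.columns:
            records[col] = records[col].fillna("")
    if "BLQ" in records.columns:
        records["BLQ"] = records["BLQ"].fillna(0).astype(int)
    for col in ("TIME", "AMT", "DV"):
        if col in records.columns:
            records[col] = pd.to_numeric(records[col], errors="coerce")
    validate_records(records)

    meta_path = Path(str(path) + ".meta")
    lloq, label, seed, truths, n_trunc = 0.1, "", None, None, 0
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
        lloq = float(meta.get("lloq", 0.1))
        label = meta.get("design_label", "")
        seed = meta.get("seed")
        n_trunc = int(meta.get("n_truncated_pd", 0))
        if "true_parameters" in meta:
            truths = pd.DataFrame(meta["true_parameters"])
    return StudyDataset(
        records=records, lloq=lloq, design_label=label, seed=seed,
        true_parameters=truths, n_truncated_pd=n_trunc,
    )


def read_config(path: str | Path) -> dict:
    """Read a plain-text key-value (YAML mapping) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping, for run logs."""
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
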