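"""Data ingestion, bilateral averaging and report serialization.

Cohort tables are plain CSV/TSV with a header row; empty fields are
missing cells.  Predictor columns follow the package convention
``tissue.metric.region`` with optional hemisphere suffixes ``_lh``/``_rh``
(a sidecar JSON mapping supports arbitrary external naming).  Reports are
written deterministically (sorted keys, fixed float formatting) together
with a manifest of content hashes, so identical runs produce identical
bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from .model import ModelError

log = logging.getLogger("mimiclasso")

HEMI_SUFFIXES = ("_lh", "_rh")


class ContractError(ModelError):
    pass


@dataclasses.dataclass
class ColumnContract:
    """Which columns are indicators, predictors and covariates.

    Predictor columns are recognised either through the
    ``tissue.metric.region[_lh|_rh]`` naming scheme or through an explicit
    ``mapping`` of column name -> (tissue, metric, region).  ``unpaired``
    lists midline regions that legitimately appear without a hemisphere
    suffix.
    """

    indicators: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    unpaired: tuple[str, ...] = ()
    mapping: dict | None = None
    id_column: str = "subject_id"

    def parse_predictor(self, column: str):
        """Return (tissue, metric, region, hemisphere-or-None) or None if
        the column is not a predictor."""
        if self.mapping is not None and column in self.mapping:
            t, m, r = self.mapping[column]
            hemi = None
            for suf in HEMI_SUFFIXES:
                if r.endswith(suf):
                    hemi, r = suf[1:], r[:-len(suf)]
            return t, m, r, hemi
        parts = column.split(".")
        if len(parts) != 3:
            return None
        t, m, r = parts
        hemi = None
        for suf in HEMI_SUFFIXES:
            if r.endswith(suf):
                hemi, r = suf[1:], r[:-len(suf)]
        return t, m, r, hemi

    @classmethod
    def from_sidecar(cls, indicators, path, **kw) -> "ColumnContract":
        with open(path) as fh:
            raw = json.load(fh)
        mapping = {c: tuple(v) for c, v in raw.items()}
        return cls(tuple(indicators), mapping=mapping, **kw)


def read_cohort(path, contract: ColumnContract) -> pd.DataFrame:
    """Read and validate a cohort table.

    Every non-indicator, non-covariate, non-id column must map to exactly
    one (tissue, metric, region); a non-numeric cell in a numeric column is
    rejected with its row and column.
    """
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    known = set(contract.indicators) | set(contract.covariates) \
        | {contract.id_column}
    mapped = {}
    for col in raw.columns:
        if col in known:
            continue
        parsed = contract.parse_predictor(col)
        if parsed is None:
            raise ContractError(f"unmapped predictor column: {col!r}")
        t, m, r, hemi = parsed
        key = (t, m, r, hemi)
        if key in mapped.values():
            raise ContractError(f"duplicate mapped name for column {col!r}")
        mapped[col] = key

    columns = {}
    numeric_cols = []
    for col in raw.columns:
        if col == contract.id_column:
            columns[col] = raw[col]
        elif _is_string_col(col, contract):
            columns[col] = raw[col].replace("", np.nan)
        else:
            vals = raw[col].str.strip()
            empty = vals == ""
            converted = pd.to_numeric(vals.where(~empty), errors="coerce")
            bad = converted.isna() & ~empty & vals.notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ContractError(
                    f"non-numeric cell at row {i}, column {col!r}: "
                    f"{raw[col].iloc[i]!r}")
            columns[col] = converted
            numeric_cols.append(col)
    out = pd.DataFrame(columns, index=raw.index)
    obs = out[[c for c in numeric_cols]].notna()
    if len(out) and not obs.any(axis=1).all():
        raise ContractError("a row has no observed numeric value at all")
    log.info("read %s: %d rows, %d columns, %.1f%% missing cells",
             path.name, len(out), out.shape[1],
             100.0 * (1.0 - obs.to_numpy().mean()) if len(out) else 0.0)
    return out


def _is_string_col(col: str, contract: ColumnContract) -> bool:
    return col in ("sex", "site") or (col in contract.covariates
                                      and col in ("sex", "site"))


def write_cohort(table: pd.DataFrame, path) -> None:
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table.to_csv(path, sep=sep, index=False, float_format="%.10g", na_rep="")


def bilateral_average(table: pd.DataFrame,
                      contract: ColumnContract) -> pd.DataFrame:
    """Average each left/right predictor pair into one bilateral column.

    Missing-aware: if one hemisphere is missing the other passes through,
    so partial rows stay usable for FIML; both missing stays missing.
    Columns without a hemisphere suffix (midline tracts, covariates,
    indicators) pass through unchanged.  A suffixed column whose partner
    is absent is an error unless its region is declared unpaired.
    """
    pairs: dict[str, dict[str, str]] = {}
    passthrough = []
    for col in table.columns:
        parsed = contract.parse_predictor(col)
        if parsed is None:
            passthrough.append(col)
            continue
        t, m, r, hemi = parsed
        if hemi is None:
            passthrough.append(col)
            continue
        pairs.setdefault(f"{t}.{m}.{r}", {})[hemi] = col

    out = table[passthrough].copy()
    for name, sides in pairs.items():
        if len(sides) == 1:
            region = name.split(".")[2]
            if region not in contract.unpaired:
                (hemi, col), = sides.items()
                raise ContractError(
                    f"column {col!r} has a {hemi} suffix but no partner and "
                    f"region {region!r} is not declared unpaired")
            out[name] = table[next(iter(sides.values()))]
            continue
        both = table[[sides["lh"], sides["rh"]]].to_numpy(dtype=float)
        cnt = (~np.isnan(both)).sum(axis=1)
        total = np.nansum(both, axis=1)
        out[name] = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (str, bool)) or obj is None:
        return obj
    return str(obj)


def write_reports(results: dict, out_dir) -> dict:
    """Serialise a name -> object mapping deterministically.

    DataFrames become TSV tables, everything else JSON.  Returns the
    manifest {filename: sha256}, which is itself written as
    ``manifest.json``.
    """
    out_dir = pathlib.Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ContractError(f"cannot create output directory {out_dir}") from exc
    manifest = {}
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            text = obj.to_csv(sep="\t", float_format="%.10g", na_rep="NA")
        else:
            fname = f"{name}.json"
            text = json.dumps(_jsonable(obj), sort_keys=True, indent=1) + "\n"
        (out_dir / fname).write_text(text)
        manifest[fname] = hashlib.sha256(text.encode()).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
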