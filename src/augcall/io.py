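"""Tab-separated readers and writers for panels, known genotypes and calls.

Formats are deliberately vendor-neutral plain TSV:

* wide panel — one row per sample, columns ``sample_id`` then ``<snp>.r`` /
  ``<snp>.g`` pairs in SNP order;
* long panel — columns ``sample_id``, ``snp_id``, ``r``, ``g``;
* known genotypes — columns ``sample_id``, ``snp_id``, ``genotype`` with
  tokens AA/AB/BB/NA;
* calls — columns ``sample_id``, ``snp_id``, ``genotype`` (AA/AB/BB/NoCall),
  ``PR``, ``APR``, ``snp_pass``.

Readers never coerce silently: every malformed cell raises a FormatError
naming the offending row and column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    GENOTYPES,
    MISSING,
    NOCALL,
    FormatError,
    IntensityPanel,
    KnownGenotypeTable,
    RunConfig,
)
from .stage2 import CallSet


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_intensity_column(col: pd.Series, colname: str) -> np.ndarray:
    coerced = pd.to_numeric(col, errors="coerce")
    bad = coerced.isna() | (coerced < 0)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise FormatError(
            f"invalid intensity {col.iloc[row]!r} at data row {row + 1}, "
            f"column {colname!r} (must be a non-negative number)"
        )
    # numpy's string->float conversion is correctly rounded, so written
    # panels read back bit-identical
    return col.to_numpy().astype(float)


def read_intensity_panel(path, format: str = "wide") -> IntensityPanel:
    """Read a panel from a wide or long TSV; order is preserved from the file."""
    df = _read_tsv(path)
    if format == "wide":
        return _panel_from_wide(df)
    if format == "long":
        return _panel_from_long(df)
    raise ValueError(f"unknown panel format {format!r}")


def _panel_from_wide(df: pd.DataFrame) -> IntensityPanel:
    if df.columns[0] != "sample_id":
        raise FormatError("wide panel must start with a 'sample_id' column")
    value_cols = list(df.columns[1:])
    snp_ids: list[str] = []
    for i in range(0, len(value_cols), 2):
        pair = value_cols[i : i + 2]
        if len(pair) != 2 or not pair[0].endswith(".r") or not pair[1].endswith(".g"):
            raise FormatError(f"expected '<snp>.r'/'<snp>.g' column pair at {pair}")
        name_r, name_g = pair[0][:-2], pair[1][:-2]
        if name_r != name_g:
            raise FormatError(f"mismatched column pair {pair[0]!r}/{pair[1]!r}")
        snp_ids.append(name_r)
    sample_ids = list(df["sample_id"])
    red = np.column_stack(
        [_parse_intensity_column(df[f"{s}.r"], f"{s}.r") for s in snp_ids]
    ) if snp_ids else np.empty((len(sample_ids), 0))
    green = np.column_stack(
        [_parse_intensity_column(df[f"{s}.g"], f"{s}.g") for s in snp_ids]
    ) if snp_ids else np.empty((len(sample_ids), 0))
    return IntensityPanel(snp_ids=snp_ids, sample_ids=sample_ids, red=red, green=green)


def _panel_from_long(df: pd.DataFrame) -> IntensityPanel:
    required = ["sample_id", "snp_id", "r", "g"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"long panel must have columns {required}")
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    snp_ids = list(dict.fromkeys(df["snp_id"]))
    r = _parse_intensity_column(df["r"], "r")
    g = _parse_intensity_column(df["g"], "g")
    n, s = len(sample_ids), len(snp_ids)
    srow = {x: i for i, x in enumerate(sample_ids)}
    scol = {x: j for j, x in enumerate(snp_ids)}
    red = np.full((n, s), np.nan)
    green = np.full((n, s), np.nan)
    for idx, (sid, pid) in enumerate(zip(df["sample_id"], df["snp_id"])):
        i, j = srow[sid], scol[pid]
        if np.isfinite(red[i, j]):
            raise FormatError(f"duplicate entry for sample {sid!r}, SNP {pid!r}")
        red[i, j] = r[idx]
        green[i, j] = g[idx]
    if np.isnan(red).any():
        i, j = np.argwhere(np.isnan(red))[0]
        raise FormatError(
            f"incomplete panel: no row for sample {sample_ids[i]!r}, "
            f"SNP {snp_ids[j]!r}"
        )
    return IntensityPanel(snp_ids=snp_ids, sample_ids=sample_ids, red=red, green=green)


def write_intensity_panel(panel: IntensityPanel, path, format: str = "wide") -> None:
    path = Path(path)
    if format == "wide":
        data = {"sample_id": panel.sample_ids}
        for j, snp in enumerate(panel.snp_ids):
            data[f"{snp}.r"] = panel.red[:, j]
            data[f"{snp}.g"] = panel.green[:, j]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    elif format == "long":
        n, s = panel.n_samples, panel.n_snps
        pd.DataFrame(
            {
                "sample_id": np.repeat(panel.sample_ids, s),
                "snp_id": np.tile(panel.snp_ids, n),
                "r": panel.red.ravel(),
                "g": panel.green.ravel(),
            }
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown panel format {format!r}")


def read_known_genotypes(path) -> KnownGenotypeTable:
    """Read a long known-genotype TSV; unlisted pairs are missing."""
    df = _read_tsv(path)
    required = ["sample_id", "snp_id", "genotype"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"known-genotype table must have columns {required}")
    allowed = set(GENOTYPES) | {MISSING}
    mapping: dict[tuple[str, str], str] = {}
    for idx, (sid, pid, g) in enumerate(
        zip(df["sample_id"], df["snp_id"], df["genotype"])
    ):
        if g not in allowed:
            raise FormatError(
                f"invalid genotype token {g!r} at data row {idx + 1} "
                f"(allowed: AA, AB, BB, NA)"
            )
        if g != MISSING:
            mapping[(sid, pid)] = g
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    return KnownGenotypeTable(sample_ids=sample_ids, genotypes=mapping)


def write_known_genotypes(table: KnownGenotypeTable, path) -> None:
    rows = [
        {"sample_id": s, "snp_id": p, "genotype": g}
        for (s, p), g in table.genotypes.items()
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "snp_id", "genotype"])
    # Preserve the table's declared sample order even for all-missing samples.
    order = {s: i for i, s in enumerate(table.sample_ids)}
    if len(df):
        df = df.sort_values(
            by=["sample_id", "snp_id"], key=lambda c: c.map(order) if c.name == "sample_id" else c
        , kind="stable")
    df.to_csv(path, sep="\t", index=False)


def write_calls(calls: CallSet, path) -> None:
    """Write the call set as a long TSV (observed samples only)."""
    snp_info = calls.snp_report.set_index("snp_id")
    df = calls.calls.copy()
    df["APR"] = [snp_info.loc[s, "apr_augmented"] for s in df["snp_id"]]
    df["snp_pass"] = [bool(snp_info.loc[s, "snp_pass"]) for s in df["snp_id"]]
    df.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    """Read a calls TSV back into a long DataFrame."""
    df = _read_tsv(path)
    required = ["sample_id", "snp_id", "genotype", "PR", "APR", "snp_pass"]
    if list(df.columns[:6]) != required:
        raise FormatError(f"calls table must have columns {required}")
    allowed = set(GENOTYPES) | {NOCALL}
    bad = ~df["genotype"].isin(allowed)
    if bad.any():
        idx = int(np.argmax(bad.to_numpy()))
        raise FormatError(f"invalid call token {df['genotype'].iloc[idx]!r} at data row {idx + 1}")
    df["PR"] = pd.to_numeric(df["PR"], errors="coerce")
    df["APR"] = pd.to_numeric(df["APR"], errors="coerce")
    df["snp_pass"] = df["snp_pass"].map({"True": True, "False": False})
    return df


def write_snp_report(calls: CallSet, path) -> None:
    calls.snp_report.to_csv(path, sep="\t", index=False)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_mapping(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_mapping(), fh, sort_keys=False)
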