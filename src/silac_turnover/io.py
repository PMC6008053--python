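"""Readers and writers for the tab-delimited tables the pipeline exchanges.

All tables are UTF-8, tab-delimited, single header row; "NA" or an empty
cell denotes an absent H/L ratio. Peptide tables default to MaxQuant column
names ("Sequence", "Proteins", "Missed cleavages", "Ratio H/L") remappable
through a dialect map, because deposited tables vary across versions.
Readers validate type invariants and report rejected-row counts instead of
silently coercing.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .errors import FormatError
from .types import HalfLifeRecord, LABEL_COUNT_COLUMNS, PEPTIDE_COLUMNS, SAMPLE_KEY

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DIALECT",
    "read_peptide_table",
    "write_peptide_table",
    "read_label_counts",
    "write_label_counts",
    "read_complex_table",
    "write_complex_table",
    "read_puncta_table",
    "write_puncta_table",
    "write_halflife_table",
    "read_halflife_table",
    "write_purity_table",
]

#: canonical field -> column name in the file (MaxQuant conventions)
DEFAULT_DIALECT = {
    "sequence": "Sequence",
    "protein_group": "Proteins",
    "missed_cleavages": "Missed cleavages",
    "ratio_HL": "Ratio H/L",
    "light_only": "Light only",
    "timepoint": "Timepoint",
    "replicate": "Replicate",
    "injection": "Injection",
    "condition": "Condition",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}

#: protein-group prefixes marking decoy / contaminant entries
_DECOY_PREFIXES = ("REV__", "CON__")

_MANDATORY = (
    "sequence",
    "protein_group",
    "missed_cleavages",
    "ratio_HL",
    "timepoint",
    "replicate",
    "injection",
)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )


def _lines(frame_index) -> list[int]:
    """1-based data line numbers (header is line 1)."""
    return [int(i) + 2 for i in frame_index]


def read_peptide_table(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a MaxQuant-style peptide evidence table.

    Decoy and contaminant rows are dropped (marker columns with "+" or
    protein groups prefixed ``REV__``/``CON__``); rows violating value
    invariants (negative missed cleavages, negative ratio) are rejected and
    counted. Non-numeric ratios and duplicate measurement keys raise
    :class:`FormatError` with line numbers.
    """
    cols = dict(DEFAULT_DIALECT)
    cols.update(dialect or {})
    raw = _read_tsv(path)
    for field in _MANDATORY:
        if cols[field] not in raw.columns:
            raise FormatError(
                f"{path}: missing mandatory column {cols[field]!r} (field {field})"
            )
    n_raw = len(raw)

    # decoy / contaminant removal
    drop = raw[cols["protein_group"]].str.startswith(_DECOY_PREFIXES)
    for marker in ("reverse", "contaminant"):
        if cols[marker] in raw.columns:
            drop |= raw[cols[marker]].str.strip() == "+"
    table = raw.loc[~drop]
    logger.info(
        "read_peptide_table: %d rows, %d decoy/contaminant dropped",
        n_raw,
        int(drop.sum()),
    )

    out = pd.DataFrame(
        {
            "sequence": table[cols["sequence"]],
            "protein_group": table[cols["protein_group"]],
            "replicate": table[cols["replicate"]],
            "injection": table[cols["injection"]],
        }
    )
    out["condition"] = (
        table[cols["condition"]] if cols["condition"] in table.columns else "default"
    )

    mc = pd.to_numeric(table[cols["missed_cleavages"]], errors="coerce")
    if mc.isna().any():
        raise FormatError(
            f"{path}: non-integer missed cleavages at lines "
            f"{_lines(table.index[mc.isna()])}"
        )
    out["missed_cleavages"] = mc.astype(int)

    tp = pd.to_numeric(table[cols["timepoint"]], errors="coerce")
    if tp.isna().any():
        raise FormatError(
            f"{path}: non-numeric timepoint at lines {_lines(table.index[tp.isna()])}"
        )
    out["timepoint"] = tp.astype(float)

    ratio_str = table[cols["ratio_HL"]].str.strip()
    absent = ratio_str.isin(("", "NA", "NaN", "nan"))
    ratio = pd.to_numeric(ratio_str.where(~absent, other="nan"), errors="coerce")
    bad = (~absent) & ratio.isna()
    if bad.any():
        raise FormatError(
            f"{path}: non-numeric H/L ratio at lines {_lines(table.index[bad])}"
        )
    out["ratio_HL"] = ratio.astype(float)

    if cols["light_only"] in table.columns:
        out["light_only"] = table[cols["light_only"]].str.strip().isin(
            ("1", "true", "True", "+")
        )
    else:
        out["light_only"] = absent.to_numpy()

    invalid = (out["missed_cleavages"] < 0) | (out["ratio_HL"] < 0)
    if invalid.any():
        logger.warning(
            "read_peptide_table: rejected %d rows violating invariants "
            "(negative missed cleavages or ratio) at lines %s",
            int(invalid.sum()),
            _lines(out.index[invalid]),
        )
        out = out.loc[~invalid]

    key = ["sequence", "timepoint", "replicate", "injection", "condition"]
    dup = out.duplicated(subset=key)
    if dup.any():
        raise FormatError(
            f"{path}: duplicate measurement keys at lines {_lines(out.index[dup])}"
        )
    out = out.reset_index(drop=True)
    logger.info("read_peptide_table: %d rows retained", len(out))
    return out[list(PEPTIDE_COLUMNS)]


def write_peptide_table(table: pd.DataFrame, path, dialect: dict | None = None) -> None:
    cols = dict(DEFAULT_DIALECT)
    cols.update(dialect or {})
    out = table[list(PEPTIDE_COLUMNS)].rename(columns=cols)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_label_counts(path) -> pd.DataFrame:
    """Read per-sample light-heavy / heavy-heavy detection counts."""
    raw = _read_tsv(path)
    for column in LABEL_COUNT_COLUMNS:
        if column not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {column!r}")
    out = raw.copy()
    out["timepoint"] = pd.to_numeric(out["timepoint"], errors="coerce")
    for column in ("LH_count", "HH_count"):
        values = pd.to_numeric(out[column], errors="coerce")
        bad = values.isna() | (values < 0) | (values != values.round())
        if bad.any():
            raise FormatError(
                f"{path}: {column} must be a non-negative integer at lines "
                f"{_lines(out.index[bad])}"
            )
        out[column] = values.astype(int)
    t0 = out["timepoint"] == 0
    if t0.any():
        logger.info("read_label_counts: dropping %d t0 rows", int(t0.sum()))
        out = out.loc[~t0]
    return out.reset_index(drop=True)[list(LABEL_COUNT_COLUMNS)]


def write_label_counts(table: pd.DataFrame, path) -> None:
    table[list(LABEL_COUNT_COLUMNS)].to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_complex_table(path) -> pd.DataFrame:
    """Read CORUM-style complex membership (complex_id, protein_group)."""
    raw = _read_tsv(path)
    for column in ("complex_id", "protein_group"):
        if column not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {column!r}")
    empty = (raw["complex_id"].str.strip() == "") | (
        raw["protein_group"].str.strip() == ""
    )
    if empty.any():
        raise FormatError(
            f"{path}: empty identifiers at lines {_lines(raw.index[empty])}"
        )
    return raw[["complex_id", "protein_group"]].reset_index(drop=True)


def write_complex_table(table: pd.DataFrame, path) -> None:
    table[["complex_id", "protein_group"]].to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_puncta_table(path) -> pd.DataFrame:
    """Read per-cell puncta counts over chase days."""
    raw = _read_tsv(path)
    for column in ("cell_id", "chase_days", "puncta_count", "target"):
        if column not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {column!r}")
    out = raw.copy()
    days = pd.to_numeric(out["chase_days"], errors="coerce")
    if (days.isna() | (days < 0)).any():
        raise FormatError(
            f"{path}: chase_days must be non-negative at lines "
            f"{_lines(out.index[days.isna() | (days < 0)])}"
        )
    out["chase_days"] = days.astype(float)
    counts = pd.to_numeric(out["puncta_count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        raise FormatError(
            f"{path}: puncta_count must be a non-negative integer at lines "
            f"{_lines(out.index[bad])}"
        )
    out["puncta_count"] = counts.astype(int)
    dup = out.duplicated(subset=["target", "cell_id", "chase_days"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (cell_id, chase_days) at lines {_lines(out.index[dup])}"
        )
    return out.reset_index(drop=True)[["cell_id", "chase_days", "puncta_count", "target"]]


def write_puncta_table(table: pd.DataFrame, path) -> None:
    table[["cell_id", "chase_days", "puncta_count", "target"]].to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


_HL_COLUMNS = (
    "protein_group",
    "n_peptides",
    "n_points",
    "k_per_day",
    "se_k",
    "r_squared",
    "half_life_days",
    "censored",
)


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.6g}"


def write_halflife_table(records: list[HalfLifeRecord], path) -> None:
    """Write per-protein half-life fits; censored records render as "<1"."""
    if not records:
        raise ValueError("write_halflife_table: no records to write")
    rows = []
    for rec in records:
        if rec.censored:
            rows.append(
                (rec.protein_group, rec.n_peptides, rec.n_points, "NA", "NA", "NA",
                 "<1", 1)
            )
        else:
            rows.append(
                (rec.protein_group, rec.n_peptides, rec.n_points, _fmt(rec.k_per_day),
                 _fmt(rec.se_k), _fmt(rec.r_squared), _fmt(rec.half_life_days), 0)
            )
    pd.DataFrame(rows, columns=_HL_COLUMNS).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )


def read_halflife_table(path) -> list[HalfLifeRecord]:
    raw = _read_tsv(path)
    for column in _HL_COLUMNS:
        if column not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {column!r}")
    records = []
    for _, row in raw.iterrows():
        censored = str(row["censored"]).strip() in ("1", "True", "true")
        if censored:
            records.append(
                HalfLifeRecord(
                    protein_group=row["protein_group"],
                    n_peptides=int(row["n_peptides"]),
                    n_points=int(row["n_points"]),
                    k_per_day=None, se_k=None, r_squared=None,
                    half_life_days=None, censored=True,
                )
            )
        else:
            records.append(
                HalfLifeRecord(
                    protein_group=row["protein_group"],
                    n_peptides=int(row["n_peptides"]),
                    n_points=int(row["n_points"]),
                    k_per_day=float(row["k_per_day"]),
                    se_k=float(row["se_k"]),
                    r_squared=float(row["r_squared"]),
                    half_life_days=float(row["half_life_days"]),
                    censored=False,
                )
            )
    return records


def halflife_map(records: list[HalfLifeRecord]) -> dict[str, float]:
    """protein_group -> numeric half-life (censored records excluded)."""
    return {
        rec.protein_group: rec.half_life_days
        for rec in records
        if not rec.censored and rec.half_life_days is not None
    }


def write_purity_table(purities, path) -> None:
    """Write per-sample purity estimates (sample key, LH, HH, P_H, P_L)."""
    rows = []
    for pur in purities:
        rows.append(tuple(pur.sample) + (pur.LH_count, pur.HH_count,
                                         f"{pur.P_H:.6g}", f"{pur.P_L:.6g}"))
    columns = list(SAMPLE_KEY) + ["LH_count", "HH_count", "P_H", "P_L"]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep="\t", index=False, encoding="utf-8"
    )
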