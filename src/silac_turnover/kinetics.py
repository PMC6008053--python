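"""Label-incorporation purity and the pre-existing-protein fraction.

After a light-to-heavy medium switch that leaves residual light amino
acids, a nascent protein incorporates a heavy Arg/Lys only with probability
P(H) < 1. Missed-cleavage peptides carry two labelable residues, so the
label species of *nascent* molecules are distributed LL : LH : HH =
P(L)^2 : 2 P(L) P(H) : P(H)^2. LL is unobservable (indistinguishable from
pre-existing peptide) but cancels: from the observable detection counts,

    P(H) = (2 * HH / LH) / (1 + 2 * HH / LH).

Each peptide's measured heavy/light ratio is first converted to the light
fraction %L = 1 / (1 + H/L), then corrected for light incorporation into
nascent protein to give the pre-existing fraction

    %old = 1 - (1 - %L) / P(H)**n,

where n counts the heavy-labelable residues that must all be heavy for a
nascent molecule to appear in the heavy channel. Corrections driving %old
negative are excluded from further analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import SilacError
from .types import LabelPurity, SAMPLE_KEY

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_purity",
    "estimate_purity_table",
    "fraction_light",
    "fraction_old",
    "compute_old_fractions",
]


def estimate_purity(LH_count: int, HH_count: int, sample=()) -> LabelPurity:
    """Closed-form heavy-incorporation probability from species counts.

    With LH > 0, P(H) = (2*HH/LH) / (1 + 2*HH/LH). LH = 0 with HH > 0 means
    the light pool is undetectably small; P(H) saturates at 1 (warned).
    """
    if LH_count < 0 or HH_count < 0:
        raise ValueError("label species counts must be non-negative")
    if LH_count + HH_count == 0:
        raise SilacError(f"sample {sample}: no labelled species detected")
    if LH_count == 0:
        logger.warning(
            "sample %s: LH=0 with HH=%d, purity saturated at P_H=1",
            sample, HH_count,
        )
        p_h = 1.0
    else:
        q = 2.0 * HH_count / LH_count
        p_h = q / (1.0 + q)
    return LabelPurity(sample=tuple(sample), LH_count=int(LH_count),
                       HH_count=int(HH_count), P_H=p_h)


def estimate_purity_table(
    label_counts: pd.DataFrame, pooled: bool = False
) -> list[LabelPurity]:
    """Per-sample purity estimates from a label-count table.

    t0 samples carry no nascent protein and are skipped. ``pooled=True``
    sums detections over all samples and returns a single estimate, an
    option for designs with low per-sample counts.
    """
    counts = label_counts[label_counts["timepoint"] > 0]
    if pooled:
        return [
            estimate_purity(
                counts["LH_count"].sum(), counts["HH_count"].sum(), ("pooled",)
            )
        ]
    out = []
    for key, grp in counts.groupby(list(SAMPLE_KEY), sort=False):
        out.append(
            estimate_purity(grp["LH_count"].sum(), grp["HH_count"].sum(), key)
        )
    return out


def fraction_light(ratio_HL, light_only=False):
    """Light fraction %L = 1 / (1 + H/L); 1.0 for light-only detections."""
    ratio = np.asarray(ratio_HL, dtype=float)
    if np.any(ratio[~np.isnan(ratio)] < 0):
        raise ValueError("H/L ratio must be non-negative")
    frac = 1.0 / (1.0 + ratio)
    frac = np.where(np.asarray(light_only, dtype=bool), 1.0, frac)
    if frac.ndim == 0:
        return float(frac)
    return frac


def fraction_old(frac_light, p_h: float, missed_cleavages, exponent_rule="MC+1"):
    """Correct %L for light incorporation into nascent protein.

    Returns (fraction_old, excluded) arrays; excluded marks values driven
    negative by the correction ("negative_after_correction"), which the
    pipeline removes. ``exponent_rule`` chooses n = MC+1 (one factor of
    P(H) per labelable residue, exact for fully tryptic peptides) or the
    per-missed-cleavage rule n = MC.
    """
    if p_h <= 0:
        raise SilacError("correction undefined for P_H = 0")
    if exponent_rule not in ("MC", "MC+1"):
        raise ValueError(f"unknown exponent rule {exponent_rule!r}")
    frac_light = np.asarray(frac_light, dtype=float)
    mc = np.asarray(missed_cleavages, dtype=float)
    n = mc + 1.0 if exponent_rule == "MC+1" else mc
    old = 1.0 - (1.0 - frac_light) / p_h**n
    excluded = old < 0
    if old.ndim == 0:
        return float(old), bool(excluded)
    return old, excluded


def compute_old_fractions(
    peptides: pd.DataFrame,
    purities: list[LabelPurity],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Attach %L and %old columns to a peptide table.

    Each measurement is corrected with its own sample's P(H); t0 rows,
    whose samples have no purity estimate (no nascent protein exists), use
    the mean P(H) of their condition x replicate — at t0 %L is 1 for
    light-only rows anyway, so this only touches rare noisy detections.
    Rows where the correction goes negative are flagged ``excluded`` with
    ``reason = "negative_after_correction"``.
    """
    config = config or PipelineConfig()
    table = peptides.copy()
    table["fraction_light"] = fraction_light(
        table["ratio_HL"].to_numpy(), table["light_only"].to_numpy()
    )

    purity_map = {p.sample: p.P_H for p in purities}
    if not purity_map:
        raise SilacError("no purity estimates supplied")
    pooled = len(purity_map) == 1 and ("pooled",) in purity_map

    # condition x replicate fallback for t0 rows
    by_rep: dict[tuple, list[float]] = {}
    for sample, p_h in purity_map.items():
        if sample == ("pooled",):
            continue
        by_rep.setdefault(sample[:2], []).append(p_h)
    global_mean = float(np.mean(list(purity_map.values())))

    def lookup(row) -> float:
        if pooled:
            return purity_map[("pooled",)]
        key = (row["condition"], row["replicate"], row["injection"],
               row["timepoint"])
        if key in purity_map:
            return purity_map[key]
        rep = key[:2]
        if rep in by_rep:
            return float(np.mean(by_rep[rep]))
        return global_mean

    sample_cols = table[list(SAMPLE_KEY)]
    unique_samples = sample_cols.drop_duplicates()
    p_per_sample = {
        tuple(row): lookup(row) for _, row in unique_samples.iterrows()
    }
    table["P_H"] = [p_per_sample[tuple(row)] for row in
                    sample_cols.itertuples(index=False)]

    old = np.empty(len(table))
    excluded = np.empty(len(table), dtype=bool)
    for p_h, idx in table.groupby("P_H", sort=False).groups.items():
        sub = table.loc[idx]
        old_part, excl_part = fraction_old(
            sub["fraction_light"].to_numpy(), float(p_h),
            sub["missed_cleavages"].to_numpy(), config.exponent_rule,
        )
        pos = table.index.get_indexer(idx)
        old[pos] = old_part
        excluded[pos] = excl_part

    table["fraction_old"] = old
    table["excluded"] = excluded
    table["reason"] = np.where(excluded, "negative_after_correction", "")
    n_excl = int(excluded.sum())
    if n_excl:
        logger.info(
            "compute_old_fractions: %d/%d values negative after correction, "
            "excluded", n_excl, len(table),
        )
    return table
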