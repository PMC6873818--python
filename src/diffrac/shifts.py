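"""Elution-shift and abundance-change classification.

Two independent axes summarize how a protein's elution changes on
treatment.  The elution position is the PSM-weighted mean fraction index
(1-based); the shift is

    shift = w_control - w_treated

so that movement from a high to a low apparent molecular weight — toward
later fractions, since size-exclusion columns elute large species first —
gives a negative value.  The abundance change is

    d_abundance = (total_treated - total_control) / (total_treated + total_control)

bounded in [-1, 1], positive when the protein is more abundant (more
soluble) after treatment.  Signs map to four signal classes (MW decrease /
increase, abundance decrease / increase); exact zeros are tracked as their
own "none" class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PairedExperiment


def weighted_fraction(x) -> float:
    """PSM-weighted mean fraction index (1-based); NaN for an empty profile."""
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total == 0:
        return float("nan")
    i = np.arange(1, x.size + 1)
    return float((i * x).sum() / total)


def elution_shift(x, y) -> float:
    """Signed shift of the weighted elution position, control minus treated.

    Negative = apparent molecular weight decreased (moved to later
    fractions).  NaN when either profile is empty.
    """
    return weighted_fraction(x) - weighted_fraction(y)


def abundance_change(x, y) -> float:
    """Normalized abundance change in [-1, 1]; positive = gain on treatment."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    total = x.sum() + y.sum()
    if total == 0:
        return float("nan")
    return float((y.sum() - x.sum()) / total)


def shift_records(pair: PairedExperiment, subset=None) -> pd.DataFrame:
    """Per-protein shift metrics for an aligned pair.

    ``subset`` restricts to the given protein IDs (typically the
    significant calls); default is every protein in the pair.
    """
    c = pair.control.data
    t = pair.treated.data
    if subset is not None:
        subset = pd.Index(subset)
        c = c.loc[c.index.intersection(subset)]
        t = t.loc[c.index]
    ci = c.to_numpy(dtype=float)
    ti = t.to_numpy(dtype=float)
    i = np.arange(1, ci.shape[1] + 1, dtype=float)

    def _wf(m):
        tot = m.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, (m * i).sum(axis=1) / np.where(tot > 0, tot, 1), np.nan)

    w_c = _wf(ci)
    w_t = _wf(ti)
    tot_c = ci.sum(axis=1)
    tot_t = ti.sum(axis=1)
    tot = tot_c + tot_t
    with np.errstate(invalid="ignore", divide="ignore"):
        d_ab = np.where(tot > 0, (tot_t - tot_c) / np.where(tot > 0, tot, 1), np.nan)
    out = pd.DataFrame(
        {
            "w_control": w_c,
            "w_treated": w_t,
            "shift": w_c - w_t,
            "d_abundance": d_ab,
        },
        index=c.index.copy(),
    )
    out.index.name = "id"
    return out.sort_index()


def classify_signals(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach MW and solubility class labels and tabulate them.

    ``mw_class``: positive shift → ``increase_mw`` (earlier elution),
    negative → ``decrease_mw``, exact zero or undefined → ``none``.
    ``solubility_class`` analogously from the sign of ``d_abundance``.
    Returns (labelled records, summary table of counts and percentages).
    """
    out = records.copy()
    shift = out["shift"]
    d_ab = out["d_abundance"]
    out["mw_class"] = np.select(
        [shift > 0, shift < 0], ["increase_mw", "decrease_mw"], default="none"
    )
    out["solubility_class"] = np.select(
        [d_ab > 0, d_ab < 0],
        ["increase_abundance", "decrease_abundance"],
        default="none",
    )
    rows = []
    for axis in ("mw_class", "solubility_class"):
        counts = out[axis].value_counts()
        for label, count in counts.items():
            rows.append(
                {
                    "axis": axis,
                    "label": label,
                    "count": int(count),
                    "percent": 100.0 * count / len(out) if len(out) else np.nan,
                }
            )
    summary = pd.DataFrame(rows, columns=["axis", "label", "count", "percent"])
    return out, summary


def write_shifts(records: pd.DataFrame, path) -> None:
    cols = ["w_control", "w_treated", "shift", "d_abundance"]
    cols += [c for c in ("mw_class", "solubility_class") if c in records.columns]
    records[cols].to_csv(path, sep="\t", index_label="id")
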