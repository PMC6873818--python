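"""The differential-fractionation score.

For each protein the control and treated elution profiles X_p and Y_p are
compared by their L1 distance

    D_p = sum_i |X_p,i - Y_p,i|

which is normalized by the protein's total abundance across both conditions

    D_p^norm = 2 * D_p / (sum_i X_p,i + sum_i Y_p,i)

so D_norm lies in [0, 2]: 0 for identical profiles, 2 when the two profiles
have disjoint support (e.g. a protein detected in only one condition).
D_norm is scale-invariant and symmetric in the two conditions.  Proteins
with zero total abundance in both conditions have no defined score and are
flagged rather than erroring, so sparse matrices process cleanly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PairedExperiment

SCORE_COLUMNS = [
    "D",
    "D_norm",
    "total_control",
    "total_treated",
    "mean_abundance",
    "defined",
]


def diffrac_distance(x, y) -> float:
    """L1 distance between two same-length elution profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"profile length mismatch: {x.shape} vs {y.shape}")
    return float(np.abs(x - y).sum())


def diffrac_score_norm(x, y) -> float:
    """Abundance-normalized differential score, in [0, 2].

    Returns NaN (undefined) when both profiles are entirely zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    total = x.sum() + y.sum()
    if total == 0:
        return float("nan")
    return 2.0 * diffrac_distance(x, y) / float(total)


def score_experiment(pair: PairedExperiment) -> pd.DataFrame:
    """Score every protein of an aligned pair.

    Returns a DataFrame indexed by protein ID (sorted, deterministic) with
    columns ``D``, ``D_norm``, ``total_control``, ``total_treated``,
    ``mean_abundance`` and ``defined`` (False where both totals are zero;
    such proteins carry D_norm = NaN and are excluded downstream).
    """
    c = pair.control.data.to_numpy(dtype=float)
    t = pair.treated.data.to_numpy(dtype=float)
    d = np.abs(c - t).sum(axis=1)
    total_c = c.sum(axis=1)
    total_t = t.sum(axis=1)
    total = total_c + total_t
    defined = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d_norm = np.where(defined, 2.0 * d / np.where(defined, total, 1.0), np.nan)
    out = pd.DataFrame(
        {
            "D": d,
            "D_norm": d_norm,
            "total_control": total_c,
            "total_treated": total_t,
            "mean_abundance": total / 2.0,
            "defined": defined,
        },
        index=pair.protein_ids.copy(),
    )
    out.index.name = "id"
    return out.sort_index()


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="id")
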