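"""Significance of differential elution scores.

The normalized score D_norm is biased by abundance (low-count proteins are
noisier), so each protein is compared to an empirical null built from
proteins of similar abundance: the 2s+1 proteins surrounding it in
abundance rank, restricted to proteins not already literature-annotated as
RNA-associated.  Each window's score distribution is modelled as a mixture
of a non-RNA-associated bulk and a possible RNA-associated tail: a two-
component Gaussian mixture is accepted over a single Gaussian only when

  (a) its BIC is no worse than the single component's,
  (b) the lowest-mean component carries the largest weight, and
  (c) that weight reaches a threshold ``t_weight`` (the expected fraction
      of non-RNA-binders; 0.6-0.75 in practice, default 0.7).

The protein's Z-score against the chosen null component,
Z = (D_norm - mu) / sigma, is converted to an upper-tail normal p-value,
Benjamini-Hochberg corrected across the proteome, and called significant
below a 5% FDR by default.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _gmm

DEFAULT_WINDOW = 100
DEFAULT_T_WEIGHT = 0.7
DEFAULT_ALPHA = 0.05
DEFAULT_N_RESTARTS = 3
SIGMA_FLOOR = 1e-6


@dataclass
class BackgroundWindow:
    """Abundance-rank window of background scores for one protein."""

    center_protein_id: str
    member_ids: list
    member_scores: np.ndarray
    s: int = DEFAULT_WINDOW


@dataclass
class GmmFit:
    """Fitted background model for one protein's abundance window."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic_1: float
    bic_2: float
    mu: float
    sigma: float
    criteria_passed: dict = field(default_factory=dict)
    t_weight: float = DEFAULT_T_WEIGHT
    degenerate: bool = False


def order_background_pool(scores: pd.DataFrame, annotated=frozenset()) -> pd.DataFrame:
    """Background pool: unannotated proteins with defined scores, by abundance.

    Sorted by mean abundance descending; ties broken by protein ID so the
    ordering (and everything downstream) is deterministic.  ``annotated``
    is any container of protein IDs with prior literature RNA-association
    (see :mod:`diffrac.annotations`); pass an :class:`AnnotationSet`'s
    union or a plain set.
    """
    annotated = set(annotated)
    pool = scores[scores["defined"] & ~scores.index.isin(annotated)]
    if len(pool) < 3:
        raise ValueError(
            f"background pool has {len(pool)} proteins; need >= 3 unannotated "
            "proteins with defined scores to fit a null"
        )
    order = np.lexsort((pool.index.to_numpy(), -pool["mean_abundance"].to_numpy()))
    return pool.iloc[order]


def _window_bounds(rank: int, n: int, s: int) -> tuple[int, int]:
    """[lo, hi] pool positions for a query at ``rank``, clamped inward.

    The window keeps its full width 2s+1 where the pool allows, extending
    inward at the edges; a pool smaller than 2s+1 yields the whole pool.
    """
    if n <= 2 * s + 1:
        return 0, n - 1
    lo, hi = rank - s, rank + s
    if lo < 0:
        hi -= lo
        lo = 0
    if hi > n - 1:
        lo -= hi - (n - 1)
        hi = n - 1
    return lo, hi


def background_window(
    protein_id: str, pool: pd.DataFrame, s: int = DEFAULT_WINDOW,
    mean_abundance: float | None = None,
) -> BackgroundWindow:
    """Window of background scores around one protein's abundance rank.

    A protein in the pool occupies its own rank and its own score is
    excluded from the window.  An annotated (out-of-pool) protein is
    slotted at the rank it would occupy by abundance; ``mean_abundance``
    must then be given.
    """
    n = len(pool)
    pool_ids = pool.index.to_numpy()
    positions = {pid: i for i, pid in enumerate(pool_ids)}
    if protein_id in positions:
        rank = positions[protein_id]
        self_pos = rank
    else:
        if mean_abundance is None:
            raise ValueError(
                f"{protein_id!r} is not in the pool; supply its mean_abundance"
            )
        keys = list(zip(-pool["mean_abundance"].to_numpy(), pool_ids))
        rank = bisect.bisect_left(keys, (-float(mean_abundance), protein_id))
        self_pos = -1
    lo, hi = _window_bounds(rank, n, int(s))
    idx = [i for i in range(lo, hi + 1) if i != self_pos]
    return BackgroundWindow(
        center_protein_id=protein_id,
        member_ids=list(pool_ids[idx]),
        member_scores=pool["D_norm"].to_numpy()[idx],
        s=int(s),
    )


def fit_background(
    window: BackgroundWindow,
    t_weight: float = DEFAULT_T_WEIGHT,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    sigma_floor: float = SIGMA_FLOOR,
) -> GmmFit:
    """Fit the 1- and 2-component null to one window and select between them."""
    if not 0.0 < t_weight < 1.0:
        raise ValueError(f"t_weight must be in (0, 1), got {t_weight}")
    x = np.asarray(window.member_scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty background window")
    X = x[None, :]
    mask = np.ones_like(X, dtype=bool)
    res = _fit_windows_batch(
        X, mask, t_weight=t_weight, seed=seed,
        n_restarts=n_restarts, sigma_floor=sigma_floor,
    )
    i = 0
    two = bool(res["two_ok"][i])
    return GmmFit(
        n_components=2 if two else 1,
        weights=res["w2"][i] if two else np.array([1.0]),
        means=res["mu2"][i] if two else np.array([res["mu1"][i]]),
        sds=np.sqrt(res["var2"][i]) if two else np.array([np.sqrt(res["var1"][i])]),
        bic_1=float(res["bic1"][i]),
        bic_2=float(res["bic2"][i]),
        mu=float(res["mu"][i]),
        sigma=float(res["sigma"][i]),
        criteria_passed={
            "bic": bool(res["crit_bic"][i]),
            "lowest_mean_weight": bool(res["crit_wmax"][i]),
            "weight_threshold": bool(res["crit_tw"][i]),
        },
        t_weight=t_weight,
        degenerate=bool(res["degenerate"][i]),
    )


def _fit_windows_batch(X, mask, *, t_weight, seed, n_restarts, sigma_floor):
    """Fit both models to every masked row and apply the selection criteria."""
    mu1, var1, _, bic1 = _gmm.fit_1comp(X, mask)
    w2, mu2, var2, _, bic2 = _gmm.fit_2comp(
        X, mask, n_restarts=n_restarts, seed=seed
    )
    crit_bic = bic2 <= bic1
    crit_wmax = w2[:, 0] >= w2[:, 1]  # lowest-mean component has largest weight
    crit_tw = w2.max(axis=1) >= t_weight
    two_ok = crit_bic & crit_wmax & crit_tw
    mu = np.where(two_ok, mu2[:, 0], mu1)
    sigma = np.sqrt(np.where(two_ok, var2[:, 0], var1))
    # zero-variance windows: keep sigma finite, flag as degenerate
    n_valid = mask.sum(axis=1)
    xm = np.where(mask, X, np.nan)
    raw_var = np.nanvar(xm, axis=1)
    degenerate = raw_var <= sigma_floor**2
    sigma = np.maximum(sigma, sigma_floor)
    return {
        "mu1": mu1, "var1": var1, "bic1": bic1,
        "w2": w2, "mu2": mu2, "var2": var2, "bic2": bic2,
        "crit_bic": crit_bic, "crit_wmax": crit_wmax, "crit_tw": crit_tw,
        "two_ok": two_ok, "mu": mu, "sigma": sigma,
        "degenerate": degenerate, "n_valid": n_valid,
    }


def z_and_p(d_norm: float, fit: GmmFit) -> tuple[float, float]:
    """Z-score against the fitted null component and its upper-tail p-value."""
    if fit.degenerate or not np.isfinite(d_norm):
        return float("nan"), float("nan")
    z = (d_norm - fit.mu) / max(fit.sigma, SIGMA_FLOOR)
    return float(z), float(stats.norm.sf(z))


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries (undefined p) stay NaN and do not count toward the number
    of tests.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if finite.sum() > 0:
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def call_rna_associated(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Flag proteins with FDR-corrected q strictly below ``alpha``."""
    out = records.copy()
    out["significant"] = out["q"] < alpha
    return out


def assign_significance(
    scores: pd.DataFrame,
    annotated=frozenset(),
    *,
    s: int = DEFAULT_WINDOW,
    t_weight: float = DEFAULT_T_WEIGHT,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    sigma_floor: float = SIGMA_FLOOR,
) -> pd.DataFrame:
    """Proteome-wide significance: windows, mixture nulls, Z, p, BH q, calls.

    The per-protein route (:func:`background_window` + :func:`fit_background`
    + :func:`z_and_p`) and this batched route share the same fitting code.

    Returns a DataFrame indexed like ``scores`` with columns ``D_norm``,
    ``mean_abundance``, ``Z``, ``p``, ``q``, ``significant`` plus the
    background-fit diagnostics ``mu_bg``, ``sigma_bg``, ``n_components``.
    """
    if not 0.0 < t_weight < 1.0:
        raise ValueError(f"t_weight must be in (0, 1), got {t_weight}")
    pool = order_background_pool(scores, annotated)
    n = len(pool)
    pool_ids = pool.index.to_numpy()
    pool_scores = pool["D_norm"].to_numpy()
    pool_pos = {pid: i for i, pid in enumerate(pool_ids)}
    pool_keys = list(zip(-pool["mean_abundance"].to_numpy(), pool_ids))

    queries = scores[scores["defined"]]
    qids = queries.index.to_numpy()
    B = len(qids)
    ranks = np.empty(B, dtype=int)
    self_pos = np.full(B, -1, dtype=int)
    for j, pid in enumerate(qids):
        if pid in pool_pos:
            ranks[j] = self_pos[j] = pool_pos[pid]
        else:
            ranks[j] = bisect.bisect_left(
                pool_keys, (-float(queries["mean_abundance"].iloc[j]), pid)
            )

    width = min(n, 2 * int(s) + 1)
    lo = np.empty(B, dtype=int)
    hi = np.empty(B, dtype=int)
    for j in range(B):
        lo[j], hi[j] = _window_bounds(int(ranks[j]), n, int(s))
    idx = lo[:, None] + np.arange(width)[None, :]
    mask = idx <= hi[:, None]
    idx = np.minimum(idx, n - 1)
    mask &= idx != self_pos[:, None]
    X = pool_scores[idx]

    res = _fit_windows_batch(
        X, mask, t_weight=t_weight, seed=seed,
        n_restarts=n_restarts, sigma_floor=sigma_floor,
    )
    d_norm = queries["D_norm"].to_numpy()
    z = np.where(
        res["degenerate"], np.nan, (d_norm - res["mu"]) / res["sigma"]
    )
    p = stats.norm.sf(z)

    out = pd.DataFrame(
        {
            "D_norm": scores["D_norm"],
            "mean_abundance": scores["mean_abundance"],
            "Z": np.nan,
            "p": np.nan,
            "mu_bg": np.nan,
            "sigma_bg": np.nan,
            "n_components": 0,
        },
        index=scores.index.copy(),
    )
    out.loc[qids, "Z"] = z
    out.loc[qids, "p"] = p
    out.loc[qids, "mu_bg"] = res["mu"]
    out.loc[qids, "sigma_bg"] = res["sigma"]
    out.loc[qids, "n_components"] = np.where(res["two_ok"], 2, 1)
    out["q"] = fdr_correct(out["p"].to_numpy())
    out = call_rna_associated(out, alpha=alpha)
    out["significant"] = out["significant"].fillna(False).astype(bool)
    out.index.name = "id"
    return out


def write_significance(records: pd.DataFrame, path) -> None:
    cols = ["D_norm", "mean_abundance", "Z", "p", "q", "significant"]
    records[cols].to_csv(path, sep="\t", index_label="id")
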