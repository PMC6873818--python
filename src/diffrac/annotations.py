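"""RNA-binding annotation sets and ranking evaluation.

Annotations arrive as plain-text files (one protein ID per line, ``#``
comments, optional TAB-separated source tag): low-throughput (LT) sets are
typically assembled offline from GO "RNA binding" terms restricted to
experimental/curated evidence codes plus UniProt ribonucleoprotein
keywords; high-throughput (HT) sets from published interactome capture
style studies.  No live database querying happens here — file inputs keep
runs reproducible.

Ranked predictions are evaluated on the -ln(p) scale (with a tiny
pseudocount so p = 0 stays finite): precision = TP/AP over proteins scoring
strictly above each threshold, recall = TP/AKP against the annotated set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1e-308


@dataclass
class AnnotationSet:
    """Low- and high-throughput RNA-association annotations."""

    lt: set = field(default_factory=set)
    ht: set = field(default_factory=set)
    sources: dict = field(default_factory=dict)  # protein -> set of source tags

    @property
    def union(self) -> set:
        return self.lt | self.ht


def _read_id_file(path, id_map, sources, default_tag):
    ids = set()
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            parts = line.split("\t")
            pid, tag = parts[0], (parts[1] if len(parts) > 1 else default_tag)
            if id_map is not None:
                if pid not in id_map:
                    logger.warning("ID %r not in id_map; dropped", pid)
                    continue
                pid = id_map[pid]
            ids.add(pid)
            sources.setdefault(pid, set()).add(tag)
    if n_lines == 0:
        warnings.warn(f"annotation file {path} is empty", stacklevel=3)
    return ids


def load_annotations(lt_files=(), ht_files=(), id_map_path=None) -> AnnotationSet:
    """Load and deduplicate LT/HT annotation files.

    ``id_map_path`` is an optional two-column TSV mapping file IDs into the
    elution-matrix namespace; unmapped IDs are dropped with a logged
    warning.
    """
    id_map = None
    if id_map_path is not None:
        df = pd.read_csv(id_map_path, sep="\t", header=None, dtype=str)
        id_map = dict(zip(df[0], df[1]))
    ann = AnnotationSet()
    for path in lt_files:
        ann.lt |= _read_id_file(path, id_map, ann.sources, "lt")
    for path in ht_files:
        ann.ht |= _read_id_file(path, id_map, ann.sources, "ht")
    return ann


def neg_ln_p(p) -> np.ndarray | float:
    """-ln(p + 1e-308); maps p in [0, 1] onto [~0, ~709]."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = -np.log(p_arr + PSEUDOCOUNT)
    return float(out) if out.ndim == 0 else out


def precision_curve(scores: pd.Series, positives) -> pd.DataFrame:
    """Precision over score thresholds.

    For each threshold t (the distinct scores, plus one below the minimum),
    precision = TP/AP where AP = proteins with score strictly greater than
    t and TP = those also in ``positives``.  Thresholds above the maximum
    score leave no predictions and are omitted.
    """
    positives = set(positives)
    s = scores.dropna().sort_values(ascending=False)
    is_pos = s.index.isin(positives).astype(int)
    tp_cum = np.cumsum(is_pos)
    ap_cum = np.arange(1, len(s) + 1)
    rows = []
    vals = s.to_numpy()
    # at threshold just below each distinct score, all entries >= that score predict
    for t in np.unique(vals):
        k = int(np.searchsorted(-vals, -t, side="right"))  # count of scores >= t
        # strictly greater than a threshold infinitesimally below t == score >= t
        rows.append(
            {
                "threshold": float(np.nextafter(t, -np.inf)),
                "tp": int(tp_cum[k - 1]),
                "ap": int(ap_cum[k - 1]),
            }
        )
    out = pd.DataFrame(rows, columns=["threshold", "tp", "ap"]).sort_values(
        "threshold", ascending=False, ignore_index=True
    )
    out["precision"] = out["tp"] / out["ap"]
    return out


def precision_recall(scores: pd.Series, positives) -> pd.DataFrame:
    """Precision-recall curve; recall = TP / |positives| (all known positives)."""
    positives = set(positives)
    if not positives:
        raise ValueError("recall is undefined with no known positives")
    out = precision_curve(scores, positives)
    out["recall"] = out["tp"] / len(positives)
    return out


def overlap_summary(
    set_a,
    set_b,
    set_c,
    score_records: pd.DataFrame | None = None,
    min_mean_abundance: float | None = 10.0,
) -> dict:
    """Counts of the 7 regions of a three-set Venn diagram.

    When ``score_records`` is given, membership is restricted to proteins
    with ``mean_abundance >= min_mean_abundance`` (pass ``None`` to skip
    the filter).  Keys are 'a', 'b', 'c', 'ab', 'ac', 'bc', 'abc' for the
    exclusive regions.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    if score_records is not None and min_mean_abundance is not None:
        keep = set(
            score_records.index[
                score_records["mean_abundance"] >= min_mean_abundance
            ]
        )
        a, b, c = a & keep, b & keep, c & keep
    return {
        "a": len(a - b - c),
        "b": len(b - a - c),
        "c": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
    }
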