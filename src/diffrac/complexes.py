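"""RNP complex calling on curated complex definitions.

Complexes come from curated resources (CORUM-style) or computational maps
(hu.MAP-style); the two are merged into a non-redundant set in which only
complexes with identical membership (Jaccard coefficient exactly 1.0) are
collapsed, curated source taking precedence.

A complex is called an RNP when strictly more than half of its subunits
carry RNA-association evidence from any of three sources: a significant
differential-elution call, high-throughput annotation, or low-throughput
annotation.  The stricter "RNP Select" set additionally requires the
subunits to co-elute in the control sample (mean pairwise Pearson
correlation of their control profiles > 0.75) with a majority of subunits
passing a relaxed per-protein significance threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ElutionMatrix

R_MIN = 0.75
P_RELAXED = 0.5


@dataclass(frozen=True)
class Complex:
    complex_id: str
    name: str
    source: str  # "CORUM", "huMAP", or other
    members: frozenset


@dataclass
class ComplexSet:
    """Named complexes with subunit membership."""

    complexes: dict = field(default_factory=dict)  # complex_id -> Complex

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes.values())

    def add(self, cplx: Complex) -> None:
        if len(cplx.members) < 2:
            raise ValueError(
                f"complex {cplx.complex_id!r} has fewer than 2 subunits"
            )
        self.complexes[cplx.complex_id] = cplx


def jaccard(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for two non-empty sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Jaccard coefficient is undefined for empty sets")
    return len(a & b) / len(a | b)


def read_complexes(path, source: str = "other") -> ComplexSet:
    """Read a complex file: one complex per line, TAB-separated subunit IDs.

    An optional leading ``complex_id:`` token names the complex; otherwise
    complexes are numbered ``<source>_1``, ``<source>_2``, ...  CORUM-style
    TSVs (header with a name column and semicolon-separated subunits) are
    also accepted.
    """
    cs = ComplexSet()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if lines and "\t" in lines[0] and ";" in lines[0].split("\t")[-1]:
        # CORUM-style: name <TAB> semicolon-separated subunits (no header needed)
        for k, ln in enumerate(lines, 1):
            parts = ln.split("\t")
            members = frozenset(p for p in parts[-1].split(";") if p)
            cs.add(Complex(f"{source}_{k}", parts[0], source, members))
        return cs
    for k, ln in enumerate(lines, 1):
        fields = [f for f in ln.split("\t") if f]
        cid, name = f"{source}_{k}", f"{source}_{k}"
        if fields and fields[0].endswith(":"):
            cid = name = fields[0][:-1]
            fields = fields[1:]
        cs.add(Complex(cid, name, source, frozenset(fields)))
    return cs


def merge_complex_sets(corum: ComplexSet, humap: ComplexSet,
                       precedence: str = "CORUM") -> ComplexSet:
    """Combine two complex sets, collapsing identical-membership duplicates.

    Only complexes with Jaccard coefficient exactly 1.0 (same subunit set)
    are deduplicated; similar-but-distinct complexes are both kept.  When a
    duplicate spans both sources the representative comes from the
    ``precedence`` source.
    """
    first, second = (corum, humap)
    if precedence != "CORUM":
        first, second = second, first
    merged = ComplexSet()
    seen: dict[frozenset, str] = {}
    for cs in (first, second):
        for cplx in cs:
            if cplx.members in seen:
                continue
            seen[cplx.members] = cplx.complex_id
            merged.add(cplx)
    return merged


def coelution(members, control: ElutionMatrix) -> float:
    """Mean pairwise Pearson correlation of detected subunits' control profiles.

    Subunits absent from the matrix or with all-zero profiles are not
    detected; with fewer than 2 detected subunits (or no variable pair) the
    value is undefined (NaN) and the complex cannot enter RNP Select.
    """
    detected = [
        m for m in sorted(members)
        if m in control.protein_ids and control.data.loc[m].sum() > 0
    ]
    if len(detected) < 2:
        return float("nan")
    profiles = control.data.loc[detected].to_numpy(dtype=float)
    rs = []
    for i, j in itertools.combinations(range(len(detected)), 2):
        xi, xj = profiles[i], profiles[j]
        if xi.std() == 0 or xj.std() == 0:
            continue  # constant profile: correlation undefined for this pair
        rs.append(np.corrcoef(xi, xj)[0, 1])
    return float(np.mean(rs)) if rs else float("nan")


def _evidence_fractions(members, diffrac_significant, ht, lt):
    n = len(members)
    ev_d = len(members & diffrac_significant)
    ev_h = len(members & ht)
    ev_l = len(members & lt)
    ev_u = len(members & (diffrac_significant | ht | lt))
    return ev_d / n, ev_h / n, ev_l / n, ev_u / n


def call_rnp(
    complexes: ComplexSet,
    diffrac_significant=frozenset(),
    ht_annotated=frozenset(),
    lt_annotated=frozenset(),
) -> pd.DataFrame:
    """Call RNP complexes by strict-majority subunit evidence.

    ``is_rnp`` is true when strictly more than half the subunits are in the
    union of the three evidence sets; the per-source fractions are reported
    for transparency.
    """
    diffrac_significant = set(diffrac_significant)
    ht, lt = set(ht_annotated), set(lt_annotated)
    rows = []
    for cplx in complexes:
        f_d, f_h, f_l, f_u = _evidence_fractions(
            cplx.members, diffrac_significant, ht, lt
        )
        rows.append(
            {
                "complex_id": cplx.complex_id,
                "source": cplx.source,
                "n_subunits": len(cplx.members),
                "frac_diffrac": f_d,
                "frac_ht": f_h,
                "frac_lt": f_l,
                "frac_union": f_u,
                "is_rnp": f_u > 0.5,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "complex_id", "source", "n_subunits",
            "frac_diffrac", "frac_ht", "frac_lt", "frac_union", "is_rnp",
        ],
    ).set_index("complex_id")
    return out.sort_index()


def call_rnp_select(
    complexes: ComplexSet,
    control: ElutionMatrix,
    q_values: pd.Series,
    r_min: float = R_MIN,
    p_relaxed: float = P_RELAXED,
    relaxed_is_upper_bound: bool = True,
) -> pd.DataFrame:
    """Call the high-confidence RNP Select set.

    A complex is selected when its detected subunits co-elute in the
    control sample (mean pairwise Pearson r > ``r_min``) and strictly more
    than half of all its subunits pass the relaxed per-protein threshold on
    their FDR-corrected p-value (``q < p_relaxed``; set
    ``relaxed_is_upper_bound=False`` to flip the inequality to
    ``q > p_relaxed``).
    """
    rows = []
    for cplx in complexes:
        r = coelution(cplx.members, control)
        n = len(cplx.members)
        qs = q_values.reindex(sorted(cplx.members))
        if relaxed_is_upper_bound:
            n_pass = int((qs < p_relaxed).sum())
        else:
            n_pass = int((qs > p_relaxed).sum())
        frac_pass = n_pass / n
        selected = bool(np.isfinite(r) and r > r_min and frac_pass > 0.5)
        rows.append(
            {
                "complex_id": cplx.complex_id,
                "source": cplx.source,
                "n_subunits": n,
                "n_detected": sum(
                    1 for m in cplx.members
                    if m in control.protein_ids and control.data.loc[m].sum() > 0
                ),
                "mean_pairwise_r": r,
                "frac_relaxed_pass": frac_pass,
                "is_rnp_select": selected,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "complex_id", "source", "n_subunits", "n_detected",
            "mean_pairwise_r", "frac_relaxed_pass", "is_rnp_select",
        ],
    ).set_index("complex_id")
    return out.sort_index()


def call_complexes(
    complexes: ComplexSet,
    control: ElutionMatrix,
    significance: pd.DataFrame,
    ht_annotated=frozenset(),
    lt_annotated=frozenset(),
    r_min: float = R_MIN,
    p_relaxed: float = P_RELAXED,
) -> pd.DataFrame:
    """Full complex-level report: RNP and RNP Select calls side by side."""
    sig_set = set(significance.index[significance["significant"]])
    rnp = call_rnp(complexes, sig_set, ht_annotated, lt_annotated)
    select = call_rnp_select(
        complexes, control, significance["q"], r_min=r_min, p_relaxed=p_relaxed
    )
    out = rnp.join(select[["n_detected", "mean_pairwise_r", "frac_relaxed_pass",
                           "is_rnp_select"]])
    return out


def write_complex_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="complex_id")
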