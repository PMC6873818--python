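"""Reading, writing and aligning elution matrices.

An elution matrix is a proteins × fractions table of peptide-spectral-match
(PSM) counts from one co-fractionation MS run.  The on-disk format is a wide
TSV (".elut" dialect): first column = protein ID, remaining columns =
fractions in elution order, blank cells meaning zero.  Fraction indices are
1-based everywhere they surface in reports, matching elution-fraction
numbering on chromatograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ElutionError(ValueError):
    """Raised when an elution matrix or pair violates a structural invariant."""


@dataclass
class ElutionMatrix:
    """PSM counts for one condition, proteins × fractions.

    Parameters
    ----------
    data
        DataFrame indexed by protein ID with one column per fraction, in
        elution order.  Values are non-negative reals (counts, or rescaled
        counts).
    condition_label
        Free-text label for the condition ("control", "rnase", ...).
    """

    data: pd.DataFrame
    condition_label: str = ""

    def __post_init__(self) -> None:
        validate_matrix(self.data)

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def fraction_labels(self) -> pd.Index:
        return self.data.columns

    @property
    def n_fractions(self) -> int:
        return self.data.shape[1]

    def profile(self, protein_id: str) -> np.ndarray:
        """Elution profile of one protein as a float array."""
        return self.data.loc[protein_id].to_numpy(dtype=float)

    def totals(self) -> pd.Series:
        """Total PSMs per protein across all fractions."""
        return self.data.sum(axis=1)


def validate_matrix(data: pd.DataFrame) -> None:
    if data.shape[1] < 2:
        raise ElutionError(
            f"elution matrix needs at least 2 fraction columns, got {data.shape[1]}"
        )
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][0]
        raise ElutionError(f"duplicate protein ID: {dup!r}")
    if bool((data.to_numpy() < 0).any()):
        raise ElutionError("negative PSM counts are not allowed")
    if data.isna().any().any():
        raise ElutionError("internal error: NaN cells after load")


def read_elution_matrix(path, condition_label: str = "") -> ElutionMatrix:
    """Read a wide-TSV elution matrix.

    Blank cells are zero-filled; column order is preserved as elution order.
    Duplicate protein IDs, negative values and fewer than two fraction
    columns are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df = df.replace("", "0").astype(float).fillna(0.0)
    df.index = df.index.astype(str)
    return ElutionMatrix(df, condition_label=condition_label)


def write_elution_matrix(matrix: ElutionMatrix, path) -> None:
    """Write a matrix back to wide TSV, losslessly for integer counts."""
    out = matrix.data.copy()
    # keep integer counts as integers on disk so round-trips are byte-stable
    if np.allclose(out.to_numpy(), np.round(out.to_numpy())):
        out = out.astype(np.int64)
    out.to_csv(path, sep="\t", index_label="id")


@dataclass
class PairedExperiment:
    """A control/treated pair on a shared protein universe and fraction grid.

    After alignment the protein universe is the union of the two input
    universes; a protein absent from one condition keeps an all-zero profile
    there (such proteins attain the maximal differential score and belong to
    the abundance-gain/loss classes, so they stay in the analysis).
    """

    control: ElutionMatrix
    treated: ElutionMatrix

    @property
    def protein_ids(self) -> pd.Index:
        return self.control.protein_ids

    @property
    def n_fractions(self) -> int:
        return self.control.n_fractions


def align_pair(control: ElutionMatrix, treated: ElutionMatrix) -> PairedExperiment:
    """Align two single-condition matrices onto the union protein universe.

    Fraction grids must match exactly by index: the differential score is a
    fraction-by-fraction comparison and no cross-grid interpolation is
    defined.  Idempotent on already-aligned pairs.
    """
    if control.n_fractions != treated.n_fractions:
        raise ElutionError(
            "fraction grids differ: control has "
            f"{control.n_fractions} fractions, treated has {treated.n_fractions}"
        )
    universe = control.protein_ids.union(treated.protein_ids).sort_values()
    c = control.data.reindex(universe, fill_value=0.0)
    t = treated.data.reindex(universe, fill_value=0.0)
    return PairedExperiment(
        ElutionMatrix(c, condition_label=control.condition_label or "control"),
        ElutionMatrix(t, condition_label=treated.condition_label or "treated"),
    )


@dataclass
class MwCalibration:
    """Log-linear fraction → molecular-weight calibration.

    Size-exclusion columns are calibrated with standards of known molecular
    weight (e.g. thyroglobulin 669 kDa ... carbonic anhydrase 29 kDa);
    log10(kDa) is close to linear in elution position, so a least-squares
    line through the standards predicts apparent MW for any fraction.
    """

    standards: list = field(default_factory=list)  # (fraction, kda) pairs
    slope: float = 0.0
    intercept: float = 0.0

    def predict_kda(self, fraction) -> np.ndarray | float:
        """Apparent molecular weight (kDa) at the given fraction position(s)."""
        f = np.asarray(fraction, dtype=float)
        out = 10.0 ** (self.slope * f + self.intercept)
        return float(out) if out.ndim == 0 else out


def calibrate_mw(standards) -> MwCalibration:
    """Fit log10(kDa) ~ fraction by least squares.

    Standards are (fraction position, kDa) pairs; at least two are required.
    MW should decrease with fraction position (SEC elutes large species
    first); a non-monotonic set gets a warning but the fit is still returned.
    """
    standards = [(float(f), float(k)) for f, k in standards]
    if len(standards) < 2:
        raise ElutionError("molecular-weight calibration needs >= 2 standards")
    standards.sort(key=lambda fk: fk[0])
    kdas = np.array([k for _, k in standards])
    if np.any(np.diff(kdas) >= 0):
        warnings.warn(
            "calibration standards are not strictly decreasing in MW with "
            "fraction position; fit returned anyway",
            stacklevel=2,
        )
    fracs = np.array([f for f, _ in standards])
    slope, intercept = np.polyfit(fracs, np.log10(kdas), deg=1)
    return MwCalibration(standards=standards, slope=float(slope), intercept=float(intercept))
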