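"""Synthetic paired co-fractionation experiments with known ground truth.

The generator emulates a size-exclusion separation of a few thousand
proteins over ~50 fractions: each protein gets a log-normal total abundance
(PSM units), a Gaussian elution peak with uniform-random center and width,
and its observed per-fraction counts are Poisson draws (optionally
negative-binomial for overdispersion) from the peak discretized onto the
fraction grid.  Peaks are truncated at the grid edges with their mass
renormalized, so every protein keeps its drawn abundance in expectation.

True "RNA-associated" proteins have their treated peak shifted by a drawn
number of fractions (by default mostly toward later fractions, i.e. toward
lower apparent molecular weight, the dominant behavior on RNA removal) and
their treated abundance rescaled by a log-normal multiplier.  A small
abundance-coupled jitter on the per-condition peak center makes low-
abundance null proteins noisier than high-abundance ones — the abundance
dependence the windowed background model exists to absorb.

Planted complexes let subunits share one elution template (plus
per-subunit noise) and, when flagged as true RNPs, shift coherently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ElutionMatrix


@dataclass
class PlantedComplex:
    """A complex to plant: ``size`` subunits, optionally sharing a template
    elution peak, optionally a true RNP (all subunits shift coherently)."""

    size: int
    shared_template: bool = True
    true_rnp: bool = False


@dataclass
class SimConfig:
    """Generator parameters; defaults emulate a 50-fraction SEC experiment."""

    n_proteins: int = 2000
    n_fractions: int = 50
    # log-normal PSM abundance: median ~33 PSMs, heavy right tail
    abundance_log_mean: float = 3.5
    abundance_log_sd: float = 1.0
    # Gaussian elution peaks
    peak_width_min: float = 1.5
    peak_width_max: float = 4.0
    # truth model
    rna_fraction: float = 0.1
    shift_min: float = 10.0
    shift_max: float = 15.0
    shift_positive_prob: float = 0.8  # toward later fractions (lower MW)
    abundance_multiplier_log_sd: float = 0.25
    # noise
    jitter_scale: float = 2.0  # per-condition center jitter sd = scale/sqrt(abundance)
    overdispersion: float = 0.0  # negative-binomial dispersion; 0 = Poisson
    planted_complexes: list = field(default_factory=list)
    # planted complexes emulate detectably co-eluting stable assemblies:
    # curated complex databases skew toward abundant proteins, and a complex
    # whose subunits are at the Poisson noise floor would not co-elute
    # measurably however perfect its shared template
    complex_abundance_min: float = 50.0
    complex_center_noise: float = 0.25
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.rna_fraction <= 1.0:
            raise ValueError("rna_fraction must be in [0, 1]")
        if self.n_fractions < 2:
            raise ValueError("need at least 2 fractions")
        if self.n_proteins < 1:
            raise ValueError("need at least 1 protein")
        for name in (
            "abundance_log_mean", "abundance_log_sd", "peak_width_min",
            "peak_width_max", "shift_min", "shift_max", "jitter_scale",
            "overdispersion",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.peak_width_min <= 0 or self.peak_width_max < self.peak_width_min:
            raise ValueError("peak widths must satisfy 0 < min <= max")
        total_planted = sum(pc.size for pc in self.planted_complexes)
        if total_planted > self.n_proteins:
            raise ValueError("planted complexes exceed the proteome size")


def _expected_profile(center: float, width: float, abundance: float,
                      n_fractions: int) -> np.ndarray:
    """Discretized Gaussian peak renormalized to carry ``abundance`` mass."""
    i = np.arange(1, n_fractions + 1, dtype=float)
    dens = np.exp(-0.5 * ((i - center) / width) ** 2)
    total = dens.sum()
    if total == 0:  # peak entirely off-grid; park all mass at nearest edge
        dens = np.zeros(n_fractions)
        dens[0 if center < 1 else -1] = 1.0
        total = 1.0
    return abundance * dens / total


def _sample_counts(rng: np.random.Generator, lam: np.ndarray,
                   overdispersion: float) -> np.ndarray:
    if overdispersion <= 0:
        return rng.poisson(lam).astype(float)
    # gamma-Poisson with var = lam * (1 + overdispersion)
    shape = lam / overdispersion
    rate = rng.gamma(np.where(shape > 0, shape, 1.0), overdispersion)
    rate = np.where(lam > 0, rate, 0.0)
    return rng.poisson(rate).astype(float)


@dataclass
class SimTruth:
    """Ground truth of one simulated pair."""

    proteins: pd.DataFrame  # is_rna_associated, true_shift, abundance_multiplier, complex_id
    complexes: pd.DataFrame  # size, shared_template, is_true_rnp


def simulate_pair(config: SimConfig) -> tuple[ElutionMatrix, ElutionMatrix, SimTruth]:
    """Generate one control/treated pair plus its ground truth.

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, nf = config.n_proteins, config.n_fractions
    ids = np.array([f"P{k:06d}" for k in range(1, n + 1)])

    abundance = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, n)
    center = rng.uniform(1.0, nf, n)
    width = rng.uniform(config.peak_width_min, config.peak_width_max, n)

    # truth labels: exact count for stable proportions
    n_true = int(round(config.rna_fraction * n))
    is_true = np.zeros(n, dtype=bool)
    is_true[rng.choice(n, size=n_true, replace=False)] = True

    sign = np.where(rng.random(n) < config.shift_positive_prob, 1.0, -1.0)
    magnitude = rng.uniform(config.shift_min, config.shift_max, n)
    true_shift = np.where(is_true, sign * magnitude, 0.0)
    multiplier = np.where(
        is_true, rng.lognormal(0.0, config.abundance_multiplier_log_sd, n), 1.0
    )

    # planted complexes occupy the first proteins, disjointly
    complex_id = np.array([""] * n, dtype=object)
    complex_rows = []
    cursor = 0
    for k, pc in enumerate(config.planted_complexes, 1):
        cid = f"C{k:03d}"
        members = slice(cursor, cursor + pc.size)
        cursor += pc.size
        complex_id[members] = cid
        abundance[members] = np.maximum(abundance[members], config.complex_abundance_min)
        if pc.shared_template:
            center[members] = rng.uniform(1.0, nf) + rng.normal(
                0.0, config.complex_center_noise, pc.size
            )
            width[members] = rng.uniform(config.peak_width_min, config.peak_width_max)
        if pc.true_rnp:
            is_true[members] = True
            shared = (1.0 if rng.random() < config.shift_positive_prob else -1.0) * \
                rng.uniform(config.shift_min, config.shift_max)
            true_shift[members] = shared
            multiplier[members] = rng.lognormal(
                0.0, config.abundance_multiplier_log_sd, pc.size
            )
        else:
            is_true[members] = False
            true_shift[members] = 0.0
            multiplier[members] = 1.0
        complex_rows.append(
            {
                "complex_id": cid,
                "size": pc.size,
                "shared_template": pc.shared_template,
                "is_true_rnp": pc.true_rnp,
                "members": ";".join(ids[members]),
            }
        )

    jitter_sd = config.jitter_scale / np.sqrt(abundance)
    control = np.empty((n, nf))
    treated = np.empty((n, nf))
    for j in range(n):
        c_center = center[j] + rng.normal(0.0, jitter_sd[j])
        t_center = center[j] + true_shift[j] + rng.normal(0.0, jitter_sd[j])
        lam_c = _expected_profile(c_center, width[j], abundance[j], nf)
        lam_t = _expected_profile(
            t_center, width[j], abundance[j] * multiplier[j], nf
        )
        control[j] = _sample_counts(rng, lam_c, config.overdispersion)
        treated[j] = _sample_counts(rng, lam_t, config.overdispersion)

    fractions = [f"f{i}" for i in range(1, nf + 1)]
    cm = ElutionMatrix(
        pd.DataFrame(control, index=ids, columns=fractions), "control"
    )
    tm = ElutionMatrix(
        pd.DataFrame(treated, index=ids, columns=fractions), "treated"
    )
    truth_proteins = pd.DataFrame(
        {
            "is_rna_associated": is_true,
            "true_shift": true_shift,
            "abundance_multiplier": multiplier,
            "drawn_abundance": abundance,
            "complex_id": complex_id,
        },
        index=pd.Index(ids, name="id"),
    )
    truth_complexes = pd.DataFrame(
        complex_rows,
        columns=["complex_id", "size", "shared_template", "is_true_rnp", "members"],
    ).set_index("complex_id") if complex_rows else pd.DataFrame(
        columns=["size", "shared_template", "is_true_rnp", "members"],
        index=pd.Index([], name="complex_id"),
    )
    return cm, tm, SimTruth(truth_proteins, truth_complexes)


def truth_complex_set(truth: SimTruth):
    """Planted complexes as a :class:`~diffrac.complexes.ComplexSet`."""
    from .complexes import Complex, ComplexSet

    cs = ComplexSet()
    for cid, row in truth.complexes.iterrows():
        cs.add(Complex(cid, cid, "simulated", frozenset(row["members"].split(";"))))
    return cs


def evaluate_recovery(
    significance: pd.DataFrame,
    truth: SimTruth,
    complex_calls: pd.DataFrame | None = None,
) -> dict:
    """Confusion metrics of protein- (and optionally complex-) level calls.

    Returns realized false-discovery proportion, sensitivity and
    specificity; complex metrics use the ``is_rnp_select`` column when
    complex calls are supplied.
    """
    truth_p = truth.proteins
    if set(significance.index) != set(truth_p.index):
        raise ValueError("protein IDs of results and truth do not match")
    called = significance["significant"].reindex(truth_p.index).fillna(False)
    is_true = truth_p["is_rna_associated"]
    tp = int((called & is_true).sum())
    fp = int((called & ~is_true).sum())
    fn = int((~called & is_true).sum())
    tn = int((~called & ~is_true).sum())
    metrics = {
        "n_called": tp + fp,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "fdp": fp / (tp + fp) if tp + fp else 0.0,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
    if complex_calls is not None and len(truth.complexes):
        truth_c = truth.complexes["is_true_rnp"]
        sel = complex_calls["is_rnp_select"].reindex(truth_c.index).fillna(False)
        ctp = int((sel & truth_c).sum())
        cfp = int((sel & ~truth_c).sum())
        cfn = int((~sel & truth_c).sum())
        ctn = int((~sel & ~truth_c).sum())
        metrics.update(
            {
                "complex_tp": ctp, "complex_fp": cfp,
                "complex_fn": cfn, "complex_tn": ctn,
                "complex_sensitivity": ctp / (ctp + cfn) if ctp + cfn else float("nan"),
                "complex_specificity": ctn / (ctn + cfp) if ctn + cfp else float("nan"),
            }
        )
    return metrics


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["planted_complexes"] = [asdict(pc) for pc in config.planted_complexes]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["planted_complexes"] = [
        PlantedComplex(**pc) for pc in d.get("planted_complexes", [])
    ]
    return SimConfig(**d)
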