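"""Synthetic aCGH cohorts and the calibration experiments.

The generator emulates the standard simulation model for aCGH methods
benchmarks: each clone's log2 ratio is drawn independently from a Gaussian
with mean mu inside a planted aberration and mean 0 outside, with one
standard deviation sigma shared by all clones of a profile.  A cohort is
120 profiles of 100 clones split equally into test and control groups
(all sizes configurable).  Planted aberrations are centered in the profile
unless a start is given.

Four experiment harnesses calibrate the detection pipeline:

* window size  — correlation of section p-values across embedding dimensions;
* sensitivity/specificity — detection rate over a (mu, lambda) grid and the
  false-alarm rate on pure-null cohorts;
* section size — sensitivity/specificity as the analyzed point cloud grows;
* overlapping aberrations — both cohorts carry an aberration at the same
  location and detection is resolved by which cohort's aberration dominates.

"Detection" means: at least one section overlapping an aberrant clone is
significant after FDR (q < 0.05) and test-driven; significant sections
elsewhere count against specificity.

Randomness: every harness takes one integer seed; replicate substreams are
derived as ``default_rng([seed, cell_index, rep])`` so results are
reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profile_io import ProfileMatrix
from .sectioning import section_starts
from .stats import compare_cohort_sections

__all__ = [
    "AberrationSpec",
    "SimulationDesign",
    "ExperimentResult",
    "OverlapResult",
    "centered_aberration",
    "simulate_profile",
    "simulate_cohort",
    "analyze_simulated_cohort",
    "run_sensitivity_experiment",
    "run_null_specificity",
    "run_section_size_experiment",
    "run_dimension_experiment",
    "run_overlap_experiment",
    "classify_overlap_cell",
]

DEFAULT_SIGMA = 0.5
DEFAULT_B = 1_000
DEFAULT_Q = 0.05


@dataclass(frozen=True)
class AberrationSpec:
    """A planted aberration: mean shift ``mu`` over ``length`` clones at ``start``."""

    mu: float
    length: int
    start: int
    sigma: float | None = None  # defaults to the profile's background sigma

    def rows(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.length)


def centered_aberration(mu: float, length: int, n_clones: int,
                        sigma: float | None = None) -> AberrationSpec:
    """Aberration of ``length`` clones centered in a profile of ``n_clones``."""
    return AberrationSpec(mu=mu, length=length,
                          start=(n_clones - length) // 2, sigma=sigma)


@dataclass
class SimulationDesign:
    """A full cohort design on a single synthetic chromosome arm."""

    n_test: int = 60
    n_control: int = 60
    n_clones: int = 100
    test_aberrations: list[AberrationSpec] = field(default_factory=list)
    control_aberrations: list[AberrationSpec] = field(default_factory=list)
    sigma_background: float = DEFAULT_SIGMA
    seed: int = 0


def _validate_aberrations(aberrations: Sequence[AberrationSpec], n_clones: int) -> None:
    covered = np.zeros(n_clones, dtype=bool)
    for a in aberrations:
        if a.length < 0:
            raise ValueError("aberration length must be >= 0")
        if a.start < 0 or a.start + a.length > n_clones:
            raise ValueError(
                f"aberration [{a.start}, {a.start + a.length}) outside profile "
                f"of {n_clones} clones")
        rows = a.rows()
        if covered[rows].any():
            raise ValueError("overlapping aberrations in one profile")
        covered[rows] = True


def simulate_profile(n_clones: int, aberrations: Sequence[AberrationSpec],
                     sigma: float, rng: np.random.Generator) -> np.ndarray:
    """One profile: Normal(mu_of_covering_aberration or 0, sigma) per clone."""
    _validate_aberrations(aberrations, n_clones)
    mean = np.zeros(n_clones)
    sd = np.full(n_clones, float(sigma))
    for a in aberrations:
        mean[a.rows()] = a.mu
        if a.sigma is not None:
            sd[a.rows()] = a.sigma
    return rng.normal(mean, sd)


def simulate_cohort(design: SimulationDesign,
                    rng: np.random.Generator | None = None) -> ProfileMatrix:
    """Generate a labelled test/control cohort as a ProfileMatrix.

    Clones sit on one synthetic arm ('1q') at 1 Mb spacing; test patients
    come first.  Deterministic given the design seed (or an explicit rng).
    """
    if design.n_test < 2 or design.n_control < 2:
        raise ValueError("need at least 2 patients per group")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n = design.n_clones
    P = design.n_test + design.n_control
    values = np.empty((n, P))
    for j in range(design.n_test):
        values[:, j] = simulate_profile(n, design.test_aberrations,
                                        design.sigma_background, rng)
    for j in range(design.n_control):
        values[:, design.n_test + j] = simulate_profile(
            n, design.control_aberrations, design.sigma_background, rng)
    clones = pd.DataFrame({
        "clone_id": [f"sim{i:05d}" for i in range(n)],
        "chromosome": "1",
        "arm": "q",
        "position_bp": np.arange(n, dtype=np.int64) * 1_000_000 + 1,
    })
    patients = pd.DataFrame({
        "patient_id": ([f"t{j:03d}" for j in range(design.n_test)]
                       + [f"c{j:03d}" for j in range(design.n_control)]),
        "label": ["test"] * design.n_test + ["control"] * design.n_control,
    })
    return ProfileMatrix(clones, values, patients)


# ---------------------------------------------------------------------------
# pipeline wrapper shared by the harnesses


def analyze_simulated_cohort(values: np.ndarray, test_mask: np.ndarray,
                             section_size: int, overlap: int, D: int,
                             step: float, B: int, q_threshold: float,
                             rng) -> pd.DataFrame:
    """Section the synthetic arm and run the full comparison."""
    n_clones = values.shape[0]
    size = min(section_size, n_clones)
    sections = [np.arange(s, s + size)
                for s in section_starts(n_clones, size, min(overlap, size - 1))]
    table, _ = compare_cohort_sections(values, test_mask, sections, D=D,
                                       step=step, B=B, seed=rng,
                                       q_threshold=q_threshold)
    return table


def _detection(table: pd.DataFrame, aberrant_rows: np.ndarray) -> tuple[bool, int]:
    """(aberration detected, number of off-target significant sections)."""
    hit = False
    off = 0
    aberrant = set(int(r) for r in aberrant_rows)
    for _, row in table[table["significant"]].iterrows():
        span = set(range(int(row["first_clone"]), int(row["last_clone"]) + 1))
        if span & aberrant:
            hit = True
        else:
            off += 1
    return hit, off


@dataclass
class ExperimentResult:
    """Per-condition table plus pooled sensitivity/specificity."""

    table: pd.DataFrame
    sensitivity: float
    specificity: float


def _run_cell(mu: float, lam: int, sigma: float, reps: int, cell_index: int,
              seed: int, *, n_test: int, n_control: int, n_clones: int,
              section_size: int, overlap: int, D: int, step: float, B: int,
              q_threshold: float,
              control_aberration: AberrationSpec | None = None,
              ) -> tuple[int, int]:
    """(detections, reps with off-target significant sections) for one cell."""
    hits = 0
    false_reps = 0
    for rep in range(reps):
        rng = np.random.default_rng([seed, cell_index, rep])
        test_ab = [centered_aberration(mu, lam, n_clones)] if lam > 0 and mu != 0 else []
        ctrl_ab = [control_aberration] if control_aberration is not None else []
        design = SimulationDesign(n_test=n_test, n_control=n_control,
                                  n_clones=n_clones, test_aberrations=test_ab,
                                  control_aberrations=ctrl_ab,
                                  sigma_background=sigma)
        pm = simulate_cohort(design, rng)
        table = analyze_simulated_cohort(pm.values, pm.label_mask("test"),
                                         section_size, overlap, D, step, B,
                                         q_threshold, rng)
        aberrant = test_ab[0].rows() if test_ab else np.empty(0, dtype=int)
        hit, off = _detection(table, aberrant)
        hits += int(hit)
        false_reps += int(off > 0)
    return hits, false_reps


def run_sensitivity_experiment(mu_grid: Sequence[float] = (-1.0, 0.6, 1.0),
                               sigma: float = DEFAULT_SIGMA,
                               lambda_grid: Sequence[int] = (2, 3, 5, 10, 20, 50, 75),
                               reps: int = 20, seed: int = 0, *,
                               n_test: int = 60, n_control: int = 60,
                               n_clones: int = 100, section_size: int = 20,
                               overlap: int = 10, D: int = 2, step: float = 0.05,
                               B: int = DEFAULT_B, q_threshold: float = DEFAULT_Q,
                               ) -> ExperimentResult:
    """Detection rate over a (mu, lambda) grid with a single planted
    test-group aberration per cohort.

    Cells with ``mu == 0`` or ``lambda == 0`` are pure-null cells and
    contribute to specificity only.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    cell = 0
    for mu in mu_grid:
        for lam in lambda_grid:
            hits, false_reps = _run_cell(
                mu, lam, sigma, reps, cell, seed, n_test=n_test,
                n_control=n_control, n_clones=n_clones,
                section_size=section_size, overlap=overlap, D=D, step=step,
                B=B, q_threshold=q_threshold)
            is_null = (mu == 0) or (lam == 0)
            rows.append({"mu": mu, "lambda": lam, "reps": reps,
                         "null_cell": is_null,
                         "sensitivity": np.nan if is_null else hits / reps,
                         "false_positive_rate": false_reps / reps})
            cell += 1
    table = pd.DataFrame(rows)
    aberrant = table[~table["null_cell"]]
    sens = float(aberrant["sensitivity"].mean()) if len(aberrant) else float("nan")
    spec = float(1.0 - table["false_positive_rate"].mean())
    return ExperimentResult(table=table, sensitivity=sens, specificity=spec)


def run_null_specificity(reps: int = 20, sigma: float = DEFAULT_SIGMA,
                         seed: int = 0, **kwargs) -> ExperimentResult:
    """Fraction of pure-null cohorts with no significant section at all."""
    res = run_sensitivity_experiment(mu_grid=(0.0,), sigma=sigma,
                                     lambda_grid=(0,), reps=reps, seed=seed,
                                     **kwargs)
    return ExperimentResult(table=res.table, sensitivity=float("nan"),
                            specificity=res.specificity)


def run_section_size_experiment(sizes: Sequence[int] = (20, 50, 80, 100),
                                reps: int = 100, mu: float = 1.0,
                                sigma: float = DEFAULT_SIGMA, lam: int = 2,
                                seed: int = 0, *, n_test: int = 60,
                                n_control: int = 60, D: int = 2,
                                step: float = 0.05, B: int = DEFAULT_B,
                                q_threshold: float = DEFAULT_Q,
                                ) -> ExperimentResult:
    """Sensitivity and specificity as the single analyzed section grows.

    For each size the whole profile is one point cloud of that many points;
    the planted test-group aberration is ``lam`` clones at ``mu``.
    Specificity comes from matched null replicates with no aberration.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for k, size in enumerate(sizes):
        hits, _ = _run_cell(mu, lam, sigma, reps, 2 * k, seed,
                            n_test=n_test, n_control=n_control, n_clones=size,
                            section_size=size, overlap=0, D=D, step=step, B=B,
                            q_threshold=q_threshold)
        _, false_reps = _run_cell(0.0, 0, sigma, reps, 2 * k + 1, seed,
                                  n_test=n_test, n_control=n_control,
                                  n_clones=size, section_size=size, overlap=0,
                                  D=D, step=step, B=B, q_threshold=q_threshold)
        rows.append({"size": size, "reps": reps, "sensitivity": hits / reps,
                     "specificity": 1.0 - false_reps / reps})
    table = pd.DataFrame(rows)
    return ExperimentResult(table=table,
                            sensitivity=float(table["sensitivity"].mean()),
                            specificity=float(table["specificity"].mean()))


def run_dimension_experiment(dims: Sequence[int] = (2, 5, 10, 15, 20, 35, 50),
                             reps: int = 84,
                             lambdas: Sequence[int] = (2, 3, 5, 10, 20),
                             mus: Sequence[float] = (-1.0, 1.0, 0.6),
                             sigmas: Sequence[float] = (0.2, 0.5),
                             seed: int = 0, *, n_test: int = 60,
                             n_control: int = 60, n_clones: int = 50,
                             step: float = 0.05, B: int = DEFAULT_B,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation of section p-values across embedding window sizes.

    Each (lambda, mu, sigma) condition and replicate yields one 50-clone
    cohort (test aberration only) analyzed as a single section at every
    window size; the same cohort is reused across window sizes so the
    correlation reflects the statistic, not sampling noise.

    Returns
    -------
    (correlations, pvalues): a dims-by-dims Pearson correlation DataFrame
    and the underlying p-value table (one row per condition x rep).
    """
    dims = list(dims)
    if any(d >= n_clones or d < 2 for d in dims):
        raise ValueError("window sizes must satisfy 2 <= D < section length")
    records = []
    cell = 0
    for lam in lambdas:
        for mu in mus:
            for sg in sigmas:
                for rep in range(reps):
                    rng = np.random.default_rng([seed, cell, rep])
                    design = SimulationDesign(
                        n_test=n_test, n_control=n_control, n_clones=n_clones,
                        test_aberrations=[centered_aberration(mu, lam, n_clones)],
                        sigma_background=sg)
                    pm = simulate_cohort(design, rng)
                    rec = {"lambda": lam, "mu": mu, "sigma": sg, "rep": rep}
                    for Dv in dims:
                        # same permutation splits at every window size: the
                        # comparison is paired on both the cohort and the
                        # permutation family, isolating the statistic itself
                        perm_rng = np.random.default_rng([seed, cell, rep, 1])
                        table = analyze_simulated_cohort(
                            pm.values, pm.label_mask("test"), n_clones, 0,
                            Dv, step, B, DEFAULT_Q, perm_rng)
                        rec[f"p_D{Dv}"] = float(table["p"].iloc[0])
                    records.append(rec)
                cell += 1
    pvals = pd.DataFrame(records)
    mat = np.corrcoef(np.array([pvals[f"p_D{d}"] for d in dims]))
    corr = pd.DataFrame(mat, index=dims, columns=dims)
    return corr, pvals


# ---------------------------------------------------------------------------
# overlapping-aberration experiment


def classify_overlap_cell(mu_t: float, mu_c: float) -> str:
    """Which cohort's aberration dominates the beta0 signal.

    The beta0 statistic sees only the distance of aberrant points from the
    origin, i.e. the aberration magnitude: ``|mu_t| > |mu_c|`` makes the
    section detectable in the test group, the reverse makes it
    control-driven, and equal means (or equal magnitudes of opposite sign)
    give neither cohort an edge.
    """
    if abs(mu_t) > abs(mu_c):
        return "test_dominant"
    if abs(mu_t) < abs(mu_c):
        return "control_dominant"
    return "equal_mean" if mu_t == mu_c else "equal_magnitude"


@dataclass
class OverlapResult:
    table: pd.DataFrame
    pooled: dict[str, float]


def run_overlap_experiment(mu_values: Sequence[float] = (0.6, 1.0, -1.0),
                           lambda_values: Sequence[int] = (5, 10, 15),
                           reps: int = 30, seed: int = 0, *,
                           cells: Sequence[tuple[float, float, int, int]] | None = None,
                           sigma: float = DEFAULT_SIGMA, n_test: int = 60,
                           n_control: int = 60, n_clones: int = 100,
                           section_size: int = 20, overlap: int = 10,
                           D: int = 2, step: float = 0.05, B: int = DEFAULT_B,
                           q_threshold: float = DEFAULT_Q) -> OverlapResult:
    """Detection when test AND control carry an aberration at the same spot.

    Cells are all ordered pairs (mu_t, mu_c) x (lambda_t, lambda_c) unless an
    explicit cell list is given.  Both aberrations are centered at the
    profile midpoint.  Pooled sensitivities are reported per dominance class
    (see :func:`classify_overlap_cell`) and additionally for the
    equal-mean cells whose test aberration has medium length, i.e. strictly
    between 25% and 75% of the section size.
    """
    if cells is None:
        cells = [(mt, mc, lt, lc)
                 for mt in mu_values for mc in mu_values
                 for lt in lambda_values for lc in lambda_values]
    rows = []
    for ci, (mu_t, mu_c, lam_t, lam_c) in enumerate(cells):
        ctrl = centered_aberration(mu_c, lam_c, n_clones)
        hits, _ = _run_cell(mu_t, lam_t, sigma, reps, ci, seed,
                            n_test=n_test, n_control=n_control,
                            n_clones=n_clones, section_size=section_size,
                            overlap=overlap, D=D, step=step, B=B,
                            q_threshold=q_threshold, control_aberration=ctrl)
        rows.append({"mu_t": mu_t, "mu_c": mu_c, "lambda_t": lam_t,
                     "lambda_c": lam_c, "reps": reps,
                     "class": classify_overlap_cell(mu_t, mu_c),
                     "sensitivity": hits / reps})
    table = pd.DataFrame(rows)
    pooled = {}
    for cls, sub in table.groupby("class"):
        pooled[cls] = float(sub["sensitivity"].mean())
    lo, hi = 0.25 * section_size, 0.75 * section_size
    medium = table[(table["class"] == "equal_mean")
                   & (table["lambda_t"] > lo) & (table["lambda_t"] < hi)]
    if len(medium):
        pooled["equal_mean_medium_lambda"] = float(medium["sensitivity"].mean())
    return OverlapResult(table=table, pooled=pooled)
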