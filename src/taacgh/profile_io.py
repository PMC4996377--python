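"""Reading, harmonizing and imputing aCGH profile matrices.

Inputs are plain TSV files: a log2-ratio matrix (rows = clones, columns =
patients, first column ``clone_id``), a clone map (``clone_id``,
``chromosome``, ``arm``, ``position_bp``), a patient label file
(``patient_id``, ``subtype``) and optionally a BED-like arm-boundary table
(``chromosome``, ``start``, ``end``, ``arm``; 0-based half-open).

Harmonization reconciles clone positions against a user-supplied reference
map with four removal rules (no reference position; chromosome mismatch;
reference position further than a distance threshold from the reported one;
relative order inconsistent with the immediate surviving neighbors), after
which clones mapped to identical positions are averaged and remaining
missing values are imputed by lowess smoothing of each patient's profile
along each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

__all__ = [
    "CloneRecord",
    "ProfileMatrix",
    "PreprocessReport",
    "read_profile_matrix",
    "read_arm_boundaries",
    "assign_arms",
    "harmonize_clone_map",
    "average_duplicate_positions",
    "impute_missing_lowess",
    "preprocess",
    "normalize_chromosome",
    "chromosome_sort_key",
]

DEFAULT_MAX_DISTANCE_BP = 5_000_000  # reference vs reported position tolerance
DEFAULT_LOWESS_SPAN = 0.3
DEFAULT_NA_VALUES = ("", "NA")

CLONE_COLUMNS = ["clone_id", "chromosome", "arm", "position_bp"]


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    chromosome: str
    arm: str
    position_bp: int


@dataclass
class PreprocessReport:
    """Tally of clones touched by each preprocessing rule."""

    n_input: int = 0
    n_updated: int = 0
    n_removed_no_position: int = 0
    n_removed_chrom_mismatch: int = 0
    n_removed_far: int = 0
    n_removed_order_inconsistent: int = 0
    n_duplicates_averaged: int = 0
    n_imputed: int = 0

    @property
    def n_removed(self) -> int:
        return (self.n_removed_no_position + self.n_removed_chrom_mismatch
                + self.n_removed_far + self.n_removed_order_inconsistent)

    def as_dict(self) -> dict:
        return asdict(self)


def normalize_chromosome(chrom: str) -> str:
    """Normalize chromosome naming to the un-prefixed dialect ('chr17' -> '17')."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    c = normalize_chromosome(chrom)
    if c.isdigit():
        return (int(c), "")
    order = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return (order.get(c.upper(), 26), c)


@dataclass
class ProfileMatrix:
    """Clones-by-patients log2-ratio matrix with genome annotation.

    Attributes
    ----------
    clones
        DataFrame with columns ``clone_id, chromosome, arm, position_bp``,
        sorted by (chromosome, position).
    values
        ``(n_clones, n_patients)`` float array; NaN marks missing entries
        before imputation.
    patients
        DataFrame with columns ``patient_id, label``.
    """

    clones: pd.DataFrame
    values: np.ndarray
    patients: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.clones), len(self.patients)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.clones)} clones x {len(self.patients)} patients")

    # -- basic accessors -----------------------------------------------------

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    def patient_index(self, patient_id: str) -> int:
        ids = self.patient_ids
        try:
            return ids.index(patient_id)
        except ValueError:
            raise KeyError(f"unknown patient {patient_id!r}") from None

    def label_mask(self, label: str) -> np.ndarray:
        return (self.patients["label"] == label).to_numpy()

    def arm_name(self) -> pd.Series:
        return self.clones["chromosome"].astype(str) + self.clones["arm"].astype(str)

    def arms(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.arm_name():
            seen.setdefault(a, None)
        return list(seen)

    def arm_indices(self, arm: str) -> np.ndarray:
        return np.flatnonzero((self.arm_name() == arm).to_numpy())

    def copy(self) -> "ProfileMatrix":
        return ProfileMatrix(self.clones.reset_index(drop=True).copy(),
                             self.values.copy(), self.patients.copy())

    def select_patients(self, keep: np.ndarray) -> "ProfileMatrix":
        keep = np.asarray(keep)
        return ProfileMatrix(self.clones.reset_index(drop=True).copy(),
                             self.values[:, keep],
                             self.patients.iloc[keep].reset_index(drop=True))

    def sorted_by_position(self) -> "ProfileMatrix":
        key = self.clones["chromosome"].map(chromosome_sort_key)
        order = (pd.DataFrame({"k": key, "pos": self.clones["position_bp"]})
                 .sort_values(["k", "pos"], kind="stable").index.to_numpy())
        return ProfileMatrix(self.clones.iloc[order].reset_index(drop=True),
                             self.values[order], self.patients.copy())


# ---------------------------------------------------------------------------
# readers


def read_profile_matrix(matrix_path, clone_map_path, labels_path,
                        na_values: Sequence[str] = DEFAULT_NA_VALUES) -> ProfileMatrix:
    """Read matrix, clone map and labels into a position-sorted ProfileMatrix.

    Raises
    ------
    FileNotFoundError, ValueError
        Missing files; matrix columns not covered by the label file; clones
        with no clone-map entry (reported with identities and count).
    """
    for p in (matrix_path, clone_map_path, labels_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    mat = pd.read_csv(matrix_path, sep="\t", dtype={0: str},
                      na_values=list(na_values), keep_default_na=False)
    mat = mat.rename(columns={mat.columns[0]: "clone_id"})
    cmap = pd.read_csv(clone_map_path, sep="\t", dtype={"clone_id": str})
    missing_cols = [c for c in CLONE_COLUMNS if c not in cmap.columns]
    if missing_cols:
        raise ValueError(f"clone map lacks columns {missing_cols}")
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if not {"patient_id", "subtype"} <= set(labels.columns):
        raise ValueError("labels file must have columns patient_id, subtype")

    patient_cols = [c for c in mat.columns if c != "clone_id"]
    label_map = dict(zip(labels["patient_id"], labels["subtype"]))
    unlabeled = [c for c in patient_cols if c not in label_map]
    if unlabeled:
        raise ValueError(f"matrix patients missing from labels file: {unlabeled}")

    cmap = cmap.copy()
    cmap["chromosome"] = cmap["chromosome"].map(normalize_chromosome)
    map_idx = cmap.set_index("clone_id")
    unmapped = [cid for cid in mat["clone_id"] if cid not in map_idx.index]
    if unmapped:
        raise ValueError(
            f"{len(unmapped)} matrix clones have no clone-map entry: "
            f"{unmapped[:10]}{'...' if len(unmapped) > 10 else ''}")

    ann = map_idx.loc[mat["clone_id"], CLONE_COLUMNS[1:]].reset_index()
    clones = ann[CLONE_COLUMNS].copy()
    clones["position_bp"] = clones["position_bp"].astype(np.int64)
    values = mat[patient_cols].to_numpy(dtype=float)
    patients = pd.DataFrame({"patient_id": patient_cols,
                             "label": [label_map[c] for c in patient_cols]})
    return ProfileMatrix(clones, values, patients).sorted_by_position()


def read_arm_boundaries(path) -> pd.DataFrame:
    """BED-like arm boundary table: chromosome, start, end, arm (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chromosome", "start", "end", "arm"], dtype={0: str})
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    return df


def assign_arms(pm: ProfileMatrix, boundaries: pd.DataFrame) -> ProfileMatrix:
    """Overwrite clone arm labels from an arm-boundary table."""
    pm = pm.copy()
    arms = pm.clones["arm"].astype(str).to_numpy(dtype=object)
    chrom = pm.clones["chromosome"].map(normalize_chromosome)
    pos = pm.clones["position_bp"].to_numpy()
    for _, row in boundaries.iterrows():
        inside = ((chrom == row["chromosome"]).to_numpy()
                  & (pos >= int(row["start"])) & (pos < int(row["end"])))
        arms[inside] = str(row["arm"])
    pm.clones["arm"] = arms
    return pm


# ---------------------------------------------------------------------------
# harmonization


def harmonize_clone_map(pm: ProfileMatrix, reference: Iterable[CloneRecord] | pd.DataFrame,
                        max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
                        ) -> tuple[ProfileMatrix, PreprocessReport]:
    """Reconcile clone positions against a reference map.

    Removal rules, applied in order: (1) clone absent from the reference;
    (2) reference chromosome differs from the reported one; (3) reference
    position further than ``max_distance_bp`` from the reported position;
    (4) after surviving clones take their reference position, a single
    left-to-right pass per chromosome removes clones whose updated position
    falls below the last kept neighbor or above the next surviving one
    (ties allowed, so co-located clones survive for later averaging).
    Applying the same harmonization twice is a no-op.
    """
    if max_distance_bp <= 0:
        raise ValueError("max_distance_bp must be positive")
    if isinstance(reference, pd.DataFrame):
        ref_df = reference
    else:
        ref_df = pd.DataFrame([asdict(r) for r in reference])
    if ref_df.empty:
        raise ValueError("empty reference map")
    ref_df = ref_df.copy()
    ref_df["chromosome"] = ref_df["chromosome"].map(normalize_chromosome)
    ref = {r.clone_id: r for r in ref_df.itertuples()}

    report = PreprocessReport(n_input=pm.n_clones)
    clones = pm.clones.reset_index(drop=True)
    chrom = clones["chromosome"].map(normalize_chromosome)

    state = np.zeros(pm.n_clones, dtype=int)  # 0 keep, >0 removal rule id
    new_pos = clones["position_bp"].to_numpy().copy()
    new_arm = clones["arm"].astype(str).to_numpy(dtype=object)
    for i, cid in enumerate(clones["clone_id"]):
        r = ref.get(cid)
        if r is None or pd.isna(r.position_bp):
            state[i] = 1
            report.n_removed_no_position += 1
        elif normalize_chromosome(r.chromosome) != chrom.iloc[i]:
            state[i] = 2
            report.n_removed_chrom_mismatch += 1
        elif abs(int(r.position_bp) - int(new_pos[i])) > max_distance_bp:
            state[i] = 3
            report.n_removed_far += 1
        else:
            if int(r.position_bp) != int(new_pos[i]):
                report.n_updated += 1
            new_pos[i] = int(r.position_bp)
            if isinstance(r.arm, str) and r.arm:
                new_arm[i] = r.arm

    # rule 4: order consistency among rule-1..3 survivors, per chromosome
    for c in chrom.unique():
        surv = [i for i in np.flatnonzero((chrom == c).to_numpy()) if state[i] == 0]
        last_kept: int | None = None
        for k, i in enumerate(surv):
            nxt = surv[k + 1] if k + 1 < len(surv) else None
            lo_bad = last_kept is not None and new_pos[i] < new_pos[last_kept]
            hi_bad = nxt is not None and new_pos[i] > new_pos[nxt]
            if lo_bad or hi_bad:
                state[i] = 4
                report.n_removed_order_inconsistent += 1
            else:
                last_kept = i

    keep = state == 0
    clones = clones.loc[keep].copy()
    clones["position_bp"] = new_pos[keep]
    clones["arm"] = new_arm[keep]
    out = ProfileMatrix(clones.reset_index(drop=True), pm.values[keep],
                        pm.patients.copy()).sorted_by_position()
    return out, report


def average_duplicate_positions(pm: ProfileMatrix) -> ProfileMatrix:
    """Merge clones sharing (chromosome, position) by per-patient mean.

    Missing entries are ignored in the mean; a group that is missing for a
    patient everywhere stays missing.  The first clone id of each group is
    retained and genome order is preserved.
    """
    clones = pm.clones.reset_index(drop=True)
    key = list(zip(clones["chromosome"], clones["position_bp"]))
    first_row: dict = {}
    groups: dict = {}
    for i, k in enumerate(key):
        groups.setdefault(k, []).append(i)
        first_row.setdefault(k, i)
    if all(len(g) == 1 for g in groups.values()):
        return pm.copy()
    keep_rows = sorted(first_row.values())
    values = np.empty((len(keep_rows), pm.n_patients))
    for r, i in enumerate(keep_rows):
        g = groups[key[i]]
        block = pm.values[g]
        counts = (~np.isnan(block)).sum(axis=0)
        sums = np.nansum(block, axis=0)
        # groups with no observed entry for a patient stay missing
        values[r] = np.divide(sums, counts, out=np.full(block.shape[1], np.nan),
                              where=counts > 0)
    return ProfileMatrix(clones.iloc[keep_rows].reset_index(drop=True),
                         values, pm.patients.copy())


# ---------------------------------------------------------------------------
# imputation


def impute_missing_lowess(pm: ProfileMatrix, span: float = DEFAULT_LOWESS_SPAN,
                          ) -> tuple[ProfileMatrix, PreprocessReport]:
    """Impute missing entries by per-patient, per-chromosome lowess.

    For each patient and chromosome, a lowess smooth of the observed log2
    ratios against base-pair position is evaluated at the missing clones'
    positions.  Non-missing entries are never touched.

    Raises
    ------
    ValueError
        When a (chromosome, patient) stratum holds fewer than 3 observed
        values (named in the message), or span is outside (0, 1].
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    report = PreprocessReport(n_input=pm.n_clones)
    values = pm.values.copy()
    chrom = pm.clones["chromosome"].to_numpy()
    pos = pm.clones["position_bp"].to_numpy(dtype=float)
    for c in pd.unique(chrom):
        rows = np.flatnonzero(chrom == c)
        x = pos[rows]
        for j, pid in enumerate(pm.patient_ids):
            y = values[rows, j]
            miss = np.isnan(y)
            if not miss.any():
                continue
            obs = ~miss
            if obs.sum() < 3:
                raise ValueError(
                    f"chromosome {c}, patient {pid}: only {int(obs.sum())} "
                    "observed values; need >= 3 for lowess imputation")
            # it=0: plain local linear regression; robustness reweighting is
            # undefined at out-of-sample abscissae and would yield NaN.
            # The window is floored at 3 observed points so small strata
            # still define a local fit.
            frac = min(1.0, max(span, 3.0 / int(obs.sum())))
            fitted = _lowess(y[obs], x[obs], frac=frac, xvals=x[miss], it=0)
            values[rows[miss], j] = np.atleast_1d(fitted)
            report.n_imputed += int(miss.sum())
    return ProfileMatrix(pm.clones.reset_index(drop=True).copy(), values,
                         pm.patients.copy()), report


def preprocess(pm: ProfileMatrix, reference=None,
               max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
               span: float = DEFAULT_LOWESS_SPAN,
               ) -> tuple[ProfileMatrix, PreprocessReport]:
    """Harmonize (optional), average duplicates and impute, in that order."""
    report = PreprocessReport(n_input=pm.n_clones)
    if reference is not None:
        pm, h = harmonize_clone_map(pm, reference, max_distance_bp)
        for f in ("n_updated", "n_removed_no_position", "n_removed_chrom_mismatch",
                  "n_removed_far", "n_removed_order_inconsistent"):
            setattr(report, f, getattr(h, f))
    before = pm.n_clones
    pm = average_duplicate_positions(pm)
    report.n_duplicates_averaged = before - pm.n_clones
    if np.isnan(pm.values).any():
        pm, imp = impute_missing_lowess(pm, span)
        report.n_imputed = imp.n_imputed
    return pm, report
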