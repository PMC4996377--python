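"""Cohort comparison statistics for beta0 curves.

Test and control cohorts are compared section by section.  For each section
the per-patient beta0 curves are averaged within cohort, truncated at K (the
first filtration value where both mean curves equal 1), and summarized by

    S_exp = sum_{k=0..K} (t_k - c_k)^2

where ``t`` and ``c`` are the mean test and control curves.  Significance is
assessed by permuting cohort labels: per-patient curves are computed once
and only re-averaged under each shuffle.  p-values across sections are
corrected by Benjamini-Hochberg FDR, and sections whose signal is driven by
the control cohort (control curve above the test curve on the truncated
grid) are excluded from the significant list regardless of p, since they
describe the control population rather than the test one.

Clone-level gain/loss calls and the whole-arm center-of-mass test use the
same permutation machinery on per-clone and per-arm mean log ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .embedding import EmbeddingConfig, embed_cohort
from .homology import (
    BettiCurve,
    FiltrationGrid,
    grid_for_max_distance,
    pairwise_distances,
    _uf_merge_heights,
    curves_from_heights,
    DEFAULT_GRID_STEP,
)

__all__ = [
    "CurveComparison",
    "CloneTestResult",
    "ArmCOMResult",
    "mean_curve",
    "truncation_K",
    "s_exp",
    "dominance_filter",
    "fdr_adjust",
    "permutation_test",
    "compare_cohort_sections",
    "clone_level_test",
    "com_arm_test",
]

TEST_DRIVEN = "test-driven"
CONTROL_DRIVEN = "control-driven"


# ---------------------------------------------------------------------------
# elementary statistics


@dataclass
class CurveComparison:
    """Comparison summary for one section."""

    t: np.ndarray
    c: np.ndarray
    K: int
    s_exp: float
    p: float
    q: float
    direction: str


@dataclass
class CloneTestResult:
    """Per-clone permutation test of the group mean difference."""

    clone_id: str
    chromosome: str
    arm: str
    position_bp: int
    mean_test: float
    mean_control: float
    p: float
    call: str  # gain | loss | not-significant


@dataclass
class ArmCOMResult:
    """Whole-arm center-of-mass displacement test."""

    arm: str
    mean_com_test: float
    mean_com_control: float
    p_diff: float
    p_origin: float
    significant: bool


def _as_test_mask(labels: Sequence, n: int | None = None) -> np.ndarray:
    mask = np.asarray(labels)
    if mask.dtype != bool:
        raise TypeError("labels must be a boolean mask (True = test cohort)")
    if n is not None and mask.size != n:
        raise ValueError(f"labels length {mask.size} != number of patients {n}")
    if mask.all() or not mask.any():
        raise ValueError("both cohorts must be non-empty")
    return mask


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mean_curve(curves) -> np.ndarray:
    """Element-wise mean of beta0 curves sharing one grid."""
    if isinstance(curves, np.ndarray):
        if curves.ndim != 2 or curves.shape[0] == 0:
            raise ValueError("need a non-empty (n_curves, n_eps) array")
        return curves.mean(axis=0)
    curves = list(curves)
    if not curves:
        raise ValueError("empty curve collection")
    if isinstance(curves[0], BettiCurve):
        grid0 = curves[0].grid
        for cv in curves[1:]:
            if not np.array_equal(cv.grid.epsilons, grid0.epsilons):
                raise ValueError("curves must share one filtration grid")
        return np.mean([cv.beta0 for cv in curves], axis=0)
    return np.mean([np.asarray(cv, dtype=float) for cv in curves], axis=0)


def truncation_K(t: np.ndarray, c: np.ndarray) -> int:
    """Smallest grid index where both mean curves equal exactly 1.

    Means of integer curves hit 1.0 exactly only when every patient curve is
    at 1, so exact comparison is well defined.  If the curves never jointly
    reach 1 on the grid, the last index is returned.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.shape != c.shape:
        raise ValueError("curves must share one grid")
    both = (t == 1.0) & (c == 1.0)
    if both.any():
        return int(np.argmax(both))
    return t.size - 1


def s_exp(t: np.ndarray, c: np.ndarray, K: int) -> float:
    """Sum of squared mean-curve differences over grid indices 0..K."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if not 0 <= K < t.size:
        raise ValueError(f"K={K} outside grid of length {t.size}")
    d = t[: K + 1] - c[: K + 1]
    return float(d @ d)


def dominance_filter(t: np.ndarray, c: np.ndarray, K: int) -> str:
    """Classify a section as test- or control-driven.

    The signed sum of (t - c) over the truncated grid decides which cohort
    carries the larger beta0 signal; a negative sum means the control curve
    dominates and the section reflects control-population aberrations.
    Ties count as test-driven (moot, since then S_exp = 0).
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    signed = float(np.sum(t[: K + 1] - c[: K + 1]))
    return CONTROL_DRIVEN if signed < 0 else TEST_DRIVEN


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation machinery


def _observed_stats(curves: np.ndarray, mask: np.ndarray):
    t = curves[mask].mean(axis=0)
    c = curves[~mask].mean(axis=0)
    K = truncation_K(t, c)
    return t, c, K, s_exp(t, c, K)


def _split_stat(curves: np.ndarray, masks: np.ndarray, nt: int, nc: int):
    """S_exp (with per-split K) for many label splits at once.

    curves : (P, G) float; masks : (B, P) bool. Returns (B,) array of S.
    """
    mf = masks.astype(float)
    t = (mf @ curves) / nt
    c = ((1.0 - mf) @ curves) / nc
    both = (t == 1.0) & (c == 1.0)
    G = curves.shape[1]
    K = np.where(both.any(axis=1), both.argmax(axis=1), G - 1)
    csum = np.cumsum((t - c) ** 2, axis=1)
    return np.take_along_axis(csum, K[:, None], axis=1)[:, 0]


def permutation_test(per_patient_curves: np.ndarray, labels, B: int = 10_000,
                     seed=None, exhaustive: bool = False) -> tuple[float, float]:
    """Permutation test of S_exp = 0 for one section.

    Parameters
    ----------
    per_patient_curves
        ``(n_patients, n_eps)`` beta0 values on a shared grid.
    labels
        Boolean mask, True for the test cohort.
    B
        Number of random label shuffles (ignored when ``exhaustive``).
    exhaustive
        Enumerate every split of the patients into groups of the observed
        sizes; the p-value is then the exact fraction of splits with
        ``S >= S_obs`` (the identity split included).  Random sampling uses
        the add-one estimator ``(1 + #{S_perm >= S_obs}) / (B + 1)`` instead,
        which can never return 0.

    Returns
    -------
    (S_obs, p)
    """
    curves = np.asarray(per_patient_curves, dtype=float)
    mask = _as_test_mask(labels, curves.shape[0])
    nt = int(mask.sum())
    nc = curves.shape[0] - nt
    if nt < 2 or nc < 2:
        raise ValueError("need at least 2 patients per cohort")
    _, _, _, S_obs = _observed_stats(curves, mask)

    if exhaustive:
        P = curves.shape[0]
        splits = list(combinations(range(P), nt))
        masks = np.zeros((len(splits), P), dtype=bool)
        for i, comb in enumerate(splits):
            masks[i, list(comb)] = True
        S = _split_stat(curves, masks, nt, nc)
        p = float((S >= S_obs).sum() / len(splits))
        return S_obs, p

    if B < 1:
        raise ValueError("B must be >= 1")
    rng = _rng(seed)
    masks = _permute_masks(mask, B, rng)
    S = _split_stat(curves, masks, nt, nc)
    p = float((1 + (S >= S_obs).sum()) / (B + 1))
    return S_obs, p


def _permute_masks(mask: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    order = np.argsort(rng.random((B, mask.size)), axis=1)
    return mask[order]


# ---------------------------------------------------------------------------
# cohort-level engine


def compare_cohort_sections(values: np.ndarray, labels, sections, *, D: int = 2,
                            step: float = DEFAULT_GRID_STEP, B: int = 1_000,
                            seed=None, q_threshold: float = 0.05,
                            ) -> tuple[pd.DataFrame, FiltrationGrid]:
    """Run the full section comparison for one cohort matrix.

    Embeds every section for every patient, computes beta0 curves on one
    shared grid covering the largest pairwise distance of any cloud, runs a
    label-permutation test per section (one permutation set shared across
    sections so the heavy averaging is a single matrix product), applies the
    dominance filter, and BH-adjusts the p-values as a single family.

    Parameters
    ----------
    values
        ``(n_clones, n_patients)`` imputed log2 ratios.
    labels
        Boolean test-cohort mask over patients.
    sections
        Sequence of :class:`~taacgh.sectioning.Section` or plain index
        arrays (rows of ``values``).

    Returns
    -------
    (table, grid) where ``table`` has one row per section with columns
    ``K, s_exp, p, q, direction, significant`` (plus section metadata when
    Section objects were given).
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("values contain missing entries; impute first")
    mask = _as_test_mask(labels, values.shape[1])
    nt = int(mask.sum())
    nc = mask.size - nt
    if nt < 2 or nc < 2:
        raise ValueError("need at least 2 patients per cohort")
    idx_list = [np.asarray(getattr(s, "clone_indices", s), dtype=int) for s in sections]
    if not idx_list:
        raise ValueError("empty section list")
    rng = _rng(seed)

    # --- beta0 curves per (section, patient), grouped by section length
    heights_by_section: dict[int, np.ndarray] = {}
    m_by_section: dict[int, int] = {}
    max_dist = 0.0
    by_m: dict[int, list[int]] = {}
    for si, idx in enumerate(idx_list):
        by_m.setdefault(len(idx), []).append(si)
    for m, sids in by_m.items():
        if m <= D:
            raise ValueError(f"section of length {m} cannot be embedded at D={D}")
        clouds = np.concatenate(
            [embed_cohort(values[idx_list[si]], D) for si in sids], axis=0
        )  # (len(sids)*P, m, D)
        dist = pairwise_distances(clouds)
        max_dist = max(max_dist, float(dist.max(initial=0.0)))
        order = np.argsort(dist, axis=1)
        ii, jj = np.triu_indices(m, 1)
        hts = np.empty((clouds.shape[0], m - 1))
        _uf_merge_heights(dist, order, ii.astype(np.int64), jj.astype(np.int64), m, hts)
        P = mask.size
        for gi, si in enumerate(sids):
            heights_by_section[si] = hts[gi * P:(gi + 1) * P]
            m_by_section[si] = m

    grid = grid_for_max_distance(max_dist, step)
    G = len(grid)
    S_n = len(idx_list)
    curves = np.empty((S_n, mask.size, G))
    for si in range(S_n):
        curves[si] = curves_from_heights(
            heights_by_section[si], m_by_section[si], grid
        ).astype(float)

    # --- observed statistics
    t_obs = curves[:, mask].mean(axis=1)
    c_obs = curves[:, ~mask].mean(axis=1)
    K_obs = np.empty(S_n, dtype=int)
    S_obs = np.empty(S_n)
    direction = []
    for si in range(S_n):
        K_obs[si] = truncation_K(t_obs[si], c_obs[si])
        S_obs[si] = s_exp(t_obs[si], c_obs[si], int(K_obs[si]))
        direction.append(dominance_filter(t_obs[si], c_obs[si], int(K_obs[si])))

    # --- one permutation family shared across sections
    masks = _permute_masks(mask, B, rng).astype(float)
    flat = curves.transpose(1, 0, 2).reshape(mask.size, S_n * G)
    T = (masks @ flat) / nt
    C = ((1.0 - masks) @ flat) / nc
    T = T.reshape(B, S_n, G)
    C = C.reshape(B, S_n, G)
    both = (T == 1.0) & (C == 1.0)
    Kp = np.where(both.any(axis=2), both.argmax(axis=2), G - 1)
    csum = np.cumsum((T - C) ** 2, axis=2)
    Sp = np.take_along_axis(csum, Kp[..., None], axis=2)[..., 0]  # (B, S_n)
    p = (1 + (Sp >= S_obs[None, :]).sum(axis=0)) / (B + 1)

    q = fdr_adjust(p)
    significant = (q < q_threshold) & (np.array(direction) == TEST_DRIVEN)

    table = pd.DataFrame({
        "section": np.arange(S_n),
        "m": [m_by_section[si] for si in range(S_n)],
        "K": K_obs,
        "s_exp": S_obs,
        "p": p,
        "q": q,
        "direction": direction,
        "significant": significant,
    })
    arms, starts, ends = [], [], []
    for s, idx in zip(sections, idx_list):
        arms.append(getattr(s, "arm", ""))
        starts.append(int(idx[0]))
        ends.append(int(idx[-1]))
    table.insert(1, "arm", arms)
    table.insert(2, "first_clone", starts)
    table.insert(3, "last_clone", ends)
    return table, grid


# ---------------------------------------------------------------------------
# clone-level and whole-arm tests


def _two_sided_perm_p(x: np.ndarray, mask: np.ndarray, B: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p for the group mean difference, per column.

    x : (n_items, P) values; returns (diff_obs, p) per item.
    """
    nt = int(mask.sum())
    nc = mask.size - nt
    diff_obs = x[:, mask].mean(axis=1) - x[:, ~mask].mean(axis=1)
    mf = _permute_masks(mask, B, rng).astype(float)
    tm = (mf @ x.T) / nt
    cm = ((1.0 - mf) @ x.T) / nc
    exceed = (np.abs(tm - cm) >= np.abs(diff_obs)[None, :]).sum(axis=0)
    p = (1 + exceed) / (B + 1)
    return diff_obs, p


def clone_level_test(pm, section, labels, B: int = 10_000, alpha: float = 0.05,
                     seed=None) -> list[CloneTestResult]:
    """Gain/loss calls for each clone of a (significant) section.

    Two-sided permutation test of the per-clone group mean difference.
    Clones with p < alpha are called ``gain`` when the test mean exceeds the
    control mean and ``loss`` otherwise.  p-values are not corrected within
    the section.  A section whose every clone stays non-significant should
    be reported as undetermined by the caller.
    """
    mask = _as_test_mask(labels, pm.n_patients)
    if int(mask.sum()) < 2 or int((~mask).sum()) < 2:
        raise ValueError("need at least 2 patients per cohort")
    idx = np.asarray(getattr(section, "clone_indices", section), dtype=int)
    x = np.asarray(pm.values, dtype=float)[idx]
    if np.isnan(x).any():
        raise ValueError("section contains missing values; impute first")
    rng = _rng(seed)
    diff, p = _two_sided_perm_p(x, mask, B, rng)
    mt = x[:, mask].mean(axis=1)
    mc = x[:, ~mask].mean(axis=1)
    out = []
    rows = pm.clones.iloc[idx]
    for k, (_, row) in enumerate(rows.iterrows()):
        if p[k] < alpha:
            call = "gain" if diff[k] > 0 else "loss"
        else:
            call = "not-significant"
        out.append(CloneTestResult(
            clone_id=str(row["clone_id"]), chromosome=str(row["chromosome"]),
            arm=str(row["arm"]), position_bp=int(row["position_bp"]),
            mean_test=float(mt[k]), mean_control=float(mc[k]),
            p=float(p[k]), call=call,
        ))
    return out


def com_arm_test(pm, arm: str, labels, cfg: EmbeddingConfig | int = 2,
                 B: int = 10_000, alpha: float = 0.05, seed=None,
                 summary: str = "mean") -> ArmCOMResult:
    """Whole-arm aberration test via center-of-mass displacement.

    Under the cyclic embedding every coordinate of a cloud's center of mass
    equals the arm's mean log ratio, so the per-patient summary reduces to
    the arm mean (``summary='mean'``) or its norm ``|mean| * sqrt(D)``
    (``summary='norm'``).  Two permutation tests guard the call: ``p_diff``
    compares the cohorts, ``p_origin`` (sign randomization of the signed
    test-cohort arm means) checks that the test cohort itself is displaced
    from the origin, dropping arms whose displacement is control-driven.
    """
    D = cfg.D if isinstance(cfg, EmbeddingConfig) else int(cfg)
    mask = _as_test_mask(labels, pm.n_patients)
    idx = pm.arm_indices(arm)
    if idx.size <= D:
        raise ValueError(f"arm {arm!r} has {idx.size} clones; need more than D={D}")
    x = np.asarray(pm.values, dtype=float)[idx]
    if np.isnan(x).any():
        raise ValueError("arm contains missing values; impute first")
    arm_means = x.mean(axis=0)  # per patient; == each COM coordinate
    if summary == "mean":
        s = arm_means
    elif summary == "norm":
        s = np.abs(arm_means) * np.sqrt(D)
    else:
        raise ValueError("summary must be 'mean' or 'norm'")
    rng = _rng(seed)
    _, p_diff = _two_sided_perm_p(s[None, :], mask, B, rng)
    xt = arm_means[mask]
    obs = abs(xt.mean())
    signs = rng.choice([-1.0, 1.0], size=(B, xt.size))
    flipped = np.abs(signs @ xt) / xt.size
    p_origin = float((1 + (flipped >= obs).sum()) / (B + 1))
    return ArmCOMResult(
        arm=arm,
        mean_com_test=float(s[mask].mean()),
        mean_com_control=float(s[~mask].mean()),
        p_diff=float(p_diff[0]),
        p_origin=p_origin,
        significant=bool(p_diff[0] < alpha and p_origin < alpha),
    )
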