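"""End-to-end subtype analysis and experiment dispatch.

``run_subtype_analysis`` composes the whole method: read and preprocess the
profile matrix, section each arm, embed and compute beta0 curves per
patient, compare cohorts by permutation with FDR and the dominance filter,
call significant clones within significant sections, and test whole-arm
displacements of the point-cloud centers of mass.  One subtype is the test
cohort; the remaining subtypes (minus any excluded) are the control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import profile_io, sectioning, simulate
from .profile_io import PreprocessReport, ProfileMatrix
from .stats import clone_level_test, com_arm_test, compare_cohort_sections

__all__ = ["RunConfig", "ResultTable", "run_subtype_analysis",
           "write_results", "run_experiments", "EXPERIMENTS"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one subtype analysis run."""

    matrix_path: str = ""
    clone_map_path: str = ""
    labels_path: str = ""
    arm_boundaries_path: str | None = None
    reference_map_path: str | None = None
    test_label: str = ""
    excluded_control_labels: list[str] = field(default_factory=list)
    excluded_patients: list[str] = field(default_factory=list)
    D: int = 2
    section_size: int = 20
    overlap: int = 10
    step: float = 0.05
    B: int = 10_000
    alpha: float = 0.05          # clone-level and arm-level threshold
    q_threshold: float = 0.05    # section-level FDR threshold
    lowess_span: float = 0.3
    max_distance_bp: int = 5_000_000
    com_summary: str = "mean"
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.test_label:
            raise ValueError("test_label is required")
        if self.test_label in self.excluded_control_labels:
            raise ValueError("test_label cannot be excluded from the control set")


@dataclass
class ResultTable:
    """All tables produced by one run."""

    sections: pd.DataFrame
    clones: pd.DataFrame
    arms: pd.DataFrame
    metadata: dict
    report: PreprocessReport | None = None


def _prepare_matrix(cfg: RunConfig) -> tuple[ProfileMatrix, PreprocessReport]:
    pm = profile_io.read_profile_matrix(cfg.matrix_path, cfg.clone_map_path,
                                        cfg.labels_path)
    reference = None
    if cfg.reference_map_path:
        ref_df = pd.read_csv(cfg.reference_map_path, sep="\t",
                             dtype={"clone_id": str})
        reference = ref_df
    pm, report = profile_io.preprocess(pm, reference=reference,
                                       max_distance_bp=cfg.max_distance_bp,
                                       span=cfg.lowess_span)
    return pm, report


def run_subtype_analysis(cfg: RunConfig,
                         pm: ProfileMatrix | None = None) -> ResultTable:
    """Execute the full analysis for one test subtype.

    A preprocessed ``ProfileMatrix`` may be passed directly (e.g. a
    simulated cohort); otherwise it is read from the configured paths.
    """
    cfg.validate()
    report = None
    if pm is None:
        pm, report = _prepare_matrix(cfg)

    labels = pm.patients["label"]
    if cfg.test_label not in set(labels):
        raise ValueError(f"test label {cfg.test_label!r} absent from labels "
                         f"(present: {sorted(set(labels))})")
    keep = ~pm.patients["patient_id"].isin(cfg.excluded_patients)
    keep &= ~(labels.isin(cfg.excluded_control_labels)
              & (labels != cfg.test_label))
    pm = pm.select_patients(keep.to_numpy())
    mask = pm.label_mask(cfg.test_label)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError(
            f"need >= 2 patients per cohort, got {int(mask.sum())} test / "
            f"{int((~mask).sum())} control")

    boundaries = (profile_io.read_arm_boundaries(cfg.arm_boundaries_path)
                  if cfg.arm_boundaries_path else None)
    plan = sectioning.plan_sections(pm, boundaries, cfg.section_size, cfg.overlap)
    if not plan.sections:
        raise ValueError("empty section plan; no arm has enough clones")

    rng = np.random.default_rng(cfg.seed)
    sect, grid = compare_cohort_sections(pm.values, mask, plan.sections,
                                         D=cfg.D, step=cfg.step, B=cfg.B,
                                         seed=rng, q_threshold=cfg.q_threshold)
    sect = sect.copy()
    pos = pm.clones["position_bp"].to_numpy()
    sect["first_clone_bp"] = pos[sect["first_clone"]]
    sect["last_clone_bp"] = pos[sect["last_clone"]]

    clone_rows = []
    undetermined = np.zeros(len(sect), dtype=bool)
    for si in sect.index[sect["significant"]]:
        results = clone_level_test(pm, plan.sections[si], mask, B=cfg.B,
                                   alpha=cfg.alpha, seed=rng)
        called = [r for r in results if r.call != "not-significant"]
        undetermined[si] = not called
        for r in called:
            clone_rows.append({"arm": r.arm if r.arm.startswith(r.chromosome)
                               else r.chromosome + r.arm,
                               "section": si, "clone_id": r.clone_id,
                               "position_bp": r.position_bp, "call": r.call,
                               "mean_test": r.mean_test,
                               "mean_control": r.mean_control, "p": r.p})
    sect["undetermined"] = undetermined
    clones_df = pd.DataFrame(clone_rows, columns=[
        "arm", "section", "clone_id", "position_bp", "call", "mean_test",
        "mean_control", "p"])

    arm_rows = []
    for arm in pm.arms():
        if pm.arm_indices(arm).size <= cfg.D:
            logger.warning("skipping center-of-mass test for short arm %s", arm)
            continue
        r = com_arm_test(pm, arm, mask, cfg.D, B=cfg.B, alpha=cfg.alpha,
                         seed=rng, summary=cfg.com_summary)
        arm_rows.append(asdict(r))
    arms_df = pd.DataFrame(arm_rows, columns=[
        "arm", "mean_com_test", "mean_com_control", "p_diff", "p_origin",
        "significant"])

    meta = {"config": asdict(cfg),
            "n_test": int(mask.sum()), "n_control": int((~mask).sum()),
            "n_sections": len(plan.sections),
            "skipped_arms": plan.skipped_arms,
            "grid_step": cfg.step, "grid_points": len(grid)}
    if report is not None:
        meta["preprocess"] = report.as_dict()
    return ResultTable(sections=sect, clones=clones_df, arms=arms_df,
                       metadata=meta, report=report)


def write_results(rt: ResultTable, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sections": outdir / "sections.tsv",
        "clones": outdir / "clones.tsv",
        "arms": outdir / "arms.tsv",
        "metadata": outdir / "run_metadata.yaml",
    }
    rt.sections.to_csv(paths["sections"], sep="\t", index=False)
    rt.clones.to_csv(paths["clones"], sep="\t", index=False)
    rt.arms.to_csv(paths["arms"], sep="\t", index=False)
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(rt.metadata, fh, sort_keys=False)
    return paths


# ---------------------------------------------------------------------------
# experiment dispatch

EXPERIMENTS = ("sensitivity", "specificity", "section_size", "dimension",
               "overlap")


def run_experiments(config: dict | str, outdir=None) -> dict[str, Path]:
    """Dispatch a simulation experiment from a YAML config or dict.

    The config holds ``experiment`` (one of ``EXPERIMENTS``), optional
    ``params`` passed to the harness, and optional ``output_dir``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    name = config.get("experiment")
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; valid: {EXPERIMENTS}")
    params = dict(config.get("params") or {})
    outdir = Path(outdir or config.get("output_dir") or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if name == "sensitivity":
        res = simulate.run_sensitivity_experiment(**params)
        paths["table"] = outdir / "sensitivity.tsv"
        res.table.to_csv(paths["table"], sep="\t", index=False)
    elif name == "specificity":
        res = simulate.run_null_specificity(**params)
        paths["table"] = outdir / "specificity.tsv"
        res.table.to_csv(paths["table"], sep="\t", index=False)
    elif name == "section_size":
        res = simulate.run_section_size_experiment(**params)
        paths["table"] = outdir / "section_size.tsv"
        res.table.to_csv(paths["table"], sep="\t", index=False)
    elif name == "dimension":
        corr, pvals = simulate.run_dimension_experiment(**params)
        paths["correlations"] = outdir / "dimension_correlations.tsv"
        paths["pvalues"] = outdir / "dimension_pvalues.tsv"
        corr.to_csv(paths["correlations"], sep="\t")
        pvals.to_csv(paths["pvalues"], sep="\t", index=False)
    elif name == "overlap":
        res = simulate.run_overlap_experiment(**params)
        paths["table"] = outdir / "overlap.tsv"
        res.table.to_csv(paths["table"], sep="\t", index=False)
        paths["pooled"] = outdir / "overlap_pooled.tsv"
        pd.Series(res.pooled, name="sensitivity").rename_axis("class") \
            .to_frame().to_csv(paths["pooled"], sep="\t")
    logger.info("experiment %s written to %s", name, outdir)
    return paths
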