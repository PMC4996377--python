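"""Partition chromosome arms into overlapping fixed-size clone windows.

Each arm is covered by windows of ``section_size`` clones stepping by
``section_size - overlap``; when the last full step does not land on the
arm end, a final window anchored at the arm end is appended so telomeric
clones are never dropped (the last pair of sections may then overlap by
more than ``overlap``).  Arms shorter than the section size yield a single
section of all their clones; arms with fewer than 4 clones carry no usable
beta0 contrast at D=2 and are skipped (and recorded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .profile_io import ProfileMatrix, assign_arms

__all__ = [
    "Section",
    "SectionPlan",
    "section_starts",
    "plan_sections",
    "extract_section_values",
    "export_plan_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_SECTION_SIZE = 20
DEFAULT_OVERLAP = 10
MIN_ARM_CLONES = 4


@dataclass(frozen=True)
class Section:
    """A window of consecutive clones on one arm."""

    arm: str
    index: int
    clone_indices: np.ndarray  # row indices into the profile matrix
    m: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.clone_indices, dtype=int)
        object.__setattr__(self, "clone_indices", idx)
        object.__setattr__(self, "m", int(idx.size))


@dataclass
class SectionPlan:
    sections: list[Section]
    section_size: int
    overlap: int
    skipped_arms: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sections)


def section_starts(c: int, section_size: int = DEFAULT_SECTION_SIZE,
                   overlap: int = DEFAULT_OVERLAP) -> list[int]:
    """Window start offsets for an arm of ``c`` clones.

    Starts step by ``section_size - overlap``; a final end-anchored start is
    appended when the last full window does not reach clone ``c - 1``.
    """
    if not 0 <= overlap < section_size:
        raise ValueError(f"need 0 <= overlap < section_size, got "
                         f"overlap={overlap}, section_size={section_size}")
    if c <= section_size:
        return [0]
    step = section_size - overlap
    starts = list(range(0, c - section_size + 1, step))
    if starts[-1] + section_size < c:
        starts.append(c - section_size)
    return starts


def plan_sections(pm: ProfileMatrix, arm_boundaries: pd.DataFrame | None = None,
                  section_size: int = DEFAULT_SECTION_SIZE,
                  overlap: int = DEFAULT_OVERLAP) -> SectionPlan:
    """Build the overlapping section plan for every arm of a profile matrix.

    When ``arm_boundaries`` is given, clone arm labels are first re-derived
    from it; otherwise the clone map's own arm column is used.
    """
    if arm_boundaries is not None:
        pm = assign_arms(pm, arm_boundaries)
    plan = SectionPlan([], section_size, overlap)
    for arm in pm.arms():
        rows = pm.arm_indices(arm)
        c = rows.size
        if c < MIN_ARM_CLONES:
            logger.warning("skipping arm %s with only %d clones", arm, c)
            plan.skipped_arms.append(arm)
            continue
        size = min(section_size, c)
        for k, s in enumerate(section_starts(c, section_size, overlap)):
            plan.sections.append(Section(arm=arm, index=k,
                                         clone_indices=rows[s:s + size], m=size))
    return plan


def extract_section_values(pm: ProfileMatrix, section: Section,
                           patient: str) -> np.ndarray:
    """The section's ``m`` log2 ratios for one patient, in genomic order."""
    j = pm.patient_index(patient)
    vals = pm.values[section.clone_indices, j]
    if np.isnan(vals).any():
        raise ValueError(
            f"section {section.arm}:{section.index} holds missing values for "
            f"patient {patient!r}; impute before sectioning analysis")
    return vals


def export_plan_tsv(plan: SectionPlan, pm: ProfileMatrix, path) -> None:
    """Write the plan as TSV (arm, section_index, first/last clone bp)."""
    pos = pm.clones["position_bp"].to_numpy()
    rows = [{
        "arm": s.arm,
        "section_index": s.index,
        "first_clone_bp": int(pos[s.clone_indices[0]]),
        "last_clone_bp": int(pos[s.clone_indices[-1]]),
    } for s in plan.sections]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
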