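import numpy as np
import pandas as pd
import pytest

from taacgh.profile_io import ProfileMatrix


def make_pm(chrom, arm, pos, values, labels=None, clone_ids=None):
    """Assemble a ProfileMatrix from parallel per-clone sequences."""
    n = len(pos)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    P = values.shape[1]
    if labels is None:
        labels = ["test"] * (P // 2) + ["control"] * (P - P // 2)
    clones = pd.DataFrame({
        "clone_id": clone_ids or [f"cl{i}" for i in range(n)],
        "chromosome": chrom if not isinstance(chrom, str) else [chrom] * n,
        "arm": arm if not isinstance(arm, str) else [arm] * n,
        "position_bp": np.asarray(pos, dtype=np.int64),
    })
    patients = pd.DataFrame({"patient_id": [f"p{j}" for j in range(P)],
                             "label": labels})
    return ProfileMatrix(clones, values, patients)


@pytest.fixture
def toy_files(tmp_path):
    """3-clone x 2-patient TSV trio (matrix, clone map, labels)."""
    (tmp_path / "matrix.tsv").write_text(
        "clone_id\tpA\tpB\n"
        "c1\t0.1\t-0.2\n"
        "c2\t0.05\t0.3\n"
        "c3\t-0.1\t0.0\n")
    (tmp_path / "clones.tsv").write_text(
        "clone_id\tchromosome\tarm\tposition_bp\n"
        "c1\t1\tp\t1000\n"
        "c2\t1\tp\t2000\n"
        "c3\t1\tq\t5000\n")
    (tmp_path / "labels.tsv").write_text(
        "patient_id\tsubtype\npA\tlumA\npB\tbasal\n")
    return {"matrix": tmp_path / "matrix.tsv",
            "clone_map": tmp_path / "clones.tsv",
            "labels": tmp_path / "labels.tsv"}
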