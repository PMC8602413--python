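"""Relative copy-number calling from qPCR threshold cycles (ddCT method).

For a genomic segment assayed against an internal reference gene in a
test and a control sample:

    dCT(sample)  = CT_segment(sample) - CT_reference(sample)
    ddCT         = dCT(target) - dCT(control)
    copy number  = 2 * 2^(-ddCT)

with replicate-SD propagation s = sqrt(s1^2 + s2^2), where s1 and s2 are
the sample standard deviations of the per-replicate dCT values in the
target and control sample. Copy number in the closed interval [1.5, 3]
is called a normal diploid two copies; below 1.5 a deletion; above 3 a
duplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QpcrAssay", "QpcrResult", "delta_delta_ct", "call_assays"]

DELETION_BELOW = 1.5
DUPLICATION_ABOVE = 3.0


@dataclass
class QpcrAssay:
    """Replicate CT values for the four wells of one ddCT assay."""

    assay_id: str
    ct_segment_target: np.ndarray
    ct_reference_target: np.ndarray
    ct_segment_control: np.ndarray
    ct_reference_control: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ct_segment_target", "ct_reference_target",
                     "ct_segment_control", "ct_reference_control"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.size == 0:
                raise ValueError(f"{self.assay_id}: no replicates in {name}")
            if not np.isfinite(v).all():
                raise ValueError(f"{self.assay_id}: non-finite CT in {name}")
            setattr(self, name, v)
        n = {getattr(self, f).size for f in ("ct_segment_target",
                                             "ct_reference_target")}
        m = {getattr(self, f).size for f in ("ct_segment_control",
                                             "ct_reference_control")}
        if len(n) != 1 or len(m) != 1:
            raise ValueError(f"{self.assay_id}: replicate counts of segment "
                             "and reference wells must match within a sample")


@dataclass
class QpcrResult:
    assay_id: str
    ddct: float
    s1: float
    s2: float
    s: float
    copy_number: float
    call: str


def _call(copy_number: float) -> str:
    if copy_number < DELETION_BELOW:
        return "deletion"
    if copy_number > DUPLICATION_ABOVE:
        return "duplication"
    return "normal"


def delta_delta_ct(assay: QpcrAssay) -> QpcrResult:
    """ddCT, propagated SD, relative copy number and the 1.5/3-rule call.

    s1/s2 are sample SDs (ddof=1; 0 for a single replicate) of the paired
    per-replicate dCT differences in the target and control sample.
    """
    dct_target = assay.ct_segment_target - assay.ct_reference_target
    dct_control = assay.ct_segment_control - assay.ct_reference_control
    ddct = float(dct_target.mean() - dct_control.mean())
    s1 = float(dct_target.std(ddof=1)) if dct_target.size > 1 else 0.0
    s2 = float(dct_control.std(ddof=1)) if dct_control.size > 1 else 0.0
    s = float(np.hypot(s1, s2))
    cn = float(2.0 * 2.0 ** (-ddct))
    return QpcrResult(assay.assay_id, ddct, s1, s2, s, cn, _call(cn))


def call_assays(table: pd.DataFrame) -> pd.DataFrame:
    """Run ddCT on a tidy replicate table.

    Expected columns: ``assay_id``, ``well_role`` (one of segment_target,
    reference_target, segment_control, reference_control) and ``ct``
    (one row per replicate). Returns one row per assay.
    """
    required = {"assay_id", "well_role", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"replicate table needs columns {sorted(required)}")
    roles = ("segment_target", "reference_target",
             "segment_control", "reference_control")
    rows = []
    for assay_id, grp in table.groupby("assay_id", sort=False):
        wells = {}
        for role in roles:
            ct = grp.loc[grp["well_role"] == role, "ct"].to_numpy()
            if ct.size == 0:
                raise ValueError(f"{assay_id}: missing well {role}")
            wells[f"ct_{role}"] = ct
        res = delta_delta_ct(QpcrAssay(str(assay_id), **wells))
        rows.append(vars(res))
    return pd.DataFrame(rows)
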