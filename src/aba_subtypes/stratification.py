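"""ABA/RBA stratification from the sign pattern of multimodal BrainAGE.

A subject is an *accelerated* brain ager (ABA) when the brain-age gap is
strictly positive in all three imaging modalities, *resilient* (RBA)
when strictly negative in all three, and MIXED otherwise.  An exact zero
in any modality falls to MIXED (strict inequalities; a measure-zero
convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ABA", "RBA", "MIXED", "StratificationResult", "stratify", "stratification_summary"]

ABA = "ABA"
RBA = "RBA"
MIXED = "MIXED"


class AlignmentError(ValueError):
    """Subject IDs differ across modality inputs."""


@dataclass
class StratificationResult:
    """Per-subject group labels plus the BrainAGE values that produced them."""

    subject_ids: np.ndarray
    brainage_by_modality: pd.DataFrame  # one column per modality, indexed by ID
    group: pd.Series  # index: subject ID, values in {ABA, RBA, MIXED}

    def to_frame(self) -> pd.DataFrame:
        out = self.brainage_by_modality.copy()
        out.insert(0, "subject_id", out.index)
        out["group"] = self.group
        return out.reset_index(drop=True)

    def ids_in_group(self, label: str) -> np.ndarray:
        return self.group.index[self.group == label].to_numpy()


def stratify(
    brainage_smri: pd.Series,
    brainage_dmri: pd.Series,
    brainage_rsfmri: pd.Series,
) -> StratificationResult:
    """Label each subject ABA / RBA / MIXED from three aligned BrainAGE series.

    The three series must be indexed by identical subject IDs (any
    order); they are aligned to the sMRI order.
    """
    base = brainage_smri.index
    for other in (brainage_dmri, brainage_rsfmri):
        if len(other.index) != len(base) or set(other.index) != set(base):
            raise AlignmentError("subject IDs differ across modalities")
    mat = pd.DataFrame(
        {
            "sMRI": brainage_smri,
            "dMRI": brainage_dmri.reindex(base),
            "rsfMRI": brainage_rsfmri.reindex(base),
        }
    )
    values = mat.to_numpy()
    all_pos = np.all(values > 0, axis=1)
    all_neg = np.all(values < 0, axis=1)
    labels = np.where(all_pos, ABA, np.where(all_neg, RBA, MIXED))
    return StratificationResult(
        subject_ids=base.to_numpy(),
        brainage_by_modality=mat,
        group=pd.Series(labels, index=base),
    )


def stratification_summary(result: StratificationResult) -> dict[str, int]:
    """Group counts; always includes all three labels."""
    counts = result.group.value_counts().to_dict()
    return {label: int(counts.get(label, 0)) for label in (ABA, RBA, MIXED)}
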