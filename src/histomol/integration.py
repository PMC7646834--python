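"""Integration of MSI and microproteomics calls into one diagnosis.

The two tracks each produce a per-patient call: the MSI side a winner with
an optional ambiguity set (margin rule) and an irregularity flag, the
LC-MS/MS side a class with an irregularity flag.  The decision table:

1. either side irregular                          -> "further validation"
2. MSI ambiguous between set S, LC-MS/MS class in S -> the LC-MS/MS class
3. both unambiguous and equal                     -> that class
4. unambiguous but different                      -> LC-MS/MS class
                                                     + "/further validation"

Conflicts resolve toward the proteomics call (rule 4) because that track
carries the lower cross-validated error.

An MSI call is *irregular* (rather than merely ambiguous) when the runner-up
median score sits within the margin of the winner AND the co-scoring pair is
not {RO, ChRCC} — those two subtypes are expected spectral near-neighbors,
whereas e.g. ccRCC/ChRCC co-scoring signals a phenotype outside the model
(the sarcomatoid case).  A proteomics sample is irregular when it falls
outside its predicted class's 95% prediction ellipse in PCA score space.

``REFERENCE_COHORT`` holds the published 23-patient renal cohort
(per-patient MSI and LC-MS/MS diagnosis strings with the pathologist's
label), usable to exercise the decision table end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msi_classify import PatientCall
from .proteomics_pipeline import PredictionEllipse

__all__ = [
    "ModalityCall",
    "IntegratedDiagnosis",
    "parse_diagnosis",
    "integrate",
    "flag_irregular_msi",
    "flag_irregular_proteomics",
    "REFERENCE_COHORT",
    "integrate_cohort",
]

_EXPECTED_NEIGHBORS = frozenset({"RO", "ChRCC"})


@dataclass
class ModalityCall:
    """One modality's per-patient diagnosis."""

    winner: str
    ambiguous_with: set[str] = field(default_factory=set)
    irregular: bool = False
    reason: str = ""

    @property
    def label(self) -> str:
        parts = [self.winner] + sorted(self.ambiguous_with)
        text = "/".join(parts)
        return f"{text} with irregularities" if self.irregular else text


@dataclass
class IntegratedDiagnosis:
    patient_id: str
    msi_call: ModalityCall
    lcms_call: ModalityCall
    conclusion: str


def parse_diagnosis(text: str) -> ModalityCall:
    """Parse a printed diagnosis string such as ``"RO/ChRCC"`` or
    ``"ChRCC with irregularities"`` into a :class:`ModalityCall`."""
    text = text.strip()
    irregular = False
    if text.endswith("with irregularities"):
        irregular = True
        text = text[: -len("with irregularities")].strip()
    parts = [p.strip() for p in text.split("/") if p.strip()]
    if not parts:
        raise ValueError("empty diagnosis string")
    return ModalityCall(parts[0], set(parts[1:]), irregular)


def integrate(msi_call: ModalityCall | str | None,
              lcms_call: ModalityCall | str | None,
              patient_id: str = "") -> IntegratedDiagnosis:
    """Apply the decision table to one patient's pair of calls."""
    if msi_call is None or lcms_call is None:
        raise ValueError(f"patient {patient_id!r}: both modality calls are required")
    if isinstance(msi_call, str):
        msi_call = parse_diagnosis(msi_call)
    if isinstance(lcms_call, str):
        lcms_call = parse_diagnosis(lcms_call)

    if msi_call.irregular or lcms_call.irregular:
        conclusion = "further validation"
    elif msi_call.ambiguous_with:
        candidates = {msi_call.winner} | msi_call.ambiguous_with
        if lcms_call.winner in candidates:
            conclusion = lcms_call.winner
        else:
            conclusion = f"{lcms_call.winner}/further validation"
    elif msi_call.winner == lcms_call.winner:
        conclusion = msi_call.winner
    else:
        conclusion = f"{lcms_call.winner}/further validation"
    return IntegratedDiagnosis(patient_id, msi_call, lcms_call, conclusion)


def flag_irregular_msi(call: PatientCall,
                       coscore_fraction: float = 0.6) -> tuple[bool, str]:
    """Irregularity rule (a): co-scoring between classes that should not mix.

    Fires when the runner-up median reaches ``coscore_fraction`` of the
    winner's median and the winner/runner-up pair is not the expected
    {RO, ChRCC} neighborhood.  Co-scoring (both classes high) is a weaker
    condition than the 10% ambiguity margin: a section mixing two
    phenotypes half/half scores high for both classes without their medians
    being statistically indistinguishable, while clean sections keep the
    runner-up well below half the winner.
    """
    medians = call.median_scores
    winner = call.winner
    others = [c for c in medians if c != winner]
    if not others or medians[winner] <= 0:
        return False, ""
    runner_up = max(others, key=lambda c: medians[c])
    co_scoring = medians[runner_up] >= coscore_fraction * medians[winner]
    if co_scoring and {winner, runner_up} != _EXPECTED_NEIGHBORS:
        return True, (f"high scores for both {winner} and {runner_up} "
                      f"({medians[runner_up]:.3f} vs {medians[winner]:.3f})")
    return False, ""


def flag_irregular_proteomics(sample_scores: np.ndarray, predicted_class: str,
                              ellipses: dict[str, PredictionEllipse],
                              ) -> tuple[bool, str]:
    """Irregularity rule (b): PCA outlier relative to the predicted class.

    ``sample_scores`` are (PC1, PC2) coordinates of the patient's extraction
    spots; the patient is irregular when at least half of them fall outside
    the predicted class's 95% prediction ellipse (a single straggler spot is
    tolerated, a coherently displaced patient is not).
    """
    ellipse = ellipses.get(predicted_class)
    if ellipse is None:
        return False, ""
    pts = np.atleast_2d(np.asarray(sample_scores, dtype=np.float64))[:, :2]
    outside = ~ellipse.contains(pts)
    if np.mean(outside) >= 0.5:
        d = float(np.sqrt(ellipse.mahalanobis_sq(pts).max()))
        return True, (f"outside the {predicted_class} 95% prediction ellipse "
                      f"(Mahalanobis {d:.2f} vs "
                      f"{np.sqrt(ellipse.radius_sq):.2f})")
    return False, ""


#: Published 23-patient renal cohort: pathologist label, per-modality calls.
REFERENCE_COHORT = pd.DataFrame(
    [
        ("RO", "839", "RO/ChRCC", "RO", "RO"),
        ("RO", "119", "RO", "RO", "RO"),
        ("RO", "527", "RO", "RO", "RO"),
        ("RO", "270", "RO", "RO", "RO"),
        ("RO", "529", "RO/ChRCC", "RO", "RO"),
        ("RO", "560", "RO", "RO", "RO"),
        ("RO", "940", "RO", "RO", "RO"),
        ("RO", "857", "RO", "RO", "RO"),
        ("RO", "381", "RO", "RO", "RO"),
        ("ccRCC", "427", "ccRCC", "ccRCC", "ccRCC"),
        ("ccRCC", "370", "ccRCC", "ccRCC", "ccRCC"),
        ("ccRCC", "620", "ccRCC", "ccRCC", "ccRCC"),
        ("ccRCC", "73", "ccRCC", "ccRCC", "ccRCC"),
        ("ccRCC", "545", "ccRCC", "ccRCC", "ccRCC"),
        ("ccRCC", "999", "ccRCC", "ccRCC", "ccRCC"),
        ("ccRCC", "797", "RO", "ccRCC", "ccRCC/further validation"),
        ("ccRCC", "601", "ccRCC", "ccRCC", "ccRCC"),
        ("ccRCC", "336", "ccRCC", "ccRCC", "ccRCC"),
        ("ChRCC", "634", "ChRCC", "ChRCC", "ChRCC"),
        ("ChRCC", "835", "ChRCC", "ChRCC", "ChRCC"),
        ("ChRCC", "264", "ChRCC with irregularities",
         "ChRCC with irregularities",
         "further validation → sarcomatoid transformation"),
        ("ChRCC", "756", "ChRCC", "ChRCC", "ChRCC"),
        ("ChRCC", "925", "ChRCC", "ChRCC", "ChRCC"),
    ],
    columns=["pathology", "patient", "msi_diagnosis", "lcms_diagnosis",
             "conclusion"],
)


def _normalize_conclusion(text: str) -> str:
    """Strip post-hoc pathology annotations ("→ ...") from a printed conclusion."""
    return text.split("→")[0].strip()


def integrate_cohort(cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run the decision table over a cohort of printed per-modality calls.

    Returns the cohort with a ``derived_conclusion`` column and a boolean
    ``matches`` column comparing it with the recorded conclusion (after
    normalizing away annotation suffixes).
    """
    cohort = (REFERENCE_COHORT if cohort is None else cohort).copy()
    derived = [
        integrate(row.msi_diagnosis, row.lcms_diagnosis, row.patient).conclusion
        for row in cohort.itertuples()
    ]
    cohort["derived_conclusion"] = derived
    cohort["matches"] = [
        d == _normalize_conclusion(c)
        for d, c in zip(derived, cohort["conclusion"])
    ]
    return cohort
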