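"""Bundled example cohort: a published gynaecological-cancer plasma study.

The summary tables of a 100-patient gynaecological cancer cohort (ovarian
n=36, cervical n=11, endometrial n=53) screened for plasma CNA on an
NIPT-style platform are transcribed here: group sizes and detected counts
per cancer type and FIGO stage group, and the total CNA size (Mb) of each
of the 19 CNA-positive patients.  These are the quantities the detection
table reproduces.

Patient-level survival follow-up was never published; the PFS/OS fields of
this cohort are SYNTHETIC (drawn from exponential models in which
CNA-positive patients progress faster, matching the study's qualitative
finding) and exist only so survival code paths run end to end.  No survival
number derived from this cohort reproduces a published value.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortRecord

__all__ = ["published_cohort", "DETECTED_PATIENTS", "GROUP_SIZES"]

# (cancer_type, stage_group) -> number of patients enrolled
GROUP_SIZES: dict[tuple[str, str], int] = {
    ("ovarian", "early"): 21,
    ("ovarian", "advanced"): 15,
    ("cervical", "early"): 11,
    ("endometrial", "early"): 41,
    ("endometrial", "advanced"): 12,
}

# the 19 CNA-positive patients: (cancer_type, figo_stage, total CNA size in Mb)
DETECTED_PATIENTS: list[tuple[str, str, float]] = [
    ("ovarian", "III", 31),
    ("ovarian", "III", 565),
    ("ovarian", "III", 771),
    ("ovarian", "III", 981),
    ("ovarian", "III", 1767),
    ("ovarian", "I", 2448),
    ("cervical", "II", 21),
    ("cervical", "I", 89),
    ("cervical", "I", 1077),
    ("endometrial", "III", 62),
    ("endometrial", "III", 79),
    ("endometrial", "I", 93),
    ("endometrial", "I", 97),
    ("endometrial", "III", 102),
    ("endometrial", "I", 248),
    ("endometrial", "II", 248),
    ("endometrial", "III", 82),
    ("endometrial", "IV", 834),
    ("endometrial", "I", 1491),
]

_STAGE_FILL = {"early": ("I", "II"), "advanced": ("III", "IV")}


def published_cohort(survival_seed: int = 20_160_101) -> list[CohortRecord]:
    """The transcribed 100-patient cohort with synthetic survival fields.

    Detection-related fields (group sizes, CNA positivity, total CNA Mb)
    are the published ones; PFS/OS are deterministic synthetic draws (see
    module docstring).
    """
    rng = np.random.default_rng(survival_seed)
    records: list[CohortRecord] = []

    def survival(positive: bool, advanced: bool) -> tuple[float, int, float, int]:
        # exponential PFS; CNA-positive and advanced-stage patients progress faster
        scale_pfs = 18.0 if positive else 40.0
        scale_os = 30.0 if positive else 60.0
        if advanced:
            scale_pfs *= 0.7
            scale_os *= 0.7
        follow_up = 36.0
        pfs = float(rng.exponential(scale_pfs))
        osur = float(max(pfs, rng.exponential(scale_os)))
        pfs_event = int(pfs <= follow_up)
        os_event = int(osur <= follow_up)
        return min(pfs, follow_up), pfs_event, min(osur, follow_up), os_event

    i = 0
    for ctype, stage, size_mb in DETECTED_PATIENTS:
        i += 1
        grp = "advanced" if stage in ("III", "IV") else "early"
        pfs, pe, osur, oe = survival(True, grp == "advanced")
        records.append(CohortRecord(
            sample_id=f"P{i:03d}", cancer_type=ctype, figo_stage=stage,
            pfs_months=pfs, pfs_event=pe, os_months=osur, os_event=oe,
            cna_positive=True, total_cna_mb=size_mb,
        ))
    for (ctype, grp), n in GROUP_SIZES.items():
        n_detected = sum(
            1 for c, s, _ in DETECTED_PATIENTS
            if c == ctype and ("advanced" if s in ("III", "IV") else "early") == grp
        )
        for j in range(n - n_detected):
            i += 1
            stage = _STAGE_FILL[grp][j % 2]
            pfs, pe, osur, oe = survival(False, grp == "advanced")
            records.append(CohortRecord(
                sample_id=f"P{i:03d}", cancer_type=ctype, figo_stage=stage,
                pfs_months=pfs, pfs_event=pe, os_months=osur, os_event=oe,
                cna_positive=False, total_cna_mb=0.0,
            ))
    assert len(records) == 100
    return records
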