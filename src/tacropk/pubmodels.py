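"""Published population-PK covariate models for tacrolimus apparent clearance.

Three literature formulas are evaluated at arbitrary covariate values so a
cohort's own geometric-mean CL/F can be compared against other transplant
populations on a common "typical patient":

* Darley:  CL/F = 14.4 / (HCT/45)
* Chen:    CL/F = 3.7 * (WT/70)^0.75 * (VOZ/2.02)^-0.288 * (DD/0.75)^0.618
                  * (HCT/31.5)^-0.511
* Cai:     CL/F = 13.1 * (WT/70)^0.75 * (HCT/30)^-0.868 * (DD/3)^0.616
                  * (POT/30)^0.0807 * 1.3 [CYP3A5*1 carrier]
                  * 0.638 [voriconazole comedication]

Units: WT kg, HCT %, DD mg/day, POT days; VOZ is treated as a dimensionless
ratio to its reference 2.02 (no units are published for it).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

MODELS = ("darley", "chen", "cai")

CHEN_VOZ_REFERENCE = 2.02


@dataclass(frozen=True)
class CovariateProfile:
    """Covariates required by the published clearance models.

    Missing optional fields stay ``None``; each model checks what it needs.
    """

    wt: float | None = None    # kg
    hct: float | None = None   # %
    dd: float | None = None    # tacrolimus daily dose, mg
    voz: float | None = None   # voriconazole trough (reference-ratio units)
    pot: float | None = None   # postoperative time, days
    cyp3a5_expresser: bool = False
    voriconazole_comed: bool = False

    def require(self, model: str, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ValidationError(f"{model} model requires covariate {name!r}")
            if not value > 0:
                raise ValidationError(
                    f"{model} model: covariate {name!r} must be positive, got {value}"
                )


#: the comparison table's reference patient: 64.5 kg, haematocrit 30%,
#: 2 mg tacrolimus daily, 3.5 days post-transplant, on voriconazole
TYPICAL_PATIENT = CovariateProfile(wt=64.5, hct=30.0, dd=2.0, pot=3.5,
                                   voriconazole_comed=True)


def evaluate_published_clf(model: str, cov: CovariateProfile) -> float:
    """Apparent clearance (L/h) from one published covariate model.

    ``model`` is ``"darley"``, ``"chen"`` or ``"cai"``.  Chen's missing
    voriconazole trough defaults to its reference 2.02, making that factor 1.
    """
    model = model.lower()
    if model == "darley":
        cov.require(model, "hct")
        return 14.4 / (cov.hct / 45.0)
    if model == "chen":
        cov.require(model, "wt", "dd", "hct")
        voz = CHEN_VOZ_REFERENCE if cov.voz is None else cov.voz
        if not voz > 0:
            raise ValidationError("chen model: covariate 'voz' must be positive")
        return (
            3.7
            * (cov.wt / 70.0) ** 0.75
            * (voz / CHEN_VOZ_REFERENCE) ** -0.288
            * (cov.dd / 0.75) ** 0.618
            * (cov.hct / 31.5) ** -0.511
        )
    if model == "cai":
        cov.require(model, "wt", "hct", "dd", "pot")
        clf = (
            13.1
            * (cov.wt / 70.0) ** 0.75
            * (cov.hct / 30.0) ** -0.868
            * (cov.dd / 3.0) ** 0.616
            * (cov.pot / 30.0) ** 0.0807
        )
        if cov.cyp3a5_expresser:
            clf *= 1.3
        if cov.voriconazole_comed:
            clf *= 0.638
        return clf
    raise ValidationError(f"unknown published model {model!r}; choose from {MODELS}")


def comparison_table(cov: CovariateProfile, own_clf: float) -> pd.DataFrame:
    """Side-by-side adjusted CL/F of the published models and this cohort.

    ``own_clf`` is the cohort's geometric-mean CL/F; the ratio column is
    model/own.
    """
    if not own_clf > 0:
        raise ValidationError("own_clf must be positive")
    rows = []
    for model in MODELS:
        clf = evaluate_published_clf(model, cov)
        rows.append({"model": model, "adjusted_clf": clf, "ratio_to_own": clf / own_clf})
    rows.append({"model": "this cohort", "adjusted_clf": own_clf, "ratio_to_own": 1.0})
    return pd.DataFrame(rows)
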