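"""Non-compartmental analysis of a single 12-h dosing-interval profile.

The dosing-interval AUC uses the linear-up log-down trapezoidal rule: rising
(or flat, or zero-bounded) segments are integrated with the linear trapezoid,
falling strictly-positive segments with the log trapezoid, which is exact for
mono-exponential decline.  Apparent clearance follows from CL/F = Dose/AUC at
steady state; summaries are geometric (the parameters are near log-normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InsufficientDataError, ValidationError


@dataclass
class ConcProfile:
    """One subject's concentration-time series over a dosing interval.

    ``concs`` may contain NaN for below-quantification samples; those points
    are excluded from every computation.  Units: times h, concentrations
    ng/mL, dose mg per interval.
    """

    subject_id: str
    times: np.ndarray
    concs: np.ndarray
    dose: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concs.shape:
            raise ValidationError(
                f"subject {self.subject_id}: times and concs must be equal-length vectors"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"subject {self.subject_id}: times must be strictly increasing"
            )
        if self.times[0] < 0:
            raise ValidationError(f"subject {self.subject_id}: negative sampling time")
        obs = self.concs[~np.isnan(self.concs)]
        if obs.size < 3:
            raise InsufficientDataError(
                f"subject {self.subject_id}: fewer than 3 quantifiable concentrations"
            )
        if np.any(obs < 0):
            raise ValidationError(f"subject {self.subject_id}: negative concentration")
        if not self.dose > 0:
            raise ValidationError(f"subject {self.subject_id}: dose must be positive")

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations with BLQ-censored points removed."""
        mask = ~np.isnan(self.concs)
        return self.times[mask], self.concs[mask]

    def conc_at(self, t: float) -> float:
        """Observed concentration at a sampled time (NaN if censored or absent)."""
        idx = np.flatnonzero(np.isclose(self.times, t))
        return float(self.concs[idx[0]]) if idx.size else float("nan")


@dataclass(frozen=True)
class NCAResult:
    """Per-subject exposure metrics over the 0-12 h interval."""

    subject_id: str
    dose: float
    auc_0_12: float  # ng*h/mL
    cmax: float      # ng/mL
    cmin: float      # ng/mL
    tmax: float      # h
    clf: float       # L/h

    @property
    def auc_per_dose(self) -> float:
        return self.auc_0_12 / self.dose

    @property
    def cmax_per_dose(self) -> float:
        return self.cmax / self.dose

    @property
    def cmin_per_dose(self) -> float:
        return self.cmin / self.dose


@dataclass(frozen=True)
class GeoSummary:
    """Geometric mean, geometric SD and geometric CV% of a positive sample."""

    gm: float
    gsd: float
    cv_pct: float
    n: int


def auc_linuplogdown(times, concs) -> float:
    """Linear-up log-down trapezoidal AUC over the sampled interval.

    Per segment [t1, t2]: linear trapezoid (C1+C2)/2 * dt when C2 >= C1 or
    either endpoint is zero; log trapezoid (C1-C2)/ln(C1/C2) * dt when the
    segment declines between two positive values.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.ndim != 1 or times.shape != concs.shape:
        raise ValidationError("times and concs must be equal-length vectors")
    if times.size < 2:
        raise InsufficientDataError("need at least 2 points for an AUC")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    if np.any(np.isnan(concs)):
        raise ValidationError("censored points must be removed before AUC computation")
    if np.any(concs < 0):
        raise ValidationError("negative concentration")

    c1, c2 = concs[:-1], concs[1:]
    dt = np.diff(times)
    log_down = (c2 < c1) & (c1 > 0) & (c2 > 0)
    seg = np.where(
        log_down,
        (c1 - c2) / np.log(np.where(log_down, c1 / np.where(c2 > 0, c2, 1.0), 2.0)),
        (c1 + c2) / 2.0,
    )
    return float(np.sum(seg * dt))


def run_nca(profile: ConcProfile) -> NCAResult:
    """Non-compartmental metrics for one dosing-interval profile.

    C_max/C_min are the observed extrema over all sampled points (including
    the 0-h trough); T_max is the earliest time attaining C_max; CL/F in L/h
    is 1000 * dose(mg) / AUC(ng*h/mL).
    """
    t, c = profile.observed()
    auc = auc_linuplogdown(t, c)
    if auc <= 0:
        raise DegenerateFitError(
            f"subject {profile.subject_id}: zero AUC (all-zero profile?)"
        )
    i_max = int(np.argmax(c))  # argmax returns the first maximum: earliest T_max on ties
    return NCAResult(
        subject_id=profile.subject_id,
        dose=profile.dose,
        auc_0_12=auc,
        cmax=float(c[i_max]),
        cmin=float(np.min(c)),
        tmax=float(t[i_max]),
        clf=1000.0 * profile.dose / auc,
    )


def geo_summary(values) -> GeoSummary:
    """Geometric mean / SD / CV% via log moments.

    gm = exp(mean(ln v)); gsd = exp(sd(ln v)) with the sample (n-1)
    denominator (gsd := 1 for n = 1); cv% = 100*sqrt(exp(s^2)-1), the exact
    relative dispersion of a log-normal with log-SD s.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValidationError("empty sample")
    if np.any(~(values > 0)):
        raise ValidationError("geometric summary requires strictly positive values")
    logs = np.log(values)
    gm = float(np.exp(np.mean(logs)))
    if values.size == 1:
        return GeoSummary(gm=gm, gsd=1.0, cv_pct=0.0, n=1)
    s = float(np.std(logs, ddof=1))
    return GeoSummary(
        gm=gm,
        gsd=float(np.exp(s)),
        cv_pct=float(100.0 * np.sqrt(np.expm1(s**2))),
        n=int(values.size),
    )
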