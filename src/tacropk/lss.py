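"""Limited-sampling-strategy development and predictive performance.

For every time on the shared sampling grid the dosing-interval AUC is
regressed on the single concentration at that time (OLS); predictive
performance follows the Sheiner-Beal convention on percent relative
prediction errors: MPE (mean signed), MAE (mean absolute), and the fractions
F15/F20/F25 of subjects whose absolute error stays within 15/20/25 percent.
A strategy is clinically acceptable when |MPE| <= 15, MAE <= 30, F15 > 40,
F20 > 45 and F25 > 50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError, ValidationError
from .nca import ConcProfile, NCAResult, geo_summary

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (15.0, 20.0, 25.0)
#: acceptability bounds: |MPE| limit, MAE limit, floors for F at each threshold
DEFAULT_BOUNDS = (15.0, 30.0, (40.0, 45.0, 50.0))


@dataclass
class LSSPerformance:
    """Regression and predictive-performance summary for one sampling time.

    ``pe`` holds the per-subject percent prediction errors
    100*(AUC_pred - AUC_obs)/AUC_obs.  ``n_exceed``/``f_within`` align with
    ``thresholds``; with the default thresholds the ``f15``-style properties
    apply.  ``f_within`` is stored unrounded.
    """

    n: int
    pe: np.ndarray = field(repr=False)
    mpe_mean: float
    mae_mean: float
    mpe_median: float
    mpe_range: tuple[float, float]
    mae_median: float
    mae_range: tuple[float, float]
    thresholds: tuple[float, ...]
    n_exceed: tuple[int, ...]
    f_within: tuple[float, ...]
    sampling_time: float | None = None
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None
    conc_gm: float | None = None
    conc_gsd: float | None = None
    acceptable: bool | None = None
    n_excluded: int = 0

    def _f(self, i: int) -> float:
        return self.f_within[i]

    @property
    def f15(self) -> float:
        return self._f(0)

    @property
    def f20(self) -> float:
        return self._f(1)

    @property
    def f25(self) -> float:
        return self._f(2)

    @property
    def n_exceed_15(self) -> int:
        return self.n_exceed[0]

    @property
    def n_exceed_20(self) -> int:
        return self.n_exceed[1]

    @property
    def n_exceed_25(self) -> int:
        return self.n_exceed[2]


def fit_single_point(conc_at_t, auc_obs) -> tuple[float, float, float]:
    """OLS fit AUC = intercept + slope * C_t; returns (slope, intercept, r2)."""
    x = np.asarray(conc_at_t, dtype=float)
    y = np.asarray(auc_obs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired vectors of equal length required")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor: single-point fit undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def predictive_performance(
    auc_pred,
    auc_obs,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> LSSPerformance:
    """Sheiner-Beal predictive performance of AUC predictions.

    PE_i = 100*(pred_i - obs_i)/obs_i; MPE/MAE are means of signed and
    absolute PE; medians and ranges are reported alongside (signed for MPE,
    absolute for MAE).  A PE exactly on a threshold counts as within it.
    """
    pred = np.asarray(auc_pred, dtype=float)
    obs = np.asarray(auc_obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size == 0:
        raise ValidationError("equal-length non-empty vectors required")
    if np.any(~(obs > 0)):
        raise ValidationError("observed AUC values must be positive")
    pe = 100.0 * (pred - obs) / obs
    ape = np.abs(pe)
    n = pe.size
    n_exceed = tuple(int(np.sum(ape > k)) for k in thresholds)
    f_within = tuple(100.0 * (n - ne) / n for ne in n_exceed)
    return LSSPerformance(
        n=n,
        pe=pe,
        mpe_mean=float(np.mean(pe)),
        mae_mean=float(np.mean(ape)),
        mpe_median=float(np.median(pe)),
        mpe_range=(float(np.min(pe)), float(np.max(pe))),
        mae_median=float(np.median(ape)),
        mae_range=(float(np.min(ape)), float(np.max(ape))),
        thresholds=tuple(float(k) for k in thresholds),
        n_exceed=n_exceed,
        f_within=f_within,
    )


def acceptability(perf: LSSPerformance, bounds=DEFAULT_BOUNDS) -> bool:
    """Clinical acceptability verdict.

    True iff |MPE| <= 15%, MAE <= 30%, and F15/F20/F25 strictly exceed
    40/45/50% (with the default bounds).  MPE/MAE use the means; the F
    floors pair positionally with the thresholds.
    """
    mpe_limit, mae_limit, f_floors = bounds
    if len(f_floors) != len(perf.f_within):
        raise ValidationError("F floors must match the number of thresholds")
    return bool(
        abs(perf.mpe_mean) <= mpe_limit
        and perf.mae_mean <= mae_limit
        and all(f > floor for f, floor in zip(perf.f_within, f_floors))
    )


def lss_scan(
    profiles: list[ConcProfile],
    nca_results: list[NCAResult],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    bounds=DEFAULT_BOUNDS,
    loo: bool = False,
) -> list[LSSPerformance]:
    """Single-point LSS evaluation at every time on the shared sampling grid.

    Subjects missing (censored) at a given time are excluded from that row
    only.  ``loo=True`` switches the in-sample predictions to leave-one-out
    cross-validated ones (the regression coefficients reported stay the
    full-sample fit).
    """
    if len(profiles) != len(nca_results):
        raise ValidationError("profiles and NCA results must pair one-to-one")
    if len(profiles) < 3:
        raise InsufficientDataError("need at least 3 subjects")
    auc_by_id = {r.subject_id: r.auc_0_12 for r in nca_results}
    missing = sorted(p.subject_id for p in profiles if p.subject_id not in auc_by_id)
    if missing:
        raise ValidationError(f"subjects without NCA results: {', '.join(missing)}")
    grid = profiles[0].times
    for p in profiles[1:]:
        if p.times.shape != grid.shape or not np.allclose(p.times, grid):
            raise ValidationError(
                f"subject {p.subject_id} is not on the shared sampling grid"
            )

    rows: list[LSSPerformance] = []
    for j, t in enumerate(grid):
        conc = np.array([p.concs[j] for p in profiles])
        auc = np.array([auc_by_id[p.subject_id] for p in profiles])
        mask = ~np.isnan(conc)
        n_excl = int(np.sum(~mask))
        if n_excl:
            logger.info("t=%g h: excluded %d subject(s) with censored concentration",
                        t, n_excl)
        x, y = conc[mask], auc[mask]
        if x.size < 3:
            raise InsufficientDataError(
                f"t={t} h: fewer than 3 quantifiable concentrations"
            )
        slope, intercept, r2 = fit_single_point(x, y)
        if loo:
            pred = np.empty_like(y)
            for i in range(y.size):
                keep = np.arange(y.size) != i
                s_i, b_i, _ = fit_single_point(x[keep], y[keep])
                pred[i] = b_i + s_i * x[i]
        else:
            pred = intercept + slope * x
        perf = predictive_performance(pred, y, thresholds=thresholds)
        gs = geo_summary(x) if np.all(x > 0) else None
        perf.sampling_time = float(t)
        perf.slope, perf.intercept, perf.r2 = slope, intercept, r2
        if gs is not None:
            perf.conc_gm, perf.conc_gsd = gs.gm, gs.gsd
        perf.n_excluded = n_excl
        perf.acceptable = acceptability(perf, bounds=bounds)
        rows.append(perf)
    return rows
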