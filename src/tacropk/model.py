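"""Cohort-level analysis model and results.

``CohortPKModel`` bundles a cohort's concentration profiles, doses and
genotypes (read from CSV, built from DataFrames, or simulated) and ``fit()``
runs the full analysis chain: per-subject non-compartmental analysis,
genotype-stratified geometric summaries with log-scale ANOVA, single-point
limited-sampling evaluation, Hardy-Weinberg and linkage-disequilibrium
statistics, and the published covariate-model comparison.  The returned
``CohortPKResults`` carries the raw numbers, renders publication-style
tables via ``summary()``, and writes the report bundle with ``save()``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .errors import ConfigError, ValidationError
from .lss import DEFAULT_BOUNDS, DEFAULT_THRESHOLDS, LSSPerformance, lss_scan
from .nca import ConcProfile, GeoSummary, NCAResult, geo_summary, run_nca
from .pgx import (
    CYP3A5_NONEXPRESSER,
    GenotypeRecord,
    LDResult,
    HWEResult,
    classify_carriers,
    compare_groups,
    em_haplotypes,
    hwe_test,
)
from .pubmodels import TYPICAL_PATIENT, CovariateProfile, comparison_table
from .simulate import SimConfig, SubjectTruth, simulate_population

DEFAULT_STAR_LEVELS = (0.05, 0.01, 0.001)

#: parameters summarised geometrically in the stratified table, in print order
_TABLE2_PARAMS = (
    ("C_max (ng/mL)", "cmax"),
    ("C_max/D (ng/mL)", "cmax_per_dose"),
    ("C_min (ng/mL)", "cmin"),
    ("C_min/D (ng/mL)", "cmin_per_dose"),
    ("CL/F (L/h)", "clf"),
    ("AUC_0-12h (ng*h/mL)", "auc_0_12"),
    ("AUC_0-12h/D (ng*h/mL)", "auc_per_dose"),
)


def p_stars(p: float, levels=DEFAULT_STAR_LEVELS) -> str:
    """Significance stars: * / ** / *** at the three nested alpha levels."""
    if p is None or np.isnan(p):
        return ""
    for n_stars, alpha in ((3, levels[2]), (2, levels[1]), (1, levels[0])):
        if p <= alpha:
            return "*" * n_stars
    return ""


def format_gm_cell(gs: GeoSummary, stars: str = "") -> str:
    """``"9.95 ± 2.60 (121.94)"`` — GM ± geometric SD (geometric CV%)."""
    cell = f"{gs.gm:.2f} ± {gs.gsd:.2f} ({gs.cv_pct:.2f})"
    return f"{cell} {stars}" if stars else cell


def format_median_range(values) -> str:
    """``"2.00 (2.00–4.00)"`` — median (minimum–maximum)."""
    v = np.asarray(values, dtype=float)
    return f"{np.median(v):.2f} ({np.min(v):.2f}–{np.max(v):.2f})"


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Either the three input CSV paths or a ``simulate`` block must be set.
    Thresholds are the |PE| cut-offs (percent, strictly increasing);
    acceptability bounds are (|MPE| limit, MAE limit, F floors).
    """

    conc_csv: str | None = None
    dose_csv: str | None = None
    geno_csv: str | None = None
    simulate: SimConfig | None = None
    out_dir: str | None = None
    seed: int | None = None
    lss_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    acceptability_bounds: tuple = DEFAULT_BOUNDS
    star_levels: tuple[float, float, float] = DEFAULT_STAR_LEVELS
    loo: bool = False
    typical_covariates: CovariateProfile = TYPICAL_PATIENT

    def __post_init__(self) -> None:
        th = np.asarray(self.lss_thresholds, dtype=float)
        if np.any(np.diff(th) <= 0) or np.any(th <= 0):
            raise ConfigError("lss_thresholds must be positive and strictly increasing")
        mpe_limit, mae_limit, floors = self.acceptability_bounds
        if mpe_limit <= 0 or mae_limit <= 0 or any(f < 0 for f in floors):
            raise ConfigError("acceptability bounds must be positive")
        if self.simulate is None and not (self.conc_csv and self.dose_csv and self.geno_csv):
            raise ConfigError(
                "either a simulate block or all three input CSV paths are required"
            )


_RUNCONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_run_config(path) -> RunConfig:
    """Load a flat key-value (YAML) config file.

    Keys matching ``RunConfig`` fields configure the run; with
    ``simulate: true`` every remaining key is passed to :class:`SimConfig`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    run_kwargs = {k: v for k, v in raw.items() if k in _RUNCONFIG_KEYS and k != "simulate"}
    rest = {k: v for k, v in raw.items() if k not in _RUNCONFIG_KEYS}
    if raw.get("simulate"):
        sim_block = dict(rest)
        if run_kwargs.get("seed") is not None:
            sim_block.setdefault("seed", run_kwargs["seed"])
        run_kwargs["simulate"] = SimConfig.from_mapping(sim_block)
    elif rest:
        raise ConfigError(f"{path}: unknown setting(s) {', '.join(sorted(rest))}")
    if "lss_thresholds" in run_kwargs:
        run_kwargs["lss_thresholds"] = tuple(float(x) for x in run_kwargs["lss_thresholds"])
    return RunConfig(**run_kwargs)


class CohortPKModel:
    """Dosing-interval PK analysis of one cohort.

    Parameters
    ----------
    profiles, genotypes
        One :class:`ConcProfile` and one :class:`GenotypeRecord` per subject;
        the subject sets must match exactly.
    truths
        Optional simulation ground truth, carried through for recovery checks.
    """

    def __init__(
        self,
        profiles: list[ConcProfile],
        genotypes: list[GenotypeRecord],
        truths: list[SubjectTruth] | None = None,
        lss_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
        acceptability_bounds=DEFAULT_BOUNDS,
        star_levels=DEFAULT_STAR_LEVELS,
        typical_covariates: CovariateProfile = TYPICAL_PATIENT,
        loo: bool = False,
        seed: int | None = None,
    ) -> None:
        prof_ids = {p.subject_id for p in profiles}
        geno_ids = {g.subject_id for g in genotypes}
        if prof_ids != geno_ids:
            only_prof = sorted(prof_ids - geno_ids)
            only_geno = sorted(geno_ids - prof_ids)
            parts = []
            if only_prof:
                parts.append(f"missing genotypes for: {', '.join(only_prof)}")
            if only_geno:
                parts.append(f"missing profiles for: {', '.join(only_geno)}")
            raise ValidationError("; ".join(parts))
        self.profiles = sorted(profiles, key=lambda p: p.subject_id)
        self.genotypes = sorted(genotypes, key=lambda g: g.subject_id)
        self.truths = sorted(truths, key=lambda t: t.subject_id) if truths else None
        self.lss_thresholds = lss_thresholds
        self.acceptability_bounds = acceptability_bounds
        self.star_levels = star_levels
        self.typical_covariates = typical_covariates
        self.loo = loo
        self.seed = seed

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(cls, conc_csv, dose_csv, geno_csv, **opts) -> "CohortPKModel":
        conc = io.read_concentrations(conc_csv)
        dose = io.read_doses(dose_csv)
        genotypes = io.read_genotypes(geno_csv)
        return cls(io.profiles_from_frames(conc, dose), genotypes, **opts)

    @classmethod
    def from_dataframes(cls, conc: pd.DataFrame, dose: pd.DataFrame,
                        geno: pd.DataFrame, **opts) -> "CohortPKModel":
        genotypes = [
            GenotypeRecord(str(r.subject_id), r.cyp3a5, r.cyp3a4)
            for r in geno.itertuples()
        ]
        return cls(io.profiles_from_frames(conc, dose), genotypes, **opts)

    @classmethod
    def from_simulation(cls, config: SimConfig, **opts) -> "CohortPKModel":
        truths, profiles = simulate_population(config)
        opts.setdefault("seed", config.seed)
        return cls(profiles, io.genotypes_from_truths(truths), truths=truths, **opts)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "CohortPKResults":
        nca_results = [run_nca(p) for p in self.profiles]
        nca_table = self._nca_table(nca_results)
        table2, anova_p = self._stratified_table(nca_table)
        lss_rows = lss_scan(
            self.profiles, nca_results,
            thresholds=self.lss_thresholds,
            bounds=self.acceptability_bounds,
            loo=self.loo,
        )
        hwe = {
            "CYP3A5*3 (rs776746)": hwe_test(self._genotype_counts("cyp3a5")),
            "CYP3A4*1G (rs2242480)": hwe_test(self._genotype_counts("cyp3a4")),
        }
        ld = em_haplotypes(self.genotypes)
        own_gm_clf = geo_summary(nca_table["clf"]).gm
        table4 = comparison_table(self.typical_covariates, own_gm_clf)
        return CohortPKResults(
            model=self,
            nca_results=nca_results,
            nca_table=nca_table,
            table2=table2,
            anova_p=anova_p,
            lss_rows=lss_rows,
            hwe=hwe,
            ld=ld,
            table4=table4,
            seed=self.seed,
        )

    # -- internals ----------------------------------------------------------

    def _nca_table(self, nca_results: list[NCAResult]) -> pd.DataFrame:
        carrier = {g.subject_id: classify_carriers(g) for g in self.genotypes}
        geno = {g.subject_id: g for g in self.genotypes}
        rows = []
        for r in nca_results:
            c5, c4 = carrier[r.subject_id]
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "dose": r.dose,
                    "auc_0_12": r.auc_0_12,
                    "cmax": r.cmax,
                    "cmin": r.cmin,
                    "tmax": r.tmax,
                    "clf": r.clf,
                    "auc_per_dose": r.auc_per_dose,
                    "cmax_per_dose": r.cmax_per_dose,
                    "cmin_per_dose": r.cmin_per_dose,
                    "cyp3a5": geno[r.subject_id].cyp3a5,
                    "cyp3a4": geno[r.subject_id].cyp3a4,
                    "cyp3a5_class": c5,
                    "cyp3a4_class": c4,
                }
            )
        return pd.DataFrame(rows)

    def _genotype_counts(self, locus: str) -> tuple[int, int, int]:
        # counts ordered as (variant-hom, het, wild-hom) with A = *1 (CYP3A5)
        # or *1G (CYP3A4); the HWE test is symmetric in the ordering
        strings = [getattr(g, locus) for g in self.genotypes]
        if locus == "cyp3a5":
            order = ("*1/*1", "*1/*3", "*3/*3")
        else:
            order = ("*1G/*1G", "*1/*1G", "*1/*1")
        return tuple(sum(s == g for s in strings) for g in order)

    def _stratified_table(self, nca_table: pd.DataFrame):
        """Geometric summaries by CYP3A5 carrier class + log-scale ANOVA p."""
        is_nonexpr = nca_table["cyp3a5_class"] == CYP3A5_NONEXPRESSER
        groups = {
            "all": nca_table,
            "cyp3a5_33": nca_table[is_nonexpr],
            "non_cyp3a5_33": nca_table[~is_nonexpr],
        }
        rows, anova_p = [], {}
        for label, col in _TABLE2_PARAMS:
            row = {"parameter": label}
            for gname, frame in groups.items():
                if len(frame) == 0:
                    row[gname] = None
                    continue
                gs = geo_summary(frame[col].to_numpy())
                row[gname] = gs
            try:
                _, p = compare_groups(
                    nca_table[col].to_numpy(), nca_table["cyp3a5_class"].to_numpy()
                )
            except ValidationError:
                p = float("nan")
            row["p"] = p
            anova_p[label] = p
            rows.append(row)
        tmax_row = {"parameter": "T_max (h)", "p": float("nan")}
        for gname, frame in groups.items():
            tmax_row[gname] = frame["tmax"].to_numpy() if len(frame) else None
        rows.append(tmax_row)
        return rows, anova_p


@dataclass
class CohortPKResults:
    """Fitted cohort analysis: estimates, comparisons and report rendering."""

    model: CohortPKModel
    nca_results: list[NCAResult]
    nca_table: pd.DataFrame
    table2: list[dict]
    anova_p: dict[str, float]
    lss_rows: list[LSSPerformance]
    hwe: dict[str, HWEResult]
    ld: LDResult
    table4: pd.DataFrame
    seed: int | None = None

    # -- rendered tables ----------------------------------------------------

    def rendered_table2(self) -> pd.DataFrame:
        rows = []
        for row in self.table2:
            out = {"parameter": row["parameter"]}
            for gname, header in (("all", "all"), ("cyp3a5_33", "CYP3A5*3/*3"),
                                  ("non_cyp3a5_33", "non-CYP3A5*3/*3")):
                value = row[gname]
                if value is None:
                    out[header] = ""
                elif isinstance(value, GeoSummary):
                    stars = (
                        p_stars(row["p"], self.model.star_levels)
                        if gname == "non_cyp3a5_33"
                        else ""
                    )
                    out[header] = format_gm_cell(value, stars)
                else:  # T_max vector -> median (range)
                    out[header] = format_median_range(value)
            rows.append(out)
        return pd.DataFrame(rows)

    def rendered_table3(self) -> pd.DataFrame:
        rows = []
        for r in self.lss_rows:
            rows.append(
                {
                    "sampling_time_h": f"{r.sampling_time:g}",
                    "conc_gm_gsd": f"{r.conc_gm:.2f} ± {r.conc_gsd:.2f}",
                    "r2": f"{r.r2:.3f}",
                    "mpe_pct_median_range": (
                        f"{r.mpe_median:.0f} ({r.mpe_range[0]:.0f}–{r.mpe_range[1]:.0f})"
                    ),
                    "mae_pct_median_range": (
                        f"{r.mae_median:.0f} ({r.mae_range[0]:.0f}–{r.mae_range[1]:.0f})"
                    ),
                    "n_exceed_15": r.n_exceed[0],
                    "n_exceed_20": r.n_exceed[1],
                    "n_exceed_25": r.n_exceed[2],
                    "f15_pct": f"{r.f_within[0]:.0f}",
                    "f20_pct": f"{r.f_within[1]:.0f}",
                    "f25_pct": f"{r.f_within[2]:.0f}",
                    "acceptable": "yes" if r.acceptable else "no",
                }
            )
        return pd.DataFrame(rows)

    def lss_metrics_frame(self) -> pd.DataFrame:
        """Unrounded machine-readable limited-sampling metrics."""
        rows = []
        for r in self.lss_rows:
            rows.append(
                {
                    "sampling_time_h": r.sampling_time,
                    "n": r.n,
                    "n_excluded": r.n_excluded,
                    "conc_gm": r.conc_gm,
                    "conc_gsd": r.conc_gsd,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "r2": r.r2,
                    "mpe_mean": r.mpe_mean,
                    "mae_mean": r.mae_mean,
                    "mpe_median": r.mpe_median,
                    "mpe_min": r.mpe_range[0],
                    "mpe_max": r.mpe_range[1],
                    "mae_median": r.mae_median,
                    "mae_min": r.mae_range[0],
                    "mae_max": r.mae_range[1],
                    "f15": r.f_within[0],
                    "f20": r.f_within[1],
                    "f25": r.f_within[2],
                    "acceptable": bool(r.acceptable),
                }
            )
        return pd.DataFrame(rows)

    def pgx_report(self) -> str:
        lines = ["Hardy-Weinberg equilibrium"]
        for locus, res in self.hwe.items():
            exp = ", ".join(f"{e:.2f}" for e in res.expected)
            lines.append(
                f"  {locus}: observed {res.observed}, expected ({exp}), "
                f"chi2 = {res.chi2:.3f}, p = {res.p:.3f} ({res.method})"
            )
        lines.append("Linkage disequilibrium (CYP3A5*1 vs CYP3A4*1G)")
        f = ", ".join(f"{x:.4f}" for x in self.ld.hap_freqs)
        lines.append(f"  haplotype frequencies (*1-*1G, *1-*1, *3-*1G, *3-*1): ({f})")
        if self.ld.polymorphic:
            lines.append(
                f"  D = {self.ld.D:.4f}, D' = {self.ld.d_prime:.3f}, "
                f"r2 = {self.ld.r2:.3f} ({self.ld.em_iterations} EM iterations)"
            )
        else:
            lines.append("  a locus is monomorphic in this sample: D'/r2 undefined")
        return "\n".join(lines)

    def rendered_table4(self) -> pd.DataFrame:
        df = self.table4.copy()
        df["adjusted_clf"] = df["adjusted_clf"].map(lambda x: f"{x:.2f}")
        df["ratio_to_own"] = df["ratio_to_own"].map(lambda x: f"{x:.2f}")
        return df

    def summary(self) -> str:
        """Human-readable report over all analysis stages."""
        n = len(self.model.profiles)
        parts = [
            f"Tacrolimus dosing-interval PK analysis — {n} subjects"
            + (f" (seed {self.seed})" if self.seed is not None else ""),
            "",
            "Pharmacokinetic parameters by CYP3A5 carrier class",
            "(geometric mean ± geometric SD (geometric CV%); T_max median (range);"
            " stars: non-carriers vs carriers, log-scale ANOVA)",
            self.rendered_table2().to_string(index=False),
            "",
            "Single-point limited sampling strategies for AUC_0-12h",
            self.rendered_table3().to_string(index=False),
            "",
            self.pgx_report(),
            "",
            "Published covariate models at the typical patient",
            self.rendered_table4().to_string(index=False),
        ]
        return "\n".join(parts)

    # -- persistence and plotting ------------------------------------------

    def save(self, out_dir) -> None:
        """Write the report bundle (CSV tables, pgx report, run log)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.nca_table.to_csv(out / "nca_per_subject.csv", index=False)
        self.rendered_table2().to_csv(out / "table2_stratified.csv", index=False)
        self.rendered_table3().to_csv(out / "table3_lss.csv", index=False)
        self.lss_metrics_frame().to_csv(out / "lss_metrics.csv", index=False)
        self.table4.to_csv(out / "table4_published_models.csv", index=False)
        (out / "pgx_report.txt").write_text(self.pgx_report() + "\n")
        from . import __version__

        log = [
            f"tacropk {__version__}",
            f"numpy {np.__version__}, pandas {pd.__version__}",
            f"seed: {self.seed}",
            f"subjects: {len(self.model.profiles)}",
        ]
        (out / "run_log.txt").write_text("\n".join(log) + "\n")

    def plot_profiles(self, ax=None, dose_normalised: bool = True):
        """Spaghetti plot of the concentration-time profiles by carrier class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        classes = dict(zip(self.nca_table["subject_id"], self.nca_table["cyp3a5_class"]))
        colors = {CYP3A5_NONEXPRESSER: "tab:red"}
        seen = set()
        for p in self.model.profiles:
            cls = classes[p.subject_id]
            t, c = p.observed()
            y = c / p.dose if dose_normalised else c
            ax.plot(t, y, color=colors.get(cls, "tab:blue"), alpha=0.6,
                    label=cls if cls not in seen else None)
            seen.add(cls)
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel("concentration" + ("/dose (ng/mL per mg)" if dose_normalised else " (ng/mL)"))
        ax.legend(frameon=False)
        return ax


def run_pipeline(config: RunConfig) -> CohortPKResults:
    """simulate/load -> NCA -> stratify -> LSS -> PGx -> published models.

    A pure function of (inputs, config, seed): identical configuration
    produces byte-identical report files.  When the config carries a
    simulate block the generated input CSVs and ground truth are written
    next to the report.
    """
    opts = dict(
        lss_thresholds=config.lss_thresholds,
        acceptability_bounds=config.acceptability_bounds,
        star_levels=config.star_levels,
        typical_covariates=config.typical_covariates,
        loo=config.loo,
    )
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None and config.seed != sim.seed:
            sim = dataclasses.replace(sim, seed=config.seed)
        model = CohortPKModel.from_simulation(sim, **opts)
    else:
        model = CohortPKModel.from_csv(
            config.conc_csv, config.dose_csv, config.geno_csv,
            seed=config.seed, **opts,
        )
    results = model.fit()
    if config.out_dir is not None:
        results.save(config.out_dir)
        if model.truths is not None:
            out = Path(config.out_dir)
            io.write_concentrations(model.profiles, out / "concentrations.csv")
            io.write_doses(model.profiles, out / "doses.csv")
            io.write_genotypes(model.genotypes, out / "genotypes.csv")
            io.write_truths(model.truths, out / "truth.csv")
    return results
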