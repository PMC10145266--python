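"""Pharmacogenetic statistics for the CYP3A5*3 / CYP3A4*1G locus pair.

Carrier classification, Hardy-Weinberg testing (chi-squared or exact),
two-locus haplotype frequency estimation by EM with D'/r2 linkage
disequilibrium, genotype-group comparison of log-scale PK parameters, and
Spearman scans of clinical covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

CYP3A5_GENOTYPES = ("*1/*1", "*1/*3", "*3/*3")
CYP3A4_GENOTYPES = ("*1/*1", "*1/*1G", "*1G/*1G")

#: carrier-class labels used throughout reports
CYP3A5_NONEXPRESSER = "CYP3A5*3/*3"
CYP3A5_EXPRESSER = "non-CYP3A5*3/*3"
CYP3A4_WILD = "CYP3A4*1/*1"
CYP3A4_VARIANT = "non-CYP3A4*1/*1"


@dataclass(frozen=True)
class GenotypeRecord:
    """Unphased two-locus genotype of one subject.

    ``cyp3a5`` is one of ``*1/*1``, ``*1/*3``, ``*3/*3`` (rs776746);
    ``cyp3a4`` is one of ``*1/*1``, ``*1/*1G``, ``*1G/*1G`` (rs2242480).
    """

    subject_id: str
    cyp3a5: str
    cyp3a4: str

    def __post_init__(self) -> None:
        if self.cyp3a5 not in CYP3A5_GENOTYPES:
            raise ValidationError(
                f"subject {self.subject_id}: unknown CYP3A5 genotype "
                f"{self.cyp3a5!r}; expected one of {CYP3A5_GENOTYPES}"
            )
        if self.cyp3a4 not in CYP3A4_GENOTYPES:
            raise ValidationError(
                f"subject {self.subject_id}: unknown CYP3A4 genotype "
                f"{self.cyp3a4!r}; expected one of {CYP3A4_GENOTYPES}"
            )

    @property
    def cyp3a5_expresser(self) -> bool:
        """True for CYP3A5*1 carriers (functional-enzyme expressers)."""
        return self.cyp3a5 != "*3/*3"


def classify_carriers(record: GenotypeRecord) -> tuple[str, str]:
    """Binary carrier classes used for stratified comparisons.

    CYP3A5 splits into ``CYP3A5*3/*3`` (non-expressers) versus everyone
    carrying at least one functional *1 allele; CYP3A4 splits into *1/*1
    homozygotes versus *1G carriers.
    """
    c5 = CYP3A5_NONEXPRESSER if record.cyp3a5 == "*3/*3" else CYP3A5_EXPRESSER
    c4 = CYP3A4_WILD if record.cyp3a4 == "*1/*1" else CYP3A4_VARIANT
    return c5, c4


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HWEResult:
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p: float
    method: str  # "chi-squared" | "exact" | "monomorphic"


def _exact_hwe_p(n_het_obs: int, n_a_alleles: int, n: int) -> float:
    """Exact HWE p-value by full enumeration (Levene-Haldane distribution).

    Conditional on sample size and allele counts, the heterozygote count h
    follows P(h) = 2**h * n! * nA! * na! / (nAA! h! naa! (2n)!).  The
    two-sided p sums the probabilities of all h no more probable than the
    observed one.
    """
    n_b_alleles = 2 * n - n_a_alleles
    rare = min(n_a_alleles, n_b_alleles)
    log_const = (
        math.lgamma(n + 1)
        + math.lgamma(n_a_alleles + 1)
        + math.lgamma(n_b_alleles + 1)
        - math.lgamma(2 * n + 1)
    )

    def log_prob(h: int) -> float:
        n_aa = (n_a_alleles - h) // 2
        n_bb = (n_b_alleles - h) // 2
        return (
            log_const
            + h * math.log(2.0)
            - math.lgamma(n_aa + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n_bb + 1)
        )

    hs = range(rare % 2, rare + 1, 2)  # h shares the parity of the rare count
    logps = {h: log_prob(h) for h in hs}
    p_obs = logps[n_het_obs]
    total = sum(math.exp(lp) for lp in logps.values())
    p = sum(math.exp(lp) for lp in logps.values() if lp <= p_obs + 1e-12)
    return min(1.0, p / total)


def hwe_test(counts: tuple[int, int, int], method: str = "auto") -> HWEResult:
    """Test genotype counts ``(n_AA, n_Aa, n_aa)`` against Hardy-Weinberg.

    ``method`` is ``"auto"`` (exact when any HWE-expected cell is below 5,
    chi-squared otherwise), ``"chi-squared"`` or ``"exact"``.  A monomorphic
    sample returns p = 1 by convention.
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise ValidationError(f"genotype counts must be 3 non-negative ints, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValidationError("empty sample")
    n_aa_obs, n_het, n_bb_obs = counts
    n_a = 2 * n_aa_obs + n_het
    p_hat = n_a / (2 * n)
    expected = (n * p_hat**2, 2 * n * p_hat * (1 - p_hat), n * (1 - p_hat) ** 2)

    if p_hat in (0.0, 1.0):
        return HWEResult(counts, expected, 0.0, 1, 1.0, "monomorphic")

    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected) if e > 0)
    if method == "auto":
        method = "exact" if min(expected) < 5 else "chi-squared"
    if method == "chi-squared":
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "exact":
        p = _exact_hwe_p(n_het, n_a, n)
    else:
        raise ValidationError(f"unknown HWE method {method!r}")
    return HWEResult(counts, expected, float(chi2), 1, p, method)


# ---------------------------------------------------------------------------
# Two-locus haplotype EM and linkage disequilibrium
# ---------------------------------------------------------------------------

#: haplotype order used everywhere: (CYP3A5 allele, CYP3A4 allele)
HAPLOTYPE_ORDER = (("*1", "*1G"), ("*1", "*1"), ("*3", "*1G"), ("*3", "*1"))


@dataclass(frozen=True)
class LDResult:
    hap_freqs: tuple[float, float, float, float]
    D: float | None
    d_prime: float | None
    r2: float | None
    em_iterations: int
    loglik: float
    loglik_path: tuple[float, ...] = field(repr=False, default=())
    polymorphic: bool = True


def _genotype_dosages(record: GenotypeRecord) -> tuple[int, int]:
    """(copies of CYP3A5*1, copies of CYP3A4*1G)."""
    g5 = record.cyp3a5.count("*1")  # *1/*1 -> 2, *1/*3 -> 1, *3/*3 -> 0
    g4 = record.cyp3a4.count("*1G")
    return g5, g4


def em_haplotypes(
    records: list[GenotypeRecord],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LDResult:
    """Estimate the four two-locus haplotype frequencies by EM.

    Double heterozygotes are phase-ambiguous: the E-step splits them between
    the cis (*1-*1G / *3-*1) and trans (*1-*1 / *3-*1G) configurations in
    proportion to the current frequency products; the M-step renormalises the
    expected haplotype counts.  D is reported for the (*1, *1G) allele pair,
    with D' = |D|/D_max and r2 = D^2/(pA pa pB pb).  A monomorphic locus
    leaves D'/r2 undefined and the result flagged.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 subjects for haplotype estimation")
    table = np.zeros((3, 3))
    for rec in records:
        g5, g4 = _genotype_dosages(rec)
        table[g5, g4] += 1
    n = table.sum()

    def loglik(f: np.ndarray) -> float:
        f_ab, f_a, f_b, f_0 = f  # AB=*1-*1G, Ab=*1-*1, aB=*3-*1G, ab=*3-*1
        probs = np.empty((3, 3))
        # genotype (g5 copies of *1, g4 copies of *1G); random union of haplotypes
        probs[2, 2] = f_ab**2
        probs[2, 1] = 2 * f_ab * f_a
        probs[2, 0] = f_a**2
        probs[1, 2] = 2 * f_ab * f_b
        probs[1, 1] = 2 * f_ab * f_0 + 2 * f_a * f_b
        probs[1, 0] = 2 * f_a * f_0
        probs[0, 2] = f_b**2
        probs[0, 1] = 2 * f_b * f_0
        probs[0, 0] = f_0**2
        mask = table > 0
        with np.errstate(divide="ignore"):
            return float(np.sum(table[mask] * np.log(probs[mask])))

    # initialise at linkage equilibrium from observed allele dosages
    p_a = float((2 * table[2, :].sum() + table[1, :].sum()) / (2 * n))  # *1 at CYP3A5
    p_b = float((2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n))  # *1G at CYP3A4
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    path = [loglik(f)]
    n_dh = table[1, 1]
    iters = 0
    for iters in range(1, max_iter + 1):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = np.array(
            [
                2 * table[2, 2] + table[2, 1] + table[1, 2] + w * n_dh,
                2 * table[2, 0] + table[2, 1] + table[1, 0] + (1 - w) * n_dh,
                2 * table[0, 2] + table[1, 2] + table[0, 1] + (1 - w) * n_dh,
                2 * table[0, 0] + table[1, 0] + table[0, 1] + w * n_dh,
            ]
        )
        f_new = counts / (2 * n)
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        path.append(loglik(f))
        if delta < tol:
            break

    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 0:
        return LDResult(tuple(f), None, None, None, iters, path[-1], tuple(path), False)

    D = float(f[0] - p_a * p_b)
    if D >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(tuple(f), D, float(d_prime), float(r2), iters, path[-1], tuple(path))


# ---------------------------------------------------------------------------
# Group comparison and covariate scans
# ---------------------------------------------------------------------------

def compare_groups(values, groups) -> tuple[float, float]:
    """One-way ANOVA on log-transformed PK parameters.

    PK exposure metrics are approximately log-normal, so the comparison is
    run on natural logs.  Returns ``(F, p)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have equal length")
    if np.any(values <= 0):
        raise ValidationError("PK parameters must be positive for log-scale ANOVA")
    samples = []
    for g in pd.unique(groups):
        sample = np.log(values[groups == g])
        if sample.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 members")
        samples.append(sample)
    if len(samples) < 2:
        raise ValidationError("need at least 2 groups")
    f_stat, p = stats.f_oneway(*samples)
    return float(f_stat), float(p)


def spearman_scan(covariates: pd.DataFrame, parameter) -> pd.DataFrame:
    """Spearman rank correlation of each covariate column against a PK parameter.

    Mid-rank ties, two-sided p.  Constant covariates are flagged with
    undefined rho rather than dropped silently.
    """
    parameter = np.asarray(parameter, dtype=float)
    if len(covariates) != len(parameter):
        raise ValidationError("covariate table and parameter vector lengths differ")
    rows = []
    for name in covariates.columns:
        x = pd.to_numeric(covariates[name], errors="coerce").to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(parameter))
        n = int(mask.sum())
        if n < 3:
            raise ValidationError(f"covariate {name!r}: fewer than 3 paired values")
        if np.ptp(x[mask]) == 0:
            rows.append({"covariate": name, "n": n, "rho": np.nan, "p": np.nan,
                         "note": "constant covariate"})
            continue
        rho, p = stats.spearmanr(x[mask], parameter[mask])
        rows.append({"covariate": name, "n": n, "rho": float(rho), "p": float(p), "note": ""})
    return pd.DataFrame(rows)
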