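"""Case-control statistics for biallelic loci: Hardy-Weinberg exact test,
allele frequencies, the four standard inheritance models with OR/CI/p/AIC,
haplotype EM with linkage-disequilibrium measures, diagnostic performance,
two-locus allele burden, and chi-square power.

The expansion locus is collapsed to two alleles (N = normal, X = expanded,
i.e. > 40 CTG triplets) and the rs613872 SNP to T/G (G the risk allele), so
every locus is analysed as an ordinary biallelic marker.  Model fitting
mirrors the SNPStats conventions: logistic regression of case status on a
genotype coding (codominant: two indicators; dominant / recessive: one;
log-additive: allele dose), likelihood-ratio p-values against the
covariate-only null, Wald confidence intervals, and AIC = 2k - 2 log L for
model selection.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "GenotypeCounts",
    "InheritanceModel",
    "OddsRatio",
    "AssocResult",
    "LdEstimate",
    "PowerSpec",
    "hwe_exact",
    "allele_frequency",
    "fit_inheritance_model",
    "fit_all_models",
    "select_model",
    "haplotype_em",
    "haplotype_loglik",
    "haplotype_case_control_or",
    "diagnostic_performance",
    "allele_burden",
    "chisq_power",
]


# ---------------------------------------------------------------------------
# genotype counts

@dataclass(frozen=True)
class GenotypeCounts:
    """Per-status genotype counts at one biallelic locus.

    Counts are ordered (ref-homozygote, heterozygote, risk-homozygote),
    e.g. (N/N, N/X, X/X) for the expansion or (T/T, G/T, G/G) for the SNP.
    """

    controls: tuple[int, int, int]
    cases: tuple[int, int, int]
    genotype_labels: tuple[str, str, str] = ("A/A", "A/B", "B/B")

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.controls + self.cases):
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_controls(self) -> int:
        return sum(self.controls)

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    def percentages(self, status: str, decimals: int = 1) -> tuple[float, ...]:
        """Genotype percentages within one status group (table-style rounding)."""
        counts = self.cases if status == "case" else self.controls
        total = sum(counts)
        if total == 0:
            raise ValueError("empty status group")
        return tuple(round(100.0 * c / total, decimals) for c in counts)


def allele_frequency(counts: tuple[int, int, int]) -> float:
    """Frequency of the risk allele from (ref-hom, het, risk-hom) counts."""
    total = sum(counts)
    if total == 0:
        raise ValueError("cannot compute an allele frequency from zero subjects")
    return (counts[1] + 2 * counts[2]) / (2 * total)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test

def hwe_exact(counts: tuple[int, int, int]) -> float:
    """Exact conditional Hardy-Weinberg test for one biallelic locus.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of the same parity, summing the probabilities of all
    configurations no more likely than the observed one (the standard exact
    test of HWE).  A monomorphic locus is trivially in equilibrium (p = 1).
    """
    hom_ref, het, hom_alt = counts
    if min(counts) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_ref + het + hom_alt
    n_rare = het + 2 * min(hom_ref, hom_alt)
    if n == 0 or n_rare == 0:
        return 1.0

    def log_prob(n_het: int) -> float:
        # P(het | allele counts) ∝ 2^het * n! / (hom_ref! het! hom_alt!)
        n_hom_rare = (n_rare - n_het) // 2
        n_hom_common = n - n_het - n_hom_rare
        return (
            n_het * math.log(2.0)
            + gammaln(n + 1)
            - gammaln(n_het + 1)
            - gammaln(n_hom_rare + 1)
            - gammaln(n_hom_common + 1)
            - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
        )

    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logs = np.array([log_prob(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[np.where(hets == het)[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# inheritance models

class InheritanceModel(str, enum.Enum):
    CODOMINANT = "codominant"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    LOG_ADDITIVE = "log-additive"


@dataclass(frozen=True)
class OddsRatio:
    """One genotype contrast's odds ratio with a Wald 95% CI.

    ``estimate`` is NaN when a zero cell makes the OR non-identifiable;
    ``one_sided`` marks the matching open-ended confidence bound (the
    table convention "NA (0.00-NA)").
    """

    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    one_sided: bool = False

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.estimate)


@dataclass
class AssocResult:
    model: InheritanceModel
    odds_ratios: list[OddsRatio]
    p_value: float
    aic: float
    n_params: int
    loglik: float
    adjusted: bool = False
    separation: bool = False


def _genotype_design(g: np.ndarray, model: InheritanceModel) -> np.ndarray:
    """Code genotype dose 0/1/2 for one inheritance model."""
    if model is InheritanceModel.CODOMINANT:
        return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    if model is InheritanceModel.DOMINANT:
        return (g >= 1).astype(float)[:, None]
    if model is InheritanceModel.RECESSIVE:
        return (g == 2).astype(float)[:, None]
    return g.astype(float)[:, None]  # log-additive dose


def _contrast_labels(model: InheritanceModel, labels: tuple[str, str, str]) -> list[str]:
    aa, ab, bb = labels
    if model is InheritanceModel.CODOMINANT:
        return [f"{ab} vs {aa}", f"{bb} vs {aa}"]
    if model is InheritanceModel.DOMINANT:
        return [f"{ab}-{bb} vs {aa}"]
    if model is InheritanceModel.RECESSIVE:
        return [f"{bb} vs {aa}-{ab}"]
    return ["per risk allele"]


def _zero_cell_contrasts(counts: GenotypeCounts, model: InheritanceModel) -> list[bool]:
    """Which contrasts have a zero cell in their collapsed 2x2 table."""
    ctrl, case = counts.controls, counts.cases
    tables: list[tuple[int, int, int, int]]
    if model is InheritanceModel.CODOMINANT:
        tables = [
            (case[1], ctrl[1], case[0], ctrl[0]),
            (case[2], ctrl[2], case[0], ctrl[0]),
        ]
    elif model is InheritanceModel.DOMINANT:
        tables = [(case[1] + case[2], ctrl[1] + ctrl[2], case[0], ctrl[0])]
    elif model is InheritanceModel.RECESSIVE:
        tables = [(case[2], ctrl[2], case[0] + case[1], ctrl[0] + ctrl[1])]
    else:  # log-additive: allele-level 2x2
        tables = [
            (case[1] + 2 * case[2], ctrl[1] + 2 * ctrl[2],
             2 * case[0] + case[1], 2 * ctrl[0] + ctrl[1])
        ]
    return [min(t) == 0 for t in tables]


def _expand_counts(counts: GenotypeCounts) -> pd.DataFrame:
    rows = []
    for status, triple in ((0, counts.controls), (1, counts.cases)):
        for g, k in enumerate(triple):
            rows.extend([(status, g)] * k)
    return pd.DataFrame(rows, columns=["status", "genotype"])


def fit_inheritance_model(
    data: GenotypeCounts | pd.DataFrame,
    model: InheritanceModel | str,
    covariates: list[str] | None = None,
) -> AssocResult:
    """Fit one inheritance model by logistic regression.

    ``data`` is either a :class:`GenotypeCounts` table (unadjusted fit) or
    a per-subject DataFrame with columns ``status`` (0/1), ``genotype``
    (risk-allele dose 0/1/2) and any covariate columns (e.g. sex, age).
    Without covariates the dominant/recessive odds ratios equal the 2x2
    cross-product ratios exactly.  Contrasts with a zero cell are reported
    NA with a one-sided CI flag instead of a Haldane-corrected estimate.
    """
    model = InheritanceModel(model)
    labels = ("A/A", "A/B", "B/B")
    zero_flags: list[bool] | None = None
    if isinstance(data, GenotypeCounts):
        labels = data.genotype_labels
        zero_flags = _zero_cell_contrasts(data, model)
        df = _expand_counts(data)
        covariates = None
    else:
        df = data
    if df["status"].nunique() < 2:
        raise ValueError("both case and control subjects are required")

    g = df["genotype"].to_numpy()
    X = _genotype_design(g, model)
    cov_arr = df[covariates].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    exog = sm.add_constant(np.column_stack([X, cov_arr]), has_constant="add")
    y = df["status"].to_numpy(dtype=float)

    fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
    exog0 = sm.add_constant(cov_arr, has_constant="add")
    fit0 = sm.GLM(y, exog0, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)

    k_geno = X.shape[1]
    params = fit.params[1 : 1 + k_geno]
    ses = fit.bse[1 : 1 + k_geno]
    separation = bool(np.any(np.abs(params) > 15))

    if zero_flags is None:
        zero_flags = [bool(abs(b) > 15) for b in params]
    contrasts = _contrast_labels(model, labels)
    z = sps.norm.ppf(0.975)
    ors: list[OddsRatio] = []
    for name, b, se, zero in zip(contrasts, params, ses, zero_flags):
        if zero:
            ors.append(OddsRatio(name, float("nan"), 0.0, float("inf"), one_sided=True))
        else:
            ors.append(
                OddsRatio(name, math.exp(b), math.exp(b - z * se), math.exp(b + z * se))
            )

    lrt = 2.0 * (fit.llf - fit0.llf)
    p = float(sps.chi2.sf(max(lrt, 0.0), df=k_geno))
    n_params = int(exog.shape[1])
    return AssocResult(
        model=model,
        odds_ratios=ors,
        p_value=p,
        aic=float(2 * n_params - 2 * fit.llf),
        n_params=n_params,
        loglik=float(fit.llf),
        adjusted=bool(covariates),
        separation=separation,
    )


def fit_all_models(
    data: GenotypeCounts | pd.DataFrame, covariates: list[str] | None = None
) -> list[AssocResult]:
    return [fit_inheritance_model(data, m, covariates) for m in InheritanceModel]


def select_model(results: list[AssocResult]) -> AssocResult:
    """Pick the minimum-AIC model; ties break toward fewer parameters."""
    if len(results) < 2:
        raise ValueError("model selection needs at least two fitted models")
    return min(results, key=lambda r: (r.aic, r.n_params))


# ---------------------------------------------------------------------------
# haplotype EM and linkage disequilibrium

@dataclass
class LdEstimate:
    """Maximum-likelihood haplotype frequencies and LD summaries.

    Haplotype order: (AB, Ab, aB, ab) with A/B the risk alleles at the two
    loci.  ``d_prime`` and ``r`` are NaN (with a note) when a locus is
    monomorphic.
    """

    haplotype_freqs: np.ndarray
    d: float
    d_prime: float
    r: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)
    note: str = ""


def _genotype_table(dose_a: np.ndarray, dose_b: np.ndarray) -> np.ndarray:
    table = np.zeros((3, 3))
    for i, j in zip(dose_a, dose_b):
        table[int(i), int(j)] += 1
    return table


def haplotype_loglik(freqs: np.ndarray, table: np.ndarray) -> float:
    """Observed-data log-likelihood of a 3x3 two-locus genotype table
    under random mating, given haplotype frequencies (AB, Ab, aB, ab)."""
    pAB, pAb, paB, pab = np.clip(freqs, 1e-300, None)
    # genotype probability = sum over unordered haplotype pairs
    probs = np.empty((3, 3))
    h = {(1, 1): pAB, (1, 0): pAb, (0, 1): paB, (0, 0): pab}
    for i in range(3):
        for j in range(3):
            total = 0.0
            for a1 in (0, 1):
                for b1 in (0, 1):
                    a2, b2 = i - a1, j - b1
                    if a2 in (0, 1) and b2 in (0, 1):
                        total += h[(a1, b1)] * h[(a2, b2)]
            probs[i, j] = total
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    mask = table > 0
    return float((table[mask] * logp[mask]).sum())


def haplotype_em(
    dose_a: np.ndarray,
    dose_b: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> LdEstimate:
    """EM estimation of two-locus haplotype frequencies from unphased
    genotypes (risk-allele doses 0/1/2 at each locus).

    Phase is ambiguous only for double heterozygotes; EM splits them
    between AB/ab and Ab/aB in proportion to the current frequency
    products.  Convergence when the largest frequency change falls below
    ``tol`` (or after ``max_iter`` iterations).
    """
    dose_a = np.asarray(dose_a, dtype=int)
    dose_b = np.asarray(dose_b, dtype=int)
    if dose_a.shape != dose_b.shape or dose_a.ndim != 1:
        raise ValueError("locus dose vectors must be equal-length 1-D arrays")
    table = _genotype_table(dose_a, dose_b)
    n = len(dose_a)
    pA = dose_a.mean() / 2.0
    pB = dose_b.mean() / 2.0

    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        freqs = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
        return LdEstimate(
            haplotype_freqs=freqs, d=0.0, d_prime=float("nan"), r=float("nan"),
            loglik=haplotype_loglik(freqs, table), n_iter=0, converged=True,
            note="monomorphic locus: LD undefined",
        )

    freqs = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    n_dh = table[1, 1]  # double heterozygotes
    path = [haplotype_loglik(freqs, table)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pAB, pAb, paB, pab = freqs
        # E-step: expected fraction of double hets in AB/ab phase
        denom = pAB * pab + pAb * paB
        w = 0.5 if denom == 0 else (pAB * pab) / denom
        # M-step: haplotype counts from unambiguous genotypes + split hets
        cAB = 2 * table[2, 2] + table[2, 1] + table[1, 2] + w * n_dh
        cAb = 2 * table[2, 0] + table[2, 1] + table[1, 0] + (1 - w) * n_dh
        caB = 2 * table[0, 2] + table[0, 1] + table[1, 2] + (1 - w) * n_dh
        cab = 2 * table[0, 0] + table[0, 1] + table[1, 0] + w * n_dh
        new = np.array([cAB, cAb, caB, cab]) / (2.0 * n)
        path.append(haplotype_loglik(new, table))
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            converged = True
            break
        freqs = new

    pAB = float(freqs[0])
    d = pAB - pA * pB
    if d >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = d / d_max if d_max > 0 else 0.0
    r = d / math.sqrt(pA * (1 - pA) * pB * (1 - pB))
    return LdEstimate(
        haplotype_freqs=freqs, d=float(d), d_prime=float(d_prime), r=float(r),
        loglik=path[-1], n_iter=it, converged=converged, loglik_path=path,
    )


def haplotype_case_control_or(
    case_est: LdEstimate, control_est: LdEstimate, n_cases: int, n_controls: int
) -> tuple[float, bool]:
    """Odds ratio of the double-risk (AB) haplotype frequency between
    statuses; flagged unstable when any haplotype frequency is below one
    chromosome's worth (1 / 2n) in either group."""
    fc = float(case_est.haplotype_freqs[0])
    f0 = float(control_est.haplotype_freqs[0])
    unstable = bool(
        (case_est.haplotype_freqs < 1.0 / (2 * n_cases)).any()
        or (control_est.haplotype_freqs < 1.0 / (2 * n_controls)).any()
    )
    if f0 in (0.0, 1.0) or fc in (0.0, 1.0):
        return float("inf") if fc > f0 else 0.0, True
    return (fc / (1 - fc)) / (f0 / (1 - f0)), unstable


# ---------------------------------------------------------------------------
# diagnostic performance, allele burden, power

def diagnostic_performance(
    carrier: np.ndarray, disease: np.ndarray
) -> tuple[float, float]:
    """Sensitivity and specificity of carrier status for disease status."""
    carrier = np.asarray(carrier, dtype=bool)
    disease = np.asarray(disease, dtype=bool)
    n_case = int(disease.sum())
    n_ctrl = int((~disease).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both cases and controls are required")
    sensitivity = float((carrier & disease).sum() / n_case)
    specificity = float((~carrier & ~disease).sum() / n_ctrl)
    return sensitivity, specificity


def allele_burden(x_dose: int | None, g_dose: int | None) -> tuple[int, str] | None:
    """Total pathological-allele burden across the two *TCF4* loci.

    Sums the expanded-allele count (0-2) and risk-G-allele count (0-2) and
    bins it as '0-1' (likely other-gene aetiology), '2' (grey zone: effect
    depends on cis/trans phase) or '3-4' (both chromosomes affected).
    Missing genotypes propagate as None.
    """
    if x_dose is None or g_dose is None:
        return None
    if not (0 <= x_dose <= 2 and 0 <= g_dose <= 2):
        raise ValueError("allele doses must be in 0..2")
    burden = x_dose + g_dose
    category = "0-1" if burden <= 1 else ("2" if burden == 2 else "3-4")
    return burden, category


@dataclass(frozen=True)
class PowerSpec:
    """Chi-square power computation inputs: Cohen's effect size w, test
    degrees of freedom, total N and significance level."""

    effect_size_w: float
    df: int
    n_total: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.effect_size_w < 0 or self.n_total < 1 or self.df < 1:
            raise ValueError("invalid power specification")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def chisq_power(spec: PowerSpec) -> float:
    """Power of a chi-square test: P(noncentral chi2(df, N w^2) > crit)."""
    crit = sps.chi2.ppf(1 - spec.alpha, spec.df)
    lam = spec.n_total * spec.effect_size_w**2
    return float(sps.ncx2.sf(crit, spec.df, lam)) if lam > 0 else spec.alpha
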