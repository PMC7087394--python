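"""Rule-based phenome scan of a genetic risk score against every trait.

Mirrors the automated regression battery used in biobank phenome scans:
trait type is inferred from the data (or taken from a declared kind),
continuous traits are inverse-normal rank transformed, and the score is
tested with linear, logistic, ordered-logistic or multinomial-logistic
regression as appropriate. Multiple testing is handled by the rank-based
5% false-discovery-rate threshold P_t(rank) = q * rank / n and by
Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import InputError, ParameterError

P_FLOOR = 2.23e-308  # smallest p distinguishable from zero in double precision


class NoVariationError(InputError):
    """Trait column is constant and cannot be scanned."""


@dataclass
class ScanResult:
    trait: str
    test: str | None = None
    n: int = 0
    beta: float | None = None
    se: float | None = None
    pval: float | None = None
    category: str = ""
    skip_reason: str | None = None

    @property
    def tested(self) -> bool:
        return self.pval is not None


@dataclass(frozen=True)
class ThresholdReport:
    n_tests: int
    fdr_threshold: float
    fdr_rank: int
    n_fdr: int
    bonferroni_threshold: float
    n_bonf: int


@dataclass(frozen=True)
class ScanOptions:
    """Tunable scan rules (all configurable; defaults documented in docs)."""

    case_floor: int = 50            # minimum minority-class count for binary traits
    max_ordered_levels: int = 20    # integer-coded distinct values treated as ordered
    int_offset: float = 0.375       # Blom constant in the rank transform
    q_fdr: float = 0.05
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# Trait typing and transformation
# ---------------------------------------------------------------------------

def infer_trait_type(values, declared: str | None = None,
                     max_ordered_levels: int = 20) -> str:
    """Classify a trait column as continuous/binary/ordered/unordered.

    A declared kind wins. Otherwise: exactly two distinct non-missing values
    is binary; integer-coded data with at most ``max_ordered_levels`` distinct
    values is ordered; non-numeric codes are unordered; anything else is
    continuous. A constant column raises :class:`NoVariationError`.
    """
    if declared is not None:
        return declared
    s = pd.Series(values).dropna()
    distinct = s.unique()
    if len(distinct) < 2:
        raise NoVariationError("no variation")
    if len(distinct) == 2:
        return "binary"
    numeric = pd.to_numeric(s, errors="coerce")
    if numeric.isna().any():
        return "unordered"
    vals = numeric.to_numpy(dtype=float)
    if np.allclose(vals, np.round(vals)) and len(distinct) <= max_ordered_levels:
        return "ordered"
    return "continuous"


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Blom-style inverse normal rank transform, ties averaged.

    Maps the rank r of each non-missing value through
    Phi^-1((r - offset) / (n + 1 - 2*offset)); missing entries stay missing.
    """
    x = pd.Series(values).to_numpy(dtype=float)
    mask = np.isfinite(x)
    if mask.sum() == 0:
        raise InputError("all values missing")
    if mask.sum() < 2:
        raise InputError("need >= 2 non-missing values")
    ranks = stats.rankdata(x[mask], method="average")
    n = mask.sum()
    out = np.full_like(x, np.nan)
    out[mask] = special.ndtri((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return out


# ---------------------------------------------------------------------------
# Per-trait regression dispatch
# ---------------------------------------------------------------------------

def scan_trait(
    score: np.ndarray,
    values,
    kind: str,
    covariates: np.ndarray | None = None,
    options: ScanOptions | None = None,
    trait: str = "",
    category: str = "",
) -> ScanResult:
    """Test one trait against the score with the regression matching its kind.

    Continuous traits are inverse-normal transformed first. Two-sided p-values
    come from the large-sample normal for linear/logistic/ordered models; the
    multinomial test reports only a likelihood-ratio p with levels-1 degrees
    of freedom. Non-convergence or a binary trait with fewer minority cases
    than the configured floor produces a skipped result, never an exception.
    """
    import statsmodels.api as sm

    options = options or ScanOptions()
    score = np.asarray(score, dtype=float)
    raw = pd.Series(values)
    numeric_kinds = ("continuous", "binary", "ordered")
    y = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float) if kind in numeric_kinds else None

    mask = np.ones(len(raw), dtype=bool)
    if y is not None:
        mask &= np.isfinite(y)
    else:
        mask &= raw.notna().to_numpy()
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(raw):
            covariates = covariates.T
        mask &= np.isfinite(covariates).all(axis=1)
    n_used = int(mask.sum())
    res = ScanResult(trait=trait, n=n_used, category=category)
    if n_used < 3:
        res.skip_reason = "too few observations"
        return res

    s = score[mask]
    cov = covariates[mask] if covariates is not None else None
    base = np.ones((n_used, 1)) if cov is None else np.column_stack([np.ones(n_used), cov])
    X = np.column_stack([base, s])

    try:
        if kind == "continuous":
            res.test = "linear"
            yt = inverse_normal_transform(y[mask], options.int_offset)
            fit = sm.OLS(yt, X).fit()
            res.beta, res.se = float(fit.params[-1]), float(fit.bse[-1])
        elif kind == "binary":
            res.test = "logistic"
            yb = _as_binary(y[mask])
            minority = int(min(yb.sum(), n_used - yb.sum()))
            if minority < options.case_floor:
                res.skip_reason = f"minority class {minority} below floor {options.case_floor}"
                return res
            fit = sm.Logit(yb, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                res.skip_reason = "non-convergence"
                return res
            res.beta, res.se = float(fit.params[-1]), float(fit.bse[-1])
        elif kind == "ordered":
            from statsmodels.miscmodels.ordinal_model import OrderedModel
            res.test = "ordered_logistic"
            codes = _as_ordered_codes(y[mask])
            exog = X[:, 1:]  # OrderedModel estimates its own cut-points
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = OrderedModel(codes, exog, distr="logit").fit(method="bfgs", disp=0)
            res.beta, res.se = float(fit.params[exog.shape[1] - 1]), float(fit.bse[exog.shape[1] - 1])
        elif kind == "unordered":
            res.test = "multinomial"
            labels = pd.Categorical(raw[mask])
            codes = _most_frequent_reference(labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.MNLogit(codes, X).fit(disp=0, maxiter=200)
                reduced = sm.MNLogit(codes, base).fit(disp=0, maxiter=200)
            lrt = 2.0 * (full.llf - reduced.llf)
            df = len(labels.categories) - 1
            res.pval = _clip_p(stats.chi2.sf(max(lrt, 0.0), df))
            return res
        else:
            raise ParameterError(f"unknown trait kind {kind!r}")
    except (np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
        res.skip_reason = f"fit failed: {type(exc).__name__}"
        return res

    if res.se is None or not np.isfinite(res.se) or res.se == 0:
        res.skip_reason = "degenerate standard error"
        res.beta = res.se = None
        return res
    res.pval = _clip_p(2.0 * special.ndtr(-abs(res.beta / res.se)))
    return res


def _as_binary(y: np.ndarray) -> np.ndarray:
    lo, hi = np.sort(np.unique(y))
    return (y == hi).astype(float)


def _as_ordered_codes(y: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.unique(y), y).astype(int)


def _most_frequent_reference(labels: pd.Categorical) -> np.ndarray:
    counts = pd.Series(labels).value_counts()
    order = [counts.idxmax()] + [c for c in labels.categories if c != counts.idxmax()]
    return labels.rename_categories({c: i for i, c in enumerate(order)}).codes.astype(int)


def _clip_p(p: float) -> float:
    return float(min(max(p, P_FLOOR), 1.0))


# ---------------------------------------------------------------------------
# Multiple-testing thresholds
# ---------------------------------------------------------------------------

def fdr_threshold(pvalues, q: float = 0.05):
    """Rank-based FDR threshold: largest rank r with p_(r) < q*r/n.

    Returns ``(threshold, rank, flags)`` where threshold = q*rank/n (0 when no
    rank passes) and flags marks tests with p strictly below the threshold.
    The strict inequality follows the printed rule; ties at the threshold are
    non-discoveries.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise InputError("need a non-empty 1-d p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ranks = np.arange(1, n + 1)
    passing = sorted_p < q * ranks / n
    if not passing.any():
        return 0.0, 0, np.zeros(n, dtype=bool)
    rank = int(ranks[passing][-1])
    threshold = q * rank / n
    return float(threshold), rank, p < threshold


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha divided by the number of tests performed."""
    if n_tests < 1:
        raise InputError("n_tests must be >= 1")
    return alpha / n_tests


def qq_data(pvalues, floor: float = P_FLOOR) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a QQ plot.

    Observed p are sorted ascending; expected quantiles are (i - 0.5)/n.
    P-values below the representable floor are clipped and flagged.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    n = len(p)
    sorted_p = np.sort(p)
    floored = sorted_p < floor
    return pd.DataFrame({
        "expected": -np.log10((np.arange(1, n + 1) - 0.5) / n),
        "observed": -np.log10(np.maximum(sorted_p, floor)),
        "floored": floored,
    })


# ---------------------------------------------------------------------------
# Full scan
# ---------------------------------------------------------------------------

def run_phewas(
    cohort,
    score: np.ndarray,
    traits: list | None = None,
    covariates: np.ndarray | None = None,
    options: ScanOptions | None = None,
):
    """Scan the score against every phenome trait; returns results + report.

    Traits are processed in sorted-name order; every trait yields either a
    tested ScanResult or one carrying a skip reason. Thresholds are computed
    on the tested subset only. Covariates default to age plus the cohort's
    genetic principal components.
    """
    options = options or ScanOptions()
    names = sorted(traits if traits is not None else cohort.phenome.columns)
    if not names:
        raise InputError("empty phenome: nothing to scan")
    if covariates is None:
        covariates = cohort.default_covariates()

    results = []
    for name in names:
        values = cohort.phenome[name]
        spec = cohort.trait_specs.get(name)
        category = spec.category if spec is not None else ""
        try:
            kind = infer_trait_type(values, declared=spec.kind if spec else None)
        except NoVariationError:
            results.append(ScanResult(trait=name, category=category,
                                      skip_reason="no variation"))
            continue
        results.append(scan_trait(score, values, kind, covariates,
                                  options, trait=name, category=category))

    tested = [r for r in results if r.tested]
    if tested:
        pvals = np.array([r.pval for r in tested])
        fdr_t, fdr_rank, _ = fdr_threshold(pvals, options.q_fdr)
        bonf_t = bonferroni_threshold(len(tested), options.alpha)
        report = ThresholdReport(
            n_tests=len(tested), fdr_threshold=fdr_t, fdr_rank=fdr_rank,
            n_fdr=int(np.sum(pvals < fdr_t)),
            bonferroni_threshold=bonf_t, n_bonf=int(np.sum(pvals < bonf_t)),
        )
    else:
        report = ThresholdReport(0, 0.0, 0, 0, float("nan"), 0)
    return results, report


def results_frame(results: list, report: ThresholdReport | None = None) -> pd.DataFrame:
    """Tabular scan output, one row per trait."""
    rows = []
    for r in results:
        rows.append({
            "trait": r.trait, "category": r.category, "test": r.test, "n": r.n,
            "beta": r.beta, "se": r.se, "pval": r.pval,
            "fdr_pass": bool(r.tested and report and report.fdr_threshold > 0
                             and r.pval < report.fdr_threshold),
            "bonf_pass": bool(r.tested and report and r.pval < report.bonferroni_threshold),
            "skip_reason": r.skip_reason or "",
        })
    return pd.DataFrame(rows)
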