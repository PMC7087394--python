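"""One- and two-sample Mendelian randomization estimators and diagnostics.

Two-sample methods operate on harmonized per-variant summary pairs
(beta_exp, se_exp, beta_out, se_out): Wald ratios pooled by fixed- or
random-effects inverse-variance weighting, MR-Egger regression with an
unconstrained intercept, the weighted median, simple/weighted mode-based
estimation, and the MR-PRESSO residual-sum-and-outlier framework. One-sample
methods (2SLS with bootstrap standard errors, multivariable MR) operate on
individual-level cohorts.

Estimates are computed on the natural per-unit-increase scale of the
exposure; :func:`per_year_decrease` flips the orientation at the reporting
layer so public outputs read "per year decrease in age at menarche".
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import EstimationError, InputError, MethodError

Z95 = float(stats.norm.ppf(0.975))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMES = ({"A", "T"}, {"C", "G"})


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    extras: dict = field(default_factory=dict)


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outlier_p: pd.Series
    outliers: list
    beta_raw: MREstimate
    beta_adjusted: MREstimate | None
    distortion_p: float | None
    report_adjusted: bool


def _normal_estimate(method, beta, se, n_snps, extras=None) -> MREstimate:
    p = float(2.0 * special.ndtr(-abs(beta / se))) if se > 0 else 0.0
    return MREstimate(method, float(beta), float(se),
                      float(beta - Z95 * se), float(beta + Z95 * se),
                      p, int(n_snps), extras or {})


def per_year_decrease(est: MREstimate) -> MREstimate:
    """Reporting orientation: flip the estimate to per-unit *decrease*."""
    return dataclasses.replace(
        est, beta=-est.beta, ci_low=-est.ci_high, ci_high=-est.ci_low)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def harmonize(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    palindrome_eaf_window: float = 0.08,
) -> pd.DataFrame:
    """Align outcome summary rows to the exposure's effect allele.

    Swapped effect/other alleles flip the outcome beta (and frequency);
    strand mismatches are resolved by complementing the outcome alleles.
    Palindromic (A/T or C/G) variants whose exposure frequency is within
    ``palindrome_eaf_window`` of 0.5 are dropped as strand-ambiguous.
    Returns an MRInput table (rsid, beta_exp, se_exp, beta_out, se_out,
    palindromic, flipped); dropped rows with reasons sit in
    ``result.attrs["dropped"]``.
    """
    exp = _std_stats(exposure_stats, "exp")
    out = _std_stats(outcome_stats, "out")
    merged = exp.merge(out, on="rsid", how="inner", suffixes=("", "_o"))
    if merged.empty:
        raise InputError("no shared rsids between exposure and outcome")

    rows, dropped = [], []
    for _, r in merged.iterrows():
        ea_e, oa_e = r["effect_allele"], r["other_allele"]
        ea_o, oa_o = r["effect_allele_o"], r["other_allele_o"]
        palindromic = {ea_e, oa_e} in _PALINDROMES
        if palindromic and min(r["eaf"], 1.0 - r["eaf"]) > 0.5 - palindrome_eaf_window:
            dropped.append((r["rsid"], "ambiguous palindrome"))
            continue
        flipped = False
        if (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (oa_o, ea_o) == (ea_e, oa_e):
            flipped = True
        elif not palindromic and (_COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)) == (ea_e, oa_e):
            pass
        elif not palindromic and (_COMPLEMENT.get(oa_o), _COMPLEMENT.get(ea_o)) == (ea_e, oa_e):
            flipped = True
        else:
            dropped.append((r["rsid"], f"allele mismatch {ea_o}/{oa_o} vs {ea_e}/{oa_e}"))
            continue
        rows.append({
            "rsid": r["rsid"],
            "beta_exp": r["beta_exp"], "se_exp": r["se_exp"],
            "beta_out": -r["beta_out"] if flipped else r["beta_out"],
            "se_out": r["se_out"],
            "palindromic": palindromic, "flipped": flipped,
        })
    result = pd.DataFrame(rows, columns=["rsid", "beta_exp", "se_exp",
                                         "beta_out", "se_out", "palindromic", "flipped"])
    result.attrs["dropped"] = pd.DataFrame(dropped, columns=["rsid", "reason"])
    return result


def _std_stats(df: pd.DataFrame, role: str) -> pd.DataFrame:
    """Map panel / summary-stat column conventions onto beta_/se_ names."""
    rename = {}
    for generic in ("beta", "se", "pval"):
        for cand in (f"{generic}_exposure", f"{generic}_outcome", generic):
            if cand in df.columns:
                rename[cand] = f"{generic}_{role}"
                break
    need = {"rsid", "effect_allele", "other_allele"}
    if not need <= set(df.columns):
        raise InputError(f"summary table missing columns {sorted(need - set(df.columns))}")
    out = df.rename(columns=rename)
    keep = ["rsid", "effect_allele", "other_allele", f"beta_{role}", f"se_{role}"]
    if "eaf" in out.columns:
        keep.append("eaf")
    missing = [c for c in keep if c not in out.columns]
    if missing:
        raise InputError(f"summary table missing columns {missing}")
    dup = out["rsid"][out["rsid"].duplicated()]
    if len(dup):
        raise InputError(f"duplicate rsids: {sorted(set(dup))}")
    return out[keep]


def mr_input_from_arrays(beta_exp, se_exp, beta_out, se_out, rsid=None) -> pd.DataFrame:
    """Convenience constructor for already-harmonized summary pairs."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    if rsid is None:
        rsid = [f"rs{i + 1}" for i in range(len(beta_exp))]
    df = pd.DataFrame({
        "rsid": rsid, "beta_exp": beta_exp,
        "se_exp": np.asarray(se_exp, dtype=float),
        "beta_out": np.asarray(beta_out, dtype=float),
        "se_out": np.asarray(se_out, dtype=float),
        "palindromic": False, "flipped": False,
    })
    if (df["se_exp"] <= 0).any() or (df["se_out"] <= 0).any():
        raise InputError("standard errors must be positive")
    return df


# ---------------------------------------------------------------------------
# Wald ratios and IVW
# ---------------------------------------------------------------------------

def wald_ratios(mr_input: pd.DataFrame, second_order: bool = False) -> pd.DataFrame:
    """Per-variant causal ratios beta_out/beta_exp with delta-method SEs.

    The default first-order SE, |se_out/beta_exp|, ignores exposure
    uncertainty (standard for strong instruments); ``second_order`` adds the
    exposure-variance term. Rows with beta_exp = 0 are excluded with a
    warning.
    """
    d = mr_input
    zero = d["beta_exp"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} variant(s) with beta_exp = 0",
                      stacklevel=2)
        d = d[~zero]
    if d.empty:
        raise MethodError("no usable variants (all beta_exp = 0)")
    be, bo = d["beta_exp"].to_numpy(), d["beta_out"].to_numpy()
    so, se_ = d["se_out"].to_numpy(), d["se_exp"].to_numpy()
    ratio = bo / be
    if second_order:
        se = np.sqrt(so**2 / be**2 + bo**2 * se_**2 / be**4)
    else:
        se = np.abs(so / be)
    return pd.DataFrame({"rsid": d["rsid"].to_numpy(), "ratio": ratio, "se": se})


def ivw(mr_input: pd.DataFrame, model: str = "random") -> MREstimate:
    """Inverse-variance-weighted pooling of Wald ratios.

    Fixed effects: beta = sum(w r)/sum(w) with w = 1/se^2. Random effects add
    a DerSimonian–Laird tau^2 to every variance. Heterogeneity is summarized
    by Cochran's Q and I^2 = max(0, (Q - df)/Q).
    """
    if model not in ("fixed", "random"):
        raise MethodError(f"unknown IVW model {model!r}")
    w_df = wald_ratios(mr_input)
    r, se = w_df["ratio"].to_numpy(), w_df["se"].to_numpy()
    m = len(r)
    w = 1.0 / se**2
    beta_f = float(np.sum(w * r) / np.sum(w))
    Q = float(np.sum(w * (r - beta_f) ** 2))
    df = m - 1
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    Q_p = float(stats.chi2.sf(Q, df)) if df > 0 else float("nan")
    tau2 = 0.0
    if model == "random":
        if m < 2:
            warnings.warn("single variant: random-effects falls back to fixed",
                          stacklevel=2)
            model = "fixed"
        else:
            c = np.sum(w) - np.sum(w**2) / np.sum(w)
            tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    if model == "random":
        w_star = 1.0 / (se**2 + tau2)
        beta = float(np.sum(w_star * r) / np.sum(w_star))
        se_pool = float(1.0 / np.sqrt(np.sum(w_star)))
    else:
        beta, se_pool = beta_f, float(1.0 / np.sqrt(np.sum(w)))
    return _normal_estimate(f"ivw_{model}", beta, se_pool, m,
                            {"tau2": tau2, "Q": Q, "Q_p": Q_p, "I2": I2})


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(mr_input: pd.DataFrame) -> MREstimate:
    """Weighted regression of outcome on exposure effects with an intercept.

    Rows are oriented so every beta_exp is non-negative; weights are
    1/se_out^2. The slope is the causal estimate; a non-zero intercept
    indicates unbalanced directional pleiotropy. Standard errors use a
    multiplicative overdispersion scale floored at 1, with two-sided p from
    t with n_snps - 2 degrees of freedom.
    """
    m = len(mr_input)
    if m < 3:
        raise MethodError("MR-Egger needs at least 3 variants")
    sign = np.where(mr_input["beta_exp"].to_numpy() < 0, -1.0, 1.0)
    bx = mr_input["beta_exp"].to_numpy() * sign
    by = mr_input["beta_out"].to_numpy() * sign
    w = 1.0 / mr_input["se_out"].to_numpy() ** 2
    X = np.column_stack([np.ones(m), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, rss_w / (m - 2))
    cov = np.linalg.inv(xtwx) * scale
    se = np.sqrt(np.diag(cov))
    t_p = lambda b, s: float(2.0 * stats.t.sf(abs(b / s), m - 2))
    tcrit = float(stats.t.ppf(0.975, m - 2))
    return MREstimate(
        "egger", float(coef[1]), float(se[1]),
        float(coef[1] - tcrit * se[1]), float(coef[1] + tcrit * se[1]),
        t_p(coef[1], se[1]), m,
        {"intercept": float(coef[0]), "intercept_se": float(se[0]),
         "intercept_p": t_p(coef[0], se[0]), "scale": scale},
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    w = weights / weights.sum()
    if w.max() > 0.5:
        # exact dominance: a variant with a strict weight majority is the median
        return float(ratios[np.argmax(w)])
    order = np.argsort(ratios)
    r, w = ratios[order], w[order]
    cum = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, cum, r))


def weighted_median(
    mr_input: pd.DataFrame,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median of the Wald ratios (consistent if >= 50% of the weight
    comes from valid instruments), SE by parametric bootstrap of the
    per-variant summary pairs."""
    m = len(mr_input)
    if m < 3:
        raise MethodError("weighted median needs at least 3 variants")
    w_df = wald_ratios(mr_input)
    weights = 1.0 / w_df["se"].to_numpy() ** 2
    if np.all(weights == 0):
        raise MethodError("all weights are zero")
    beta = _weighted_median(w_df["ratio"].to_numpy(), weights)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    be = mr_input["beta_exp"].to_numpy()
    se_e = mr_input["se_exp"].to_numpy()
    bo = mr_input["beta_out"].to_numpy()
    so = mr_input["se_out"].to_numpy()
    boots = np.empty(bootstrap_reps)
    bx = rng.normal(be, se_e, size=(bootstrap_reps, m))
    byy = rng.normal(bo, so, size=(bootstrap_reps, m))
    bx[bx == 0] = np.finfo(float).tiny
    for b in range(bootstrap_reps):
        ratios_b = byy[b] / bx[b]
        weights_b = bx[b] ** 2 / so**2
        boots[b] = _weighted_median(ratios_b, weights_b)
    se = float(np.std(boots, ddof=1))
    est = _normal_estimate("weighted_median", beta, se, m,
                           {"bootstrap_reps": bootstrap_reps})
    return est


# ---------------------------------------------------------------------------
# Mode-based estimation
# ---------------------------------------------------------------------------

def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    s = np.std(ratios, ddof=1) if len(ratios) > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    spread = min(x for x in (s, mad) if x > 0) if (s > 0 or mad > 0) else 0.0
    return phi * 0.9 * spread * len(ratios) ** (-1.0 / 5.0)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, h: float,
                grid_size: int) -> float:
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = np.zeros_like(grid)
    for r_i, w_i in zip(ratios, weights):
        dens += w_i * np.exp(-0.5 * ((grid - r_i) / h) ** 2)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    mr_input: pd.DataFrame,
    weighted: bool = False,
    phi: float = 1.0,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    grid_size: int = 10_000,
    bootstrap_grid: int = 512,
) -> MREstimate:
    """Mode of the smoothed Wald-ratio density (normal kernel).

    The bandwidth is phi times a modified-Silverman scale of the ratios; the
    weighted variant multiplies each kernel by its normalized inverse-variance
    weight. Consistent when the largest homogeneous cluster of ratios comes
    from valid instruments. SE by parametric bootstrap.
    """
    m = len(mr_input)
    if m < 3:
        raise MethodError("mode estimator needs at least 3 variants")
    w_df = wald_ratios(mr_input)
    ratios = w_df["ratio"].to_numpy()
    se_r = w_df["se"].to_numpy()
    weights = (1.0 / se_r**2) if weighted else np.ones(m)
    weights = weights / weights.sum()
    method = "weighted_mode" if weighted else "simple_mode"

    if np.ptp(ratios) == 0.0:
        return _normal_estimate(method, float(ratios[0]), 0.0, m,
                                {"bootstrap_reps": 0, "bandwidth": 0.0})
    h = _mode_bandwidth(ratios, phi)
    if h == 0.0:  # degenerate spread (mad 0); fall back to the range scale
        h = phi * 0.9 * np.ptp(ratios) * m ** (-0.2)
    beta = _mode_point(ratios, weights, h, grid_size)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 43]))
    be = mr_input["beta_exp"].to_numpy()
    se_e = mr_input["se_exp"].to_numpy()
    bo = mr_input["beta_out"].to_numpy()
    so = mr_input["se_out"].to_numpy()
    bx = rng.normal(be, se_e, size=(bootstrap_reps, m))
    byy = rng.normal(bo, so, size=(bootstrap_reps, m))
    bx[bx == 0] = np.finfo(float).tiny
    ratios_b = byy / bx                      # (B, m)
    w_b = (bx**2 / so**2) if weighted else np.ones_like(ratios_b)
    w_b = w_b / w_b.sum(axis=1, keepdims=True)
    s_b = np.std(ratios_b, axis=1, ddof=1)
    mad_b = stats.median_abs_deviation(ratios_b, axis=1, scale="normal")
    spread_b = np.where((s_b > 0) & (mad_b > 0), np.minimum(s_b, mad_b),
                        np.maximum(s_b, mad_b))
    h_b = np.maximum(phi * 0.9 * spread_b * m ** (-0.2), 1e-12)
    lo = ratios_b.min(axis=1) - 3 * h_b
    hi = ratios_b.max(axis=1) + 3 * h_b
    u = np.linspace(0.0, 1.0, bootstrap_grid)
    grid_b = lo[:, None] + (hi - lo)[:, None] * u[None, :]   # (B, G)
    dens = np.zeros_like(grid_b)
    for j in range(m):
        z = (grid_b - ratios_b[:, [j]]) / h_b[:, None]
        dens += w_b[:, [j]] * np.exp(-0.5 * z**2)
    boots = grid_b[np.arange(bootstrap_reps), np.argmax(dens, axis=1)]
    # MAD-based bootstrap scale: robust to stray secondary modes, which
    # otherwise make the plain SD (and hence the CI) badly conservative
    se = float(stats.median_abs_deviation(boots, scale="normal"))
    return _normal_estimate(method, beta, se, m,
                            {"bootstrap_reps": bootstrap_reps, "bandwidth": float(h)})


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_predictions(be, bo, so):
    """Leave-one-out IVW slope and predicted outcome effect per variant."""
    wr = be**2 / so**2          # ratio weights
    r = bo / be
    S1, S0 = np.sum(wr * r, axis=-1, keepdims=True), np.sum(wr, axis=-1, keepdims=True)
    theta_loo = (S1 - wr * r) / (S0 - wr)
    return theta_loo * be


def mr_presso(
    mr_input: pd.DataFrame,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual-sum-and-outlier test.

    The observed statistic is the inverse-variance-weighted residual sum of
    squares of each variant's outcome effect around its leave-one-out IVW
    prediction. The null distribution is built by parametric simulation of
    the full summary table (both exposure and outcome effects) with the
    leave-one-out predictions recomputed on every simulated dataset, which is
    what keeps the global test calibrated. Per-variant outlier p-values are
    Bonferroni-corrected across variants; the outlier-adjusted IVW estimate is
    flagged for reporting only when both the global and the distortion test
    have p < 0.05.
    """
    m = len(mr_input)
    if m < 4:
        raise MethodError("MR-PRESSO needs at least 4 variants")
    be = mr_input["beta_exp"].to_numpy()
    se_e = mr_input["se_exp"].to_numpy()
    bo = mr_input["beta_out"].to_numpy()
    so = mr_input["se_out"].to_numpy()
    if np.any(be == 0):
        raise MethodError("beta_exp = 0 rows must be removed before MR-PRESSO")
    if m / (n_sim + 1) >= outlier_alpha:
        warnings.warn(
            f"n_sim={n_sim} cannot resolve Bonferroni-adjusted outlier "
            f"p-values below {outlier_alpha} for {m} variants", stacklevel=2)

    pred = _loo_predictions(be, bo, so)
    resid2 = (bo - pred) ** 2 / so**2
    rss_obs = float(np.sum(resid2))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 47]))
    be_s = rng.normal(be, se_e, size=(n_sim, m))
    be_s[be_s == 0] = np.finfo(float).tiny
    bo_s = rng.normal(pred, so, size=(n_sim, m))
    pred_s = _loo_predictions(be_s, bo_s, so)
    resid2_s = (bo_s - pred_s) ** 2 / so**2
    rss_s = resid2_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    p_i = (1 + np.sum(resid2_s >= resid2, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_i * m)
    outlier_p = pd.Series(p_adj, index=mr_input["rsid"].to_numpy())
    outliers = list(outlier_p.index[p_adj < outlier_alpha])

    beta_raw = ivw(mr_input, model="fixed")
    beta_adjusted = None
    distortion_p = None
    if outliers and m - len(outliers) >= 2:
        keep = ~mr_input["rsid"].isin(outliers)
        beta_adjusted = ivw(mr_input[keep], model="fixed")
        d_obs = (beta_adjusted.beta - beta_raw.beta) / abs(beta_adjusted.beta) \
            if beta_adjusted.beta != 0 else 0.0
        k = len(outliers)
        d_sim = np.empty(n_sim)
        idx = np.arange(m)
        for s in range(n_sim):
            drop = rng.choice(idx, size=k, replace=False)
            mask = np.ones(m, dtype=bool)
            mask[drop] = False
            est_s = ivw(mr_input[mask], model="fixed")
            d_sim[s] = (est_s.beta - beta_raw.beta) / abs(est_s.beta) \
                if est_s.beta != 0 else 0.0
        distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))

    report_adjusted = bool(
        beta_adjusted is not None and global_p < 0.05
        and distortion_p is not None and distortion_p < 0.05)
    return PressoResult(rss_obs, global_p, outlier_p, outliers,
                        beta_raw, beta_adjusted, distortion_p, report_adjusted)


# ---------------------------------------------------------------------------
# One-sample 2SLS
# ---------------------------------------------------------------------------

def _two_stage(exposure, outcome, score, covariates, binary):
    import statsmodels.api as sm
    n = len(exposure)
    base = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    X1 = np.column_stack([base, score])
    coef1, *_ = np.linalg.lstsq(X1, exposure, rcond=None)
    pred = X1 @ coef1
    X2 = np.column_stack([base, pred])
    if binary:
        fit = sm.Logit(outcome, X2).fit(disp=0, maxiter=100)
        beta2 = float(fit.params[-1])
    else:
        coef2, *_ = np.linalg.lstsq(X2, outcome, rcond=None)
        beta2 = float(coef2[-1])
    return beta2, coef1, X1


def one_sample_mr(
    cohort,
    score: np.ndarray,
    outcome: str,
    covariates: np.ndarray | None = None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    f_floor: float = 10.0,
) -> MREstimate:
    """One-sample MR by two-stage regression with bootstrap standard errors.

    Stage 1 regresses the exposure on the score (plus covariates); stage 2
    regresses the outcome on the genetically predicted exposure (logistic for
    a binary outcome). The SE/CI come from a nonparametric bootstrap over
    individuals re-running both stages. A stage-1 partial F below ``f_floor``
    sets a weak-instrument flag in the extras.
    """
    from .instruments import instrument_strength

    score = np.asarray(score, dtype=float)
    if np.std(score) == 0:
        raise EstimationError("score is constant")
    y = np.asarray(cohort.column(outcome), dtype=float)
    expo = np.asarray(cohort.exposure, dtype=float)
    binary = set(np.unique(y[np.isfinite(y)])) <= {0.0, 1.0}

    beta, _, _ = _two_stage(expo, y, score, covariates, binary)
    strength = instrument_strength(score, expo, covariates)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]))
    n = len(expo)
    boots = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        cov_b = covariates[idx] if covariates is not None else None
        try:
            boots[b], _, _ = _two_stage(expo[idx], y[idx], score[idx], cov_b, binary)
        except Exception:
            boots[b] = np.nan
    boots = boots[np.isfinite(boots)]
    if len(boots) < 2:
        raise EstimationError("bootstrap failed in nearly all replicates")
    se = float(np.std(boots, ddof=1))
    est = _normal_estimate("tsls", beta, se, cohort.dosages.shape[1], {
        "bootstrap_reps": bootstrap_reps,
        "stage1_f": strength.f_statistic,
        "stage1_r2": strength.r_squared,
        "weak_instrument": strength.f_statistic < f_floor,
        "binary_outcome": binary,
        "seed": int(seed),
    })
    if strength.f_statistic < f_floor:
        warnings.warn(f"weak instrument: stage-1 F = {strength.f_statistic:.2f} "
                      f"< {f_floor}", stacklevel=2)
    return est


# ---------------------------------------------------------------------------
# Multivariable MR
# ---------------------------------------------------------------------------

def multivariable_mr(
    cohort,
    scores: dict,
    outcome: str,
    covariates: np.ndarray | None = None,
    bootstrap_reps: int = 500,
    seed: int = 0,
) -> dict:
    """Joint two-stage estimation of several instrumented exposures.

    Each exposure is regressed on *all* scores jointly (stage 1); the outcome
    is then regressed on all predicted exposures together (stage 2), giving
    the direct effect of each exposure conditional on the others — the
    instrumental-variable analogue of multivariable regression. Returns
    a dict of per-exposure estimates. Collinear scores raise an error naming
    the offending pair.
    """
    if len(scores) < 2:
        raise MethodError("multivariable MR needs at least 2 instrumented exposures")
    names = list(scores)
    S = np.column_stack([np.asarray(scores[k], dtype=float) for k in names])
    corr = np.corrcoef(S, rowvar=False)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 1 - 1e-9:
                raise EstimationError(
                    f"collinear scores: {names[i]!r} and {names[j]!r}")
    y = np.asarray(cohort.column(outcome), dtype=float)
    E = np.column_stack([np.asarray(cohort.column(k), dtype=float) for k in names])
    binary = set(np.unique(y[np.isfinite(y)])) <= {0.0, 1.0}

    def fit_once(E_, y_, S_, cov_):
        import statsmodels.api as sm
        n_ = len(y_)
        base = np.ones((n_, 1)) if cov_ is None else np.column_stack([np.ones(n_), cov_])
        X1 = np.column_stack([base, S_])
        coef1, *_ = np.linalg.lstsq(X1, E_, rcond=None)
        pred = X1 @ coef1
        X2 = np.column_stack([base, pred])
        if binary:
            f = sm.Logit(y_, X2).fit(disp=0, maxiter=100)
            return np.asarray(f.params[-len(names):], dtype=float)
        coef2, *_ = np.linalg.lstsq(X2, y_, rcond=None)
        return coef2[-len(names):]

    betas = fit_once(E, y, S, covariates)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 59]))
    n = len(y)
    boots = np.full((bootstrap_reps, len(names)), np.nan)
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        cov_b = covariates[idx] if covariates is not None else None
        try:
            boots[b] = fit_once(E[idx], y[idx], S[idx], cov_b)
        except Exception:
            pass
    ses = np.nanstd(boots, axis=0, ddof=1)
    out = {}
    for k, name in enumerate(names):
        out[name] = _normal_estimate("mvmr", betas[k], float(ses[k]),
                                     cohort.dosages.shape[1],
                                     {"bootstrap_reps": bootstrap_reps,
                                      "binary_outcome": binary})
    return out


# ---------------------------------------------------------------------------
# Cross-cohort heterogeneity
# ---------------------------------------------------------------------------

def cohort_heterogeneity(estimates: list):
    """Cochran's Q, its df and p, and I^2 across cohort-level estimates."""
    if len(estimates) < 2:
        raise InputError("need at least 2 estimates")
    b = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise InputError("all estimates need positive standard errors")
    w = 1.0 / se**2
    pooled = np.sum(w * b) / np.sum(w)
    Q = float(np.sum(w * (b - pooled) ** 2))
    df = len(b) - 1
    p = float(stats.chi2.sf(Q, df))
    I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return Q, df, p, I2
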