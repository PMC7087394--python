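"""Synthetic cohorts with the causal structure assumed by the menarche MR-pheWAS.

The generator emulates a biobank-style design: a panel of independent
(linkage-equilibrium, Hardy–Weinberg) variants jointly explaining a target
fraction of the variance in age at menarche; childhood BMI receiving direct
(horizontally pleiotropic) effects from a designated variant subset; adult BMI
lying downstream of both childhood BMI and the exposure (vertical pleiotropy);
and a phenome of continuous / binary / ordered / unordered traits whose causal
dependence on the exposure is configurable per trait.

All randomness flows from a single integer seed expanded into per-stage
substreams, so adding a trait never perturbs the genotype draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigError, ParameterError

PANEL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta_exposure", "se_exposure", "pval_exposure",
]

SUMMARY_COLUMNS = [
    "rsid", "effect_allele", "other_allele", "eaf",
    "beta_outcome", "se_outcome", "pval_outcome", "n", "error",
]

_ALLELES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Trait specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    """Causal recipe for one phenome trait.

    Parameters
    ----------
    name
        Unique trait identifier.
    kind
        One of ``continuous``, ``binary``, ``ordered``, ``unordered``.
    beta_menarche
        Causal effect of the exposure on the trait's latent scale
        (latent-SD units per year of menarche age).
    mediation_via_bmi
        Fraction of the exposure effect routed through adult BMI, in [0, 1].
    pleiotropy
        Mapping rsid -> direct (horizontal) effect of that variant's dosage
        on the trait latent.
    noise_sd
        Residual SD of the latent trait.
    levels
        Category count for ordered/unordered traits.
    prevalence
        Case fraction for binary traits.
    category
        Free-text grouping carried into scan output.
    """

    name: str
    kind: str = "continuous"
    beta_menarche: float = 0.0
    mediation_via_bmi: float = 0.0
    pleiotropy: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    levels: int | None = None
    prevalence: float | None = None
    category: str = "synthetic"

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "ordered", "unordered"):
            raise ConfigError(f"unknown trait kind {self.kind!r} for {self.name!r}")
        if not 0.0 <= self.mediation_via_bmi <= 1.0:
            raise ConfigError(f"mediation_via_bmi must be in [0,1] for {self.name!r}")
        if self.kind == "binary" and self.prevalence is None:
            object.__setattr__(self, "prevalence", 0.5)
        if self.kind in ("ordered", "unordered") and self.levels is None:
            object.__setattr__(self, "levels", 3)
        if self.levels is not None and self.levels < 2:
            raise ConfigError(f"levels must be >= 2 for {self.name!r}")
        if self.prevalence is not None and not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must be in (0,1) for {self.name!r}")


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration for :func:`simulate_cohort`.

    The defaults encode the study conditions the pipeline targets: exposure
    (age at menarche) mean 12.9 y and SD 1.6 y, BMI mediators on an SD-like
    scale, and no horizontal pleiotropy unless a variant subset is named.
    """

    exposure_mean: float = 12.9
    exposure_sd: float = 1.6
    #: rsid -> effect of one effect-allele copy on childhood BMI (latent SD)
    bmi_pleiotropy: dict = field(default_factory=dict)
    #: confounding path: effect of childhood BMI on the exposure (years per SD)
    child_bmi_to_exposure: float = 0.0
    child_bmi_noise: float = 1.0
    #: tracking of childhood into adult BMI (SD per SD)
    child_to_adult: float = 0.5
    #: vertical pleiotropy: effect of the exposure on adult BMI (SD per year)
    exposure_to_adult: float = -0.1
    adult_bmi_noise: float = 0.8
    age_low: float = 40.0
    age_high: float = 69.0
    n_pcs: int = 10


@dataclass
class Cohort:
    """Individual-level synthetic cohort.

    ``dosages`` is an n x m DataFrame with rsid columns and entries in
    {0, 1, 2}; ``phenome`` holds trait columns keyed by TraitSpec name and may
    contain missing values.
    """

    dosages: pd.DataFrame
    exposure: np.ndarray
    child_bmi: np.ndarray
    adult_bmi: np.ndarray
    height: np.ndarray
    age: np.ndarray
    pcs: np.ndarray
    phenome: pd.DataFrame
    trait_specs: dict = field(default_factory=dict)
    params: CohortParams = field(default_factory=CohortParams)

    @property
    def n(self) -> int:
        return len(self.exposure)

    def column(self, name: str) -> np.ndarray:
        """Look up a named column across core variables and the phenome."""
        core = {
            "exposure": self.exposure, "child_bmi": self.child_bmi,
            "adult_bmi": self.adult_bmi, "height": self.height, "age": self.age,
        }
        if name in core:
            return np.asarray(core[name], dtype=float)
        if name in self.phenome.columns:
            return self.phenome[name].to_numpy()
        raise KeyError(f"no column named {name!r} in cohort")

    def default_covariates(self) -> np.ndarray:
        """Age plus the genetic principal components, as an n x (1+k) matrix."""
        return np.column_stack([self.age, self.pcs])


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

def simulate_panel(
    m: int,
    seed: int = 0,
    freq_low: float = 0.05,
    freq_high: float = 0.95,
    target_r2: float = 0.061,
    exposure_sd: float = 1.6,
    gwas_n: int = 370_000,
    min_spacing_bp: int = 500_001,
) -> pd.DataFrame:
    """Draw an instrument panel of ``m`` independent variants.

    Effect-allele frequencies are uniform on [freq_low, freq_high]; per-allele
    effects (years of menarche age, sign free) are scaled so that the panel's
    analytic variance explained, sum_j 2 p_j (1-p_j) beta_j^2, equals
    ``target_r2`` times the exposure variance. Positions are laid out on
    chromosomes 1-22 with successive same-chromosome variants at least
    ``min_spacing_bp`` apart, so the default panel never self-triggers a
    500-kb proximity exclusion.
    """
    if m < 1:
        raise ParameterError("variant count m must be >= 1")
    if not (0.0 < freq_low < freq_high < 1.0):
        raise ParameterError("need 0 < freq_low < freq_high < 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    eaf = rng.uniform(freq_low, freq_high, m)
    raw = rng.normal(0.0, 1.0, m)
    het = 2.0 * eaf * (1.0 - eaf)
    scale = np.sqrt(target_r2 * exposure_sd**2 / np.sum(het * raw**2))
    beta = raw * scale
    se = exposure_sd / np.sqrt(gwas_n * het)
    pval = 2.0 * special.ndtr(-np.abs(beta) / se)

    chrom = (np.arange(m) % 22) + 1
    within = np.arange(m) // 22
    # stride exceeds the window by the jitter range, so spacing always holds
    pos = 1_000_000 + within * (int(min_spacing_bp) + 1000) + rng.integers(0, 1000, m)

    ea_idx = rng.integers(0, 4, m)
    oa_idx = (ea_idx + rng.integers(1, 4, m)) % 4
    return pd.DataFrame({
        "rsid": [f"rs{i + 1}" for i in range(m)],
        "chrom": [f"{c}" for c in chrom],
        "pos": pos.astype(np.int64),
        "effect_allele": _ALLELES[ea_idx],
        "other_allele": _ALLELES[oa_idx],
        "eaf": eaf,
        "beta_exposure": beta,
        "se_exposure": se,
        "pval_exposure": pval,
    })


def panel_variance_explained(panel: pd.DataFrame, exposure_sd: float = 1.6) -> float:
    """Analytic fraction of exposure variance explained by a panel."""
    het = 2.0 * panel["eaf"].to_numpy() * (1.0 - panel["eaf"].to_numpy())
    return float(np.sum(het * panel["beta_exposure"].to_numpy() ** 2) / exposure_sd**2)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    panel: pd.DataFrame,
    n: int,
    params: CohortParams | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate ``n`` individuals under the assumed causal diagram.

    Dosages are Binomial(2, eaf) per variant; the exposure is
    mean + G beta + (confounding via childhood BMI) + residual, with the
    residual SD solved so the marginal exposure SD matches the configured
    target; adult BMI = tracking * child BMI + vertical path * centred
    exposure + noise. A fixed seed gives byte-identical output.
    """
    if n < 1:
        raise ParameterError("cohort size n must be >= 1")
    params = params or CohortParams()
    ss = np.random.SeedSequence([int(seed), 17])
    s_geno, s_child, s_expo, s_adult, s_height, s_age, s_pcs = ss.spawn(7)

    eaf = panel["eaf"].to_numpy()
    beta = panel["beta_exposure"].to_numpy()
    rsids = panel["rsid"].tolist()
    dos = np.random.default_rng(s_geno).binomial(2, eaf, size=(n, len(eaf))).astype(float)

    gamma = np.array([params.bmi_pleiotropy.get(r, 0.0) for r in rsids])
    unknown = set(params.bmi_pleiotropy) - set(rsids)
    if unknown:
        raise ConfigError(f"bmi_pleiotropy names unknown rsids: {sorted(unknown)}")

    # centre genetic contributions at their expectation 2*eaf so the
    # configured exposure mean is the marginal mean, not an intercept
    dos_c = dos - 2.0 * eaf
    child = dos_c @ gamma + np.random.default_rng(s_child).normal(0.0, params.child_bmi_noise, n)

    het = 2.0 * eaf * (1.0 - eaf)
    var_g = float(np.sum(het * beta**2))
    var_child = float(np.sum(het * gamma**2) + params.child_bmi_noise**2)
    explained = var_g + params.child_bmi_to_exposure**2 * var_child
    resid_sd = np.sqrt(max(params.exposure_sd**2 - explained, 1e-12))
    exposure = (
        params.exposure_mean
        + dos_c @ beta
        + params.child_bmi_to_exposure * child
        + np.random.default_rng(s_expo).normal(0.0, resid_sd, n)
    )

    adult = (
        params.child_to_adult * child
        + params.exposure_to_adult * (exposure - params.exposure_mean)
        + np.random.default_rng(s_adult).normal(0.0, params.adult_bmi_noise, n)
    )
    height = np.random.default_rng(s_height).normal(0.0, 1.0, n)
    age = np.random.default_rng(s_age).uniform(params.age_low, params.age_high, n)
    pcs = np.random.default_rng(s_pcs).normal(0.0, 1.0, (n, params.n_pcs))
    pcs -= pcs.mean(axis=0, keepdims=True)

    return Cohort(
        dosages=pd.DataFrame(dos, columns=rsids),
        exposure=exposure, child_bmi=child, adult_bmi=adult,
        height=height, age=age, pcs=pcs,
        phenome=pd.DataFrame(index=pd.RangeIndex(n)),
        params=params,
    )


# ---------------------------------------------------------------------------
# Phenome
# ---------------------------------------------------------------------------

def _latent_trait(cohort: Cohort, spec: TraitSpec, rng: np.random.Generator) -> np.ndarray:
    x = cohort.exposure - cohort.params.exposure_mean
    direct = (1.0 - spec.mediation_via_bmi) * x
    mediated = spec.mediation_via_bmi * cohort.adult_bmi
    latent = spec.beta_menarche * (direct + mediated)
    for rsid, eff in spec.pleiotropy.items():
        if rsid not in cohort.dosages.columns:
            raise ConfigError(f"pleiotropy_set of {spec.name!r} names unknown rsid {rsid!r}")
        latent = latent + eff * cohort.dosages[rsid].to_numpy()
    if spec.noise_sd > 0:
        latent = latent + rng.normal(0.0, spec.noise_sd, cohort.n)
    return np.asarray(latent, dtype=float)


def _discretize(latent: np.ndarray, spec: TraitSpec, rng: np.random.Generator):
    if spec.kind == "continuous":
        return latent
    if spec.kind == "binary":
        # cut-point solved from the requested marginal prevalence
        cut = np.quantile(latent, 1.0 - spec.prevalence)
        return (latent > cut).astype(float)
    if spec.kind == "ordered":
        cuts = np.quantile(latent, np.linspace(0, 1, spec.levels + 1)[1:-1])
        return np.searchsorted(cuts, latent, side="right").astype(float)
    # unordered: multinomial softmax with per-level loadings on the latent;
    # loadings vanish nowhere, but with a null latent the class probabilities
    # carry no score signal
    loadings = np.linspace(-1.0, 1.0, spec.levels)
    z = (latent - latent.mean())[:, None] * loadings[None, :]
    gumbel = rng.gumbel(size=z.shape)
    labels = np.argmax(z + gumbel, axis=1)
    return np.array([f"cat{k}" for k in labels], dtype=object)


def simulate_phenome(cohort: Cohort, specs: list[TraitSpec], seed: int = 0) -> Cohort:
    """Fill the cohort's phenome according to the trait specifications.

    Continuous traits are the latent variable itself; binary/ordered traits
    threshold the latent at cut-points solved from the requested prevalence /
    level count; unordered traits are drawn from a softmax over per-level
    loadings on the latent. Returns a new Cohort, leaving the input untouched.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise ConfigError(f"duplicate trait names: {dupes}")
    ss = np.random.SeedSequence([int(seed), 23])
    phenome = {}
    for spec, child_ss in zip(specs, ss.spawn(len(specs))):
        rng = np.random.default_rng(child_ss)
        latent = _latent_trait(cohort, spec, rng)
        phenome[spec.name] = _discretize(latent, spec, rng)
    out = dataclasses.replace(cohort)
    out.phenome = pd.DataFrame(phenome, index=pd.RangeIndex(cohort.n))
    out.trait_specs = {s.name: s for s in specs}
    return out


# ---------------------------------------------------------------------------
# Per-variant association summaries (for two-sample MR)
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), covariates])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def gwas_summarize(
    cohort: Cohort,
    trait: str,
    covariates: np.ndarray | None = None,
    kind: str | None = None,
) -> pd.DataFrame:
    """Per-variant regression of a trait on dosage, adjusted for covariates.

    Continuous traits use exact OLS via Frisch–Waugh residualization (fully
    vectorized across variants); binary traits use per-variant logistic
    regression. Returns GWAS-summary-statistic rows (one per panel variant);
    a variant whose fit fails is flagged in the ``error`` column, never
    silently dropped. ``sample_size`` is recorded in ``DataFrame.attrs``.
    """
    y = np.asarray(cohort.column(trait), dtype=float)
    D = cohort.dosages.to_numpy()
    n, m = D.shape
    if kind is None:
        kind = "binary" if set(np.unique(y[np.isfinite(y)])) <= {0.0, 1.0} else "continuous"

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    err = np.array([""] * m, dtype=object)

    if np.nanstd(y) == 0.0:
        err[:] = "constant trait"
    elif kind == "continuous":
        yr = _residualize(y, covariates)
        Dr = np.column_stack([_residualize(D[:, j], covariates) for j in range(m)]) \
            if covariates is not None else D - D.mean(axis=0)
        sxx = np.einsum("ij,ij->j", Dr, Dr)
        ok = sxx > 0
        k_cov = 0 if covariates is None else np.atleast_2d(covariates.T).shape[0]
        dof = n - k_cov - 2
        beta[ok] = (Dr[:, ok].T @ yr) / sxx[ok]
        rss = np.sum(yr**2) - beta[ok] ** 2 * sxx[ok]
        se[ok] = np.sqrt(np.maximum(rss, 0.0) / dof / sxx[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            pval[ok] = 2.0 * special.ndtr(-np.abs(beta[ok] / se[ok]))
        err[~ok] = "constant dosage"
    else:
        import statsmodels.api as sm
        base = np.ones((n, 1)) if covariates is None else np.column_stack(
            [np.ones(n), covariates])
        for j in range(m):
            X = np.column_stack([base, D[:, j]])
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                beta[j], se[j] = fit.params[-1], fit.bse[-1]
                pval[j] = 2.0 * special.ndtr(-abs(beta[j] / se[j]))
                if not fit.mle_retvals.get("converged", True):
                    err[j] = "non-convergence"
            except Exception as exc:  # separation, singularity
                err[j] = f"fit failed: {type(exc).__name__}"

    out = pd.DataFrame({
        "rsid": cohort.dosages.columns,
        "effect_allele": _panel_lookup(cohort, "effect_allele"),
        "other_allele": _panel_lookup(cohort, "other_allele"),
        "eaf": D.mean(axis=0) / 2.0,
        "beta_outcome": beta,
        "se_outcome": se,
        "pval_outcome": pval,
        "n": n,
        "error": err,
    })
    out.attrs["sample_size"] = n
    out.attrs["trait"] = trait
    return out


def _panel_lookup(cohort: Cohort, col: str):
    # allele bookkeeping is optional for purely synthetic dosage matrices
    panel = getattr(cohort, "_panel", None)
    if panel is not None and col in panel.columns:
        return panel.set_index("rsid").loc[cohort.dosages.columns, col].to_numpy()
    return np.array(["A" if col == "effect_allele" else "G"] * cohort.dosages.shape[1])


def attach_panel(cohort: Cohort, panel: pd.DataFrame) -> Cohort:
    """Remember panel allele labels so summary output carries real alleles."""
    cohort._panel = panel  # type: ignore[attr-defined]
    return cohort
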