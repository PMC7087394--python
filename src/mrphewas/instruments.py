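"""Genetic risk score construction and the instrument variant-set strategies.

The score is a weighted sum of menarche-*decreasing* allele counts: every
variant is oriented so the counted allele lowers the exposure, so a higher
score means genetically earlier menarche. Three exclusion strategies address
pleiotropy via BMI: Steiger filtering (variants explaining more variance in
adult BMI than in the exposure), and proximity exclusion of variants within a
window of published childhood-BMI or any-BMI hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError

SET_LABELS = ("all", "steiger", "child_bmi", "bmi")


@dataclass
class GRSVariantSet:
    """Partition of a panel into included and excluded instrument variants."""

    label: str
    included_rsids: list
    #: rsid -> human-readable exclusion reason
    excluded: dict = field(default_factory=dict)

    @property
    def excluded_rsids(self) -> list:
        return list(self.excluded)

    def validate_partition(self, panel: pd.DataFrame) -> None:
        inc, exc = set(self.included_rsids), set(self.excluded)
        if inc & exc:
            raise InputError(f"set {self.label!r}: included/excluded overlap")
        if inc | exc != set(panel["rsid"]):
            raise InputError(f"set {self.label!r}: does not partition the panel")

    def subset(self, panel: pd.DataFrame) -> pd.DataFrame:
        return panel[panel["rsid"].isin(set(self.included_rsids))].reset_index(drop=True)

    def to_frame(self, panel: pd.DataFrame) -> pd.DataFrame:
        reasons = {r: "" for r in self.included_rsids} | self.excluded
        return pd.DataFrame({
            "rsid": panel["rsid"],
            "included": [r not in self.excluded for r in panel["rsid"]],
            "exclusion_reason": [reasons.get(r, "") for r in panel["rsid"]],
        })


@dataclass(frozen=True)
class InstrumentStrength:
    r_squared: float
    f_statistic: float
    n: int


def compute_grs(dosages: pd.DataFrame, weights: pd.Series | pd.DataFrame) -> np.ndarray:
    """Weighted count of menarche-decreasing alleles per individual.

    ``weights`` maps rsid to the per-effect-allele exposure effect in years
    (sign free). Variants with a positive effect are re-oriented (dosage
    2 - d, weight sign flipped) so each contribution counts the allele that
    decreases the exposure; the score is the oriented dot product with the
    absolute weights.
    """
    if isinstance(weights, pd.DataFrame):
        weights = weights.set_index("rsid")["beta_exposure"]
    unknown = [r for r in weights.index if r not in dosages.columns]
    if unknown:
        raise InputError(f"weights name rsids absent from dosage columns: {unknown}")
    rsids = list(weights.index)
    beta = weights.to_numpy(dtype=float)
    D = dosages[rsids].to_numpy(dtype=float)
    oriented = np.where(beta > 0, 2.0 - D, D)
    return oriented @ np.abs(beta)


def instrument_strength(
    score: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
) -> InstrumentStrength:
    """Incremental R^2 and partial F of the score in a linear exposure model.

    R^2 is the gain from adding the score to a covariate-only model; F is the
    partial F for the single score term, F = (RSS0 - RSS1) / (RSS1 / dof1).
    """
    score = np.asarray(score, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    n = len(exposure)
    if covariates is None:
        X0 = np.ones((n, 1))
    else:
        X0 = np.column_stack([np.ones(n), covariates])
    if n <= X0.shape[1] + 2:
        raise ParameterError("need n > number of covariates + 2")
    if np.std(score) == 0.0:
        warnings.warn("zero-variance score: r_squared defined as 0", stacklevel=2)
        return InstrumentStrength(0.0, 0.0, n)
    X1 = np.column_stack([X0, score])
    rss0 = _rss(X0, exposure)
    rss1 = _rss(X1, exposure)
    tss = float(np.sum((exposure - exposure.mean()) ** 2))
    dof1 = n - X1.shape[1]
    f = (rss0 - rss1) / (rss1 / dof1)
    return InstrumentStrength(float((rss0 - rss1) / tss), float(max(f, 0.0)), n)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ coef) ** 2))


def steiger_filter(cohort, panel: pd.DataFrame, competing_trait: str = "adult_bmi") -> GRSVariantSet:
    """Exclude variants explaining strictly more variance in a competing trait.

    Per variant, r^2 with the exposure and with the competing trait are the
    squared sample correlations between dosage and each trait; ties (to
    machine precision) keep the variant, since exclusion requires the
    competing r^2 to be strictly greater.
    """
    try:
        comp = np.asarray(cohort.column(competing_trait), dtype=float)
    except KeyError as exc:
        raise InputError(str(exc)) from exc
    expo = np.asarray(cohort.exposure, dtype=float)
    D = cohort.dosages[panel["rsid"]].to_numpy(dtype=float)
    r2_exp = _corr_sq(D, expo)
    r2_comp = _corr_sq(D, comp)
    excluded = {}
    for rsid, a, b in zip(panel["rsid"], r2_exp, r2_comp):
        if b > a:
            excluded[rsid] = f"steiger: r2_{competing_trait}={b:.3e} > r2_exposure={a:.3e}"
    included = [r for r in panel["rsid"] if r not in excluded]
    return GRSVariantSet("steiger", included, excluded)


def _corr_sq(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    Dc = D - D.mean(axis=0)
    yc = y - y.mean()
    num = Dc.T @ yc
    den = np.sqrt(np.einsum("ij,ij->j", Dc, Dc) * np.sum(yc**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r**2


def proximity_filter(
    panel: pd.DataFrame,
    reference_hits,
    window_bp: int = 500_000,
    label: str = "child_bmi",
) -> GRSVariantSet:
    """Exclude panel variants on the same chromosome within ``window_bp`` of
    any reference hit (boundary inclusive: a distance of exactly ``window_bp``
    excludes), or whose rsid matches a hit rsid. Empty hit lists exclude
    nothing.
    """
    if window_bp < 0:
        raise ParameterError("window_bp must be >= 0")
    hits = _normalize_hits(reference_hits)
    hit_rsids = {h[0] for h in hits if h[0] is not None}
    excluded = {}
    for rsid, chrom, pos in zip(panel["rsid"], panel["chrom"], panel["pos"]):
        if rsid in hit_rsids:
            excluded[rsid] = "matches reference hit rsid"
            continue
        for h_rsid, h_chrom, h_pos in hits:
            if h_chrom is not None and str(chrom) == str(h_chrom) and abs(int(pos) - int(h_pos)) <= window_bp:
                excluded[rsid] = f"within {window_bp} bp of hit at {h_chrom}:{h_pos}"
                break
    included = [r for r in panel["rsid"] if r not in excluded]
    return GRSVariantSet(label, included, excluded)


def _normalize_hits(hits):
    """Accept a DataFrame (rsid, chrom, pos), tuples (chrom, pos), or rsids."""
    if isinstance(hits, pd.DataFrame):
        return [(r.get("rsid"), r["chrom"], int(r["pos"])) for _, r in hits.iterrows()]
    out = []
    for h in hits or []:
        if isinstance(h, str):
            out.append((h, None, -1))
        else:
            out.append((None, h[0], int(h[1])))
    return out


def build_instrument_sets(
    panel: pd.DataFrame,
    cohort=None,
    child_hits=None,
    adult_hits=None,
    window_bp: int = 500_000,
    competing_trait: str = "adult_bmi",
) -> dict:
    """The four instrument strategies keyed by label.

    ``all`` uses every panel variant; ``steiger`` drops variants explaining
    more variance in the competing trait (skipped — no exclusions — when no
    individual-level cohort is supplied); ``child_bmi`` drops variants near
    childhood-BMI hits; ``bmi`` drops variants near childhood or adult BMI
    hits.
    """
    rsids = list(panel["rsid"])
    sets = {"all": GRSVariantSet("all", rsids, {})}
    if cohort is not None:
        sets["steiger"] = steiger_filter(cohort, panel, competing_trait)
    else:
        sets["steiger"] = GRSVariantSet("steiger", rsids, {})
    child_hits = child_hits if child_hits is not None else []
    adult_hits = adult_hits if adult_hits is not None else []
    sets["child_bmi"] = proximity_filter(panel, child_hits, window_bp, "child_bmi")
    combined = _concat_hits(child_hits, adult_hits)
    sets["bmi"] = proximity_filter(panel, combined, window_bp, "bmi")
    for s in sets.values():
        s.validate_partition(panel)
    return sets


def _concat_hits(a, b):
    if isinstance(a, pd.DataFrame) or isinstance(b, pd.DataFrame):
        frames = [x for x in (a, b) if isinstance(x, pd.DataFrame) and len(x)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["rsid", "chrom", "pos"])
    return list(a or []) + list(b or [])
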