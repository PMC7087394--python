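"""Tabular file formats and run configuration.

Every table is tab-separated UTF-8 with '.' decimals and 'NA' for missing,
matching GWAS summary-statistic conventions, and carries a header comment
with the package version, a hash of the run configuration, and the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError

PANEL_REQUIRED = ["rsid", "chrom", "pos", "effect_allele", "other_allele",
                  "eaf", "beta", "se"]
_VALID_ALLELES = {"A", "C", "G", "T"}


@dataclass
class RunConfig:
    """Validated configuration for the end-to-end pipeline."""

    seed: int
    out_dir: str = "mrphewas_out"
    # generator
    n_individuals: int = 5000
    n_variants: int = 60
    n_traits: int = 150
    target_r2: float = 0.061
    exposure_mean: float = 12.9
    exposure_sd: float = 1.6
    # instruments
    instrument_sets: tuple = ("all", "steiger", "child_bmi", "bmi")
    proximity_window_bp: int = 500_000
    # scan
    case_floor: int = 50
    max_ordered_levels: int = 20
    int_offset: float = 0.375
    q_fdr: float = 0.05
    alpha: float = 0.05
    covariates: tuple = ("age", "pcs")
    # MR follow-up
    followup_traits: tuple = ()
    bootstrap_reps: int = 500
    presso_sims: int = 1000
    palindrome_eaf_window: float = 0.08
    # optional external inputs
    panel_path: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ConfigError("config requires a seed")
        d = dict(d)
        for key in ("instrument_sets", "covariates", "followup_traits"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("instrument_sets", "covariates", "followup_traits"):
            d[key] = list(d[key])
        return d

    def digest(self) -> str:
        # where the outputs land does not change what was computed
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def echo(self, out_dir: Path) -> None:
        with open(out_dir / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("mrphewas")
    except Exception:
        return "unknown"


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed=None) -> None:
    """TSV writer with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mrphewas v{_version()} config={config_hash or 'NA'} "
                 f"seed={seed if seed is not None else 'NA'}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def read_weight_table(path) -> pd.DataFrame:
    """Read and validate a variant-weight table (instrument panel).

    Expected tab-separated columns: rsid, chrom, pos, effect_allele,
    other_allele, eaf, beta, se[, pval, n]. Errors name the offending row
    (1-based, excluding header/comments) or rsid.
    """
    df = read_table(path)
    missing = [c for c in PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"weight table missing columns: {missing}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if len(dup):
        raise InputError(f"duplicate rsid(s): {sorted(set(dup))}")
    for i, row in df.iterrows():
        rowno = i + 1
        if not 0.0 < row["eaf"] < 1.0:
            raise InputError(f"row {rowno}: eaf {row['eaf']} outside (0, 1)")
        if not row["se"] > 0:
            raise InputError(f"row {rowno}: se must be > 0")
        ea, oa = str(row["effect_allele"]), str(row["other_allele"])
        if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
            raise InputError(f"row {rowno}: alleles must be A/C/G/T")
        if ea == oa:
            raise InputError(f"row {rowno}: effect and other allele identical")
    out = df.rename(columns={"beta": "beta_exposure", "se": "se_exposure",
                             "pval": "pval_exposure"})
    if "pval_exposure" not in out.columns:
        from scipy import special
        out["pval_exposure"] = 2.0 * special.ndtr(
            -np.abs(out["beta_exposure"] / out["se_exposure"]))
    return out


def write_panel(panel: pd.DataFrame, path, **meta) -> None:
    out = panel.rename(columns={"beta_exposure": "beta", "se_exposure": "se",
                                "pval_exposure": "pval"})
    write_table(out, path, **meta)


def write_summary_stats(stats_df: pd.DataFrame, path, **meta) -> None:
    write_table(stats_df, path, **meta)


def read_summary_stats(path) -> pd.DataFrame:
    df = read_table(path)
    need = {"rsid", "effect_allele", "other_allele", "eaf", "beta_outcome", "se_outcome"}
    missing = sorted(need - set(df.columns))
    if missing:
        raise InputError(f"summary-stat table missing columns: {missing}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if len(dup):
        raise InputError(f"duplicate rsid(s): {sorted(set(dup))}")
    return df


def write_cohort(cohort, out_dir, config: RunConfig | None = None) -> None:
    """Cohort as a dosage TSV + phenotype TSV + sidecar generator config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.digest() if config else "",
            "seed": config.seed if config else None}
    write_table(cohort.dosages, out_dir / "dosages.tsv", **meta)
    pheno = pd.DataFrame({
        "exposure": cohort.exposure, "child_bmi": cohort.child_bmi,
        "adult_bmi": cohort.adult_bmi, "height": cohort.height, "age": cohort.age,
    })
    for k in range(cohort.pcs.shape[1]):
        pheno[f"pc{k + 1}"] = cohort.pcs[:, k]
    pheno = pd.concat([pheno, cohort.phenome], axis=1)
    write_table(pheno, out_dir / "phenotypes.tsv", **meta)
    sidecar = {"params": asdict(cohort.params)}
    if config is not None:
        sidecar["config"] = config.to_dict()
    with open(out_dir / "cohort.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)
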