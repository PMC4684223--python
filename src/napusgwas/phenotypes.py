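"""Phenotype statistics for replicated multi-environment trials.

Covers the descriptive statistics usually tabulated for a diversity
panel (range, mean +/- SD, CV%, skewness, excess kurtosis), Pearson
correlations, method-of-moments variance components from a balanced
two-way ANOVA (genotype x environment with replicates), broad-sense
heritability on an entry-mean basis,

    h2 = sigma2_g / (sigma2_g + sigma2_ge/n + sigma2_e/(n*r)) * 100%,

with n environments (years) and r replicates, and a grid-search Box-Cox
transformation for non-normal traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few (or degenerate) observations for the requested statistic."""


@dataclass(frozen=True)
class TraitSummary:
    n: int
    mean: float
    sd: float
    cv_pct: float
    min: float
    max: float
    skewness: float | None
    kurtosis: float | None


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: int
    h2_pct: float
    p_g: float | None = None
    p_e: float | None = None
    p_ge: float | None = None


@dataclass
class BoxCoxResult:
    lambda_hat: float
    loglik_profile: pd.DataFrame  # columns: lam, loglik
    transformed_values: np.ndarray


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x[np.isfinite(x)]


def summarize_trait(values) -> TraitSummary:
    """Descriptive statistics of one trait across accessions.

    CV% is ``100 * sd / mean`` with the sample (n-1) standard deviation.
    For constant input, skewness and kurtosis are reported as ``None``
    rather than NaN.
    """
    x = _clean(values)
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 observations, got {x.size}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if mean == 0.0:
        raise InsufficientDataError("mean is zero; CV undefined")
    if sd == 0.0:
        skew = kurt = None
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return TraitSummary(
        n=int(x.size),
        mean=mean,
        sd=sd,
        cv_pct=100.0 * sd / mean,
        min=float(np.min(x)),
        max=float(np.max(x)),
        skewness=skew,
        kurtosis=kurt,
    )


def pearson_correlation(x, y) -> float:
    """Pairwise-complete Pearson correlation of two paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientDataError("need >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y)[0])


def anova_components(table: pd.DataFrame, trait: str | None = None) -> VarianceComponents:
    """Two-way ANOVA variance components from a balanced trial.

    Expects long format with columns ``accession, env, rep, value`` (and
    optionally ``trait`` to select one trait).  Method-of-moments
    estimates from the expected mean squares of the random model:
    ``sigma2_e = MS_err``, ``sigma2_ge = (MS_GE - MS_err)/r``,
    ``sigma2_g = (MS_G - MS_GE)/(n*r)``; negative estimates are clamped
    to zero with a logged warning.  F tests use the random-model
    denominators (G and E against GxE, GxE against error).
    """
    df = table
    if trait is not None:
        df = df[df["trait"] == trait]
    for col in ("accession", "env", "value"):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    counts = df.groupby(["accession", "env"], observed=True)["value"].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal replicate counts per accession x env")
    r = int(counts.iloc[0])
    g = df["accession"].nunique()
    e = df["env"].nunique()
    if g < 2 or e < 2:
        raise ValueError("need >= 2 accessions and >= 2 environments")
    if len(df) != g * e * r:
        raise ValueError("unbalanced design: missing accession x env cells")
    if r < 2:
        raise ValueError("need >= 2 replicates to separate G x E from residual error")

    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    cell = df.groupby(["accession", "env"], observed=True)["value"].mean()
    acc = df.groupby("accession", observed=True)["value"].mean()
    env = df.groupby("env", observed=True)["value"].mean()

    ss_g = e * r * float(((acc - grand) ** 2).sum())
    ss_e = g * r * float(((env - grand) ** 2).sum())
    cell_dev = cell - acc.reindex(cell.index.get_level_values(0)).to_numpy() \
        - env.reindex(cell.index.get_level_values(1)).to_numpy() + grand
    ss_ge = r * float((cell_dev**2).sum())
    fitted_cell = df.set_index(["accession", "env"]).index.map(cell)
    ss_err = float(((y - fitted_cell.to_numpy()) ** 2).sum())

    df_g, df_e, df_ge, df_err = g - 1, e - 1, (g - 1) * (e - 1), g * e * (r - 1)
    ms_g, ms_e_, ms_ge, ms_err = ss_g / df_g, ss_e / df_e, ss_ge / df_ge, ss_err / df_err

    s2_e = ms_err
    s2_ge = (ms_ge - ms_err) / r
    s2_g = (ms_g - ms_ge) / (e * r)
    for name, val in (("sigma2_ge", s2_ge), ("sigma2_g", s2_g)):
        if val < 0:
            logger.warning("negative %s estimate %.4g clamped to 0", name, val)
    s2_ge = max(s2_ge, 0.0)
    s2_g = max(s2_g, 0.0)

    p_g = float(stats.f.sf(ms_g / ms_ge, df_g, df_ge)) if ms_ge > 0 else None
    p_e = float(stats.f.sf(ms_e_ / ms_ge, df_e, df_ge)) if ms_ge > 0 else None
    p_ge = float(stats.f.sf(ms_ge / ms_err, df_ge, df_err)) if ms_err > 0 else None

    vc = VarianceComponents(
        sigma2_g=s2_g, sigma2_ge=s2_ge, sigma2_e=s2_e, n_env=e, n_rep=r,
        h2_pct=0.0, p_g=p_g, p_e=p_e, p_ge=p_ge,
    )
    return VarianceComponents(**{**vc.__dict__, "h2_pct": heritability(vc)})


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability (percent) on an entry-mean basis."""
    s2g, s2ge, s2e = vc.sigma2_g, vc.sigma2_ge, vc.sigma2_e
    if min(s2g, s2ge, s2e) < 0:
        raise ValueError("variance components must be >= 0")
    denom = s2g + s2ge / vc.n_env + s2e / (vc.n_env * vc.n_rep)
    if denom == 0:
        raise InsufficientDataError("all variance components are zero; h2 undefined")
    return 100.0 * s2g / denom


def boxcox(values, lambda_min: float = -5.0, lambda_max: float = 5.0, step: float = 0.01) -> BoxCoxResult:
    """Box-Cox power transform with lambda chosen by profile-likelihood grid search.

    Uses the standard profile log-likelihood; the grid (rather than a
    line search) makes the chosen lambda exactly reproducible.  Values
    must be strictly positive — no automatic shifting.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("need >= 3 observations")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive, finite values")
    lams = np.arange(lambda_min, lambda_max + step / 2, step)
    lls = np.array([stats.boxcox_llf(lam, x) for lam in lams])
    i = int(np.argmax(lls))
    lam_hat = float(lams[i])
    transformed = special.boxcox(x, lam_hat)
    profile = pd.DataFrame({"lam": lams, "loglik": lls})
    return BoxCoxResult(lambda_hat=lam_hat, loglik_profile=profile, transformed_values=transformed)


def normality_metrics(values) -> tuple[float, float]:
    """Adjusted Fisher-Pearson skewness and excess kurtosis."""
    x = _clean(values)
    if x.size < 4:
        raise InsufficientDataError("need >= 4 observations")
    if np.std(x) == 0:
        raise InsufficientDataError("metrics undefined for constant input")
    return (
        float(stats.skew(x, bias=False)),
        float(stats.kurtosis(x, fisher=True, bias=False)),
    )


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait summary rows (range, mean+/-SD, CV%, h2 when estimable)."""
    rows = []
    for trait, grp in table.groupby("trait", observed=True):
        s = summarize_trait(grp["value"])
        row = {
            "trait": trait,
            "n": s.n,
            "range": f"{s.min:.2f}-{s.max:.2f}",
            "mean_sd": f"{s.mean:.2f}+/-{s.sd:.2f}",
            "cv_pct": round(s.cv_pct, 2),
            "skewness": None if s.skewness is None else round(s.skewness, 3),
            "kurtosis": None if s.kurtosis is None else round(s.kurtosis, 3),
        }
        try:
            vc = anova_components(grp)
            row["h2_pct"] = round(vc.h2_pct, 2)
        except ValueError:
            row["h2_pct"] = None
        rows.append(row)
    return pd.DataFrame(rows)
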