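"""Q + K mixed-linear-model association scan and FDR selection.

The phenotype is modelled as ``y = X b + u + e`` with fixed effects
``X = [1 | Q]`` (intercept plus population-structure covariates), a
polygenic random effect ``u ~ N(0, sigma2_g K)`` defined by the kinship
matrix, and residuals ``e ~ N(0, sigma2_e I)``.  Variance components are
estimated once under the null by spectral (eigendecomposition) REML over
the single ratio ``delta = sigma2_e / sigma2_g``, and each marker is then
tested by generalized least squares with the null covariance held fixed
— the standard "population parameters previously determined" (P3D /
EMMAX) approximation.  An exact mode re-estimates delta per marker.

Multiple testing uses the rank-based step-up rule on sorted p-values:
select the largest rank n with ``m * p_(n) / n <= q`` — the achieved
false discovery rate ``(m * P / n) x 100%`` of the selected set is then
at most ``q x 100%``.  This is the Benjamini-Hochberg procedure written
in its step-up form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# null-model REML
# ---------------------------------------------------------------------------


@dataclass
class NullModelFit:
    """Variance components and eigendecomposition context of the null model."""

    delta: float                    # sigma2_e / sigma2_g
    sigma2_g: float
    sigma2_e: float
    loglik: float                   # REML log-likelihood (up to a constant)
    beta: np.ndarray                # GLS fixed effects for [1 | Q]
    eigvals: np.ndarray = field(repr=False)   # eigenvalues of K
    eigvecs: np.ndarray = field(repr=False)   # eigenvectors of K (columns)
    X: np.ndarray = field(repr=False)         # fixed-effect design [1 | Q]
    n: int = 0


def _as_design(Q, n: int) -> np.ndarray:
    """[1 | Q] design with the intercept prepended; Q may be None/empty."""
    one = np.ones((n, 1))
    if Q is None:
        return one
    Qa = np.asarray(Q, dtype=float)
    if Qa.ndim == 1:
        Qa = Qa[:, None]
    if Qa.size == 0:
        return one
    if Qa.shape[0] != n:
        raise ValueError("Q row count does not match sample count")
    return np.hstack([one, Qa])


def _reml_neg2ll(delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    w = lam + delta
    nq = lam.size
    return nq * np.log(np.sum(eta2 / w) / nq) + np.sum(np.log(w))


def fit_null(y, Q, K, log10_bounds: tuple[float, float] = (-5.0, 5.0)) -> NullModelFit:
    """Spectral REML fit of the polygenic null model.

    Profiles the REML likelihood over ``delta`` on the rotated
    (eigenbasis) problem: with ``T`` an orthonormal basis of the
    complement of the fixed effects, ``eta = V' T y`` where ``M = T K T'
    = V diag(lam) V'``, the restricted -2 log-likelihood is
    ``(n-q) log(sum eta_i^2/(lam_i+delta)) + sum log(lam_i+delta)`` up to
    a constant.  Deterministic: bounded Brent search seeded by a coarse
    log-grid.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if np.std(y) == 0:
        raise ValueError("phenotype has zero variance")
    X = _as_design(Q, n)
    q = np.linalg.matrix_rank(X)
    if q < X.shape[1]:
        raise ValueError("fixed-effect design is singular (collinear Q columns)")
    Ka = np.asarray(K, dtype=float)
    if Ka.shape != (n, n):
        raise ValueError("K must be n x n aligned with y")

    # orthonormal complement of X
    Qfull, _ = np.linalg.qr(X, mode="complete")
    T = Qfull[:, q:].T                       # (n-q) x n, T X = 0, T T' = I
    M = T @ Ka @ T.T
    lam, V = np.linalg.eigh(M)
    lam = np.clip(lam, 0.0, None)
    eta = V.T @ (T @ y)
    eta2 = eta**2

    lo, hi = log10_bounds
    grid = np.linspace(lo, hi, 61)
    vals = [_reml_neg2ll(10.0**g, lam, eta2) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        lambda g: _reml_neg2ll(10.0**g, lam, eta2),
        bounds=(max(lo, g0 - 1.0), min(hi, g0 + 1.0)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(10.0**res.x)
    nq = lam.size
    sigma2_g = float(np.sum(eta2 / (lam + delta)) / nq)
    sigma2_e = delta * sigma2_g

    s, U = np.linalg.eigh(Ka)
    s = np.clip(s, 0.0, None)
    w = 1.0 / (s + delta)
    Uty = U.T @ y
    UtX = U.T @ X
    XtVX = UtX.T @ (UtX * w[:, None])
    beta = np.linalg.solve(XtVX, UtX.T @ (Uty * w))
    return NullModelFit(
        delta=delta,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        loglik=-0.5 * _reml_neg2ll(delta, lam, eta2),
        beta=beta,
        eigvals=s,
        eigvecs=U,
        X=X,
        n=n,
    )


# ---------------------------------------------------------------------------
# marker scan
# ---------------------------------------------------------------------------


def scan(
    G: GenotypeMatrix,
    y,
    Q=None,
    K=None,
    marker_map: pd.DataFrame | None = None,
    mode: str = "p3d",
    null: NullModelFit | None = None,
) -> pd.DataFrame:
    """Single-marker Q+K mixed-model scan.

    Each marker's minor-allele dosage is added to the fixed effects
    ``[1 | Q]`` and tested (two-sided t, df = n - rank([1|Q|g])) under
    the null-model covariance.  Missing dosages are mean-imputed; dosages
    are flipped where needed so effects are per minor-allele copy.
    Markers that are monomorphic after imputation get ``p = 1`` and a
    ``degenerate`` flag rather than being dropped, so the scan length
    always equals the marker count (this keeps ``m`` honest in the FDR
    step).  ``contrib_pct`` is the marker's phenotypic contribution: the
    squared partial correlation (in percent) between the whitened dosage
    and whitened phenotype given the fixed effects — the model-R²
    increment in the decorrelated space.

    Returns a DataFrame with one row per marker: ``id, chrom, pos, maf,
    beta, se, t, p_value, contrib_pct, n_used, degenerate`` (map columns
    present only when ``marker_map`` is given).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if G.n_samples != n:
        raise ValueError("genotype and phenotype sample counts differ")
    if K is None:
        K = np.eye(n)
    K = np.asarray(K, dtype=float) if not isinstance(K, pd.DataFrame) else K.to_numpy()
    if null is None:
        null = fit_null(y, Q, K)
    X = null.X

    freq = G.alt_freq()
    Xdose = G.imputed()
    flip = np.nan_to_num(freq) > 0.5
    Xdose[:, flip] = 2.0 - Xdose[:, flip]
    maf = np.minimum(np.nan_to_num(freq), 1.0 - np.nan_to_num(freq))
    n_used = (~G.missing_mask()).sum(axis=0)

    if mode == "p3d":
        w = 1.0 / np.sqrt(null.eigvals + null.delta)
        W = null.eigvecs * w[None, :]          # whitening: W.T @ v
        yt = W.T @ y
        Xt = W.T @ X
        Gt = W.T @ Xdose
        # residualize against the whitened fixed effects
        Qx, _ = np.linalg.qr(Xt)
        yr = yt - Qx @ (Qx.T @ yt)
        Gr = Gt - Qx @ (Qx.T @ Gt)
        gg = np.einsum("ij,ij->j", Gr, Gr)
        gy = Gr.T @ yr
        yy = float(yr @ yr)
        dfree = n - X.shape[1] - 1
        good = gg > 1e-12 * n
        beta = np.where(good, gy / np.where(good, gg, 1.0), 0.0)
        rss = np.maximum(yy - beta * gy, 0.0)
        sigma2 = rss / dfree
        se = np.sqrt(np.where(good, sigma2 / np.where(good, gg, 1.0), np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(good, beta / se, 0.0)
        p = np.where(good, 2.0 * stats.t.sf(np.abs(tstat), dfree), 1.0)
        contrib = np.where(good & (yy > 0), 100.0 * (gy**2) / (np.where(good, gg, 1.0) * yy), 0.0)
    elif mode == "exact":
        m = G.n_markers
        beta = np.zeros(m)
        se = np.full(m, np.nan)
        tstat = np.zeros(m)
        p = np.ones(m)
        contrib = np.zeros(m)
        good = np.zeros(m, dtype=bool)
        dfree = n - X.shape[1] - 1
        for j in range(m):
            g = Xdose[:, j]
            if np.std(g) == 0:
                continue
            fit_j = fit_null(y, np.hstack([X[:, 1:], g[:, None]]), K)
            w = 1.0 / np.sqrt(fit_j.eigvals + fit_j.delta)
            W = fit_j.eigvecs * w[None, :]
            yt, Xt, gt = W.T @ y, W.T @ X, W.T @ g
            Qx, _ = np.linalg.qr(Xt)
            yr = yt - Qx @ (Qx.T @ yt)
            gr = gt - Qx @ (Qx.T @ gt)
            gg = float(gr @ gr)
            if gg <= 1e-12 * n:
                continue
            good[j] = True
            beta[j] = float(gr @ yr) / gg
            rss = max(float(yr @ yr) - beta[j] * float(gr @ yr), 0.0)
            se[j] = np.sqrt(rss / dfree / gg)
            tstat[j] = beta[j] / se[j]
            p[j] = 2.0 * stats.t.sf(abs(tstat[j]), dfree)
            contrib[j] = 100.0 * (float(gr @ yr) ** 2) / (gg * float(yr @ yr))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t": tstat,
            "p_value": np.clip(p, np.nextafter(0, 1), 1.0),
            "contrib_pct": np.clip(contrib, 0.0, 100.0),
            "maf": maf,
            "n_used": n_used,
            "degenerate": ~good,
        }
    )
    if marker_map is not None:
        for col in ("id", "chrom", "pos", "major_allele", "minor_allele"):
            if col in marker_map.columns:
                out.insert(0, col, marker_map[col].to_numpy())
        cols = [c for c in ("id", "chrom", "pos", "major_allele", "minor_allele") if c in out.columns]
        out = out[cols + [c for c in out.columns if c not in cols]]
    return out


def snp_contribution(results: pd.DataFrame, marker_id: str) -> float:
    """Phenotypic contribution (%) of one scanned marker."""
    row = results.loc[results["id"] == marker_id] if "id" in results.columns else results.iloc[[int(marker_id)]]
    if len(row) == 0:
        raise KeyError(f"marker {marker_id!r} not in scan results")
    return float(row["contrib_pct"].iloc[0])


# ---------------------------------------------------------------------------
# FDR selection
# ---------------------------------------------------------------------------


@dataclass
class SignificanceSet:
    q_level: float
    m: int
    n_selected: int
    p_threshold: float | None
    selected_ids: list
    achieved_fdr_pct: float | None   # (m * P / n) x 100%

    def __post_init__(self) -> None:
        if self.n_selected > 0 and self.p_threshold is not None:
            assert self.m * self.p_threshold / self.n_selected <= self.q_level + 1e-12


def fdr_select(p_values, q: float = 0.01, ids=None) -> SignificanceSet:
    """Step-up selection at FDR level ``q`` on ranked p-values.

    Sort ascending and select the largest rank ``n`` with
    ``m * p_(n) / n <= q``; all markers with ``p <= p_(n)`` are selected.
    Empty selection if no rank qualifies.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if ids is None:
        ids = np.arange(m)
    ids = np.asarray(ids, dtype=object)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    ok = m * ranked / ranks <= q
    if not ok.any():
        return SignificanceSet(q, m, 0, None, [], None)
    n_sel = int(np.flatnonzero(ok)[-1]) + 1
    p_thr = float(ranked[n_sel - 1])
    selected = list(ids[order[:n_sel]])
    return SignificanceSet(q, m, n_sel, p_thr, selected, 100.0 * m * p_thr / n_sel)


# ---------------------------------------------------------------------------
# allele effects and inflation
# ---------------------------------------------------------------------------


def allele_effects(g_snp, y, min_class_n: int = 2) -> dict:
    """Mean phenotype per dosage class and homozygote percent difference.

    ``pct_reduction`` is ``100 * (mean_high - mean_low) / mean_high``
    between the two homozygote classes (dosage 0 vs 2), the way favorable
    alleles are usually reported for a decrease-the-trait objective.
    """
    g = np.asarray(g_snp, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (g >= 0) & np.isfinite(y)
    g, y = g[ok], y[ok]
    if np.unique(g).size < 2:
        raise ValueError("marker is monomorphic")
    means = {}
    counts = {}
    for cls in (0, 1, 2):
        sel = g == cls
        counts[cls] = int(sel.sum())
        means[cls] = float(y[sel].mean()) if sel.any() else None
    for cls in (0, 2):
        if counts[cls] < min_class_n:
            raise ValueError(f"homozygote class {cls} has {counts[cls]} accessions (class counts: {counts})")
    hi, lo = max(means[0], means[2]), min(means[0], means[2])
    pct = 100.0 * (hi - lo) / hi if hi != 0 else float("nan")
    return {"class_means": means, "class_counts": counts, "pct_reduction": pct}


def genomic_inflation(p_values) -> float:
    """Median-based genomic-inflation factor lambda_GC of a p-value vector."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
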