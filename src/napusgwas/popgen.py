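"""Marker QC, genomic relationships, structure covariates and LD.

Conventions: dosages count the minor allele; missing data are
mean-imputed for kinship and PCA, handled pairwise-complete for LD, and
never imputed for the QC statistics themselves.  Coordinates are
1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class UndefinedLDError(ValueError):
    """r² undefined: one of the vectors is constant on the complete pairs."""


@dataclass(frozen=True)
class LDPair:
    r2: float
    n_used: int


def filter_markers(
    G: GenotypeMatrix,
    marker_map: pd.DataFrame,
    maf_min: float = 0.05,
    missing_max: float = 0.20,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain markers with missingness < ``missing_max`` and MAF >= ``maf_min``.

    MAF is computed on observed calls only; marker order is preserved and
    the returned map row-aligns with the returned matrix.  Idempotent.
    """
    maf = G.maf()
    miss = G.missing_frac()
    maf_ok = np.where(np.isnan(maf), -1.0, maf) >= maf_min
    keep = (miss < missing_max) & maf_ok
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        warnings.warn("marker QC removed every marker", stacklevel=2)
    return G.take_markers(idx), marker_map.iloc[idx].reset_index(drop=True)


def compute_kinship(G: GenotypeMatrix, clamp_below: float | None = None) -> pd.DataFrame:
    """Centered genomic relationship matrix (VanRaden).

    ``K = Z Zᵀ / (2 Σ p_j (1 - p_j))`` with ``Z = dosage - 2p`` and missing
    dosages mean-imputed per marker.  ``clamp_below`` optionally zeroes
    off-diagonal entries below the given value (the study zeroed weak
    relationships below 0.05); off by default.
    """
    if G.n_samples < 2:
        raise ValueError("need >= 2 samples")
    freq = G.alt_freq()
    ok = np.isfinite(freq)
    if not ok.all():
        logger.warning("removing %d all-missing markers before kinship", (~ok).sum())
    X = G.imputed()[:, ok]
    p = freq[ok]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all retained markers are monomorphic")
    Z = X - 2.0 * p
    K = (Z @ Z.T) / denom
    if clamp_below is not None:
        off = ~np.eye(K.shape[0], dtype=bool)
        K[off & (K < clamp_below)] = 0.0
    return pd.DataFrame(K, index=G.samples, columns=G.samples)


def structure_pca(
    G: GenotypeMatrix,
    k: int = 2,
    maf_min: float = 0.2,
    max_markers: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Population-structure covariates: top-k PCs of the standardized dosages.

    The study inferred two groups with a Bayesian clustering model from
    5,000 SNPs at MAF >= 0.2; principal components computed under the same
    marker filter are the standard fixed-effect surrogate for that
    membership matrix.  Columns are zero-mean PC scores; ``k=0`` returns
    an empty covariate set (intercept-only fixed effects downstream).
    """
    if k >= G.n_samples:
        raise ValueError("k must be smaller than the sample count")
    if k == 0:
        return pd.DataFrame(index=G.samples)
    maf = G.maf()
    idx = np.flatnonzero(np.where(np.isnan(maf), -1.0, maf) >= maf_min)
    if idx.size == 0:
        raise ValueError("no markers pass the structure MAF filter")
    if idx.size > max_markers:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(idx, size=max_markers, replace=False))
    X = G.imputed()[:, idx]
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|score| entry of each PC is positive
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(scores, index=G.samples, columns=[f"PC{j+1}" for j in range(k)])


def ld_r2(g1, g2) -> LDPair:
    """Composite LD: squared Pearson correlation of dosages, pairwise-complete."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING) & np.isfinite(g1) & np.isfinite(g2)
    x, y = g1[ok], g2[ok]
    if x.size < 3:
        raise UndefinedLDError(f"only {x.size} complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedLDError("constant dosage vector on the complete pairs")
    r = np.corrcoef(x, y)[0, 1]
    return LDPair(r2=float(r * r), n_used=int(x.size))


@dataclass
class LDDecay:
    """Binned LD-decay curve for one chromosome."""

    curve: pd.DataFrame  # columns: bin_mid, mean_r2, n_pairs
    max_dist_bp: int

    BELOW_FIRST_BIN = -1.0

    def crossing_distance(self, level: float) -> float:
        """First distance (bp) at which binned mean r² drops below ``level``.

        Linear interpolation between bin midpoints; returns
        ``BELOW_FIRST_BIN`` if even the first bin is already below the
        requested level, and NaN if the curve never crosses it.
        """
        cv = self.curve.dropna(subset=["mean_r2"])
        mids = cv["bin_mid"].to_numpy()
        r2 = cv["mean_r2"].to_numpy()
        if len(r2) == 0:
            return float("nan")
        if r2[0] < level:
            return self.BELOW_FIRST_BIN
        below = np.flatnonzero(r2 < level)
        if below.size == 0:
            return float("nan")
        i = below[0]
        x0, x1, y0, y1 = mids[i - 1], mids[i], r2[i - 1], r2[i]
        if y0 == y1:
            return float(x1)
        return float(x0 + (y0 - level) * (x1 - x0) / (y0 - y1))


def ld_decay(
    G: GenotypeMatrix,
    marker_map: pd.DataFrame,
    chrom: str,
    max_dist_bp: int = 500_000,
    n_bins: int = 20,
) -> LDDecay:
    """Mean pairwise r² per physical-distance bin on one chromosome.

    Missing dosages are mean-imputed for this summary (pairwise-complete
    LD is available via :func:`ld_r2` for individual pairs).
    """
    sel = np.flatnonzero((marker_map["chrom"] == chrom).to_numpy())
    pos = marker_map["pos"].to_numpy()[sel]
    if sel.size < 2:
        return LDDecay(pd.DataFrame(columns=["bin_mid", "mean_r2", "n_pairs"]), max_dist_bp)
    X = G.imputed()[:, sel]
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    poly = sd > 0
    X, pos = X[:, poly] / sd[poly], pos[poly]
    m = X.shape[1]
    if m < 2:
        return LDDecay(pd.DataFrame(columns=["bin_mid", "mean_r2", "n_pairs"]), max_dist_bp)
    C = (X.T @ X) / X.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    d = pos[ju] - pos[iu]
    within = d <= max_dist_bp
    d, r2 = d[within], C[iu[within], ju[within]] ** 2
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel_b = which == b
        rows.append(
            {
                "bin_mid": 0.5 * (edges[b] + edges[b + 1]),
                "mean_r2": float(r2[sel_b].mean()) if sel_b.any() else np.nan,
                "n_pairs": int(sel_b.sum()),
            }
        )
    return LDDecay(pd.DataFrame(rows), max_dist_bp)


def mean_adjacent_r2(G: GenotypeMatrix, marker_map: pd.DataFrame) -> float:
    """Mean composite r² between map-adjacent marker pairs (all chromosomes)."""
    vals = []
    chroms = marker_map["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        X = G.imputed()[:, idx]
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        for j in range(len(idx) - 1):
            if sd[j] > 0 and sd[j + 1] > 0:
                r = float(np.mean(X[:, j] * X[:, j + 1]) / (sd[j] * sd[j + 1]))
                vals.append(r * r)
    return float(np.mean(vals)) if vals else float("nan")
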