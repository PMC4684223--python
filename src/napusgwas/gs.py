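"""Ridge-regression BLUP genomic prediction.

Fits ``y = 1 mu + M u + e`` with i.i.d. marker effects
``u ~ N(0, sigma2_u I)``.  The shrinkage parameter
``lambda = sigma2_e / sigma2_u`` is estimated by REML on the equivalent
GBLUP model (kernel ``M Mᵀ``), and effects are recovered through the
dual identity ``(MᵀM + lambda I)⁻¹ Mᵀ v = Mᵀ (M Mᵀ + lambda I)⁻¹ v`` so
the cost scales with the sample count, not the marker count.  Predictive
ability is the Pearson correlation between predicted and observed
phenotypes in a validation set.

The experiment runner reproduces the training-fraction x marker-panel
design used to compare whole-genome panels against GWAS-significant
markers: for each random train/validation split, markers can be (a) all
markers, (b) those significant in a Q+K GWAS run *inside the training
fold only* (no leakage of validation phenotypes into marker selection),
or (c) an equal number of randomly drawn markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, popgen
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RRBLUPFit:
    mu: float
    effects: np.ndarray
    sigma2_marker: float
    sigma2_resid: float
    train_col_means: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass(frozen=True)
class GSDesign:
    train_fractions: tuple = (0.4, 0.5, 0.6, 0.7, 0.8)
    marker_modes: tuple = ("all", "gwas_significant", "random_matched")
    n_reps: int = 100
    q_level: float = 0.01
    n_pcs: int = 2
    fallback_top_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < f < 1 for f in self.train_fractions):
            raise ValueError("train fractions must lie in (0, 1)")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")


def rrblup_fit(G_train, y_train, lam: float | None = None) -> RRBLUPFit:
    """Fit RR-BLUP marker effects.

    Markers are centered by their training means (the intercept absorbs
    the offset).  With ``lam`` given, uses the closed-form ridge solution
    ``u = (MᵀM + lam I)⁻¹ Mᵀ (y - ȳ)`` on the centered design with
    ``mu = ȳ``.  With ``lam=None``, lambda is the REML variance ratio of
    the equivalent GBLUP model and ``mu`` its GLS intercept.
    """
    if isinstance(G_train, GenotypeMatrix):
        M = G_train.imputed()
    else:
        M = np.asarray(G_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, m = M.shape
    if y.size != n:
        raise ValueError("phenotype length does not match sample count")
    if n < 10:
        raise ValueError("need >= 10 training samples")
    if np.std(y) == 0:
        raise ValueError("zero phenotypic variance in the training set")
    col_means = M.mean(axis=0)
    Mc = M - col_means  # markers centered by training means; mu absorbs the offset

    if lam is not None:
        if lam <= 0:
            raise ValueError("lam must be > 0")
        yc = y - y.mean()
        if n <= m:
            alpha = np.linalg.solve(Mc @ Mc.T + lam * np.eye(n), yc)
            u = Mc.T @ alpha
        else:
            u = np.linalg.solve(Mc.T @ Mc + lam * np.eye(m), Mc.T @ yc)
        return RRBLUPFit(float(y.mean()), u, float("nan"), float("nan"), col_means)

    # REML on the scaled kernel keeps the variance ratio well inside the
    # optimizer's bounds; the scale divides back out of sigma2_marker.
    K = Mc @ Mc.T
    c = float(np.trace(K)) / n
    if c == 0:
        raise ValueError("all markers are monomorphic in the training set")
    null = association.fit_null(y, None, K / c)
    mu = float(null.beta[0])
    alpha = null.eigvecs @ ((null.eigvecs.T @ (y - mu)) / (null.eigvals + null.delta))
    u = Mc.T @ alpha / c
    return RRBLUPFit(mu, u, null.sigma2_g / c, null.sigma2_e, col_means)


def gebv_predict(fit: RRBLUPFit, G_new) -> np.ndarray:
    """Genomic estimated breeding values ``mu + M u`` for new samples.

    Missing dosages are imputed with the training-set marker means.
    """
    if isinstance(G_new, GenotypeMatrix):
        M = G_new.imputed(col_means=fit.train_col_means)
    else:
        M = np.asarray(G_new, dtype=float)
    if M.shape[1] != fit.effects.size:
        raise ValueError(
            f"marker mismatch: fit has {fit.effects.size} effects, input has {M.shape[1]} markers"
        )
    return fit.mu + (M - fit.train_col_means) @ fit.effects


def predictive_ability(predicted, observed) -> float:
    """Pearson correlation of predicted vs observed phenotypes."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size != o.size or p.size < 3:
        raise ValueError("need >= 3 aligned validation samples")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("predictive ability undefined for constant input")
    return float(np.corrcoef(p, o)[0, 1])


def run_gs_experiment(
    G: GenotypeMatrix,
    y,
    design: GSDesign,
    marker_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Training-fraction x marker-panel cross-validation experiment.

    ``y`` holds one (replicate-averaged) phenotype per accession.  For
    every fraction x mode x rep, a seeded random split is drawn; the
    ``gwas_significant`` mode recomputes kinship, structure PCs, the Q+K
    scan and step-up FDR selection within the training fold, falling back
    to the top ``fallback_top_n`` markers by p-value when the selection
    is empty (logged).  ``random_matched`` draws the same number of
    markers uniformly at random.  Returns one row per rep with columns
    ``fraction, mode, rep, ability, n_markers`` (summarize with
    :func:`summarize_gs`).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = G.n_samples
    if y.size != n:
        raise ValueError("phenotype length does not match sample count")
    rows = []
    for fraction in design.train_fractions:
        n_train = int(round(fraction * n))
        if n_train < 10:
            raise ValueError(f"training fold of {n_train} samples is too small")
        for rep in range(design.n_reps):
            rng = np.random.default_rng((design.seed, int(fraction * 1000), rep))
            perm = rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            Gtr, Gva = G.take_samples(tr), G.take_samples(va)
            ytr, yva = y[tr], y[va]

            sig_idx: np.ndarray | None = None
            n_sig = 0
            if "gwas_significant" in design.marker_modes or "random_matched" in design.marker_modes:
                K = popgen.compute_kinship(Gtr).to_numpy()
                Q = popgen.structure_pca(Gtr, k=design.n_pcs, seed=rep).to_numpy() if design.n_pcs else None
                res = association.scan(Gtr, ytr, Q=Q, K=K)
                sel = association.fdr_select(res["p_value"].to_numpy(), q=design.q_level)
                if sel.n_selected > 0:
                    sig_idx = np.asarray(sel.selected_ids, dtype=int)
                else:
                    sig_idx = np.argsort(res["p_value"].to_numpy(), kind="stable")[: design.fallback_top_n]
                    logger.info(
                        "empty within-fold significant set (fraction %.2f rep %d); "
                        "falling back to top %d markers by p",
                        fraction, rep, design.fallback_top_n,
                    )
                n_sig = sig_idx.size

            for mode in design.marker_modes:
                if mode == "all":
                    idx = np.arange(G.n_markers)
                elif mode == "gwas_significant":
                    idx = sig_idx
                elif mode == "random_matched":
                    idx = rng.choice(G.n_markers, size=n_sig, replace=False)
                else:
                    raise ValueError(f"unknown marker mode {mode!r}")
                fit = rrblup_fit(Gtr.take_markers(idx), ytr)
                pred = gebv_predict(fit, Gva.take_markers(idx))
                rows.append(
                    {
                        "fraction": fraction,
                        "mode": mode,
                        "rep": rep,
                        "ability": predictive_ability(pred, yva),
                        "n_markers": int(idx.size),
                    }
                )
    return pd.DataFrame(rows)


def summarize_gs(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD predictive ability per fraction x mode."""
    out = (
        per_rep.groupby(["fraction", "mode"], observed=True)
        .agg(
            mean_ability=("ability", "mean"),
            sd_ability=("ability", "std"),
            mean_n_markers=("n_markers", "mean"),
            n_reps=("ability", "count"),
        )
        .reset_index()
    )
    return out
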