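"""Core genotype container shared by every analysis stage.

Genotypes are stored as minor/alt-allele dosages (0, 1, 2) in a dense
``int8`` matrix of shape ``(n_samples, n_markers)``; missing calls use the
sentinel ``MISSING`` (-1).  The marker map is a plain :class:`pandas.DataFrame`
with one row per marker and columns ``id, chrom, pos, major_allele,
minor_allele`` — positions are 1-based and strictly increasing within a
chromosome, matching VCF/GFF3 conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

MAP_COLUMNS = ["id", "chrom", "pos", "major_allele", "minor_allele"]


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    """Check required columns and strictly increasing within-chromosome positions."""
    missing_cols = [c for c in ("id", "chrom", "pos") if c not in marker_map.columns]
    if missing_cols:
        raise ValueError(f"marker map lacks required columns: {missing_cols}")
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix with sample identifiers.

    Parameters
    ----------
    dosages
        ``(n_samples, n_markers)`` integer array in {0, 1, 2, MISSING}.
    samples
        Sample identifiers, length ``n_samples``.
    """

    dosages: np.ndarray
    samples: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x markers array")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values: {bad}")
        if self.samples is None:
            self.samples = np.array([f"S{i:04d}" for i in range(self.n_samples)])
        else:
            self.samples = np.asarray(self.samples, dtype=object)
            if len(self.samples) != self.n_samples:
                raise ValueError("sample id count does not match dosage rows")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def missing_frac(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return self.missing_mask().mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted (alt) allele among observed calls."""
        obs = self.dosages != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(obs, self.dosages, 0).sum(axis=0) / (2.0 * n_obs)
        return np.where(n_obs > 0, freq, np.nan)

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency (min(f, 1-f) of the observed alt freq)."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def imputed(self, col_means: np.ndarray | None = None) -> np.ndarray:
        """Float dosage matrix with missing entries replaced by per-marker means.

        ``col_means`` overrides the imputation values (e.g. training-set means
        when imputing a validation set).  Markers with no observed calls are
        imputed to 0 and should normally be removed by QC beforehand.
        """
        X = self.dosages.astype(float)
        miss = self.missing_mask()
        if col_means is None:
            obs = ~miss
            n_obs = obs.sum(axis=0)
            sums = np.where(obs, X, 0.0).sum(axis=0)
            col_means = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), 0.0)
        if miss.any():
            X[miss] = np.broadcast_to(col_means, X.shape)[miss]
        return X

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, idx], self.samples)

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[idx, :], self.samples[idx])
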