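"""Synthetic population generator.

Emulates the statistical structure of a rapeseed (*Brassica napus*)
diversity panel: ~520 inbred-line accessions drawn from two weakly
diverged subpopulations, ~32k biallelic SNPs after QC, linkage
disequilibrium decaying over tens of kilobases, and replicated multi-year
phenotypes with genotype (G), environment (E) and G x E variance
components giving broad-sense heritabilities in the 0.75-0.89 range.

Model
-----
Ancestral allele frequencies are drawn uniformly on ``[maf_low, maf_high]``;
subpopulation frequencies follow the Balding-Nichols Beta model
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` parameterised by ``fst``.  Within each
haplotype, LD is produced by a first-order Markov copying process on a
latent uniform: at each marker the latent value is copied from the
previous marker with probability ``ld_rho`` and redrawn otherwise, and the
allele is the indicator ``u < p``.  Copying the latent rank rather than
the allele keeps every marker's marginal frequency exactly at its
subpopulation value while adjacent-marker correlation increases
monotonically with ``ld_rho``.

Phenotypes follow the balanced two-way model
``y_ijk = mu + g_i + e_j + (ge)_ij + eps_ijk`` with the genetic value
``g_i`` the sum of planted-QTL additive effects and an i.i.d. polygenic
term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

_BASES = np.array(list("ACGT"))


def default_chromosomes(n_markers_total: int = 31839) -> list[tuple[str, int, int]]:
    """The 19 B. napus pseudochromosomes (A01-A10, C01-C09) with markers
    distributed proportionally to physical length (A ~25 Mb, C ~40 Mb)."""
    names = [f"A{i:02d}" for i in range(1, 11)] + [f"C{i:02d}" for i in range(1, 10)]
    lengths = [25_000_000] * 10 + [40_000_000] * 9
    total = sum(lengths)
    counts = [max(1, int(round(n_markers_total * l / total))) for l in lengths]
    return [(n, c, l) for n, c, l in zip(names, counts, lengths)]


@dataclass(frozen=True)
class SimConfig:
    """Genotype-simulation parameters; defaults emulate the study panel."""

    n_samples: int = 520
    chromosomes: tuple = tuple(default_chromosomes())
    n_subpops: int = 2
    fst: float = 0.05
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.7
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        for chrom in self.chromosomes:
            name, n_markers, length_bp = chrom
            if n_markers < 1 or length_bp < n_markers:
                raise ValueError(f"chromosome {name}: invalid marker count or length")


@dataclass(frozen=True)
class QTLSpec:
    """A planted causal marker with an additive effect per minor-allele copy."""

    marker_id: str
    effect: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("QTL effect must be finite")


@dataclass(frozen=True)
class TraitSimParams:
    """Variance components of the balanced two-way phenotype model."""

    mu: float = 0.0
    var_g_poly: float = 1.0
    var_e: float = 0.5
    var_ge: float = 0.5
    var_resid: float = 0.5
    n_env: int = 2
    n_rep: int = 3

    def __post_init__(self) -> None:
        for name in ("var_g_poly", "var_e", "var_ge", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")


@dataclass
class GenotypeSimulation:
    """Output bundle of :func:`simulate_genotypes`.

    ``haplotypes`` holds the phased, fully observed haplotype pair per
    sample (shape ``2*n_samples x n_markers``, rows ``2i`` and ``2i+1``
    belong to sample ``i``) — the ground truth behind the unphased,
    possibly missing ``genotypes`` — for use as an oracle in
    haplotype-frequency tests.
    """

    genotypes: GenotypeMatrix
    marker_map: pd.DataFrame
    subpops: np.ndarray
    haplotypes: np.ndarray
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _positions(rng: np.random.Generator, n: int, length_bp: int) -> np.ndarray:
    """n strictly increasing 1-based positions on [1, length_bp]."""
    raw = np.sort(rng.random(n)) * max(length_bp - n, 1)
    pos = raw.astype(np.int64) + 1 + np.arange(n)
    return pos


def simulate_genotypes(config: SimConfig) -> GenotypeSimulation:
    """Simulate a structured SNP panel.

    Deterministic for a given config (including its seed).  Returns the
    unphased dosage matrix, a marker map, per-sample subpopulation labels
    and the underlying phased haplotypes.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.n_subpops
    # contiguous, near-equal subpopulation blocks
    subpops = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    hap_pop = np.repeat(subpops, 2)

    map_rows = []
    hap_chunks = []
    for chrom, m, length_bp in config.chromosomes:
        pos = _positions(rng, m, length_bp)
        p_anc = rng.uniform(config.maf_low, config.maf_high, size=m)
        if config.fst > 0 and k > 1:
            F = config.fst
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            p_sub = rng.beta(a[None, :].repeat(k, 0), b[None, :].repeat(k, 0))
        else:
            p_sub = np.broadcast_to(p_anc, (k, m)).copy()
        # latent-uniform Markov chain along each haplotype
        u = np.empty((2 * n, m))
        u[:, 0] = rng.random(2 * n)
        if m > 1:
            copy = rng.random((2 * n, m - 1)) < config.ld_rho
            fresh = rng.random((2 * n, m - 1))
            for j in range(1, m):
                u[:, j] = np.where(copy[:, j - 1], u[:, j - 1], fresh[:, j - 1])
        haps = (u < p_sub[hap_pop, :]).astype(np.int8)
        hap_chunks.append(haps)
        major = rng.integers(0, 4, size=m)
        minor = (major + rng.integers(1, 4, size=m)) % 4
        map_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "major_allele": _BASES[major],
                    "minor_allele": _BASES[minor],
                }
            )
        )

    haplotypes = np.concatenate(hap_chunks, axis=1)
    marker_map = pd.concat(map_rows, ignore_index=True)
    marker_map.insert(0, "id", [f"rs{i}" for i in range(len(marker_map))])

    dosage = (haplotypes[0::2, :] + haplotypes[1::2, :]).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = MISSING

    samples = np.array([f"ACC{i:04d}" for i in range(n)], dtype=object)
    return GenotypeSimulation(
        genotypes=GenotypeMatrix(dosage, samples),
        marker_map=marker_map,
        subpops=subpops,
        haplotypes=haplotypes,
        config=config,
    )


def simulate_phenotypes(
    G: GenotypeMatrix,
    marker_map: pd.DataFrame,
    qtls: list[QTLSpec],
    params: TraitSimParams,
    seed: int,
    trait: str = "trait",
) -> pd.DataFrame:
    """Balanced replicated phenotypes for every accession.

    Returns a long-format table with columns
    ``accession, trait, env, rep, value`` and exactly
    ``n_samples * n_env * n_rep`` rows.
    """
    rng = np.random.default_rng(seed)
    n = G.n_samples
    ids = marker_map["id"].to_numpy()
    g = np.zeros(n)
    for q in qtls:
        hit = np.flatnonzero(ids == q.marker_id)
        if hit.size == 0:
            raise KeyError(f"QTL marker {q.marker_id!r} not in marker map")
        dose = G.imputed()[:, hit[0]]
        g += q.effect * dose
    if params.var_g_poly > 0:
        g += rng.normal(0.0, np.sqrt(params.var_g_poly), size=n)

    e = rng.normal(0.0, np.sqrt(params.var_e), size=params.n_env) if params.var_e > 0 else np.zeros(params.n_env)
    ge = (
        rng.normal(0.0, np.sqrt(params.var_ge), size=(n, params.n_env))
        if params.var_ge > 0
        else np.zeros((n, params.n_env))
    )
    eps = (
        rng.normal(0.0, np.sqrt(params.var_resid), size=(n, params.n_env, params.n_rep))
        if params.var_resid > 0
        else np.zeros((n, params.n_env, params.n_rep))
    )
    y = params.mu + g[:, None, None] + e[None, :, None] + ge[:, :, None] + eps

    idx = pd.MultiIndex.from_product(
        [G.samples, [f"env{j+1}" for j in range(params.n_env)], np.arange(1, params.n_rep + 1)],
        names=["accession", "env", "rep"],
    )
    out = pd.DataFrame(index=idx).reset_index()
    out.insert(1, "trait", trait)
    out["value"] = y.ravel()
    return out


def simulate_annotation(
    marker_map: pd.DataFrame,
    qtls: list[QTLSpec],
    gene_density: float,
    seed: int,
    causal_offset_bp: int = 10_000,
    gene_length_bp: tuple[int, int] = (500, 5000),
) -> pd.DataFrame:
    """Random gene models plus one guaranteed gene near each planted QTL.

    ``gene_density`` is genes per Mb of mapped chromosome span.  Genes are
    non-overlapping, sorted by (chrom, start), stranded, and each QTL
    marker has at least one gene whose nearest edge lies within
    ``causal_offset_bp`` of it.  Returns a DataFrame with columns
    ``gene_id, chrom, start, end, strand``.
    """
    if gene_density < 0:
        raise ValueError("gene_density must be >= 0")
    rng = np.random.default_rng(seed)
    ids = marker_map["id"].to_numpy()
    taken: dict[str, list[tuple[int, int]]] = {}
    rows: list[dict] = []

    def _free(chrom: str, start: int, end: int) -> bool:
        return all(end < s or start > e for s, e in taken.get(chrom, []))

    # causal genes first so their placement is never displaced
    for q in qtls:
        hit = np.flatnonzero(ids == q.marker_id)
        if hit.size == 0:
            raise KeyError(f"QTL marker {q.marker_id!r} not in marker map")
        chrom = marker_map["chrom"].iloc[hit[0]]
        pos = int(marker_map["pos"].iloc[hit[0]])
        gap = int(rng.integers(1, max(causal_offset_bp, 2)))
        length = int(rng.integers(*gene_length_bp))
        start, end = pos + gap, pos + gap + length - 1
        rows.append(
            {
                "gene_id": f"gene_causal_{q.marker_id}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        taken.setdefault(chrom, []).append((start, end))

    if gene_density > 0:
        for chrom, grp in marker_map.groupby("chrom", sort=False):
            span = int(grp["pos"].max())
            n_genes = int(round(gene_density * span / 1e6))
            starts = np.sort(rng.integers(1, max(span, 2), size=n_genes))
            lengths = rng.integers(*gene_length_bp, size=n_genes)
            for i, (s, ln) in enumerate(zip(starts, lengths)):
                start, end = int(s), int(s + ln - 1)
                if not _free(chrom, start, end):
                    continue
                rows.append(
                    {
                        "gene_id": f"gene_{chrom}_{i:05d}",
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "strand": "+" if rng.random() < 0.5 else "-",
                    }
                )
                taken.setdefault(chrom, []).append((start, end))

    if not rows:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])
    return pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
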