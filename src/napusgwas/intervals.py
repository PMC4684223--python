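"""QTL determination intervals, haplotype blocks and candidate genes.

The R-QTL walk delimits the physical region tagged by a significant SNP
using LD alone: starting from the lead SNP, step outward marker by
marker computing r² against the lead; the first flanking SNP whose r²
drops below the threshold (default 0.1) *is accepted as the border* —
its position bounds the interval.  If the chromosome end is reached
first, the terminal marker is the border.  Markers whose r² with the
lead is undefined (monomorphic on the complete pairs) carry no evidence
of linkage and stop the walk the same way.

Haplotype blocks follow the four-gamete rule: adjacent markers stay in
one block while at most three of the four possible two-locus gametes
exceed a small frequency threshold; the fourth gamete implies a
detected recombination and opens a new block.  Gamete frequencies are
estimated from unphased genotypes by the standard two-locus EM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .popgen import UndefinedLDError, ld_r2

logger = logging.getLogger(__name__)


@dataclass
class RQTLInterval:
    chrom: str
    lead_ids: list
    left_border_pos: int
    right_border_pos: int

    @property
    def length_kb(self) -> float:
        return interval_length_kb(self.left_border_pos, self.right_border_pos)


@dataclass(frozen=True)
class HaplotypeBlock:
    chrom: str
    start_pos: int
    end_pos: int
    marker_ids: tuple


@dataclass(frozen=True)
class GeneHit:
    gene_id: str
    chrom: str
    start: int
    end: int
    distance_bp: int
    relation: str  # upstream / downstream / contains


def interval_length_kb(start_bp: int, end_bp: int) -> float:
    """Interval length in kb, rounded half-up to 2 decimals for reporting."""
    if end_bp < start_bp:
        raise ValueError("end < start")
    kb = Decimal(int(end_bp) - int(start_bp)) / Decimal(1000)
    return float(kb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _r2_below(G: GenotypeMatrix, i: int, j: int, r2_min: float) -> bool:
    """True when r²(marker_i, marker_j) is below threshold or undefined."""
    try:
        return ld_r2(G.dosages[:, i], G.dosages[:, j]).r2 < r2_min
    except UndefinedLDError:
        return True


def rqtl_walk(
    lead_id: str,
    G: GenotypeMatrix,
    marker_map: pd.DataFrame,
    r2_min: float = 0.1,
    stop_at: set | None = None,
) -> RQTLInterval:
    """LD walk outward from one significant SNP.

    ``stop_at`` optionally names marker indices (map row positions) that
    terminate the walk immediately when they are the adjacent marker —
    used by :func:`build_rqtl_set` for map-adjacent significant SNPs.
    """
    ids = marker_map["id"].to_numpy()
    hits = np.flatnonzero(ids == lead_id)
    if hits.size == 0:
        raise KeyError(f"lead marker {lead_id!r} not in map")
    i = int(hits[0])
    chrom = marker_map["chrom"].iloc[i]
    on_chrom = np.flatnonzero((marker_map["chrom"] == chrom).to_numpy())
    lo, hi = int(on_chrom[0]), int(on_chrom[-1])
    pos = marker_map["pos"].to_numpy()
    stop_at = stop_at or set()

    left = i
    j = i - 1
    while j >= lo:
        left = j
        if j in stop_at or _r2_below(G, i, j, r2_min):
            break
        j -= 1

    right = i
    j = i + 1
    while j <= hi:
        right = j
        if j in stop_at or _r2_below(G, i, j, r2_min):
            break
        j += 1

    return RQTLInterval(
        chrom=chrom,
        lead_ids=[lead_id],
        left_border_pos=int(pos[left]),
        right_border_pos=int(pos[right]),
    )


def build_rqtl_set(
    significant_ids,
    G: GenotypeMatrix,
    marker_map: pd.DataFrame,
    r2_min: float = 0.1,
) -> list[RQTLInterval]:
    """One R-QTL per significant SNP, with the map-adjacency rule and merging.

    When two significant SNPs occupy immediately adjacent map positions,
    each bounds the other's interval on the shared side (the left member
    delimits the right member's leftward walk and vice versa).  Intervals
    whose borders coincide exactly are merged, pooling their lead SNPs,
    so e.g. two peak SNPs inside one LD block report a single interval.
    """
    ids = marker_map["id"].to_numpy()
    sig_idx = []
    for mid in significant_ids:
        hits = np.flatnonzero(ids == mid)
        if hits.size == 0:
            raise KeyError(f"significant marker {mid!r} not in map")
        sig_idx.append(int(hits[0]))
    sig_set = set(sig_idx)

    merged: dict[tuple, RQTLInterval] = {}
    for i in sorted(sig_idx):
        adjacent_sig = {j for j in (i - 1, i + 1) if j in sig_set}
        iv = rqtl_walk(ids[i], G, marker_map, r2_min=r2_min, stop_at=adjacent_sig)
        key = (iv.chrom, iv.left_border_pos, iv.right_border_pos)
        if key in merged:
            merged[key].lead_ids.extend(iv.lead_ids)
            logger.info("merged R-QTL leads %s at %s:%d-%d", merged[key].lead_ids, *key)
        else:
            merged[key] = iv
    return list(merged.values())


# ---------------------------------------------------------------------------
# four-gamete haplotype blocks
# ---------------------------------------------------------------------------


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value (Wigginton et al. style).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on allele counts.  Mid-p off.
    """
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # ensure "minor" really is the rarer allele
        n_minor = 2 * n - n_minor
    if n == 0 or n_minor == 0:
        return 1.0
    het_probs = np.zeros(n_minor + 1)
    mid = int(round(n_minor * (2 * n - n_minor) / (2.0 * n)))
    if mid % 2 != n_minor % 2:
        mid += 1
    het_probs[mid] = 1.0
    # downward recurrence
    het, hom_r, hom_c = mid, (n_minor - mid) // 2, n - (mid + (n_minor - mid) // 2)
    h, hr, hc = mid, hom_r, hom_c
    while h > 1:
        het_probs[h - 2] = het_probs[h] * h * (h - 1.0) / (4.0 * (hr + 1.0) * (hc + 1.0))
        h -= 2
        hr += 1
        hc += 1
    h, hr, hc = mid, hom_r, hom_c
    while h <= n_minor - 2:
        het_probs[h + 2] = het_probs[h] * 4.0 * hr * hc / ((h + 2.0) * (h + 1.0))
        h += 2
        hr -= 1
        hc -= 1
    het_probs /= het_probs.sum()
    obs = n_het if n_het <= n_minor else n_minor
    return float(min(1.0, het_probs[het_probs <= het_probs[obs] * (1 + 1e-12)].sum()))


def two_locus_em(gA, gB, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """EM estimate of the four two-locus haplotype frequencies (AB, Ab, aB, ab)
    from unphased dosages, using pairwise-complete samples.

    Only the double heterozygotes are phase-ambiguous; EM splits them
    between the coupling (AB/ab) and repulsion (Ab/aB) configurations in
    proportion to the current frequency estimates.
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    ok = (gA >= 0) & (gB >= 0)
    a, b = gA[ok].astype(int), gB[ok].astype(int)
    n = a.size
    if n == 0:
        raise ValueError("no complete pairs")
    cnt = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            cnt[i, j] = np.sum((a == i) & (b == j))
    # known haplotype counts (allele 1 = counted/minor allele)
    #   haplotypes: [11, 10, 01, 00] w.r.t. (A, B) counted alleles
    base = np.array(
        [
            2 * cnt[2, 2] + cnt[2, 1] + cnt[1, 2],            # 11
            2 * cnt[2, 0] + cnt[2, 1] + cnt[1, 0],            # 10
            2 * cnt[0, 2] + cnt[0, 1] + cnt[1, 2],            # 01
            2 * cnt[0, 0] + cnt[0, 1] + cnt[1, 0],            # 00
        ],
        dtype=float,
    )
    ndh = cnt[1, 1]  # double heterozygotes
    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        pc = freqs[0] * freqs[3]
        pr = freqs[1] * freqs[2]
        share = pc / (pc + pr) if pc + pr > 0 else 0.5
        counts = base + ndh * np.array([share, 1 - share, 1 - share, share])
        new = counts / counts.sum()
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    return freqs


def four_gamete_blocks(
    G: GenotypeMatrix,
    marker_map: pd.DataFrame,
    fourth_gamete_freq: float = 0.01,
    maf_min: float = 0.05,
    hw_p_min: float = 0.001,
    min_genotype_rate: float = 0.75,
) -> list[HaplotypeBlock]:
    """Four-gamete haplotype blocks over QC-passing markers.

    Markers failing the MAF, genotype-rate or Hardy-Weinberg filters are
    excluded before blocking.  A block extends while each adjacent
    retained pair shows at most three gametes above
    ``fourth_gamete_freq``; the retained markers are partitioned into
    map-contiguous, non-overlapping blocks.
    """
    maf = G.maf()
    rate = 1.0 - G.missing_frac()
    keep = (np.where(np.isnan(maf), -1, maf) >= maf_min) & (rate >= min_genotype_rate)
    for j in np.flatnonzero(keep):
        g = G.dosages[:, j]
        obs = g[g >= 0]
        p = hwe_exact_p(int((obs == 1).sum()), int((obs == 2).sum()), int((obs == 0).sum()))
        if p < hw_p_min:
            keep[j] = False
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        return []

    pos = marker_map["pos"].to_numpy()
    chroms = marker_map["chrom"].to_numpy()
    ids = marker_map["id"].to_numpy()
    blocks: list[HaplotypeBlock] = []
    cur = [int(idx[0])]
    for j in idx[1:]:
        j = int(j)
        prev = cur[-1]
        same_chrom = chroms[j] == chroms[prev]
        compatible = False
        if same_chrom:
            freqs = two_locus_em(G.dosages[:, prev], G.dosages[:, j])
            compatible = np.sum(freqs > fourth_gamete_freq) <= 3
        if compatible:
            cur.append(j)
        else:
            blocks.append(
                HaplotypeBlock(chroms[cur[0]], int(pos[cur[0]]), int(pos[cur[-1]]), tuple(ids[cur]))
            )
            cur = [j]
    blocks.append(HaplotypeBlock(chroms[cur[0]], int(pos[cur[0]]), int(pos[cur[-1]]), tuple(ids[cur])))
    return blocks


# ---------------------------------------------------------------------------
# candidate genes
# ---------------------------------------------------------------------------


def candidate_genes(
    query_pos: int,
    chrom: str,
    annotation: pd.DataFrame,
    window_bp: int = 250_000,
) -> list[GeneHit]:
    """Genes overlapping the +/- ``window_bp`` window around a lead SNP.

    Distance is 0 for genes containing the query position, otherwise the
    bp distance to the nearer gene edge; results sorted by distance.
    """
    if len(annotation) == 0:
        return []
    if chrom not in set(annotation["chrom"]):
        warnings.warn(f"chromosome {chrom!r} absent from annotation", stacklevel=2)
        return []
    sub = annotation[annotation["chrom"] == chrom]
    lo, hi = query_pos - window_bp, query_pos + window_bp
    sub = sub[(sub["end"] >= lo) & (sub["start"] <= hi)]
    hits = []
    for _, g in sub.iterrows():
        if g["start"] <= query_pos <= g["end"]:
            dist, rel = 0, "contains"
        elif g["end"] < query_pos:
            dist, rel = int(query_pos - g["end"]), "upstream"
        else:
            dist, rel = int(g["start"] - query_pos), "downstream"
        hits.append(GeneHit(str(g["gene_id"]), chrom, int(g["start"]), int(g["end"]), dist, rel))
    return sorted(hits, key=lambda h: (h.distance_bp, h.start))
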