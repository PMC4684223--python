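"""End-to-end pipeline: QC -> phenotype statistics -> K/Q -> Q+K scan ->
FDR -> R-QTL intervals -> haplotype blocks -> candidate genes -> GS."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, gs, intervals, io, phenotypes, popgen
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotype_tsv: str
    marker_map_tsv: str
    phenotype_tsv: str
    out_dir: str
    annotation_gff3: str | None = None
    maf_min: float = 0.05
    missing_max: float = 0.20
    structure_k: int = 2
    fdr_q: float = 0.01
    r2_min: float = 0.1
    gene_window_bp: int = 250_000
    gs_design: gs.GSDesign = field(default_factory=lambda: gs.GSDesign(n_reps=20))
    run_gs: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = raw.pop("gs_design", None)
        cfg = cls(**raw)
        if design is not None:
            cfg.gs_design = gs.GSDesign(**{k: tuple(v) if isinstance(v, list) else v for k, v in design.items()})
        return cfg


class PipelineError(RuntimeError):
    pass


def _align_samples(G: GenotypeMatrix, pheno: pd.DataFrame) -> tuple[GenotypeMatrix, pd.DataFrame]:
    geno_ids = set(map(str, G.samples))
    pheno_ids = set(map(str, pheno["accession"].unique()))
    common = geno_ids & pheno_ids
    if not common:
        raise PipelineError(
            f"no overlapping samples: {len(geno_ids)} genotyped vs {len(pheno_ids)} phenotyped"
        )
    logger.info("using %d samples common to genotype and phenotype files", len(common))
    keep = np.array([str(s) in common for s in G.samples])
    return G.take_samples(np.flatnonzero(keep)), pheno[pheno["accession"].astype(str).isin(common)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest dict (also written to out_dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {**asdict(config), "gs_design": asdict(config.gs_design)}, "stages": {}}

    G, marker_ids = io.read_genotype_tsv(config.genotype_tsv)
    mm = io.read_marker_map(config.marker_map_tsv)
    if list(mm["id"]) != list(marker_ids):
        raise PipelineError("marker map does not align with genotype TSV header")
    pheno = io.read_phenotype_tsv(config.phenotype_tsv)
    G, pheno = _align_samples(G, pheno)

    # --- QC ---
    Gq, mmq = popgen.filter_markers(G, mm, config.maf_min, config.missing_max)
    if Gq.n_markers == 0:
        raise PipelineError(
            f"marker QC (MAF >= {config.maf_min}, missing < {config.missing_max}) removed all "
            f"{G.n_markers} markers; relax the thresholds"
        )
    io.write_marker_map(mmq.assign(maf=Gq.maf(), missing_frac=Gq.missing_frac()), out / "qc_markers.tsv")
    manifest["stages"]["qc"] = {"n_markers_in": G.n_markers, "n_markers_out": Gq.n_markers}

    # --- phenotype statistics ---
    summary = phenotypes.summarize_table(pheno)
    summary.to_csv(out / "phenotype_summary.tsv", sep="\t", index=False)
    manifest["stages"]["pheno"] = {"n_traits": len(summary)}

    # --- K, Q, scan, FDR per trait ---
    K = popgen.compute_kinship(Gq)
    io.write_matrix_tsv(K, out / "kinship.tsv")
    Q = popgen.structure_pca(Gq, k=config.structure_k, seed=config.seed)
    io.write_matrix_tsv(Q, out / "structure_pcs.tsv")

    traits = list(pheno["trait"].unique())
    gwas_frames = []
    sig_by_trait: dict[str, list] = {}
    order = {str(s): i for i, s in enumerate(Gq.samples)}
    for trait in traits:
        sub = pheno[pheno["trait"] == trait]
        means = sub.groupby("accession", observed=True)["value"].mean()
        means = means[[str(a) in order for a in means.index]]
        idx = np.array([order[str(a)] for a in means.index])
        Gt = Gq.take_samples(idx)
        y = means.to_numpy()
        res = association.scan(
            Gt, y, Q=Q.to_numpy()[idx] if config.structure_k else None,
            K=K.to_numpy()[np.ix_(idx, idx)], marker_map=mmq,
        )
        sel = association.fdr_select(res["p_value"].to_numpy(), q=config.fdr_q, ids=res["id"].to_numpy())
        res.insert(0, "trait", trait)
        res["significant"] = res["id"].isin(set(sel.selected_ids))
        gwas_frames.append(res)
        sig_by_trait[trait] = list(sel.selected_ids)
        manifest["stages"].setdefault("gwas", {})[trait] = {
            "n_selected": sel.n_selected,
            "p_threshold": sel.p_threshold,
        }
        # --- R-QTL intervals ---
        if sel.n_selected > 0:
            ivs = intervals.build_rqtl_set(sel.selected_ids, Gt, mmq, r2_min=config.r2_min)
            iv_rows = [
                {
                    "trait": trait,
                    "leads": ",".join(map(str, iv.lead_ids)),
                    "chrom": iv.chrom,
                    "physical_interval": f"{iv.left_border_pos}...{iv.right_border_pos}",
                    "length_kb": iv.length_kb,
                }
                for iv in ivs
            ]
            pd.DataFrame(iv_rows).to_csv(out / f"rqtl_{trait}.tsv", sep="\t", index=False)
            manifest["stages"].setdefault("rqtl", {})[trait] = len(ivs)

    gwas_all = pd.concat(gwas_frames, ignore_index=True)
    gwas_all.to_csv(out / "gwas_results.tsv", sep="\t", index=False)

    # --- haplotype blocks ---
    blocks = intervals.four_gamete_blocks(Gq, mmq)
    pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "start_pos": b.start_pos,
                "end_pos": b.end_pos,
                "n_markers": len(b.marker_ids),
                "marker_ids": ",".join(map(str, b.marker_ids)),
            }
            for b in blocks
        ]
    ).to_csv(out / "haplotype_blocks.tsv", sep="\t", index=False)
    manifest["stages"]["blocks"] = {"n_blocks": len(blocks)}

    # --- candidate genes ---
    if config.annotation_gff3:
        ann = io.read_gff3(config.annotation_gff3)
        gene_rows = []
        mm_idx = mmq.set_index("id")
        for trait, sig in sig_by_trait.items():
            for mid in sig:
                row = mm_idx.loc[mid]
                for hit in intervals.candidate_genes(
                    int(row["pos"]), row["chrom"], ann, window_bp=config.gene_window_bp
                ):
                    gene_rows.append(
                        {
                            "trait": trait,
                            "lead_snp": mid,
                            "gene_id": hit.gene_id,
                            "chrom": hit.chrom,
                            "start": hit.start,
                            "end": hit.end,
                            "distance_bp": hit.distance_bp,
                            "relation": hit.relation,
                        }
                    )
        pd.DataFrame(
            gene_rows,
            columns=["trait", "lead_snp", "gene_id", "chrom", "start", "end", "distance_bp", "relation"],
        ).to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
        manifest["stages"]["genes"] = {"n_hits": len(gene_rows)}

    # --- genomic selection ---
    if config.run_gs:
        trait = traits[0]
        sub = pheno[pheno["trait"] == trait]
        means = sub.groupby("accession", observed=True)["value"].mean()
        idx = np.array([order[str(a)] for a in means.index if str(a) in order])
        per_rep = gs.run_gs_experiment(Gq.take_samples(idx), means.to_numpy()[: len(idx)], config.gs_design)
        per_rep.to_csv(out / "gs_per_rep.tsv", sep="\t", index=False)
        gs.summarize_gs(per_rep).to_csv(out / "gs_summary.tsv", sep="\t", index=False)
        manifest["stages"]["gs"] = {"n_rows": len(per_rep)}

    io.write_metadata(manifest, out / "manifest.json")
    return manifest
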