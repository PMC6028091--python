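"""End-to-end orchestration: simulate -> QC/GWAS -> AWM -> PCIT -> report.

Each stage writes its interface artifacts under the output directory and a
final JSON manifest records seeds, stage attrition counts (tested SNP,
QC survivors, per-trait significant SNP, primary/secondary selections,
set1/set2 sizes, AWM rows, common SNP, significant edges) and the sha256
of every text artifact, so two runs with the same config and seed produce
byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import awm as awm_mod
from . import gwas as gwas_mod
from . import io as io_mod
from . import pcit as pcit_mod
from . import simdata
from ._utils import child_seeds, sha256_file


@dataclass
class RunConfig:
    """Declarative configuration; every pipeline constant is a named key."""

    seed: int = 1
    outdir: str = "awmpcit_run"
    # simulation
    n_per_breed: tuple[int, ...] = (800, 500, 300)
    n_snps: int = 4000
    n_chrom: int = 5
    chrom_length: int = 10_000_000
    maf_range: tuple[float, float] = (0.02, 0.5)
    divergence: float = 0.05
    n_genes: int = 700
    mean_gene_length: int = 15_000
    n_causal: int = 120
    cm_incidence: float = 0.25
    h2: float | None = None   # uniform heritability override (None: trait defaults)
    # QC
    qc_call_rate: float = 0.99
    qc_maf: float = 0.02
    qc_hwe_p: float = 1e-4
    # AWM
    alpha: float = 0.05
    key_trait: str = simdata.KEY_TRAIT
    window_bp: int = 10_000
    min_udder: int = 2
    min_other: int | None = None
    use_bonferroni_step1: bool = False
    keep_all_primary: bool = False
    # PCIT / multi-breed
    breed_combination: str = "per_breed"  # or "stacked"
    pcit_max_nodes: int = 3000

    def validate(self) -> None:
        if not (0 < self.qc_call_rate <= 1 and 0 < self.qc_maf < 0.5
                and 0 < self.qc_hwe_p < 1):
            raise ValueError("QC thresholds out of range")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha out of range")
        if self.breed_combination not in ("per_breed", "stacked"):
            raise ValueError("breed_combination must be per_breed or stacked")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["n_per_breed"] = list(self.n_per_breed)
        d["maf_range"] = list(self.maf_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n_per_breed" in d:
            d["n_per_breed"] = tuple(d["n_per_breed"])
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    def awm_config(self) -> awm_mod.AWMConfig:
        return awm_mod.AWMConfig(
            alpha=self.alpha, key_trait=self.key_trait,
            min_udder=self.min_udder, min_other=self.min_other,
            window_bp=self.window_bp, use_bonferroni=self.use_bonferroni_step1,
            keep_all_primary=self.keep_all_primary,
        )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> tuple:
    s_geno, s_gene, s_pheno = child_seeds(cfg.seed, 3)
    chrom_lengths = {c: cfg.chrom_length for c in range(1, cfg.n_chrom + 1)}
    panel = simdata.simulate_genotypes(
        cfg.n_per_breed, cfg.n_snps, cfg.n_chrom, cfg.maf_range,
        seed=s_geno, divergence=cfg.divergence, chrom_lengths=chrom_lengths,
    )
    genes = simdata.simulate_gene_map(
        cfg.n_genes, chrom_lengths, cfg.mean_gene_length, seed=s_gene
    )
    traits, truth = simdata.simulate_phenotypes(
        panel, cfg.n_causal, target_h2=cfg.h2, seed=s_pheno,
        cm_incidence=cfg.cm_incidence,
    )
    io_mod.write_vcf(panel, outdir / "genotypes.vcf")
    io_mod.write_dosage_tsv(panel, outdir / "genotypes.tsv", outdir / "samples.tsv")
    io_mod.write_bed(genes, outdir / "genes.bed")
    io_mod.write_phenotypes(traits, outdir / "phenotypes.tsv")
    io_mod.write_table(truth.true_effects, outdir / "truth_effects.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "causal_snp_ids": truth.causal_snp_ids.tolist(),
                "true_h2": {k: float(v) for k, v in truth.true_h2.items()},
                "realized_h2": {k: float(v) for k, v in truth.realized_h2.items()},
            },
            fh, indent=2, sort_keys=True,
        )
    return panel, genes, traits, truth


def stage_gwas(cfg: RunConfig, outdir: Path, panel, traits) -> tuple:
    qc_panel, report = gwas_mod.apply_qc(
        panel, gwas_mod.QCThresholds(cfg.qc_call_rate, cfg.qc_maf, cfg.qc_hwe_p)
    )
    io_mod.write_table(report.table, outdir / "qc_report.tsv")
    assoc_by_breed: dict[str, dict[str, gwas_mod.AssocResult]] = {}
    for breed in qc_panel.breeds:
        cohort = qc_panel.subset_breed(breed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grm = gwas_mod.compute_grm(cohort, on_degenerate="drop")
        io_mod.write_grm(cohort.sample_ids, grm.matrix, outdir / f"grm_{breed}.tsv")
        assoc = gwas_mod.gwas_breed(cohort, traits.values, breed, grm=grm)
        assoc_by_breed[breed] = assoc
        for trait, res in assoc.items():
            safe = trait.replace("%", "pct")
            io_mod.write_table(res.table.drop(columns="reason"),
                              outdir / f"assoc_{breed}_{safe}.tsv")
    return qc_panel, report, assoc_by_breed


def stage_awm(cfg: RunConfig, outdir: Path, assoc_by_breed, genes) -> dict:
    awms = {}
    for breed, assoc in assoc_by_breed.items():
        matrix = awm_mod.build_awm(assoc, genes, cfg.awm_config(), allow_empty=True)
        awms[breed] = matrix
        matrix.matrix.to_csv(outdir / f"awm_{breed}.csv",
                             float_format=io_mod.FLOAT_FMT)
        io_mod.write_table(matrix.provenance, outdir / f"awm_{breed}_provenance.tsv")
        if matrix.n_rows >= 3:
            io_mod.write_table(awm_mod.awm_trait_correlations(matrix),
                              outdir / f"snp_correlations_{breed}.tsv")
    return awms


def stage_pcit(cfg: RunConfig, outdir: Path, awms: dict) -> dict:
    import networkx as nx

    summaries = {}
    overlap = awm_mod.combine_breeds(*awms.values())
    with open(outdir / "venn_counts.json", "w") as fh:
        json.dump(overlap, fh, indent=2, sort_keys=True)

    if cfg.breed_combination == "stacked":
        common = overlap["common_snp_ids"]
        inputs = {}
        if len(common) >= 3:
            stacked = pd.concat(
                [a.matrix.loc[common].add_suffix(f"_{b}") for b, a in awms.items()],
                axis=1,
            )
            inputs["stacked"] = (stacked, awms[next(iter(awms))])
    else:
        inputs = {b: (a.matrix, a) for b, a in awms.items()}

    for name, (matrix, awm_obj) in inputs.items():
        if len(matrix) < 3:
            summaries[name] = {"n_nodes": int(len(matrix)), "n_edges_significant": 0,
                               "skipped": "fewer than 3 AWM rows"}
            continue
        labels = awm_obj.provenance.loc[matrix.index, "row_label"].tolist()
        corr, dropped = pcit_mod.row_correlations(matrix)
        net = pcit_mod.pcit_filter(corr.to_numpy(), labels=[labels[matrix.index.get_loc(i)]
                                                            for i in corr.index],
                                   max_nodes=cfg.pcit_max_nodes)
        io_mod.write_table(net.edges_frame(), outdir / f"edges_{name}.tsv", index=False)
        io_mod.write_table(net.edges_frame(significant_only=True),
                          outdir / f"edges_{name}_significant.tsv", index=False)
        nx.write_graphml(net.to_networkx(significant_only=True),
                         outdir / f"network_{name}.graphml")
        summary = pcit_mod.network_summary(net)
        if dropped:
            summary["constant_rows_dropped"] = len(dropped)
        summaries[name] = summary
    with open(outdir / "network_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
    return summaries


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the manifest; returns the manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    panel, genes, traits, truth = stage_simulate(cfg, outdir)
    qc_panel, qc_report, assoc_by_breed = stage_gwas(cfg, outdir, panel, traits)
    awms = stage_awm(cfg, outdir, assoc_by_breed, genes)
    summaries = stage_pcit(cfg, outdir, awms)

    sig_per_trait = {
        breed: {t: int((r.table["p_bonferroni"] < cfg.alpha).sum())
                for t, r in assoc.items()}
        for breed, assoc in assoc_by_breed.items()
    }
    with open(outdir / "venn_counts.json") as fh:
        overlap = json.load(fh)

    manifest = {
        "config": yaml.safe_load((outdir / "config.yaml").read_text()),
        "seed": cfg.seed,
        "counts": {
            "snps_simulated": int(panel.n_snps),
            "snps_after_qc": int(qc_panel.n_snps),
            "samples": int(panel.n_samples),
            "genes": int(genes.n_genes),
            "bonferroni_significant_per_trait": sig_per_trait,
            "awm": {b: {k: (float(v) if isinstance(v, float) else int(v))
                        for k, v in a.counts.items()}
                    for b, a in awms.items()},
            "venn": overlap["regions"],
            "common_snps": overlap["n_common_snps"],
            "common_genes": overlap["n_common_genes"],
            "network": summaries,
        },
        "artifacts": {},
    }
    for p in sorted(outdir.iterdir()):
        if p.suffix in (".tsv", ".csv", ".vcf", ".bed", ".json", ".yaml", ".graphml") \
                and p.name != "manifest.json":
            manifest["artifacts"][p.name] = sha256_file(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def render_report(outdir: str | Path) -> dict:
    """Render figures from a completed run's artifacts.

    Returns a mapping of figure name to the data each was drawn from so
    callers can verify figures against the underlying tables.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    if not (outdir / "manifest.json").exists():
        raise FileNotFoundError("run the pipeline before rendering the report")
    manifest = json.loads((outdir / "manifest.json").read_text())
    report_dir = outdir / "report"
    report_dir.mkdir(exist_ok=True)
    drawn: dict = {}

    # MAF spectrum
    panel = io_mod.read_dosage_tsv(outdir / "genotypes.tsv", outdir / "samples.tsv")
    fig, ax = plt.subplots(figsize=(6, 4))
    maf = np.nanmin(np.minimum(panel.allele_freq, 1 - panel.allele_freq), axis=0)
    ax.hist(maf, bins=20, color="steelblue", edgecolor="white")
    ax.set_xlabel("minor allele frequency")
    ax.set_ylabel("SNP count")
    fig.savefig(report_dir / "maf_histogram.png", dpi=100)
    plt.close(fig)
    drawn["maf_histogram"] = maf

    breeds = list(dict.fromkeys(panel.breed))
    traits = [c for c in io_mod.read_phenotypes(outdir / "phenotypes.tsv").values.columns]
    for breed in breeds:
        fig, axes = plt.subplots(4, 3, figsize=(12, 10), sharex=True)
        for ax, trait in zip(axes.ravel(), traits):
            safe = trait.replace("%", "pct")
            f = outdir / f"assoc_{breed}_{safe}.tsv"
            if not f.exists():
                continue
            tab = pd.read_csv(f, sep="\t")
            logp = -np.log10(tab["p_raw"])
            ax.scatter(np.arange(len(tab)), logp, s=2,
                       c=tab["chrom"] % 2, cmap="tab10", rasterized=True)
            ax.set_title(trait, fontsize=9)
        fig.suptitle(f"per-trait association, breed {breed}")
        fig.savefig(report_dir / f"manhattan_{breed}.png", dpi=100)
        plt.close(fig)

        corr_f = outdir / f"snp_correlations_{breed}.tsv"
        if corr_f.exists():
            corr = pd.read_csv(corr_f, sep="\t", index_col=0)
            fig, ax = plt.subplots(figsize=(6, 5))
            im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
            ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
            ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
            fig.colorbar(im, ax=ax, label="SNP-based correlation")
            fig.savefig(report_dir / f"snp_correlation_{breed}.png", dpi=100)
            plt.close(fig)
            drawn[f"snp_correlation_{breed}"] = corr

    venn = manifest["counts"]["venn"]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(range(len(venn)), list(venn.values()), color="darkseagreen")
    ax.set_xticks(range(len(venn)), list(venn.keys()), rotation=45, ha="right")
    ax.set_ylabel("AWM SNP count")
    fig.tight_layout()
    fig.savefig(report_dir / "venn_counts.png", dpi=100)
    plt.close(fig)
    drawn["venn_counts"] = venn

    net = manifest["counts"]["network"]
    lines = ["network summary", "==============="]
    for name, s in net.items():
        if s.get("n_edges_significant", 0) == 0:
            lines.append(f"{name}: no significant edges")
        else:
            lines.append(f"{name}: {s['n_nodes']} nodes, "
                         f"{s['n_edges_significant']} significant edges, "
                         f"{s['n_components']} components")
    (report_dir / "network_summary.txt").write_text("\n".join(lines) + "\n")
    drawn["network_summary"] = net
    return drawn
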