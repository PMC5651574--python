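"""End-to-end orchestration: QC → diversity → FST → clustering/AMOVA →
PCA selection → FST validation → gene windows, from one flat configuration.

Every stage writes its table under the output directory and the run is
summarised in a manifest JSON recording input hashes, seeds and thresholds,
so a rerun with the same inputs and seeds is byte-reproducible.  A stage
failure raises :class:`PipelineError` naming the stage; outputs of completed
stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from goatpop import diversity as dv
from goatpop import differentiation as df
from goatpop import distance_amova as da
from goatpop import gene_windows as gw
from goatpop import pca_selection as ps
from goatpop.io_formats import (
    read_gene_annotation,
    read_genotypes,
    read_sample_map,
    read_snp_metadata,
    write_distance_matrix,
    write_newick,
)
from goatpop.qc import QcConfig, apply_qc

logger = logging.getLogger("goatpop.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat configuration; every published threshold is a named key."""

    genotypes: str
    samples: str
    out_dir: str
    snps: str | None = None
    annotation: str | None = None
    genotype_format: str = "tsv_matrix"
    qc: QcConfig = field(default_factory=QcConfig)
    bootstrap_reps: int = 1000
    fst_alpha: float = 0.005
    amova_permutations: int = 10000
    linkage: str = "complete"
    unbiased_he: bool = True
    selection_component: int = 1
    selection_factor: float = 10.0
    validation_k: float = 2.0
    window_half_width_bp: int = 250_000
    run_gene_windows: bool = True
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        qc_raw = raw.pop("qc", {})
        return cls(qc=QcConfig(**qc_raw), **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the manifest dict."""
    out = Path(config.out_dir)

    # fail before any compute if referenced inputs are absent
    inputs = {"genotypes": Path(config.genotypes), "samples": Path(config.samples)}
    if config.snps:
        inputs["snps"] = Path(config.snps)
    if config.run_gene_windows:
        if not config.annotation:
            raise PipelineError(
                "validate_config",
                FileNotFoundError("gene-window stage enabled but no annotation path"),
            )
        inputs["annotation"] = Path(config.annotation)
    missing = [str(p) for p in inputs.values() if not p.exists()]
    if missing:
        raise PipelineError(
            "validate_config", FileNotFoundError(f"missing inputs: {missing}")
        )
    if config.genotype_format == "ped_map":
        inputs["genotypes"] = Path(config.genotypes).with_suffix(".ped")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in inputs.items()},
        "seed": config.seed,
        "parameters": {
            "qc": asdict(config.qc),
            "bootstrap_reps": config.bootstrap_reps,
            "fst_alpha": config.fst_alpha,
            "amova_permutations": config.amova_permutations,
            "linkage": config.linkage,
            "selection_component": config.selection_component,
            "selection_factor": config.selection_factor,
            "validation_k": config.validation_k,
            "window_half_width_bp": config.window_half_width_bp,
        },
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s", name)

        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc

        return wrap

    # ---- load -----------------------------------------------------------
    def _load():
        snps = read_snp_metadata(config.snps) if config.snps else None
        gm, snps_out = read_genotypes(
            config.genotypes, config.genotype_format, snps=snps
        )
        samples = read_sample_map(config.samples)
        sample_set = {s.sample_id for s in samples}
        keep = [s for s in gm.sample_ids if s in sample_set]
        if len(keep) < gm.n_samples:
            gm = gm.subset_samples(keep)
        return gm, snps_out, samples

    gm, snps, samples = stage("load")(_load)

    # ---- qc -------------------------------------------------------------
    def _qc():
        filtered, report = apply_qc(gm, snps, config.qc)
        _write_tsv(
            out / "qc_report.tsv",
            ["step", "removed"],
            [[name, n] for name, n in report.steps],
        )
        (out / "qc_surviving_loci.tsv").write_text(
            "\n".join(report.surviving_locus_ids) + "\n"
        )
        manifest["stages"]["qc"] = {
            "initial_loci": report.initial_loci,
            "steps": report.steps,
            "surviving": report.surviving_count,
            "hwe_fail_count": report.hwe_fail_count,
            "removed_samples": report.removed_sample_ids,
        }
        return filtered

    gm_qc = stage("qc")(_qc)
    kept_samples = [s for s in samples if s.sample_id in set(gm_qc.sample_ids)]
    snp_by_id = {s.locus_id: s for s in snps}

    # ---- diversity ------------------------------------------------------
    def _diversity():
        rows = dv.summarize_diversity(
            gm_qc,
            kept_samples,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
            unbiased=config.unbiased_he,
        )
        _write_tsv(
            out / "diversity.tsv",
            ["breed", "n", "H_E", "H_O", "F_IS", "F_IS_ci_low", "F_IS_ci_high",
             "F_IS_significant", "pct_polymorphic", "maf_mean", "maf_sd",
             "maf_rare", "maf_intermediate", "maf_common", "maf_frequent"],
            [
                [
                    r.breed, r.n, f"{r.h_e:.4f}", f"{r.h_o:.4f}",
                    "NA" if r.f_is is None else f"{r.f_is:.4f}",
                    "NA" if r.f_is_ci is None else f"{r.f_is_ci[0]:.4f}",
                    "NA" if r.f_is_ci is None else f"{r.f_is_ci[1]:.4f}",
                    "NA" if r.f_is_significant is None else r.f_is_significant,
                    f"{r.pct_polymorphic:.1f}", f"{r.maf_mean:.4f}",
                    f"{r.maf_sd:.4f}", *r.maf_class_counts,
                ]
                for r in rows
            ],
        )
        manifest["stages"]["diversity"] = {
            r.breed: {"H_E": round(r.h_e, 4), "H_O": round(r.h_o, 4)} for r in rows
        }
        return rows

    diversity_rows = stage("diversity")(_diversity)

    # ---- differentiation ------------------------------------------------
    def _fst():
        pairwise = df.fst_pairwise(
            gm_qc, kept_samples, config.bootstrap_reps, config.fst_alpha, config.seed
        )
        breeds = sorted({s.breed for s in kept_samples})
        one_vs_rest = {
            b: df.fst_one_vs_rest(
                gm_qc, kept_samples, b, config.bootstrap_reps, config.fst_alpha,
                config.seed,
            )
            for b in breeds
        }
        _write_tsv(
            out / "fst_pairwise.tsv",
            ["breed_1", "breed_2", "theta", "ci_low", "ci_high", "significant",
             "suggestive"],
            [
                [b1, b2, f"{e.theta:.4f}", f"{e.ci_low:.4f}", f"{e.ci_high:.4f}",
                 e.significant, e.suggestive]
                for (b1, b2), e in pairwise.items()
            ]
            + [
                [b, "rest", f"{e.theta:.4f}", f"{e.ci_low:.4f}", f"{e.ci_high:.4f}",
                 e.significant, e.suggestive]
                for b, e in one_vs_rest.items()
            ],
        )
        # per-locus one-vs-rest θ table for outlier plots
        theta_cols = {b: dict(zip(e.locus_ids, e.theta_per_locus))
                      for b, e in one_vs_rest.items()}
        rows = []
        for locus in gm_qc.locus_ids:
            rec = snp_by_id[locus]
            row = [locus, rec.chromosome, rec.position_bp]
            for b in breeds:
                v = theta_cols[b].get(locus)
                row.append("NA" if v is None else f"{v:.6f}")
            rows.append(row)
        _write_tsv(
            out / "fst_per_locus.tsv",
            ["locus_id", "chromosome", "position_bp"]
            + [f"theta_{b}_vs_rest" for b in breeds],
            rows,
        )
        manifest["stages"]["fst"] = {
            f"{b1}-{b2}": round(e.theta, 4) for (b1, b2), e in pairwise.items()
        } | {f"{b}-rest": round(e.theta, 4) for b, e in one_vs_rest.items()}
        return pairwise, one_vs_rest

    pairwise_fst, one_vs_rest_fst = stage("fst")(_fst)

    # ---- distances / clustering / AMOVA / kinship -----------------------
    def _distance():
        nei = da.nei_distance_matrix(gm_qc)
        write_distance_matrix(nei, out / "nei_distances.tsv")
        tree = da.hierarchical_cluster(da.cap_infinite(nei), config.linkage)
        write_newick(da.tree_to_newick(tree), out / "tree.nwk")
        amova_res = da.amova(
            nei, kept_samples, config.amova_permutations, config.seed
        )
        _write_tsv(
            out / "amova.tsv",
            ["component", "df", "SS", "sigma2", "pct", "phi_st", "p_value"],
            [
                ["among_populations", amova_res.df_among,
                 f"{amova_res.ss_among:.6f}", f"{amova_res.sigma2_among:.6g}",
                 f"{amova_res.pct_among:.2f}", f"{amova_res.phi_st:.4f}",
                 "NA" if amova_res.p_value is None else f"{amova_res.p_value:.3g}"],
                ["within_populations", amova_res.df_within,
                 f"{amova_res.ss_within:.6f}", f"{amova_res.sigma2_within:.6g}",
                 f"{amova_res.pct_within:.2f}", "", ""],
            ],
        )
        kin = da.ibs_kinship(gm_qc)
        off = kin.values[~np.eye(len(kin.labels), dtype=bool)]
        manifest["stages"]["distance_amova"] = {
            "amova_pct_among": round(amova_res.pct_among, 2),
            "amova_p": amova_res.p_value,
            "kinship_offdiag_range": [round(float(off.min()), 3),
                                      round(float(off.max()), 3)],
        }
        return amova_res

    amova_res = stage("distance_amova")(_distance)

    # ---- PCA + selection + validation ------------------------------------
    def _pca():
        pca = ps.run_pca(gm_qc)
        k_show = min(10, pca.sdev.size)
        _write_tsv(
            out / "pca_scores.tsv",
            ["sample_id"] + [f"PC{i + 1}" for i in range(k_show)],
            [
                [sid] + [f"{v:.6g}" for v in pca.scores[i, :k_show]]
                for i, sid in enumerate(pca.sample_ids)
            ],
        )
        contribs = ps.snp_contributions(pca, config.selection_component)
        _write_tsv(
            out / "pca_contributions.tsv",
            ["locus_id", "correlation", "cos2", "contribution_pct"],
            [
                [l, f"{contribs.correlation[j]:.6g}", f"{contribs.cos2[j]:.6g}",
                 f"{contribs.contribution_pct[j]:.6g}"]
                for j, l in enumerate(contribs.locus_ids)
            ],
        )
        selected = ps.select_high_contribution(contribs, config.selection_factor)
        sel_rows = []
        for l, c in zip(selected.locus_ids, selected.contribution_pct):
            rec = snp_by_id[l]
            sel_rows.append([l, rec.chromosome, rec.position_bp, f"{c:.6g}"])
        _write_tsv(
            out / "selected_snps.tsv",
            ["locus_id", "chromosome", "position_bp", "contribution_pct"],
            sel_rows,
        )
        validation = ps.validate_selected_by_fst(
            selected,
            {b: e for b, e in one_vs_rest_fst.items()},
            k=config.validation_k,
            pca_locus_ids=pca.locus_ids,
        )
        (out / "fst_validation.json").write_text(
            json.dumps({b: asdict(v) for b, v in validation.items()}, indent=1)
        )
        manifest["stages"]["pca_selection"] = {
            "pc1_var_pct": round(float(pca.var_fraction[0] * 100), 3),
            "pc2_var_pct": round(float(pca.var_fraction[1] * 100), 3),
            "n_selected": len(selected.locus_ids),
            "validation_above": {
                b: v.n_selected_above for b, v in validation.items()
            },
        }
        return pca, selected, validation

    pca, selected, validation = stage("pca")(_pca)

    # ---- gene windows ---------------------------------------------------
    if config.run_gene_windows:
        def _genes():
            annotation = read_gene_annotation(config.annotation)
            sel_snps = [snp_by_id[l] for l in selected.locus_ids]
            windows = gw.build_windows(sel_snps, config.window_half_width_bp)
            report = gw.extract_genes(windows, annotation)
            rows = []
            for w, hits in zip(report.windows, report.genes_per_window):
                for g in hits:
                    rows.append([w.locus_id, w.chromosome, w.start_bp, w.end_bp,
                                 g.gene_id, g.start_bp, g.end_bp])
            _write_tsv(
                out / "gene_windows.tsv",
                ["locus_id", "chromosome", "window_start", "window_end",
                 "gene_id", "gene_start", "gene_end"],
                rows,
            )
            manifest["stages"]["gene_windows"] = {
                "n_windows": len(report.windows),
                "unique_genes": report.unique_gene_count,
            }
            return report

        stage("gene_windows")(_genes)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
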