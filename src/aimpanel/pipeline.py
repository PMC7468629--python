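"""End-to-end orchestration of the full analysis sequence.

``run_all`` executes, in order: forensic parameters + HWE/Bonferroni,
informativeness, locus/group F_st with threshold counts, LOOCV
classification, admixture fits over a K range with delta-K, supervised
ancestry components for a designated target group, PCA, MDS and the D_A
neighbor-joining tree.  Every artifact lands in the output directory and is
listed in a JSON manifest together with the configuration, seed and
per-stage timing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import (admixture_model, ancestry_classify, differentiation,
               ordination_tree, popgen_core)
from .errors import AimPanelError
from .io_formats import GenotypeTable, RunConfig, read_genotype_table, write_newick

logger = logging.getLogger(__name__)

ALL_STAGES = ["forensic", "informativeness", "fst", "classify",
              "admixture", "supervised", "pca", "mds", "njtree"]


@dataclass
class PipelineReport:
    artifacts: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps({
            "artifacts": self.artifacts,
            "timings_s": {k: round(v, 4) for k, v in self.timings.items()},
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "failed_stage": self.failed_stage,
        }, indent=2)


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the root seed."""
    import zlib

    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


def run_all(config: RunConfig, table: GenotypeTable | None = None) -> PipelineReport:
    """Run the configured stages on ``table`` (or the table at ``config.input_path``)."""
    if table is None:
        if config.input_path is None:
            raise AimPanelError("no input table and no input_path configured")
        table = read_genotype_table(config.input_path)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.stages or ALL_STAGES
    report = PipelineReport(config=config.to_dict(), seed=config.seed)

    full = table.subset_loci(config.include_loci) if config.include_loci else table
    # forensic uses the full panel; cross-population stages drop the exclusions
    cross = full.subset_loci(exclude=config.exclude_loci) if config.exclude_loci else full
    logger.info("pipeline: %d loci for forensic stage, %d for cross-population stages "
                "(excluded: %s); smoothing=%s, estimator=weir-cockerham, mds=classical, "
                "em_restarts=%d",
                full.n_loci, cross.n_loci, config.exclude_loci or "none",
                config.smoothing, config.em_restarts)

    target = config.target_group
    reference = cross.subset_populations(
        [p for p in cross.populations if p != target]) if target else cross

    def _run(stage, fn):
        if stage not in stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception:
            report.failed_stage = stage
            _write_manifest()
            raise
        report.timings[stage] = time.perf_counter() - t0

    def _save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, **kw)
        report.artifacts[name] = str(path)

    def _forensic():
        df = popgen_core.forensic_table(full)
        _save(df, "forensic_table.csv")
        pvals = df.drop(index="mean")["hwe_p"]
        flags = popgen_core.bonferroni_correct(pvals.tolist())
        hwe = pd.DataFrame({"hwe_p": pvals,
                            "significant_after_bonferroni": flags})
        _save(hwe, "hwe_flags.csv")

    def _informativeness():
        _save(differentiation.informativeness_table(cross), "informativeness.csv")

    def _fst():
        locus = differentiation.locus_fst_table(cross)
        _save(locus, "locus_fst.csv")
        counts = differentiation.count_loci_above(locus, 0.25)
        _save(counts.to_frame("n_loci_fst_gt_0.25"), "fst_threshold_counts.csv")
        _save(differentiation.pairwise_fst_matrix(cross), "pairwise_fst.csv")

    def _classify():
        cm = ancestry_classify.loocv(reference, smoothing=config.smoothing)
        _save(cm.counts, "confusion_counts.csv")
        _save((cm.proportions * 100).round(2), "confusion_percent.csv")

    def _admixture():
        k_lo, k_hi = config.k_range
        seed = _stage_seed(config.seed, "admixture")
        series = admixture_model.run_series(
            cross, range(max(k_lo - 1, 1), k_hi + 2), seed=seed,
            restarts=max(config.em_restarts, 2), max_iter=config.em_max_iter,
            tol=config.em_tol)
        try:
            delta = admixture_model.evanno_delta_k(series)
            _save(delta.to_frame(), "delta_k.csv")
            best_k = int(delta.idxmax())
        except AimPanelError:
            logger.warning("delta-K degenerate (no restart spread); using K=%d", k_lo)
            best_k = k_lo
        fit = admixture_model.fit_admixture(
            cross, best_k, seed=seed, max_iter=config.em_max_iter,
            tol=config.em_tol, restarts=config.em_restarts)
        q = pd.DataFrame(fit.Q, index=cross.sample_ids,
                         columns=[f"cluster_{k+1}" for k in range(fit.K)])
        q.insert(0, "population", cross.population_labels)
        _save(q, "admixture_q.csv")
        comp = admixture_model.population_components(fit, cross.population_labels)
        _save(comp, "population_components.csv")

    def _supervised():
        if not target:
            return
        ref_p = np.vstack([
            np.clip(reference.insertion_frequencies(p), 1e-6, 1 - 1e-6)
            for p in reference.populations])
        tgt = cross.subset_populations([target])
        seed = _stage_seed(config.seed, "supervised")
        q = admixture_model.supervised_components(tgt, ref_p, seed=seed)
        df = pd.DataFrame(q, index=tgt.sample_ids, columns=reference.populations)
        df.loc["mean"] = df.mean(axis=0)
        df.loc["group"] = admixture_model.fit_supervised_group_q(tgt, ref_p, seed=seed)
        _save(df, "target_supervised_q.csv")

    def _pca():
        res = ordination_tree.genotype_pca(cross, n_components=10)
        df = pd.DataFrame(res.scores, index=cross.sample_ids,
                          columns=[f"PC{c+1}" for c in range(res.scores.shape[1])])
        df.insert(0, "population", cross.population_labels)
        _save(df, "pca_scores.csv")
        _save(pd.DataFrame({"explained": res.explained}), "pca_explained.csv",
              index=False)

    def _mds():
        fst = differentiation.pairwise_fst_matrix(cross, clamp_negative=True)
        res = ordination_tree.classical_mds(fst)
        _save(res.coordinates, "mds_coordinates.csv")

    def _njtree():
        da = differentiation.da_distance_matrix(cross)
        tree = ordination_tree.neighbor_joining(da)
        path = out / "nj_tree.nwk"
        write_newick(tree, path)
        report.artifacts["nj_tree.nwk"] = str(path)
        _save(da, "da_distances.csv")

    def _write_manifest():
        (out / "manifest.json").write_text(report.to_json() + "\n")
        report.artifacts["manifest.json"] = str(out / "manifest.json")

    _run("forensic", _forensic)
    _run("informativeness", _informativeness)
    _run("fst", _fst)
    _run("classify", _classify)
    _run("admixture", _admixture)
    _run("supervised", _supervised)
    _run("pca", _pca)
    _run("mds", _mds)
    _run("njtree", _njtree)
    _write_manifest()
    return report
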