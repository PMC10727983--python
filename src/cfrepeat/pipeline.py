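"""End-to-end driver: toy genome -> reads -> quantification -> aggregation ->
differential expression -> classifier training/evaluation.

This is the programmatic counterpart of the CLI's ``run-all``: it wires the
stage functions together on a simulated cohort and returns every
intermediate, which is also what the acceptance checks exercise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import annotation, classify, diffexp, features, quantify, synthetic

logger = logging.getLogger(__name__)


@dataclass
class CohortResult:
    """Everything produced by one simulated-cohort pipeline run."""

    toy: synthetic.ToyGenome
    catalog_aware: annotation.FeatureCatalog
    catalog_naive: annotation.FeatureCatalog
    counts: quantify.CountMatrix
    metadata: pd.DataFrame
    mapping_rates: pd.DataFrame  # per sample: naive and aware rates
    de: diffexp.DEResult | None
    model: classify.ModelFit | None
    eval_result: classify.EvalResult | None
    train_ids: list[str]
    test_ids: list[str]


def simulate_cohort_reads(
    cfg: synthetic.SimulationConfig,
    planted_subfamilies: dict[str, float],
    reads_per_sample: int = 300,
    read_length: int = 50,
    repeat_weight_healthy: float = 0.15,
) -> CohortResult:
    """Read-level cohort: plant subfamily enrichment, quantify, aggregate, test.

    Healthy samples spend ``repeat_weight_healthy`` of their reads on repeat
    units; cases multiply the planted subfamilies' weights by 2**log2fc.
    Quantification runs against both the repeat-aware and repeat-naive
    references so mapping rates can be compared, then the aware counts flow
    through DE and the classifier protocol.
    """
    toy = synthetic.make_toy_genome(cfg)
    cat_aware = annotation.build_catalog(toy.genes, toy.instances, "repeat_aware")
    cat_naive = annotation.build_catalog(toy.genes, None, "repeat_naive")
    ref_all = toy.unit_sequences("all")
    ref_genes = toy.unit_sequences("genes")

    rng = cfg.rng(stage=4)
    n = cfg.n_healthy + cfg.n_case
    samples = [f"S{j:03d}" for j in range(n)]
    condition = ["healthy"] * cfg.n_healthy + ["case"] * cfg.n_case

    gene_units = [u.unit_id for u in toy.transcript_units]
    inst_by_sub: dict[str, list[str]] = {}
    for inst in toy.instances:
        inst_by_sub.setdefault(inst.subfamily, []).append(inst.instance_id)

    aware_tables, naive_tables = [], []
    for sample_id, cond in zip(samples, condition):
        weights: dict[str, float] = {}
        gene_w = np.maximum(rng.lognormal(0.0, 0.5, len(gene_units)), 1e-3)
        gene_w = (1.0 - repeat_weight_healthy) * gene_w / gene_w.sum()
        weights.update(zip(gene_units, gene_w))
        sub_names = sorted(inst_by_sub)
        sub_w = np.full(len(sub_names), repeat_weight_healthy / len(sub_names))
        for k, sub in enumerate(sub_names):
            if cond == "case" and sub in planted_subfamilies:
                sub_w[k] *= 2.0 ** planted_subfamilies[sub]
        for sub, w in zip(sub_names, sub_w):
            per_inst = w / len(inst_by_sub[sub])
            for iid in inst_by_sub[sub]:
                weights[iid] = per_inst
        reads = synthetic.simulate_reads(ref_all, weights, reads_per_sample, read_length, rng)
        aware_tables.append(synthetic.toy_quantify(reads, ref_all, sample_id))
        naive_tables.append(synthetic.toy_quantify(reads, ref_genes, sample_id))

    counts, _ = quantify.aggregate(aware_tables, cat_aware)
    rates = pd.DataFrame(
        {
            "naive": quantify.mapping_rate_table(naive_tables)["mapping_rate"],
            "aware": quantify.mapping_rate_table(aware_tables)["mapping_rate"],
        }
    )

    metadata = pd.DataFrame(
        {
            "condition": condition,
            "age": np.round(rng.normal(60, 10, n)).clip(30, 90),
            "gender": rng.choice(["F", "M"], size=n),
            "input_volume": np.round(rng.normal(1.0, 0.2, n).clip(0.4, 2.0), 2),
            "stage": ["NA" if c == "healthy" else "II" for c in condition],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CohortResult(
        toy=toy,
        catalog_aware=cat_aware,
        catalog_naive=cat_naive,
        counts=counts,
        metadata=metadata,
        mapping_rates=rates,
        de=None,
        model=None,
        eval_result=None,
        train_ids=[],
        test_ids=[],
    )


def run_diagnostic_protocol(
    result: CohortResult,
    seed: int,
    alpha_grid: Sequence[float] = (0.0, 0.5, 1.0),
    folds: int = 10,
    min_feature_count: float = 1.0,
    design: diffexp.DesignSpec | None = None,
) -> CohortResult:
    """Training-split DE, feature selection, CV training and held-out evaluation.

    DE runs on the training split only (leakage guard downstream); the
    classifier input is log2(normalized count + 1) restricted to DE features
    when any pass padj < 0.01, else all repeat-aware features.
    """
    counts, metadata = result.counts, result.metadata
    labels = pd.Series(
        (metadata["condition"] == "case").astype(int), index=metadata.index
    )
    train_ids, test_ids = classify.stratified_split(
        list(metadata.index), labels.to_numpy(), classify.SplitSpec(seed=seed)
    )
    result.train_ids, result.test_ids = train_ids, test_ids

    keep = counts.data.mean(axis=1) >= min_feature_count
    sub = quantify.CountMatrix(counts.data.loc[keep], state="raw")
    if design is None:
        design = diffexp.DesignSpec(covariates=[], condition="condition", reference_level="healthy")
    train_counts = quantify.CountMatrix(sub.data[train_ids], state="raw")
    de = diffexp.nb_wald_test(train_counts, metadata.loc[train_ids], design)
    result.de = de

    sf = features.size_factors(sub)
    norm = features.normalize(sub, sf)
    logm = features.log_transform(norm)
    X = logm.data.T  # samples x features

    de_feats = list(de.significant().index)
    feat_ids = de_feats if de_feats else list(X.columns)
    Xsel = X[feat_ids]
    model = classify.cv_train(
        Xsel.loc[train_ids],
        labels.loc[train_ids],
        feature_set_name="de_aware" if de_feats else "total_aware",
        alpha_grid=alpha_grid,
        folds=folds,
        seed=seed,
    )
    result.model = model
    result.eval_result = classify.evaluate_test(model, Xsel.loc[test_ids], labels.loc[test_ids])
    return result


# ---------------------------------------------------------------------------
# file-based run-all (CLI)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: dict, outdir: Union[str, Path], resume: bool = False) -> dict:
    """File-based pipeline over a simulated cohort; returns the provenance manifest.

    Stages: simulate, build-annotation, quantify, aggregate, features,
    diffexp, train, evaluate.  Each stage records its outputs and their
    checksums; with ``resume`` a stage whose outputs exist and match the
    manifest is skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    old_manifest = {}
    if resume and manifest_path.exists():
        old_manifest = json.loads(manifest_path.read_text())

    seed = int(config.get("seed", 0))
    cfg = synthetic.SimulationConfig(
        seed=seed,
        n_healthy=int(config.get("n_healthy", 20)),
        n_case=int(config.get("n_case", 20)),
        n_genes=int(config.get("n_genes", 20)),
        n_subfamilies=int(config.get("n_subfamilies", 3)),
        instances_per_subfamily=int(config.get("instances_per_subfamily", 4)),
    )
    planted = dict(config.get("planted_subfamilies", {"Alu_sf0": 2.0}))
    alpha_grid = tuple(config.get("alpha_grid", (0.0, 0.5, 1.0)))

    manifest: dict = {"seed": seed, "stages": {}, "config": config}

    def record(stage: str, paths: dict[str, Path]):
        manifest["stages"][stage] = {
            "outputs": {k: str(p) for k, p in paths.items()},
            "sha256": {k: _checksum(Path(p)) for k, p in paths.items()},
        }

    def fresh(stage: str, paths: dict[str, Path]) -> bool:
        """True when resume is on and every recorded output still matches."""
        if not resume or stage not in old_manifest.get("stages", {}):
            return False
        rec = old_manifest["stages"][stage]
        for k, p in paths.items():
            p = Path(p)
            if not p.exists() or rec["sha256"].get(k) != _checksum(p):
                return False
        manifest["stages"][stage] = rec
        return True

    # the in-memory pipeline recomputes everything; file outputs are the contract
    res = simulate_cohort_reads(cfg, planted)

    sim_paths = {
        "genome": outdir / "genome.fa",
        "rmsk": outdir / "rmsk.tsv",
        "gtf": outdir / "genes.gtf",
    }
    if not fresh("simulate", sim_paths):
        synthetic.write_toy_genome(res.toy, outdir)
        record("simulate", sim_paths)

    ann_paths = {"t2g": outdir / "t2g.tsv", "catalog": outdir / "catalog.json",
                 "features": outdir / "features.tsv"}
    if not fresh("build-annotation", ann_paths):
        res.catalog_aware.write_t2g(ann_paths["t2g"])
        res.catalog_aware.write_summary(ann_paths["catalog"])
        res.catalog_aware.write_features(ann_paths["features"])
        record("build-annotation", ann_paths)

    quant_paths = {"mapping_rates": outdir / "mapping_rates.tsv"}
    if not fresh("quantify", quant_paths):
        res.mapping_rates.to_csv(quant_paths["mapping_rates"], sep="\t")
        record("quantify", quant_paths)

    agg_paths = {"matrix": outdir / "counts.tsv", "metadata": outdir / "metadata.tsv"}
    if not fresh("aggregate", agg_paths):
        res.counts.write_tsv(agg_paths["matrix"])
        synthetic.write_metadata(res.metadata, agg_paths["metadata"])
        record("aggregate", agg_paths)

    res = run_diagnostic_protocol(res, seed=seed, alpha_grid=alpha_grid)

    feat_paths = {"entropy": outdir / "entropy.tsv", "fractions": outdir / "fractions.tsv"}
    if not fresh("features", feat_paths):
        sf = features.size_factors(res.counts)
        norm = features.normalize(res.counts, sf)
        grouping = res.catalog_aware.group_of()
        features.shannon_entropy(norm, grouping).to_csv(feat_paths["entropy"], sep="\t")
        features.group_fractions(norm, grouping).to_csv(feat_paths["fractions"], sep="\t")
        record("features", feat_paths)

    de_paths = {"de": outdir / "de.tsv"}
    if not fresh("diffexp", de_paths):
        res.de.write_tsv(de_paths["de"])
        record("diffexp", de_paths)

    model_paths = {"model": outdir / "model.json"}
    if not fresh("train", model_paths):
        res.model.save(model_paths["model"])
        record("train", model_paths)

    eval_paths = {"metrics": outdir / "metrics.json"}
    if not fresh("evaluate", eval_paths):
        payload = res.eval_result.to_dict()
        payload["train"] = {
            k: v for k, v in res.model.train_metrics.items() if k != "leaderboard"
        }
        with open(eval_paths["metrics"], "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        record("evaluate", eval_paths)

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
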