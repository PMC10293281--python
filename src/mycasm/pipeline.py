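"""End-to-end pipeline: synthesize or ingest, then run every analysis stage.

One YAML config and one master seed drive the whole run. Per-stage seeds are
derived by stable hashing of the stage name, so adding or removing a stage
never shifts another stage's random stream. Each stage writes TSV/JSON
outputs plus a manifest entry (parameter hash + input hashes); a rerun with
unchanged inputs reuses the cached stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import NullModelConfig, compute_bnri, compute_nst, compute_rc_bray, partition_processes
from .calibration import assign_genera, fit_threshold_map, p_distance_matrix, ubiquity_abundance_summary
from .core import (
    goods_coverage,
    patristic_distances,
    read_alignment,
    read_community_table,
    read_metadata,
    read_tree,
)
from .phylosig import (
    abouheif_proximity,
    abundance_trait,
    global_phylo_signal,
    inverse_patristic_weights,
    lipa,
    lipa_summarize,
    paco_fit,
    paco_subsample,
    per_sample_host_tree,
)
from .structure import alpha_diversity, beta_diversity, pcoa, permanova, permuted_mrm
from .synth import make_study_fixture, write_fixture

logger = logging.getLogger("mycasm")

_KNOWN_KEYS = {
    "master_seed", "output_dir", "input", "stages", "params",
}
_KNOWN_INPUT_KEYS = {
    "preset", "truth_overrides", "table", "metadata", "host_tree", "symbiont_tree",
    "markers_full", "markers_sub",
}
_KNOWN_PARAM_KEYS = {
    "n_null", "n_boot", "n_perm", "group_by", "beta_metric", "permanova_factors",
    "n_subsamples", "n_perm_outer", "n_perm_inner", "min_significant",
    "genus_threshold", "species_thr_full", "genus_thr_full", "lipa_top_genera",
}
_STAGES = ("synthesize", "calibration", "assembly", "structure", "phylosymbiosis")


@dataclass
class PipelineConfig:
    master_seed: int = 0
    output_dir: str = "mycasm_out"
    input: dict = field(default_factory=lambda: {"preset": "small"})
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.input) - _KNOWN_INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage names: {sorted(unknown)}")
        unknown = set(self.params) - _KNOWN_PARAM_KEYS
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def stage_seed(self, stage: str) -> int:
        return (int(self.master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)

    def param(self, key: str, default):
        return self.params.get(key, default)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "master_seed": int(config.master_seed),
        "stages": {},
    }

    # ---- inputs -----------------------------------------------------------
    synth_dir = out / "synthesize"
    if config.stages.get("synthesize", True) and "preset" in config.input:
        seed = config.stage_seed("synthesize")
        stamp = {"preset": config.input["preset"], "seed": seed,
                 "truth_overrides": config.input.get("truth_overrides", {})}
        if not _stage_cached(synth_dir, stamp):
            fixture = make_study_fixture(
                config.input["preset"], seed=seed,
                **(config.input.get("truth_overrides") or {}),
            )
            paths = write_fixture(fixture, synth_dir)
            _stamp_stage(synth_dir, stamp, paths)
        paths = json.loads((synth_dir / "stage_manifest.json").read_text())["outputs"]
        inputs = dict(paths)
    else:
        inputs = {k: config.input[k] for k in config.input if k not in
                  ("preset", "truth_overrides")}
    manifest["inputs"] = {k: _hash_file(v) for k, v in inputs.items()
                          if k != "truth" and Path(v).exists()}

    table = read_community_table(inputs["table"])
    meta = read_metadata(inputs["metadata"])
    host_tree = read_tree(inputs["host_tree"]) if "host_tree" in inputs else None
    sym_tree = read_tree(inputs["symbiont_tree"]) if "symbiont_tree" in inputs else None

    # ---- calibration ------------------------------------------------------
    if config.stages.get("calibration", True):
        stage_dir = out / "calibration"
        stage_dir.mkdir(exist_ok=True)
        seed = config.stage_seed("calibration")
        outputs = {}
        summary = {}
        if "markers_full" in inputs and "markers_sub" in inputs:
            full = read_alignment(inputs["markers_full"])
            sub = read_alignment(inputs["markers_sub"])
            tm = fit_threshold_map(
                p_distance_matrix(full), p_distance_matrix(sub),
                species_thr_full=config.param("species_thr_full", 0.02),
                genus_thr_full=config.param("genus_thr_full", 0.03),
            )
            summary["threshold_map"] = {
                "slope": tm.slope, "intercept": tm.intercept, "r_squared": tm.r_squared,
                "mapped_species_threshold": tm.mapped_species_threshold,
                "mapped_genus_threshold": tm.mapped_genus_threshold,
            }
            # two-tier assignment demo: first half of the pool act as named
            # references, the rest are queries to be recovered or NY-labelled
            ids = sub.ids
            n_ref = max(2, len(ids) // 2)
            ref_aln = type(sub)(ids[:n_ref], sub.seqs[:n_ref])
            qry_aln = type(sub)(ids[n_ref:], sub.seqs[n_ref:])
            assigns = assign_genera(
                qry_aln, ref_aln, {i: i for i in ids[:n_ref]},
                genus_threshold=config.param(
                    "genus_threshold", float(tm.mapped_genus_threshold)),
            )
            adf = pd.DataFrame([dataclasses.asdict(a) for a in assigns])
            adf.to_csv(stage_dir / "assignments.tsv", sep="\t", index=False)
            outputs["assignments"] = str(stage_dir / "assignments.tsv")
            novel = adf.loc[adf["is_novel"], "genus_label"]
            summary["n_novel_genera"] = int(novel.nunique())
        if table.is_integer():
            cov = goods_coverage(table)
            cdf = pd.DataFrame([dataclasses.asdict(c) for c in cov])
            cdf.to_csv(stage_dir / "coverage.tsv", sep="\t", index=False)
            outputs["coverage"] = str(stage_dir / "coverage.tsv")
            summary["median_goods_coverage"] = float(cdf["goods_coverage"].median())
        ua, r2 = ubiquity_abundance_summary(table)
        ua.to_csv(stage_dir / "ubiquity.tsv", sep="\t", index_label="taxon")
        outputs["ubiquity"] = str(stage_dir / "ubiquity.tsv")
        summary["ubiquity_abundance_r_squared"] = r2
        _write_json(summary, stage_dir / "summary.json")
        outputs["summary"] = str(stage_dir / "summary.json")
        manifest["stages"]["calibration"] = {"seed": seed, "outputs": outputs}

    # ---- assembly ---------------------------------------------------------
    if config.stages.get("assembly", True):
        stage_dir = out / "assembly"
        stage_dir.mkdir(exist_ok=True)
        seed = config.stage_seed("assembly")
        n_null = int(config.param("n_null", 299))
        group_by = config.param("group_by", "gut_type")
        cfg = NullModelConfig(n_null=n_null, seed=seed)
        groups = meta.loc[table.sample_ids, group_by]
        nst_summary = {}
        for index in ("jaccard", "bray"):
            for res in compute_nst(table, groups, index=index, config=cfg,
                                   n_boot=int(config.param("n_boot", 1000))):
                nst_summary[f"{index}:{res.group_id}"] = {
                    "nst_percent": res.nst_point,
                    "bootstrap_q05": float(np.nanquantile(res.nst_bootstrap, 0.05)),
                    "bootstrap_q95": float(np.nanquantile(res.nst_bootstrap, 0.95)),
                    "n_samples": len(res.sample_ids),
                }
        bnri = compute_bnri(table, sym_tree, config=cfg)
        rc = compute_rc_bray(table, config=cfg)
        part = partition_processes(bnri, rc)
        part.pairs.to_csv(stage_dir / "partition_pairs.tsv", sep="\t", index=False)
        _write_json({"nst": nst_summary, "fractions": part.fractions},
                    stage_dir / "summary.json")
        manifest["stages"]["assembly"] = {
            "seed": seed,
            "outputs": {"pairs": str(stage_dir / "partition_pairs.tsv"),
                        "summary": str(stage_dir / "summary.json")},
        }

    # ---- community structure ---------------------------------------------
    if config.stages.get("structure", True):
        stage_dir = out / "structure"
        stage_dir.mkdir(exist_ok=True)
        seed = config.stage_seed("structure")
        metric = config.param("beta_metric", "bray")
        factors = list(config.param(
            "permanova_factors", ["species", "family", "gut_type", "domestication"]))
        alpha = alpha_diversity(table)
        alpha.to_csv(stage_dir / "alpha.tsv", sep="\t", index_label="sample_id")
        dist = beta_diversity(table, metric, tree=sym_tree)
        pd.DataFrame(dist.data, index=list(dist.ids), columns=list(dist.ids)).to_csv(
            stage_dir / f"dist_{metric}.tsv", sep="\t", index_label="sample_id")
        ordn = pcoa(dist)
        ordn.coordinates.to_csv(stage_dir / "pcoa.tsv", sep="\t", index_label="sample_id")
        perm = permanova(dist, meta, factors,
                         n_perm=int(config.param("n_perm", 999)), seed=seed)
        perm.to_csv(stage_dir / "permanova.tsv", sep="\t")
        host_dm = patristic_distances(host_tree) if host_tree is not None else None
        verdicts = permuted_mrm(
            table, meta, metrics=(metric,), tree=sym_tree,
            host_tree_distance=host_dm,
            n_perm_outer=int(config.param("n_perm_outer", 100)),
            n_perm_inner=int(config.param("n_perm_inner", 199)),
            min_significant=int(config.param("min_significant", 75)),
            seed=seed,
        )
        vdf = pd.DataFrame(
            [
                {"factor": v.factor, "metric": v.metric,
                 "n_significant": v.n_significant,
                 "median_coefficient": float(np.nanmedian(v.coefficients)),
                 "significant_overall": bool(v.significant_overall)}
                for v in verdicts.values()
            ]
        )
        vdf.to_csv(stage_dir / "permuted_mrm.tsv", sep="\t", index=False)
        _write_json(
            {
                "permanova_r_squared": perm["r_squared"].drop("Residual").to_dict(),
                "permanova_p": perm["p_value"].drop("Residual").to_dict(),
                "permuted_mrm": {
                    f"{v.factor}:{v.metric}": bool(v.significant_overall)
                    for v in verdicts.values()
                },
            },
            stage_dir / "summary.json",
        )
        manifest["stages"]["structure"] = {
            "seed": seed,
            "outputs": {k: str(stage_dir / k) for k in
                        ("alpha.tsv", "pcoa.tsv", "permanova.tsv",
                         "permuted_mrm.tsv", "summary.json")},
        }

    # ---- phylosymbiosis ---------------------------------------------------
    if config.stages.get("phylosymbiosis", True):
        stage_dir = out / "phylosymbiosis"
        stage_dir.mkdir(exist_ok=True)
        seed = config.stage_seed("phylosymbiosis")
        sample_tree = per_sample_host_tree(host_tree, meta.loc[table.sample_ids])
        host_dm = patristic_distances(sample_tree)
        sym_dm = patristic_distances(sym_tree)
        assoc = table.relative_abundance()  # abundance-weighted links
        fit = paco_fit(host_dm, sym_dm, assoc,
                       n_perm=int(config.param("n_perm", 499)), seed=seed)
        sub = paco_subsample(table, meta, host_tree, sym_tree,
                             n_subsamples=int(config.param("n_subsamples", 100)),
                             seed=seed)
        sub.residuals.to_csv(stage_dir / "paco_residuals.tsv", sep="\t", index=False)
        sub.comparisons.to_csv(stage_dir / "paco_comparisons.tsv", sep="\t", index=False)
        weights = inverse_patristic_weights(sample_tree)
        abo = abouheif_proximity(sample_tree)
        rel = table.relative_abundance()
        top = rel.mean(axis=0).nlargest(int(config.param("lipa_top_genera", 20))).index
        lipa_rows, signal_rows = [], []
        for genus in top:
            trait = abundance_trait(table, genus)
            if np.ptp(trait.to_numpy()) == 0:
                continue
            sig = global_phylo_signal(trait, sample_tree, n_perm=499, seed=seed,
                                      genus=genus, weights=weights, abouheif=abo)
            signal_rows.append({
                "genus": genus, "cmean": sig.cmean, "moran_i": sig.moran_i,
                "pagel_lambda": sig.pagel_lambda, **{f"p_{k}": v for k, v in sig.p_values.items()},
            })
            lipa_rows.append(lipa(trait, sample_tree, n_perm=499, seed=seed,
                                  genus=genus, weights=weights))
        signal_df = pd.DataFrame(signal_rows)
        signal_df.to_csv(stage_dir / "signal.tsv", sep="\t", index=False)
        lipa_df = pd.concat(lipa_rows, ignore_index=True) if lipa_rows else pd.DataFrame()
        lipa_df.to_csv(stage_dir / "lipa.tsv", sep="\t", index=False)
        if len(lipa_df):
            lipa_summarize(lipa_df, meta).to_csv(stage_dir / "lipa_summary.tsv",
                                                 sep="\t", index=False)
        _write_json(
            {
                "paco_m2": fit.m2,
                "paco_p": fit.p_value,
                "paco_comparisons": sub.comparisons.to_dict(orient="records"),
                "n_genera_with_signal": int(
                    (signal_df[["p_cmean", "p_moran_i", "p_pagel_lambda"]] < 0.05)
                    .any(axis=1).sum()) if len(signal_df) else 0,
            },
            stage_dir / "summary.json",
        )
        manifest["stages"]["phylosymbiosis"] = {
            "seed": seed,
            "outputs": {k: str(stage_dir / k) for k in
                        ("paco_residuals.tsv", "paco_comparisons.tsv", "signal.tsv",
                         "lipa.tsv", "summary.json")},
        }

    _write_json(manifest, out / "manifest.json")
    return manifest


def _stage_cached(stage_dir: Path, stamp: dict) -> bool:
    mf = stage_dir / "stage_manifest.json"
    if not mf.exists():
        return False
    try:
        doc = json.loads(mf.read_text())
    except json.JSONDecodeError:
        return False
    if doc.get("stamp") != stamp:
        return False
    return all(Path(p).exists() for p in doc.get("outputs", {}).values())


def _stamp_stage(stage_dir: Path, stamp: dict, outputs: dict) -> None:
    _write_json({"stamp": stamp, "outputs": outputs}, stage_dir / "stage_manifest.json")
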