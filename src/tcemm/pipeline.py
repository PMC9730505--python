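"""End-to-end orchestration: synthesize/derive -> screen -> select -> network -> logo.

A declarative YAML config drives every stage; all randomness derives from
one global seed, so a rerun with the same config and seed reproduces every
output file byte for byte (verified via the checksum manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .coexpression import CoexpressionProfiler, export_graph
from .engine import build_matrix, pairs_to_tsv
from .logo import compare_groups
from .presentation import DefaultPresentationModel
from .registry import (
    AlleleRegistry,
    load_registry,
    mutate_registry,
    synthesize_registry,
)
from .screen import frequency_compare, score_association, screen_tcemm
from .selection import CoxLassoSelector, selection_summary
from .version_diff import diff_versions

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``default_config`` for the schema)."""

    seed: int = 1
    output_dir: str = "tcemm_out"
    registry: dict = field(default_factory=lambda: {
        "fasta": None, "version_tag": "synthetic-1",
        "n_alleles_per_locus": 6, "n_polymorphic_sites": 14,
    })
    pool: dict = field(default_factory=lambda: {"n_haplotypes": 12, "concentration": 1.0})
    engine: dict = field(default_factory=lambda: {
        "q_bind": 0.2, "scoring": "distinct_core",
        "self_repertoire_binding_filtered": False,
    })
    cohort: dict = field(default_factory=lambda: {
        "n_pairs": 2000, "admin_censor_time": 15.0, "weibull_sigma": 0.8,
        "target_event_fraction": 0.17, "random_censor_rate": 0.025,
        "n_planted": 5, "planted_beta": -0.5, "planted_min_support": 50,
    })
    screen: dict = field(default_factory=lambda: {
        "min_support": 50, "alpha": 0.05, "ph_test_on": "significant",
    })
    selection: dict = field(default_factory=lambda: {
        "n_folds": 10, "posi_method": "split", "n_alphas": 50,
    })
    network: dict = field(default_factory=lambda: {"beta": 4.0, "adjacency_threshold": 0.3})
    logo: dict = field(default_factory=lambda: {"n_perm": 1000, "comparison": "lasso_selected"})
    version_diff: dict = field(default_factory=lambda: {"enabled": True, "n_edits": 2})

    def validate(self) -> None:
        fasta = self.registry.get("fasta")
        if fasta is not None and not Path(fasta).exists():
            raise FileNotFoundError(f"registry FASTA not found: {fasta}")
        if not 0.0 <= self.engine["q_bind"] <= 1.0:
            raise ValueError("engine.q_bind must be in [0, 1]")
        if self.cohort["n_pairs"] < 2:
            raise ValueError("cohort.n_pairs must be >= 2")


def load_config(path: str | Path, seed: Optional[int] = None) -> RunConfig:
    """Load a YAML config; missing sections fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config section {key!r}")
        if isinstance(val, dict):
            getattr(cfg, key).update(val)
        else:
            setattr(cfg, key, val)
    if seed is not None:
        cfg.seed = int(seed)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _build_registry(cfg: RunConfig) -> AlleleRegistry:
    rcfg = cfg.registry
    if rcfg.get("fasta"):
        return load_registry(rcfg["fasta"], rcfg.get("version_tag", "user"))
    return synthesize_registry(
        rcfg["n_alleles_per_locus"], rcfg["n_polymorphic_sites"], cfg.seed,
        version_tag=rcfg.get("version_tag", "synthetic-1"),
    )


def run_all(config: RunConfig, stop_after: Optional[str] = None) -> Dict:
    """Execute the full pipeline; returns the output manifest.

    Stages: simulate (registry, pool, cohort, mismatch matrix), screen,
    select, network, logo, version-diff (optional). ``stop_after`` limits
    execution to a stage prefix (used by the CLI subcommands). Any stage
    failure aborts with the stage name.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"seed": config.seed, "stages": {}, "files": {}}
    stage_order = ["simulate", "screen", "select", "network", "logo", "version_diff"]
    if stop_after is not None and stop_after not in stage_order:
        raise ValueError(f"unknown stage {stop_after!r}")

    def record(name: str, t0: float) -> None:
        manifest["stages"][name] = {"seconds": round(_time.time() - t0, 3)}
        logger.info("stage %s done in %.2fs", name, _time.time() - t0)

    def done(name: str) -> bool:
        return stop_after is not None and stage_order.index(name) >= stage_order.index(stop_after)

    try:
        stage = "simulate"
        t0 = _time.time()
        registry = _build_registry(config)
        registry.to_fasta(out / "registry.fasta")
        _write_json(registry.summary(), out / "registry_summary.json")
        pool = cohort_mod.build_haplotype_pool(
            registry, config.pool["n_haplotypes"], config.seed,
            concentration=config.pool.get("concentration", 1.0),
        )
        model = DefaultPresentationModel(registry, config.engine["q_bind"], config.seed)
        ccfg = config.cohort
        pairs = cohort_mod.sample_genotypes(pool, ccfg["n_pairs"], config.seed)
        from .engine import derive_tcemm

        sets = [
            derive_tcemm(
                p, registry, model,
                scoring=config.engine["scoring"],
                self_repertoire_binding_filtered=config.engine["self_repertoire_binding_filtered"],
            )
            for p in pairs
        ]
        matrix = build_matrix(sets)
        planted = cohort_mod.choose_plantable_cores(
            matrix, ccfg.get("n_planted", 0), ccfg.get("planted_beta", -0.5),
            ccfg.get("planted_min_support", 50), config.seed,
        )
        cohort_cfg = cohort_mod.CohortConfig(
            n_pairs=ccfg["n_pairs"], seed=config.seed,
            admin_censor_time=ccfg["admin_censor_time"],
            weibull_sigma=ccfg["weibull_sigma"],
            planted_effects=planted,
            target_event_fraction=ccfg["target_event_fraction"],
            random_censor_rate=ccfg["random_censor_rate"],
        )
        cohort_df, matrix, truth = cohort_mod.generate_cohort(
            registry, pool, model, cohort_cfg,
            scoring=config.engine["scoring"],
            pairs=pairs, matrix=matrix,
            drb1_min_count=config.screen["min_support"],
        )
        pairs_to_tsv(pairs, out / "pairs.tsv")
        cohort_df.to_csv(out / "cohort.tsv", sep="\t", index=False, float_format="%.10g")
        matrix.write_triplets(out / "tcemm_matrix.tsv")
        matrix.write_scores(out / "pirche_scores.tsv")
        _write_json(
            {k: v for k, v in truth.items() if k != "pairs"}, out / "truth.json"
        )
        record(stage, t0)
        if done(stage):
            return _finish(manifest, out, config)

        stage = "screen"
        t0 = _time.time()
        cov_cols = [
            c for c in cohort_df.columns if c not in ("pair_id", "time", "event")
        ]
        cov_design = cohort_mod.covariate_design(
            cohort_df[[c for c in cov_cols if not c.startswith("drb1_")]]
        )
        drb1_cols = [c for c in cov_cols if c.startswith("drb1_")]
        full_design = pd.concat(
            [cov_design.reset_index(drop=True), cohort_df[drb1_cols].reset_index(drop=True)],
            axis=1,
        )
        screen_cohort = pd.concat(
            [cohort_df[["pair_id", "time", "event"]].reset_index(drop=True), full_design],
            axis=1,
        )
        scr = screen_tcemm(
            screen_cohort, matrix, covariate_cols=list(full_design.columns),
            min_support=config.screen["min_support"], alpha=config.screen["alpha"],
            ph_test_on=config.screen["ph_test_on"],
        )
        scr.to_csv(out / "screen.tsv", sep="\t", index=False, float_format="%.10g")
        assoc = score_association(
            cohort_df["time"], cohort_df["event"], matrix.scores, design=full_design
        )
        freq = frequency_compare(scr, alpha=config.screen["alpha"]) if scr["q"].notna().any() else {}
        _write_json(
            {"score_association": assoc, "frequency_by_significance": freq,
             "aic_note": "Cox AIC uses the partial likelihood; cross-family comparison is heuristic"},
            out / "screen_summary.json",
        )
        record(stage, t0)
        if done(stage):
            return _finish(manifest, out, config)

        stage = "select"
        t0 = _time.time()
        import sksurv.util

        y = sksurv.util.Surv.from_arrays(
            event=cohort_df["event"].to_numpy(bool), time=cohort_df["time"].to_numpy(float)
        )
        supp = matrix.support()
        keep = [
            matrix.tcemm_ids[j]
            for j in range(len(matrix.tcemm_ids))
            if supp[j] >= config.screen["min_support"] and supp[j] < matrix.n_pairs
        ]
        Xsel = matrix.to_dense_df()[keep].reset_index(drop=True).astype(float)
        std_design = cohort_mod.covariate_design(
            cohort_df[[c for c in cov_cols if not c.startswith("drb1_")]], standardize=True
        )
        Xfull = pd.concat(
            [Xsel, std_design.reset_index(drop=True), cohort_df[drb1_cols].reset_index(drop=True)],
            axis=1,
        )
        unpen = list(std_design.columns) + drb1_cols
        selector = CoxLassoSelector(
            unpenalized_cols=unpen,
            n_folds=config.selection["n_folds"],
            seed=config.seed,
            posi_method=config.selection["posi_method"],
            n_alphas=config.selection["n_alphas"],
        ).fit(Xfull, y)
        sel_table = selector.result_.table.copy()
        sel_table.insert(1, "class_origin", [
            "+".join(sorted(matrix.class_origin.get(c, frozenset()))) for c in sel_table["tcemm"]
        ])
        sel_table.to_csv(out / "selection.tsv", sep="\t", index=False, float_format="%.10g")
        selector.path_.to_frame().to_csv(
            out / "cv_curve.tsv", sep="\t", index=False, float_format="%.10g"
        )
        summary = selection_summary(selector.result_, matrix.class_origin)
        summary["lambda_min"] = selector.lambda_min_
        summary["kkt_ok"] = bool(selector.kkt_ok_)
        summary["n_candidates"] = len(keep)
        _write_json(summary, out / "selection_summary.json")
        record(stage, t0)
        if done(stage):
            return _finish(manifest, out, config)

        stage = "network"
        t0 = _time.time()
        prof = CoexpressionProfiler(
            beta=config.network["beta"],
            adjacency_threshold=config.network["adjacency_threshold"],
            min_support=config.screen["min_support"],
        ).fit(matrix)
        prof.profile_table().to_csv(out / "profiles.tsv", sep="\t", index=False)
        annotations = {
            "aft_significant": dict(zip(scr["tcemm"], scr["significant"].astype(bool))),
            "lasso_selected": {c: True for c in selector.selected_},
            "posi_significant": {c: True for c in selector.result_.posi_significant},
        }
        export_graph(
            prof.network_, prof.profiles_, annotations,
            adjacency_threshold=config.network["adjacency_threshold"],
            path=out / "network.graphml",
        )
        _write_json(
            {
                "n_nodes": len(prof.network_.tcemm_ids),
                "n_profiles": len(prof.profiles_),
                "n_in_profiles": int(sum(p.size for p in prof.profiles_)),
                "n_singletons": len(prof.singletons_),
                "fraction_in_profiles": prof.fraction_in_profiles_,
            },
            out / "network_summary.json",
        )
        record(stage, t0)
        if done(stage):
            return _finish(manifest, out, config)

        stage = "logo"
        t0 = _time.time()
        if config.logo["comparison"] == "posi_significant":
            chosen = set(selector.result_.posi_significant)
        else:
            chosen = set(selector.selected_)
        pool_ids = [c for c in keep]
        sel_cores = [c for c in pool_ids if c in chosen]
        uns_cores = [c for c in pool_ids if c not in chosen]
        if len(sel_cores) >= 2 and len(uns_cores) >= 2:
            logo_res = compare_groups(
                sel_cores, uns_cores, n_perm=config.logo["n_perm"], seed=config.seed
            )
        else:
            logger.warning("logo: too few selected cores for comparison; writing empty table")
            logo_res = pd.DataFrame(columns=["position", "divergence", "p", "q"])
        logo_res.to_csv(out / "logo.tsv", sep="\t", index=False, float_format="%.10g")
        record(stage, t0)
        if done(stage):
            return _finish(manifest, out, config)

        if config.version_diff.get("enabled", False):
            stage = "version_diff"
            t0 = _time.time()
            rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
            names = sorted(registry.records)
            edits = {}
            for _ in range(int(config.version_diff.get("n_edits", 1))):
                nm = names[int(rng.integers(len(names)))]
                seq = registry.records[nm].sequence
                pos = int(rng.integers(len(seq)))
                from .registry import AMINO_ACIDS

                cur = seq[pos]
                alt = AMINO_ACIDS[(AMINO_ACIDS.index(cur) + 1 + int(rng.integers(19))) % 20]
                if alt == cur:
                    alt = AMINO_ACIDS[(AMINO_ACIDS.index(cur) + 1) % 20]
                edits.setdefault(nm, []).append((pos, alt))
            v2 = mutate_registry(registry, edits, version_tag=registry.version_tag + "-next")
            report = diff_versions(
                pairs, registry, v2,
                model=lambda reg: DefaultPresentationModel(
                    reg, config.engine["q_bind"], config.seed
                ),
                scoring=config.engine["scoring"],
            )
            _write_json(report.to_dict(), out / "version_diff.json")
            report.per_pair_changes.to_csv(
                out / "version_diff_pairs.tsv", sep="\t", index=False
            )
            record(stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return _finish(manifest, out, config)


def _finish(manifest: Dict, out: Path, config: RunConfig) -> Dict:
    manifest["config"] = asdict(config)
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest["files"][f.name] = _sha256(f)
    _write_json(manifest, out / "manifest.json")
    return manifest
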