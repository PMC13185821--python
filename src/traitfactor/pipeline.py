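"""End-to-end pipeline: simulate -> rank scan -> fit -> subgroup -> direction scan.

A RunConfig (YAML/JSON/dict) fixes every stage parameter and a master seed
from which each stage derives its own sub-seed, so a run is bit-reproducible.
Every output CSV gets a JSON sidecar naming its producing stage, parameters
and seed; the run ends with a manifest listing every file with a content
hash and the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import ingest, modeval, opnmf, subgroup, synth, traitspace
from .utils import derive_seed


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "traitfactor_run"
    synth: dict = field(default_factory=dict)
    rank_scan: dict = field(default_factory=dict)
    fit_ranks: list = field(default_factory=lambda: [2, 5])
    subgroup: dict = field(default_factory=dict)
    direction_scan: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def resolved(self) -> dict:
        d = asdict(self)
        d["synth"] = {**_SYNTH_DEFAULTS, **self.synth}
        d["rank_scan"] = {**_RANK_SCAN_DEFAULTS, **self.rank_scan}
        d["subgroup"] = {**_SUBGROUP_DEFAULTS, **self.subgroup}
        d["direction_scan"] = {**_SCAN_DEFAULTS, **self.direction_scan}
        return d


_SYNTH_DEFAULTS = {
    "n_items_per_dimension": 4,
    "structure": "big2_hier",
    "cross_loading": 0.1,
    "noise_sd": 0.5,
    "missing_rate": 0.02,
    "acquiescence_sd": 0.0,
    "groups": [
        {"name": "g1", "n": 200},
        {"name": "g2", "n": 200},
        {"name": "g3", "n": 200},
        {"name": "g4", "n": 200, "noise_multiplier": 2.0},
    ],
}
_RANK_SCAN_DEFAULTS = {"ranks": [2, 3, 4, 5, 6], "n_reps": 5, "n_folds": 5, "scheme": "kfold"}
_SUBGROUP_DEFAULTS = {"label_field": "group", "rank": 2, "n_null": 20}
_SCAN_DEFAULTS = {
    "theta_true": 147,
    "n_features": 40,
    "signal_fraction": 0.5,
    "noise_sd": 0.5,
    "family_size": 2,
    "n_reps": 2,
    "n_folds": 5,
    "n_perm": 100,
    "alpha_fdr": 0.05,
    "K_grid": [2, 4],
    "eta_grid": [0.25, 1.0],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(path: Path, stage: str, params: dict, seed: int) -> Path:
    side = path.with_suffix(path.suffix + ".meta.json")
    with open(side, "w") as fh:
        json.dump({"stage": stage, "params": params, "seed": seed}, fh, indent=2, sort_keys=True)
    return side


def run_pipeline(config: RunConfig | dict | str) -> dict:
    """Execute all stages; return the manifest (also written to manifest.json)."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_file(config)
    elif isinstance(config, dict):
        config = RunConfig(**config)
    cfg = config.resolved()
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    stage = "init"
    try:
        # --- stage 1: simulate ---------------------------------------------
        stage = "simulate"
        sc = cfg["synth"]
        seed_sim = derive_seed(cfg["seed"], 1)
        groups = [
            synth.GroupSpec(
                name=g["name"],
                n=int(g["n"]),
                loading_perturbation=float(g.get("loading_perturbation", 0.0)),
                noise_multiplier=float(g.get("noise_multiplier", 1.0)),
            )
            for g in sc["groups"]
        ]
        truth = synth.build_true_loadings(
            sc["n_items_per_dimension"],
            structure=sc["structure"],
            cross_loading=sc["cross_loading"],
            seed=seed_sim,
            noise_sd=sc["noise_sd"],
            missing_rate=sc["missing_rate"],
            acquiescence_sd=sc["acquiescence_sd"],
            group_spec=groups,
        )
        R_raw, H_true = synth.simulate_subgroups(truth)
        paths = synth.write_synthetic_dataset(outdir / "data", truth, R_raw, H_true)
        files.extend(Path(p) for p in paths.values())

        R = ingest.apply_reverse_scoring(R_raw)

        # --- stage 2: rank scan --------------------------------------------
        stage = "rank-scan"
        rs = cfg["rank_scan"]
        seed_rs = derive_seed(cfg["seed"], 2)
        records = modeval.run_crossvalidation(
            R,
            ranks=rs["ranks"],
            scheme=rs["scheme"],
            n_reps=rs["n_reps"],
            n_folds=rs["n_folds"],
            seed=seed_rs,
        )
        rec_path = outdir / "cv_records.csv"
        modeval.records_to_frame(records).to_csv(rec_path, index=False)
        files += [rec_path, _sidecar(rec_path, stage, rs, seed_rs)]
        summary = modeval.summarize_rank_selection(records, seed=seed_rs)
        sum_path = outdir / "rank_summary.json"
        with open(sum_path, "w") as fh:
            json.dump(summary.to_json_dict(), fh, indent=2, sort_keys=True)
        files.append(sum_path)

        # --- stage 3: fit at chosen ranks ----------------------------------
        stage = "fit"
        X = ingest.impute_missing(R)
        models = {}
        for rank in cfg["fit_ranks"]:
            model = opnmf.fit_opnmf(X, int(rank))
            models[int(rank)] = model
            saved = opnmf.save_model(
                model, outdir / "models", item_ids=X.item_ids,
                extra_meta={"stage": stage, "seed": cfg["seed"]},
            )
            files += [Path(saved["W"]), Path(saved["meta"])]

        # --- stage 4: subgroup analysis ------------------------------------
        stage = "subgroup"
        sg = cfg["subgroup"]
        seed_sg = derive_seed(cfg["seed"], 4)
        rank_sg = int(sg["rank"])
        overall = models.get(rank_sg) or opnmf.fit_opnmf(X, rank_sg)
        reports = subgroup.analyze_subgroups(
            overall, R, label_field=sg["label_field"], rank=rank_sg,
            n_null=sg["n_null"], seed=seed_sg,
        )
        rep_path = outdir / "subgroup_report.csv"
        subgroup.reports_to_frame(reports).to_csv(rep_path, index=False)
        files += [rep_path, _sidecar(rep_path, stage, sg, seed_sg)]
        reg_path = outdir / "subgroup_regressions.json"
        with open(reg_path, "w") as fh:
            json.dump(
                subgroup.explain_generalizability(reports).to_dict(orient="records"),
                fh, indent=2, sort_keys=True,
            )
        files.append(reg_path)

        # --- stage 5: direction scan ---------------------------------------
        stage = "direction-scan"
        ds = cfg["direction_scan"]
        seed_ds = derive_seed(cfg["seed"], 5)
        S2 = synth.true_big_two_scores(truth, H_true)
        pheno, _ = synth.simulate_phenotypes(
            S2,
            theta_true=ds["theta_true"],
            n_features=ds["n_features"],
            signal_fraction=ds["signal_fraction"],
            noise_sd=ds["noise_sd"],
            family_size=ds["family_size"],
            seed=seed_ds,
        )
        scores = traitspace.standardize_scores(S2, family_id=pheno.family_id)
        scan = traitspace.direction_scan(
            pheno,
            scores,
            n_reps=ds["n_reps"],
            n_folds=ds["n_folds"],
            n_perm=ds["n_perm"],
            alpha_fdr=ds["alpha_fdr"],
            seed=seed_ds,
            K_grid=ds["K_grid"],
            eta_grid=ds["eta_grid"],
        )
        scan_path = outdir / "direction_scan.csv"
        scan.table.to_csv(scan_path, index=False)
        files += [scan_path, _sidecar(scan_path, stage, ds, seed_ds)]
        scan_meta = outdir / "direction_scan.json"
        with open(scan_meta, "w") as fh:
            json.dump(
                {"peak_angle": scan.peak_angle, "peak_accuracy": scan.peak_accuracy,
                 "n_perm": scan.n_perm, "alpha_fdr": scan.alpha_fdr},
                fh, indent=2, sort_keys=True,
            )
        files.append(scan_meta)
    except Exception as exc:
        partial = {
            "failed_stage": stage,
            "error": str(exc),
            "files": {str(p.relative_to(outdir)): _sha256(p) for p in files if p.exists()},
        }
        with open(outdir / "manifest_partial.json", "w") as fh:
            json.dump(partial, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "config": cfg,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(files))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
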