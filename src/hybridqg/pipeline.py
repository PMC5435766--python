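"""End-to-end orchestration: simulate -> QC -> means -> variance components
-> scans -> prediction, driven by one validated config with a master seed
split hierarchically per stage, and a manifest recording hashes of every
stage output."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import genotype, gwas, kernels as kernels_mod, phenostat, predict as predict_mod, simdata
from .core import (
    ConfigurationError,
    DataError,
    GROUP_HYBRID,
    GROUP_INBRED,
    PhenotypeTable,
    read_crosses_tsv,
    read_genotype_tsv,
    read_phenotype_tsv,
    write_crosses_tsv,
    write_genotype_tsv,
    write_phenotype_tsv,
    write_relationship_tsv,
)

STAGES = ("simulate", "qc", "kernels", "means", "varcomp", "scan", "scan2d", "predict")

DEFAULTS: dict = {
    "seed": 1,
    "out_dir": "run",
    "simulate": {
        "enabled": True,
        "n_lines": 60,
        "n_crosses": 100,
        "n_env": 3,
        "n_rep": 2,
        "n_qtl": 20,
        "n_epi_pairs": 6,
        "map": {"n_chromosomes": 19, "chrom_length_cm": 80.0, "markers_per_chrom": 20},
        "sigma2_g": 0.0267,
        "shares": [0.27, 0.49, 0.24],
        "sigma2_gxe": 0.0805,
        "sigma2_resid": 0.0211,
        "env_sd": 0.1,
    },
    "qc": {"enabled": True, "maf": 0.05, "miss": 0.05, "dedup": True, "geno": None},
    "kernels": {
        "enabled": True,
        "types": ["kinship", "additive", "dominance", "gaussian"],
        "shrink": True,
        "bandwidth": "median",
    },
    "means": {"enabled": True, "pheno": None, "outliers": True},
    "varcomp": {"enabled": True, "significance": [], "crosses": None},
    "scan": {"enabled": True, "alpha": 0.1},
    "scan2d": {"enabled": False, "n_perm": 100, "alpha": 0.05, "max_markers": 40},
    "predict": {"enabled": True, "models": ["A", "AD", "ADE"], "folds": 5, "repeats": 1},
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict) and k in user:
            out[k] = _merge(v, user[k], f"{path}{k}.")
        else:
            out[k] = user.get(k, v)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(path + u for u in unknown)}")
    return out


@dataclass
class RunConfig:
    data: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        user = yaml.safe_load(Path(path).read_text()) or {}
        return cls(_merge(DEFAULTS, user))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(_merge(DEFAULTS, d))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=False)

    def __getitem__(self, key):
        return self.data[key]


def template() -> str:
    """A fully populated config template with all defaults."""
    return yaml.safe_dump(DEFAULTS, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    cfg = config.data
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "stages": {}, "config": cfg}
    state: dict = {}

    def record(stage: str, files: dict, t0: float):
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in files.items()},
            "sha256": {k: _sha256(Path(v)) for k, v in files.items()},
            "seconds": round(time.time() - t0, 3),
        }

    def need(stage: str, key: str, reader, filename: str):
        if key in state:
            return state[key]
        p = out / filename
        if not p.exists():
            raise ConfigurationError(
                f"stage {stage!r} requires output {filename!r}; enable the producing stage"
            )
        state[key] = reader(p)
        return state[key]

    if cfg["simulate"]["enabled"]:
        t0 = time.time()
        sc = cfg["simulate"]
        gmap = simdata.default_map(**sc["map"])
        dh = simdata.simulate_dh_population(gmap, sc["n_lines"], seed=seed)
        design = simdata.make_crossing_design(
            list(dh.individual_ids), sc["n_crosses"], seed=seed
        )
        raw = simdata.random_truth(
            gmap, sc["n_qtl"], sc["n_epi_pairs"], seed=seed, n_env=sc["n_env"]
        )
        truth = simdata.calibrate_truth(
            dh,
            design,
            raw,
            sigma2_g=sc["sigma2_g"],
            shares=tuple(sc["shares"]),
            sigma2_gxe=sc["sigma2_gxe"],
            sigma2_resid=sc["sigma2_resid"],
            env_sd=sc["env_sd"],
            n_env=sc["n_env"],
        )
        pheno = simdata.simulate_trait(dh, design, truth, sc["n_env"], sc["n_rep"])
        hybrids = genotype.infer_hybrid_genotypes(dh, design)
        geno = dh.concat(hybrids)
        files = {
            "geno": out / "geno.tsv",
            "crosses": out / "crosses.tsv",
            "pheno": out / "pheno.tsv",
            "truth": out / "truth.json",
        }
        write_genotype_tsv(geno, files["geno"])
        write_crosses_tsv(design, files["crosses"])
        write_phenotype_tsv(pheno, files["pheno"])
        truth.to_json(files["truth"])
        state.update({"geno": geno, "crosses": design, "pheno": pheno, "truth": truth})
        record("simulate", files, t0)

    if cfg["qc"]["enabled"]:
        t0 = time.time()
        qcfg = cfg["qc"]
        if qcfg["geno"]:
            geno = read_genotype_tsv(qcfg["geno"])
            state["geno"] = geno
        else:
            geno = need("qc", "geno", read_genotype_tsv, "geno.tsv")
        filtered, report = genotype.qc_filter(geno, qcfg["maf"], qcfg["miss"])
        clusters = {}
        if qcfg["dedup"]:
            filtered = genotype.impute_marker_means(filtered)
            filtered, clusters = genotype.dedup_perfect_ld(filtered)
        files = {"filtered": out / "filtered.tsv", "qc_report": out / "qc.json"}
        write_genotype_tsv(filtered, files["filtered"])
        rep = report.to_dict()
        rep["ld_clusters"] = {str(k): [str(x) for x in v] for k, v in clusters.items()}
        Path(files["qc_report"]).write_text(json.dumps(rep, indent=1))
        state["filtered"] = filtered
        record("qc", files, t0)

    if cfg["kernels"]["enabled"]:
        t0 = time.time()
        kcfg = cfg["kernels"]
        filtered = need("kernels", "filtered", read_genotype_tsv, "filtered.tsv")
        design_mats = genotype.f_infinity_design(filtered, impute=True)
        kdir = out / "K"
        kdir.mkdir(exist_ok=True)
        files = {}
        built = {}
        for t in kcfg["types"]:
            if t == "kinship":
                K = kernels_mod.rogers_kinship(filtered)
            elif t == "additive":
                K = kernels_mod.additive_relationship(design_mats, shrink=kcfg["shrink"])
            elif t == "dominance":
                K = kernels_mod.dominance_relationship(design_mats, shrink=kcfg["shrink"])
            elif t == "gaussian":
                K = kernels_mod.gaussian_kernel(design_mats, bandwidth=kcfg["bandwidth"])
            else:
                raise ConfigurationError(f"unknown kernel type {t!r}")
            p = kdir / f"{t}.tsv"
            write_relationship_tsv(K, p)
            files[t] = p
            built[t] = K
        state["kernels"] = built
        state["design_mats"] = design_mats
        record("kernels", files, t0)

    if cfg["means"]["enabled"]:
        t0 = time.time()
        mcfg = cfg["means"]
        if mcfg["pheno"]:
            pheno = read_phenotype_tsv(mcfg["pheno"])
            state["pheno"] = pheno
        else:
            pheno = need("means", "pheno", read_phenotype_tsv, "pheno.tsv")
        if mcfg["outliers"]:
            pheno, removed = phenostat.detect_outliers(pheno)
        within = phenostat.adjust_means_within_env(pheno)
        across = phenostat.adjust_means_across_env(within)
        files = {"within": out / "means_within.tsv", "across": out / "means_across.tsv"}
        write_phenotype_tsv(within, files["within"])
        write_phenotype_tsv(across, files["across"])
        state["within"] = within
        state["across"] = across
        record("means", files, t0)

    def groups_from_geno():
        geno = state.get("filtered") or state.get("geno")
        if geno is None:
            geno = need("groups", "geno", read_genotype_tsv, "geno.tsv")
        return dict(zip(geno.individual_ids, geno.group))

    if cfg["varcomp"]["enabled"]:
        t0 = time.time()
        vcfg = cfg["varcomp"]
        pheno = state.get("pheno") or need("varcomp", "pheno", read_phenotype_tsv, "pheno.tsv")
        if vcfg["crosses"]:
            design = read_crosses_tsv(vcfg["crosses"])
        else:
            design = state.get("crosses") or need(
                "varcomp", "crosses", read_crosses_tsv, "crosses.tsv"
            )
        groups = groups_from_geno()
        vc = phenostat.fit_gca_sca(
            pheno, design, groups, significance=tuple(vcfg["significance"])
        )
        files = {"vc": out / "vc.json"}
        Path(files["vc"]).write_text(json.dumps(vc.to_dict(), indent=1))
        state["vc"] = vc
        record("varcomp", files, t0)

    if cfg["scan"]["enabled"]:
        t0 = time.time()
        if "kernels" not in state or "kinship" not in state["kernels"]:
            raise ConfigurationError("stage 'scan' requires the kernels stage with 'kinship'")
        within = state.get("within") or need(
            "scan", "within", lambda p: read_phenotype_tsv(p, stage="within_env_means"), "means_within.tsv"
        )
        res = gwas.main_effect_scan(within, state["design_mats"], state["kernels"]["kinship"])
        p_all = np.concatenate([res.table["p_a"].to_numpy(), res.table["p_d"].to_numpy()])
        flags = gwas.holm_correct(p_all, cfg["scan"]["alpha"])
        m = len(res.table)
        res.table["holm_a"] = flags[:m]
        res.table["holm_d"] = flags[m:]
        files = {"scan": out / "scan.tsv"}
        res.table.to_csv(files["scan"], sep="\t", index=False)
        state["scan"] = res
        record("scan", files, t0)

    if cfg["scan2d"]["enabled"]:
        t0 = time.time()
        if "kernels" not in state or "kinship" not in state["kernels"]:
            raise ConfigurationError("stage 'scan2d' requires the kernels stage with 'kinship'")
        s2 = cfg["scan2d"]
        within = state["within"]
        dm = state["design_mats"]
        idx = None
        if dm.n_markers > s2["max_markers"]:
            idx = np.linspace(0, dm.n_markers - 1, s2["max_markers"]).astype(int)
        res = gwas.epistasis_scan_2d(within, dm, state["kernels"]["kinship"], marker_idx=idx)
        groups = groups_from_geno()
        thresholds = gwas.permutation_threshold(
            within,
            dm,
            state["kernels"]["kinship"],
            groups,
            n_perm=s2["n_perm"],
            alpha=s2["alpha"],
            seed=seed,
            marker_idx=idx,
        )
        files = {"scan2d": out / "scan2d.tsv", "thresholds": out / "thresholds.json"}
        res.table.to_csv(files["scan2d"], sep="\t", index=False)
        Path(files["thresholds"]).write_text(json.dumps(thresholds, indent=1))
        record("scan2d", files, t0)

    if cfg["predict"]["enabled"]:
        t0 = time.time()
        if "kernels" not in state:
            raise ConfigurationError("stage 'predict' requires the kernels stage")
        pc = cfg["predict"]
        across = state["across"]
        groups = groups_from_geno()
        vc = state.get("vc")
        h2 = vc.heritability if vc is not None else 0.5
        report = predict_mod.crossvalidate(
            across,
            state["kernels"],
            groups,
            h2,
            folds=pc["folds"],
            n_repeats=pc["repeats"],
            seed=seed,
            models=tuple(pc["models"]),
        )
        files = {"cv": out / "cv.json"}
        Path(files["cv"]).write_text(
            json.dumps(
                {
                    "summary": report.summary().to_dict(orient="records"),
                    "results": report.results.to_dict(orient="records"),
                    "seed": seed,
                },
                indent=1,
            )
        )
        record("predict", files, t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
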