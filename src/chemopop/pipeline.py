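"""End-to-end pipeline orchestration.

A single YAML config drives the fixed stage order

    simulate? -> features -> diversity -> popgen -> structure
             -> gwa (per covariate config) -> network -> biomarkers

Each stage writes its outputs plus a JSON manifest recording the stage
parameters, SHA-256 hashes of its input files, the seed, and the package
version.  A stage is skipped on re-run when its manifest matches the
current parameters and input hashes and all outputs still exist, so
corrupting or changing an intermediate re-executes exactly the downstream
stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import chemodiversity as cdiv
from . import ggm_network, health_biomarkers, lcms_features, mixed_model_gwa, popgen
from . import multivariate_structure as mvs
from . import synthetic_data

logger = logging.getLogger("chemopop.pipeline")

STAGE_ORDER = [
    "simulate", "features", "diversity", "popgen", "structure",
    "gwa", "network", "biomarkers",
]

DEFAULTS = {
    "seed": 0,
    "output_dir": "chemopop_out",
    "simulate": {},
    "features": {"rt_tol": 5.0, "cor_min": 0.75, "dmodx_components": 3,
                 "dmodx_alpha": 0.05, "dmodx_min_detection": 0.95,
                 "drop_outliers": True, "log_offset": 1.0},
    "diversity": {"detection_threshold": 0.0},
    "popgen": {"maf_min": 0.05, "call_rate_min": 0.80, "hwe_alpha": 0.05},
    "structure": {"n_perm": 999, "n_boot": 100, "anosim_perm": 499},
    "gwa": {"configs": ["none", "tcol", "bio14", "both"], "alpha": 0.05},
    "network": {"q_max": 0.05},
    "biomarkers": {"n_trees": 500, "top_k": 12},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULTS))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Manifest-backed stage wrapper providing skip-on-hash-match."""

    def __init__(self, name: str, outdir: Path, params: dict, inputs: list, seed: int):
        self.name = name
        self.dir = outdir / name
        self.params = params
        self.inputs = [Path(p) for p in inputs]
        self.seed = seed
        self.manifest_path = self.dir / "manifest.json"

    def up_to_date(self) -> bool:
        if not self.manifest_path.exists():
            return False
        try:
            manifest = json.loads(self.manifest_path.read_text())
        except json.JSONDecodeError:
            return False
        if manifest.get("params") != self.params or manifest.get("seed") != self.seed:
            return False
        if manifest.get("input_hashes") != {str(p): _sha256(p) for p in self.inputs}:
            return False
        return all((self.dir / f).exists() for f in manifest.get("outputs", []))

    def finish(self, outputs: list) -> None:
        manifest = {
            "stage": self.name,
            "params": self.params,
            "seed": self.seed,
            "input_hashes": {str(p): _sha256(p) for p in self.inputs},
            "outputs": outputs,
            "version": __version__,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.manifest_path.write_text(json.dumps(manifest, indent=1))


def run_pipeline(config: dict, stages: list | None = None) -> dict:
    """Execute the pipeline; returns a manifest of produced outputs per stage.

    ``stages`` restricts execution (dependencies must already have outputs).
    """
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    run = dict.fromkeys(STAGE_ORDER)
    want = stages or STAGE_ORDER

    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s [%(name)s] %(message)s"))
    logging.getLogger("chemopop").addHandler(handler)
    try:
        return _run(config, outdir, seed, want, run)
    except Exception as exc:
        logger.error("stage failure: %s (see %s)", exc, outdir / "pipeline.log")
        raise
    finally:
        logging.getLogger("chemopop").removeHandler(handler)


def _run(config, outdir, seed, want, run):
    simulate_mode = "inputs" not in config

    # ------------------------------------------------------------- simulate
    if simulate_mode:
        params = dict(config.get("simulate") or {})
        st = _Stage("simulate", outdir, params, [], seed)
        if "simulate" in want and not st.up_to_date():
            st.dir.mkdir(parents=True, exist_ok=True)
            logger.info("[simulate] generating synthetic cohort")
            cc = synthetic_data.CohortConfig(seed=seed, **params)
            cohort = synthetic_data.simulate_cohort(cc)
            synthetic_data.write_cohort(cohort, st.dir)
            st.finish(["feature_table.tsv", "genotypes.tsv", "metadata.tsv", "truth.json"])
        inputs = {
            "features": st.dir / "feature_table.tsv",
            "genotypes": st.dir / "genotypes.tsv",
            "metadata": st.dir / "metadata.tsv",
        }
        run["simulate"] = {"dir": str(st.dir)}
    else:
        inputs = {k: Path(v) for k, v in config["inputs"].items()}

    def finished_after(stage):
        later = STAGE_ORDER[STAGE_ORDER.index(stage) + 1:]
        return not (set(want) & set(later))

    if finished_after("simulate"):
        return {k: v for k, v in run.items() if v is not None}

    metadata = pd.read_csv(inputs["metadata"], sep="\t", index_col=0)
    grouping = metadata["subpopulation"]

    # ------------------------------------------------------------- features
    p = config["features"]
    st = _Stage("features", outdir, p, [inputs["features"]], seed)
    if "features" in want and not st.up_to_date():
        st.dir.mkdir(parents=True, exist_ok=True)
        table = lcms_features.read_feature_table(inputs["features"])
        mets = lcms_features.group_features(table, rt_tol=p["rt_tol"], cor_min=p["cor_min"])
        # Outlier screen on the collapsed metabolite matrix: redundant peaks
        # of one metabolite repeat the same residual, overcounting the
        # distance-to-model degrees of freedom ~redundancy-fold on the raw
        # feature table.  Log scale, below-detection cells masked out, and
        # a Bonferroni-level alpha across samples for the drop decision.
        x = mets.abundance.to_numpy().copy()
        detected = x > 0
        for i in range(x.shape[0]):
            row = x[i]
            if (row > 0).any():
                row[row == 0] = 0.5 * row[row > 0].min()
        n_m = x.shape[0]
        screen_table = lcms_features.FeatureTable(
            list(mets.abundance.index), np.linspace(100, 1500, n_m),
            np.linspace(60, 1200, n_m), np.log(x) - np.log(x).min() + 1.0,
            list(mets.abundance.columns))
        outliers = lcms_features.dmodx_outliers(
            screen_table, n_components=p["dmodx_components"],
            alpha=p["dmodx_alpha"] / table.n_samples, observed=detected)
        logger.info("[features] DModX flagged %d outlier samples", len(outliers))
        if p["drop_outliers"] and outliers:
            table = table.drop_samples(outliers)
            mets = lcms_features.group_features(table, rt_tol=p["rt_tol"],
                                                cor_min=p["cor_min"])
        lcms_features.log_transform(mets, offset=p["log_offset"])
        mets.write(st.dir / "abundance.tsv", st.dir / "groups.json")
        mets.log_abundance.to_csv(st.dir / "log_abundance.tsv", sep="\t")
        # correlation-based stages use the detection-limit-imputed log matrix
        lcms_features.impute_undetected(mets).to_csv(
            st.dir / "log_abundance_imputed.tsv", sep="\t")
        (st.dir / "outliers.json").write_text(json.dumps(outliers))
        logger.info("[features] %d features -> %d metabolite groups",
                    table.n_features, len(mets.group_ids))
        st.finish(["abundance.tsv", "groups.json", "log_abundance.tsv",
                   "log_abundance_imputed.tsv", "outliers.json"])
    fdir = st.dir
    run["features"] = {"dir": str(fdir)}
    if finished_after("features"):
        return {k: v for k, v in run.items() if v is not None}

    abundance = pd.read_csv(fdir / "abundance.tsv", sep="\t", index_col=0)
    log_abundance = pd.read_csv(fdir / "log_abundance_imputed.tsv", sep="\t",
                                index_col=0)
    samples = [s for s in abundance.columns if s in metadata.index]

    # ------------------------------------------------------------- diversity
    p = config["diversity"]
    st = _Stage("diversity", outdir, p, [fdir / "abundance.tsv"], seed)
    if "diversity" in want and not st.up_to_date():
        st.dir.mkdir(parents=True, exist_ok=True)
        profiles = cdiv.diversity_table(abundance, p["detection_threshold"])
        profiles.to_csv(st.dir / "profiles.tsv", sep="\t")
        ag = cdiv.alpha_gamma_richness(abundance[samples], grouping.loc[samples],
                                       p["detection_threshold"])
        ag.to_csv(st.dir / "alpha_gamma.tsv", sep="\t")
        logger.info("[diversity] wrote per-sample profiles for %d samples", len(profiles))
        st.finish(["profiles.tsv", "alpha_gamma.tsv"])
    run["diversity"] = {"dir": str(st.dir)}
    ddir = st.dir
    if finished_after("diversity"):
        return {k: v for k, v in run.items() if v is not None}

    # ------------------------------------------------------------- popgen
    p = config["popgen"]
    st = _Stage("popgen", outdir, p, [inputs["genotypes"]], seed)
    if "popgen" in want and not st.up_to_date():
        st.dir.mkdir(parents=True, exist_ok=True)
        g = popgen.read_dosage_tsv(inputs["genotypes"])
        g_f, report = popgen.filter_snps(
            g, grouping, maf_min=p["maf_min"], call_rate_min=p["call_rate_min"],
            hwe_alpha=p["hwe_alpha"])
        report.to_csv(st.dir / "filter_report.tsv", sep="\t")
        neutral, assoc = popgen.select_one_snp_per_tag(g_f)
        neutral.to_tsv(st.dir / "neutral_panel.tsv")
        assoc.to_tsv(st.dir / "association_panel.tsv")
        popgen.ibs_matrix(neutral).to_csv(st.dir / "kinship.tsv", sep="\t")
        het = popgen.heterozygosity(neutral, grouping, seed=seed)
        het.join(popgen.nucleotide_diversity(neutral, grouping)).join(
            popgen.rarefied_allelic_richness(neutral, grouping)
        ).to_csv(st.dir / "diversity_stats.tsv", sep="\t")
        popgen.inbreeding_f(neutral).to_csv(st.dir / "inbreeding.tsv", sep="\t")
        popgen.pairwise_fst(neutral, grouping).to_csv(st.dir / "fst_linearized.tsv", sep="\t")
        logger.info("[popgen] %d SNPs kept; panels: %d neutral / %d association",
                    g_f.n_snps, neutral.n_snps, assoc.n_snps)
        st.finish(["filter_report.tsv", "neutral_panel.tsv", "association_panel.tsv",
                   "kinship.tsv", "diversity_stats.tsv", "inbreeding.tsv",
                   "fst_linearized.tsv"])
    pdir = st.dir
    run["popgen"] = {"dir": str(pdir)}
    if finished_after("popgen"):
        return {k: v for k, v in run.items() if v is not None}

    # ------------------------------------------------------------- structure
    p = config["structure"]
    st = _Stage("structure", outdir, p,
                [pdir / "neutral_panel.tsv", fdir / "log_abundance_imputed.tsv"], seed)
    if "structure" in want and not st.up_to_date():
        st.dir.mkdir(parents=True, exist_ok=True)
        neutral = popgen.read_dosage_tsv(pdir / "neutral_panel.tsv")
        mats = mvs.subpop_distance_matrices(
            metadata.loc[samples], log_abundance[samples], neutral,
            grouping.loc[samples], n_perm_anosim=p["anosim_perm"], seed=seed)
        for name, mat in mats.items():
            mat.to_csv(st.dir / f"dist_{name}.tsv", sep="\t")
        tests = [
            ("metabolic", "geographic", None), ("genetic", "geographic", None),
            ("metabolic", "genetic", None), ("metabolic", "tcol", None),
            ("metabolic", "bio14", None), ("metabolic", "genetic", "geographic"),
            ("metabolic", "genetic", "tcol"), ("metabolic", "genetic", "bio14"),
        ]
        rows = []
        for a, b, c in tests:
            r, pv, ci = mvs.mantel(mats[a], mats[b], n_perm=p["n_perm"],
                                   n_boot=p["n_boot"],
                                   conditioning=mats[c] if c else None, seed=seed)
            rows.append({"a": a, "b": b, "conditioning": c or "", "r": r, "p": pv,
                         "ci_low": ci[0], "ci_high": ci[1]})
        pd.DataFrame(rows).to_csv(st.dir / "mantel.tsv", sep="\t", index=False)
        dos = pd.DataFrame(neutral.dosage, index=neutral.sample_ids,
                           columns=neutral.snp_ids).fillna(0.0)
        dapc_gen = mvs.dapc(dos.loc[samples], groups=grouping.loc[samples], seed=seed)
        dapc_met = mvs.dapc(log_abundance[samples].T, groups=grouping.loc[samples],
                            seed=seed)
        dapc_gen.coordinates.to_csv(st.dir / "dapc_genetic_coords.tsv", sep="\t")
        dapc_met.coordinates.to_csv(st.dir / "dapc_metabolic_coords.tsv", sep="\t")
        logger.info("[structure] Mantel and DAPC complete")
        st.finish(["mantel.tsv", "dapc_genetic_coords.tsv", "dapc_metabolic_coords.tsv"]
                  + [f"dist_{n}.tsv" for n in mats])
    sdir = st.dir
    run["structure"] = {"dir": str(sdir)}
    if finished_after("structure"):
        return {k: v for k, v in run.items() if v is not None}

    # ------------------------------------------------------------- gwa
    p = config["gwa"]
    st = _Stage("gwa", outdir, p,
                [pdir / "association_panel.tsv", pdir / "kinship.tsv",
                 fdir / "log_abundance_imputed.tsv"], seed)
    if "gwa" in want and not st.up_to_date():
        st.dir.mkdir(parents=True, exist_ok=True)
        assoc_panel = popgen.read_dosage_tsv(pdir / "association_panel.tsv")
        kinship = pd.read_csv(pdir / "kinship.tsv", sep="\t", index_col=0)
        profiles = pd.read_csv(ddir / "profiles.tsv", sep="\t", index_col=0)
        traits = log_abundance[samples].T
        traits["richness"] = profiles.loc[samples, "S"].astype(float)
        results = {}
        for cfg_name in p["configs"]:
            results[cfg_name] = mixed_model_gwa.gwa_scan(
                traits, assoc_panel, kinship, covariates=metadata.loc[samples],
                config=cfg_name, alpha=p["alpha"])
            results[cfg_name].table.to_csv(
                st.dir / f"associations_{cfg_name}.tsv", sep="\t", index=False)
            results[cfg_name].qq.to_csv(st.dir / f"qq_{cfg_name}.tsv", sep="\t")
        overlap = mixed_model_gwa.overlap_summary(results)
        (st.dir / "overlap.json").write_text(json.dumps(overlap, indent=1))
        logger.info("[gwa] %d configs scanned; union significant features: %d",
                    len(results), overlap["features"]["union"])
        st.finish([f"associations_{c}.tsv" for c in p["configs"]]
                  + [f"qq_{c}.tsv" for c in p["configs"]] + ["overlap.json"])
    gdir = st.dir
    run["gwa"] = {"dir": str(gdir)}
    if finished_after("gwa"):
        return {k: v for k, v in run.items() if v is not None}

    # ------------------------------------------------------------- network
    p = config["network"]
    st = _Stage("network", outdir, p, [fdir / "log_abundance_imputed.tsv"], seed)
    if "network" in want and not st.up_to_date():
        st.dir.mkdir(parents=True, exist_ok=True)
        ggm = ggm_network.shrinkage_pcor(log_abundance[samples].T, q_max=p["q_max"])
        gwa_results = {}
        for cfg_name in config["gwa"]["configs"]:
            path = gdir / f"associations_{cfg_name}.tsv"
            if path.exists():
                table = pd.read_csv(path, sep="\t")
                gwa_results[cfg_name] = mixed_model_gwa.AssociationResult(
                    table, np.nan, pd.DataFrame(), {})
        net = ggm_network.integrate_network(ggm, gwa_results)
        ggm_network.write_network(net, st.dir / "network.graphml",
                                  st.dir / "ggm_edges.tsv", st.dir / "gwa_edges.tsv")
        logger.info("[network] %d nodes, %d edges (lambda=%.3f)",
                    net.number_of_nodes(), net.number_of_edges(), ggm.shrinkage_lambda)
        st.finish(["network.graphml", "ggm_edges.tsv", "gwa_edges.tsv"])
    ndir = st.dir
    run["network"] = {"dir": str(ndir)}
    if finished_after("network"):
        return {k: v for k, v in run.items() if v is not None}

    # ------------------------------------------------------------- biomarkers
    p = config["biomarkers"]
    st = _Stage("biomarkers", outdir, p,
                [fdir / "log_abundance_imputed.tsv", inputs["metadata"]], seed)
    if "biomarkers" in want and not st.up_to_date():
        st.dir.mkdir(parents=True, exist_ok=True)
        meta = metadata.loc[samples].copy()
        if "health_binary" not in meta.columns:
            meta["health_binary"] = meta["health_score"].map(
                health_biomarkers.recode_health)
        if "F" not in meta.columns:
            meta = meta.join(pd.read_csv(pdir / "inbreeding.tsv", sep="\t",
                                         index_col=0)["F"])
        ranking = health_biomarkers.rf_biomarkers(
            log_abundance[samples].T, meta["health_binary"],
            n_trees=p["n_trees"], seed=seed, top_k=p["top_k"])
        ranking.importance.to_csv(st.dir / "rf_ranking.tsv", sep="\t", index=False)
        fits = []
        for met in ranking.selected:
            try:
                fit = health_biomarkers.logistic_mixed(
                    meta["health_binary"], log_abundance.loc[met, samples],
                    meta[["F", "tcol"]], meta["subpopulation"], focal_name=met)
                row = fit.term(met)
                fits.append({"metabolite": met, "estimate": row["estimate"],
                             "se": row["se"], "z": row["z"], "p": row["p"],
                             "converged": fit.converged})
            except ValueError as exc:
                fits.append({"metabolite": met, "estimate": np.nan, "se": np.nan,
                             "z": np.nan, "p": np.nan, "converged": False,
                             "note": str(exc)})
        pd.DataFrame(fits).to_csv(st.dir / "logistic_fits.tsv", sep="\t", index=False)

        # chemodiversity of the GGM component around the top biomarker
        ggm_edges = pd.read_csv(ndir / "ggm_edges.tsv", sep="\t")
        import networkx as nx

        comp_graph = nx.from_pandas_edgelist(ggm_edges, "metabolite_a", "metabolite_b")
        top = ranking.selected[0]
        subset = (sorted(nx.node_connected_component(comp_graph, top))
                  if comp_graph.has_node(top) else ranking.selected[:3])
        if len(subset) >= 2:
            models = health_biomarkers.subset_chemodiv_models(
                abundance[samples], subset, meta)
            rows = []
            for idx, fit in models.items():
                if isinstance(fit, str):
                    rows.append({"index": idx, "note": fit})
                else:
                    r = fit.term(idx)
                    rows.append({"index": idx, "estimate": r["estimate"], "se": r["se"],
                                 "z": r["z"], "p": r["p"], "converged": fit.converged})
            pd.DataFrame(rows).to_csv(st.dir / "subset_chemodiv.tsv", sep="\t",
                                      index=False)
        (st.dir / "subset.json").write_text(json.dumps(list(subset)))
        logger.info("[biomarkers] top biomarker %s; subset size %d", top, len(subset))
        st.finish(["rf_ranking.tsv", "logistic_fits.tsv", "subset.json"])
    run["biomarkers"] = {"dir": str(st.dir)}
    return {k: v for k, v in run.items() if v is not None}
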