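"""End-to-end runner: simulate -> QC -> LOGO PRS -> external scoring ->
clustering -> centroid assignment -> group statistics.

Every stage writes plain-text artifacts (TSV/JSON) whose headers record the
package version, the seed, and a hash of the run configuration, and can be
re-run from the intermediates of an earlier invocation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import GenotypeMatrix, read_genotypes
from .simulate import SimConfig, simulate_reference_panel, simulate_phenotypes, simulate_asthma_cohort
from .qc import QcConfig, apply_qc
from .logo import IgePrsLogo
from .cluster import TwoStepCluster
from . import centroid as centroid_mod
from . import stats as stats_mod

logger = logging.getLogger(__name__)

CLUSTER_FEATURES = ["ige_prs_z", "log_ige", "onset_age", "pfev1"]


@dataclass
class RunConfig:
    out_dir: str = "igeprs_run"
    genotypes_controls: str | None = None  # None -> simulate
    genotypes_cases: str | None = None
    cohort_table: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    logo_k: int = 5
    n_pcs: int = 5
    cluster_k_max: int = 15
    seed: int = 0
    run_qc: bool = True
    run_logo: bool = True
    run_cluster: bool = True
    run_centroid: bool = True
    run_stats: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        qc = QcConfig(**raw.pop("qc", {}))
        return cls(sim=sim, qc=qc, **raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # hash the scientific configuration, not paths
        d["sim"]["cluster_spec"] = [list(c.values()) for c in d["sim"]["cluster_spec"]]
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _header(config: RunConfig) -> list:
    return [
        f"igeprs {__version__}",
        f"seed {config.seed}",
        f"config {config.config_hash()}",
    ]


def write_tsv(df: pd.DataFrame, path, config: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of artifact paths and
    key in-memory results. Raises :class:`StageError` naming the failing
    stage; outputs written before the failure are left in place."""
    os.makedirs(config.out_dir, exist_ok=True)
    art: dict = {"out_dir": config.out_dir}

    # ------------------------------ inputs ---------------------------- #
    if config.genotypes_controls is None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        g_ctrl, truth = simulate_reference_panel(sim)
        cohort_ctrl = simulate_phenotypes(g_ctrl, truth, sim)
        g_case, cohort_case = simulate_asthma_cohort(sim, truth)
        cohort = pd.concat([cohort_ctrl, cohort_case], ignore_index=True)
        g_ctrl.write_dosage_tsv(os.path.join(config.out_dir, "controls.dosage.tsv"))
        g_case.write_dosage_tsv(os.path.join(config.out_dir, "cases.dosage.tsv"))
        write_tsv(cohort, os.path.join(config.out_dir, "cohort.tsv"), config)
        truth.to_json(os.path.join(config.out_dir, "truth.json"))
        art["truth"] = truth
    else:
        g_ctrl = read_genotypes(config.genotypes_controls)
        g_case = read_genotypes(config.genotypes_cases) if config.genotypes_cases else None
        if config.cohort_table is None:
            raise StageError("inputs", "cohort_table is required with external genotypes")
        cohort = pd.read_csv(config.cohort_table, sep="\t", comment="#")
    art["cohort"] = cohort

    # -------------------------------- QC ------------------------------ #
    if config.run_qc:
        try:
            g_ctrl, reports = apply_qc(g_ctrl, config.qc)
            summary = {
                name: rep.excluded.groupby("reason").size().to_dict()
                for name, rep in reports.items()
            }
            with open(os.path.join(config.out_dir, "qc_controls.json"), "w") as fh:
                json.dump(summary, fh, indent=1)
            for name, rep in reports.items():
                rep.to_tsv(os.path.join(config.out_dir, f"qc_controls_{name}.tsv"))
            if g_case is not None:
                from .qc import relatedness_qc

                rrep = relatedness_qc(g_case, config.qc)
                g_case = g_case.take_samples(rrep.kept)
                g_case = g_case.take_snps(
                    np.isin(g_case.snps["id"].to_numpy(), g_ctrl.snps["id"].to_numpy())
                )
                rrep.to_tsv(os.path.join(config.out_dir, "qc_cases_relatedness.tsv"))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("qc", str(exc)) from exc
    art["genotypes_controls"], art["genotypes_cases"] = g_ctrl, g_case

    # ------------------------------- LOGO ----------------------------- #
    results = None
    if config.run_logo:
        try:
            ctrl_cohort = cohort[cohort["asthma"] == 0]
            model = IgePrsLogo(
                g_ctrl, ctrl_cohort, k=config.logo_k, n_pcs=config.n_pcs
            )
            results = model.fit(seed=config.seed)
            write_tsv(results.scores.reset_index(),
                      os.path.join(config.out_dir, "logo_scores.tsv"), config)
            bundle = {
                "seed": config.seed,
                "fold_ses": results.fold_ses.tolist(),
                "zref": {"mu": results.zref.mu, "sigma": results.zref.sigma},
                "thresholds": [m.p_threshold for m in results.fold_models],
                "models": [
                    {
                        "snps": m.snps,
                        "effect_alleles": m.effect_alleles,
                        "weights": np.asarray(m.weights).tolist(),
                        "p_threshold": m.p_threshold,
                        "fold": m.fold,
                    }
                    for m in results.fold_models
                ],
            }
            with open(os.path.join(config.out_dir, "logo_models.json"), "w") as fh:
                json.dump(bundle, fh)
            art["logo"] = results
        except StageError:
            raise
        except Exception as exc:
            raise StageError("logo", str(exc)) from exc

    # ------------------------ external case scores -------------------- #
    case_table = None
    if results is not None and g_case is not None:
        try:
            z_case = results.apply_to_external(g_case)
            case_table = cohort[cohort["asthma"] == 1].set_index("sample")
            case_table = case_table.loc[[s for s in z_case.index if s in case_table.index]]
            case_table["ige_prs_z"] = z_case.loc[case_table.index]
            write_tsv(case_table.reset_index(),
                      os.path.join(config.out_dir, "case_scores.tsv"), config)
            art["case_table"] = case_table
        except Exception as exc:
            raise StageError("score_external", str(exc)) from exc

    # ----------------------------- clustering ------------------------- #
    clus = None
    if config.run_cluster:
        if case_table is None:
            raise StageError("cluster", "LOGO scores for cases are required first")
        try:
            feats = case_table[CLUSTER_FEATURES]
            clus = TwoStepCluster(feats, k_max=config.cluster_k_max).fit(seed=config.seed)
            labels = clus.labels.rename("cluster").reset_index()
            write_tsv(labels, os.path.join(config.out_dir, "clusters.tsv"), config)
            with open(os.path.join(config.out_dir, "cluster_model.json"), "w") as fh:
                json.dump(
                    {
                        "k": clus.k,
                        "bic_trace": {str(k): v for k, v in clus.bic_trace.items()},
                        "silhouette": clus.silhouette,
                        "standardize_mean": clus.standardize_mean.tolist(),
                        "standardize_sd": clus.standardize_sd.tolist(),
                        "centroids": clus.centroids.to_numpy().tolist(),
                    },
                    fh, indent=1,
                )
            art["cluster"] = clus
        except StageError:
            raise
        except Exception as exc:
            raise StageError("cluster", str(exc)) from exc

    # ------------------------------ centroid -------------------------- #
    if config.run_centroid:
        if clus is None:
            raise StageError("centroid", "clustering results required; enable run_cluster")
        try:
            cmodel = centroid_mod.from_clustering(case_table[CLUSTER_FEATURES], clus)
            cmodel.to_json(os.path.join(config.out_dir, "centroid_model.json"))
            assign = centroid_mod.assign_nearest(cmodel, case_table[CLUSTER_FEATURES])
            write_tsv(assign.reset_index(),
                      os.path.join(config.out_dir, "assignments.tsv"), config)
            art["centroid"] = cmodel
            art["assignments"] = assign
        except StageError:
            raise
        except Exception as exc:
            raise StageError("centroid", str(exc)) from exc

    # -------------------------------- stats --------------------------- #
    if config.run_stats and clus is not None and results is not None:
        try:
            rows = []
            if clus.k < 2:
                write_tsv(
                    pd.DataFrame([("kruskal_wallis_prs_z_controls_vs_clusters",
                                   float("nan"), 0, float("nan"))],
                                 columns=["test", "statistic", "df", "p"]),
                    os.path.join(config.out_dir, "stats.tsv"), config,
                )
                return art
            groups = [results.z.to_numpy()] + [
                case_table.loc[clus.labels.index[clus.labels == c], "ige_prs_z"].to_numpy()
                for c in range(1, clus.k + 1)
            ]
            h, p = stats_mod.kruskal_wallis(groups)
            rows.append(("kruskal_wallis_prs_z_controls_vs_clusters", h, len(groups) - 1, p))
            dunn = stats_mod.dunn_bonferroni(groups)
            write_tsv(dunn.table, os.path.join(config.out_dir, "dunn_prs_z.tsv"), config)
            sex_tab = pd.crosstab(
                case_table.loc[clus.labels.index, "sex"], clus.labels
            ).to_numpy()
            stat, df, p2 = stats_mod.chi_square_independence(sex_tab)
            rows.append(("chi2_sex_by_cluster", stat, df, p2))
            write_tsv(
                pd.DataFrame(rows, columns=["test", "statistic", "df", "p"]),
                os.path.join(config.out_dir, "stats.tsv"), config,
            )
        except Exception as exc:
            raise StageError("stats", str(exc)) from exc

    return art
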