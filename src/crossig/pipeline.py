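"""End-to-end synthetic pipeline: simulate the knockdown experiment and
human cohorts, derive the signature, transfer it across species, call
signature status per tumor, and compute the downstream statistics
(survival, subtype concordance, shared signature, regulator activation).

This is the path behind ``crossig run-all`` and the package's own
integration checks; every stage is the public module API, nothing bespoke.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from . import bccp, cluster, concordance, preprocess, regnet, signature, survival
from .bccp import ASS_PRESENT
from .io import ExpressionMatrix, OrthologMap, RegulatorNetwork
from .signature import CONTROL, PERTURBED
from .simulate import CohortSimConfig, MouseSimConfig, simulate_cohort, simulate_mouse

logger = logging.getLogger("crossig")


def identity_ortholog_map(mouse_genes) -> OrthologMap:
    """Symbol-case ortholog correspondence (mouse 'Abc1' <-> human 'ABC1')."""
    return OrthologMap(pairs=tuple((g, g.upper()) for g in mouse_genes))


def run_pipeline(
    seed: int,
    mouse_config: MouseSimConfig | None = None,
    cohort_config: CohortSimConfig | None = None,
    n_cohorts: int = 2,
    fold: float = 1.5,
    p: float = 0.005,
    shared_fold: float = 1.2,
    shared_p: float = 0.01,
) -> dict:
    """Run the full synthetic analysis and return every stage's result.

    Cohort ``i`` uses seed ``seed*1000 + i`` (kept below 2**31 upstream).
    The shared-signature thresholds are intentionally laxer than the
    derivation thresholds: the per-cohort DE contrast (predicted classes on a
    cohort) has different power than the designed two-arm experiment.
    """
    ss = np.random.SeedSequence(seed)
    mouse_config = mouse_config or MouseSimConfig(seed=seed)
    mouse_config = replace(mouse_config, seed=seed)

    # --- mouse experiment and signature ------------------------------------
    mouse_m, mouse_labels, truth = simulate_mouse(mouse_config)
    sig = signature.derive_signature(mouse_m, mouse_labels, fold=fold, p=p)
    loocv_res = bccp.loocv(mouse_m, mouse_labels, fold=fold, p=p)

    results: dict = {
        "mouse": {"matrix": mouse_m, "labels": mouse_labels, "truth": truth},
        "signature": sig,
        "loocv": loocv_res,
        "cohorts": [],
    }
    if len(sig) == 0:
        logger.warning("empty signature; downstream stages skipped")
        return results

    omap = identity_ortholog_map(mouse_m.gene_ids)
    per_cohort_de = []
    net, universe = _truth_network(truth)
    results["regnet_network"] = net

    base_cc = cohort_config or CohortSimConfig()
    for i in range(n_cohorts):
        cc = replace(base_cc, seed=seed * 1000 + i)
        human_m, clinical, latent = simulate_cohort(cc, truth)

        mouse_h, human_h = preprocess.map_orthologs(mouse_m, human_m, omap)
        mouse_std = preprocess.standardize(mouse_h)
        human_std = preprocess.standardize(human_h)
        pooled = preprocess.pool([mouse_std, human_std])

        sig_human = [g.upper() for g in sig.genes if g.upper() in pooled.values.index]
        assign = cluster.hier_cluster(pooled, sig_human, mouse_labels, k=2)

        sig_h = signature.GeneSignature(
            entries=sig.entries.set_axis([g.upper() for g in sig.genes]),
            fold_threshold=sig.fold_threshold,
            p_threshold=sig.p_threshold,
        )
        model, genes_used = bccp.train(mouse_std, mouse_labels, sig_h)
        calls_df = bccp.predict(human_std, model, genes_used)
        calls = calls_df["label"]

        # survival of the call
        g01 = (calls.reindex(clinical.sample_ids) == ASS_PRESENT).astype(int)
        chi2, logrank_p = survival.logrank(
            clinical.data["os_months"].to_numpy(),
            clinical.data["os_event"].to_numpy(),
            g01.to_numpy(),
        )
        cox_df = clinical.data.copy()
        cox_df["call"] = g01
        cox_df["stage_num"] = cox_df["stage"].map({"I": 1, "II": 2, "III": 3, "IV": 4})
        cox = survival.cox_fit(cox_df, ["call", "stage_num", "tumor_size"])
        early = survival.subgroup_survival(
            clinical, calls, strata=["I", "II"], stage_col="stage"
        )

        # concordance with alternative subtype labels
        subtypes = clinical.data[["NCIP", "HS", "SNUR"]].copy()
        subtypes["RS"] = concordance.rs_dichotomize(clinical.data["RS_score"])
        conc = concordance.concordance_report(calls, subtypes)

        # per-cohort DE against the predicted classes (log2 scale)
        de_labels = calls.map(
            lambda lab: PERTURBED if lab == ASS_PRESENT else CONTROL
        )
        if de_labels.value_counts().min() >= 2:
            de = signature.derive_signature(
                human_m, de_labels, fold=shared_fold, p=shared_p
            )
            per_cohort_de.append(de.entries)

        accuracy = float(
            (g01.to_numpy() == latent.reindex(clinical.sample_ids).to_numpy()).mean()
        )
        results["cohorts"].append(
            {
                "clinical": clinical,
                "latent": latent,
                "cluster": assign,
                "calls": calls_df,
                "accuracy": accuracy,
                "logrank": {"chi2": chi2, "p": logrank_p},
                "cox": cox,
                "early_stage": early,
                "concordance": conc,
            }
        )

    if len(per_cohort_de) >= 2:
        results["shared_signature"] = signature.shared_signature(per_cohort_de)

    de_dirs = {
        g.upper(): (1 if d == "up_in_perturbed" else -1)
        for g, d in sig.entries["direction"].items()
    }
    results["regnet"] = regnet.score_regulators(net, de_dirs, universe)
    return results


def _truth_network(truth: pd.DataFrame, n_regulators: int = 4) -> tuple[RegulatorNetwork, int]:
    """A small signed network whose regulators target planted genes.

    Regulator REG_k takes every (n_regulators)-th planted gene with the
    planted direction as edge sign, so a perfect signature recovery yields
    z = sqrt(n) per regulator.
    """
    genes = [g.upper() for g in truth.index]
    dirs = truth["direction"].to_numpy()
    edges = []
    for k in range(n_regulators):
        for j in range(k, len(genes), n_regulators):
            edges.append((f"REG_{k}", genes[j], int(dirs[j])))
    return RegulatorNetwork(edges=tuple(edges)), max(20000, 2 * len(genes))
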