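"""Synthetic data with the statistical structure the pipeline assumes.

``simulate_mouse`` emulates a liver siRNA-knockdown experiment: two genetic
backgrounds, two siRNA arms plus a vehicle-control arm per background, iid
Gaussian log2 noise, an optional shared per-background offset, and a planted
differentially expressed gene set (half shifted up, half down in the
perturbed arms) whose identity and direction are returned as ground truth.

``simulate_cohort`` emulates a tumor cohort with a latent two-class structure
shifting signature-gene expression, exponential survival with a
class-dependent hazard, independent exponential censoring calibrated to a
requested censoring fraction, clinical covariates correlated with class, and
alternative subtype labels agreeing with the latent class with probability
rho.

All randomness flows from a single seed; per-stage substreams are derived
deterministically with numpy's SeedSequence spawning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix
from .signature import CONTROL, PERTURBED

logger = logging.getLogger("crossig")

BASELINE_MEAN = 8.0  # typical log2 intensity center
BASELINE_SD = 1.5  # spread of per-gene baseline levels


@dataclass
class MouseSimConfig:
    """Design of the simulated knockdown experiment.

    ``effect_size`` is the mean log2 shift on planted genes in units of the
    within-group noise SD; ``batch_sd`` is the SD of the per-background
    offset added to every gene of a background's samples.
    """

    n_genes: int = 5000
    n_de: int = 150
    n_per_arm: int = 6
    n_backgrounds: int = 2
    effect_size: float = 3.0
    noise_sd: float = 0.5
    batch_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if min(self.n_genes, self.n_de, self.n_per_arm, self.n_backgrounds) < 2:
            raise ValueError("all sizes must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class CohortSimConfig:
    """Design of a simulated human tumor cohort.

    ``prevalence`` is the latent signature-present fraction; ``class_shift``
    the per-gene log2 shift (in noise-SD units) applied with the planted
    direction in signature-present patients; ``hazard_ratio`` multiplies the
    baseline exponential hazard in that class; ``concordance`` is the
    probability an alternative subtype label agrees with the latent class.
    """

    n_patients: int = 300
    n_genes: int = 2000
    prevalence: float = 0.5
    overlap_fraction: float = 1.0
    class_shift: float = 2.0
    noise_sd: float = 0.5
    baseline_hazard: float = 0.02  # per month
    hazard_ratio: float = 2.0
    censoring_rate: float = 0.3
    concordance: float = 0.9
    stage_probs_present: tuple = (0.3, 0.3, 0.3, 0.1)
    stage_probs_absent: tuple = (0.5, 0.3, 0.15, 0.05)
    tumor_size_meanlog: float = 1.2
    tumor_size_sdlog: float = 0.4
    afp_high_prob: tuple = (0.5, 0.25)  # (present, absent)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0,1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0,1)")
        if not 0.5 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0.5,1]")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in (0,1]")


def simulate_mouse(
    config: MouseSimConfig,
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Simulate the two-arm knockdown experiment.

    Returns the log2 expression matrix, perturbed/control sample labels
    (with a ``background`` tag recoverable from sample names), and the
    planted truth table (gene, direction in {+1,-1}).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    g, b = config.n_genes, config.n_backgrounds
    genes = [f"mgene{i:05d}" for i in range(g)]

    samples, labels, backgrounds = [], [], []
    for k in range(b):
        for arm in (1, 2):  # two distinct siRNAs
            for r in range(config.n_per_arm):
                samples.append(f"bg{k}_siRNA{arm}_{r}")
                labels.append(PERTURBED)
                backgrounds.append(k)
        for r in range(config.n_per_arm):
            samples.append(f"bg{k}_ctrl_{r}")
            labels.append(CONTROL)
            backgrounds.append(k)
    n = len(samples)

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=g)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(g, n))
    offsets = rng.normal(0.0, config.batch_sd, size=b)
    values += offsets[np.asarray(backgrounds)][None, :]

    de_idx = rng.choice(g, size=config.n_de, replace=False)
    directions = np.ones(config.n_de, dtype=int)
    directions[config.n_de // 2 :] = -1
    shift = config.effect_size * config.noise_sd
    pert = np.asarray([lab == PERTURBED for lab in labels])
    for j, d in zip(de_idx, directions):
        values[j, pert] += d * shift

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        species="mouse",
        cohort="knockdown",
        collapsed=True,
    )
    label_series = pd.Series(labels, index=samples, name="class")
    truth = pd.DataFrame(
        {"direction": directions},
        index=pd.Index([genes[j] for j in de_idx], name="gene"),
    )
    logger.info("simulate_mouse: %d genes x %d samples, %d planted", g, n, config.n_de)
    return matrix, label_series, truth


def simulate_cohort(
    config: CohortSimConfig, signature_genes: pd.DataFrame | list
) -> tuple[ExpressionMatrix, ClinicalTable, pd.Series]:
    """Simulate a human cohort carrying the signature in a latent subclass.

    ``signature_genes`` is either a truth-style frame (index gene, column
    ``direction``) or a plain gene list (directions then alternate +1/-1).
    Mouse-style gene names are converted to human-style symbols by
    upper-casing, emulating ortholog symbol correspondence. Returns the log2
    matrix, the clinical table (survival, stage, size, AFP, subtype labels)
    and the latent truth.
    """
    if isinstance(signature_genes, pd.DataFrame):
        sig = signature_genes["direction"].astype(int)
    else:
        genes = list(signature_genes)
        if not genes:
            raise ValueError("signature_genes must be non-empty")
        sig = pd.Series(
            [1 if i % 2 == 0 else -1 for i in range(len(genes))], index=genes
        )
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_expr = np.random.default_rng(ss[0])
    rng_surv = np.random.default_rng(ss[1])
    rng_cov = np.random.default_rng(ss[2])
    rng_sub = np.random.default_rng(ss[3])

    n = config.n_patients
    patients = [f"pt{i:04d}" for i in range(n)]
    latent = rng_expr.binomial(1, config.prevalence, size=n)  # 1 = present

    n_keep = max(1, int(round(config.overlap_fraction * len(sig))))
    kept = sig.iloc[:n_keep]
    human_sig_genes = [g.upper() for g in kept.index]

    n_bg = max(config.n_genes - n_keep, 0)
    bg_genes = [f"HGENE{i:05d}" for i in range(n_bg)]
    all_genes = human_sig_genes + bg_genes

    baseline = rng_expr.normal(BASELINE_MEAN, BASELINE_SD, size=len(all_genes))
    values = baseline[:, None] + rng_expr.normal(
        0.0, config.noise_sd, size=(len(all_genes), n)
    )
    shift = config.class_shift * config.noise_sd
    dirs = kept.to_numpy()
    values[: n_keep, latent == 1] += (dirs * shift)[:, None]

    # survival: exponential with hazard lambda * HR^class, censoring
    # exponential per class calibrated so P(censored) equals the requested rate
    lam = config.baseline_hazard * config.hazard_ratio**latent
    t_event = rng_surv.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        c_rate = config.censoring_rate / (1.0 - config.censoring_rate) * lam
        t_cens = rng_surv.exponential(1.0 / c_rate)
        os_months = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_months = t_event
        os_event = np.ones(n, dtype=int)

    stage_levels = np.array(["I", "II", "III", "IV"])
    stages = np.where(
        latent == 1,
        rng_cov.choice(4, size=n, p=config.stage_probs_present),
        rng_cov.choice(4, size=n, p=config.stage_probs_absent),
    )
    tumor_size = rng_cov.lognormal(
        config.tumor_size_meanlog + 0.2 * latent, config.tumor_size_sdlog, size=n
    )
    afp = rng_cov.binomial(1, np.where(latent == 1, *config.afp_high_prob), size=n)

    agree = rng_sub.random(size=(n, 4)) < config.concordance
    eff = np.where(agree.T, latent, 1 - latent)  # 4 x n effective classes
    ncip = np.where(eff[0] == 1, "A", "B")
    hs = np.where(eff[1] == 1, "HS", "HC")
    snur = np.where(eff[2] == 1, "high", "low")
    rs_score = np.where(
        eff[3] == 1,
        rng_sub.uniform(50.0 + 1e-9, 100.0, size=n),
        rng_sub.uniform(0.0, 50.0, size=n),
    )

    clinical = ClinicalTable(
        data=pd.DataFrame(
            {
                "os_months": os_months,
                "os_event": os_event,
                "stage": stage_levels[stages],
                "tumor_size": tumor_size,
                "afp_high": afp,
                "NCIP": ncip,
                "HS": hs,
                "SNUR": snur,
                "RS_score": rs_score,
            },
            index=pd.Index(patients, name="sample_id"),
        )
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=all_genes, columns=patients),
        species="human",
        cohort="synthetic",
        collapsed=True,
    )
    truth = pd.Series(latent, index=patients, name="latent_class")
    logger.info(
        "simulate_cohort: %d genes x %d patients, prevalence %.2f",
        len(all_genes), n, latent.mean(),
    )
    return matrix, clinical, truth
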