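"""Synthetic breast-cancer-like cohort with known ground truth.

The generator inverts the mixing model the rest of the package estimates:
each bulk sample is built as ``b = p·t + (1−p)·s`` in linear intensity
space, where ``t`` is the malignant (TC) profile, ``s`` the admixed
tumour-adjacent (TAC) profile and ``p`` the RNA-signal purity.  Ground
truth (purities, compartment matrices, planted survival and mutation
effects) is returned alongside, so every downstream stage can be scored
against what was planted.

Construction, per cohort:

* a log-normal per-gene baseline emulating ~HT-12 log2 intensities;
* ``K`` latent cell-type archetypes (epithelial-, fibroblast-, immune- and
  adipose-like) whose convex mixtures form the adjacent-normal panel and
  the per-sample TAC profiles;
* per-subtype TC archetypes carrying receptor-gene patterns (basal-like
  low in *ESR1*/*PGR*/*ERBB2*, HER2-enriched high *ERBB2*, luminal high
  *ESR1*/*PGR*) plus subtype marker genes;
* designated unexpressed genes (a chrY set and extra autosomal genes) held
  at the array background just below the 6.5 log2 floor; the chrY rows
  touch the floor exactly so the threshold is recoverable from data;
* purities drawn from a scaled Beta on [0.06, 0.88];
* overall survival from an exponential proportional-hazards model whose
  log-hazard sums planted (βT, βA, βI) terms over dichotomized true
  compartment values, plus a broad TC "aggressiveness programme" factor;
  independent uniform censoring;
* a targeted driver-gene panel with Bernoulli mutations and planted
  cis/trans expression shifts applied in a single compartment.

All profiles are normalized to a common total intensity over the ordinary
genes, so the mixing weight ``p`` is exactly the RNA-signal fraction that
the deconvolution estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulatorConfig
from .datatypes import ClinicalTable, ExpressionMatrix, MutationMatrix, ValidationError

RECEPTOR_GENES = ("ESR1", "PGR", "ERBB2")
_DRIVER_NAMES = ("TP53", "PIK3CA", "GATA3", "CDH1", "MUC16", "AHNAK2", "CBFB")

LN2 = np.log(2.0)


@dataclass
class MutationEffect:
    driver: str
    target: str
    compartment: str  # "TC" or "TAC"
    log2_shift: float


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic cohort."""

    purity: pd.Series
    tc: ExpressionMatrix  # linear, pre-noise
    tac: ExpressionMatrix  # linear, pre-noise
    effects: pd.DataFrame  # gene, effect_class, beta_tc, beta_tac, beta_int (log2 HR)
    mutation_effects: list[MutationEffect]
    program_genes: list[str]
    program_activity: pd.Series
    unexpressed_genes: list[str]
    chry_genes: list[str]
    tac_perturbed_genes: list[str]
    subtype_markers: dict[str, list[str]]
    seed: int


@dataclass
class GenePlan:
    """Deterministic gene layout shared by panel and cohort generation."""

    gene_ids: list[str]
    chromosomes: dict[str, str]
    chry: list[str]
    unexpressed: list[str]  # chrY + extra autosomal background genes
    stromal_restricted: list[str]  # silent in carcinoma cells
    tumor_specific: list[str]  # silent in non-cancerous tissue
    receptor: list[str]
    markers: dict[str, list[str]]
    program: list[str]
    effects: pd.DataFrame
    tac_perturbed: list[str]
    drivers: list[str]
    baseline: np.ndarray  # linear-space per-gene baseline (ordinary genes)
    background: np.ndarray  # linear constants for unexpressed genes
    archetypes: np.ndarray  # genes × K, linear


def _build_gene_plan(config: SimulatorConfig, seed: int) -> GenePlan:
    rng = np.random.default_rng(seed)
    G = config.n_genes
    gene_ids: list[str] = []
    chromosomes: dict[str, str] = {}

    chry = [f"CHRY_{i:03d}" for i in range(config.n_chry_genes)]
    drivers = list(_DRIVER_NAMES[: config.n_driver_genes])
    drivers += [f"DRIVER_{i:03d}" for i in range(len(drivers), config.n_driver_genes)]
    named = list(RECEPTOR_GENES) + drivers
    n_generic = G - len(chry) - len(named)
    generic = [f"GENE_{i:05d}" for i in range(n_generic)]
    gene_ids = named + generic + chry
    for g in gene_ids:
        chromosomes[g] = "Y" if g.startswith("CHRY_") else "1"

    unexpressed_extra = generic[: config.n_unexpressed_extra]
    unexpressed = chry + unexpressed_extra
    pool = [g for g in generic[config.n_unexpressed_extra:]]

    def take(n: int) -> list[str]:
        taken, rest = pool[:n], pool[n:]
        pool[:] = rest
        return taken

    stromal_restricted = take(config.n_stromal_restricted)
    tumor_specific = take(config.n_tumor_specific)
    markers = {st: take(config.n_subtype_markers) for st in config.subtypes}
    effect_rows = []
    sizes = config.effect_sizes
    for cls, count in config.effect_counts.items():
        bT, bA, bI = getattr(sizes, cls)
        for g in take(count):
            effect_rows.append((g, cls, bT, bA, bI))
    effects = pd.DataFrame(
        effect_rows, columns=["gene", "effect_class", "beta_tc", "beta_tac", "beta_int"]
    )
    program = take(config.n_program_genes)
    tac_perturbed = take(config.n_tac_perturbed)

    is_unexpr = np.isin(gene_ids, unexpressed)
    baseline = np.where(
        is_unexpr,
        0.0,
        2.0 ** rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, G),
    )
    # array background: constants just under the floor; one chrY gene is
    # pinned exactly at the floor so the threshold is identifiable
    floor = config.floor_log2 if config.floor_log2 is not None else 6.5
    background = np.zeros(G)
    bg_log2 = rng.uniform(floor - 0.45, floor - 0.05, G)
    background[is_unexpr] = 2.0 ** bg_log2[is_unexpr]
    pin = gene_ids.index(chry[0])
    background[pin] = 2.0**floor

    K = config.n_archetypes
    arch = baseline[:, None] * 2.0 ** rng.normal(0.0, config.archetype_sd_log2, (G, K))
    arch[is_unexpr, :] = background[is_unexpr, None]
    # tumour-specific genes are (near) silent in every non-cancerous archetype
    ts_idx = np.isin(gene_ids, tumor_specific)
    arch[ts_idx, :] *= 2.0**-config.restricted_log2_drop
    return GenePlan(
        gene_ids=gene_ids,
        chromosomes=chromosomes,
        chry=chry,
        unexpressed=unexpressed,
        stromal_restricted=stromal_restricted,
        tumor_specific=tumor_specific,
        receptor=list(RECEPTOR_GENES),
        markers=markers,
        program=program,
        effects=effects,
        tac_perturbed=tac_perturbed,
        drivers=drivers,
        baseline=baseline,
        background=background,
        archetypes=arch,
    )


def _normalize_columns(values: np.ndarray, ordinary: np.ndarray, total: float) -> None:
    """Rescale ordinary-gene rows per column to a common total, in place.

    Unexpressed background rows stay untouched so their constants (and the
    floor they encode) survive normalization and convex mixing.
    """
    col_sums = values[ordinary, :].sum(axis=0)
    values[ordinary, :] *= total / col_sums


def _lognoise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv <= 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, shape))


def _clamp_unexpressed(values: np.ndarray, plan: GenePlan, config: SimulatorConfig) -> None:
    """Cap designated background rows at the linear floor, in place."""
    if config.floor_log2 is None:
        return
    cap = 2.0**config.floor_log2
    idx = np.isin(plan.gene_ids, plan.unexpressed)
    values[idx, :] = np.minimum(values[idx, :], cap)


def generate_normal_panel(
    config: SimulatorConfig, seed: int, plan: GenePlan | None = None
) -> ExpressionMatrix:
    """Adjacent-normal reference panel: convex archetype mixtures plus
    multiplicative log-normal noise, background genes capped at the floor."""
    config.validate()
    if plan is None:
        plan = _build_gene_plan(config, seed)
    rng = np.random.default_rng((seed, 1))
    R = config.n_normal_refs
    weights = rng.dirichlet(
        np.full(config.n_archetypes, config.panel_dirichlet_alpha), size=R
    ).T  # K × R
    values = plan.archetypes @ weights
    ordinary = ~np.isin(plan.gene_ids, plan.unexpressed)
    # panel donors carry the same per-gene biological variation as any other
    # normal tissue sample, plus measurement noise
    if config.tac_sd_log2 > 0:
        values[ordinary, :] *= 2.0 ** rng.normal(
            0.0, config.tac_sd_log2, (int(ordinary.sum()), R)
        )
    values *= _lognoise(rng, config.noise_cv, values.shape)
    _normalize_columns(values, ordinary, plan.baseline.sum())
    _clamp_unexpressed(values, plan, config)
    return ExpressionMatrix(
        values=values,
        space="linear",
        gene_ids=plan.gene_ids,
        sample_ids=[f"NORM_{i:03d}" for i in range(R)],
        gene_chromosomes=plan.chromosomes,
    )


def _tac_profiles(
    config: SimulatorConfig,
    plan: GenePlan,
    rng: np.random.Generator,
    n: int,
    perturb: bool,
) -> np.ndarray:
    """Per-sample TAC profiles: archetype mixtures with biological noise and,
    for tumour-adjacent tissue, a planted perturbation on designated genes."""
    weights = rng.dirichlet(
        np.full(config.n_archetypes, config.tac_dirichlet_alpha), size=n
    ).T
    s = plan.archetypes @ weights
    if config.tac_sd_log2 > 0:
        ordinary = ~np.isin(plan.gene_ids, plan.unexpressed)
        s[ordinary, :] *= 2.0 ** rng.normal(
            0.0, config.tac_sd_log2, (int(ordinary.sum()), n)
        )
    if perturb and config.tac_perturb_log2 != 0:
        idx = [plan.gene_ids.index(g) for g in plan.tac_perturbed]
        s[idx, :] *= 2.0**config.tac_perturb_log2
    ordinary = ~np.isin(plan.gene_ids, plan.unexpressed)
    _normalize_columns(s, ordinary, plan.baseline.sum())
    return s


def _tc_archetypes(config: SimulatorConfig, plan: GenePlan, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Subtype TC archetypes with receptor patterns and marker genes."""
    gene_pos = {g: i for i, g in enumerate(plan.gene_ids)}
    out: dict[str, np.ndarray] = {}
    for st in config.subtypes:
        t = plan.baseline * 2.0 ** rng.normal(0.0, config.archetype_sd_log2, len(plan.gene_ids))
        t[np.isin(plan.gene_ids, plan.unexpressed)] = plan.background[
            np.isin(plan.gene_ids, plan.unexpressed)
        ]
        t[np.isin(plan.gene_ids, plan.stromal_restricted)] *= (
            2.0**-config.restricted_log2_drop
        )
        esr1, pgr, erbb2 = (gene_pos[g] for g in RECEPTOR_GENES)
        base = plan.baseline
        if st == "Basal":
            t[[esr1, pgr, erbb2]] = base[[esr1, pgr, erbb2]] * 2.0**-3
        elif st == "Her2":
            t[erbb2] = base[erbb2] * 2.0**3
            t[[esr1, pgr]] = base[[esr1, pgr]] * 2.0**-2
        else:  # luminal subtypes: high hormone receptors
            t[[esr1, pgr]] = base[[esr1, pgr]] * 2.0**3
        for g in plan.markers[st]:
            t[gene_pos[g]] *= 2.0**config.subtype_marker_log2fc
        out[st] = t
    return out


def generate_cohort(
    config: SimulatorConfig,
    panel: ExpressionMatrix,
    seed: int,
    plan: GenePlan | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable, MutationMatrix, SyntheticTruth]:
    """Simulate bulk, clinical, mutation and truth tables for one cohort."""
    config.validate()
    if plan is None:
        plan = _build_gene_plan(config, seed)
    if panel.gene_ids != plan.gene_ids:
        raise ValidationError("panel genes do not match the cohort gene plan")
    rng = np.random.default_rng((seed, 2))
    G = len(plan.gene_ids)
    n = config.n_per_subtype * len(config.subtypes)
    sample_ids = [f"TUMOR_{i:04d}" for i in range(n)]
    subtype_labels = np.repeat(list(config.subtypes), config.n_per_subtype)
    gene_pos = {g: i for i, g in enumerate(plan.gene_ids)}
    ordinary = ~np.isin(plan.gene_ids, plan.unexpressed)
    total = plan.baseline.sum()

    lo, hi = config.purity_range
    a, b = config.purity_beta
    purity = lo + (hi - lo) * rng.beta(a, b, n)

    # --- TC compartment ---------------------------------------------------
    tc_arch = _tc_archetypes(config, plan, rng)
    t = np.column_stack([tc_arch[st] for st in subtype_labels])
    if config.tc_sd_log2 > 0:
        t[ordinary, :] = t[ordinary, :] * 2.0 ** rng.normal(
            0.0, config.tc_sd_log2, (int(ordinary.sum()), n)
        )
    program_activity = rng.normal(0.0, 1.0, n)
    prog_idx = [gene_pos[g] for g in plan.program]
    # signed loadings: an up-regulated and a down-regulated programme arm,
    # keeping the programme roughly mass-neutral as real signatures are
    loadings = config.program_sd_log2 * np.where(
        np.arange(len(prog_idx)) % 2 == 0, 1.0, -1.0
    )
    t[prog_idx, :] *= 2.0 ** np.outer(loadings, program_activity)

    # --- mutations --------------------------------------------------------
    prevalence = rng.uniform(*config.mutation_prevalence, len(plan.drivers))
    mut = (rng.random((len(plan.drivers), n)) < prevalence[:, None]).astype(np.int8)
    mutations = MutationMatrix(mut, list(plan.drivers), list(sample_ids))

    mutation_effects: list[MutationEffect] = []
    trans_pool = [g for g in plan.gene_ids
                  if g.startswith("GENE_") and g not in plan.unexpressed
                  and g not in set(plan.effects["gene"])]
    for i, driver in enumerate(plan.drivers[: config.n_cis_effects]):
        shift = config.mutation_shift_log2 * (1 if i % 2 == 0 else -1)
        mutation_effects.append(MutationEffect(driver, driver, "TC", shift))
    trans_targets = rng.choice(len(trans_pool), config.n_trans_effects, replace=False)
    for i, driver in enumerate(plan.drivers[: config.n_trans_effects]):
        mutation_effects.append(
            MutationEffect(driver, trans_pool[trans_targets[i]], "TAC",
                           config.mutation_shift_log2)
        )

    # --- TAC compartment --------------------------------------------------
    s = _tac_profiles(config, plan, rng, n, perturb=True)

    for eff in mutation_effects:
        carriers = mut[plan.drivers.index(eff.driver)] == 1
        target = gene_pos[eff.target]
        if eff.compartment == "TC":
            t[target, carriers] *= 2.0**eff.log2_shift
        else:
            s[target, carriers] *= 2.0**eff.log2_shift

    _normalize_columns(t, ordinary, total)
    _normalize_columns(s, ordinary, total)

    # --- mixing, noise, floor ----------------------------------------------
    bulk_values = purity[None, :] * t + (1.0 - purity[None, :]) * s
    bulk_values = bulk_values * _lognoise(rng, config.noise_cv, bulk_values.shape)
    _clamp_unexpressed(bulk_values, plan, config)
    bulk = ExpressionMatrix(
        bulk_values, "linear", list(plan.gene_ids), sample_ids, plan.chromosomes
    )

    # --- survival ----------------------------------------------------------
    eta = config.program_log_hazard * program_activity
    for _, row in plan.effects.iterrows():
        gi = gene_pos[row["gene"]]
        hi_t = (t[gi] > np.median(t[gi])).astype(float)
        hi_s = (s[gi] > np.median(s[gi])).astype(float)
        eta = eta + LN2 * (
            row["beta_tc"] * hi_t
            + row["beta_tac"] * hi_s
            + row["beta_int"] * hi_t * hi_s
        )
    eta = eta - eta.mean()
    event_time = rng.exponential(1.0 / (config.baseline_hazard_per_day * np.exp(eta)))
    censor_time = rng.uniform(0.0, config.followup_max_days, n)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    cellularity = np.select(
        [purity < 0.4, purity <= 0.7], ["low_moderate", "moderate"], "high"
    )
    # pathologist categories disagree with molecular purity for a minority
    flip = rng.random(n) < 0.1
    shuffled = rng.permutation(np.asarray(cellularity))
    cellularity = np.where(flip, shuffled, cellularity)

    er = np.where(np.isin(subtype_labels, ["LumA", "LumB"]), "pos", "neg")
    pr = er.copy()
    her2 = np.where(subtype_labels == "Her2", "pos", "neg")
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "subtype": subtype_labels,
                "cellularity": cellularity,
                "er_status": er,
                "pr_status": pr,
                "her2_status": her2,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    truth = SyntheticTruth(
        purity=pd.Series(purity, index=sample_ids, name="purity"),
        tc=ExpressionMatrix(t, "linear", list(plan.gene_ids), sample_ids, plan.chromosomes),
        tac=ExpressionMatrix(s, "linear", list(plan.gene_ids), sample_ids, plan.chromosomes),
        effects=plan.effects.copy(),
        mutation_effects=mutation_effects,
        program_genes=list(plan.program),
        program_activity=pd.Series(program_activity, index=sample_ids),
        unexpressed_genes=list(plan.unexpressed),
        chry_genes=list(plan.chry),
        tac_perturbed_genes=list(plan.tac_perturbed),
        subtype_markers={k: list(v) for k, v in plan.markers.items()},
        seed=seed,
    )
    return bulk, clinical, mutations, truth


def generate_negative_controls(
    config: SimulatorConfig,
    panel: ExpressionMatrix,
    n: int = 75,
    seed: int = 0,
    plan: GenePlan | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Pure-normal samples (true purity 0) built by the TAC generator."""
    if n < 1:
        raise ValidationError("need at least one negative-control sample")
    if plan is None:
        plan = _build_gene_plan(config, seed)
    rng = np.random.default_rng((seed, 3))
    s = _tac_profiles(config, plan, rng, n, perturb=False)
    s = s * _lognoise(rng, config.noise_cv, s.shape)
    _clamp_unexpressed(s, plan, config)
    ids = [f"NEGCTRL_{i:03d}" for i in range(n)]
    matrix = ExpressionMatrix(s, "linear", list(plan.gene_ids), ids, plan.chromosomes)
    return matrix, pd.Series(np.zeros(n), index=ids, name="purity")


# ---------------------------------------------------------------------------
# per-gene survival panels: replicated single-gene cohorts used to measure
# screen sensitivity / calibration and interaction-class recovery
# ---------------------------------------------------------------------------


@dataclass
class GeneSurvivalRecord:
    gene: str
    effect_class: str
    tc: np.ndarray  # continuous log2-like values
    tac: np.ndarray
    os_time: np.ndarray
    os_event: np.ndarray
    betas: tuple[float, float, float] = (0.0, 0.0, 0.0)


def simulate_gene_survival_panel(
    class_counts: dict[str, int],
    n_samples: int,
    effect_sizes,
    seed: int,
    baseline_hazard: float = 3.5e-4,
    followup_max: float = 3652.5,
) -> list[GeneSurvivalRecord]:
    """One independent cohort per gene, with survival generated from that
    gene's dichotomized TC/TAC values under planted log2 hazard ratios.

    This is the harness for power and classification-recovery experiments:
    effects do not interfere across genes, so per-gene recovery measures the
    modelling pipeline rather than omitted-covariate attenuation.
    ``effect_class`` "none" plants a global null (βT = βA = βI = 0).
    """
    rng = np.random.default_rng(seed)
    records: list[GeneSurvivalRecord] = []
    idx = 0
    for cls, count in class_counts.items():
        if cls == "none":
            betas = (0.0, 0.0, 0.0)
        else:
            betas = tuple(getattr(effect_sizes, cls))
        for _ in range(count):
            tc = rng.normal(8.0, 1.0, n_samples)
            tac = rng.normal(8.0, 1.0, n_samples)
            hi_t = (tc > np.median(tc)).astype(float)
            hi_s = (tac > np.median(tac)).astype(float)
            eta = LN2 * (betas[0] * hi_t + betas[1] * hi_s + betas[2] * hi_t * hi_s)
            eta = eta - eta.mean()
            t_ev = rng.exponential(1.0 / (baseline_hazard * np.exp(eta)))
            c = rng.uniform(0.0, followup_max, n_samples)
            records.append(
                GeneSurvivalRecord(
                    gene=f"SIM_{idx:04d}",
                    effect_class=cls,
                    tc=tc,
                    tac=tac,
                    os_time=np.minimum(t_ev, c),
                    os_event=(t_ev <= c).astype(int),
                    betas=betas,
                )
            )
            idx += 1
    return records
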