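"""Run configuration: seeds, thresholds, deconvolution hyper-parameters and
simulator settings, with lossless YAML round-tripping.

All randomness in the package flows from the named seeds held here; nothing
touches global RNG state.  Defaults follow the study conventions: seed 374
for deconvolution step one, 719 for step two, 17 for consensus clustering;
q-value cutoff 0.05, effect-size cutoff |log2 HR| > 0.4, unexpressed
intensity 6.5 (log2), dichotomization power floor of 79 patients and a
minimum of 50 mutated patients per subtype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .datatypes import ValidationError


@dataclass
class Seeds:
    global_seed: int = 20
    deconvolution_step1: int = 374
    deconvolution_step2: int = 719
    consensus: int = 17
    signatures: int = 42

    def derive(self, offset: int) -> int:
        # keep derived seeds in 32-bit range for portability
        return (self.global_seed * 100003 + offset) % (2**31 - 1)


@dataclass
class Thresholds:
    q_max: float = 0.05
    interaction_q_max: float = 0.1
    min_abs_log2hr: float = 0.4
    unexpressed_override: float | None = None
    min_group_size: int = 79
    min_mutated: int = 50
    ph_p_min: float = 0.1

    def validate(self) -> None:
        for name in ("q_max", "interaction_q_max", "min_abs_log2hr"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be > 0")
        if self.min_group_size <= 0 or self.min_mutated <= 0:
            raise ValidationError("group-size cutoffs must be > 0")


@dataclass
class DeconvolutionParams:
    lam: float = 0.3  # ridge pull of per-sample TC profiles toward the reference
    max_iter: int = 60
    tol: float = 5e-4  # max purity change per iteration at convergence
    p_max: float = 0.999
    ridge_frac: float = 0.01  # purity-coefficient ridge, as fraction of ‖m‖²
    n_folds: int = 5  # cross-fitting folds for purity scoring

    def validate(self) -> None:
        if self.lam < 0:
            raise ValidationError("regularization weight λ must be ≥ 0")
        if not 0 < self.p_max < 1:
            raise ValidationError("p_max must lie in (0, 1)")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValidationError("max_iter ≥ 1 and tol > 0 required")
        if self.n_folds < 1:
            raise ValidationError("n_folds must be ≥ 1")


@dataclass
class EffectSizes:
    """Planted log2 hazard-ratio coefficients (βT, βA, βI) per effect class.

    Values are strong by design so that class recovery measures pipeline
    correctness rather than statistical power at the margin.
    """

    tc_only: tuple[float, float, float] = (1.4, 0.0, 0.0)
    tac_only: tuple[float, float, float] = (0.0, 1.4, 0.0)
    additive: tuple[float, float, float] = (1.2, 1.2, 0.0)
    saturation: tuple[float, float, float] = (2.4, 1.4, -1.4)
    antagonistic: tuple[float, float, float] = (1.5, 0.0, -1.5)
    synergistic: tuple[float, float, float] = (0.8, 0.6, 1.2)


@dataclass
class SimulatorConfig:
    """Conditions of the synthetic cohort (microarray-like log2 intensities).

    The cohort emulates a large breast-cancer study: ~HT-12-style
    intensities with an unexpressed floor at 6.5 (log2), an adjacent-normal
    reference panel, four intrinsic subtypes with receptor-gene patterns,
    tumour purities spanning 6–88%, overall survival with censoring and a
    targeted driver-gene mutation panel with cis/trans expression effects.
    """

    n_genes: int = 2000
    subtypes: tuple[str, ...] = ("Basal", "Her2", "LumA", "LumB")
    n_per_subtype: int = 150
    n_normal_refs: int = 60
    n_archetypes: int = 4  # epithelial-, fibroblast-, immune-, adipose-like
    purity_range: tuple[float, float] = (0.06, 0.88)
    purity_beta: tuple[float, float] = (2.0, 2.0)
    noise_cv: float = 0.1  # multiplicative measurement noise
    # panel donors spread toward the cell-type extremes so the panel spans
    # the non-cancerous diversity; tumour-adjacent admixtures are interior
    panel_dirichlet_alpha: float = 0.4
    tac_dirichlet_alpha: float = 1.0
    tc_sd_log2: float = 0.3  # per-sample biological variation of TC profiles
    tac_sd_log2: float = 0.3
    archetype_sd_log2: float = 0.8
    baseline_mean_log2: float = 9.0
    baseline_sd_log2: float = 1.6
    floor_log2: float | None = 6.5  # None disables the unexpressed floor
    n_chry_genes: int = 25
    n_unexpressed_extra: int = 75  # autosomal genes below the floor
    n_subtype_markers: int = 40  # per-subtype upregulated TC genes
    subtype_marker_log2fc: float = 2.0
    n_tac_perturbed: int = 50
    tac_perturb_log2: float = 1.0
    # compartment-restricted genes: stromal/immune/adipose genes silent in
    # carcinoma cells, and tumour-specific genes silent in normal tissue.
    # These anchor the purity scale, as they do in real tumours.
    n_stromal_restricted: int = 250
    n_tumor_specific: int = 100
    restricted_log2_drop: float = 7.0
    effect_counts: dict = field(
        default_factory=lambda: {
            "tc_only": 3, "tac_only": 3, "additive": 2,
            "saturation": 2, "antagonistic": 2, "synergistic": 2,
        }
    )
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    # latent TC aggressiveness program: broad transcriptional programme whose
    # activity drives hazard, making many TC genes weakly prognostic
    n_program_genes: int = 300
    program_sd_log2: float = 0.8
    program_log_hazard: float = 0.6  # natural-log hazard per SD of activity
    baseline_hazard_per_day: float = 3.5e-4
    followup_max_days: float = 3652.5  # uniform censoring horizon (10 years)
    n_driver_genes: int = 20
    mutation_prevalence: tuple[float, float] = (0.05, 0.30)
    n_cis_effects: int = 6
    n_trans_effects: int = 4
    mutation_shift_log2: float = 1.0

    def validate(self) -> None:
        lo, hi = self.purity_range
        if not (0 < lo < hi < 1):
            raise ValidationError("purity range must satisfy 0 < lo < hi < 1")
        if self.n_normal_refs < 2:
            raise ValidationError("need at least two normal reference samples")
        planted = (
            self.n_chry_genes + self.n_unexpressed_extra + self.n_tac_perturbed
            + self.n_subtype_markers * len(self.subtypes)
            + sum(self.effect_counts.values()) + self.n_program_genes
            + self.n_stromal_restricted + self.n_tumor_specific
        )
        if planted > self.n_genes:
            raise ValidationError(
                f"planted gene features ({planted}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class BiomarkerConfig:
    n_signatures: int = 20
    genes_per_signature: int = 50
    n_trees: int = 200
    cv_folds: int = 3
    train_fraction: float = 0.8


@dataclass
class RunConfig:
    seeds: Seeds = field(default_factory=Seeds)
    thresholds: Thresholds = field(default_factory=Thresholds)
    deconvolution: DeconvolutionParams = field(default_factory=DeconvolutionParams)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    biomarkers: BiomarkerConfig = field(default_factory=BiomarkerConfig)
    outdir: str = "tactome_out"
    simulate: bool = True  # generate the cohort rather than reading inputs
    bulk_path: str | None = None
    panel_path: str | None = None
    clinical_path: str | None = None
    mutations_path: str | None = None
    consensus_reps: int = 50
    consensus_k: int = 4

    def validate(self) -> None:
        self.thresholds.validate()
        self.deconvolution.validate()
        self.simulator.validate()
        if not self.simulate:
            for name in ("bulk_path", "panel_path", "clinical_path"):
                if getattr(self, name) is None:
                    raise ValidationError(
                        f"simulator disabled but {name} not provided"
                    )


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


_NESTED = {
    "seeds": Seeds,
    "thresholds": Thresholds,
    "deconvolution": DeconvolutionParams,
    "simulator": SimulatorConfig,
    "biomarkers": BiomarkerConfig,
}

_TUPLE_FIELDS = {
    "subtypes", "purity_range", "purity_beta", "mutation_prevalence",
    "tc_only", "tac_only", "additive", "saturation", "antagonistic",
    "synergistic",
}


def config_to_dict(config: RunConfig) -> dict:
    return _to_dict(config)


def config_from_dict(data: dict) -> RunConfig:
    def build(cls, payload):
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in payload:
                continue
            v = payload[f.name]
            if f.name in _NESTED and isinstance(v, dict):
                v = build(_NESTED[f.name], v)
            elif f.name == "effect_sizes" and isinstance(v, dict):
                v = EffectSizes(**{k: tuple(t) for k, t in v.items()})
            elif f.name in _TUPLE_FIELDS and isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)

    return build(RunConfig, data)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = config_from_dict(data)
    cfg.validate()
    return cfg


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))
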