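"""End-to-end pipeline: simulate → deconvolve → qc → survival →
interaction → subtypes → biomarkers → mutations.

Every stage writes its result tables as TSV into the configured output
directory; a JSON metadata file records seeds and parameters and a plain
log records stage progress.  With fixed seeds the result tables are
byte-identical across runs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import evaluate_signatures, make_labels, split_cohort, summarize_distributions
from .config import RunConfig, config_to_dict
from .datatypes import ClinicalTable, ExpressionMatrix, MutationMatrix, ValidationError
from .deconvolution import run_deconvolution_by_subtype, to_log2_with_floor
from .interaction import interaction_results_frame, interaction_screen, summarize_relationships
from .io import read_clinical, read_expression, read_mutations, write_clinical, write_expression, write_mutations
from .mutations import mutation_expression_screen
from .qc import compare_purity_estimates, flag_unexpressed, scale_genewise, select_variable_genes, unexpressed_threshold
from .simulate import GenePlan, _build_gene_plan, generate_cohort, generate_normal_panel
from .subtypes import classification_agreement, classify_nearest_centroid, consensus_cluster, subtype_de_genes, train_centroids
from .survival import intersecting_proportion, significant_genes, survival_screen


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        self.lines.append(msg)
        self.path.write_text("\n".join(self.lines) + "\n")


STAGES = (
    "simulate", "deconvolve", "qc", "survival", "interaction",
    "subtypes", "biomarkers", "mutations",
)


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run.log")
    t_start = time.time()
    state: dict = {}

    for stage in STAGES:
        if stage not in stages:
            continue
        fn = globals()[f"_stage_{stage}"]
        log.info(f"stage {stage}: start")
        try:
            fn(config, state, outdir, log)
        except Exception as exc:
            log.info(f"stage {stage}: FAILED ({exc})")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info(f"stage {stage}: done")

    meta = {
        "version": __version__,
        "config": config_to_dict(config),
        "stages": list(stages),
        "runtime_s": round(time.time() - t_start, 1),
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True, default=str) + "\n")
    return outdir


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise ValidationError(f"stage {stage} requires {key}; run earlier stages first")
    return state[key]


def _stage_simulate(config: RunConfig, state: dict, outdir: Path, log: _Log) -> None:
    if config.simulate:
        seed = config.seeds.derive(1)
        plan = _build_gene_plan(config.simulator, seed)
        panel = generate_normal_panel(config.simulator, seed, plan)
        bulk, clinical, mutations, truth = generate_cohort(config.simulator, panel, seed, plan)
        state.update(plan=plan, panel=panel, bulk=bulk, clinical=clinical,
                     mutations=mutations, truth=truth)
        write_expression(bulk, outdir / "bulk.tsv")
        write_expression(panel, outdir / "panel.tsv")
        write_clinical(clinical, outdir / "clinical.tsv")
        write_mutations(mutations, outdir / "mutations.tsv")
        truth.purity.to_frame().to_csv(outdir / "truth_purity.tsv", sep="\t")
        truth.effects.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
        log.info(f"simulated {bulk.n_genes} genes × {bulk.n_samples} samples, seed {seed}")
    else:
        for name, path in (
            ("bulk", config.bulk_path), ("panel", config.panel_path),
        ):
            if not Path(path).exists():
                raise ValidationError(f"{name} input {path} does not exist")
        state["bulk"] = read_expression(config.bulk_path, space_hint="linear")
        state["panel"] = read_expression(config.panel_path, space_hint="linear")
        state["clinical"] = read_clinical(config.clinical_path)
        if config.mutations_path:
            state["mutations"] = read_mutations(config.mutations_path)
        log.info("loaded user-provided inputs")


def _stage_deconvolve(config: RunConfig, state: dict, outdir: Path, log: _Log) -> None:
    bulk = _require(state, "bulk", "deconvolve")
    panel = _require(state, "panel", "deconvolve")
    clinical = _require(state, "clinical", "deconvolve")
    result = run_deconvolution_by_subtype(bulk, panel, clinical, config)
    state["deconvolution"] = result
    kept = list(result.purity.index)
    bulk_kept = bulk.subset_samples(kept)
    b_log, t_log, s_log, floor = to_log2_with_floor(bulk_kept, result.tc, result.tac)
    state.update(bulk_log2=b_log, tc_log2=t_log, tac_log2=s_log, log2_floor=floor)
    result.purity.to_frame().to_csv(outdir / "purity.tsv", sep="\t")
    write_expression(result.tc, outdir / "tc.tsv")
    write_expression(result.tac, outdir / "tac.tsv")
    result.reference.to_csv(outdir / "reference.tsv", sep="\t")
    conv = {
        st: {k: v for k, v in c.items() if k != "objectives"}
        for st, c in result.convergence.items()
    }
    (outdir / "convergence.json").write_text(json.dumps(conv, indent=1, sort_keys=True) + "\n")
    log.info(f"deconvolved {len(kept)} samples; median purity {result.purity.median():.3f}")


def _stage_qc(config: RunConfig, state: dict, outdir: Path, log: _Log) -> None:
    bulk_log = _require(state, "bulk_log2", "qc")
    clinical = _require(state, "clinical", "qc")
    thr = unexpressed_threshold(
        bulk_log, override=config.thresholds.unexpressed_override
    )
    state["threshold"] = thr
    flags = flag_unexpressed(bulk_log, thr)
    state["unexpressed"] = flags
    concordance = compare_purity_estimates(state["deconvolution"].purity, clinical)
    pd.DataFrame(
        {"unexpressed": flags}
    ).to_csv(outdir / "unexpressed_genes.tsv", sep="\t")
    concordance.to_csv(outdir / "purity_concordance.tsv", sep="\t")
    (outdir / "threshold.json").write_text(json.dumps(
        {"value": thr.value, "source": thr.source, "n_chry_genes": thr.n_chry_genes},
        indent=1) + "\n")
    log.info(f"unexpressed threshold {thr.value:.3f} ({thr.source}); "
             f"{int(flags.sum())} genes flagged")


def _profiles_log2(state: dict) -> dict[str, ExpressionMatrix]:
    return {"bulk": state["bulk_log2"], "tc": state["tc_log2"], "tac": state["tac_log2"]}


def _stage_survival(config: RunConfig, state: dict, outdir: Path, log: _Log) -> None:
    clinical = _require(state, "clinical", "survival")
    thr = _require(state, "threshold", "survival")
    screens = {}
    sig_sets = {}
    for name, expr in _profiles_log2(state).items():
        frame = survival_screen(
            expr, clinical, threshold=thr.value, profile_type=name,
            min_above=config.thresholds.min_group_size,
        )
        frame.to_csv(outdir / f"survival_{name}.tsv", sep="\t")
        screens[name] = frame
        sig_sets[name] = significant_genes(
            frame, config.thresholds.q_max, config.thresholds.min_abs_log2hr,
            config.thresholds.ph_p_min,
        )
    state["survival_screens"] = screens
    state["survival_significant"] = sig_sets
    pairs = {}
    for a in sig_sets:
        for b in sig_sets:
            if a < b and (sig_sets[a] or sig_sets[b]):
                pairs[f"{a}_vs_{b}"] = intersecting_proportion(sig_sets[a], sig_sets[b])
    summary = pd.DataFrame(
        {
            "n_significant": {k: len(v) for k, v in sig_sets.items()},
        }
    )
    summary.to_csv(outdir / "survival_summary.tsv", sep="\t")
    (outdir / "intersecting_proportions.json").write_text(
        json.dumps(pairs, indent=1, sort_keys=True) + "\n"
    )
    log.info("survival screen significant genes: "
             + ", ".join(f"{k}={len(v)}" for k, v in sig_sets.items()))


def _stage_interaction(config: RunConfig, state: dict, outdir: Path, log: _Log) -> None:
    clinical = _require(state, "clinical", "interaction")
    thr = _require(state, "threshold", "interaction")
    results = interaction_screen(
        state["tc_log2"], state["tac_log2"], clinical,
        threshold=thr.value, min_above=config.thresholds.min_group_size,
        q_max=config.thresholds.interaction_q_max,
        min_abs_log2hr=config.thresholds.min_abs_log2hr,
    )
    state["interaction_results"] = results
    interaction_results_frame(results).to_csv(outdir / "interaction.tsv", sep="\t")
    summary = summarize_relationships(results)
    summary.to_csv(outdir / "interaction_summary.tsv", sep="\t")
    log.info(f"interaction screen: {len(summary)} classes populated")


def _stage_subtypes(config: RunConfig, state: dict, outdir: Path, log: _Log) -> None:
    clinical = _require(state, "clinical", "subtypes")
    profiles = _profiles_log2(state)
    labels = clinical.frame["subtype"].reindex(profiles["bulk"].sample_ids)

    # marker panel: receptor genes + one-vs-rest DE markers from bulk
    de = subtype_de_genes(profiles["bulk"], labels, top_n=10)
    panel_genes = sorted({g for gs in de.values() for g in gs}
                         | ({"ESR1", "PGR", "ERBB2"} & set(profiles["bulk"].gene_ids)))
    pd.Series({st: ";".join(gs) for st, gs in de.items()}).to_csv(
        outdir / "subtype_de_genes.tsv", sep="\t", header=["genes"])

    scaled = {k: scale_genewise(v) for k, v in profiles.items()}
    model = train_centroids(scaled["bulk"], labels, panel_genes)
    agreements = {}
    for name, expr in scaled.items():
        assigned, corr = classify_nearest_centroid(expr, model)
        agreement, _ = classification_agreement(assigned, labels)
        agreements[name] = agreement
        assigned.to_frame().to_csv(outdir / f"subtype_calls_{name}.tsv", sep="\t")
    state["subtype_agreements"] = agreements

    variable = select_variable_genes(profiles["bulk"], profiles["tc"], profiles["tac"])
    state["variable_genes"] = variable
    consensus = {}
    for name in ("bulk", "tc", "tac"):
        res = consensus_cluster(
            scaled[name], variable, k=config.consensus_k,
            reps=config.consensus_reps, seed=config.seeds.consensus,
        )
        res.labels.to_frame().to_csv(outdir / f"consensus_labels_{name}.tsv", sep="\t")
        agree, _ = classification_agreement(res.labels.astype(str), labels)
        consensus[name] = agree
    state["consensus_agreements"] = consensus
    pd.DataFrame({
        "centroid_agreement": agreements, "consensus_agreement": consensus,
    }).to_csv(outdir / "subtype_agreement.tsv", sep="\t")
    log.info("subtype agreement (centroid): "
             + ", ".join(f"{k}={v:.2f}" for k, v in agreements.items()))


def _stage_biomarkers(config: RunConfig, state: dict, outdir: Path, log: _Log) -> None:
    clinical = _require(state, "clinical", "biomarkers")
    profiles = _profiles_log2(state)
    ids = profiles["bulk"].sample_ids
    n_train = int(round(config.biomarkers.train_fraction * len(ids)))
    n_test = len(ids) - n_train
    train, test = split_cohort(ids, n_train, n_test, config.seeds.derive(4))
    evals = evaluate_signatures(
        profiles, clinical.subset(ids), train, test,
        n_signatures=config.biomarkers.n_signatures,
        genes_per=config.biomarkers.genes_per_signature,
        n_trees=config.biomarkers.n_trees,
        folds=config.biomarkers.cv_folds,
        seed=config.seeds.signatures,
    )
    state["biomarker_evals"] = evals
    evals.to_csv(outdir / "biomarker_evaluations.tsv", sep="\t", index=False)
    summary = summarize_distributions(evals)
    summary.to_csv(outdir / "biomarker_summary.tsv", sep="\t")
    log.info("biomarker median AUC: "
             + ", ".join(f"{k}={v:.3f}" for k, v in summary["auc_median"].items()))


def _stage_mutations(config: RunConfig, state: dict, outdir: Path, log: _Log) -> None:
    if "mutations" not in state:
        log.info("no mutation matrix available; stage skipped")
        return
    clinical = _require(state, "clinical", "mutations")
    reports = mutation_expression_screen(
        _profiles_log2(state), state["mutations"], clinical,
        min_mutated=config.thresholds.min_mutated,
    )
    state["mutation_reports"] = reports
    rows = []
    for r in reports:
        row = {
            "subtype": r.subtype, "driver": r.driver,
            "n_mutated": r.n_mutated, "n_wildtype": r.n_wildtype,
            "n_bulk_missed": r.n_bulk_missed,
        }
        for name, cis in r.cis.items():
            row[f"cis_log2fc_{name}"] = cis[0] if cis else np.nan
            row[f"cis_q_{name}"] = cis[1] if cis else np.nan
        for name in r.tables:
            row[f"n_significant_{name}"] = int(r.found_in[name].sum()) if r.found_in is not None and name in r.found_in else 0
        rows.append(row)
    frame = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["subtype", "driver", "n_mutated", "n_wildtype", "n_bulk_missed"])
    frame.to_csv(outdir / "mutation_de.tsv", sep="\t", index=False)
    log.info(f"mutation screen: {len(rows)} testable subtype/driver pairs")
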