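import numpy as np
import pandas as pd
import pytest

from tactome.config import BiomarkerConfig, RunConfig, SimulatorConfig
from tactome.datatypes import ClinicalTable, ExpressionMatrix
from tactome.simulate import _build_gene_plan, generate_cohort, generate_normal_panel


def small_sim_config(**overrides) -> SimulatorConfig:
    """Desk-scale simulator settings shared by the unit tests."""
    base = dict(
        n_genes=600,
        n_per_subtype=40,
        n_normal_refs=30,
        n_program_genes=60,
        n_stromal_restricted=80,
        n_tumor_specific=40,
        n_subtype_markers=15,
        n_chry_genes=10,
        n_unexpressed_extra=20,
        n_tac_perturbed=20,
    )
    base.update(overrides)
    return SimulatorConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    config = small_sim_config()
    seed = 11
    plan = _build_gene_plan(config, seed)
    panel = generate_normal_panel(config, seed, plan)
    bulk, clinical, mutations, truth = generate_cohort(config, panel, seed, plan)
    return {
        "config": config, "plan": plan, "panel": panel, "bulk": bulk,
        "clinical": clinical, "mutations": mutations, "truth": truth,
    }


@pytest.fixture(scope="session")
def deconvolved(small_cohort):
    from tactome.deconvolution import run_deconvolution_by_subtype, to_log2_with_floor

    res = run_deconvolution_by_subtype(
        small_cohort["bulk"], small_cohort["panel"], small_cohort["clinical"],
        RunConfig(),
    )
    kept = list(res.purity.index)
    b_log, t_log, s_log, floor = to_log2_with_floor(
        small_cohort["bulk"].subset_samples(kept), res.tc, res.tac
    )
    return {"result": res, "bulk_log2": b_log, "tc_log2": t_log,
            "tac_log2": s_log, "floor": floor}


def toy_matrix(values, space="log2", genes=None, samples=None, **kw) -> ExpressionMatrix:
    v = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(v.shape[0])]
    samples = samples or [f"s{j}" for j in range(v.shape[1])]
    return ExpressionMatrix(v, space, genes, samples, **kw)


def toy_clinical(times, events, subtype="LumA", **columns) -> ClinicalTable:
    n = len(times)
    frame = pd.DataFrame(
        {
            "os_time": np.asarray(times, dtype=float),
            "os_event": np.asarray(events, dtype=int),
            "subtype": subtype,
            "cellularity": columns.pop("cellularity", "moderate"),
            "er_status": "pos",
            "pr_status": "pos",
            "her2_status": "neg",
            **columns,
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    return ClinicalTable(frame)
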