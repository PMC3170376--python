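"""Shared fixtures: programmatically generated experiments at test scale."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from toxtemp_gxe import diffexpr as de
from toxtemp_gxe import pipeline_report as pr
from toxtemp_gxe import preprocess as pp
from toxtemp_gxe import synthetic_data as sd


def channels_matrix(raw: pd.DataFrame, sheet: pd.DataFrame) -> pp.ExpressionMatrix:
    """Raw intensities -> channel-level log2 matrix, no normalization."""
    ma_list = []
    for array_id, sub in raw.groupby("array_id", sort=False):
        sub = sub.set_index("gene_id")
        ma_list.append(
            pp.ma_transform(
                sub["red_intensity"].to_numpy(),
                sub["green_intensity"].to_numpy(),
                gene_ids=sub.index.to_numpy(),
                array_id=str(array_id),
            )
        )
    return pp.channels_from_ma(ma_list, sheet)


@pytest.fixture(scope="session")
def small_null_experiment():
    """Tiny all-null experiment: raw, sheet, truth."""
    cfg = sd.SimulationConfig(
        n_genes=120,
        seed=42,
        sigma_spot=0.25,
        gene_class_proportions={"null": 1.0},
        effect_model={"null": {}},
    )
    return sd.generate_experiment(cfg), cfg


@pytest.fixture(scope="session")
def null_run():
    """All-null 2000-gene experiment, fully normalized, scanned, permuted.

    Outlier removal is disabled: recursive tail-trimming deflates residual
    variance and is assessed separately.
    """
    cfg = sd.SimulationConfig(
        n_genes=2000,
        seed=11,
        sigma_spot=0.25,
        gene_class_proportions={"null": 1.0},
        effect_model={"null": {}},
    )
    raw, sheet, truth = sd.generate_experiment(cfg)
    run_cfg = pr.RunConfig(simulation=cfg, out_dir="scratch/null", seed=11, max_remove=0)
    matrix, _ = pr.preprocess_experiment(raw, sheet, run_cfg)
    spec = de.ModelSpec.full_factorial()
    results, skipped = de.genome_scan(matrix, spec)
    null = de.permutation_null(matrix, spec, n_perm=2000, seed=1)
    return {
        "matrix": matrix,
        "results": results,
        "skipped": skipped,
        "null": null,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def recovery_run():
    """Planted-effect experiment on clean channels (no bias, no warping).

    200 genes with a marginal CPF effect of 1.0 log2 and 200 genes with a
    CPF:DZN interaction of 1.0 log2 at sigma 0.25, 6 replicates per cell.
    """
    cfg = sd.SimulationConfig(
        n_genes=1000,
        seed=7,
        sigma_spot=0.25,
        gene_class_proportions={"null": 0.6, "marginal": 0.2, "interaction": 0.2},
        effect_model={
            "null": {},
            "marginal": {"CPF": 1.0},
            "interaction": {"CPF:DZN": 1.0},
        },
    )
    raw, sheet, truth = sd.generate_experiment(cfg)
    matrix = channels_matrix(raw, sheet)
    results, _ = de.genome_scan(matrix, de.ModelSpec.full_factorial())
    return {"matrix": matrix, "results": results, "truth": truth, "config": cfg}


@pytest.fixture()
def ratio_sample_sheet():
    """Ratio-level observation sheet: one row per array, no control cells."""
    rows = [
        {"cpf": c, "dzn": d, "temp": t, "replicate": r}
        for t in (0, 1)
        for (c, d) in ((1, 0), (0, 1), (1, 1))
        for r in range(1, 7)
    ]
    sheet = pd.DataFrame(rows)
    sheet.index = pd.Index([f"obs{i}" for i in range(len(rows))], name="observation_id")
    return sheet
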