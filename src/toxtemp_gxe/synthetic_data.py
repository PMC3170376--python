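"""Synthetic two-color dye-swap microarray experiments with known ground truth.

Generates raw two-channel spot intensities for a factorial toxicant x
temperature experiment in which every array hybridizes a treatment extract
against a control extract, with the dye assignment swapped between
consecutive replicates.  The true per-gene signal is additive on the log2
scale over the 0/1 indicators CPF, DZN, Temp and all their products, so the
full factorial model downstream can recover the planted coefficients
exactly in the noise-free limit.

Random streams are per-gene (keyed on the top-level seed and the gene
index), so generating a subset of genes yields the same values for the
genes that are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FULL_TERMS",
    "SimulationConfig",
    "TruthTable",
    "generate_experiment",
    "plant_outliers",
    "generate_annotations",
    "true_signal_matrix",
    "treatment_label",
]

#: Fixed order of the non-intercept factorial terms.
FULL_TERMS: tuple[str, ...] = (
    "CPF",
    "DZN",
    "Temp",
    "CPF:DZN",
    "CPF:Temp",
    "DZN:Temp",
    "CPF:DZN:Temp",
)

_FACTORS = {"CPF": 0, "DZN": 1, "Temp": 2}

# Stream keys used to derive independent sub-streams from the master seed.
_STREAM_ARRAY_SHIFT = 982451653
_STREAM_OUTLIERS = 879190747
_STREAM_ANNOT = 15485863


def term_indicator(term: str, cpf: int, dzn: int, temp: int) -> int:
    """Value of a (possibly interaction) 0/1 indicator term at one cell."""
    value = 1
    for part in term.split(":"):
        value *= (cpf, dzn, temp)[_FACTORS[part]]
    return value


def treatment_label(cpf: int, dzn: int) -> str:
    return {(0, 0): "control", (1, 0): "CPF", (0, 1): "DZN", (1, 1): "CPF+DZN"}[
        (int(cpf), int(dzn))
    ]


def _default_effect_model() -> dict[str, dict[str, float]]:
    return {
        "null": {},
        "marginal": {"CPF": 1.0},
        "interaction": {"CPF:DZN": 1.0},
        "detox": {"CPF": 1.0, "DZN": 1.0, "CPF:Temp": 0.5},
    }


def _default_proportions() -> dict[str, float]:
    return {"null": 0.85, "marginal": 0.06, "interaction": 0.04, "detox": 0.05}


@dataclass
class SimulationConfig:
    """Configuration of one synthetic dye-swap experiment.

    ``effect_model`` maps a gene-class name to the non-zero true log2
    coefficients of that class (term name -> magnitude); classes absent
    from ``gene_class_proportions`` are ignored.  ``dye_bias`` holds
    polynomial coefficients (highest power first, ``numpy.polyval``
    convention) of the intensity-dependent bias added to the log-ratio.
    """

    n_genes: int = 18889
    n_replicates: int = 6
    treatments: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1))
    temperatures: tuple[int, ...] = (0, 1)
    effect_model: dict[str, dict[str, float]] = field(default_factory=_default_effect_model)
    gene_class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    baseline_range: tuple[float, float] = (8.0, 12.0)
    sigma_spot: float = 0.25
    dye_bias: tuple[float, ...] = (0.0,)
    array_shift_sd: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 2.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_replicates < 2:
            raise ValueError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if not self.treatments:
            raise ValueError("treatments must be non-empty")
        for cell in self.treatments:
            if tuple(cell) == (0, 0):
                raise ValueError("(0, 0) is the control extract, not a treatment cell")
        if self.sigma_spot < 0:
            raise ValueError(f"sigma_spot must be >= 0, got {self.sigma_spot}")
        total = sum(self.gene_class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gene class proportions must sum to 1, got {total}")
        for cls in self.gene_class_proportions:
            if cls not in self.effect_model:
                raise ValueError(f"gene class {cls!r} missing from effect_model")
        for cls, effects in self.effect_model.items():
            for term in effects:
                if term not in FULL_TERMS:
                    raise ValueError(f"unknown term {term!r} in effect_model[{cls!r}]")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError(f"outlier_rate must be in [0, 1), got {self.outlier_rate}")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene class, baseline and coefficients.

    ``table`` has one row per gene with columns ``gene_id``, ``gene_class``,
    ``baseline`` and ``coef_<term>`` for every term in :data:`FULL_TERMS`.
    ``outlier_sites`` lists ``(gene_id, observation_id)`` pairs of planted
    gross outliers.
    """

    table: pd.DataFrame
    outlier_sites: list[tuple[str, str]] = field(default_factory=list)

    def coefficients(self) -> pd.DataFrame:
        """Genes x terms frame of true coefficients (index = gene_id)."""
        cols = {f"coef_{t}": t for t in FULL_TERMS}
        out = self.table.set_index("gene_id")[list(cols)].rename(columns=cols)
        return out

    def genes_of_class(self, name: str) -> frozenset[str]:
        sub = self.table[self.table["gene_class"] == name]
        return frozenset(sub["gene_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _gene_classes(config: SimulationConfig) -> list[str]:
    """Deterministic block assignment of gene classes by proportion."""
    names = list(config.gene_class_proportions)
    counts = [int(round(config.gene_class_proportions[c] * config.n_genes)) for c in names]
    # fix rounding drift on the first (largest-by-convention) class
    counts[0] += config.n_genes - sum(counts)
    classes: list[str] = []
    for name, count in zip(names, counts):
        classes.extend([name] * count)
    return classes[: config.n_genes]


def _array_layout(config: SimulationConfig) -> pd.DataFrame:
    """One row per array: id, treatment cell, temperature, replicate, dye."""
    rows = []
    for temp in config.temperatures:
        for cpf, dzn in config.treatments:
            label = treatment_label(cpf, dzn)
            for rep in range(1, config.n_replicates + 1):
                # balanced swap: even replicates carry the treatment in red
                treatment_dye = "red" if rep % 2 == 1 else "green"
                rows.append(
                    {
                        "array_id": f"t{temp}_{label}_r{rep}",
                        "cpf": int(cpf),
                        "dzn": int(dzn),
                        "temp": int(temp),
                        "replicate": rep,
                        "treatment_channel": treatment_dye,
                    }
                )
    return pd.DataFrame(rows)


def _sample_sheet(arrays: pd.DataFrame) -> pd.DataFrame:
    """Two observation rows (one per channel) per array."""
    rows = []
    for rec in arrays.itertuples(index=False):
        for channel in ("red", "green"):
            is_treatment = channel == rec.treatment_channel
            rows.append(
                {
                    "array_id": rec.array_id,
                    "channel": channel,
                    "dye": "Cy5" if channel == "red" else "Cy3",
                    "treatment": treatment_label(rec.cpf, rec.dzn) if is_treatment else "control",
                    "cpf": rec.cpf if is_treatment else 0,
                    "dzn": rec.dzn if is_treatment else 0,
                    "toxicant": int(is_treatment),
                    "temp": rec.temp,
                    "replicate": rec.replicate,
                }
            )
    sheet = pd.DataFrame(rows)
    sheet.index = pd.Index(
        sheet["array_id"] + "." + sheet["channel"], name="observation_id"
    )
    return sheet


def true_signal_matrix(truth: TruthTable, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Noise-free true log2 signal per gene x observation.

    Control channels have CPF = DZN = 0, so only the Temp coefficient (and
    the baseline) contributes there.
    """
    coefs = truth.coefficients()
    baseline = truth.table.set_index("gene_id")["baseline"]
    design = np.array(
        [
            [term_indicator(t, r.cpf, r.dzn, r.temp) for t in FULL_TERMS]
            for r in sample_sheet.itertuples(index=False)
        ],
        dtype=float,
    )
    values = baseline.to_numpy()[:, None] + coefs.to_numpy() @ design.T
    return pd.DataFrame(values, index=coefs.index, columns=sample_sheet.index)


def generate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate raw two-channel intensities for a dye-swap experiment.

    Returns ``(raw, sample_sheet, truth)`` where ``raw`` is a long table
    with columns ``gene_id, array_id, red_intensity, green_intensity``.
    """
    config.validate()
    arrays = _array_layout(config)
    sheet = _sample_sheet(arrays)
    n_arrays = len(arrays)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    classes = _gene_classes(config)

    # per-array additive log2 shift (applied to both channels)
    shift_rng = np.random.default_rng([config.seed, _STREAM_ARRAY_SHIFT])
    shifts = shift_rng.normal(0.0, config.array_shift_sd, n_arrays) if config.array_shift_sd > 0 else np.zeros(n_arrays)

    cells = arrays[["cpf", "dzn", "temp"]].to_numpy()
    trt_design = np.array(
        [[term_indicator(t, c, d, tp) for t in FULL_TERMS] for c, d, tp in cells],
        dtype=float,
    )
    ctl_design = np.array(
        [[term_indicator(t, 0, 0, tp) for t in FULL_TERMS] for _, _, tp in cells],
        dtype=float,
    )
    trt_is_red = (arrays["treatment_channel"] == "red").to_numpy()

    lo, hi = config.baseline_range
    red_log = np.empty((config.n_genes, n_arrays))
    green_log = np.empty((config.n_genes, n_arrays))
    truth_rows = []
    for g, gene_id in enumerate(gene_ids):
        rng = np.random.default_rng([config.seed, g])
        baseline = rng.uniform(lo, hi)
        noise = rng.normal(0.0, config.sigma_spot, (n_arrays, 2)) if config.sigma_spot > 0 else np.zeros((n_arrays, 2))
        coef = np.array(
            [config.effect_model[classes[g]].get(t, 0.0) for t in FULL_TERMS]
        )
        sig_trt = baseline + trt_design @ coef
        sig_ctl = baseline + ctl_design @ coef
        red = np.where(trt_is_red, sig_trt + noise[:, 0], sig_ctl + noise[:, 0])
        green = np.where(trt_is_red, sig_ctl + noise[:, 1], sig_trt + noise[:, 1])
        a_pre = 0.5 * (red + green)
        bias = np.polyval(config.dye_bias, a_pre)
        red_log[g] = red + 0.5 * bias + shifts
        green_log[g] = green - 0.5 * bias + shifts
        truth_rows.append(
            {
                "gene_id": gene_id,
                "gene_class": classes[g],
                "baseline": baseline,
                **{f"coef_{t}": coef[j] for j, t in enumerate(FULL_TERMS)},
            }
        )

    truth = TruthTable(table=pd.DataFrame(truth_rows))

    if config.outlier_rate > 0:
        # channel-level planting on the log2 scale, before exponentiation
        channels = np.concatenate([red_log, green_log], axis=1)
        channels, sites = plant_outliers(
            channels,
            config.outlier_rate,
            config.outlier_magnitude,
            seed=[config.seed, _STREAM_OUTLIERS],
        )
        red_log = channels[:, :n_arrays]
        green_log = channels[:, n_arrays:]
        obs_ids = list(arrays["array_id"] + ".red") + list(arrays["array_id"] + ".green")
        truth.outlier_sites = [(gene_ids[i], obs_ids[j]) for i, j in sites]

    raw = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, n_arrays),
            "array_id": np.tile(arrays["array_id"].to_numpy(), config.n_genes),
            "red_intensity": np.exp2(red_log).ravel(),
            "green_intensity": np.exp2(green_log).ravel(),
        }
    )
    return raw, sheet, truth


def plant_outliers(
    matrix: np.ndarray | pd.DataFrame,
    rate: float,
    magnitude: float,
    seed,
) -> tuple[np.ndarray | pd.DataFrame, list[tuple]]:
    """Shift randomly selected entries of a values matrix by +/- magnitude.

    Returns a copy of the matrix and the list of planted sites as
    ``(row, column)`` positional indices (labels when given a DataFrame).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"outlier rate must be in [0, 1), got {rate}")
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    values = values.astype(float, copy=True)
    rng = np.random.default_rng(seed)
    if rate == 0.0:
        out = matrix.copy() if isinstance(matrix, pd.DataFrame) else values
        return out, []
    hit = rng.random(values.shape) < rate
    signs = np.where(rng.random(values.shape) < 0.5, -1.0, 1.0)
    values[hit] += signs[hit] * magnitude
    rows, cols = np.nonzero(hit)
    if isinstance(matrix, pd.DataFrame):
        out = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
        sites = [(matrix.index[i], matrix.columns[j]) for i, j in zip(rows, cols)]
        return out, sites
    return values, list(zip(rows.tolist(), cols.tolist()))


# detox domain ids used when planting enriched annotations; mirrors the
# default vocabulary shipped with detox_catalog.
_PLANTED_DETOX_DOMAINS = ("PF00067", "PF00106", "PF00201", "PF00043", "PF00005")


def generate_annotations(
    truth: TruthTable,
    n_go_terms: int = 60,
    n_domain_terms: int = 40,
    enrichment_factor: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random gene->term maps with planted detox-domain enrichment.

    Produces two two-column frames (``gene_id``, ``term_id``) emulating GO
    and protein-domain annotation extracts.  Genes of the ``detox`` class
    carry the detox domain ids at ``enrichment_factor`` times the
    background membership rate.  One term of each type is given exactly
    three member genes to exercise the minimum-term-size filter
    downstream.
    """
    if enrichment_factor < 1.0:
        raise ValueError(f"enrichment_factor must be >= 1, got {enrichment_factor}")
    rng = np.random.default_rng([seed, _STREAM_ANNOT])
    gene_ids = truth.table["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    is_detox = (truth.table["gene_class"] == "detox").to_numpy()

    def membership(prob_background: float, boosted: bool) -> np.ndarray:
        prob = np.full(n_genes, prob_background)
        if boosted:
            prob[is_detox] = np.minimum(1.0, prob_background * enrichment_factor)
        return rng.random(n_genes) < prob

    def small_term(term_id: str, rows: list) -> None:
        members = rng.choice(gene_ids, size=3, replace=False)
        rows.extend((g, term_id) for g in members)

    go_rows: list[tuple[str, str]] = []
    for i in range(n_go_terms):
        term_id = f"GO:{7000001 + i:07d}"
        prob = float(np.exp(rng.uniform(np.log(0.002), np.log(0.05))))
        hit = membership(prob, boosted=False)
        go_rows.extend((g, term_id) for g in gene_ids[hit])
    small_term("GO:7999999", go_rows)

    dom_rows: list[tuple[str, str]] = []
    for i in range(n_domain_terms):
        if i < len(_PLANTED_DETOX_DOMAINS):
            term_id = _PLANTED_DETOX_DOMAINS[i]
            prob = 0.01
            boosted = True
        else:
            term_id = f"IPR{800001 + i:06d}"
            prob = float(np.exp(rng.uniform(np.log(0.002), np.log(0.05))))
            boosted = False
        hit = membership(prob, boosted)
        dom_rows.extend((g, term_id) for g in gene_ids[hit])
    small_term("IPR899999", dom_rows)

    go = pd.DataFrame(go_rows, columns=["gene_id", "term_id"])
    domains = pd.DataFrame(dom_rows, columns=["gene_id", "term_id"])
    return go, domains
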