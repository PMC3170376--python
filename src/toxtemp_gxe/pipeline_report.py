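"""Set-operation reports, percentage formatting and pipeline orchestration.

Venn partitions decompose 2-3 named gene sets into exclusive regions;
overlap matrices report pairwise intersections plus the genes hit by
exactly one set.  Percentages of tested genes are rounded
half-away-from-zero to one decimal.  :func:`run_pipeline` drives the full
synthetic workflow: simulate -> normalize -> outlier removal -> single and
full-model scans -> permutation null / FDR -> set reports -> enrichment ->
detox tables, writing a deterministic TSV/JSON bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_enrichment as ae
from . import detox_catalog as dc
from . import diffexpr as de
from . import preprocess as pp
from . import synthetic_data as sd

__all__ = [
    "VennPartition",
    "RunConfig",
    "venn_partition",
    "overlap_matrix",
    "percent_of_tested",
    "percent_value",
    "run_pipeline",
]


@dataclass
class VennPartition:
    """Exclusive regions of 2-3 named sets.

    ``regions`` maps the sorted tuple of covering set names to the genes
    found in exactly those sets.  Regions are pairwise disjoint and their
    union equals the union of the input sets.
    """

    set_names: tuple[str, ...]
    regions: dict[tuple[str, ...], frozenset]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {region: len(members) for region, members in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": "&".join(region),
                "count": len(members),
                "genes": ",".join(sorted(map(str, members))),
            }
            for region, members in self.regions.items()
        ]
        return pd.DataFrame(rows, columns=["region", "count", "genes"])


def venn_partition(named_sets: dict[str, frozenset]) -> VennPartition:
    """All 2^m - 1 exclusive regions of 2 or 3 named sets."""
    names = tuple(named_sets)
    if not (2 <= len(names) <= 3):
        raise ValueError(f"venn partition supports 2-3 sets, got {len(names)}")
    sets = {name: frozenset(named_sets[name]) for name in names}
    regions: dict[tuple[str, ...], frozenset] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            members = frozenset.intersection(*(sets[n] for n in inside))
            for outside in names:
                if outside not in inside:
                    members = members - sets[outside]
            regions[inside] = members
    return VennPartition(set_names=names, regions=regions)


def overlap_matrix(
    named_sets: dict[str, frozenset],
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise intersection counts plus exactly-one-set counts.

    The diagonal holds set sizes; the returned Series counts, per set, the
    genes belonging to that set and no other.
    """
    names = list(named_sets)
    if not names:
        raise ValueError("need at least one set")
    sets = {name: frozenset(named_sets[name]) for name in names}
    matrix = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            matrix.loc[a, b] = len(sets[a] & sets[b])
    exclusive = {}
    for a in names:
        others = frozenset().union(*(sets[b] for b in names if b != a)) if len(names) > 1 else frozenset()
        exclusive[a] = len(sets[a] - others)
    return matrix, pd.Series(exclusive, name="exclusive")


def percent_value(n_sig: int, n_tested: int) -> float:
    """100 * n_sig / n_tested rounded half-away-from-zero to 1 decimal."""
    if n_tested <= 0:
        raise ValueError(f"n_tested must be positive, got {n_tested}")
    if not (0 <= n_sig <= n_tested):
        raise ValueError(f"n_sig must be in [0, n_tested], got {n_sig}")
    exact = Decimal(100 * n_sig) / Decimal(n_tested)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def percent_of_tested(n_sig: int, n_tested: int) -> str:
    """Percentage string with one decimal, e.g. ``'4.7%'``."""
    return f"{percent_value(n_sig, n_tested):.1f}%"


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end pipeline run."""

    simulation: sd.SimulationConfig = field(default_factory=sd.SimulationConfig)
    out_dir: str = "results"
    seed: int = 0
    n_perm: int = 2000
    threshold: float = 2.0
    alpha: float = 0.05
    ci_level: float = 0.995
    max_remove: int = 6
    loess_span: float = 0.3
    loess_degree: int = 2
    loess_iterations: int = 3
    skip_loess: bool = False
    n_go_terms: int = 60
    n_domain_terms: int = 40
    enrichment_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = sd.SimulationConfig(**{
            **raw.pop("simulation", {}),
        })
        # YAML lists -> tuples for the simulation cells
        sim.treatments = tuple(tuple(c) for c in sim.treatments)
        sim.temperatures = tuple(sim.temperatures)
        sim.dye_bias = tuple(sim.dye_bias)
        sim.baseline_range = tuple(sim.baseline_range)
        return cls(simulation=sim, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def preprocess_experiment(
    raw: pd.DataFrame, sample_sheet: pd.DataFrame, config: RunConfig
) -> tuple[pp.ExpressionMatrix, pd.DataFrame]:
    """Normalize raw intensities and remove per-gene outliers."""
    ma_list = []
    for array_id, sub in raw.groupby("array_id", sort=False):
        sub = sub.set_index("gene_id")
        ma = pp.ma_transform(
            sub["red_intensity"].to_numpy(),
            sub["green_intensity"].to_numpy(),
            gene_ids=sub.index.to_numpy(),
            array_id=str(array_id),
        )
        if not config.skip_loess:
            ma = pp.loess_normalize_within_array(
                ma,
                span=config.loess_span,
                degree=config.loess_degree,
                iterations=config.loess_iterations,
            )
        ma_list.append(ma)
    if len(ma_list) > 1:
        ma_list = pp.aquantile_between_arrays(ma_list)
    matrix = pp.channels_from_ma(ma_list, sample_sheet)
    design = de.build_design(matrix.sample_sheet, de.ModelSpec.full_factorial())
    out_config = pp.OutlierConfig(ci_level=config.ci_level, max_remove=config.max_remove)
    matrix, removal_log = pp.remove_outliers_matrix(matrix, design.X_estimable, out_config)
    return matrix, removal_log


def _single_scans(matrix: pp.ExpressionMatrix, config: RunConfig):
    """Per-treatment, per-temperature single-toxicant scans and sets."""
    sheet = matrix.sample_sheet
    spec = de.ModelSpec.single_toxicant()
    results = {}
    sets = {}
    fdr_frames = []
    labels = sorted(t for t in sheet["treatment"].unique() if t != "control")
    for temp in sorted(sheet["temp"].unique()):
        for label_idx, label in enumerate(labels):
            arrays = sheet.loc[
                (sheet["treatment"] == label) & (sheet["temp"] == temp), "array_id"
            ].unique()
            obs = sheet.index[sheet["array_id"].isin(arrays)]
            sub = pp.ExpressionMatrix(
                matrix.values[obs], matrix.mask[obs], sheet.loc[obs]
            )
            scan, _ = de.genome_scan(sub, spec, threshold=config.threshold)
            name = f"{label}@t{temp}"
            results[name] = scan
            sets[name] = de.select_significant(scan, config.threshold).get(
                "Toxicant", frozenset()
            )
            null = de.permutation_null(
                sub,
                spec,
                config.n_perm,
                seed=[config.seed, 101, int(temp), label_idx],
                threshold=config.threshold,
            )
            fdr = de.estimate_fdr(null, scan, config.threshold)
            fdr = fdr[fdr["term"] == "Toxicant"].assign(scan=name)
            fdr_frames.append(fdr)
    return results, sets, pd.concat(fdr_frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic workflow and write the report bundle.

    Every output is a TSV (plus one YAML config and one JSON manifest);
    the bundle is byte-identical across reruns with the same config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)

    stage = "simulate"
    try:
        raw, sheet, truth = sd.generate_experiment(sim)
        go_map, domain_map = sd.generate_annotations(
            truth,
            n_go_terms=config.n_go_terms,
            n_domain_terms=config.n_domain_terms,
            enrichment_factor=config.enrichment_factor,
            seed=config.seed,
        )
        _write_tsv(raw, out / "raw_intensities.tsv")
        _write_tsv(sheet.reset_index(), out / "sample_sheet.tsv")
        truth.to_tsv(out / "truth.tsv")
        _write_tsv(go_map, out / "go_annotations.tsv")
        _write_tsv(domain_map, out / "domain_annotations.tsv")

        stage = "preprocess"
        matrix, removal_log = preprocess_experiment(raw, sheet, config)
        _write_tsv(matrix.values.round(10), out / "normalized_matrix.tsv", index=True)
        _write_tsv(matrix.mask.astype(int), out / "normalized_mask.tsv", index=True)
        _write_tsv(removal_log, out / "outlier_removals.tsv")

        stage = "scan"
        full_spec = de.ModelSpec.full_factorial()
        full_scan, skipped = de.genome_scan(matrix, full_spec, threshold=config.threshold)
        _write_tsv(full_scan.round(10), out / "scan_full_model.tsv")
        _write_tsv(skipped, out / "scan_skipped_genes.tsv")
        single_results, single_sets, single_fdr = _single_scans(matrix, config)
        for name, scan in single_results.items():
            safe = name.replace("@", "_").replace("+", "")
            _write_tsv(scan.round(10), out / f"scan_single_{safe}.tsv")

        stage = "permutation"
        null = de.permutation_null(
            matrix, full_spec, config.n_perm, seed=[config.seed, 100], threshold=config.threshold
        )
        _write_tsv(null.p_values.round(12), out / "null_distribution.tsv")
        fdr_full = de.estimate_fdr(null, full_scan, config.threshold).assign(scan="full")
        fdr_all = pd.concat([fdr_full, single_fdr], ignore_index=True)
        _write_tsv(fdr_all.round(8), out / "fdr_summary.tsv")

        stage = "report"
        term_sets = de.select_significant(full_scan, config.threshold)
        term_sets = {t: term_sets.get(t, frozenset()) for t in full_spec.terms[1:]}
        set_rows = [
            {"set_name": name, "count": len(genes), "genes": ",".join(sorted(genes))}
            for name, genes in {**single_sets, **term_sets}.items()
        ]
        _write_tsv(pd.DataFrame(set_rows), out / "significant_sets.tsv")

        n_tested = len(matrix.gene_ids)
        percent_rows = [
            {
                "set_name": name,
                "n_significant": len(genes),
                "n_tested": n_tested,
                "percent": percent_of_tested(len(genes), n_tested),
            }
            for name, genes in {**single_sets, **term_sets}.items()
        ]
        _write_tsv(pd.DataFrame(percent_rows), out / "percent_report.tsv")

        venn_frames = []
        for temp in sorted(sheet["temp"].unique()):
            names = [n for n in single_sets if n.endswith(f"@t{temp}")]
            if 2 <= len(names) <= 3:
                part = venn_partition({n: single_sets[n] for n in names})
                venn_frames.append(part.to_frame().assign(comparison=f"treatments@t{temp}"))
        labels = sorted({n.split("@")[0] for n in single_sets})
        temps = sorted(sheet["temp"].unique())
        if len(temps) >= 2:
            for label in labels:
                names = [f"{label}@t{t}" for t in temps if f"{label}@t{t}" in single_sets]
                if 2 <= len(names) <= 3:
                    part = venn_partition({n: single_sets[n] for n in names})
                    venn_frames.append(part.to_frame().assign(comparison=f"{label}-across-temps"))
        if venn_frames:
            _write_tsv(pd.concat(venn_frames, ignore_index=True), out / "venn_partitions.tsv")

        overlap, exclusive = overlap_matrix(term_sets)
        overlap.loc["only_one_variable"] = exclusive
        _write_tsv(overlap, out / "overlap_matrix.tsv", index=True)

        stage = "enrichment"
        go_terms = ae.annotations_from_frame(go_map, term_type="GO")
        domain_terms = ae.annotations_from_frame(domain_map, term_type="domain")
        tested = set(map(str, matrix.gene_ids))
        go_universe = set(go_map["gene_id"].astype(str)) & tested
        domain_universe = set(domain_map["gene_id"].astype(str)) & tested
        enrich_frames = {"go": [], "domain": []}
        for name, genes in {**single_sets, **term_sets}.items():
            for kind, terms, universe in (
                ("go", go_terms, go_universe),
                ("domain", domain_terms, domain_universe),
            ):
                table = ae.enrich_gene_set(genes, universe, terms, alpha=config.alpha)
                enrich_frames[kind].append(table.assign(set_name=name))
        _write_tsv(
            pd.concat(enrich_frames["go"], ignore_index=True).round(12),
            out / "go_enrichment.tsv",
        )
        _write_tsv(
            pd.concat(enrich_frames["domain"], ignore_index=True).round(12),
            out / "domain_enrichment.tsv",
        )

        stage = "detox"
        category_sets = dc.classify_detox(domain_map)
        group_cols = {
            f"all-treatments@t{temp}": [n for n in single_sets if n.endswith(f"@t{temp}")]
            for temp in sorted(sheet["temp"].unique())
        }
        counts_single = dc.detox_counts_table(category_sets, single_sets, groups=group_cols)
        counts_full = dc.detox_counts_table(category_sets, term_sets)
        _write_tsv(counts_single, out / "detox_counts_treatments.tsv", index=True)
        _write_tsv(counts_full, out / "detox_counts_terms.tsv", index=True)
        detox_enrich = dc.detox_category_enrichment(
            category_sets, {**single_sets, **term_sets}, domain_universe, alpha=config.alpha
        )
        _write_tsv(detox_enrich.round(12), out / "detox_enrichment.tsv")
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    config.to_yaml(out / "run_config.yaml")
    files = sorted(p.name for p in out.iterdir() if p.suffix == ".tsv")
    manifest = {
        "seed": config.seed,
        "n_genes": int(sim.n_genes),
        "n_perm": int(config.n_perm),
        "threshold": config.threshold,
        "alpha": config.alpha,
        "files": {name: _digest(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
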