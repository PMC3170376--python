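"""Per-gene linear models, permutation null distributions and FDR.

Two model families are supported: the single-toxicant model
(intercept + toxicant indicator) fit per treatment and temperature, and
the full factorial model over the CPF, DZN and Temp indicators with all
interaction products.  Inference is ordinary least squares with
two-sided t-tests on individual coefficients.  Terms that are linearly
dependent on earlier terms (fixed left-to-right order) are flagged as
aliased and never reported as numbers.

The significance threshold is calibrated by a transcript permutation
scheme: each permutation picks one distinct transcript, shuffles its
values uniformly across all observations, refits the model and records
the per-term p-values.  The per-term FDR at a threshold is the expected
null rejection count (scaled to the number of genes tested) divided by
the observed rejection count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "NullDistribution",
    "build_design",
    "fit_gene_model",
    "genome_scan",
    "permutation_null",
    "estimate_fdr",
    "select_significant",
]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term list of a per-gene linear model."""

    name: str
    terms: tuple[str, ...]

    @classmethod
    def full_factorial(cls) -> "ModelSpec":
        return cls(
            name="full",
            terms=(
                "Intercept",
                "CPF",
                "DZN",
                "Temp",
                "CPF:DZN",
                "CPF:Temp",
                "DZN:Temp",
                "CPF:DZN:Temp",
            ),
        )

    @classmethod
    def single_toxicant(cls) -> "ModelSpec":
        return cls(name="single", terms=("Intercept", "Toxicant"))


_COLUMN_SOURCES = {"CPF": "cpf", "DZN": "dzn", "Temp": "temp", "Toxicant": "toxicant"}


@dataclass
class DesignMatrix:
    """Design matrix with rank and aliasing report.

    ``aliased`` lists terms that are linear combinations of earlier terms
    (greedy elimination in fixed term order); ``estimable`` holds the
    remaining terms, whose columns form a full-rank basis.
    """

    X: np.ndarray
    terms: tuple[str, ...]
    observation_ids: pd.Index
    rank: int
    aliased: tuple[str, ...]
    estimable: tuple[str, ...] = field(init=False)
    X_estimable: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        keep = [t for t in self.terms if t not in self.aliased]
        self.estimable = tuple(keep)
        cols = [self.terms.index(t) for t in keep]
        self.X_estimable = self.X[:, cols]


def build_design(sample_sheet: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Build the 0/1-indicator design for a model spec.

    Columns follow the spec's fixed term order; aliased terms are detected
    by greedy rank elimination (a term is aliased iff adding its column to
    the columns of earlier non-aliased terms does not increase the rank).
    """
    if len(sample_sheet) == 0:
        raise ValueError("empty sample sheet")
    columns = []
    for term in spec.terms:
        if term == "Intercept":
            columns.append(np.ones(len(sample_sheet)))
            continue
        col = np.ones(len(sample_sheet))
        for part in term.split(":"):
            source = _COLUMN_SOURCES.get(part)
            if source is None or source not in sample_sheet.columns:
                raise ValueError(f"term {term!r}: no column for factor {part!r} in sample sheet")
            col = col * sample_sheet[source].to_numpy(dtype=float)
        columns.append(col)
    X = np.column_stack(columns)

    aliased: list[str] = []
    kept: list[int] = []
    rank = 0
    for j, term in enumerate(spec.terms):
        candidate = X[:, kept + [j]]
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept.append(j)
            rank = new_rank
        else:
            aliased.append(term)
    return DesignMatrix(
        X=X,
        terms=spec.terms,
        observation_ids=sample_sheet.index,
        rank=rank,
        aliased=tuple(aliased),
    )


@dataclass
class GeneFit:
    """OLS result for one gene: per-term estimate/se/p plus alias flags."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    aliased: tuple[str, ...]
    df_resid: int


def fit_gene_model(
    values: np.ndarray,
    mask: np.ndarray | None,
    design: DesignMatrix,
) -> GeneFit | str:
    """Fit one gene by OLS; returns a GeneFit or a skip-reason string.

    The response is restricted to unmasked, finite observations; aliased
    terms are flagged and carry NaN statistics.  Genes with residual df
    < 1 are skipped with reason ``"insufficient_df"``.
    """
    y = np.asarray(values, dtype=float)
    active = np.isfinite(y)
    if mask is not None:
        active &= ~np.asarray(mask, dtype=bool)
    Xe = design.X_estimable[active]
    ya = y[active]
    n_act, p = Xe.shape
    if n_act < p + 1 or np.linalg.matrix_rank(Xe) < p:
        return "insufficient_df"
    xtx = Xe.T @ Xe
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (Xe.T @ ya)
    resid = ya - Xe @ beta
    df_resid = n_act - p
    s2 = float(resid @ resid) / df_resid
    se = np.sqrt(np.clip(np.diag(xtx_inv) * s2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    p_val = np.clip(2.0 * stats.t.sf(np.abs(t_stat), df_resid), _P_FLOOR, 1.0)
    est = dict(zip(design.estimable, beta))
    ses = dict(zip(design.estimable, se))
    ps = dict(zip(design.estimable, p_val))
    for term in design.aliased:
        est[term] = np.nan
        ses[term] = np.nan
        ps[term] = np.nan
    return GeneFit(est, ses, ps, design.aliased, df_resid)


def _grouped_ols(values: np.ndarray, mask: np.ndarray, Xe: np.ndarray):
    """Vectorized OLS over genes grouped by identical missingness pattern.

    Yields ``(gene_rows, beta, se, p, df_resid)`` per pattern group, and a
    list of skipped gene rows.
    """
    n_genes, n_obs = values.shape
    active = np.isfinite(values) & ~mask
    p = Xe.shape[1]
    patterns: dict[bytes, list[int]] = {}
    for g in range(n_genes):
        patterns.setdefault(active[g].tobytes(), []).append(g)
    skipped: list[int] = []
    for key, gene_rows in patterns.items():
        act = np.frombuffer(key, dtype=bool)
        Xa = Xe[act]
        n_act = int(act.sum())
        if n_act < p + 1 or np.linalg.matrix_rank(Xa) < p:
            skipped.extend(gene_rows)
            continue
        xtx_inv = np.linalg.inv(Xa.T @ Xa)
        Y = values[np.ix_(gene_rows, np.nonzero(act)[0])]
        beta = Y @ Xa @ xtx_inv.T
        resid = Y - beta @ Xa.T
        df_resid = n_act - p
        s2 = np.einsum("ij,ij->i", resid, resid) / df_resid
        se = np.sqrt(np.clip(np.outer(s2, np.diag(xtx_inv)), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
        p_val = np.clip(2.0 * stats.t.sf(np.abs(t_stat), df_resid), _P_FLOOR, 1.0)
        yield gene_rows, beta, se, p_val, df_resid
    if skipped:
        yield skipped, None, None, None, None


def genome_scan(
    matrix: ExpressionMatrix,
    spec: ModelSpec,
    threshold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the model for every gene; one result row per gene x term.

    Returns ``(results, skipped)``.  ``results`` columns: gene_id, term,
    estimate, se, p_value, neglog10_p, significant, aliased.  Aliased
    terms are present with NaN statistics and ``aliased=True``.
    Deterministic given the inputs.
    """
    design = build_design(matrix.sample_sheet, spec)
    gene_index = matrix.values.index
    values = matrix.values.to_numpy(dtype=float)
    mask = matrix.mask.to_numpy(dtype=bool)
    frames = []
    skipped_rows = []
    terms_all = list(spec.terms)
    for gene_rows, beta, se, p_val, df_resid in _grouped_ols(
        values, mask, design.X_estimable
    ):
        if beta is None:
            skipped_rows.extend(
                {"gene_id": gene_index[g], "reason": "insufficient_df"} for g in gene_rows
            )
            continue
        gids = gene_index[gene_rows]
        n_g = len(gene_rows)
        est_full = np.full((n_g, len(terms_all)), np.nan)
        se_full = np.full((n_g, len(terms_all)), np.nan)
        p_full = np.full((n_g, len(terms_all)), np.nan)
        for j_est, term in enumerate(design.estimable):
            j = terms_all.index(term)
            est_full[:, j] = beta[:, j_est]
            se_full[:, j] = se[:, j_est]
            p_full[:, j] = p_val[:, j_est]
        frame = pd.DataFrame(
            {
                "gene_id": np.repeat(gids, len(terms_all)),
                "term": np.tile(terms_all, n_g),
                "estimate": est_full.ravel(),
                "se": se_full.ravel(),
                "p_value": p_full.ravel(),
            }
        )
        frames.append(frame)
    if frames:
        results = pd.concat(frames, ignore_index=True)
    else:
        results = pd.DataFrame(columns=["gene_id", "term", "estimate", "se", "p_value"])
    results["neglog10_p"] = -np.log10(results["p_value"].astype(float))
    results["significant"] = results["neglog10_p"] > threshold
    results["aliased"] = results["term"].isin(design.aliased)
    results.loc[results["aliased"], "significant"] = False
    results = results.sort_values(["gene_id", "term"], kind="stable").reset_index(drop=True)
    skipped = pd.DataFrame(skipped_rows, columns=["gene_id", "reason"])
    return results, skipped


@dataclass
class NullDistribution:
    """Per-term permutation p-values and the derived threshold metadata."""

    p_values: pd.DataFrame  # n_perm rows x estimable terms
    n_perm: int
    threshold: float
    spec_name: str

    def exceedances(self, threshold: float | None = None) -> pd.Series:
        """Count of null p-values at or below 10**-threshold, per term."""
        thr = self.threshold if threshold is None else threshold
        cutoff = 10.0 ** (-thr)
        return (self.p_values <= cutoff).sum()


def permutation_null(
    matrix: ExpressionMatrix,
    spec: ModelSpec,
    n_perm: int,
    seed: int,
    threshold: float = 2.0,
) -> NullDistribution:
    """Transcript-permutation null of per-term p-values.

    Each permutation draws one distinct transcript (without replacement),
    shuffles its unmasked values uniformly across its unmasked
    observations, refits the model and records the per-term p-values.
    """
    n_genes = matrix.values.shape[0]
    if n_perm > n_genes:
        raise ValueError(
            f"n_perm={n_perm} exceeds the {n_genes} available transcripts; "
            "each transcript may be picked only once - lower n_perm"
        )
    design = build_design(matrix.sample_sheet, spec)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_genes, size=n_perm, replace=False)
    values = matrix.values.to_numpy(dtype=float)
    mask = matrix.mask.to_numpy(dtype=bool)
    rows = []
    for g in chosen:
        y = values[g].copy()
        act = np.isfinite(y) & ~mask[g]
        idx = np.nonzero(act)[0]
        y[idx] = y[idx[rng.permutation(idx.size)]]
        fit = fit_gene_model(y, mask[g], design)
        if isinstance(fit, str):
            rows.append({t: np.nan for t in design.estimable})
        else:
            rows.append({t: fit.p_values[t] for t in design.estimable})
    p_df = pd.DataFrame(rows, columns=list(design.estimable))
    return NullDistribution(p_df, n_perm=n_perm, threshold=threshold, spec_name=spec.name)


def estimate_fdr(
    null: NullDistribution,
    observed: pd.DataFrame,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-term plug-in FDR at a -log10 p threshold.

    FDR(term) = [G * (#null p <= 10**-threshold) / n_perm] / R(term) where
    G is the number of genes tested for the term and R the number of
    observed rejections; NaN (with a note) when R = 0.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    cutoff = 10.0 ** (-threshold)
    rows = []
    for term in null.p_values.columns:
        obs_term = observed[(observed["term"] == term) & ~observed["aliased"]]
        obs_term = obs_term[np.isfinite(obs_term["p_value"])]
        n_tested = len(obs_term)
        rejections = int((obs_term["neglog10_p"] > threshold).sum())
        null_p = null.p_values[term].dropna()
        null_hits = int((null_p <= cutoff).sum())
        expected_false = n_tested * null_hits / len(null_p) if len(null_p) else np.nan
        if rejections > 0:
            fdr = expected_false / rejections
            note = ""
        else:
            fdr = np.nan
            note = "no rejections at threshold"
        rows.append(
            {
                "term": term,
                "genes_tested": n_tested,
                "rejections": rejections,
                "null_exceedances": null_hits,
                "n_perm": len(null_p),
                "fdr": fdr,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def select_significant(
    results: pd.DataFrame, threshold: float = 2.0
) -> dict[str, frozenset[str]]:
    """Gene sets with -log10 p strictly above the threshold, per term."""
    out: dict[str, frozenset[str]] = {}
    if len(results) == 0:
        return out
    for term, sub in results.groupby("term", sort=False):
        keep = sub[~sub["aliased"] & (sub["neglog10_p"] > threshold)]
        out[str(term)] = frozenset(keep["gene_id"])
    return out
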