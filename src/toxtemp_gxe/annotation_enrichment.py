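"""Hypergeometric over-representation of GO terms and protein domains.

Terms with fewer than a minimum number of member genes (default 4) are
discarded at load time.  The test universe defaults to the annotated
genes among the tested genes, and the significant-set size counts only
annotated significant genes, so k <= min(K, n) <= N always holds.  Raw
upper-tail hypergeometric p-values are compared against a fixed alpha; a
Benjamini-Hochberg column is emitted as supplementary output only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationSet",
    "load_annotations",
    "annotations_from_frame",
    "hypergeometric_pvalue",
    "enrich_gene_set",
]


@dataclass(frozen=True)
class AnnotationSet:
    """One term and its member gene set."""

    term_id: str
    term_type: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty member set")


def annotations_from_frame(
    mapping: pd.DataFrame,
    min_term_size: int = 4,
    term_type: str = "GO",
    descriptions: dict[str, str] | None = None,
) -> list[AnnotationSet]:
    """Build term sets from a two-column (gene_id, term_id) frame.

    Duplicate (gene, term) rows are deduplicated; terms with fewer than
    ``min_term_size`` member genes are discarded.
    """
    required = {"gene_id", "term_id"}
    if not required.issubset(mapping.columns):
        raise ValueError(f"annotation frame needs columns {sorted(required)}")
    descriptions = descriptions or {}
    out = []
    for term_id, sub in mapping.groupby("term_id", sort=True):
        genes = frozenset(sub["gene_id"].astype(str))
        if len(genes) < min_term_size:
            continue
        out.append(
            AnnotationSet(
                term_id=str(term_id),
                term_type=term_type,
                genes=genes,
                description=descriptions.get(str(term_id), ""),
            )
        )
    return out


def load_annotations(
    path,
    min_term_size: int = 4,
    term_type: str = "GO",
) -> list[AnnotationSet]:
    """Load a two-column gene->term TSV, applying the term-size filter.

    Malformed rows (wrong field count, blanks) are skipped; an empty file
    raises.
    """
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                continue
            if line_no == 1 and fields[0] in ("gene_id", "gene"):
                continue
            rows.append((fields[0], fields[1]))
    if not rows:
        raise ValueError(f"{path}: empty annotation file")
    frame = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    return annotations_from_frame(frame, min_term_size=min_term_size, term_type=term_type)


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def enrich_gene_set(
    sig_genes,
    universe,
    annotations: list[AnnotationSet],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every retained term in a gene set.

    ``n`` counts only significant genes inside the universe; terms are
    intersected with the universe and rows with fewer than 4 in-universe
    member genes are dropped.  Rows are sorted by ascending p-value.
    """
    universe = frozenset(map(str, universe))
    sig = frozenset(map(str, sig_genes)) & universe
    N = len(universe)
    n = len(sig)
    rows = []
    for ann in annotations:
        members = ann.genes & universe
        K = len(members)
        if K < 4:
            continue
        k = len(members & sig)
        p = hypergeometric_pvalue(k, K, n, N)
        rows.append(
            {
                "term_id": ann.term_id,
                "term_type": ann.term_type,
                "n_universe": N,
                "genes_in_term": K,
                "significant_tested": n,
                "significant_in_term": k,
                "p_value": p,
                "description": ann.description,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_type",
            "n_universe",
            "genes_in_term",
            "significant_tested",
            "significant_in_term",
            "p_value",
            "description",
        ],
    )
    if len(table):
        table["significant"] = table["p_value"] < alpha
        table["bh_fdr"] = _bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(
            ["p_value", "term_id"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["significant"] = pd.Series(dtype=bool)
        table["bh_fdr"] = pd.Series(dtype=float)
    return table
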