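"""Detoxification gene families: classification, counting and enrichment.

Six families are catalogued: CYP (cytochrome P450s), SDR (short-chain
dehydrogenases/reductases), UGT (UDP-glucuronosyl transferases, "UDP"
accepted as an alias), GST (glutathione S-transferases), ABC
(ATP-binding-cassette transporters) and NR (nuclear receptors).  A gene
belongs to a family iff it carries at least one of the family's listed
domain ids; NR membership comes from a curated gene list instead.  A
gene may belong to several families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .annotation_enrichment import hypergeometric_pvalue

__all__ = [
    "CATEGORIES",
    "DetoxVocabulary",
    "load_default_vocabulary",
    "classify_detox",
    "detox_counts_table",
    "detox_category_enrichment",
]

CATEGORIES: tuple[str, ...] = ("CYP", "SDR", "UGT", "GST", "ABC", "NR")

_ALIASES = {"UDP": "UGT"}


@dataclass
class DetoxVocabulary:
    """Domain-id lists per family plus the curated NR gene list."""

    domains: dict[str, tuple[str, ...]]
    nr_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        normalized: dict[str, tuple[str, ...]] = {}
        for category, ids in self.domains.items():
            category = _ALIASES.get(category, category)
            if category not in CATEGORIES:
                raise ValueError(f"unknown detox category {category!r}")
            normalized[category] = tuple(ids)
        self.domains = normalized


def load_default_vocabulary(nr_genes=()) -> DetoxVocabulary:
    """The vocabulary shipped with the package (NR list supplied by caller)."""
    text = resources.files("toxtemp_gxe").joinpath("data/detox_domains.yaml").read_text()
    raw = yaml.safe_load(text)
    raw.pop("NR", None)
    return DetoxVocabulary(domains=raw, nr_genes=frozenset(map(str, nr_genes)))


def classify_detox(
    domain_annotations: pd.DataFrame,
    vocab: DetoxVocabulary | None = None,
    nr_genes=None,
) -> dict[str, frozenset[str]]:
    """Family -> gene set from a (gene_id, term_id) domain annotation map.

    Classification is idempotent and independent of annotation row order.
    """
    vocab = vocab or load_default_vocabulary()
    required = {"gene_id", "term_id"}
    if not required.issubset(domain_annotations.columns):
        raise ValueError(f"domain annotation frame needs columns {sorted(required)}")
    by_domain: dict[str, set[str]] = {}
    for gene, term in zip(
        domain_annotations["gene_id"].astype(str), domain_annotations["term_id"].astype(str)
    ):
        by_domain.setdefault(term, set()).add(gene)
    out: dict[str, frozenset[str]] = {}
    for category in CATEGORIES:
        if category == "NR":
            members = frozenset(nr_genes) if nr_genes is not None else vocab.nr_genes
            out[category] = frozenset(map(str, members))
            continue
        genes: set[str] = set()
        for domain_id in vocab.domains.get(category, ()):
            genes |= by_domain.get(domain_id, set())
        out[category] = frozenset(genes)
    return out


def detox_counts_table(
    category_sets: dict[str, frozenset[str]],
    significant_sets: dict[str, frozenset[str]],
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Counts of detox genes inside each significant set, per family.

    One row per family plus a ``unique`` row counting the union over all
    families.  ``groups`` optionally adds columns counting unique genes
    over several significant sets (e.g. all treatments at one
    temperature).
    """
    columns = list(significant_sets)
    rows = {}
    for category, genes in category_sets.items():
        rows[category] = [len(genes & significant_sets[c]) for c in columns]
    all_detox = frozenset().union(*category_sets.values()) if category_sets else frozenset()
    rows["unique"] = [len(all_detox & significant_sets[c]) for c in columns]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "category"
    if groups:
        for group_name, members in groups.items():
            union = frozenset().union(*(significant_sets[m] for m in members))
            table[group_name] = [
                len((all_detox if cat == "unique" else category_sets[cat]) & union)
                for cat in table.index
            ]
    return table


def detox_category_enrichment(
    category_sets: dict[str, frozenset[str]],
    significant_sets: dict[str, frozenset[str]],
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment flags per (family x significant set)."""
    universe = frozenset(map(str, universe))
    N = len(universe)
    rows = []
    for set_name, sig in significant_sets.items():
        sig_u = frozenset(map(str, sig)) & universe
        n = len(sig_u)
        for category, genes in category_sets.items():
            members = frozenset(map(str, genes)) & universe
            K = len(members)
            k = len(members & sig_u)
            p = hypergeometric_pvalue(k, K, n, N) if K > 0 else 1.0
            rows.append(
                {
                    "category": category,
                    "set_name": set_name,
                    "genes_in_category": K,
                    "significant_tested": n,
                    "significant_in_category": k,
                    "p_value": p,
                    "enriched": p < alpha,
                }
            )
    return pd.DataFrame(rows)
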