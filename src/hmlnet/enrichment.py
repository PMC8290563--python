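"""Gene-set over-representation analysis with metabolic-category tagging.

The statistic is the upper-tail hypergeometric probability P(X >= k) of
drawing k or more gene-set members in a query of size n from a universe of
size N containing K set members — equivalently a one-sided Fisher exact
test.  An EASE-style variant (testing k - 1, the conservative modification
used by the DAVID web tool) is available but off by default.  Multiple
testing is controlled with Benjamini-Hochberg by default, with the raw
p < 0.05 rule available for comparison.

Gene sets are read from GMT files; metabolic category labels
(carbohydrate / lipid metabolism) come from a sidecar TSV and are
propagated to individual query genes via the significant sets that
contain them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("carbohydrate_metabolism", "lipid_metabolism", "other")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (KEGG-pathway style) with optional category tags."""

    set_id: str
    name: str
    members: frozenset[str]
    categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "categories", frozenset(self.categories))


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation statistics for one gene set.

    k of n query genes fall in the set, which has K members within the
    N-gene universe.
    """

    set_id: str
    k: int
    n: int
    K: int
    N: int
    pvalue: float
    p_adjusted: float = field(default=float("nan"))

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.pvalue))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); exactly 1.0 when k == 0."""
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_bh(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if any(not (0.0 <= p <= 1.0) for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(p) for p in adjusted]


def enrich(
    query: Iterable[str],
    sets: Iterable[GeneSet],
    universe: Iterable[str],
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation of ``query`` genes.

    Each set is intersected with the universe before testing; the query must
    be a subset of the universe.  With ``ease`` the tested overlap is k - 1
    (DAVID's conservative EASE score).  Results are sorted by p-value
    ascending, ties by set_id, with BH-adjusted p-values filled in across
    all tested sets.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = frozenset(query)
    outside = query - universe
    if outside:
        raise ValueError(
            f"query genes outside universe: {sorted(outside)[:10]}"
            + ("..." if len(outside) > 10 else "")
        )
    N, n = len(universe), len(query)
    results = []
    for gs in sets:
        members = gs.members & universe
        K = len(members)
        k = len(query & members)
        tested_k = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(tested_k, N, K, n)
        results.append(EnrichmentResult(set_id=gs.set_id, k=k, n=n, K=K, N=N, pvalue=p))
    results.sort(key=lambda r: (r.pvalue, r.set_id))
    adjusted = adjust_bh([r.pvalue for r in results])
    return [replace(r, p_adjusted=p_adj) for r, p_adj in zip(results, adjusted)]


def significant_sets(
    results: Iterable[EnrichmentResult],
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> list[EnrichmentResult]:
    """Results passing BH q < alpha (default) or raw p < alpha."""
    return [
        r
        for r in results
        if (r.p_adjusted if use_adjusted else r.pvalue) < alpha
    ]


def tag_categories(
    results: Iterable[EnrichmentResult],
    sets: Iterable[GeneSet],
    query: Iterable[str],
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> dict[str, frozenset[str]]:
    """Tag each query gene with the categories of significant sets holding it.

    A gene in both a carbohydrate-metabolism and a lipid-metabolism
    significant set carries both flags (the dual-category criterion used
    for hub shortlisting).  Genes in no significant set map to an empty set.
    """
    sets_by_id = {gs.set_id: gs for gs in sets}
    sig = significant_sets(results, alpha=alpha, use_adjusted=use_adjusted)
    tags: dict[str, set[str]] = {g: set() for g in query}
    for res in sig:
        gs = sets_by_id.get(res.set_id)
        if gs is None:
            continue
        for gene in gs.members:
            if gene in tags:
                tags[gene] |= gs.categories
    return {g: frozenset(c) for g, c in tags.items()}


def pathway_counts(
    sets: Iterable[GeneSet], genes: Iterable[str]
) -> dict[str, int]:
    """Number of gene sets containing each gene (the 'n pathways' statistic)."""
    genes = set(genes)
    counts = {g: 0 for g in genes}
    for gs in sets:
        for g in gs.members & genes:
            counts[g] += 1
    return counts


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (set_id, description, members...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f">= 1 member"
                )
            set_id, name, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(set_id=set_id, name=name or set_id, members=frozenset(members)))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def read_categories(path: str | Path) -> dict[str, frozenset[str]]:
    """Read the sidecar TSV mapping set_id to comma-separated categories."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected set_id<TAB>categories")
            cats = frozenset(c.strip() for c in fields[1].split(",") if c.strip())
            bad = cats - set(CATEGORIES)
            if bad:
                raise ValueError(f"{path}:{lineno}: unknown categories {sorted(bad)}")
            out[fields[0]] = cats
    return out


def apply_categories(
    sets: Iterable[GeneSet], categories: Mapping[str, frozenset[str]]
) -> list[GeneSet]:
    """Attach sidecar categories to gene sets by set_id."""
    return [
        replace(gs, categories=frozenset(categories.get(gs.set_id, ())))
        for gs in sets
    ]


def write_results_tsv(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tk\tn\tK\tN\tpvalue\tp_adjusted\tneg_log10_p\n")
        for r in results:
            fh.write(
                f"{r.set_id}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.pvalue:.6g}\t{r.p_adjusted:.6g}\t{r.neg_log10_p:.6g}\n"
            )
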