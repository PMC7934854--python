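"""Cross-comparison differential-expression combinatorics.

Given per-gene DE tables (gene, log2 fold change, BH-adjusted p) from two
comparisons over a shared universe — e.g. a treatment comparison and the
untreated degeneration time-course — these routines extract:

* genes significant in both comparisons with **opposite** fold-change signs
  (directional discordance: the treatment pushes the gene against the
  natural history of the degeneration, the signature of a direct rescue
  effect), and the same-sign (concordant) complement;
* one-sided hypergeometric over-representation of annotation terms in a
  study set, BH-corrected across terms;
* UpSet-style exclusive intersections across any number of named lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "DiscordanceResult",
    "EnrichmentResult",
    "IntersectionResult",
    "significant_set",
    "discordant_genes",
    "hypergeom_ora",
    "shared_terms",
]

_REQUIRED_COLS = ("gene", "log2fc", "padj")


@dataclass
class DiscordanceResult:
    discordant_up_in_a: frozenset[str]
    discordant_down_in_a: frozenset[str]
    concordant: frozenset[str]
    zero_sign: frozenset[str]  # significant in both but log2fc == 0 somewhere
    alpha: float

    @property
    def discordant(self) -> frozenset[str]:
        return self.discordant_up_in_a | self.discordant_down_in_a

    def to_dict(self) -> dict:
        return {
            "discordant_up_in_a": sorted(self.discordant_up_in_a),
            "discordant_down_in_a": sorted(self.discordant_down_in_a),
            "concordant": sorted(self.concordant),
            "zero_sign": sorted(self.zero_sign),
            "alpha": self.alpha,
        }


@dataclass
class EnrichmentResult:
    term: str
    k: int  # study genes annotated to the term
    K: int  # term size within the universe
    n: int  # study size
    N: int  # universe size
    p_hypergeometric: float
    q_bh: float


@dataclass
class IntersectionResult:
    """UpSet-style decomposition of named sets.

    ``regions`` maps each non-empty combination of list names (a sorted
    tuple) to the items present in exactly those lists; the regions
    partition the union.  ``full_intersection`` is the plain intersection
    of all lists.
    """

    names: tuple[str, ...]
    regions: dict[tuple[str, ...], frozenset]
    full_intersection: frozenset

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {combo: len(items) for combo, items in self.regions.items()}

    @property
    def union(self) -> frozenset:
        out: set = set()
        for items in self.regions.values():
            out |= items
        return frozenset(out)


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLS if c not in table.columns]
    if missing:
        raise ValidationError(f"DE table missing columns: {missing}")
    if table["gene"].duplicated().any():
        dup = table.loc[table["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"duplicate gene rows in one comparison (e.g. {dup!r})")
    bad = (table["padj"] < 0) | (table["padj"] > 1)
    if bad.any():
        raise ValidationError("padj values outside [0, 1]")
    return table


def significant_set(
    table: pd.DataFrame, alpha: float = 0.05, direction: str = "any"
) -> frozenset[str]:
    """Genes with ``padj < alpha`` whose log2fc sign matches ``direction``."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    if direction not in ("up", "down", "any"):
        raise ValidationError(f"direction must be 'up', 'down' or 'any', got {direction!r}")
    if len(table) == 0:
        return frozenset()
    table = _check_table(table)
    sig = table["padj"] < alpha
    if direction == "up":
        sig &= table["log2fc"] > 0
    elif direction == "down":
        sig &= table["log2fc"] < 0
    return frozenset(table.loc[sig, "gene"])


def discordant_genes(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> DiscordanceResult:
    """Partition genes significant in both tables by fold-change sign pattern.

    Genes with a zero fold change while significant in both are reported
    separately (their direction is undefined) and excluded from every
    partition.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    a = _check_table(table_a)
    b = _check_table(table_b)
    m = a.merge(b, on="gene", suffixes=("_a", "_b"))
    both = (m["padj_a"] < alpha) & (m["padj_b"] < alpha)
    m = m.loc[both]
    sa = np.sign(m["log2fc_a"].to_numpy())
    sb = np.sign(m["log2fc_b"].to_numpy())
    genes = m["gene"].to_numpy()
    zero = (sa == 0) | (sb == 0)
    return DiscordanceResult(
        discordant_up_in_a=frozenset(genes[(sa > 0) & (sb < 0)]),
        discordant_down_in_a=frozenset(genes[(sa < 0) & (sb > 0)]),
        concordant=frozenset(genes[~zero & (sa == sb)]),
        zero_sign=frozenset(genes[zero]),
        alpha=alpha,
    )


def _term_sets(term_map) -> dict[str, frozenset]:
    if isinstance(term_map, pd.DataFrame):
        if not {"gene", "term"} <= set(term_map.columns):
            raise ValidationError("term map needs columns 'gene' and 'term'")
        return {
            t: frozenset(g) for t, g in term_map.groupby("term")["gene"]
        }
    if isinstance(term_map, Mapping):
        return {t: frozenset(g) for t, g in term_map.items()}
    raise ValidationError("term_map must be a DataFrame or mapping term -> genes")


def hypergeom_ora(
    study: Iterable[str],
    term_map,
    universe: Iterable[str],
    min_term_size: int = 1,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation of terms in a study set.

    For each term with K >= ``min_term_size`` annotated genes in the
    universe, p = P(X >= k) for X ~ Hypergeometric(N, K, n) where k is the
    overlap with the study set; q is BH-corrected across the tested terms.
    Results are sorted by p (ties by term name).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("empty universe")
    study = frozenset(study)
    if not study <= universe:
        extra = sorted(study - universe)[:3]
        raise ValidationError(f"study genes outside universe, e.g. {extra}")
    N, n = len(universe), len(study)
    results: list[EnrichmentResult] = []
    for term, genes in sorted(_term_sets(term_map).items()):
        members = genes & universe
        K = len(members)
        if K == 0 or K < min_term_size:
            continue
        k = len(members & study)
        # survival function at k-1 gives P(X >= k); k = 0 -> 1 exactly
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, K, n, N, min(max(p, 0.0), 1.0), np.nan))
    if results:
        q = multipletests([r.p_hypergeometric for r in results], method="fdr_bh")[1]
        for r, qi in zip(results, q):
            r.q_bh = float(qi)
    results.sort(key=lambda r: (r.p_hypergeometric, r.term))
    return results


def shared_terms(term_lists: Mapping[str, Iterable]) -> IntersectionResult:
    """UpSet-style exclusive intersections of >= 2 named lists.

    Every item of the union is assigned to the region of exactly the lists
    containing it, so the regions partition the union.
    """
    if len(term_lists) < 2:
        raise ValidationError("need at least two lists")
    sets = {name: frozenset(items) for name, items in term_lists.items()}
    names = tuple(sets)
    regions: dict[tuple[str, ...], set] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[tuple(sorted(combo))] = set()
    for item in frozenset().union(*sets.values()):
        membership = tuple(sorted(n for n in names if item in sets[n]))
        regions[membership].add(item)
    full = frozenset.intersection(*sets.values())
    return IntersectionResult(
        names=names,
        regions={combo: frozenset(items) for combo, items in regions.items()},
        full_intersection=full,
    )
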