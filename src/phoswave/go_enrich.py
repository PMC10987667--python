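"""Over-representation analysis against a user-supplied term->gene mapping.

p is the upper-tail (cumulative) hypergeometric probability of drawing at
least the observed overlap; q is Benjamini-Hochberg across the tested
terms.  Significance is reported at raw p < alpha, mirroring analyses that
threshold the uncorrected p, with q available for stricter use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermMap:
    """Annotation terms over a gene universe; every term is a subset."""

    terms: Mapping[str, frozenset[str]]
    names: Mapping[str, str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty universe")
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} has genes outside universe")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        universe: Iterable[str] | None = None,
        names: Mapping[str, str] | None = None,
    ) -> "TermMap":
        """Build from (term, gene) pairs; universe defaults to the union."""
        terms: dict[str, set[str]] = {}
        for term, gene in pairs:
            terms.setdefault(term, set()).add(gene)
        if universe is None:
            uni = frozenset().union(*terms.values()) if terms else frozenset()
        else:
            uni = frozenset(universe)
            terms = {t: g & uni for t, g in terms.items()}
        return cls(
            terms={t: frozenset(g) for t, g in terms.items()},
            names=dict(names or {}),
            universe=uni,
        )

    @classmethod
    def from_tsv(cls, path: str | Path,
                 universe: Iterable[str] | None = None) -> "TermMap":
        """Two-column (term TAB gene) TSV, optional third column = term name."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype=str).dropna(how="all")
        names = {}
        if df.shape[1] >= 3:
            names = dict(zip(df[0], df[2].fillna("")))
        pairs = list(zip(df[0], df[1]))
        return cls.from_pairs(pairs, universe=universe, names=names)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    foreground: Iterable[str],
    term_map: TermMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the foreground.

    Columns: term, name, k (overlap), K (term size), n (foreground size),
    N (universe size), p_value, q_value (BH), significant (p < alpha).
    Foreground genes outside the universe are logged and dropped.
    """
    fg = set(foreground)
    if not fg:
        raise ValueError("empty foreground")
    stray = fg - term_map.universe
    if stray:
        log.warning("dropping %d foreground genes outside the universe",
                    len(stray))
        fg -= stray
    if not fg:
        raise ValueError("no foreground genes inside the universe")
    N = len(term_map.universe)
    n = len(fg)
    rows = []
    for term in sorted(term_map.terms):
        genes = term_map.terms[term]
        K = len(genes)
        k = len(fg & genes)
        rows.append({
            "term": term,
            "name": term_map.names.get(term, ""),
            "k": k, "K": K, "n": n, "N": N,
            "p_value": hypergeom_upper_tail(k, K, n, N),
        })
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_value"] < alpha
    return out


def signed_log10_p(results: pd.DataFrame,
                   direction: Mapping[str, str]) -> pd.Series:
    """+log10 p for terms tied to increased groups, -log10 p for decreased."""
    sign = results["term"].map(
        lambda t: 1.0 if direction.get(t, "increased") == "increased"
        else -1.0
    )
    return sign * np.log10(results["p_value"].clip(lower=1e-300)).abs()
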