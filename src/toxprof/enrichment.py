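"""Term over-representation analysis for screen hits.

Tests whether a gene list (e.g. the chromate-sensitive mutants from a
pooled-library screen) is enriched for annotation terms relative to a fixed
background universe (the deletion collection, or all protein-coding genes),
using the hypergeometric upper-tail probability with Bonferroni correction.

Only over-representation (the upper tail) is tested: the screen logic is
one-sided — a term can be *required* for toxin resistance, and depletion of
a term from a sensitivity list carries no analogous meaning here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationSet",
    "hypergeom_tail",
    "enrich_terms",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class AnnotationSet:
    """Term -> gene-set annotations over a fixed background universe.

    Parameters
    ----------
    terms
        Mapping from term identifier to the genes annotated to it.
    background
        The gene universe the enrichment p-values condition on (size N).
        Every annotated gene must belong to it.
    descriptions
        Optional term descriptions (carried through to GMT output).
    """

    terms: Mapping[str, frozenset]
    background: frozenset
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        terms = {t: frozenset(g) for t, g in self.terms.items()}
        background = frozenset(self.background)
        for term, genes in terms.items():
            if len(genes) < 1:
                raise ValueError(f"term {term!r} is empty; term sizes must be >= 1")
            stray = genes - background
            if stray:
                raise ValueError(
                    f"term {term!r} contains {len(stray)} gene(s) outside the "
                    f"background universe (e.g. {sorted(stray)[0]!r})"
                )
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "background", background)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def background_size(self) -> int:
        return len(self.background)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap between a random size-``n`` draw (the gene list)
    and a fixed size-``K`` term, both from a universe of ``N`` genes.
    Evaluated through the survival function of the hypergeometric
    distribution, which scipy computes from log-space terms, so values far
    below double-precision epsilon of 1 (e.g. 1e-17) remain accurate.

    By exchangeability of list and term, ``hypergeom_tail(k, n, K, N) ==
    hypergeom_tail(k, K, n, N)``.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if min(k, n, K, N) < 0:
        raise ValueError("counts must be non-negative")
    if n > N or K > N:
        raise ValueError(f"list size n={n} and term size K={K} must not exceed N={N}")
    if k > min(n, K):
        raise ValueError(f"overlap k={k} exceeds min(n, K)={min(n, K)}")
    # sf(k-1) = P(X >= k); k = 0 gives the full tail, exactly 1.
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    gene_list: Iterable[str],
    annotations: AnnotationSet,
    alpha: float = 0.01,
    min_term_size: int = 1,
    max_term_size: int | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected hypergeometric enrichment of ``gene_list``.

    Genes absent from the background are dropped with a warning rather than
    grafted on: silently growing the universe would bias every p-value.
    The Bonferroni divisor ``m`` is the number of terms actually tested
    (those within the configured size bounds), and is recorded on the
    result as ``df.attrs["m_tested"]``.

    Returns a DataFrame with one row per tested term, sorted by corrected
    p-value, with columns term, k, n, K, N, p_raw, p_corrected, significant
    and genes (the overlap, comma-joined).
    """
    genes = list(dict.fromkeys(gene_list))  # preserve order, drop dups
    if not genes:
        raise ValueError("gene list is empty")
    if annotations.n_terms == 0:
        raise ValueError("annotation set has no terms")
    in_bg = [g for g in genes if g in annotations.background]
    dropped = len(genes) - len(in_bg)
    if dropped:
        warnings.warn(
            f"{dropped} of {len(genes)} list genes are absent from the "
            "background universe and were dropped",
            stacklevel=2,
        )
    if not in_bg:
        raise ValueError("no list gene is present in the background universe")

    query = frozenset(in_bg)
    n = len(query)
    N = annotations.background_size

    tested = {
        term: members
        for term, members in annotations.terms.items()
        if len(members) >= min_term_size
        and (max_term_size is None or len(members) <= max_term_size)
    }
    m = len(tested)
    if m == 0:
        raise ValueError("no term passes the size bounds")

    rows = []
    for term, members in tested.items():
        overlap = query & members
        k, K = len(overlap), len(members)
        p = hypergeom_tail(k, n, K, N)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_raw": p,
                "p_corrected": min(1.0, m * p),
                "genes": ",".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["p_corrected", "p_raw", "term"], kind="mergesort", ignore_index=True
    )
    df["significant"] = df["p_corrected"] <= alpha
    df.attrs["m_tested"] = m
    df.attrs["alpha"] = alpha
    return df


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> AnnotationSet:
    """Read GMT (term <tab> description <tab> gene...) into an AnnotationSet.

    If ``background`` is not given, the union of all term genes is used —
    adequate for round-trips, but a screen analysis should pass the true
    deletion-collection universe explicitly.
    """
    terms: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term, desc, genes = fields[0], fields[1], fields[2:]
            terms[term] = frozenset(g for g in genes if g)
            descriptions[term] = desc
    bg = frozenset(background) if background is not None else frozenset().union(*terms.values())
    return AnnotationSet(terms=terms, background=bg, descriptions=descriptions)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations.terms):
            desc = annotations.descriptions.get(term, "")
            genes = "\t".join(sorted(annotations.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")
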