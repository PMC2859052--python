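"""Cancer-gene enrichment among lncRNA-producing genes.

The question: do protein-coding genes that give rise to lncRNAs carry cancer
annotations more often than protein-coding genes at large? The counts form a
2x2 contingency table and are tested two ways, as is conventional for gene-set
over-representation:

* Pearson chi-square with Yates continuity correction on the disjoint table
  [(k, n-k), (K-k, (N-n)-(K-k))] (host genes removed from the background
  row); the uncorrected statistic is also reported for transparency.
* Exact hypergeometric probability of drawing exactly k annotated genes when
  n are drawn from N containing K annotated (the point mass P(X = k)); the
  proper upper tail P(X >= k) is provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from scipy import stats

from lncsieve.models import CancerGeneSet


@dataclass
class ContingencyTable:
    """k of n lncRNA-host genes vs K of N genome-wide genes cancer-annotated."""

    k: int  # cancer-annotated lncRNA-host genes
    n: int  # lncRNA-host genes
    K: int  # cancer-annotated genes genome-wide
    N: int  # genes genome-wide

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n and 0 <= self.K <= self.N):
            raise ValueError(f"inconsistent table {self}")
        if self.k > self.K or self.n > self.N:
            raise ValueError(f"inconsistent table {self}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """Disjoint 2x2 cells: (k, n-k, K-k, N-n-(K-k))."""
        return (self.k, self.n - self.k, self.K - self.k, self.N - self.n - (self.K - self.k))


def build_table(
    host_genes: list[str], all_genes: list[str], cancer: CancerGeneSet
) -> ContingencyTable:
    """Count cancer annotations among lncRNA-host genes and all genes."""
    hosts = set(host_genes)
    universe = set(all_genes)
    missing = hosts - universe
    if missing:
        raise ValueError(f"host genes not in gene universe: {sorted(missing)[:5]}")
    return ContingencyTable(
        k=len(hosts & cancer.gene_ids),
        n=len(hosts),
        K=len(universe & cancer.gene_ids),
        N=len(universe),
    )


def chi_square_test(
    table: ContingencyTable, correction: bool = True
) -> tuple[Optional[float], Optional[float]]:
    """Pearson chi-square (df=1, two-sided) on the disjoint 2x2.

    Yates continuity correction (|O-E|-0.5 clamped at 0) by default. Returns
    (None, None) when any expected cell is zero (test undefined).
    """
    a, b, c, d = table.cells
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in disjoint table")
    obs = [[a, b], [c, d]]
    tot = a + b + c + d
    if tot == 0:
        return None, None
    exp = [
        [(a + b) * (a + c) / tot, (a + b) * (b + d) / tot],
        [(c + d) * (a + c) / tot, (c + d) * (b + d) / tot],
    ]
    if min(min(row) for row in exp) == 0:
        return None, None
    stat = 0.0
    for i in range(2):
        for j in range(2):
            dev = abs(obs[i][j] - exp[i][j])
            if correction:
                dev = max(dev - 0.5, 0.0)
            stat += dev * dev / exp[i][j]
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def hypergeom_point(table: ContingencyTable) -> float:
    """Exact point mass P(X = k) for n draws from N containing K successes."""
    return float(stats.hypergeom(table.N, table.K, table.n).pmf(table.k))


def hypergeom_tail(table: ContingencyTable) -> float:
    """Upper tail P(X >= k), the standard one-sided enrichment p-value."""
    if table.k == 0:
        return 1.0
    return float(stats.hypergeom(table.N, table.K, table.n).sf(table.k - 1))


def enrichment_report(table: ContingencyTable) -> dict:
    """Both fractions (integer-rounded percentages) and all four statistics."""
    stat_c, p_c = chi_square_test(table, correction=True)
    stat_u, p_u = chi_square_test(table, correction=False)
    host_pct = round(100.0 * table.k / table.n) if table.n else 0
    bg_pct = round(100.0 * table.K / table.N) if table.N else 0
    return {
        "k": table.k,
        "n": table.n,
        "K": table.K,
        "N": table.N,
        "host_cancer_percent": host_pct,
        "background_cancer_percent": bg_pct,
        "chi2_yates": stat_c,
        "chi2_yates_p": p_c,
        "chi2_uncorrected": stat_u,
        "chi2_uncorrected_p": p_u,
        "hypergeom_point_p": hypergeom_point(table),
        "hypergeom_tail_p": hypergeom_tail(table),
    }
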