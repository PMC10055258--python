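"""Interaction-network construction, centralities, and the statistical tests
used alongside the DAmFRET analyses.

The network is built from a physical protein-protein edge list (e.g. a
STRING export) keeping edges with confidence score >= 900, as a simple
undirected graph.  A protein with several domains is labelled discontinuous
if any of its domains is.  Degree and betweenness centrality are computed in
both raw and normalized conventions.

Statistics: Mann-Whitney U (midrank ties, two-sided), Pearson chi-square on
2x2 tables with Cramer's V = sqrt(X^2/n) (no continuity correction by
default), Spearman rank correlation, Wald binomial confidence intervals, a
power-law fit by ordinary least squares in log-log space with a pointwise
95% confidence band, and Ward hierarchical clustering of screen matrices on
a log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import chi2_contingency, mannwhitneyu, spearmanr
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TestResult",
    "build_network",
    "protein_label_from_domains",
    "centralities",
    "mann_whitney",
    "chi_square_2x2",
    "cramers_v_from_chi2",
    "spearman",
    "wald_ci",
    "loglog_powerlaw_fit",
    "cluster_interaction_matrix",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    effect_size: float | None = None
    n: tuple | None = None


def protein_label_from_domains(domain_labels) -> str:
    """A protein is discontinuous if any of its domains is discontinuous."""
    labels = list(domain_labels)
    if not labels:
        raise ValueError("no domain labels")
    return "discontinuous" if "discontinuous" in labels else "continuous"


def build_network(
    edges: pd.DataFrame,
    min_score: float = 900.0,
    node_attributes: dict | None = None,
) -> nx.Graph:
    """Simple undirected graph from a scored edge list.

    ``edges`` has columns ``protein_a, protein_b, score``; edges below
    ``min_score`` are dropped (the threshold is inclusive), self-loops are
    removed, and duplicate edges keep the maximum score.  Malformed rows are
    recorded on the graph (``G.graph['skipped_rows']``) and skipped.
    """
    g = nx.Graph()
    skipped = 0
    for row in edges.itertuples(index=False):
        try:
            a, b = str(row.protein_a), str(row.protein_b)
            score = float(row.score)
        except (AttributeError, TypeError, ValueError):
            skipped += 1
            continue
        if not np.isfinite(score) or a == "" or b == "":
            skipped += 1
            continue
        if score < min_score or a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    g.graph["skipped_rows"] = skipped
    if node_attributes:
        for key, mapping in node_attributes.items():
            nx.set_node_attributes(g, mapping, key)
    return g


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree and betweenness centrality, raw and normalized.

    Normalized degree is degree/(n-1); normalized betweenness divides by
    (n-1)(n-2)/2, the number of node pairs that could route through a given
    node in an undirected graph.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = dict(g.degree())
    deg_c = nx.degree_centrality(g) if g.number_of_nodes() > 1 else {n: 0.0 for n in g}
    btw_raw = nx.betweenness_centrality(g, normalized=False)
    btw = nx.betweenness_centrality(g, normalized=True)
    return pd.DataFrame(
        {
            "node": list(g.nodes),
            "degree": [deg[n] for n in g.nodes],
            "degree_centrality": [deg_c[n] for n in g.nodes],
            "betweenness_raw": [btw_raw[n] for n in g.nodes],
            "betweenness_centrality": [btw[n] for n in g.nodes],
        }
    )


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U (midranks for ties; U reported for ``x``).

    Uses the exact distribution for small untied samples, otherwise the
    tie-corrected normal approximation.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), n=(x.size, y.size))


def cramers_v_from_chi2(chi2: float, n: int) -> float:
    """Cramer's V for a 2x2 table: sqrt(X^2 / n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(np.sqrt(chi2 / n))


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 contingency table with Cramer's V.

    Yates continuity correction is off by default (V = sqrt(X^2/n) is then
    self-consistent with the reported statistic); pass ``correction=True``
    to enable it.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    n = t.sum()
    chi2, p, _, _ = chi2_contingency(t, correction=correction)
    return TestResult(float(chi2), float(p), cramers_v_from_chi2(chi2, int(n)), (int(n),))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (midrank ties), two-tailed p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3:
        raise ValueError("Spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input")
    rho, p = spearmanr(x, y)
    return TestResult(float(rho), float(p), n=(x.size,))


def wald_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald (normal-approximation) binomial confidence interval, clipped to
    [0, 1]."""
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="normal")
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float  # log10 scale
    slope_ci: tuple[float, float]
    band_x: np.ndarray  # original units
    band_lo: np.ndarray
    band_hi: np.ndarray
    spearman_rho: float
    spearman_p: float


def loglog_powerlaw_fit(x, y, level: float = 0.95) -> PowerLawFit:
    """Power-law fit y = 10**b * x**m by OLS in log-log space.

    Returns the slope/intercept, the slope confidence interval, a pointwise
    confidence band for the mean line (original units), and the Spearman
    correlation of the raw data.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive x and y")
    if x.size < 3:
        raise ValueError("need n >= 3")
    lx, ly = np.log10(x), np.log10(y)
    model = sm.OLS(ly, sm.add_constant(lx)).fit()
    grid = np.linspace(lx.min(), lx.max(), 100)
    pred = model.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(alpha=1 - level)
    rho, p = spearmanr(x, y)
    ci = model.conf_int(alpha=1 - level)
    return PowerLawFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        band_x=10.0**grid,
        band_lo=10.0 ** band[:, 0],
        band_hi=10.0 ** band[:, 1],
        spearman_rho=float(rho),
        spearman_p=float(p),
    )


def cluster_interaction_matrix(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical clustering of a seedability matrix on a log scale.

    Zeros are replaced by a pseudocount of (smallest positive value)/10
    before the log.  Returns (row_order, col_order) leaf indices.
    """
    m = np.asarray(matrix, float)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("matrix must be at least 2x2")
    if np.all(m == m.flat[0]):
        raise ValueError("all-equal matrix cannot be clustered")
    pos = m[m > 0]
    pseudo = pos.min() / 10.0 if pos.size else 1.0
    lm = np.log10(np.where(m > 0, m, pseudo))
    row_order = leaves_list(linkage(lm, method="ward"))
    col_order = leaves_list(linkage(lm.T, method="ward"))
    return row_order, col_order
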