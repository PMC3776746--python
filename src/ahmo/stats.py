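"""Statistical comparison machinery for the two-atlas evaluation.

Paired t-tests with Bonferroni correction compare per-edge / per-node /
global measures between parcellations across subjects; inter-atlas
"linearity" is the Pearson correlation of a measure across subjects with a
significance cutoff obtained by inverting the t test; the atlas-by-group
interaction of a mixed two-by-two design is tested exactly via the
difference-score equivalence (a two-sample t on per-subject atlas
differences; F = t^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("ahmo")

__all__ = [
    "ComparisonTable",
    "paired_ttest_bonferroni",
    "linearity",
    "pearson_r_crit",
    "atlas_group_interaction",
    "threshold_sweep",
]


@dataclass
class ComparisonTable:
    """Column-wise paired t-test results with Bonferroni-corrected p values."""

    t: np.ndarray
    p: np.ndarray
    p_bonf: np.ndarray
    df: int
    direction: np.ndarray  # sign of mean(a - b)

    def to_frame(self, labels=None) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t, "p": self.p, "p_bonf": self.p_bonf,
                           "direction": self.direction})
        if labels is not None:
            df.insert(0, "label", list(labels))
        return df


def paired_ttest_bonferroni(a: np.ndarray, b: np.ndarray,
                            m_tests: int | None = None) -> ComparisonTable:
    """Classic paired t per column of (subjects x m) matrices a and b.

    Two-sided p from the t distribution with df = n - 1; Bonferroni
    correction multiplies by ``m_tests`` (default: the number of columns) and
    caps at 1.  Zero-variance difference columns get t = 0, p = 1 (flagged).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("a and b must have matching shapes")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a paired t-test")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    df = n - 1
    t = np.zeros_like(mean)
    p = np.ones_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2 * sps.t.sf(np.abs(t[ok]), df)
    if np.any(~ok):
        logger.warning("%d zero-variance difference column(s); p set to 1",
                       int((~ok).sum()))
    m = m_tests if m_tests is not None else d.shape[1]
    p_bonf = np.minimum(1.0, p * m)
    return ComparisonTable(t=t, p=p, p_bonf=p_bonf, df=df,
                           direction=np.sign(mean))


def pearson_r_crit(n: int, alpha: float = 0.05, m_tests: int = 1) -> float:
    """Critical |r| for a two-sided Pearson test at alpha / m_tests, df=n-2."""
    if n < 4:
        raise ValueError("need n >= 4")
    df = n - 2
    t_crit = sps.t.ppf(1 - (alpha / m_tests) / 2, df)
    return float(t_crit / np.sqrt(df + t_crit ** 2))


def linearity(a: np.ndarray, b: np.ndarray, alpha: float = 0.05,
              m_tests: int = 1) -> tuple:
    """Pearson linearity between paired subject vectors.

    Returns ``(r, r_crit, significant)`` where ``r_crit`` inverts the
    two-sided t test at ``alpha / m_tests`` with n - 2 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be matching 1D vectors")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input to linearity")
    r = float(np.corrcoef(a, b)[0, 1])
    r_crit = pearson_r_crit(a.size, alpha=alpha, m_tests=m_tests)
    return r, r_crit, bool(abs(r) > r_crit)


def atlas_group_interaction(vals: np.ndarray, group: np.ndarray) -> tuple:
    """Atlas-by-group interaction of a 2 (within) x 2 (between) design.

    ``vals`` is (subjects, 2): the measure under atlas A and atlas B;
    ``group`` a binary per-subject label.  With a two-level within factor the
    mixed-design interaction F equals the squared two-sample (pooled) t on
    the per-subject differences.  Returns ``(F, p)``.
    """
    vals = np.asarray(vals, dtype=float)
    group = np.asarray(group)
    if vals.ndim != 2 or vals.shape[1] != 2:
        raise ValueError("vals must be (subjects, 2)")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("group must have exactly 2 levels")
    d = vals[:, 0] - vals[:, 1]
    d0, d1 = d[group == levels[0]], d[group == levels[1]]
    if len(d0) < 2 or len(d1) < 2:
        raise ValueError("each group needs at least 2 subjects")
    t, p = sps.ttest_ind(d0, d1, equal_var=True)
    return float(t ** 2), float(p)


def threshold_sweep(graphs_a: list, graphs_b: list, thresholds,
                    metric_fns: dict) -> pd.DataFrame:
    """Inter-atlas linearity of global measures across a threshold sweep.

    For each network-forming threshold, both subject graph sets are
    thresholded, each metric in ``metric_fns`` (name -> callable on a
    WeightedGraph) is computed per subject, and the across-subject Pearson
    linearity between the two parcellations is tabulated.
    """
    from .graphs import threshold_graph

    if len(graphs_a) != len(graphs_b):
        raise ValueError("need one graph per subject for both parcellations")
    rows = []
    for z in thresholds:
        ga = [threshold_graph(g, z) for g in graphs_a]
        gb = [threshold_graph(g, z) for g in graphs_b]
        for name, fn in metric_fns.items():
            va = np.array([fn(g) for g in ga])
            vb = np.array([fn(g) for g in gb])
            r, r_crit, sig = linearity(va, vb)
            rows.append({"threshold": z, "metric": name, "r": r,
                         "r_crit": r_crit, "significant": sig})
    return pd.DataFrame(rows)
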