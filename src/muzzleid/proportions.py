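"""Inferential layer: exact binomial CIs and multiple-proportion comparison.

Per-category accuracies are binomial proportions (correct decisions out of
evaluated pairs).  Their confidence limits use the exact beta-distribution
(Clopper-Pearson) interval.  Categories are compared pairwise with a
Tukey-type studentized-range test on arcsine-square-root variance-stabilized
proportions; groups whose pairwise differences are not significant share a
homogeneity letter (compact letter display).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import studentized_range

from .errors import MuzzleIdError


@dataclass(frozen=True)
class ProportionSample:
    label: str
    successes: int
    trials: int

    def __post_init__(self):
        if self.trials <= 0:
            raise MuzzleIdError(f"{self.label!r}: trials must be positive")
        if not (0 <= self.successes <= self.trials):
            raise MuzzleIdError(
                f"{self.label!r}: successes {self.successes} outside [0, {self.trials}]"
            )

    @property
    def p(self) -> float:
        return self.successes / self.trials


@dataclass(frozen=True)
class BetaCI:
    lower: float
    upper: float
    alpha: float = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    q: float
    p_value: float
    significant: bool


def clopper_pearson_ci(sample: ProportionSample, alpha: float = 0.05) -> BetaCI:
    """Exact (beta-quantile) two-sided confidence interval for a proportion.

    ``lower = Beta^{-1}(alpha/2; x, n-x+1)`` (0 when x = 0) and
    ``upper = Beta^{-1}(1-alpha/2; x+1, n-x)`` (1 when x = n).
    """
    x, n = sample.successes, sample.trials
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return BetaCI(lower=lower, upper=upper, alpha=alpha)


def _phi(p: float) -> float:
    """Arcsine-square-root variance-stabilizing transform, Var ~ 1/(4n)."""
    return 2.0 * math.asin(math.sqrt(p))


def pairwise_q(a: ProportionSample, b: ProportionSample) -> float:
    """Studentized-range statistic for one pair of proportions."""
    return math.sqrt(2.0) * (_phi(a.p) - _phi(b.p)) / math.sqrt(1.0 / a.trials + 1.0 / b.trials)


def compare_proportions(
    samples: Sequence[ProportionSample], alpha: float = 0.05
) -> tuple[list[ComparisonResult], dict[str, str]]:
    """All pairwise Tukey-type comparisons plus homogeneity letters.

    Each proportion is stabilized as ``phi = 2 asin(sqrt(p))``; the pair
    statistic is ``q = sqrt(2) (phi_i - phi_j) / sqrt(1/n_i + 1/n_j)`` with
    the p-value taken from the studentized-range distribution for k groups
    at infinite degrees of freedom.  Letters come from a compact letter
    display over the non-significant graph (variants sharing a letter are
    not statistically different).
    """
    if len(samples) < 2:
        raise MuzzleIdError("need at least 2 proportion samples to compare")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise MuzzleIdError("proportion sample labels must be unique")
    k = len(samples)
    results: list[ComparisonResult] = []
    ns_edges = {lbl: {lbl} for lbl in labels}
    for i in range(k):
        for j in range(i + 1, k):
            q = pairwise_q(samples[i], samples[j])
            p = float(studentized_range.sf(abs(q), k, np.inf))
            sig = p < alpha
            results.append(
                ComparisonResult(pair=(labels[i], labels[j]), q=q, p_value=p, significant=sig)
            )
            if not sig:
                ns_edges[labels[i]].add(labels[j])
                ns_edges[labels[j]].add(labels[i])
    letters = _compact_letter_display(labels, ns_edges)
    return results, letters


def _compact_letter_display(
    labels: Sequence[str], ns_edges: dict[str, set[str]]
) -> dict[str, str]:
    """Assign shared letters to maximal cliques of the non-significant graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(labels)
    for a, nbrs in ns_edges.items():
        for b in nbrs:
            if a != b:
                g.add_edge(a, b)
    order = {lbl: i for i, lbl in enumerate(labels)}
    cliques = sorted(
        (sorted(c, key=order.get) for c in nx.find_cliques(g)),
        key=lambda c: order[c[0]],
    )
    letters: dict[str, list[str]] = {lbl: [] for lbl in labels}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for lbl in clique:
            letters[lbl].append(letter)
    return {lbl: "".join(ls) for lbl, ls in letters.items()}


def write_comparison_report(
    samples: Sequence[ProportionSample],
    out_dir: str | Path,
    alpha: float = 0.05,
    plot: bool = True,
) -> dict:
    """Write the CI table, pairwise table and homogeneity bar plot.

    Returns the computed tables (also written as CSV under ``out_dir``).
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results, letters = compare_proportions(samples, alpha=alpha)
    ci_rows = []
    for s in samples:
        ci = clopper_pearson_ci(s, alpha=alpha)
        ci_rows.append(
            {
                "label": s.label,
                "proportion": s.p,
                "ci_lower": ci.lower,
                "ci_upper": ci.upper,
                "letters": letters[s.label],
            }
        )
    ci_table = pd.DataFrame(ci_rows)
    cmp_table = pd.DataFrame(
        {
            "label_a": [r.pair[0] for r in results],
            "label_b": [r.pair[1] for r in results],
            "q": [r.q for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
    ci_table.to_csv(out_dir / "category_confidence_intervals.csv", index=False)
    cmp_table.to_csv(out_dir / "pairwise_comparisons.csv", index=False)
    if plot:
        _plot_homogeneity(ci_table, out_dir / "category_accuracy.png", alpha)
    return {"ci_table": ci_table, "comparisons": cmp_table, "letters": letters}


def _plot_homogeneity(ci_table, path: Path, alpha: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    x = np.arange(len(ci_table))
    p = ci_table["proportion"].to_numpy()
    lo = p - ci_table["ci_lower"].to_numpy()
    hi = ci_table["ci_upper"].to_numpy() - p
    ax.bar(x, 100 * p, color="#4878a8")
    ax.errorbar(x, 100 * p, yerr=100 * np.vstack([lo, hi]), fmt="none", ecolor="k", capsize=4)
    for xi, (pi, hi_i, letter) in enumerate(zip(p, hi, ci_table["letters"])):
        ax.text(xi, 100 * (pi + hi_i) + 0.5, letter, ha="center", fontsize=11)
    ax.set_xticks(x)
    ax.set_xticklabels(ci_table["label"], rotation=20, ha="right")
    ax.set_ylabel("accuracy [%]")
    ax.set_ylim(0, 105)
    ax.set_title(f"Category accuracy with {100 * (1 - alpha):.0f}% beta-distribution CIs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
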