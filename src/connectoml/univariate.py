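"""Per-edge univariate group comparison and the per-band summary.

Each edge is tested with a two-sided Welch two-sample t-test (unequal group
sizes and variances are the norm for clinical cohorts). Significance is
assessed on the *raw* p-value at alpha = 0.01 by default — deliberately no
multiple-testing correction, the screening step trades specificity for
retained variance; a Benjamini-Hochberg switch exists for reuse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import CASE, CONTROL, ConnectomeDataset
from .simulate import DECREASE, INCREASE

__all__ = [
    "UnivariateResult",
    "BandSummary",
    "edge_ttest",
    "summarize_bands",
    "summarize_counts",
    "filter_significant",
]


@dataclass
class UnivariateResult:
    """Per-edge t statistics for one band (long-table analogue of a results table)."""

    band: str
    edge_ids: np.ndarray  # global edge ids of the tested columns
    t_statistic: np.ndarray
    p_value: np.ndarray
    direction: np.ndarray  # "increase"/"decrease": case vs control mean
    significant: np.ndarray  # p_value < alpha (raw or FDR-adjusted)
    alpha: float
    tie: np.ndarray  # True where the mean difference was exactly zero
    fdr: bool = False

    def significant_edges(self) -> np.ndarray:
        """Global edge ids passing the filter, in edge-index order."""
        return self.edge_ids[self.significant]

    def to_frame(self, edge_index=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "band": self.band,
                "edge_id": self.edge_ids,
                "t_statistic": self.t_statistic,
                "p_value": self.p_value,
                "direction": self.direction,
                "significant": self.significant,
            }
        )
        if edge_index is not None:
            df.insert(2, "edge", [edge_index.edge_label(int(e)) for e in self.edge_ids])
        return df


@dataclass
class BandSummary:
    """Counts of significant edges per band, plus their across-band mean ± SD."""

    table: pd.DataFrame  # columns: band, n_significant, n_increase, n_decrease
    mean_significant: float
    sd_significant: float
    sd_defined: bool  # False when only one band was summarised


def edge_ttest(
    dataset: ConnectomeDataset, alpha: float = 0.01, fdr: bool = False
) -> UnivariateResult:
    """Welch t-test of case vs control for every edge column.

    Degenerate edges that are constant within both groups get ``t = 0,
    p = 1`` rather than NaN. Direction is the sign of (case mean − control
    mean); an exact zero difference is labelled "increase" with the tie flag
    set, keeping the output deterministic.
    """
    n_ctrl, n_case = dataset.class_counts()
    if min(n_ctrl, n_case) < 2:
        raise ValueError(f"need >= 2 subjects per group, got control={n_ctrl}, case={n_case}")
    xc = dataset.X[dataset.labels == CASE]
    x0 = dataset.X[dataset.labels == CONTROL]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xc, x0, axis=0, equal_var=False)
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    diff = xc.mean(axis=0) - x0.mean(axis=0)
    # both groups constant: 0/0 in the Welch statistic
    degenerate = ~np.isfinite(t) & (diff == 0)
    t[degenerate], p[degenerate] = 0.0, 1.0
    # constant but different means: infinite evidence
    blown = ~np.isfinite(t) & (diff != 0)
    t[blown] = np.sign(diff[blown]) * np.inf
    p[blown] = 0.0
    if fdr:
        p_crit = stats.false_discovery_control(p, method="bh")
        significant = p_crit < alpha
    else:
        significant = p < alpha
    direction = np.where(diff > 0, INCREASE, DECREASE)
    tie = diff == 0
    direction[tie] = INCREASE
    return UnivariateResult(
        band=dataset.band,
        edge_ids=dataset.edge_ids.copy(),
        t_statistic=t,
        p_value=p,
        direction=direction,
        significant=np.asarray(significant, bool),
        alpha=alpha,
        tie=tie,
        fdr=fdr,
    )


def summarize_counts(counts) -> tuple[float, float, bool]:
    """Mean and sample SD (ddof=1) of per-band significant-edge counts.

    With a single band the SD is undefined; it is reported as 0.0 with the
    defined-flag False.
    """
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise ValueError("no band counts to summarise")
    mean = float(c.mean())
    if c.size == 1:
        return mean, 0.0, False
    return mean, float(c.std(ddof=1)), True


def summarize_bands(results) -> BandSummary:
    """Per-band significant/increase/decrease counts, summary-table style."""
    results = list(results)
    if not results:
        raise ValueError("no univariate results to summarise")
    rows = []
    for r in results:
        sig = r.significant
        rows.append(
            {
                "band": r.band,
                "n_significant": int(sig.sum()),
                "n_increase": int((sig & (r.direction == INCREASE)).sum()),
                "n_decrease": int((sig & (r.direction == DECREASE)).sum()),
            }
        )
    table = pd.DataFrame(rows)
    mean, sd, defined = summarize_counts(table["n_significant"])
    return BandSummary(table=table, mean_significant=mean, sd_significant=sd, sd_defined=defined)


def filter_significant(dataset: ConnectomeDataset, result: UnivariateResult) -> ConnectomeDataset:
    """Restrict the dataset to the edges passing the univariate filter.

    Edge identities and order are preserved. An empty selection is legal and
    comes back as a zero-column dataset whose ``is_empty_selection`` flag the
    caller must check (the downstream pipeline turns it into an explicit
    no-signal result rather than crashing).
    """
    if result.band != dataset.band:
        raise ValueError(f"result band {result.band!r} does not match dataset {dataset.band!r}")
    if not np.array_equal(result.edge_ids, dataset.edge_ids):
        raise ValueError("result was computed on a different edge set than this dataset")
    return dataset.select_edges(result.significant_edges())
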