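"""Behavioral fractions (bordering, exploration) and group-comparison stats.

Bordering: fraction of animals whose whole body lies within 1 mm of the
bacterial lawn edge at a single timepoint.  Exploration: after 3 h on a
35 mm plate overlaid with a 105-square grid, the fraction of squares
containing tracks.  Group comparisons delegate to scipy/statsmodels:
one-way ANOVA with Tukey's HSD, Wilcoxon-Mann-Whitney for pairs, and the
Friedman test for matched blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EXPLORATION_GRID_SQUARES = 105


@dataclass(frozen=True)
class BehaviorCounts:
    strain: str
    condition: str
    n_scored: int
    n_positive: int
    denominator_kind: str = "animals"  # or "grid_squares_105"

    def __post_init__(self):
        if self.denominator_kind not in ("animals", "grid_squares_105"):
            raise ValueError(
                f"unknown denominator_kind {self.denominator_kind!r}")
        if self.n_positive < 0:
            raise ValueError("n_positive must be non-negative")
        if self.denominator_kind == "animals":
            if self.n_scored <= 0:
                raise ValueError("n_scored must be positive")
            if self.n_positive > self.n_scored:
                raise ValueError("n_positive cannot exceed n_scored")
        else:
            if self.n_positive > EXPLORATION_GRID_SQUARES:
                raise ValueError(
                    f"n_positive cannot exceed {EXPLORATION_GRID_SQUARES}")


def bordering_fraction(counts: BehaviorCounts) -> float:
    """Fraction of scored animals at the lawn border."""
    if counts.denominator_kind != "animals":
        raise ValueError("bordering_fraction requires animal counts")
    return counts.n_positive / counts.n_scored


def exploration_fraction(n_squares: int) -> float:
    """Fraction of the 105 grid squares containing tracks after 3 h."""
    if not (0 <= n_squares <= EXPLORATION_GRID_SQUARES):
        raise ValueError(
            f"n_squares must lie in [0, {EXPLORATION_GRID_SQUARES}]")
    return n_squares / EXPLORATION_GRID_SQUARES


def compare_groups(groups: dict, test: str) -> pd.DataFrame:
    """Compare groups of per-replicate values with the named test.

    ``groups`` maps label -> values.  Tests: ``anova_tukey`` (one-way ANOVA;
    Tukey HSD adjusted p per pair), ``wilcoxon_mw`` (exactly two groups),
    ``friedman`` (matched blocks: every group the same length, ordered by
    block).  Returns a tidy frame with columns comparison, statistic, p_value,
    p_adjusted.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if test == "anova_tukey":
        if len(arrays) < 2:
            raise ValueError("anova_tukey needs >= 2 groups")
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        f_stat, p_anova = stats.f_oneway(*arrays)
        values = np.concatenate(arrays)
        codes = np.concatenate(
            [np.full(len(a), lab, dtype=object) for a, lab in zip(arrays, labels)]
        )
        tukey = pairwise_tukeyhsd(values, codes)
        rows = [{
            "comparison": "overall (ANOVA)",
            "statistic": float(f_stat),
            "p_value": float(p_anova),
            "p_adjusted": np.nan,
        }]
        res = tukey.summary().data[1:]
        for g1, g2, meandiff, p_adj, *_ in res:
            rows.append({
                "comparison": f"{g1} vs {g2}",
                "statistic": float(meandiff),
                "p_value": np.nan,
                "p_adjusted": float(p_adj),
            })
        return pd.DataFrame(rows)
    if test == "wilcoxon_mw":
        if len(arrays) != 2:
            raise ValueError(
                "wilcoxon_mw compares exactly 2 groups; call it pairwise "
                "for more")
        u_stat, p = stats.mannwhitneyu(arrays[0], arrays[1],
                                       alternative="two-sided")
        return pd.DataFrame([{
            "comparison": f"{labels[0]} vs {labels[1]}",
            "statistic": float(u_stat),
            "p_value": float(p),
            "p_adjusted": float(p),
        }])
    if test == "friedman":
        if len(arrays) < 3:
            raise ValueError("friedman needs >= 3 matched treatments")
        if len({len(a) for a in arrays}) != 1:
            raise ValueError("friedman requires equal-length matched blocks")
        mat = np.column_stack(arrays)
        if np.all(mat == mat[:, :1]):
            # every block fully tied: no rank differences, statistic is 0
            chi2, p = 0.0, 1.0
        else:
            chi2, p = stats.friedmanchisquare(*arrays)
        return pd.DataFrame([{
            "comparison": " vs ".join(labels),
            "statistic": float(chi2),
            "p_value": float(p),
            "p_adjusted": float(p),
        }])
    raise ValueError(f"unknown test {test!r}")
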