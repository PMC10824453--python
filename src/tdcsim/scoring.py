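"""Scoring of intervention success and network-profile correlations.

Each stimulation setup is judged per outcome measure against the
untreated degeneration (ADD) condition: a significant shift of the
post-onset values toward the healthy-control mean scores 1, a significant
shift away scores -1, no significant change scores 0.  The six
per-measure scores sum to a composite in [-6, 6].  A reference table of
composite scores for the twenty standard montages ships with the package
(``load_published_scores``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stimulation import Montage

__all__ = [
    "OutcomeScores",
    "SCORE_COLUMNS",
    "score_measure",
    "composite_score",
    "timepoint_ttests",
    "network_profile_correlation",
    "load_published_scores",
]

#: Score-table columns in the canonical measure order.
SCORE_COLUMNS = ("Alpha1", "Alpha2", "TotalPower", "PeakFreq", "PLI", "AEC")

#: Map from measure name to score-table column.
MEASURE_TO_COLUMN = {
    "lower_alpha": "Alpha1",
    "upper_alpha": "Alpha2",
    "total_power": "TotalPower",
    "peak_frequency": "PeakFreq",
    "pli": "PLI",
    "aec": "AEC",
}


@dataclass(frozen=True)
class OutcomeScores:
    """Per-measure scores in {-1, 0, 1} and their composite sum."""

    per_measure: dict[str, int]

    def __post_init__(self) -> None:
        composite_score(list(self.per_measure.values()))

    @property
    def composite(self) -> int:
        return composite_score(list(self.per_measure.values()))


def score_measure(
    intervention: np.ndarray,
    add_baseline: np.ndarray,
    healthy_mean: float,
    window: slice | None = None,
    alpha_level: float = 0.05,
) -> int:
    """Score one outcome measure: 1 toward healthy, -1 away, 0 no change.

    ``intervention`` and ``add_baseline`` are (n_runs, n_timepoints)
    trajectories (or precomputed (n_runs,) window means).  Run-wise means
    over the scoring window enter a two-sided Welch t-test; a
    non-significant difference scores 0, otherwise the sign depends on
    whether the intervention mean is closer to the healthy mean than the
    ADD mean.
    """
    iv = np.asarray(intervention, dtype=float)
    ad = np.asarray(add_baseline, dtype=float)
    if iv.ndim == 2:
        iv = iv[:, window].mean(axis=1) if window is not None else iv.mean(axis=1)
    if ad.ndim == 2:
        ad = ad[:, window].mean(axis=1) if window is not None else ad.mean(axis=1)
    if iv.shape[0] < 2 or ad.shape[0] < 2:
        raise ValueError("scoring needs at least two runs per condition")
    if np.ptp(iv) == 0 and np.ptp(ad) == 0:
        if iv[0] != ad[0]:
            warnings.warn("degenerate run variance; scoring 0")
        return 0
    t, p = stats.ttest_ind(iv, ad, equal_var=False)
    if not np.isfinite(p) or p >= alpha_level:
        return 0
    return 1 if abs(iv.mean() - healthy_mean) < abs(ad.mean() - healthy_mean) else -1


def composite_score(scores: Sequence[int]) -> int:
    """Sum of exactly six per-measure scores, each in {-1, 0, 1}."""
    if len(scores) != 6:
        raise ValueError(f"expected six per-measure scores, got {len(scores)}")
    vals = []
    for s in scores:
        v = int(s)
        if v != s or v not in (-1, 0, 1):
            raise ValueError(f"per-measure score {s!r} not in {{-1, 0, 1}}")
        vals.append(v)
    return int(sum(vals))


def timepoint_ttests(
    condition_a: Mapping[str, np.ndarray],
    condition_b: Mapping[str, np.ndarray],
    healthy_means: Mapping[str, float],
    timepoints: Sequence[int] = (10, 15, 20),
    measures: Sequence[str] | None = None,
    baseline: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Independent t-tests of condition A against B at selected timepoints.

    Inputs map measure name to a (n_runs, n_timepoints) array.  The mean
    difference is signed so that positive means A lies nearer the healthy
    value than B.  When ``baseline`` (the ADD condition) is given, the
    head-to-head variant is computed: both conditions are first expressed
    as run-wise differences from the baseline mean at that timepoint.
    """
    measures = list(measures) if measures is not None else list(condition_a)
    rows = []
    for m in measures:
        a_all, b_all = np.asarray(condition_a[m], float), np.asarray(condition_b[m], float)
        for tp in timepoints:
            if tp >= a_all.shape[1] or tp >= b_all.shape[1]:
                raise ValueError(f"timepoint {tp} missing from condition trajectories")
            a, b = a_all[:, tp], b_all[:, tp]
            if baseline is not None:
                ref = float(np.asarray(baseline[m], float)[:, tp].mean())
                a, b = a - ref, b - ref
            t, p = stats.ttest_ind(a, b, equal_var=False)
            toward = np.sign(healthy_means[m] - b.mean()) or 1.0
            rows.append(
                {
                    "measure": m,
                    "timepoint": tp,
                    "mean_difference": float((a.mean() - b.mean()) * toward),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def network_profile_correlation(
    composites: Mapping[str, int],
    montages: Sequence[Montage],
    region_aec: np.ndarray,
    region_degree: np.ndarray,
) -> dict[str, float]:
    """Correlate regional average anodal composite score with connectivity.

    For every region appearing in at least one anodal set, the composite
    scores of the setups anodally stimulating it are averaged; Pearson
    correlations of that average against the region's functional (AEC)
    and structural (degree) connectivity are returned.  Only anodal
    stimulation is considered.
    """
    region_aec = np.asarray(region_aec, dtype=float)
    region_degree = np.asarray(region_degree, dtype=float)
    sums: dict[int, list[float]] = {}
    for m in montages:
        if m.id not in composites:
            continue
        for r in m.anodal_regions:
            sums.setdefault(int(r), []).append(float(composites[m.id]))
    regions = sorted(sums)
    if len(regions) < 3:
        raise ValueError("need at least three anodally stimulated regions")
    avg = np.array([np.mean(sums[r]) for r in regions])
    out: dict[str, float] = {"n_regions": float(len(regions))}
    for name, profile in (("aec", region_aec[regions]), ("degree", region_degree[regions])):
        if np.ptp(avg) == 0 or np.ptp(profile) == 0:
            warnings.warn(f"zero variance in {name} correlation; undefined")
            out[f"r_{name}"] = float("nan")
            out[f"p_{name}"] = float("nan")
        else:
            r, p = stats.pearsonr(avg, profile)
            out[f"r_{name}"] = float(r)
            out[f"p_{name}"] = float(p)
    return out


def load_published_scores() -> pd.DataFrame:
    """Reference per-measure and composite scores of the twenty standard
    stimulation setups (columns: Setup, Score, Alpha1..AEC)."""
    with resources.files("tdcsim.data").joinpath("published_scores.csv").open() as fh:
        return pd.read_csv(fh)
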