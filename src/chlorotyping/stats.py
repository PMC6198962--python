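"""Chlorotype population statistics: Pearson chi-square and AMOVA.

AMOVA follows the standard squared-distance decomposition. With
``d2(i, j)`` the squared distance between individuals i and j,

    SSD_total  = (1/N) * sum_{i<j} d2(i, j)
    SSD_within = sum_g (1/n_g) * sum_{i<j in g} d2(i, j)
    SSD_among  = SSD_total - SSD_within

with degrees of freedom G-1 among and N-G within. Variance components:
sigma2_within = MS_within and sigma2_among = (MS_among - MS_within)/n0,
where n0 = (N - sum n_g^2 / N) / (G - 1). Significance comes from a
Monte-Carlo permutation test: individuals are shuffled across groups
with group sizes fixed, and p = (1 + #{sigma2_among* >= observed}) /
(n_perm + 1).

The default squared distance is the Hamming count of differing panel
positions, which equals squared Euclidean distance on 0/1 site vectors;
novel symbols count as distinct from both 0 and 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .networks import squared_distance_matrix
from .panel import GroupedDataset

__all__ = ["ChiSquareResult", "AmovaResult", "pearson_chisq", "amova",
           "within_group_contributions"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    n_dropped_cells: int = 0
    small_expected: bool = False


def pearson_chisq(table: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square test of independence on a chlorotype x group
    count table.

    Rows/columns with zero marginals (expected counts of zero) are
    dropped with a logged warning; expected counts below 5 are flagged
    but not collapsed.
    """
    counts = np.asarray(table, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative cell counts")
    keep_rows = counts.sum(axis=1) > 0
    keep_cols = counts.sum(axis=0) > 0
    dropped = counts.size - counts[np.ix_(keep_rows, keep_cols)].size
    if dropped:
        log.warning("dropping %d cells with zero expected counts", dropped)
    counts = counts[np.ix_(keep_rows, keep_cols)]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate contingency table (needs >=2 rows and >=2 columns)")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    small = bool((expected < 5).any())
    if small:
        log.warning("expected counts below 5; chi-square approximation may be poor")
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return ChiSquareResult(stat, df, float(sps.chi2.sf(stat, df)), dropped, small)


@dataclass
class AmovaResult:
    ssd_among: float
    ssd_within: float
    ssd_total: float
    df_among: int
    df_within: int
    ms_among: float
    ms_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    p_perm: float | None
    n_perm: int
    within_contributions: dict[str, float]
    negative_component_floored: bool = False
    undefined: bool = field(default=False)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("among groups", self.df_among, self.ssd_among, self.ms_among,
             self.sigma2_among, self.pct_among),
            ("within groups", self.df_within, self.ssd_within, self.ms_within,
             self.sigma2_within, self.pct_within),
            ("total", self.df_among + self.df_within, self.ssd_total, np.nan, np.nan, np.nan),
        ]
        return pd.DataFrame(
            rows, columns=["component", "df", "SSD", "MS", "sigma2", "pct"]
        )


def _group_decomposition(
    d2: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[float, float, np.ndarray]:
    """(ssd_total, ssd_within, per-group within terms) from a squared
    distance matrix and integer group codes."""
    n = len(codes)
    iu = np.triu_indices(n, 1)
    ssd_total = d2[iu].sum() / n
    per_group = np.zeros(n_groups)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        per_group[g] = sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return float(ssd_total), float(per_group.sum()), per_group


def amova(
    dataset: GroupedDataset,
    metric: str = "hamming",
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA over a grouped chlorotype dataset (see module docstring).

    Chlorotypes must be free of ``?`` (filter with
    :meth:`GroupedDataset.complete` first). ``n_perm=0`` skips the
    permutation test (``p_perm`` is then None).
    """
    groups = dataset.groups
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least two groups")
    labels = dataset.labels()
    for g in groups:
        if labels.count(g) == 0:
            raise ValueError(f"group {g!r} is empty")
    if any("?" in c for c in dataset.chlorotypes()):
        raise ValueError("chlorotypes contain '?'; drop unresolved samples first")

    d2 = squared_distance_matrix(dataset.chlorotypes(), metric=metric)
    code_of = {g: i for i, g in enumerate(groups)}
    codes = np.array([code_of[g] for g in labels])
    n = len(codes)
    n_g = np.bincount(codes, minlength=len(groups)).astype(float)
    G = len(groups)

    ssd_total, ssd_within, per_group = _group_decomposition(d2, codes, G)
    ssd_among = ssd_total - ssd_within
    df_among, df_within = G - 1, n - G
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within if df_within else np.nan
    n0 = (n - (n_g**2).sum() / n) / (G - 1)
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0

    floored = False
    if sigma2_among < 0 or sigma2_within < 0:
        floored = True
        sigma2_among_f, sigma2_within_f = max(sigma2_among, 0.0), max(sigma2_within, 0.0)
    else:
        sigma2_among_f, sigma2_within_f = sigma2_among, sigma2_within
    total_var = sigma2_among_f + sigma2_within_f
    undefined = not np.isfinite(total_var) or total_var <= 0
    if undefined:
        pct_among = pct_within = float("nan")
        contributions = {g: float("nan") for g in groups}
    else:
        pct_among = 100.0 * sigma2_among_f / total_var
        pct_within = 100.0 * sigma2_within_f / total_var
        if ssd_within > 0:
            contributions = {
                g: 100.0 * per_group[i] / ssd_within for i, g in enumerate(groups)
            }
        else:
            contributions = {g: float("nan") for g in groups}

    p_perm = None
    if n_perm > 0 and not undefined:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            t, w, _ = _group_decomposition(d2, perm, G)
            s2a = ((t - w) / df_among - w / df_within) / n0
            if s2a >= sigma2_among - 1e-12:
                hits += 1
        p_perm = (1 + hits) / (n_perm + 1)

    return AmovaResult(
        ssd_among=ssd_among, ssd_within=ssd_within, ssd_total=ssd_total,
        df_among=df_among, df_within=df_within,
        ms_among=ms_among, ms_within=ms_within,
        sigma2_among=sigma2_among_f, sigma2_within=sigma2_within_f,
        pct_among=pct_among, pct_within=pct_within,
        p_perm=p_perm, n_perm=n_perm,
        within_contributions=contributions,
        negative_component_floored=floored, undefined=undefined,
    )


def within_group_contributions(
    dataset: GroupedDataset, metric: str = "hamming"
) -> dict[str, float]:
    """Per-group percentage share of SSD_within (sums to 100)."""
    result = amova(dataset, metric=metric, n_perm=0)
    if result.ssd_within <= 0:
        raise ValueError("SSD_within is zero; contributions undefined")
    return result.within_contributions
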