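"""Group-level statistics.

Channel selection by grand-average prediction accuracy, the attend-vs-
ignore cluster-based permutation test on difference TRFs, rank-sum tests
against the chance distribution, and pairwise model comparisons with
Benjamini-Yekutieli FDR correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# channel selection
# ---------------------------------------------------------------------------

@dataclass
class ChannelSelection:
    selected: list[int]  # channel indices, best first
    ranking_statistic: np.ndarray  # grand-average accuracy per channel
    k: int
    symmetry_required: bool = False
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.selected) != self.k:
            raise ValueError("selection size does not equal k")


def select_channels(
    accuracy_per_channel: np.ndarray,
    k: int,
    symmetry_required: bool = False,
    layout: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
) -> ChannelSelection:
    """Top-k channels by grand-average accuracy.

    Without symmetry: plain top-k, ties broken by channel order. With
    symmetry: the layout's left-right mirror pairs are ranked by pair-mean
    accuracy and the best k/2 pairs are taken (bilateral frontotemporal
    selection analogue). Requires an even ``k`` and a 2-D layout whose
    channels mirror at x -> -x.
    """
    acc = np.asarray(accuracy_per_channel, dtype=float)
    n_ch = len(acc)
    if k > n_ch:
        raise ValueError("k exceeds the channel count")
    if not symmetry_required:
        order = np.lexsort((np.arange(n_ch), -acc))
        selected = [int(i) for i in order[:k]]
    else:
        if k % 2:
            raise ValueError("symmetric selection needs an even k")
        if layout is None:
            raise ValueError("symmetric selection needs a channel layout")
        pairs = mirror_pairs(np.asarray(layout, dtype=float))
        if k // 2 > len(pairs):
            raise ValueError("not enough mirror pairs for the requested k")
        pair_means = np.array([(acc[i] + acc[j]) / 2 for i, j in pairs])
        order = np.lexsort((np.arange(len(pairs)), -pair_means))
        selected = []
        for pi in order[: k // 2]:
            selected.extend(pairs[pi])
    return ChannelSelection(
        selected=selected, ranking_statistic=acc, k=k,
        symmetry_required=symmetry_required,
        labels=[labels[i] for i in selected] if labels else [],
    )


def mirror_pairs(layout: np.ndarray, tol: float = 1e-6) -> list[tuple[int, int]]:
    """Left-right channel pairs (i, j) with layout[j] == (-x_i, y_i)."""
    pairs = []
    for i, (x, y) in enumerate(layout):
        if x >= -tol:
            continue
        d = np.hypot(layout[:, 0] + x, layout[:, 1] - y)
        j = int(np.argmin(d))
        if d[j] > tol:
            raise ValueError(f"channel {i} has no mirror partner in the layout")
        pairs.append((i, j))
    return pairs


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    lag_start_ms: float
    lag_end_ms: float
    t_sum: float
    p_value: float
    sign: int
    significant: bool


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_values: np.ndarray  # per-lag independent-t statistic
    t_threshold: float
    cluster_forming_alpha: float
    corrected_alpha: float
    n_perm: int
    excluded_lags: list[int]  # degenerate-variance lags, removed from formation
    lag_times_ms: np.ndarray

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def _pooled_t(s1, q1, n1, s2, q2, n2):
    """Pooled-df two-sample t from per-group sums and sums of squares."""
    m1, m2 = s1 / n1, s2 / n2
    ss1 = q1 - n1 * m1**2
    ss2 = q2 - n2 * m2**2
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t, denom


def _max_cluster_sum(t_row: np.ndarray, supra: np.ndarray) -> float:
    """Largest |sum of t| over contiguous same-sign supra-threshold runs."""
    best = 0.0
    run_sum = 0.0
    run_sign = 0
    for t, s in zip(t_row, supra):
        sign = 0 if not s else (1 if t > 0 else -1)
        if sign != 0 and sign == run_sign:
            run_sum += t
        else:
            best = max(best, abs(run_sum))
            run_sum = t if sign else 0.0
            run_sign = sign
    return max(best, abs(run_sum))


def _clusters_from_t(t_row, supra, lag_ms):
    clusters = []
    start = None
    sign = 0
    for i, (t, s) in enumerate(zip(t_row, supra)):
        cur = 0 if not s else (1 if t > 0 else -1)
        if cur != 0 and cur == sign:
            continue
        if sign != 0:
            clusters.append((start, i - 1, sign))
        start, sign = (i, cur) if cur != 0 else (None, 0)
    if sign != 0:
        clusters.append((start, len(t_row) - 1, sign))
    return [
        (lo, hi, sg, float(t_row[lo : hi + 1].sum())) for lo, hi, sg in clusters
    ]


def cluster_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    cluster_forming_alpha: float = 0.001,
    corrected_alpha: float = 0.001,
    n_perm: int = 2000,
    seed: int | None = 0,
    lag_times_ms: np.ndarray | None = None,
) -> ClusterTestResult:
    """Running two-sided independent-t cluster test between waveform groups.

    Group A holds per-subject difference TRFs (attend - ignore) and group B
    per-permutation grand-average chance difference TRFs; both are
    (n, n_lags). Per lag a pooled-df two-sample t is computed; contiguous
    same-sign lags exceeding the two-sided ``cluster_forming_alpha``
    threshold form clusters scored by their t sum. The null is the maximal
    |cluster sum| over ``n_perm`` random relabelings of group membership;
    p uses the inclusive (+1) convention so it is never 0. Lags with
    degenerate (zero) pooled variance are excluded from cluster formation.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the lag grid")
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 waveforms")
    L = A.shape[1]
    if lag_times_ms is None:
        lag_times_ms = np.arange(L, dtype=float)
    df = n1 + n2 - 2
    t_crit = float(spstats.t.ppf(1 - cluster_forming_alpha / 2, df))

    D = np.vstack([A, B])
    D2 = D**2
    s_tot = D.sum(axis=0)
    q_tot = D2.sum(axis=0)

    t_obs, denom = _pooled_t(
        A.sum(axis=0), (A**2).sum(axis=0), n1,
        B.sum(axis=0), (B**2).sum(axis=0), n2,
    )
    degenerate = denom <= 0
    excluded = [int(i) for i in np.flatnonzero(degenerate)]
    if excluded:
        logger.info("cluster test: %d degenerate-variance lags excluded", len(excluded))
    supra_obs = (np.abs(t_obs) > t_crit) & ~degenerate
    obs_clusters = _clusters_from_t(t_obs, supra_obs, lag_times_ms)

    rng = np.random.default_rng(seed)
    # vectorized relabelings: boolean group-A membership per permutation
    keys = rng.random((n_perm, n1 + n2))
    a_mask = np.argsort(keys, axis=1) < n1  # (n_perm, N) with exactly n1 True
    Am = a_mask.astype(float)
    S1 = Am @ D
    Q1 = Am @ D2
    S2 = s_tot[None, :] - S1
    Q2 = q_tot[None, :] - Q1
    t_null, denom_null = _pooled_t(S1, Q1, n1, S2, Q2, n2)
    supra_null = (np.abs(t_null) > t_crit) & (denom_null > 0)
    null_max = np.array([
        _max_cluster_sum(t_null[b], supra_null[b]) for b in range(n_perm)
    ])

    clusters = []
    for lo, hi, sg, t_sum in obs_clusters:
        p = (1 + int(np.sum(null_max >= abs(t_sum)))) / (1 + n_perm)
        clusters.append(Cluster(
            lag_start_ms=float(lag_times_ms[lo]),
            lag_end_ms=float(lag_times_ms[hi]),
            t_sum=t_sum, p_value=p, sign=sg,
            significant=p < corrected_alpha,
        ))
    return ClusterTestResult(
        clusters=clusters, t_values=t_obs, t_threshold=t_crit,
        cluster_forming_alpha=cluster_forming_alpha,
        corrected_alpha=corrected_alpha, n_perm=n_perm,
        excluded_lags=excluded, lag_times_ms=np.asarray(lag_times_ms, dtype=float),
    )


# ---------------------------------------------------------------------------
# accuracy tests
# ---------------------------------------------------------------------------

def test_vs_chance(
    observed: np.ndarray, chance: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of observed accuracies vs chance.

    Returns (z statistic, p). ``observed`` holds per-subject accuracies and
    ``chance`` the per-permutation grand-average null accuracies.
    """
    observed = np.asarray(observed, dtype=float)
    chance = np.asarray(chance, dtype=float)
    if observed.size == 0 or chance.size == 0:
        raise ValueError("both samples must be nonempty")
    res = spstats.ranksums(observed, chance)
    return float(res.statistic), float(res.pvalue)


test_vs_chance.__test__ = False  # not a pytest case despite the name


@dataclass
class Comparison:
    name: str
    z: float
    p_raw: float
    p_adjusted: float
    n: int
    missing: bool = False


@dataclass
class ModelComparisonResult:
    comparisons: list[Comparison]
    correction: str = "benjamini-yekutieli"

    def __getitem__(self, name: str) -> Comparison:
        for c in self.comparisons:
            if c.name == name:
                return c
        raise KeyError(name)


def benjamini_yekutieli(p_values: Sequence[float]) -> np.ndarray:
    """BY-adjusted p-values (FDR control under arbitrary dependence)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_by")[1]


def compare_models(
    paired_samples: Mapping[str, tuple[np.ndarray, np.ndarray]],
) -> ModelComparisonResult:
    """Two-sided Wilcoxon signed-rank tests with BY correction.

    ``paired_samples`` maps a comparison name to a pair of per-subject
    accuracy vectors aligned by subject. All comparisons passed in one call
    form the multiplicity family. All-zero differences make the test
    undefined; such comparisons are reported as missing and excluded from
    the correction.
    """
    names, stats, pvals, ns, missing = [], [], [], [], []
    for name, (x, y) in paired_samples.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"comparison {name!r}: unpaired samples")
        if len(x) < 5:
            raise ValueError(f"comparison {name!r}: need >= 5 subjects")
        names.append(name)
        ns.append(len(x))
        if np.allclose(x, y):
            stats.append(np.nan)
            pvals.append(np.nan)
            missing.append(True)
            continue
        res = spstats.wilcoxon(x, y, alternative="two-sided", method="approx")
        stats.append(float(res.zstatistic))
        pvals.append(float(res.pvalue))
        missing.append(False)
    adj = np.full(len(names), np.nan)
    ok = [i for i, m in enumerate(missing) if not m]
    if ok:
        adj[ok] = benjamini_yekutieli([pvals[i] for i in ok])
    return ModelComparisonResult(comparisons=[
        Comparison(
            name=names[i], z=stats[i], p_raw=pvals[i], p_adjusted=float(adj[i]),
            n=ns[i], missing=missing[i],
        )
        for i in range(len(names))
    ])
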