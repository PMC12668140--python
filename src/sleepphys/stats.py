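"""Exact and contingency statistics plus histology classification helpers.

Implements the statistics used to quantify figure-level claims: Pearson
chi-square without continuity correction, two-sided Fisher exact tests (the
point-probability convention) with Bonferroni adjustment, exact binomial
pmf/tail/Clopper–Pearson intervals, fold-changes of per-state median rates,
two-component Gaussian-mixture positivity calls on stain intensities, soma
candidate filtering, and ROI colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as st
from sklearn.mixture import GaussianMixture


@dataclass
class ContingencyTable:
    """r×c nonnegative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("table must be at least 2x2")
        if (c < 0).any() or not np.all(np.equal(np.mod(c, 1), 0)):
            raise ValueError("counts must be nonnegative integers")
        self.counts = c.astype(np.int64)


def chi_square(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, p-value). Expected counts are
    the usual row·column/total products; a zero expected cell is an error.
    """
    obs = table.counts if isinstance(table, ContingencyTable) else \
        ContingencyTable(np.asarray(table)).counts
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError("zero expected count; chi-square undefined")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(st.chi2.sf(stat, df))
    return stat, df, p


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2×2 table (point-probability method).

    With margins fixed, the p-value sums the hypergeometric probabilities of
    every admissible table whose probability does not exceed that of the
    observed table (small tolerance for floating-point ties).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    k = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = st.hypergeom.pmf(k, n, r1, c1)
    p_obs = st.hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def bonferroni(p_values: np.ndarray | list[float],
               m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p) per value (m defaults to len)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def binomial_pmf(k: int, n: int, p: float) -> float:
    """Exact binomial point probability P(X = k)."""
    return float(st.binom.pmf(k, n, p))


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper-tail probability P(X >= k)."""
    return float(st.binom.sf(k - 1, n, p))


def binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact confidence interval for a binomial proportion."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    alpha = 1 - conf
    lo = st.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = st.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def fold_change_of_medians(rates_by_state: dict[str, np.ndarray]) -> dict[str, float]:
    """Pairwise ratios of per-state medians of per-cell rates.

    Returns ``{"A/B": median_A / median_B, ...}`` for every ordered pair
    with median_A >= median_B; zero-denominator pairs are NaN.
    """
    medians = {k: float(np.median(np.asarray(v, dtype=float)))
               for k, v in rates_by_state.items()}
    out: dict[str, float] = {}
    names = list(medians)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            hi, lo = (a, b) if medians[a] >= medians[b] else (b, a)
            out[f"{hi}/{lo}"] = (medians[hi] / medians[lo]
                                 if medians[lo] > 0 else float("nan"))
    return out


@dataclass
class GMMResult:
    """Two-component mixture fit and per-item positivity calls."""

    means: np.ndarray           # (2,), sorted ascending
    sds: np.ndarray
    weights: np.ndarray
    posterior_high: np.ndarray  # per item, P(high component | x)
    positive: np.ndarray        # bool per item
    degenerate: bool = False


def gmm_positivity(intensities: np.ndarray, posterior_threshold: float = 0.9,
                   seed: int = 0, tol: float = 1e-8,
                   max_iter: int = 500) -> GMMResult:
    """Stain-positivity calls from a 2-component Gaussian mixture.

    EM is initialized at the 25th/75th intensity percentiles; an item is
    positive when its posterior probability of belonging to the higher-mean
    component exceeds ``posterior_threshold``. Degenerate (near-constant)
    inputs are flagged and everything is called negative.
    """
    x = np.asarray(intensities, dtype=float).reshape(-1, 1)
    if x.shape[0] < 4:
        raise ValueError("need >= 4 candidates")
    if np.ptp(x) < 1e-12 * max(1.0, abs(float(x.mean()))):
        n = x.shape[0]
        return GMMResult(means=np.full(2, float(x.mean())),
                         sds=np.zeros(2), weights=np.array([0.5, 0.5]),
                         posterior_high=np.zeros(n),
                         positive=np.zeros(n, dtype=bool), degenerate=True)
    init = np.percentile(x, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, means_init=init, tol=tol,
                         max_iter=max_iter, random_state=seed)
    gm.fit(x)
    order = np.argsort(gm.means_.ravel())
    post = gm.predict_proba(x)[:, order]    # columns: (low, high)
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    positive = post[:, 1] > posterior_threshold
    return GMMResult(means=means, sds=sds, weights=weights,
                     posterior_high=post[:, 1], positive=positive)


@dataclass
class RegionCandidate:
    """Segmented soma candidate with the fields the filters consult."""

    area_px: float
    circularity: float | None = None
    equivalent_diameter_px: float | None = None
    volume_um3: float | None = None
    pixels: frozenset | None = None
    median_intensity: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("area must be positive")


def filter_somata(candidates: list[RegionCandidate], mode: str = "2D",
                  area_range: tuple[float, float] = (30, 1500),
                  circularity_range: tuple[float, float] = (0.3, 1.7),
                  diameter_range: tuple[float, float] = (5, 40),
                  max_volume_um3: float = 2000.0) -> list[RegionCandidate]:
    """Keep candidates passing the soma morphology thresholds.

    2-D mode applies inclusive area / circularity / equivalent-diameter
    bounds; 3-D mode requires total volume strictly below
    ``max_volume_um3``.
    """
    kept = []
    for c in candidates:
        if mode == "2D":
            if c.circularity is None or c.equivalent_diameter_px is None:
                raise ValueError("2D mode needs circularity and diameter")
            ok = (area_range[0] <= c.area_px <= area_range[1]
                  and circularity_range[0] <= c.circularity <= circularity_range[1]
                  and diameter_range[0] <= c.equivalent_diameter_px <= diameter_range[1])
        elif mode == "3D":
            if c.volume_um3 is None:
                raise ValueError("3D mode needs volume_um3")
            ok = c.volume_um3 < max_volume_um3
        else:
            raise ValueError("mode must be '2D' or '3D'")
        if ok:
            kept.append(c)
    return kept


def colocalize(rois_a: list[frozenset | set], rois_b: list[frozenset | set],
               min_overlap_fraction: float = 0.25) -> tuple[np.ndarray, int]:
    """Flag each ROI in A that overlaps any ROI in B by at least the
    threshold fraction of A's own area; returns (flags, count)."""
    flags = np.zeros(len(rois_a), dtype=bool)
    sets_b = [set(b) for b in rois_b]
    for i, a in enumerate(rois_a):
        a = set(a)
        if not a:
            continue
        for b in sets_b:
            if len(a & b) / len(a) >= min_overlap_fraction:
                flags[i] = True
                break
    return flags, int(flags.sum())
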