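"""Enrichment and profile statistics for site sets.

Covers the comparisons made between modified and background S/T sets:
2×2 contingency enrichment (Fisher's exact test with the sample odds
ratio), pooled two-proportion z-tests, Wald proportion intervals, score
comparisons (Welch t and Kruskal–Wallis), per-offset sequence relative
entropy against a background amino-acid distribution, and per-offset
disorder log-odds profiles from external predictor score tracks.

No multiple-testing correction is applied; raw p-values are reported
with the conventional 0.05 threshold left to the caller.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable2x2",
    "PositionalProfile",
    "DisorderTrack",
    "DISORDER_THRESHOLDS",
    "fisher_exact_or",
    "two_proportion_ztest",
    "proportion_ci",
    "score_comparison",
    "relative_entropy_profile",
    "disorder_odds_profile",
    "classify_disordered",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Author-defined disorder cut-offs per predictor score
DISORDER_THRESHOLDS = {
    "DisEMBL-REM465": 0.6,
    "DisEMBL-COILS": 0.516,
    "DisEMBL-HOTLOOPS": 0.1204,
    "IUPred-Long": 0.5,
    "IUPred-Short": 0.5,
    "JRonn": 0.5,
}


@dataclass
class ContingencyTable2x2:
    """Counts with rows = (modified, unmodified), columns = (in-state, not)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0 \
                or self.a + self.c == 0 or self.b + self.d == 0:
            raise ValueError("a margin of the 2x2 table is zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class PositionalProfile:
    offsets: np.ndarray
    values: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    statistic_name: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.offsets)
        if not (len(self.values) == len(self.ci_low) == len(self.ci_high) == n):
            raise ValueError("profile arrays must have equal length")

    def at(self, offset: int) -> tuple[float, float, float]:
        idx = int(np.where(np.asarray(self.offsets) == offset)[0][0])
        return (float(self.values[idx]), float(self.ci_low[idx]),
                float(self.ci_high[idx]))


@dataclass
class DisorderTrack:
    protein_id: str
    method: str
    scores: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.threshold is None:
            self.threshold = DISORDER_THRESHOLDS[self.method]


def classify_disordered(track: DisorderTrack, position: int) -> bool:
    """Score at the 1-based position at/above the method cut-off."""
    if not 1 <= position <= len(track.scores):
        raise IndexError("position outside track")
    score = track.scores[position - 1]
    if np.isnan(score):
        raise ValueError("NaN disorder score")
    return bool(score >= track.threshold)


def fisher_exact_or(t: ContingencyTable2x2) -> tuple[float, float]:
    """Sample odds ratio (a·d)/(b·c) and two-sided Fisher exact p.

    With a zero cell the Haldane–Anscombe +0.5 correction is applied to
    the odds ratio (flagged by a warning); the p-value is exact either way.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if 0 in (a, b, c, d):
        warnings.warn("zero cell: Haldane-corrected odds ratio")
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = sps.fisher_exact(t.as_array(), alternative="two-sided")
    return float(odds), float(p)


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int
                         ) -> tuple[float, float]:
    """Pooled-variance two-proportion z statistic and two-sided p."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; p set to 1")
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2.0 * (1.0 - sps.norm.cdf(abs(z)))
    return float(z), float(p)


def proportion_ci(x: int, n: int, level: float = 0.95
                  ) -> tuple[float, float]:
    """Normal-approximation (Wald) interval for x/n, clipped to [0, 1]."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("need 0 <= x <= n with n > 0")
    low, high = proportion_confint(x, n, alpha=1 - level, method="normal")
    return float(max(low, 0.0)), float(min(high, 1.0))


def score_comparison(modified_scores, unmodified_scores, test: str = "t"
                     ) -> dict:
    """Compare two score samples (Welch t or Kruskal–Wallis).

    Returns statistic, two-sided p and per-group mean ± standard error.
    """
    x = np.asarray(modified_scores, dtype=float)
    y = np.asarray(unmodified_scores, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "t":
        stat, p = sps.ttest_ind(x, y, equal_var=False)
    elif test == "kruskal_wallis":
        if x.std() == 0 and y.std() == 0 and x[0] == y[0]:
            raise ValueError("Kruskal-Wallis undefined for constant groups")
        stat, p = sps.kruskal(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "test": test, "statistic": float(stat), "p": float(p),
        "mean_modified": float(x.mean()),
        "se_modified": float(x.std(ddof=1) / math.sqrt(len(x))),
        "mean_unmodified": float(y.mean()),
        "se_unmodified": float(y.std(ddof=1) / math.sqrt(len(y))),
    }


def _entropy_by_offset(columns: list[list[str]], q: np.ndarray,
                       alpha: float) -> np.ndarray:
    out = np.full(len(columns), np.nan)
    for i, letters in enumerate(columns):
        if not letters:
            continue
        counts = np.array([letters.count(a) for a in AMINO_ACIDS], float)
        p = (counts + alpha) / (counts.sum() + alpha * len(AMINO_ACIDS))
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / q), 0.0)
        out[i] = terms.sum()
    return out


def relative_entropy_profile(flanks: list[str], background_freqs,
                             reps: int = 200, seed: int | None = None,
                             alpha: float = 0.5) -> PositionalProfile:
    """Per-offset relative entropy (bits) of aligned site windows.

    ``flanks`` are strings of odd length aligned on the central residue,
    '-' marking padded positions which are excluded from the counts.  Per
    offset the column's amino-acid frequencies (with pseudocount ``alpha``
    per letter) are compared to the background by Kullback–Leibler
    divergence in bits.  The confidence band is a percentile bootstrap over
    sites.
    """
    if not flanks:
        raise ValueError("no flanks given")
    width = len(flanks[0])
    if width % 2 == 0 or any(len(f) != width for f in flanks):
        raise ValueError("flanks must share one odd length")
    q = np.asarray(background_freqs, dtype=float)
    if len(q) != len(AMINO_ACIDS) or not math.isclose(q.sum(), 1.0,
                                                      abs_tol=1e-6):
        raise ValueError("background must be a 20-vector summing to 1")
    half = width // 2
    offsets = np.arange(-half, half + 1)

    def columns_of(sample: list[str]) -> list[list[str]]:
        return [[f[i] for f in sample if f[i] in AMINO_ACIDS]
                for i in range(width)]

    values = _entropy_by_offset(columns_of(flanks), q, alpha)
    rng = np.random.default_rng(seed)
    boot = np.full((reps, width), np.nan)
    flank_arr = np.array(flanks)
    for r in range(reps):
        sample = list(flank_arr[rng.integers(0, len(flanks),
                                             size=len(flanks))])
        boot[r] = _entropy_by_offset(columns_of(sample), q, alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
    # the point estimate may sit outside the percentile band at degenerate
    # offsets; widen minimally so the band always contains it
    lo = np.fmin(lo, values)
    hi = np.fmax(hi, values)
    return PositionalProfile(offsets=offsets, values=values, ci_low=lo,
                             ci_high=hi,
                             statistic_name="relative_entropy_bits",
                             meta={"pseudocount": alpha, "reps": reps})


def _offset_counts(tracks: dict[str, DisorderTrack],
                   sites: list[tuple[str, int]], window: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(disordered, total) counts per offset −window..window."""
    width = 2 * window + 1
    dis = np.zeros(width, dtype=int)
    tot = np.zeros(width, dtype=int)
    for pid, pos in sites:
        track = tracks.get(pid)
        if track is None:
            continue
        n = len(track.scores)
        for k, offset in enumerate(range(-window, window + 1)):
            p = pos + offset
            if 1 <= p <= n:
                tot[k] += 1
                if track.scores[p - 1] >= track.threshold:
                    dis[k] += 1
    return dis, tot


def disorder_odds_profile(target_tracks: dict[str, DisorderTrack],
                          target_sites: list[tuple[str, int]],
                          background_tracks: dict[str, DisorderTrack],
                          background_sites: list[tuple[str, int]],
                          window: int = 50) -> PositionalProfile:
    """log10 odds ratio of disorder, target vs background, per offset.

    A residue at offset d of a site is disordered when its predictor score
    is at or above the method threshold.  The odds ratio per offset gets
    the Haldane +0.5 correction when any cell is zero; the band is a 95%
    Wald interval on the log-odds scale.  Offsets with no coverage on
    either side are dropped (NaN).
    """
    methods = {t.method for t in target_tracks.values()} | \
              {t.method for t in background_tracks.values()}
    if len(methods) > 1:
        raise ValueError("mixed predictor methods in one profile")
    t_dis, t_tot = _offset_counts(target_tracks, target_sites, window)
    b_dis, b_tot = _offset_counts(background_tracks, background_sites, window)
    width = 2 * window + 1
    values = np.full(width, np.nan)
    lo = np.full(width, np.nan)
    hi = np.full(width, np.nan)
    ln10 = math.log(10.0)
    for k in range(width):
        if t_tot[k] == 0 or b_tot[k] == 0:
            continue
        a = t_dis[k]
        b = t_tot[k] - t_dis[k]
        c = b_dis[k]
        d = b_tot[k] - b_dis[k]
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        ln_or = math.log((a * d) / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        values[k] = ln_or / ln10
        lo[k] = (ln_or - 1.959963984540054 * se) / ln10
        hi[k] = (ln_or + 1.959963984540054 * se) / ln10
    return PositionalProfile(
        offsets=np.arange(-window, window + 1), values=values,
        ci_low=lo, ci_high=hi, statistic_name="log10_odds_ratio",
        meta={"method": next(iter(methods)) if methods else "",
              "n_target_sites": len(target_sites),
              "n_background_sites": len(background_sites)})
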