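"""Non-inferiority tests and sample-size calculators.

Non-inferiority here always means "method A is not worse than method B
by more than the margin", with the direction of "worse" stated per test:
accuracy is better when larger (margin on the accuracy difference,
default 10 percentage points), distances and ranks are better when
smaller (margin 5 mm — one CT slice — and 0.25 rank units), usefulness
is better when larger (margin 0.25). All tests are one-sided; a p-value
below alpha rejects inferiority. No multiple-testing adjustment is
applied, matching the analysis this mirrors.

The paired-binary test is a Wald-type z-test on the margin-shifted
difference of paired proportions. The rank/usefulness comparison is a
Wilcoxon signed-rank test on margin-shifted paired differences (the
standard reading of a "paired rank-sum" test), exact — by convolution
over midranks, valid under ties — up to n = 25 and normal-approximated
with tie correction beyond. The distance comparison is a one-sided
paired t-test on margin-shifted differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedBinaryTable",
    "NoninfResult",
    "noninf_paired_binary",
    "noninf_paired_shifted_wilcoxon",
    "noninf_distance_test",
    "sample_size_noninf_t",
    "sample_size_paired_binary",
    "simulated_power_paired_binary",
    "signed_rank_upper_pvalue",
]


@dataclass(frozen=True)
class PairedBinaryTable:
    """Paired correct/incorrect counts: n11 both, n10 A only, n01 B only, n00 neither."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one pair")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class NoninfResult:
    statistic: float
    p_value: float
    margin: float
    alpha: float
    direction: str
    decision: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.decision != (self.p_value < self.alpha):
            raise ValueError("decision inconsistent with p_value and alpha")


def _result(stat, p, margin, alpha, direction, degenerate=False) -> NoninfResult:
    p = float(min(max(p, 0.0), 1.0))
    return NoninfResult(float(stat), p, margin, alpha, direction, p < alpha, degenerate)


def noninf_paired_binary(
    table: PairedBinaryTable, margin: float = 0.10, alpha: float = 0.05
) -> NoninfResult:
    """Wald z-test of H0: p_A - p_B <= -margin on paired binary outcomes.

    With d = (n10 - n01)/n, the standard error of the paired difference
    is se^2 = (n10 + n01 - (n10 - n01)^2 / n) / n^2 and the statistic is
    z = (d + margin)/se, referred to the upper tail of the standard
    normal.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    n = table.total
    diff = table.n10 - table.n01
    d = diff / n
    se_sq = (table.n10 + table.n01 - diff * diff / n) / (n * n)
    direction = "A non-inferior to B (accuracy margin %.3g)" % margin
    if se_sq <= 0:
        p = 0.0 if d + margin > 0 else 1.0
        return _result(np.inf if p == 0.0 else -np.inf, p, margin, alpha, direction, True)
    z = (d + margin) / np.sqrt(se_sq)
    return _result(z, stats.norm.sf(z), margin, alpha, direction)


def signed_rank_upper_pvalue(d: np.ndarray) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank p-value P(W+ >= observed) for H1: location > 0.

    Zero differences are dropped. Up to 25 non-zero differences the
    p-value is exact, computed by convolving the doubled midranks over
    all 2^n sign assignments (valid under tied magnitudes); above that a
    normal approximation with tie correction is used. Returns
    (statistic W+, p).
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= 25:
        # integerized midranks (x2); count sign assignments with S >= 2*W+
        m = np.rint(2 * ranks).astype(int)
        dist = np.zeros(m.sum() + 1)
        dist[0] = 1.0
        for mi in m:
            dist[mi:] += dist[:-mi].copy() if mi else dist.copy()
        target = int(np.rint(2 * w_pos))
        p = dist[target:].sum() / 2.0**n
        return w_pos, float(p)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean) / np.sqrt(var)
    return w_pos, float(stats.norm.sf(z))


def noninf_paired_shifted_wilcoxon(
    values_a, values_b, margin: float, alpha: float = 0.05, larger_is_better: bool = True
) -> NoninfResult:
    """Signed-rank test that A is not worse than B by more than ``margin``.

    Shifted differences d_i = (A_i - B_i) + margin when larger values are
    better, (B_i - A_i) + margin otherwise; H1 places their location
    above zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be 1D and equally long")
    if a.size < 6:
        raise ValueError("need at least 6 pairs")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    d = (a - b if larger_is_better else b - a) + margin
    direction = "A non-inferior to B (margin %.3g)" % margin
    if np.all(d == 0):
        return _result(0.0, 1.0, margin, alpha, direction, True)
    w_pos, p = signed_rank_upper_pvalue(d)
    return _result(w_pos, p, margin, alpha, direction)


def noninf_distance_test(
    distances_a, distances_b, margin_mm: float = 5.0, alpha: float = 0.05
) -> NoninfResult:
    """One-sided paired t-test that A's distances are not worse by > margin.

    Smaller distances are better; tests H0: mean(B - A + margin) <= 0.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired distances must be 1D and equally long")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a + margin_mm
    direction = "A non-inferior to B (distance margin %.3g mm)" % margin_mm
    if np.allclose(d.std(ddof=1), 0.0):
        p = 0.0 if d.mean() > 0 else 1.0
        return _result(np.inf if p == 0.0 else -np.inf, p, margin_mm, alpha, direction, True)
    res = stats.ttest_1samp(d, 0.0, alternative="greater")
    return _result(res.statistic, res.pvalue, margin_mm, alpha, direction)


def sample_size_noninf_t(
    power: float, alpha: float, margin: float, sd: float, true_diff: float = 0.0
) -> int:
    """Smallest n for the one-sided paired non-inferiority t-test.

    ``true_diff`` is the expected advantage of A over B on the "worse"
    scale (0 under exact equivalence); the detectable effect is
    ``true_diff + margin``. Normal-approximation start, then iterated
    with t quantiles to a fixed point.
    """
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    effect = (true_diff + margin) / sd
    if effect <= 0:
        raise ValueError("non-positive effect: the design cannot achieve any power")
    za, zb = stats.norm.ppf(1 - alpha), stats.norm.ppf(power)
    n = max(2, int(np.ceil(((za + zb) / effect) ** 2)))
    for _ in range(100):
        df = n - 1
        ta, tb = stats.t.ppf(1 - alpha, df), stats.t.ppf(power, df)
        n_new = max(2, int(np.ceil(((ta + tb) / effect) ** 2)))
        if n_new == n:
            break
        n = n_new
    return n


def _paired_binary_probs(p_a: float, p_b: float, discordance: float) -> np.ndarray:
    delta = p_a - p_b
    p10 = (discordance + delta) / 2.0
    p01 = (discordance - delta) / 2.0
    p11 = p_a - p10
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([p11, p10, p01, p00])
    if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
        raise ValueError(
            f"inconsistent design: accuracies ({p_a}, {p_b}) and discordance "
            f"{discordance} imply cell probabilities {probs.round(4)}"
        )
    return np.clip(probs, 0.0, 1.0)


def simulated_power_paired_binary(
    n: int,
    p_a: float,
    p_b: float,
    discordance: float,
    margin: float,
    alpha: float,
    n_sims: int,
    seed: int,
) -> float:
    """Monte-Carlo rejection rate of the Wald paired-binary test at size n."""
    probs = _paired_binary_probs(p_a, p_b, discordance)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs, size=n_sims).astype(float)
    diff = counts[:, 1] - counts[:, 2]
    d = diff / n
    se_sq = (counts[:, 1] + counts[:, 2] - diff * diff / n) / (n * n)
    z_crit = stats.norm.ppf(1 - alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d + margin) / np.sqrt(se_sq)
    reject = np.where(se_sq > 0, z > z_crit, d + margin > 0)
    return float(reject.mean())


def sample_size_paired_binary(
    power: float,
    alpha: float,
    margin: float,
    assumed_accuracy_a: float,
    assumed_accuracy_b: float,
    discordance: float,
    method: str = "normal",
    n_sims: int = 4000,
    seed: int = 0,
) -> int:
    """Smallest n for the paired-binary non-inferiority test.

    ``method="normal"`` uses the closed-form normal approximation
    n = (z_{1-a} + z_{1-b})^2 (disc - delta^2) / (delta + margin)^2;
    ``method="simulate"`` scans n upward from half the normal answer,
    accepting the first n whose Monte-Carlo power (per-n seed derived
    from ``seed``) reaches the target.
    """
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    for name, p in (("accuracy_a", assumed_accuracy_a), ("accuracy_b", assumed_accuracy_b)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie in (0, 1)")
    probs = _paired_binary_probs(assumed_accuracy_a, assumed_accuracy_b, discordance)
    delta = assumed_accuracy_a - assumed_accuracy_b
    effect = delta + margin
    if effect <= 0:
        raise ValueError("non-positive effect: the design cannot achieve any power")
    var_unit = discordance - delta**2
    if var_unit <= 0:
        return 1
    za, zb = stats.norm.ppf(1 - alpha), stats.norm.ppf(power)
    n_normal = int(np.ceil((za + zb) ** 2 * var_unit / effect**2))
    if method == "normal":
        return max(1, n_normal)
    if method != "simulate":
        raise ValueError("method must be 'normal' or 'simulate'")
    n = max(1, n_normal // 2)
    while True:
        pw = simulated_power_paired_binary(
            n, assumed_accuracy_a, assumed_accuracy_b, discordance,
            margin, alpha, n_sims, seed=seed + 1000003 * n,
        )
        if pw >= power:
            return n
        n += 1
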