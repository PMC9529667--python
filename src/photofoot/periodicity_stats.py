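"""Periodicity, correlation and quartile statistics for dyad profiles.

Periodicity of dyad-aligned profiles is quantified with a classical
normalized Lomb-Scargle periodogram over a period grid (default 5-25
bp, the range bracketing the ~10 bp helical repeat), with a seeded
permutation test for the significance of the peak. Profile pairs are
compared by Pearson correlation, and the joint geometry-damage
association is tested by a quartile x quartile grouping of step
geometry with one-way ANOVA and Tukey HSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .nucleosome_frame import PositionProfile
from .photogeometry import DipyrimidineStep

logger = logging.getLogger(__name__)

__all__ = ["Periodogram", "CorrelationResult", "QuartileCategoryTable",
           "lomb_scargle", "pearson", "quartile_analysis",
           "QUARTILE_CATEGORIES"]


@dataclass
class Periodogram:
    """Normalized Lomb-Scargle power over a period grid (bp).

    ``snr`` is peak power over the mean off-peak power (excluding a
    ±0.5 bp band around the peak); ``p_value`` is the permutation-test
    significance of the peak power. A zero-variance input yields all-zero
    power, no peak, and p = 1.
    """

    periods: np.ndarray
    power: np.ndarray
    peak_period: float | None
    peak_power: float
    snr: float
    p_value: float
    n_permutations: int = 0
    seed: int | None = None
    n_positions: int = 0


@dataclass
class CorrelationResult:
    """Pearson correlation between two profiles over shared offsets."""

    r: float
    p_value: float
    n: int


def _scargle_matrices(t: np.ndarray, periods: np.ndarray):
    """cos/sin design matrices of the classical Scargle periodogram,
    with the tau phase offset that makes the estimator time-shift
    invariant."""
    omega = 2.0 * np.pi / periods[:, None]        # (m, 1)
    wt = omega * t[None, :]                       # (m, n)
    tau = np.arctan2(np.sin(2 * wt).sum(axis=1),
                     np.cos(2 * wt).sum(axis=1)) / (2.0 * omega[:, 0])
    arg = omega * (t[None, :] - tau[:, None])
    return np.cos(arg), np.sin(arg)


def _power(C: np.ndarray, S: np.ndarray, y: np.ndarray, var: float) -> np.ndarray:
    """Scargle power for one profile (y 1-D) or a batch of permuted
    profiles (y 2-D, one column each)."""
    cy = C @ y
    sy = S @ y
    cc = (C * C).sum(axis=1)
    ss = (S * S).sum(axis=1)
    if cy.ndim == 2:
        cc, ss = cc[:, None], ss[:, None]
    # guard exact-Nyquist degeneracies where all sines vanish
    with np.errstate(divide="ignore", invalid="ignore"):
        p = cy ** 2 / cc + np.where(ss > 1e-12, sy ** 2 / ss, 0.0)
    return p / (2.0 * var)


def lomb_scargle(
    profile: PositionProfile,
    period_range: tuple[float, float] = (5.0, 25.0),
    grid_step: float = 0.01,
    n_permutations: int = 10_000,
    seed: int = 42,
) -> Periodogram:
    """Classical normalized Lomb-Scargle periodogram of a dyad profile.

    Values are mean-centered; power is normalized by the sample
    variance (Scargle normalization), so unit-variance white noise has
    expectation ~1 per period. The peak period is the argmax over the
    grid; its significance is the fraction of position-shuffled
    profiles (seeded permutations) whose maximum power meets or exceeds
    the observed peak.
    """
    clean = profile.dropna()
    t = clean.offsets
    y = clean.values.astype(float)
    if len(y) < 8:
        raise ValueError("need at least 8 positions with values")
    lo, hi = period_range
    if not (0 < lo < hi):
        raise ValueError("invalid period range")
    periods = np.round(np.arange(lo, hi + grid_step / 2, grid_step), 10)

    y = y - y.mean()
    var = float(y.var(ddof=1))
    if var <= 0:
        return Periodogram(
            periods=periods, power=np.zeros_like(periods), peak_period=None,
            peak_power=0.0, snr=float("nan"), p_value=1.0,
            n_permutations=0, seed=seed, n_positions=len(t))

    C, S = _scargle_matrices(t, periods)
    power = _power(C, S, y, var)
    ipeak = int(np.argmax(power))
    peak_period = float(periods[ipeak])
    peak_power = float(power[ipeak])
    off = np.abs(periods - peak_period) > 0.5
    snr = float(peak_power / power[off].mean()) if off.any() else float("nan")

    p_value = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        chunk = max(1, min(n_permutations, int(2e8 // (len(periods) * 8)) or 1))
        done = 0
        while done < n_permutations:
            m = min(chunk, n_permutations - done)
            Y = np.empty((len(y), m))
            for j in range(m):
                Y[:, j] = rng.permutation(y)
            perm_power = _power(C, S, Y, var)
            exceed += int((perm_power.max(axis=0) >= peak_power).sum())
            done += m
        p_value = (1.0 + exceed) / (n_permutations + 1.0)

    return Periodogram(
        periods=periods, power=power, peak_period=peak_period,
        peak_power=peak_power, snr=snr, p_value=p_value,
        n_permutations=n_permutations, seed=seed, n_positions=len(t))


def pearson(profile_a: PositionProfile, profile_b: PositionProfile) -> CorrelationResult:
    """Pearson r between two profiles over their shared finite offsets,
    with a two-sided p from the t-distribution (n - 2 df)."""
    a, b = profile_a.dropna(), profile_b.dropna()
    shared, ia, ib = np.intersect1d(a.offsets, b.offsets, return_indices=True)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared offsets")
    x = a.values[ia]
    y = b.values[ib]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(shared))


# ---------------------------------------------------------------------------
# quartile x quartile geometry-damage association

QUARTILE_CATEGORIES = ("low_low", "low_high", "mid_mid", "high_low", "high_high")


@dataclass
class QuartileCategoryTable:
    """Five-way geometry grouping of steps joined to CPD enrichment.

    Steps are labelled low (<= 25th percentile), high (>= 75th) or mid
    (strictly between) for distance and torsion separately; the five
    analysed groups are low-low, low-high, mid-mid, high-low and
    high-high (mixed mid combinations are excluded). Group enrichment
    values are compared by one-way ANOVA and Tukey HSD.
    """

    thresholds: dict[str, tuple[float, float]]
    categories: dict[str, np.ndarray]
    anova_f: float
    anova_p: float
    tukey: dict[tuple[str, str], float] = field(default_factory=dict)

    def group_means(self) -> dict[str, float]:
        return {k: (float(np.mean(v)) if len(v) else float("nan"))
                for k, v in self.categories.items()}


def _label(values: np.ndarray, low_cut: float, high_cut: float) -> np.ndarray:
    lab = np.full(len(values), "mid", dtype=object)
    lab[values <= low_cut] = "low"
    lab[values >= high_cut] = "high"
    return lab


def quartile_analysis(
    steps: list[DipyrimidineStep],
    enrichment: PositionProfile,
) -> QuartileCategoryTable:
    """Quartile x quartile comparison of step geometry against CPD
    enrichment, pooled over all structures, chains and positions.

    Each step contributes one observation: the enrichment value at its
    half-integer dyad offset (absolute offset when the enrichment
    profile is dyad-symmetrized). Distance and torsion cut points are
    the pooled 25th/75th percentiles (linear interpolation).
    """
    if len(steps) < 8:
        raise ValueError("need at least 8 pooled steps")
    dist = np.array([s.distance for s in steps])
    tors = np.array([s.torsion for s in steps])
    d_lo, d_hi = np.percentile(dist, [25, 75])
    t_lo, t_hi = np.percentile(tors, [25, 75])

    e_vals = []
    for s in steps:
        off = abs(s.half_pos) if enrichment.symmetrized else s.half_pos
        e_vals.append(enrichment.value_at(off))
    e_vals = np.array(e_vals)

    d_lab = _label(dist, d_lo, d_hi)
    t_lab = _label(tors, t_lo, t_hi)
    categories: dict[str, list[float]] = {k: [] for k in QUARTILE_CATEGORIES}
    for dl, tl, e in zip(d_lab, t_lab, e_vals):
        if not np.isfinite(e):
            continue
        key = f"{dl}_{tl}"
        if key in categories:
            categories[key].append(float(e))
    cat_arrays = {k: np.array(v) for k, v in categories.items()}

    groups = {k: v for k, v in cat_arrays.items() if len(v) > 0}
    for k in QUARTILE_CATEGORIES:
        if k not in groups:
            logger.warning("quartile category %s is empty; its comparisons "
                           "are omitted", k)
    if len(groups) < 2:
        raise ValueError("fewer than 2 nonempty categories")
    if all(np.all(g == next(iter(groups.values()))[0]) for g in groups.values()):
        f_stat, p_anova = 0.0, 1.0
    else:
        f_stat, p_anova = stats.f_oneway(*groups.values())
        if not np.isfinite(f_stat):
            f_stat, p_anova = 0.0, 1.0

    tukey: dict[tuple[str, str], float] = {}
    if len(groups) >= 2 and np.isfinite(p_anova):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        data = np.concatenate(list(groups.values()))
        if len(np.unique(data)) > 1:
            res = pairwise_tukeyhsd(data, labels)
            g1 = np.asarray(res.groupsunique)
            for (i, j), p in zip(
                    [(i, j) for i in range(len(g1)) for j in range(i + 1, len(g1))],
                    res.pvalues):
                tukey[(str(g1[i]), str(g1[j]))] = float(p)
        else:
            pairs = [(a, b) for i, a in enumerate(sorted(groups))
                     for b in sorted(groups)[i + 1:]]
            tukey = {p: 1.0 for p in pairs}

    return QuartileCategoryTable(
        thresholds={"distance": (float(d_lo), float(d_hi)),
                    "torsion": (float(t_lo), float(t_hi))},
        categories=cat_arrays,
        anova_f=float(f_stat),
        anova_p=float(p_anova),
        tukey=tukey,
    )
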