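"""Composite differential-expression testing for one pairwise contrast.

Three p-value channels are computed per protein and combined with a
fold-change gate, mirroring label-free proteomics practice on low-replicate
pooled designs:

1. an empirical-Bayes *moderated t-test* on log2 intensities — the pooled
   per-protein variance is shrunk toward a prior variance ``s0_sq`` with
   prior degrees of freedom ``d0`` estimated across all proteins by the
   method of moments on the log sample variances;
2. the same moderated t on variance-stabilized spectral counts
   (``log2(count + pseudocount)``);
3. a *rank-product* permutation test on the per-replicate log2 fold changes
   of the intensity channel (geometric mean of each protein's fold-change
   ranks across replicate experiments, null distribution from independently
   permuting each replicate's rank column).

A protein is called differentially expressed when the smallest available
p-value is below ``alpha`` (raw, no multiplicity correction — a
Benjamini-Hochberg column is emitted for information only) *and* its
ratio-scale fold change is at least ``fc_threshold`` or at most
``1/fc_threshold``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io_tables import CONDITIONS, AbundanceMatrix

EXACT_PERMUTATION_LIMIT = 10_000
_LOG_TIE_EPS = 1e-9


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ContrastSpec:
    """A pairwise contrast; fold change = numerator mean / denominator mean."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ConfigurationError("numerator and denominator must differ")
        for c in (self.numerator, self.denominator):
            if c not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {c!r}")

    @property
    def name(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"

    def reversed(self) -> "ContrastSpec":
        return ContrastSpec(self.denominator, self.numerator)


@dataclass(frozen=True)
class ModeratedTPrior:
    """Empirical-Bayes variance prior: d0 may be ``inf``, s0_sq is finite > 0."""

    d0: float
    s0_sq: float


# --------------------------------------------------------------------------
# fold change


def compute_fold_change(
    matrix: AbundanceMatrix,
    contrast: ContrastSpec,
    pseudocount: float = 0.5,
    min_obs: int = 2,
) -> pd.DataFrame:
    """Ratio-scale fold change of raw group means, per protein.

    The pseudocount is added to *both* group means only when at least one of
    them is exactly zero, so well-measured ratios are reported exactly as the
    ratio of means.  Proteins with fewer than ``min_obs`` observed values in
    either group get a missing fold change.
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    num = matrix.condition_values(contrast.numerator).to_numpy(dtype=float)
    den = matrix.condition_values(contrast.denominator).to_numpy(dtype=float)
    if num.shape[1] == 0 or den.shape[1] == 0:
        raise ConfigurationError(f"contrast {contrast.name}: a condition has no samples")

    n_num = np.sum(~np.isnan(num), axis=1)
    n_den = np.sum(~np.isnan(den), axis=1)
    with np.errstate(invalid="ignore"):
        m_num = np.nanmean(np.where(np.isnan(num), np.nan, num), axis=1)
        m_den = np.nanmean(np.where(np.isnan(den), np.nan, den), axis=1)

    zero = (m_num == 0) | (m_den == 0)
    m_num = np.where(zero, m_num + pseudocount, m_num)
    m_den = np.where(zero, m_den + pseudocount, m_den)

    fc = np.full(matrix.n_proteins, np.nan)
    ok = (n_num >= min_obs) & (n_den >= min_obs) & (m_den > 0)
    fc[ok] = m_num[ok] / m_den[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(fc > 0, np.log2(fc), np.nan)

    return pd.DataFrame(
        {
            "fc_ratio": fc,
            "log2fc": log2fc,
            "n_num": n_num.astype(int),
            "n_den": n_den.astype(int),
        },
        index=matrix.values.index,
    )


# --------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-10:
            break
    return y


def fit_f_dist(s2: np.ndarray, df: np.ndarray | float) -> ModeratedTPrior:
    """Moment fit of a scaled F prior to observed sample variances.

    Fits ``s2 ~ s0_sq * F(df, d0)`` via the log-variance moments: with
    ``e = log(s2) - digamma(df/2) + log(df/2)``, ``var(e)`` exceeds
    ``mean(trigamma(df/2))`` by ``trigamma(d0/2)``; a non-positive excess
    means the variances are consistent with a single value and ``d0`` is
    infinite.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() == 0:
        raise ValueError(
            "all sample variances are zero or undefined; add replicate noise "
            "or use an ordinary t-test"
        )
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    if s2.size < 2 or float(np.var(z)) < 1e-12:
        # variances numerically identical: prior is a point mass at that value
        return ModeratedTPrior(d0=math.inf, s0_sq=float(s2.mean()))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # consistent with one common variance: point-mass prior at its MLE
        d0 = math.inf
        s0_sq = float(s2.mean())
    return ModeratedTPrior(d0=d0, s0_sq=s0_sq)


def _group_arrays(
    values: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ConfigurationError(f"need exactly 2 groups, got {list(groups)}")
    return values[:, labels == groups[0]], values[:, labels == groups[1]]


def _pooled_stats(a: np.ndarray, b: np.ndarray):
    """Row-wise means, pooled variances and residual df with NaN handling."""
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)

    def _mean_var(x: np.ndarray, n: np.ndarray):
        s = np.nansum(x, axis=1)
        m = np.divide(s, n, out=np.full(n.shape, np.nan), where=n > 0)
        ss = np.nansum((x - m[:, None]) ** 2, axis=1)
        v = np.divide(ss, n - 1, out=np.full(n.shape, np.nan), where=n >= 2)
        return m, v

    with np.errstate(invalid="ignore"):
        ma, va = _mean_var(a, na)
        mb, vb = _mean_var(b, nb)
    df = na + nb - 2.0
    with np.errstate(invalid="ignore"):
        s2 = ((na - 1) * np.nan_to_num(va) + (nb - 1) * np.nan_to_num(vb)) / df
    s2 = np.where((na >= 2) & (nb >= 2), s2, np.nan)
    return ma, mb, na, nb, s2, df


def fit_moderated_prior(matrix: np.ndarray, grouping: np.ndarray) -> ModeratedTPrior:
    """Estimate the variance prior from a proteins x samples grid and labels."""
    values = np.asarray(matrix, dtype=float)
    a, b = _group_arrays(values, np.asarray(grouping))
    _, _, _, _, s2, df = _pooled_stats(a, b)
    return fit_f_dist(s2, df)


def moderated_t_test(
    values_a: np.ndarray, values_b: np.ndarray, prior: ModeratedTPrior
) -> tuple[float, float]:
    """Moderated two-sample t for one protein; returns (t, two-sided p).

    With ``d0 = 0`` this is the ordinary pooled two-sample t-test; with
    ``d0 = inf`` the variance is fixed at ``s0_sq`` and the reference
    distribution is standard normal.  Fewer than 2 observations in a group,
    or a zero shrunk variance, yields missing results.
    """
    a = np.asarray(values_a, dtype=float).reshape(1, -1)
    b = np.asarray(values_b, dtype=float).reshape(1, -1)
    t, p = _moderated_t_rows(a, b, prior)
    return float(t[0]), float(p[0])


def _moderated_t_rows(a: np.ndarray, b: np.ndarray, prior: ModeratedTPrior):
    ma, mb, na, nb, s2, df = _pooled_stats(a, b)
    d0, s0 = prior.d0, prior.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        t = (ma - mb) / se
    valid = (na >= 2) & (nb >= 2) & (s2_post > 0)
    t = np.where(valid, t, np.nan)
    p = np.full_like(t, np.nan)
    finite_df = np.isfinite(df_total)
    with np.errstate(invalid="ignore"):
        idx = valid & finite_df
        p[idx] = 2.0 * stats.t.sf(np.abs(t[idx]), df_total[idx])
        idx = valid & ~finite_df
        p[idx] = 2.0 * stats.norm.sf(np.abs(t[idx]))
    return t, p


class ModeratedTTest:
    """Feature-wise empirical-Bayes moderated t-test, sklearn estimator style.

    ``fit(X, y)`` takes ``X`` of shape (n_samples, n_features) — typically
    log2 abundances with samples in rows — and a binary group label vector
    ``y``; it estimates the variance prior across features (unless a prior is
    supplied) and computes per-feature statistics.

    Parameters
    ----------
    prior : ModeratedTPrior or None
        Fixed prior; ``None`` (default) estimates (d0, s0_sq) from the data.

    Attributes
    ----------
    prior_d0_, prior_s0_sq_ : float
        Estimated (or supplied) prior degrees of freedom and prior variance.
    statistic_, pvalue_ : ndarray of shape (n_features,)
        Moderated t statistic (group0 mean minus group1 mean, in the order
        labels first appear) and two-sided p-value.
    mean_diff_ : ndarray
        Difference of group means (the log2 fold change when X is log2).
    """

    def __init__(self, prior: ModeratedTPrior | None = None):
        self.prior = prior

    def get_params(self, deep: bool = True) -> dict:
        return {"prior": self.prior}

    def set_params(self, **params) -> "ModeratedTTest":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "ModeratedTTest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        values = X.T  # features in rows internally
        a, b = _group_arrays(values, y)
        prior = self.prior
        if prior is None:
            _, _, _, _, s2, df = _pooled_stats(a, b)
            prior = fit_f_dist(s2, df)
        self.prior_d0_ = prior.d0
        self.prior_s0_sq_ = prior.s0_sq
        self.statistic_, self.pvalue_ = _moderated_t_rows(a, b, prior)
        with np.errstate(invalid="ignore"):
            self.mean_diff_ = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
        self.n_features_in_ = X.shape[1]
        return self


# --------------------------------------------------------------------------
# rank product


def _rank_columns(grid: np.ndarray, direction: str) -> np.ndarray:
    """Rank each column (replicate); direction 'up' ranks largest first.

    Ties get average ranks; missing entries stay NaN and do not consume
    ranks.
    """
    if direction not in ("up", "down"):
        raise ConfigurationError("direction must be 'up' or 'down'")
    ranks = np.full(grid.shape, np.nan)
    for j in range(grid.shape[1]):
        col = grid[:, j]
        obs = ~np.isnan(col)
        if obs.sum() == 0:
            continue
        x = col[obs]
        ranks[obs, j] = stats.rankdata(-x if direction == "up" else x)
    return ranks


def _log_rank_product(ranks: np.ndarray) -> np.ndarray:
    k = np.sum(~np.isnan(ranks), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrp = np.nansum(np.log(ranks), axis=1) / k
    return np.where(k > 0, lrp, np.nan)


def _enumeration_size(ranks: np.ndarray) -> float:
    """Per-protein null enumeration size: product of observed column sizes."""
    total = 1
    for j in range(ranks.shape[1]):
        m = int(np.sum(~np.isnan(ranks[:, j])))
        total *= max(m, 1)
        if total > EXACT_PERMUTATION_LIMIT:
            return math.inf
    return float(total)


def rank_product_test(
    per_replicate_log2fc: np.ndarray,
    direction: str = "up",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank product with a column-permutation null; returns (RP, p) arrays.

    RP is the geometric mean of a protein's within-replicate ranks.  The null
    permutes each replicate's rank column independently; p is the proportion
    of null rank products at or below the observed one.  The null is computed
    exactly (equivalently to enumerating every joint column permutation) when
    the per-protein enumeration size — the product of the observed column
    sizes — is at most ``10,000``; otherwise ``n_permutations`` Monte Carlo
    permutation draws are used with the add-one correction
    ``p = (b + 1) / (B + 1)``.
    """
    grid = np.asarray(per_replicate_log2fc, dtype=float)
    if grid.ndim == 1:
        grid = grid.reshape(-1, 1)
    if grid.shape[1] < 1:
        raise ConfigurationError("need at least one replicate column")
    ranks = _rank_columns(grid, direction)
    lrp_obs = _log_rank_product(ranks)
    rp = np.exp(lrp_obs)

    if np.isfinite(_enumeration_size(ranks)):
        p = _exact_p(ranks, lrp_obs)
    else:
        if n_permutations < 100:
            raise ConfigurationError(
                "n_permutations must be >= 100 in Monte Carlo mode"
            )
        p = _monte_carlo_p(ranks, lrp_obs, n_permutations, seed)
    return rp, p


def _exact_p(ranks: np.ndarray, lrp_obs: np.ndarray) -> np.ndarray:
    """Exact null tail by enumeration.

    Permuting a column uniformly makes each row's rank an independent uniform
    draw from that column's observed rank multiset, so the per-row null is the
    product distribution over the observed columns' rank values — enumerated
    directly instead of walking all (m!)^k column permutations.
    """
    m, k = ranks.shape
    col_values = [ranks[~np.isnan(ranks[:, j]), j] for j in range(k)]
    p = np.full(m, np.nan)
    for g in range(m):
        cols = [np.log(col_values[j]) for j in range(k) if not np.isnan(ranks[g, j])]
        if not cols:
            continue
        kk = len(cols)
        total = 0
        hits = 0
        for combo in itertools.product(*cols):
            total += 1
            if sum(combo) / kk <= lrp_obs[g] + _LOG_TIE_EPS:
                hits += 1
        p[g] = hits / total
    return p


def _monte_carlo_p(
    ranks: np.ndarray, lrp_obs: np.ndarray, n_permutations: int, seed: int | None
) -> np.ndarray:
    """Monte Carlo null tail, shared across proteins.

    Under independent column permutations a protein's null rank in column j is
    uniform over that column's observed rank multiset, so the null is sampled
    iid from the sorted column values.  One null stream is drawn per
    missingness pattern and shared by all proteins with that pattern, which
    makes the p-values invariant to protein row order.
    """
    m, k = ranks.shape
    rng = np.random.default_rng(seed)
    B = n_permutations
    col_draws: list[np.ndarray | None] = []
    for j in range(k):
        vals = np.sort(np.log(ranks[~np.isnan(ranks[:, j]), j]))
        if vals.size == 0:
            col_draws.append(None)
            continue
        col_draws.append(vals[rng.integers(0, vals.size, size=B)])

    obs_mask = ~np.isnan(ranks)
    p = np.full(m, np.nan)
    patterns: dict[bytes, np.ndarray] = {}
    for g in range(m):
        key = obs_mask[g].tobytes()
        if key not in patterns:
            cols = [col_draws[j] for j in range(k) if obs_mask[g, j]]
            if not cols or any(c is None for c in cols):
                patterns[key] = np.array([])
            else:
                patterns[key] = np.sort(np.mean(cols, axis=0))
        null_lrp = patterns[key]
        if null_lrp.size == 0:
            continue
        b = int(np.searchsorted(null_lrp, lrp_obs[g] + _LOG_TIE_EPS, side="right"))
        p[g] = (b + 1.0) / (B + 1.0)
    return p


def rank_product_two_sided(
    per_replicate_log2fc: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-product p: Bonferroni-doubled minimum of up/down tests.

    The same seed drives both directions so that reversing the contrast
    (negating all fold changes) swaps the directions and leaves p unchanged.
    """
    rp_up, p_up = rank_product_test(per_replicate_log2fc, "up", n_permutations, seed)
    rp_dn, p_dn = rank_product_test(per_replicate_log2fc, "down", n_permutations, seed)
    p = np.minimum(1.0, 2.0 * np.fmin(p_up, p_dn))
    rp = np.where(np.fmin(p_up, p_dn) == p_up, rp_up, rp_dn)
    return rp, p


class RankProduct:
    """Rank-product test as a fit-style estimator.

    ``fit(F)`` takes the per-replicate log2 fold-change grid ``F`` of shape
    (n_replicates, n_features); fitted attributes are ``rank_product_`` and
    ``pvalue_`` (two-sided by default).

    Parameters
    ----------
    direction : {'two-sided', 'up', 'down'}, default 'two-sided'
    n_permutations : int, default 1000
        Monte Carlo draws when exact enumeration is infeasible.
    random_state : int or None
        Seed for the Monte Carlo null.
    """

    def __init__(
        self,
        direction: str = "two-sided",
        n_permutations: int = 1000,
        random_state: int | None = None,
    ):
        self.direction = direction
        self.n_permutations = n_permutations
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "direction": self.direction,
            "n_permutations": self.n_permutations,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "RankProduct":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "RankProduct":
        grid = np.asarray(X, dtype=float).T  # to features x replicates
        if self.direction == "two-sided":
            rp, p = rank_product_two_sided(grid, self.n_permutations, self.random_state)
        else:
            rp, p = rank_product_test(
                grid, self.direction, self.n_permutations, self.random_state
            )
        self.rank_product_ = rp
        self.pvalue_ = p
        self.n_features_in_ = grid.shape[0]
        return self


# --------------------------------------------------------------------------
# composite contrast


def per_replicate_log2fc(
    matrix: AbundanceMatrix, contrast: ContrastSpec, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Within-replicate log2 fold changes (proteins x replicates).

    For each replicate/pool id present in both conditions the ratio of the
    replicate's condition means is taken, with the pseudocount applied to both
    means when either is zero; a missing value in a replicate yields NaN for
    that column.
    """
    design = matrix.design
    reps = [
        r
        for r in dict.fromkeys(design.replicate_ids)
        if any(c == contrast.numerator for s, c, rr in zip(design.sample_ids, design.conditions, design.replicate_ids) if rr == r)
        and any(c == contrast.denominator for s, c, rr in zip(design.sample_ids, design.conditions, design.replicate_ids) if rr == r)
    ]
    if not reps:
        raise ConfigurationError(
            f"no replicate has samples in both {contrast.numerator} and {contrast.denominator}"
        )
    cols = {}
    for r in reps:
        num_samples = [
            s
            for s, c, rr in zip(design.sample_ids, design.conditions, design.replicate_ids)
            if rr == r and c == contrast.numerator
        ]
        den_samples = [
            s
            for s, c, rr in zip(design.sample_ids, design.conditions, design.replicate_ids)
            if rr == r and c == contrast.denominator
        ]
        m_num = matrix.values[num_samples].mean(axis=1, skipna=False).to_numpy()
        m_den = matrix.values[den_samples].mean(axis=1, skipna=False).to_numpy()
        zero = (m_num == 0) | (m_den == 0)
        m_num = np.where(zero, m_num + pseudocount, m_num)
        m_den = np.where(zero, m_den + pseudocount, m_den)
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[r] = np.where(
                (m_num > 0) & (m_den > 0), np.log2(m_num / m_den), np.nan
            )
    return pd.DataFrame(cols, index=matrix.values.index)


def _bh_column(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def run_contrast(
    matrix_intensity: AbundanceMatrix,
    matrix_counts: AbundanceMatrix | None,
    contrast: ContrastSpec,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    pseudocount: float = 0.5,
    min_obs: int = 2,
    n_permutations: int = 1000,
    seed: int | None = None,
    tests: tuple[str, ...] = ("modt_intensity", "modt_count", "rankprod"),
) -> pd.DataFrame:
    """All three tests plus the composite call for one contrast.

    Returns a proteins-in-rows DataFrame with fold change, the per-test p and
    BH q values, observation counts and the composite ``significant`` flag.
    Tests whose channel is unavailable are skipped and recorded in
    ``df.attrs['skipped_tests']``.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must be in (0, 1)")
    if fc_threshold <= 1:
        raise ConfigurationError("fc_threshold must be > 1")
    if matrix_counts is not None and (
        matrix_counts.protein_ids != matrix_intensity.protein_ids
    ):
        raise ConfigurationError("intensity and count matrices must share protein ids")

    fc = compute_fold_change(matrix_intensity, contrast, pseudocount, min_obs)
    out = fc.rename(columns={"n_num": "n_A", "n_den": "n_B"})
    n = matrix_intensity.n_proteins
    skipped: list[str] = []

    def modt_on(matrix: AbundanceMatrix) -> np.ndarray:
        num = matrix.condition_values(contrast.numerator).to_numpy(dtype=float)
        den = matrix.condition_values(contrast.denominator).to_numpy(dtype=float)
        vals = np.log2(np.hstack([num, den]) + pseudocount)
        labels = np.array([0] * num.shape[1] + [1] * den.shape[1])
        est = ModeratedTTest().fit(vals.T, labels)
        return est.pvalue_

    if "modt_intensity" in tests:
        out["p_modt_intensity"] = modt_on(matrix_intensity)
    else:
        out["p_modt_intensity"] = np.nan
        skipped.append("modt_intensity")

    if "modt_count" in tests and matrix_counts is not None:
        out["p_modt_count"] = modt_on(matrix_counts)
    else:
        out["p_modt_count"] = np.nan
        skipped.append("modt_count")

    if "rankprod" in tests:
        grid = per_replicate_log2fc(matrix_intensity, contrast, pseudocount)
        rp, p_rp = rank_product_two_sided(grid.to_numpy(), n_permutations, seed)
        out["rank_product"] = rp
        out["p_rankprod"] = p_rp
    else:
        out["rank_product"] = np.nan
        out["p_rankprod"] = np.nan
        skipped.append("rankprod")

    for col in ("p_modt_intensity", "p_modt_count", "p_rankprod"):
        out["q" + col[1:]] = _bh_column(out[col].to_numpy())

    pmat = out[["p_modt_intensity", "p_modt_count", "p_rankprod"]].to_numpy()
    with np.errstate(invalid="ignore"):
        min_p = np.nanmin(np.where(np.isnan(pmat), np.inf, pmat), axis=1)
    min_p = np.where(np.isfinite(min_p), min_p, np.nan)
    out["min_p"] = min_p

    fc_vals = out["fc_ratio"].to_numpy()
    tested = ~np.isnan(fc_vals) & ~np.isnan(min_p)
    with np.errstate(invalid="ignore"):
        fold_gate = (fc_vals >= fc_threshold) | (fc_vals <= 1.0 / fc_threshold)
    out["tested"] = tested
    out["significant"] = tested & (min_p < alpha) & fold_gate
    out.attrs["contrast"] = contrast.name
    out.attrs["skipped_tests"] = skipped
    out.attrs["seed"] = seed
    out.index.name = "protein_id"
    return out
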