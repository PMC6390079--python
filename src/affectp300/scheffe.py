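"""Ura's variation of Scheffe's paired-comparison analysis.

Every judge rates every ordered pair of stimuli once on a -3..+3 scale, a
positive rating meaning the *second* sound of the pair sounded more positive.
The analysis estimates a zero-sum preference value (valence scale) per
stimulus, decomposes the total sum of squares into main effect of the
ratings, individual differences of the ratings, combination effect, average
order effect and individual differences of the order effect, and attaches a
common studentized-range yardstick to all pairwise differences.

With the rating convention above the model for judge k is

    y_{ij,k} = (alpha_j - alpha_i) + gamma_{ij} + delta + delta_k + e_{ij,k},

with gamma antisymmetric (combination effect) and delta the order effect
playing the grand-mean role, so the total SS is the uncorrected sum of
squares with df = N t (t-1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RATING_COLUMNS = ["subject", "first_id", "second_id", "rating"]

ANOVA_FACTORS = [
    "main effect (average of ratings)",
    "individual difference of ratings",
    "combination effect",
    "average order effect",
    "individual order effect",
    "error",
]


@dataclass(frozen=True)
class ScheffeResult:
    """Preference values, ANOVA decomposition and yardstick CIs."""

    alpha_hat: pd.Series  # preference value per stimulus, zero-sum
    anova: pd.DataFrame  # factor, ss, df, ms, F, p
    yardstick: float  # half-width of every pairwise CI
    ci: pd.DataFrame  # first, second, estimate, lower, upper, significant
    level: float
    n_subjects: int
    n_stimuli: int


def _rating_cube(ratings: pd.DataFrame):
    """(t, t, N) array of ratings with nan diagonal; validates completeness."""
    df = ratings
    missing_cols = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"ratings table missing columns {missing_cols}")
    subjects = sorted(df["subject"].unique())
    stimuli = sorted(set(df["first_id"]).union(df["second_id"]))
    t, n = len(stimuli), len(subjects)
    if t < 2:
        raise ValueError("need at least 2 stimuli")
    s_index = {s: i for i, s in enumerate(stimuli)}
    k_index = {s: i for i, s in enumerate(subjects)}
    cube = np.full((t, t, n), np.nan)
    for row in df.itertuples(index=False):
        cube[s_index[row.first_id], s_index[row.second_id],
             k_index[row.subject]] = row.rating
    missing = []
    for i, j in itertools.permutations(range(t), 2):
        bad = np.isnan(cube[i, j])
        if bad.any():
            for k in np.nonzero(bad)[0]:
                missing.append((stimuli[i], stimuli[j], subjects[k]))
    if missing:
        raise ValueError(f"incomplete ratings table; missing pairs "
                         f"(first, second, subject): {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    return cube, stimuli, subjects


def estimate_alphas(ratings: pd.DataFrame) -> pd.Series:
    """Zero-sum preference value per stimulus.

    alpha_i = [sum of ratings where i was second - sum where i was first]
    / (2 N t); under the rating convention, more positive sounds earn larger
    alphas.  Noise-free ratings from centred true valences are recovered
    exactly.
    """
    cube, stimuli, subjects = _rating_cube(ratings)
    t, n = len(stimuli), len(subjects)
    as_second = np.nansum(cube, axis=(0, 2))  # i as second stimulus
    as_first = np.nansum(cube, axis=(1, 2))  # i as first stimulus
    alphas = (as_second - as_first) / (2.0 * n * t)
    return pd.Series(alphas, index=pd.Index(stimuli, name="stimulus"),
                     name="alpha_hat")


def scheffe_anova(ratings: pd.DataFrame) -> pd.DataFrame:
    """Sum-of-squares decomposition for Ura's variation.

    Factors and dfs (t stimuli, N judges): main effect t-1, individual
    difference of ratings (t-1)(N-1), combination (t-1)(t-2)/2, average order
    effect 1, individual order effect N-1, error = remainder of the
    uncorrected total (df N t (t-1)).  F statistics test each factor against
    the error mean square.  With a single judge the individual-difference
    factors are reported with zero df and no F.
    """
    cube, stimuli, subjects = _rating_cube(ratings)
    t, n = len(stimuli), len(subjects)
    n_obs = n * t * (t - 1)

    mean_pair = cube.mean(axis=2)  # (t, t), nan diagonal
    np.fill_diagonal(mean_pair, 0.0)
    anti = (mean_pair - mean_pair.T) / 2.0
    alpha = -anti.sum(axis=1) / t  # equals estimate_alphas
    ss_alpha = 2.0 * n * t * float(np.sum(alpha ** 2))

    cube0 = np.nan_to_num(cube, nan=0.0)
    anti_k = (cube0 - cube0.transpose(1, 0, 2)) / 2.0  # per judge
    alpha_k = -anti_k.sum(axis=1) / t  # (t, N)
    ss_alpha_b = 2.0 * t * float(np.sum(alpha_k ** 2)) - ss_alpha

    diff = alpha[None, :] - alpha[:, None]  # expected antisymmetric part
    gamma = anti - diff
    np.fill_diagonal(gamma, 0.0)
    ss_gamma = n * float(np.sum(gamma ** 2))  # = 2N * sum over i<j

    delta = float(cube0.sum()) / n_obs
    ss_delta = n_obs * delta ** 2
    delta_k = cube0.sum(axis=(0, 1)) / (t * (t - 1))
    ss_delta_b = t * (t - 1) * float(np.sum((delta_k - delta) ** 2))

    ss_total = float(np.sum(cube0 ** 2))
    parts = [ss_alpha, ss_alpha_b, ss_gamma, ss_delta, ss_delta_b]
    ss_error = max(ss_total - sum(parts), 0.0)

    dfs = [t - 1, (t - 1) * (n - 1), (t - 1) * (t - 2) // 2, 1, n - 1]
    df_error = n_obs - sum(dfs)
    ss = parts + [ss_error]
    df = dfs + [df_error]
    ms = [s / d if d > 0 else np.nan for s, d in zip(ss, df)]
    ms_error = ms[-1]
    F, p = [], []
    for i in range(5):
        if df[i] > 0 and df_error > 0 and ms_error > 0:
            F.append(ms[i] / ms_error)
            p.append(float(stats.f.sf(F[-1], df[i], df_error)))
        else:
            F.append(np.nan)
            p.append(np.nan)
    F.append(np.nan)
    p.append(np.nan)
    return pd.DataFrame({"factor": ANOVA_FACTORS, "ss": ss, "df": df,
                         "ms": ms, "F": F, "p": p})


def pairwise_ci(alpha_hat: pd.Series, anova: pd.DataFrame,
                n_subjects: int, level: float = 0.99) -> tuple[pd.DataFrame, float]:
    """Yardstick confidence intervals for all unordered stimulus pairs.

    The common half-width is ``Y = q(level; t, df_error) * sqrt(MS_error /
    (2 N t))`` with q the studentized-range quantile; a pair differs
    significantly iff its interval excludes zero.  Zero error variance gives
    degenerate intervals at the point estimates.
    """
    t = len(alpha_hat)
    err = anova.loc[anova["factor"] == "error"].iloc[0]
    df_error = int(err["df"])
    if df_error < 1:
        raise ValueError("error df must be >= 1 for confidence intervals")
    ms_error = float(err["ms"])
    if ms_error > 0:
        q = stats.studentized_range.ppf(level, t, df_error)
        yard = float(q * np.sqrt(ms_error / (2.0 * n_subjects * t)))
    else:
        yard = 0.0
    rows = []
    stimuli = list(alpha_hat.index)
    for a, b in itertools.combinations(stimuli, 2):
        est = float(alpha_hat[a] - alpha_hat[b])
        lo, hi = est - yard, est + yard
        rows.append((a, b, est, lo, hi, not (lo <= 0.0 <= hi)))
    ci = pd.DataFrame(rows, columns=["first", "second", "estimate",
                                     "lower", "upper", "significant"])
    return ci, yard


def analyze_ratings(ratings: pd.DataFrame, level: float = 0.99
                    ) -> ScheffeResult:
    """Full Ura-variation analysis: scale values, ANOVA and yardstick CIs."""
    alpha_hat = estimate_alphas(ratings)
    anova = scheffe_anova(ratings)
    n_subjects = ratings["subject"].nunique()
    ci, yard = pairwise_ci(alpha_hat, anova, n_subjects, level)
    return ScheffeResult(alpha_hat=alpha_hat, anova=anova, yardstick=yard,
                         ci=ci, level=level, n_subjects=n_subjects,
                         n_stimuli=len(alpha_hat))
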