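"""Group statistics used throughout the study.

Behavioral endpoint distributions in these assays are not normal, so group
comparisons use the tie-corrected Kruskal–Wallis omnibus test followed by
pairwise Dunn tests that are deliberately left uncorrected for multiplicity
(each species is contrasted with every other at nominal alpha). The
time-binned novel tank data instead use a mixed two-way ANOVA (species x
time bin, repeated on bin) with the Geisser–Greenhouse sphericity
correction, followed by uncorrected Fisher's LSD contrasts at each bin.
Figure-style compact letter displays and coefficients of variation round out
the layer.

All rank statistics use mid-ranks for ties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------- rank tests

def _rank_setup(groups: dict):
    labels = list(groups)
    vals = [np.asarray(groups[g], dtype=float) for g in labels]
    sizes = np.array([len(v) for v in vals])
    if (sizes == 0).any():
        keep = sizes > 0
        labels = [l for l, k in zip(labels, keep) if k]
        vals = [v for v, k in zip(vals, keep) if k]
        sizes = sizes[keep]
    pooled = np.concatenate(vals)
    ranks = sps.rankdata(pooled)           # mid-ranks
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    return labels, vals, sizes, pooled, ranks, split


def _tie_sum(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: dict, method: str = "chi2") -> dict:
    """Tie-corrected Kruskal–Wallis test.

    Parameters
    ----------
    groups : dict
        label -> 1-D array of endpoint values; >= 2 non-empty groups,
        total N >= 3.
    method : {"chi2", "exact"}
        "chi2" refers H to the chi-square distribution with k-1 df;
        "exact" enumerates every assignment of the pooled mid-ranks to the
        group sizes (feasible for small N) and reports P(H_perm >= H_obs).

    Returns dict with H, df, p. All-identical data give H = 0, p = 1 (the
    tie-correction denominator is guarded).
    """
    labels, vals, sizes, pooled, ranks, split = _rank_setup(groups)
    k = len(labels)
    N = int(sizes.sum())
    if k < 2 or N < 3:
        raise ValueError("need >= 2 non-empty groups and total N >= 3")
    H = _kw_statistic(sizes, split, N, pooled)
    df = k - 1
    if method == "chi2":
        p = 1.0 if H == 0.0 else float(sps.chi2.sf(H, df))
    elif method == "exact":
        p = _kw_exact_p(sizes, ranks, pooled, H)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"H": H, "df": df, "p": p, "method": method, "n": N}


def _kw_statistic(sizes, rank_groups, N, pooled) -> float:
    mean_rank = (N + 1) / 2.0
    H = 12.0 / (N * (N + 1)) * sum(
        n * (r.mean() - mean_rank) ** 2 for n, r in zip(sizes, rank_groups))
    denom = 1.0 - _tie_sum(pooled) / (N ** 3 - N)
    if denom <= 0:          # every value identical
        return 0.0
    return float(H / denom)


def _kw_exact_p(sizes, ranks, pooled, H_obs, tol=1e-12) -> float:
    """Exact permutation p by enumerating distinct rank assignments.

    Walks the multinomial assignments of pooled mid-ranks to group slots via
    index combinations; intended for N <= ~12.
    """
    N = len(ranks)
    idx_all = frozenset(range(N))
    count = total = 0

    def rec(remaining, gi, rank_sets):
        nonlocal count, total
        if gi == len(sizes) - 1:
            groups_ranks = rank_sets + [ranks[sorted(remaining)]]
            H = _kw_statistic(sizes, groups_ranks, N, pooled)
            total += 1
            if H >= H_obs - tol:
                count += 1
            return
        for comb in itertools.combinations(sorted(remaining), sizes[gi]):
            rec(remaining - set(comb), gi + 1, rank_sets + [ranks[list(comb)]])

    rec(set(idx_all), 0, [])
    return count / total


def dunn_uncorrected(groups: dict) -> pd.DataFrame:
    """Pairwise Dunn z tests on the pooled mid-ranks, no multiplicity
    adjustment.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )
    with T = sum(t^3 - t) over tie groups; two-sided normal p. Empty groups
    are excluded.
    """
    labels, vals, sizes, pooled, ranks, split = _rank_setup(groups)
    N = int(sizes.sum())
    mean_ranks = {l: r.mean() for l, r in zip(labels, split)}
    var_core = N * (N + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (N - 1))
    rows = []
    for (i, li), (j, lj) in itertools.combinations(enumerate(labels), 2):
        se = np.sqrt(var_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[li] - mean_ranks[lj]) / se
        rows.append({"group_1": li, "group_2": lj, "z": z,
                     "p": float(2.0 * sps.norm.sf(abs(z)))})
    return pd.DataFrame(rows)


# ------------------------------------------------- repeated-measures ANOVA

def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """Geisser–Greenhouse sphericity estimate from a within-subject
    covariance matrix over k repeated levels.

    epsilon-hat = (sum of eigenvalues of the double-centered covariance)^2 /
    ((k-1) * sum of squared eigenvalues); 1/(k-1) <= eps <= 1 and eps is
    identically 1 for k = 2.
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    D = J @ S @ J                      # double-centered covariance
    tr = np.trace(D)
    tr2 = np.trace(D @ D)
    if tr2 <= 0:
        return 1.0
    return float(tr ** 2 / ((k - 1) * tr2))


def rm_anova_gg(data: pd.DataFrame, subject: str = "subject",
                within: str = "bin", between: str = "group",
                value: str = "value") -> dict:
    """Mixed two-way ANOVA (between = group, repeated = time bin) with the
    Geisser–Greenhouse correction, plus uncorrected Fisher's LSD contrasts
    at each bin.

    Subjects with missing bins are dropped listwise (noted in the result).
    Returns the ANOVA table, the epsilon estimate, and the per-bin pairwise
    LSD table. Within-subject and interaction df are multiplied by epsilon
    before the corrected p is taken.
    """
    d = data[[subject, within, between, value]].dropna()
    bins = np.sort(d[within].unique())
    k = len(bins)
    wide = d.pivot_table(index=[subject, between], columns=within,
                         values=value, aggfunc="mean")
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    Y = complete.to_numpy(dtype=float)              # subjects x bins
    grp = np.asarray([g for _, g in complete.index])
    glabels = np.unique(grp)
    g = len(glabels)
    n_s = Y.shape[0]
    if n_s < g + 1 or k < 2:
        raise ValueError("not enough complete subjects for the mixed ANOVA")

    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    bin_means = Y.mean(axis=0)
    group_means = {gl: Y[grp == gl].mean() for gl in glabels}
    cell_means = {gl: Y[grp == gl].mean(axis=0) for gl in glabels}
    n_per = {gl: int((grp == gl).sum()) for gl in glabels}

    ss_total = float(((Y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_group = float(sum(n_per[gl] * k * (group_means[gl] - grand) ** 2
                         for gl in glabels))
    ss_subj_err = ss_between_subj - ss_group
    ss_bin = float(n_s * ((bin_means - grand) ** 2).sum())
    ss_cells = float(sum(n_per[gl] * ((cell_means[gl] - grand) ** 2).sum()
                         for gl in glabels))
    ss_inter = ss_cells - ss_group - ss_bin
    ss_within = ss_total - ss_between_subj
    ss_err_within = ss_within - ss_bin - ss_inter

    df_group, df_subj_err = g - 1, n_s - g
    df_bin = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err_within = (n_s - g) * (k - 1)

    ms = lambda ss, df: ss / df if df > 0 else np.nan
    ms_group, ms_subj = ms(ss_group, df_group), ms(ss_subj_err, df_subj_err)
    ms_bin, ms_inter = ms(ss_bin, df_bin), ms(ss_inter, df_inter)
    ms_err = ms(ss_err_within, df_err_within)

    # pooled within-group covariance of the repeated measures
    resid = np.vstack([Y[grp == gl] - cell_means[gl] for gl in glabels])
    S = resid.T @ resid / (n_s - g)
    eps = greenhouse_geisser_epsilon(S)

    def frow(name, ssv, dfv, msv, mserr, dferr, corrected):
        F = msv / mserr if mserr > 0 else np.nan
        d1, d2 = (dfv * eps, dferr * eps) if corrected else (dfv, dferr)
        p = float(sps.f.sf(F, d1, d2)) if np.isfinite(F) else np.nan
        return {"effect": name, "SS": ssv, "df": dfv, "MS": msv, "F": F,
                "df_corr": d1, "df_err_corr": d2, "p": p}

    table = pd.DataFrame([
        frow(between, ss_group, df_group, ms_group, ms_subj, df_subj_err, False),
        frow(within, ss_bin, df_bin, ms_bin, ms_err, df_err_within, True),
        frow(f"{between} x {within}", ss_inter, df_inter, ms_inter,
             ms_err, df_err_within, True),
    ])

    # Fisher's LSD between groups at each bin: SE of a cell-mean difference
    # mixes both error strata; Satterthwaite df on the combined mean square
    ms_comb = (ms_subj + (k - 1) * ms_err) / k
    df_comb = ((ms_subj + (k - 1) * ms_err) ** 2 /
               (ms_subj ** 2 / df_subj_err + ((k - 1) * ms_err) ** 2
                / ((k - 1) * df_err_within)))
    lsd_rows = []
    for bi, b in enumerate(bins):
        for g1, g2 in itertools.combinations(glabels, 2):
            diff = cell_means[g1][bi] - cell_means[g2][bi]
            se = np.sqrt(ms_comb * (1.0 / n_per[g1] + 1.0 / n_per[g2]))
            t = diff / se if se > 0 else 0.0
            lsd_rows.append({"bin": b, "group_1": g1, "group_2": g2,
                             "diff": diff, "t": t,
                             "p": float(2.0 * sps.t.sf(abs(t), df_comb))})
    return {"anova": table, "epsilon": eps, "lsd": pd.DataFrame(lsd_rows),
            "n_subjects": n_s, "n_dropped": n_dropped,
            "partition_check": abs(ss_total - (ss_group + ss_subj_err + ss_bin
                                               + ss_inter + ss_err_within))}


# ------------------------------------------------------- letters and CV

def letters(pairwise_p: pd.DataFrame, alpha: float = 0.05,
            order: list | None = None) -> dict:
    """Compact letter display by insert-and-absorb.

    ``pairwise_p`` needs columns group_1, group_2, p. Two groups share a
    letter iff their pairwise p >= alpha. Groups are processed in ``order``
    (default: sorted labels) and letters assigned a, b, c, ... in first-use
    order; the sharing invariant is guaranteed, minimality is not.
    """
    p = {}
    glabels = set()
    for _, r in pairwise_p.iterrows():
        p[(r["group_1"], r["group_2"])] = r["p"]
        p[(r["group_2"], r["group_1"])] = r["p"]
        glabels.update([r["group_1"], r["group_2"]])
    if order is None:
        order = sorted(glabels)

    # insert-and-absorb: start with one column holding every group, split
    # every column containing a significantly different pair into two
    # (one without each member), then drop columns contained in others
    cols: list[set] = [set(order)]
    for g1, g2 in itertools.combinations(order, 2):
        if p.get((g1, g2), 1.0) >= alpha:
            continue
        new_cols = []
        for col in cols:
            if g1 in col and g2 in col:
                new_cols.extend([col - {g1}, col - {g2}])
            else:
                new_cols.append(col)
        cols = []
        for c in new_cols:
            if not c or c in cols:
                continue
            if any(c < o for o in new_cols):
                continue
            cols.append(c)
    # stable column order: by first member in the requested group order
    pos = {gl: i for i, gl in enumerate(order)}
    cols.sort(key=lambda c: min(pos[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {gl: "" for gl in order}
    for li, col in enumerate(cols):
        for gl in order:
            if gl in col:
                out[gl] += alphabet[li]
    return out


def coefficient_of_variation(values) -> float:
    """Sample CV as a percentage: 100 * sd / |mean|; NaN (flagged) at mean 0."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m == 0:
        return np.nan
    return float(100.0 * v.std(ddof=1) / abs(m))
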