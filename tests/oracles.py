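"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain per-frame / per-pair loops, directly from
the endpoint definitions, with no code shared with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

JITTER = 0.05
HYST = 2


# ------------------------------------------------------------- kinematics

def brute_kinematic_endpoints(x, y, valid, fps, freeze_max=1.0, rapid_min=10.0):
    """Frame-by-frame locomotor + angular endpoints."""
    n = len(x)
    speeds, states, steps = [], [], []
    for i in range(n - 1):
        if valid[i] and valid[i + 1]:
            d = math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
            v = d * fps
            speeds.append(v)
            steps.append(d)
            if v <= freeze_max:
                states.append("freezing")
            elif v < rapid_min:
                states.append("swimming")
            else:
                states.append("rapid")
        else:
            speeds.append(None)
            steps.append(None)
            states.append("invalid")
    nv = sum(s != "invalid" for s in states)
    out = {}
    if nv == 0:
        return {k: float("nan") for k in
                ("average_speed_cm_s", "total_distance_cm", "freezing_ratio",
                 "swimming_ratio", "rapid_ratio", "angular_velocity_deg_s",
                 "meandering_deg_cm")}
    dist = sum(s for s in steps if s is not None)
    out["average_speed_cm_s"] = dist / (nv / fps)
    out["total_distance_cm"] = dist
    for name in ("freezing", "swimming", "rapid"):
        out[f"{name}_ratio"] = sum(s == name for s in states) / nv

    # headings / turns with jitter floor and chain breaks on invalid steps
    turns, usable_steps = [], []
    last_h = None
    for i in range(n - 1):
        if states[i] == "invalid":
            last_h = None
            continue
        if steps[i] < JITTER:
            continue
        h = math.degrees(math.atan2(y[i + 1] - y[i], x[i + 1] - x[i]))
        usable_steps.append(steps[i])
        if last_h is not None:
            d = abs((h - last_h + 180.0) % 360.0 - 180.0)
            turns.append(d)
        last_h = h
    if turns:
        out["angular_velocity_deg_s"] = (sum(turns) / len(turns)) * fps
        out["meandering_deg_cm"] = sum(turns) / sum(usable_steps)
    else:
        out["angular_velocity_deg_s"] = float("nan")
        out["meandering_deg_cm"] = float("nan")
    return out


# ------------------------------------------------------------------ zones

def brute_zone_occupancy(x, y, valid, times, inside, fps):
    """Zone summary from per-frame loops; ``inside`` is a precomputed
    per-frame containment list (geometry is not what this oracle checks)."""
    n = len(x)
    nv = sum(valid)
    out = {}
    ins = [bool(inside[i]) and bool(valid[i]) for i in range(n)]
    out["time_fraction"] = (sum(ins) / nv) if nv else float("nan")

    entries = 0
    latency = None
    t0 = None
    cur = None
    pend = 0
    pend_t = None
    for i in range(n):
        if not valid[i]:
            pend = 0
            continue
        if t0 is None:
            t0 = times[i]
        side = ins[i]
        if cur is None:
            cur = side
            if side:
                entries += 1
                latency = times[i] - t0
            continue
        if side == cur:
            pend = 0
            continue
        if pend == 0:
            pend_t = times[i]
        pend += 1
        if pend >= HYST:
            cur = side
            pend = 0
            if side:
                entries += 1
                if latency is None:
                    latency = pend_t - t0
    out["entries"] = entries
    out["latency_s"] = latency if latency is not None else n / fps
    out["latency_censored"] = latency is None

    dist = 0.0
    for i in range(n - 1):
        if ins[i] and ins[i + 1]:
            dist += math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
    out["distance_in_zone_cm"] = dist

    best = run = 0
    for i in range(n):
        run = run + 1 if ins[i] else 0
        best = max(best, run)
    out["longest_bout_s"] = best / fps
    return out


# --------------------------------------------------------------- shoaling

def brute_shoal_endpoints(frames):
    """``frames``: list of lists of (x, y) per fish, all-valid frames only."""
    inter, areas, nearest, farthest = [], [], [], []
    for pts in frames:
        k = len(pts)
        ds = {}
        for i, j in itertools.combinations(range(k), 2):
            ds[(i, j)] = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
        inter.append(sum(ds.values()) / len(ds))
        per_fish_n, per_fish_f = [], []
        for i in range(k):
            dd = [ds[tuple(sorted((i, j)))] for j in range(k) if j != i]
            per_fish_n.append(min(dd))
            per_fish_f.append(max(dd))
        nearest.append(sum(per_fish_n) / k)
        farthest.append(sum(per_fish_f) / k)
        if k == 3:
            (x1, y1), (x2, y2), (x3, y3) = pts
            areas.append(abs(x1 * (y2 - y3) + x2 * (y3 - y1)
                             + x3 * (y1 - y2)) / 2.0)
    m = len(frames)
    return {"avg_interfish_cm": sum(inter) / m,
            "avg_area_cm2": sum(areas) / m if areas else None,
            "avg_nearest_cm": sum(nearest) / m,
            "avg_farthest_cm": sum(farthest) / m}


# ------------------------------------------------------------------ stats

def exact_kw_permutation_p(values, labels):
    """Exact Kruskal-Wallis permutation p by enumerating label permutations.

    Uses mid-ranks and the tie-corrected H; dedupes identical label
    orderings. Small N only.
    """
    from scipy.stats import rankdata

    values = list(values)
    labels = list(labels)
    ranks = rankdata(values)
    N = len(values)
    uniq = sorted(set(labels))

    def H_of(lab):
        groups = {u: [ranks[i] for i in range(N) if lab[i] == u] for u in uniq}
        mean_rank = (N + 1) / 2
        H = 12.0 / (N * (N + 1)) * sum(
            len(r) * (np.mean(r) - mean_rank) ** 2 for r in groups.values())
        _, counts = np.unique(np.asarray(values, dtype=float),
                              return_counts=True)
        T = float(np.sum(counts ** 3 - counts))
        denom = 1 - T / (N ** 3 - N)
        return H / denom if denom > 0 else 0.0

    H_obs = H_of(labels)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if H_of(perm) >= H_obs - 1e-12:
            count += 1
    return H_obs, count / total


def gg_epsilon_eig(cov):
    """Greenhouse-Geisser epsilon via eigenvalues of the double-centered
    covariance (independent route from the trace formula)."""
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    J = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(J @ S @ J)
    lam = lam[lam > 1e-12]
    return float(lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum()))


# -------------------------------------------------------------- clustering

def brute_agglomerate(D, linkage="average"):
    """Naive O(n^3) agglomerative clustering on a full distance matrix.

    Returns the merge list [(set_a, set_b, height), ...] using average or
    complete linkage over original-point distances.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []

    def cdist(a, b):
        vals = [D[i, j] for i in a for j in b]
        return (sum(vals) / len(vals)) if linkage == "average" else max(vals)

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = cdist(clusters[i], clusters[j])
            if best is None or d < best[0] - 1e-15:
                best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


# ---------------------------------------------------------------- alignment

def brute_global_alignment_score(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Maximum global alignment score by exhaustive recursion (tiny inputs)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


# -------------------------------------------------------------------- trees

def random_additive_tree(n, rng):
    """Random binary tree over taxa t0..t{n-1} with positive branch lengths.

    Returns (newick, leaf-pair path distance dict)."""
    import itertools as it

    nodes = [(f"t{i}", None) for i in range(n)]
    paths = {f"t{i}": {f"t{i}": 0.0} for i in range(n)}
    # represent each live node by the dict leaf -> distance to this node
    live = [{f"t{i}": 0.0} for i in range(n)]
    newicks = [f"t{i}" for i in range(n)]
    while len(live) > 1:
        i, j = sorted(rng.choice(len(live), size=2, replace=False))
        li = float(rng.uniform(0.1, 2.0))
        lj = float(rng.uniform(0.1, 2.0))
        merged = {}
        for leaf, d in live[i].items():
            merged[leaf] = d + li
        for leaf, d in live[j].items():
            merged[leaf] = d + lj
        nwk = f"({newicks[i]}:{li},{newicks[j]}:{lj})"
        live = [x for k, x in enumerate(live) if k not in (i, j)] + [merged]
        newicks = [x for k, x in enumerate(newicks) if k not in (i, j)] + [nwk]
    dists = {}
    # path distance between leaves = sum of distances to their join point;
    # recompute by brute force from the final newick using dendropy
    import dendropy
    tree = dendropy.Tree.get(data=newicks[0] + ";", schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    for t1, t2 in it.combinations(tree.taxon_namespace, 2):
        dists[frozenset([t1.label, t2.label])] = pdm.patristic_distance(t1, t2)
    return newicks[0] + ";", dists
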