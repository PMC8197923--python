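"""nd2 gene tree construction and phenome-genome concordance.

The species tree is built from mitochondrial NADH dehydrogenase subunit 2
(nd2) sequences: pairwise Needleman-Wunsch global alignment, Jukes-Cantor
distances, neighbor joining, and nonparametric bootstrap over alignment
columns. The concordance layer is tree-agnostic: any Newick tree (e.g. an
externally computed maximum-likelihood tree, or the phenomic dendrogram) can
be compared via Robinson-Foulds distance and cophenetic correlation.

Trees are held as scikit-bio ``TreeNode`` objects; internal node names carry
bootstrap support percentages in Newick output.
"""

from __future__ import annotations

import io
import itertools

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from scipy import stats as sps
from skbio import TreeNode


# ----------------------------------------------------------------- sequences

def read_fasta(path) -> dict:
    """FASTA file -> ordered dict of id -> uppercase sequence string."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, s in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")


def pairwise_align(seq_a: str, seq_b: str, match: float = 1.0,
                   mismatch: float = -1.0, gap: float = -2.0):
    """Optimal global (Needleman-Wunsch) alignment under a linear gap scheme.

    Returns ``(aligned_a, aligned_b, score)``. Terminal and internal gaps are
    penalized identically.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def _as_chars(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def p_distance(aligned_a, aligned_b) -> tuple:
    """(mismatch proportion, compared sites); gap/N sites excluded pairwise."""
    a, b = _as_chars(aligned_a), _as_chars(aligned_b)
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    ok = ~(np.isin(a, (b"-", b"N")) | np.isin(b, (b"-", b"N")))
    n = int(ok.sum())
    if n == 0:
        return np.nan, 0
    diff = int((a[ok] != b[ok]).sum())
    return diff / n, n


def jc_distance(aligned_a: str, aligned_b: str) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) in substitutions/site.

    Saturated pairs (p >= 3/4) have no finite JC distance and raise.
    """
    p, n = p_distance(aligned_a, aligned_b)
    if n == 0 or not np.isfinite(p):
        raise ValueError("no comparable sites between the sequences")
    if p >= 0.75:
        raise ValueError(f"saturated pair (p = {p:.3f} >= 3/4): JC distance undefined")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def jc_distance_matrix(seqs: dict, aligned: bool = False, match: float = 1.0,
                       mismatch: float = -1.0, gap: float = -2.0) -> pd.DataFrame:
    """All-pairs JC distance matrix.

    With ``aligned=False`` every pair is globally aligned first (adequate for
    closely related ~1 kb mitochondrial genes); with ``aligned=True`` the
    inputs must share one coordinate system already.
    """
    ids = list(seqs)
    D = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        if aligned:
            sa, sb = seqs[a], seqs[b]
        else:
            sa, sb, _ = pairwise_align(seqs[a], seqs[b], match, mismatch, gap)
        d = jc_distance(sa, sb)
        D.loc[a, b] = D.loc[b, a] = d
    return D


def reference_msa(seqs: dict, reference: str | None = None) -> dict:
    """Simple reference-anchored multiple alignment.

    Each sequence is globally aligned to the reference (default: the longest
    sequence) and projected onto the reference's coordinates; insertions
    relative to the reference are discarded. Sufficient for closely related,
    near-equal-length genes; already-equal-length inputs pass through
    unchanged.
    """
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        return dict(seqs)
    if reference is None:
        reference = max(seqs, key=lambda k: len(seqs[k]))
    ref = seqs[reference]
    out = {}
    for name, s in seqs.items():
        if name == reference:
            out[name] = ref
            continue
        a_ref, a_s, _ = pairwise_align(ref, s)
        proj = [c for rc, c in zip(a_ref, a_s) if rc != "-"]
        out[name] = "".join(proj)
    return out


# ------------------------------------------------------------------ NJ trees

def neighbor_joining(D: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Produces an unrooted tree (trifurcating root node). Exact on additive
    matrices: recovers the generating topology and branch lengths. Negative
    estimated branch lengths are clamped to zero. Ties in the Q criterion are
    broken by taxon order, so the result is deterministic.
    """
    ids = list(D.index)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = D.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes = [TreeNode(name=name) for name in ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = sub[i, j] - li
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length = max(0.0, float(li))
        child_j.length = max(0.0, float(lj))
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to every other active node
        new_row = 0.5 * (d[ai] + d[aj] - d[ai, aj])
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(0.0, float(ln))
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


# ------------------------------------------------------------ tree utilities

def read_newick(source) -> TreeNode:
    """Parse Newick from a string or file path; underscores in labels are
    kept verbatim (species ids here contain them)."""
    if isinstance(source, str) and source.strip().endswith(";"):
        return TreeNode.read(io.StringIO(source), convert_underscores=False)
    return TreeNode.read(str(source), convert_underscores=False)


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions of the leaf set, orientation-normalized.

    Each internal edge induces a split; splits are stored as the
    lexicographically smaller frozenset of the two sides so rooted and
    unrooted representations of the same topology compare equal.
    """
    leaves = frozenset(t.name for t in tree.tips())
    n = len(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < n - 1:
            other = leaves - side
            splits.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return splits


def robinson_foulds(tree_1: TreeNode, tree_2: TreeNode) -> dict:
    """Symmetric-difference (RF) distance and its 2(n-3) normalization."""
    l1 = {t.name for t in tree_1.tips()}
    l2 = {t.name for t in tree_2.tips()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: only-in-1={sorted(l1 - l2)}, "
                         f"only-in-2={sorted(l2 - l1)}")
    b1, b2 = bipartitions(tree_1), bipartitions(tree_2)
    rf = len(b1 ^ b2)
    n = len(l1)
    max_rf = 2 * (n - 3)
    return {"robinson_foulds": rf,
            "normalized_rf": rf / max_rf if max_rf > 0 else 0.0}


def cophenetic_correlation(tree_1: TreeNode, tree_2: TreeNode) -> float:
    """Pearson correlation between the two trees' leaf-pair path distances."""
    ids = sorted(t.name for t in tree_1.tips())
    dm1 = tree_1.tip_tip_distances(endpoints=ids)
    dm2 = tree_2.tip_tip_distances(endpoints=ids)
    iu = np.triu_indices(len(ids), k=1)
    v1 = dm1.data[iu]
    v2 = dm2.data[iu]
    return float(sps.pearsonr(v1, v2)[0])


def tree_concordance(tree_1: TreeNode, tree_2: TreeNode) -> dict:
    """RF distance, normalized RF, and cophenetic correlation in one call."""
    out = robinson_foulds(tree_1, tree_2)
    out["cophenetic_correlation"] = cophenetic_correlation(tree_1, tree_2)
    return out


# ------------------------------------------------------------------ bootstrap

def bootstrap_support(alignment: dict, n_replicates: int = 1000,
                      seed: int | None = None) -> dict:
    """Column bootstrap of the NJ tree from a multiple alignment.

    Resamples alignment columns with replacement ``n_replicates`` times,
    rebuilds the JC + NJ tree on each replicate, and scores every internal
    bipartition of the full-data tree by the percentage of replicate trees
    containing it. Returns the tree (internal node names = support
    percentages) and the split -> support mapping. Fixing ``seed`` fixes the
    supports exactly.
    """
    ids = list(alignment)
    L = len(next(iter(alignment.values())))
    if any(len(s) != L for s in alignment.values()):
        raise ValueError("bootstrap needs equal-length aligned sequences")
    if L < 4:
        raise ValueError("alignment too short to resample (need >= 4 columns)")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    chars = np.vstack([_as_chars(alignment[i]) for i in ids])   # taxa x sites
    tree = neighbor_joining(jc_distance_matrix(alignment, aligned=True))
    target = bipartitions(tree)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    n_used = 0
    for _ in range(n_replicates):
        take = rng.integers(0, L, size=L)
        rep = {i: chars[k, take] for k, i in enumerate(ids)}
        try:
            rep_tree = neighbor_joining(jc_distance_matrix(rep, aligned=True))
        except ValueError:      # saturated replicate pair: drop replicate
            continue
        n_used += 1
        rep_splits = bipartitions(rep_tree)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / max(n_used, 1) for s, c in counts.items()}
    leaves = frozenset(ids)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, leaves - side, key=lambda s: tuple(sorted(s)))
        if key in support:
            node.name = f"{support[key]:.0f}"
    return {"tree": tree, "support": support, "n_replicates_used": n_used}
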