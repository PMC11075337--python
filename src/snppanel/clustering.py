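"""Population clustering on QC-filtered genotypes: allele-sharing and K2P
distances, neighbor-joining trees, and PCA with Patterson standardization.

The NJ implementation is deliberately self-contained so that tie-breaking is
deterministic (lowest active index pair) and branch lengths are floored at
zero; tests cross-check it against an independent library implementation on
additive matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix
from .sitestats import hwe_exact_p_sites

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.d), 0, equal_nan=True):
            raise ValueError("diagonal must be zero")


@dataclass
class PCAResult:
    """Eigenvalues (descending) and per-sample coordinates."""

    eigenvalues: np.ndarray
    coordinates: np.ndarray  # samples x components
    sample_ids: list[str]


# -- QC filter ----------------------------------------------------------------


def cluster_qc_filter(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.9,
    min_maf: float = 0.05,
    min_hwe_p: float = 1e-6,
) -> GenotypeMatrix:
    """Drop sites failing the clustering QC: call rate < 90%, MAF < 0.05,
    or HWE exact p below 1e-6."""
    codes = matrix.codes
    called = codes != MISSING
    call_rate = called.mean(axis=0)
    n_called = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(called, codes, 0).sum(axis=0) / (2 * n_called)
    maf = np.minimum(p_alt, 1 - p_alt)
    hwe_p = hwe_exact_p_sites(codes)
    keep = (
        (call_rate >= min_call_rate)
        & np.isfinite(maf)
        & (maf >= min_maf)
        & np.isfinite(hwe_p)
        & (hwe_p >= min_hwe_p)
    )
    return matrix.subset_sites(keep)


# -- distances ----------------------------------------------------------------


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance: d(i,j) = 1 - mean over co-called sites of
    (1 - |code_i - code_j| / 2).  NaN for pairs with no co-called site."""
    codes = matrix.codes.astype(np.int16)
    called = codes != MISSING
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = both.sum()
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            sharing = 1.0 - np.abs(codes[i, both] - codes[j, both]) / 2.0
            d[i, j] = d[j, i] = 1.0 - sharing.mean()
    return DistanceMatrix(list(matrix.sample_ids), d)


def genotypes_to_pseudoseqs(matrix: GenotypeMatrix) -> dict[str, str]:
    """Encode each sample's genotypes as a linear sequence.

    Homozygous calls become the corresponding allele; heterozygous and
    missing calls become N (they are then excluded pairwise by the K2P
    distance, which is only defined for unambiguous bases).
    """
    refs = np.array([s[2] for s in matrix.sites])
    alts = np.array([s[3] for s in matrix.sites])
    out = {}
    for i, sid in enumerate(matrix.sample_ids):
        col = matrix.codes[i]
        bases = np.where(col == 0, refs, np.where(col == 2, alts, "N"))
        out[sid] = "".join(bases)
    return out


def k2p_distance(pseudo_seqs: dict[str, str]) -> DistanceMatrix:
    """Kimura 2-parameter distance between pseudo-sequences.

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P, Q the transition and
    transversion proportions over positions where both sequences have an
    unambiguous base.  Out-of-domain proportions (1 - 2P - Q <= 0 or
    1 - 2Q <= 0) yield NaN.
    """
    ids = list(pseudo_seqs)
    arrs = {s: np.frombuffer(pseudo_seqs[s].encode(), dtype="S1") for s in ids}
    valid = {s: np.isin(arrs[s], np.array([b"A", b"C", b"G", b"T"])) for s in ids}
    n = len(ids)
    d = np.zeros((n, n))
    ts_pairs = {(a.encode(), b.encode()) for a, b in TRANSITIONS}
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[ids[i]] & valid[ids[j]]
            m = both.sum()
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            a, b = arrs[ids[i]][both], arrs[ids[j]][both]
            diff = a != b
            n_ts = sum(
                1 for x, y in zip(a[diff], b[diff]) if (bytes(x), bytes(y)) in ts_pairs
            )
            P = n_ts / m
            Q = (diff.sum() - n_ts) / m
            w1 = 1 - 2 * P - Q
            w2 = 1 - 2 * Q
            if w1 <= 0 or w2 <= 0:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = -0.5 * np.log(w1 * np.sqrt(w2))
    return DistanceMatrix(ids, d)


# -- neighbor joining ------------------------------------------------------------


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None,
                 children: list[tuple["_Node", float]] | None = None):
        self.name = name
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c.newick()}:{ln:.10g}" for c, ln in self.children)
        return f"({inner})"


def nj_tree(dist: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in newick.

    Joins minimise the standard Q criterion; ties break on the lowest active
    index pair; branch lengths are floored at zero.  Exact on additive
    distance matrices.
    """
    ids = list(dist.sample_ids)
    n = len(ids)
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        return f"({ids[0]});"
    if np.isnan(dist.d).any():
        raise ValueError("distance matrix contains undefined entries")
    if n == 2:
        h = dist.d[0, 1] / 2
        return f"({ids[0]}:{h:.10g},{ids[1]}:{h:.10g});"

    D = dist.d.copy()
    nodes: list[_Node] = [_Node(name=s) for s in ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major => lowest (i, j) pair on ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to every other active node
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for ak in active:
            if ak in (i, j):
                continue
            D[u, ak] = D[ak, u] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [u]

    a, b, c = active
    la = max(0.0, 0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = max(0.0, 0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = max(0.0, 0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = _Node(
        children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    )
    return root.newick() + ";"


def nj_bootstrap(
    matrix: GenotypeMatrix,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[str, dict[frozenset, float]]:
    """Site-resampling bootstrap support for the NJ tree on IBS distances.

    Returns the tree inferred from the full matrix plus support per
    non-trivial bipartition (as a fraction of replicates).  Off by default in
    the pipeline because it multiplies runtime by the replicate count.
    """
    base = nj_tree(ibs_distance(matrix))
    base_parts = _bipartitions(base, set(matrix.sample_ids))
    hits = {p: 0 for p in base_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, matrix.n_sites, matrix.n_sites)
        boot = GenotypeMatrix(
            matrix.sample_ids,
            [(c, k + 1, r, a) for k, (c, _, r, a) in enumerate(matrix.sites)],
            matrix.codes[:, idx],
            None,
            matrix.pop_labels,
        )
        parts = _bipartitions(nj_tree(ibs_distance(boot)), set(matrix.sample_ids))
        for p in base_parts:
            if p in parts:
                hits[p] += 1
    support = {p: hits[p] / n_replicates for p in base_parts}
    return base, support


def _bipartitions(newick: str, all_taxa: set[str]) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted newick tree, each as the
    canonical (lexicographically smaller) side."""
    clades = _clade_leafsets(newick)
    parts = set()
    for leaves in clades:
        if 1 < len(leaves) < len(all_taxa) - 1:
            other = all_taxa - leaves
            parts.add(frozenset(min(leaves, other, key=lambda s: sorted(s))))
    return parts


def _clade_leafsets(newick: str) -> list[set[str]]:
    """Leaf sets of every internal node of a newick string (simple parser;
    labels must not contain newick metacharacters)."""
    stack: list[set[str]] = []
    out: list[set[str]] = []
    token = ""

    def flush():
        nonlocal token
        if token and stack:
            name = token.split(":")[0]
            if name:
                stack[-1].add(name)
        token = ""

    for ch in newick:
        if ch == "(":
            flush()
            stack.append(set())
        elif ch == ",":
            flush()
        elif ch == ")":
            flush()
            done = stack.pop()
            out.append(done)
            if stack:
                stack[-1] |= done
        elif ch == ";":
            flush()
        else:
            token += ch
    return out


def leaves_monophyletic(newick: str, group: set[str], all_taxa: set[str]) -> bool:
    """True iff ``group`` forms a clade of the unrooted tree (i.e. group or
    its complement appears as a clade leaf set)."""
    comp = all_taxa - group
    for leaves in _clade_leafsets(newick):
        if leaves == group or leaves == comp:
            return True
    # at the trifurcating root the complement may never materialise as one node
    return len(group) == 1 or len(comp) == 1


# -- PCA ---------------------------------------------------------------------------


def pca(matrix: GenotypeMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of the genotype matrix with Patterson standardization.

    Each site is mean-centred and scaled by sqrt(p(1-p)) with p the alternate
    allele frequency; missing genotypes are imputed to the site mean;
    monomorphic sites are dropped.  Eigendecomposition is of the sample x
    sample covariance; coordinates are eigenvectors scaled by the square root
    of their eigenvalue.
    """
    codes = matrix.codes.astype(float)
    called = codes != MISSING
    codes[~called] = np.nan
    col_mean = np.nanmean(codes, axis=0)
    p_hat = col_mean / 2
    keep = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1)
    codes = codes[:, keep]
    col_mean = col_mean[keep]
    p_hat = p_hat[keep]
    inds = np.where(np.isnan(codes))
    codes[inds] = np.take(col_mean, inds[1])
    X = (codes - col_mean) / np.sqrt(p_hat * (1 - p_hat))
    n_sites = X.shape[1]
    if n_sites == 0:
        k = n_components or matrix.n_samples
        return PCAResult(
            np.zeros(k), np.zeros((matrix.n_samples, k)), list(matrix.sample_ids)
        )
    cov = X @ X.T / n_sites
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    if n_components is not None:
        eigval = eigval[:n_components]
        eigvec = eigvec[:, :n_components]
    coords = eigvec * np.sqrt(eigval)[None, :]
    return PCAResult(eigval, coords, list(matrix.sample_ids))
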