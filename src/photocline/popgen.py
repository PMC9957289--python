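"""Pairwise multilocus F_ST, composite LD and a neighbor-joining tree.

F_ST between two populations is a multilocus Nei-style G_ST with a
small-sample correction: per locus the within-population gene diversity is
the mean over the two populations of (2n/(2n-1)) * (1 - sum p_i^2), the
total diversity uses the mean allele frequencies with the analogous
correction at the pooled sample size, and the multilocus value sums
numerator and denominator over loci polymorphic in the pair's union before
taking the ratio. Negative estimates are clamped to zero.

Linkage disequilibrium between two sites is the composite (phase-free) r^2:
the squared Pearson correlation of per-specimen alt-allele dosages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import FrequencyMatrix, InputError

logger = logging.getLogger(__name__)


def _pair_locus_diversities(p_a, p_b, n_a, n_b):
    """Corrected within (H_S) and total (H_T) diversities at one biallelic
    locus for one population pair; returns (H_S, H_T)."""
    def h_unbiased(p, n):
        return (2 * n / (2 * n - 1.0)) * 2.0 * p * (1.0 - p)

    h_s = 0.5 * (h_unbiased(p_a, n_a) + h_unbiased(p_b, n_b))
    p_bar = 0.5 * (p_a + p_b)
    n_tot = n_a + n_b
    h_t = (2 * n_tot / (2 * n_tot - 1.0)) * 2.0 * p_bar * (1.0 - p_bar)
    return h_s, h_t


def pairwise_fst(freqs: FrequencyMatrix, pop_a: str, pop_b: str) -> float:
    """Multilocus sample-size-corrected G_ST between two populations.

    Uses the loci genotyped in both populations and polymorphic in their
    union; returns 0.0 when every shared locus is monomorphic (identical
    fixed populations). Negative estimates are clamped to 0.
    """
    fa = freqs.freq.loc[pop_a]
    fb = freqs.freq.loc[pop_b]
    na = freqs.sample_n.loc[pop_a]
    nb = freqs.sample_n.loc[pop_b]
    shared = fa.notna() & fb.notna() & (na > 0) & (nb > 0)
    if not shared.any():
        raise InputError(
            f"populations {pop_a!r} and {pop_b!r} share no genotyped loci"
        )
    sum_hs = 0.0
    sum_ht = 0.0
    for locus in fa.index[shared]:
        p_a, p_b = fa[locus], fb[locus]
        # polymorphic in the union: skip loci fixed for the same allele
        if (p_a in (0.0, 1.0)) and p_a == p_b:
            continue
        h_s, h_t = _pair_locus_diversities(p_a, p_b, na[locus], nb[locus])
        sum_hs += h_s
        sum_ht += h_t
    if sum_ht == 0.0:
        return 0.0
    fst = (sum_ht - sum_hs) / sum_ht
    if fst < 0.0:
        logger.debug("negative F_ST %.4f for (%s, %s) clamped to 0",
                     fst, pop_a, pop_b)
        return 0.0
    return min(float(fst), 1.0)


def fst_matrix(freqs: FrequencyMatrix) -> pd.DataFrame:
    """Symmetric population x population multilocus F_ST matrix."""
    pops = freqs.populations
    if len(pops) < 2:
        raise InputError("need at least 2 populations")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            v = pairwise_fst(freqs, a, b)
            mat.loc[a, b] = v
            mat.loc[b, a] = v
    return mat


def fst_summary(mat: pd.DataFrame, lineages: dict) -> dict:
    """Min/max/mean of the off-diagonal F_ST, overall and by lineage block.

    ``lineages`` maps population id -> lineage label (e.g. WEST/EAST).
    """
    pops = list(mat.index)
    values = {"overall": [], "within_WEST": [], "within_EAST": [],
              "between": []}
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            v = float(mat.loc[a, b])
            values["overall"].append(v)
            la, lb = lineages.get(a), lineages.get(b)
            if la == lb == "WEST":
                values["within_WEST"].append(v)
            elif la == lb == "EAST":
                values["within_EAST"].append(v)
            elif la != lb:
                values["between"].append(v)
    out = {}
    for key, vals in values.items():
        if vals:
            out[key] = {
                "n_pairs": len(vals),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "mean": float(np.mean(vals)),
            }
    return out


def composite_ld_r2(dosages_i, dosages_j) -> float:
    """Composite (phase-free) LD: squared Pearson correlation of diploid
    alt-allele dosages (0/1/2). Specimens missing either genotype are
    dropped pairwise; monomorphic input yields NaN."""
    x = np.asarray(dosages_i, dtype=float)
    y = np.asarray(dosages_j, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_matrix(dosages: pd.DataFrame) -> pd.DataFrame:
    """Symmetric SNP x SNP composite r^2 matrix from a specimen x SNP
    dosage table (diagonal 1, undefined pairs NaN)."""
    labels = list(dosages.columns)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    arr = dosages.to_numpy(dtype=float)
    for i in range(len(labels)):
        mat.iloc[i, i] = 1.0
        for j in range(i + 1, len(labels)):
            r2 = composite_ld_r2(arr[:, i], arr[:, j])
            mat.iloc[i, j] = r2
            mat.iloc[j, i] = r2
    return mat


class _Node:
    __slots__ = ("label", "children")  # children: [(child, branch_length)]

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return str(self.label)
        inner = ",".join(f"{c._nwk()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dist: pd.DataFrame) -> str:
    """Saitou-Nei neighbor-joining tree from a symmetric distance matrix.

    Ties in the Q criterion are broken deterministically toward the
    lowest-index pair. Negative branch-length estimates are clamped to 0
    (logged). Returns an unrooted tree in Newick format with the input
    labels as leaves.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise InputError("neighbor-joining needs at least 3 taxa")
    d = dist.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T, atol=1e-9):
        raise InputError("distance matrix must be symmetric")
    nodes = [_Node(label=l) for l in labels]
    active = list(range(len(labels)))

    def clamp(x):
        if x < 0.0:
            logger.debug("negative branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 2:
        n = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (n - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic: argmin scans row-major -> lowest-index pair wins ties
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = active[i_s], active[j_s]
        dij = sub[i_s, j_s]
        bl_i = 0.5 * dij + (row_sums[i_s] - row_sums[j_s]) / (2.0 * (n - 2))
        bl_j = dij - bl_i
        parent = _Node(children=[(nodes[i], clamp(bl_i)),
                                 (nodes[j], clamp(bl_j))])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k_s, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (sub[i_s, k_s] + sub[j_s, k_s] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    dij = d[i, j]
    root = _Node(children=[(nodes[i], clamp(0.5 * dij)),
                           (nodes[j], clamp(0.5 * dij))])
    return root.newick()
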