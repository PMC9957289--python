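"""Population-based gene-environment association.

For every SNP and every environmental proxy the analysis correlates, over
all unordered population pairs, the absolute allele-frequency difference
with the pairwise proxy distance (great-circle km for position; |delta| for
latitude, longitude, altitude and pCPP). Pearson's r is tested two-sided
against the t distribution with (number of pairs - 2) degrees of freedom,
and p-values are Benjamini-Hochberg adjusted within each proxy across the
SNPs of one lineage.

The pairwise design reuses each population in many pairs, so nominal
p-values are anticonservative; an optional permutation p-value (population
labels of the proxy permuted) is available for exchangeability-correct
inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .types import AssociationResult, FrequencyMatrix, InputError, Proxy

EARTH_RADIUS_KM = 6371.0088

DEFAULT_ALPHA = 0.05


def haversine_km(lat_a, lon_a, lat_b, lon_b) -> float:
    """Great-circle distance in km on a sphere of Earth's mean radius."""
    la, lo, lb, ln = map(np.radians, (lat_a, lon_a, lat_b, lon_b))
    h = (np.sin((lb - la) / 2.0) ** 2
         + np.cos(la) * np.cos(lb) * np.sin((ln - lo) / 2.0) ** 2)
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1))))


def pairwise_delta(values) -> np.ndarray:
    """Condensed vector of |Δ| over all unordered pairs, ordered
    lexicographically by population index (scipy condensed convention)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise InputError("need at least 3 populations")
    if np.isnan(v).any():
        raise InputError("missing values in proxy/frequency vector")
    return pdist(v[:, None], metric="cityblock")


def pairwise_geo_km(latitudes, longitudes) -> np.ndarray:
    """Condensed vector of great-circle distances over unordered pairs."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    if len(lat) < 3:
        raise InputError("need at least 3 populations")
    out = []
    for i in range(len(lat)):
        for j in range(i + 1, len(lat)):
            out.append(haversine_km(lat[i], lon[i], lat[j], lon[j]))
    return np.asarray(out)


def pearson_test(x, y):
    """Sample Pearson r with a two-sided t-test p-value (n-2 df).

    Returns (r, r^2, p). Constant input is an error: the correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need equal-length vectors of at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise InputError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def proxy_distance_table(proxies: pd.DataFrame) -> dict:
    """Condensed pairwise-distance vectors for each proxy.

    ``proxies`` is indexed by population id with columns latitude,
    longitude, altitude, pcpp_h. Pair ordering is lexicographic by row
    index and identical across proxies.
    """
    return {
        Proxy.GEO: pairwise_geo_km(proxies["latitude"], proxies["longitude"]),
        Proxy.LAT: pairwise_delta(proxies["latitude"]),
        Proxy.LON: pairwise_delta(proxies["longitude"]),
        Proxy.ALT: pairwise_delta(proxies["altitude"]),
        Proxy.PCPP: pairwise_delta(proxies["pcpp_h"]),
    }


def associate_all(
    freqs: FrequencyMatrix,
    proxies: pd.DataFrame,
    populations=None,
    alpha: float = DEFAULT_ALPHA,
    permutation_p: bool = False,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[AssociationResult]:
    """Per-SNP, per-proxy pairwise-difference Pearson tests with BH
    adjustment.

    ``proxies``: DataFrame indexed by population id with columns latitude,
    longitude, altitude, pcpp_h. ``populations`` restricts the analysis
    (e.g. to one lineage); SNPs monomorphic among the selected populations
    are excluded. BH families are per proxy across the tested SNPs.
    """
    if populations is None:
        populations = freqs.populations
    populations = [p for p in populations if p in set(freqs.populations)]
    if len(populations) < 3:
        raise InputError("need at least 3 populations for pairwise analysis")
    missing = set(populations) - set(proxies.index)
    if missing:
        raise InputError(f"proxies missing for populations {sorted(missing)}")
    prox = proxies.loc[populations]
    dist = proxy_distance_table(prox)

    sub = freqs.freq.loc[populations]
    tested = []
    for snp in sub.columns:
        col = sub[snp]
        vals = col.dropna()
        if len(vals) < 3 or np.ptp(vals.to_numpy()) == 0.0:
            continue  # monomorphic or undersampled within the selection
        tested.append(snp)
    if not tested:
        return []

    rng = np.random.default_rng(seed)
    results = []
    for proxy, x_full in dist.items():
        rows = []
        for snp in tested:
            col = sub[snp].to_numpy(dtype=float)
            keep_pop = ~np.isnan(col)
            if keep_pop.all():
                x, y = x_full, pdist(col[:, None], metric="cityblock")
            else:
                idx = np.flatnonzero(keep_pop)
                if len(idx) < 3:
                    continue
                sel = _condensed_subset(len(col), idx)
                x = x_full[sel]
                y = pdist(col[idx, None], metric="cityblock")
            if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
                continue
            r, r2, p = pearson_test(x, y)
            if permutation_p:
                p = _perm_pvalue(col, keep_pop, x_full, r, rng,
                                 n_permutations)
            rows.append((snp, len(x), r, r2, p))
        if not rows:
            continue
        padj = bh_adjust([row[4] for row in rows])
        for (snp, n_pairs, r, r2, p), pa in zip(rows, padj):
            results.append(AssociationResult(
                snp_label=snp, proxy=proxy, n_pairs=n_pairs,
                r=r, r2=r2, p=p, p_adj=float(pa),
                significant=bool(pa < alpha),
            ))
    results.sort(key=lambda a: (a.proxy.value, a.snp_label))
    return results


def _condensed_subset(n, idx):
    """Indices into a condensed n-choose-2 vector selecting the pairs whose
    both members are in ``idx``."""
    pos = {}
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            pos[(i, j)] = k
            k += 1
    return np.array([pos[(idx[a], idx[b])]
                     for a in range(len(idx)) for b in range(a + 1, len(idx))],
                    dtype=int)


def _perm_pvalue(col, keep_pop, x_full, r_obs, rng, n_perm):
    """Permutation p-value: population labels of the frequencies permuted,
    pairwise |Δfreq| recomputed, |r| compared with the observed |r|."""
    idx = np.flatnonzero(keep_pop)
    sel = (slice(None) if keep_pop.all()
           else _condensed_subset(len(col), idx))
    x = x_full[sel] if not keep_pop.all() else x_full
    vals = col[idx]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(vals)
        y = pdist(perm[:, None], metric="cityblock")
        if np.ptp(y) == 0.0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy results table (one row per SNP x proxy)."""
    return pd.DataFrame({
        "snp_label": [a.snp_label for a in results],
        "proxy": [a.proxy.value for a in results],
        "n_pairs": [a.n_pairs for a in results],
        "r": [a.r for a in results],
        "r2": [a.r2 for a in results],
        "p": [a.p for a in results],
        "p_adj": [a.p_adj for a in results],
        "significant": [a.significant for a in results],
    })


def manhattan_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Plot-ready table: -log10 adjusted p and R^2 per SNP x proxy,
    ordered by position label."""
    df = results_table(results)
    df["neg_log10_p_adj"] = -np.log10(np.maximum(df["p_adj"], 1e-300))
    return df.sort_values(["proxy", "snp_label"]).reset_index(drop=True)
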