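"""Independent reference implementations used only to check the package.

These deliberately take different algorithmic routes from the library code:
a Meeus-style solar ephemeris for declination/day length, a dense
brute-force scan for the threshold crossing, a naive column scan for SNP
calling, direct-formula popgen statistics, and a hand-rolled step-up for
the FDR adjustment.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Solar oracle: NOAA-spreadsheet (Meeus) ephemeris, independent of the
# Fourier-series route used by the package.
# ---------------------------------------------------------------------------


def _meeus_declination_deg(day_of_year: float, year: int = 2019) -> float:
    """Apparent solar declination from the Meeus low-accuracy ephemeris as
    used in NOAA's solar calculator, at solar noon of the given day."""
    # Julian day for Jan 1 of a non-leap year anchor, then add day-of-year
    # JD of year-01-01 00:00 UT (standard month/day formula with M=1, D=1)
    jd0 = 367 * year - (7 * (year + (1 + 9) // 12)) // 4 + (275 * 1) // 9 + 1 \
        + 1721013.5
    jd = jd0 + (day_of_year - 1) + 0.5  # noon
    t = (jd - 2451545.0) / 36525.0
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mr = math.radians(m)
    c = ((1.914602 - t * (0.004817 + 0.000014 * t)) * math.sin(mr)
         + (0.019993 - 0.000101 * t) * math.sin(2 * mr)
         + 0.000289 * math.sin(3 * mr))
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))
    eps0 = (23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059
            - t * 0.001813))) / 60.0) / 60.0)
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))
    decl = math.degrees(math.asin(
        math.sin(math.radians(eps)) * math.sin(math.radians(app_long))))
    return decl


def noaa_declination(day_of_year: float) -> float:
    return _meeus_declination_deg(day_of_year)


def noaa_civil_daylength(latitude: float, day_of_year: float) -> float:
    """Hours between solar altitude -6 deg crossings, from the Meeus
    declination and the standard hour-angle formula."""
    decl = math.radians(_meeus_declination_deg(day_of_year))
    phi = math.radians(latitude)
    cos_h = ((math.cos(math.radians(96.0))
              - math.sin(phi) * math.sin(decl))
             / (math.cos(phi) * math.cos(decl)))
    cos_h = min(1.0, max(-1.0, cos_h))
    return 2.0 * math.degrees(math.acos(cos_h)) / 15.0


# ---------------------------------------------------------------------------
# pCPP oracle: dense 0.01-day scan for the last rising crossing before the
# annual temperature maximum.
# ---------------------------------------------------------------------------


def brute_force_pcpp(latitude: float, monthly_temps, threshold_c: float,
                     daylength_fn) -> tuple[float, float]:
    """(crossing_day, photoperiod_h) by scanning the periodic piecewise-
    linear daily temperature at 0.01-day resolution."""
    anchors = np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    anchors = anchors - np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]) + 15
    temps = np.asarray(monthly_temps, dtype=float)
    xs = np.concatenate(([anchors[-1] - 365.0], anchors,
                         [anchors[0] + 365.0]))
    ys = np.concatenate(([temps[-1]], temps, [temps[0]]))
    grid = np.arange(1.0, 366.0, 0.01)
    tt = np.interp(grid, xs, ys)
    t_next = np.roll(tt, -1)
    rising = np.flatnonzero((tt < threshold_c) & (t_next >= threshold_c))
    assert rising.size > 0, "no crossing in oracle"
    peak = int(np.argmax(tt))
    offsets = (peak - rising) % len(grid)
    offsets[offsets == 0] = len(grid)
    i = int(rising[np.argmin(offsets)])
    day = grid[i]
    day_eval = day if day <= 365.0 else day - 365.0
    return day, daylength_fn(latitude, day_eval)


# ---------------------------------------------------------------------------
# Naive SNP-calling oracle: flat column scan over the decoded alignment.
# ---------------------------------------------------------------------------

_IUPAC = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
          "A": "AA", "C": "CC", "G": "GG", "T": "TT"}


def naive_snp_columns(seqs, reference, min_carriers_exclusive=3):
    """Set of 0-based column indices that are biallelic SNPs under the
    carrier rule (specimens with >=1 non-reference allele > threshold)."""
    out = set()
    n_cols = len(reference)
    for col in range(n_cols):
        alleles = set()
        pairs = []
        for s in seqs:
            sym = s[col].upper()
            if sym == "N":
                pairs.append(None)
                continue
            pair = _IUPAC[sym]
            pairs.append(pair)
            alleles.update(pair)
        if len(alleles) != 2:
            continue
        ref = reference[col].upper()
        if ref in alleles:
            alt = next(a for a in alleles if a != ref)
        else:
            counts = {a: sum(p.count(a) for p in pairs if p) for a in alleles}
            ref_like = max(sorted(alleles), key=lambda a: counts[a])
            alt = next(a for a in alleles if a != ref_like)
        carriers = sum(1 for p in pairs if p and alt in p)
        if carriers > min_carriers_exclusive:
            out.add(col)
    return out


# ---------------------------------------------------------------------------
# Popgen oracles.
# ---------------------------------------------------------------------------

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def substitution_is_synonymous(codon, pos, alt):
    mutated = codon[:pos] + alt + codon[pos + 1:]
    return CODON_TABLE[codon] == CODON_TABLE[mutated]


def direct_pairwise_gst(p_a, p_b, n_a, n_b):
    """Symbol-by-symbol multilocus corrected G_ST over biallelic loci.

    p_a/p_b: arrays of alt frequencies; n_a/n_b: diploid sample sizes
    (scalar or per-locus).
    """
    p_a = np.atleast_1d(np.asarray(p_a, dtype=float))
    p_b = np.atleast_1d(np.asarray(p_b, dtype=float))
    n_a = np.broadcast_to(np.asarray(n_a, dtype=float), p_a.shape)
    n_b = np.broadcast_to(np.asarray(n_b, dtype=float), p_b.shape)
    num = 0.0
    den = 0.0
    for pa, pb, na, nb in zip(p_a, p_b, n_a, n_b):
        if pa == pb and pa in (0.0, 1.0):
            continue
        hs_a = (2 * na / (2 * na - 1)) * (1 - pa ** 2 - (1 - pa) ** 2)
        hs_b = (2 * nb / (2 * nb - 1)) * (1 - pb ** 2 - (1 - pb) ** 2)
        hs = 0.5 * (hs_a + hs_b)
        pbar = 0.5 * (pa + pb)
        nt = na + nb
        ht = (2 * nt / (2 * nt - 1)) * (1 - pbar ** 2 - (1 - pbar) ** 2)
        num += ht - hs
        den += ht
    if den == 0.0:
        return 0.0
    return max(0.0, min(1.0, num / den))


def bh_stepup(pvals):
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
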