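# Methods

## Solar geometry and the predicted critical photoperiod

Day length is computed from the standard hour-angle formula with the solar
center at −6° altitude (zenith 96°), the civil-twilight convention: dawn and
dusk at −6° are the moments of fastest change in log light intensity and are
the usual "lights on/off" for biological timing. Declination comes from a
Spencer-type Fourier series (error ≤ ~0.3°, i.e. about a minute of day
length); the hour-angle cosine is clamped to [−1, 1] so polar day yields
exactly 24 h and polar night 0 h. The calendar is a fixed 365-day year; leap
days are ignored. Longitude does not enter: it shifts clock times of dawn
and dusk but not their separation.

Monthly mean temperatures are interpolated to daily values by periodic
piecewise-linear interpolation anchored at mid-month days (Jan 15 … Dec 15,
wrapping December to January). Linear interpolation cannot overshoot the
monthly extremes, which keeps the threshold-crossing logic well behaved; a
smoother spline would buy nothing at the precision of monthly climatology.

The pCPP of a locality is the photoperiod at the *spring* crossing of the
temperature threshold (default 6.6 °C): among the rising crossings of the
daily trajectory, the last one before the annual temperature maximum in
cyclic order. For a unimodal annual cycle this is unambiguous — the
trajectory crosses the threshold exactly twice, once falling (autumn) and
once rising (spring) — and matches the intuition of "the ellipse crossing
the threshold line on its way up". The crossing day is refined by linear
interpolation between adjacent days and the photoperiod linearly
interpolated at that fractional day; against a 0.01-day brute-force scan
this is accurate to well under 0.01 h. A threshold at or outside the annual
temperature range raises a `NoCrossingError` naming the locality.

The threshold default of 6.6 °C sits inside the 5–10 °C band in which grass
growth starts and is exposed as a parameter (`--threshold`) everywhere.

## SNP calling from diploid consensus sequences

Each specimen contributes one consensus sequence; a plain base is a
homozygote, an IUPAC two-allele code (R/Y/S/W/K/M) a heterozygote, N a
missing genotype. A column is called a SNP when the number of specimens
carrying at least one copy of the non-reference allele is strictly greater
than 3 (configurable). A heterozygote counts as one carrying specimen —
the rule is about specimens, not allele copies; allele-count thresholding
can be had by adjusting `min_carriers_exclusive`. Columns with more than
two segregating bases are excluded with a warning (the downstream
statistics assume biallelic sites), and N is excluded from both numerator
and denominator of the allele frequency.

Position labels count backward from the intron/exon boundary for intronic
sites (boundary-adjacent base = −1) and forward from +1 for exonic sites,
so a label like −158 is the 158th base upstream of the exon start. Coding
effects translate the reference codon and the alt-substituted codon with
the standard genetic code, using the annotated reading-frame phase of the
first exonic base; codons truncated by the fragment edge or containing N
give NA with a warning.

## Population-genetic statistics

**Pairwise multilocus F_ST.** For two populations with alt-allele
frequencies p_a, p_b and diploid sample sizes n_a, n_b at a biallelic
locus,

    Ĥ_S = ½ [ (2n_a/(2n_a−1)) 2p_a(1−p_a) + (2n_b/(2n_b−1)) 2p_b(1−p_b) ]
    Ĥ_T = (2N/(2N−1)) 2p̄(1−p̄),   p̄ = (p_a+p_b)/2,  N = n_a+n_b

and the multilocus estimate is (ΣĤ_T − ΣĤ_S)/ΣĤ_T over loci genotyped in
both populations and polymorphic in their union. Loci fixed for the same
allele in both populations contribute nothing (adding one leaves the value
unchanged — tested). Negative estimates, which arise by sampling noise when
true differentiation is ~0, are clamped to 0. This is a Nei–Chesser-style
sample-size-corrected G_ST, the estimator family used by the POPTREE
tooling common in this literature; Weir–Cockerham θ would differ by a few
hundredths at these sample sizes.

**Composite LD.** With unphased Sanger-consensus genotypes, haplotypic D is
not identifiable, so LD is reported as the squared Pearson correlation of
per-specimen alt-allele dosages (0/1/2) — the composite r², which equals
the haplotype r² for phased (heterozygote-free) data (tested). Pairs with a
monomorphic member are undefined and reported missing.

**Neighbor joining.** Saitou–Nei agglomeration on the pairwise F_ST matrix
with deterministic lowest-index tie-breaking, negative branch-length
estimates clamped to 0 (logged). On an additive metric the algorithm
reproduces topology and path lengths exactly (tested on the 4-taxon case
against the generating tree).

## Gene–environment association

The design is population-based: for each SNP, |Δ allele frequency| over all
unordered population pairs is correlated with the pairwise distance in each
of five environmental proxies — great-circle distance (haversine, Earth
mean radius 6371.0088 km), |Δlat|, |Δlon|, |Δalt|, |ΔpCPP|. Pearson's r is
tested two-sided against a t distribution with (number of pairs − 2)
degrees of freedom, and BH adjustment is applied per proxy across the SNPs
tested within one lineage (five families per lineage), α = 0.05 on the
adjusted p.

Two caveats are inherent to this design and deliberately preserved. First,
the P(P−1)/2 pairs are not independent, so nominal p-values are
anticonservative; an optional permutation p-value (population labels of the
frequency vector permuted, |r| compared to the observed) is available via
`permutation_p=True` / `--permutation-p` for exchangeability-correct
inference, default off. Second, the tests are per SNP; no attempt is made
to model spatial autocorrelation or joint SNP effects. The test suite
accordingly asserts relative behavior (planted clines rank far above
neutral SNPs) rather than exact type-I rates.

Populations can be excluded from any analysis (`--exclude-populations`),
e.g. to check that island populations do not drive a cline.

## Synthetic-study generator

The generator emulates the study design end to end with known ground
truth. Defaults: 43 localities (15 west-lineage, 28 east-lineage),
latitudes uniform in [42, 59]°N, western longitudes in [−6, 5]°E, eastern
in [14, 39]°E, altitudes log-uniform in [4, 2146] m, 6 diploid specimens
per locality; a 1678-bp fragment (829 bp intron + 849 bp exon) carrying 49
SNPs (22 intronic, 27 exonic) of which 12 (5 intronic, 7 exonic, at the
reserved labels −158, −144, −128, −97, −45, 126, 249, 366, 480, 573, 660,
729) follow a planted pCPP cline.

*Climate.* Monthly temperature is a sinusoid T(m) = μ − A·cos(2π(m−1−lag)/12)
with annual mean μ = 24 − 0.25·latitude (°C), amplitude A = 7.5 +
0.18·(longitude+6) — continentality grows eastward — and the coldest day
about 30 days after the winter solstice. These coefficients were chosen so
that (i) every site in the latitude × longitude envelope crosses 6.6 °C
(guarded by a generation-time error), and (ii) the resulting pCPPs span
roughly 11.6–15.8 h, the realistic range for this geography; steeper or
cooler parameterizations push high-latitude maritime sites into late-spring
crossings with implausibly long photoperiods.

*Allele frequencies.* Cline SNPs: p = clamp(p₀ + β·(pCPP − mean pCPP),
0.02, 0.98) with p₀ ~ U(0.3, 0.7), random sign, and slope β = 0.3 per hour
— chosen so the steepest planted clines traverse most of the frequency
range across the realized ~3 h western pCPP span, as the strongest clinal
sites do in real data of this kind; β is a knob, and β = 0 reduces cline
SNPs to neutral behavior (tested). Neutral SNPs: a lineage-specific
baseline drawn from Beta(c, c) with c = 0.5 per lineage (strongly diverged
baselines produce the high between-lineage F_ST block structure), plus
per-population Beta noise at concentration 10. Genotypes are binomial(2, p)
per specimen with beta-binomial overdispersion κ = 0.1 standing in for
drift; together these give within-lineage multilocus F_ST of ~0.11–0.16 and
between-lineage means of ~0.3–0.4. Columns that would fail the >3-carrier
rule are resampled (logged), so planted SNPs are callable by construction.

What the generator does *not* emulate: linkage between columns (sites are
independent, so LD tests use hand-built genotype fixtures), indels,
sequencing error, selection on non-synonymous sites (alt alleles are drawn
uniformly, so the synonymous fraction of exonic SNPs reflects the
genetic-code baseline of ~25%, not the enrichment seen in real data),
spatially autocorrelated drift, and real haplotype structure. Passing tests
therefore demonstrate correctness of the estimators and the detection
machinery under the planted model, not field realism of any particular
number.

All randomness flows from a single integer seed; outputs are byte-identical
across reruns (tested).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the full two-lineage study
(43 populations, 49 SNPs, 258 specimens) and the 15-population western
scenario; both complete in seconds on one core, so no down-scaling tricks
are needed. Brute-force oracles (0.01-day climate scans, naive column
scans, direct-formula G_ST, hand-rolled BH step-up, Meeus-ephemeris day
lengths) live in `tests/oracles.py` and are never called by library code.

## Known limitations

- The "spring crossing" definition assumes a unimodal annual temperature
  cycle; multi-modal daily trajectories (possible with extreme monthly
  inputs) resolve to the last rising crossing before the warmest day, which
  may not be meaningful climatologically.
- The F_ST estimator identity matters at the third decimal; comparisons
  with values computed by other tools should allow for estimator ambiguity
  (a Weir–Cockerham option would be a natural extension).
- The pairwise association design cannot give calibrated absolute p-values
  (see above); treat adjusted p-values as a ranking device unless the
  permutation option is used.
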