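"""Synthetic study generator with known ground truth.

Emulates the study design the pipeline targets: ~43 sampling localities in
two diverged lineages spanning latitudes 42-59 N, a ~1700 bp gene fragment
(829 bp intronic + 849 bp exonic), sinusoid-like annual temperature cycles
whose amplitude grows with continentality (eastness), and a SNP panel in
which a planted subset follows a frequency cline in the predicted critical
photoperiod (pCPP) while the rest drift neutrally around lineage-specific
baselines.

Diploid specimens are written as consensus sequences with IUPAC ambiguity
codes at heterozygous sites, so the generated FASTA exercises the same
decoding path as real Sanger consensus data. All randomness flows from a
single seed; outputs are byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import climate
from .types import (
    FragmentAnnotation,
    InputError,
    Lineage,
    Locality,
    MonthlyTemperatureSeries,
    SpecimenSequence,
)

logger = logging.getLogger(__name__)

#: Default planted-cline position labels: 5 intronic, 7 exonic, echoing the
#: strongest clinal sites of the study system (e.g. SNP-158, SNP-128,
#: SNP126).
DEFAULT_CLINE_LABELS = (-158, -144, -128, -97, -45,
                        126, 249, 366, 480, 573, 660, 729)

_HET_CODE = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
             frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    n_pops_west: int = 15
    n_pops_east: int = 28
    specimens_per_pop: int = 6
    intron_len: int = 829
    exon_len: int = 849
    n_intronic_snps: int = 22
    n_exonic_snps: int = 27
    cline_labels: tuple = DEFAULT_CLINE_LABELS
    cline_slope: float = 0.3         # alt-frequency change per hour of pCPP
    lineage_divergence: float = 0.5  # Beta concentration of lineage baselines
    pop_noise_concentration: float = 10.0  # per-pop Beta noise around baseline
    drift_kappa: float = 0.1         # beta-binomial overdispersion (0 = none)
    exact_genotypes: bool = False    # deterministic rounding, no sampling
    # climate: mean decreases with latitude, amplitude grows with eastness
    temp_mean_intercept: float = 24.0
    temp_mean_lat_slope: float = -0.25   # degC per degree latitude
    temp_amp_base: float = 7.5
    temp_amp_lon_slope: float = 0.18     # degC per degree east of -6
    temp_phase_lag_months: float = 0.3   # coldest day ~30 d after the solstice
    threshold_c: float = climate.DEFAULT_THRESHOLD_C

    @property
    def n_snps_total(self) -> int:
        return self.n_intronic_snps + self.n_exonic_snps

    def __post_init__(self):
        for name in ("n_pops_west", "n_pops_east"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.specimens_per_pop < 1:
            raise InputError("specimens_per_pop must be positive")
        if len(self.cline_labels) > self.n_snps_total:
            raise InputError("more cline labels than SNPs")


def west_scenario(seed: int = 0, **overrides) -> "SimulationConfig":
    """Single-lineage scenario: 15 western populations, 43 SNPs of which 12
    follow a planted pCPP cline (the emulated western-lineage panel)."""
    kw = dict(seed=seed, n_pops_west=15, n_pops_east=0,
              n_intronic_snps=22, n_exonic_snps=21)
    kw.update(overrides)
    return SimulationConfig(**kw)


def synth_localities(cfg: SimulationConfig, rng=None) -> list[Locality]:
    """Sampling sites: latitudes uniform in [42, 59]; western longitudes in
    [-6, 5], eastern in [14, 39]; altitudes log-uniform in [4, 2146] m."""
    rng = rng or np.random.default_rng(cfg.seed)
    locs = []
    spans = [(Lineage.WEST, cfg.n_pops_west, (-6.0, 5.0)),
             (Lineage.EAST, cfg.n_pops_east, (14.0, 39.0))]
    i = 0
    for lineage, n, (lo, hi) in spans:
        for _ in range(n):
            i += 1
            lat = rng.uniform(42.0, 59.0)
            lon = rng.uniform(lo, hi)
            alt = float(np.exp(rng.uniform(np.log(4.0), np.log(2146.0))))
            locs.append(Locality(
                id=f"P{i:02d}", name=f"site-{i:02d}",
                latitude=float(lat), longitude=float(lon),
                altitude=round(alt, 1), lineage=lineage,
                n_specimens=cfg.specimens_per_pop,
            ))
    return locs


def synth_climate(loc: Locality, cfg: SimulationConfig) -> MonthlyTemperatureSeries:
    """Monthly temperatures: T(m) = mu - A*cos(2*pi*(m-1-lag)/12) with the
    annual mean decreasing in latitude and the amplitude growing eastward
    (continentality). Raises if the configured threshold is never crossed."""
    mu = cfg.temp_mean_intercept + cfg.temp_mean_lat_slope * loc.latitude
    amp = cfg.temp_amp_base + cfg.temp_amp_lon_slope * (loc.longitude + 6.0)
    m = np.arange(1, 13)
    temps = mu - amp * np.cos(2 * np.pi * (m - 1 - cfg.temp_phase_lag_months) / 12.0)
    if not temps.min() < cfg.threshold_c < temps.max():
        raise InputError(
            f"climate config gives no {cfg.threshold_c} degC crossing at "
            f"locality {loc.id} (range {temps.min():.1f}..{temps.max():.1f})"
        )
    return MonthlyTemperatureSeries(locality_id=loc.id,
                                    temps=tuple(np.round(temps, 4)))


def synth_pcpps(localities, cfg: SimulationConfig) -> pd.Series:
    """pCPP per locality under the synthetic climate model."""
    out = {}
    for loc in localities:
        series = synth_climate(loc, cfg)
        out[loc.id] = climate.pcpp_for_locality(loc, series, cfg.threshold_c).pcpp_h
    return pd.Series(out, name="pcpp_h")


def _snp_columns(cfg: SimulationConfig, rng) -> tuple[list, list]:
    """Choose distinct SNP position labels: the reserved cline labels plus
    random non-cline positions split intronic/exonic per the config."""
    cline = list(cfg.cline_labels)
    n_cline_intr = sum(1 for l in cline if l < 0)
    n_cline_exon = len(cline) - n_cline_intr
    if n_cline_intr > cfg.n_intronic_snps or n_cline_exon > cfg.n_exonic_snps:
        raise InputError("cline labels exceed the configured SNP counts")
    used = set(cline)
    intr_pool = [-k for k in range(1, cfg.intron_len + 1) if -k not in used]
    exon_pool = [k for k in range(1, cfg.exon_len + 1) if k not in used]
    neutral = (
        list(rng.choice(intr_pool, cfg.n_intronic_snps - n_cline_intr,
                        replace=False))
        + list(rng.choice(exon_pool, cfg.n_exonic_snps - n_cline_exon,
                          replace=False))
    )
    return cline, [int(x) for x in neutral]


def synth_truth_and_frequencies(
    localities, pcpps: pd.Series, cfg: SimulationConfig, rng=None
):
    """Per-population true alt-allele frequencies and a truth table.

    Cline SNPs: p_pop = clamp(p0 + beta * (pCPP_pop - mean pCPP), .02, .98).
    Neutral SNPs: a lineage-specific baseline (Beta with the divergence
    concentration, drawn independently per lineage so the two lineages
    diverge) plus per-population Beta noise.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    cline, neutral = _snp_columns(cfg, rng)
    pop_ids = [loc.id for loc in localities]
    lineage_of = {loc.id: loc.lineage.value for loc in localities}
    pc = pcpps.loc[pop_ids].to_numpy()
    pc_centered = pc - pc.mean()

    freq = {}
    truth_rows = []
    for label in cline:
        p0 = rng.uniform(0.3, 0.7)
        sign = rng.choice([-1.0, 1.0])
        beta = sign * cfg.cline_slope
        freq[label] = np.clip(p0 + beta * pc_centered, 0.02, 0.98)
        truth_rows.append({"position_label": label, "class": "cline",
                           "p0": round(p0, 6), "beta": beta})
    lineages = sorted({l.lineage.value for l in localities})
    for label in neutral:
        c = cfg.lineage_divergence
        base = {lin: rng.beta(c, c) for lin in lineages}
        k = cfg.pop_noise_concentration
        p = np.array([
            rng.beta(max(base[lineage_of[pid]] * k, 1e-3),
                     max((1.0 - base[lineage_of[pid]]) * k, 1e-3))
            for pid in pop_ids
        ])
        freq[label] = np.clip(p, 0.02, 0.98)
        truth_rows.append({"position_label": label, "class": "neutral",
                           "p0": round(float(np.mean(list(base.values()))), 6),
                           "beta": 0.0})
    labels = cline + neutral
    truth = pd.DataFrame(truth_rows).set_index("position_label").loc[labels]
    freqs = pd.DataFrame(freq, index=pop_ids)[labels]
    return freqs, truth.reset_index()


def _draw_genotypes(p, n, cfg, rng):
    """Alt-allele dosages (0/1/2) for n diploids at true frequency p."""
    if cfg.exact_genotypes:
        alt_total = int(round(p * 2 * n))
        g = [2] * (alt_total // 2) + [1] * (alt_total % 2)
        g += [0] * (n - len(g))
        return np.array(g[:n], dtype=int)
    if cfg.drift_kappa > 0:
        theta = (1.0 - cfg.drift_kappa) / cfg.drift_kappa
        p = rng.beta(max(p * theta, 1e-6), max((1.0 - p) * theta, 1e-6))
    return rng.binomial(2, p, size=n)


def synth_alignment(
    localities, freqs: pd.DataFrame, cfg: SimulationConfig, rng=None,
    min_carriers_exclusive: int = 3, max_resample: int = 100,
):
    """FASTA-ready specimen sequences plus the fragment annotation.

    A random reference fragment is drawn; each SNP column receives diploid
    genotypes binomial in the population's true frequency (with optional
    beta-binomial drift overdispersion). Columns failing the >3-carrier
    rule are resampled (logged) so every planted SNP is callable.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    total_len = cfg.intron_len + cfg.exon_len
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=total_len)
    annotation = FragmentAnnotation(
        intron_len=cfg.intron_len, exon_len=cfg.exon_len,
        cds_frame_offset=0, reference_seq="".join(ref),
    )
    from .variants import label_to_column  # local import avoids a cycle

    pop_ids = list(freqs.index)
    n_per = cfg.specimens_per_pop
    n_specimens = len(pop_ids) * n_per
    seqs = np.tile(ref, (n_specimens, 1))
    specimen_meta = [(f"{pid}-{k + 1:02d}", pid)
                     for pid in pop_ids for k in range(n_per)]

    for label in freqs.columns:
        col = label_to_column(int(label), annotation)
        ref_base = annotation.reference_seq[col]
        alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
        for attempt in range(max_resample):
            dosages = np.concatenate([
                _draw_genotypes(freqs.loc[pid, label], n_per, cfg, rng)
                for pid in pop_ids
            ])
            if (dosages > 0).sum() > min_carriers_exclusive:
                break
            if cfg.exact_genotypes:
                break  # deterministic: resampling cannot change the draw
        else:
            logger.warning("SNP %s failed the carrier rule after %d "
                           "resamples; kept last draw", label, max_resample)
        column = np.where(
            dosages == 0, ref_base,
            np.where(dosages == 2, alt_base,
                     _HET_CODE[frozenset((ref_base, alt_base))]),
        )
        seqs[:, col] = column

    alignment = [
        SpecimenSequence(specimen_id=sid, locality_id=pid,
                         seq="".join(row))
        for (sid, pid), row in zip(specimen_meta, seqs)
    ]
    return alignment, annotation


def simulate_study(cfg: SimulationConfig):
    """Full synthetic study: localities, climates, pCPPs, truth frequencies
    and a diploid alignment. Returns a dict of the pieces."""
    rng = np.random.default_rng(cfg.seed)
    localities = synth_localities(cfg, rng)
    series = {loc.id: synth_climate(loc, cfg) for loc in localities}
    pcpps = synth_pcpps(localities, cfg)
    freqs, truth = synth_truth_and_frequencies(
        localities, pcpps, cfg, np.random.default_rng(cfg.seed + 1))
    alignment, annotation = synth_alignment(
        localities, freqs, cfg, np.random.default_rng(cfg.seed + 2))
    return {
        "config": cfg,
        "localities": localities,
        "temperatures": series,
        "pcpps": pcpps,
        "true_frequencies": freqs,
        "truth": truth,
        "alignment": alignment,
        "annotation": annotation,
    }
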