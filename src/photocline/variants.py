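"""SNP calling from a per-specimen consensus alignment.

Sanger consensus sequences encode diploid genotypes per position: a plain
base is a homozygote, an IUPAC two-allele ambiguity code a heterozygote, and
N a missing genotype. A column is called a SNP when strictly more than a
configurable number of specimens (default 3) carry at least one copy of the
non-reference allele; multi-allelic columns are excluded.

Position labels follow the fragment's intron/exon structure: intronic
columns count backward from the intron/exon boundary (boundary-adjacent
base = -1), exonic columns count forward from +1.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .types import (
    Effect,
    FormatError,
    FragmentAnnotation,
    FrequencyMatrix,
    InputError,
    Region,
    SnpRecord,
    SpecimenSequence,
)

logger = logging.getLogger(__name__)

#: IUPAC two-allele ambiguity codes -> unordered allele pair.
IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

_VALID = set("ACGTN") | set(IUPAC_HET)

DEFAULT_MIN_CARRIERS_EXCLUSIVE = 3


def read_alignment(fasta_path) -> list[SpecimenSequence]:
    """Read an aligned FASTA whose headers encode ``specimen_id|locality_id``.

    Raises :class:`FormatError` on ragged alignments, malformed headers, or
    symbols outside A/C/G/T/N and the two-allele IUPAC codes.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no sequences found in {fasta_path}")
    out = []
    length = None
    for rec in records:
        if "|" not in rec.id:
            raise FormatError(
                f"header {rec.id!r} lacks the 'specimen|locality' separator"
            )
        specimen_id, locality_id = rec.id.split("|", 1)
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise FormatError(
                f"ragged alignment: {rec.id!r} has length {len(seq)}, "
                f"expected {length}"
            )
        for col, sym in enumerate(seq):
            if sym not in _VALID:
                raise FormatError(
                    f"invalid symbol {sym!r} in specimen {specimen_id!r} "
                    f"at column {col}"
                )
        out.append(SpecimenSequence(specimen_id=specimen_id,
                                    locality_id=locality_id, seq=seq))
    return out


def genotype_column(column_symbols):
    """Decode one alignment column into per-specimen diploid genotypes.

    Returns ``(genotypes, multi_allelic)`` where each genotype is an
    unordered base pair or None (missing), and ``multi_allelic`` is True
    when more than two bases segregate in the column.
    """
    genotypes = []
    alleles = set()
    for sym in column_symbols:
        sym = sym.upper()
        if sym == "N":
            genotypes.append(None)
        elif sym in IUPAC_HET:
            pair = IUPAC_HET[sym]
            genotypes.append(pair)
            alleles.update(pair)
        elif sym in "ACGT":
            genotypes.append((sym, sym))
            alleles.add(sym)
        else:
            raise FormatError(f"invalid symbol {sym!r} in column")
    return genotypes, len(alleles) > 2


def classify_region(column_index: int, annotation: FragmentAnnotation):
    """Region (intronic/exonic) and position label for one column."""
    total = annotation.intron_len + annotation.exon_len
    if not 0 <= column_index < total:
        raise InputError(f"column index {column_index} outside [0, {total})")
    if column_index < annotation.intron_len:
        return Region.INTRONIC, -(annotation.intron_len - column_index)
    return Region.EXONIC, column_index - annotation.intron_len + 1


def label_to_column(position_label: int, annotation: FragmentAnnotation) -> int:
    """Inverse of :func:`classify_region`'s label mapping."""
    if position_label < 0:
        col = annotation.intron_len + position_label
    elif position_label > 0:
        col = annotation.intron_len + position_label - 1
    else:
        raise InputError("position label 0 is undefined")
    total = annotation.intron_len + annotation.exon_len
    if not 0 <= col < total:
        raise InputError(f"label {position_label} outside the fragment")
    return col


def coding_effect(column_index: int, ref_allele: str, alt_allele: str,
                  annotation: FragmentAnnotation) -> Effect:
    """Synonymous/non-synonymous classification of an exonic substitution.

    The reference codon containing the column is translated with the
    standard genetic code and compared with the alt-substituted codon.
    Codons extending outside the sequenced exon, or containing N, give
    ``Effect.NA`` with a warning.
    """
    region, _ = classify_region(column_index, annotation)
    if region is not Region.EXONIC:
        return Effect.NA
    e = column_index - annotation.intron_len  # 0-based offset into the exon
    codon_pos = (e + annotation.cds_frame_offset) % 3
    start = e - codon_pos
    if start < 0 or start + 3 > annotation.exon_len:
        warnings.warn(
            f"codon of column {column_index} extends outside the sequenced "
            f"exon; effect set to NA"
        )
        return Effect.NA
    exon_seq = annotation.reference_seq[annotation.intron_len:]
    codon = exon_seq[start:start + 3].upper()
    if "N" in codon:
        warnings.warn(f"codon {codon} contains N; effect set to NA")
        return Effect.NA
    # substitute the ref allele too, in case the ref was taken as the major
    # allele rather than the reference base
    ref_codon = codon[:codon_pos] + ref_allele.upper() + codon[codon_pos + 1:]
    alt_codon = codon[:codon_pos] + alt_allele.upper() + codon[codon_pos + 1:]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return Effect.SYNONYMOUS if aa_ref == aa_alt else Effect.NONSYNONYMOUS


def call_snps(
    alignment: list[SpecimenSequence],
    annotation: FragmentAnnotation,
    min_carriers_exclusive: int = DEFAULT_MIN_CARRIERS_EXCLUSIVE,
) -> list[SnpRecord]:
    """Call biallelic SNPs under the carrier rule.

    A column is a SNP iff the number of specimens carrying at least one
    copy of the non-reference allele is strictly greater than
    ``min_carriers_exclusive``. Multi-allelic columns are excluded with a
    logged warning. The reference allele is the base of
    ``annotation.reference_seq`` at the column (falling back to the major
    allele when the reference base does not segregate).
    """
    if not alignment:
        return []
    n_cols = len(alignment[0].seq)
    if n_cols != len(annotation.reference_seq):
        raise InputError(
            "alignment length does not match the fragment annotation"
        )
    snps = []
    for col in range(n_cols):
        column = [s.seq[col] for s in alignment]
        genotypes, multi = genotype_column(column)
        allele_counts = Counter(
            a for g in genotypes if g is not None for a in g
        )
        if len(allele_counts) < 2:
            continue
        if multi:
            logger.warning(
                "column %d is multi-allelic (%s); excluded",
                col, dict(allele_counts),
            )
            continue
        ref = annotation.reference_seq[col].upper()
        if ref not in allele_counts:
            ref = allele_counts.most_common(1)[0][0]
        alt = next(a for a in sorted(allele_counts) if a != ref)
        carriers = sum(
            1 for g in genotypes if g is not None and alt in g
        )
        if carriers <= min_carriers_exclusive:
            continue
        region, label = classify_region(col, annotation)
        effect = (
            coding_effect(col, ref, alt, annotation)
            if region is Region.EXONIC
            else Effect.NA
        )
        per_pop = {}
        for spec, g in zip(alignment, genotypes):
            if g is None:
                continue
            alt_n, tot_n = per_pop.get(spec.locality_id, (0, 0))
            per_pop[spec.locality_id] = (alt_n + g.count(alt), tot_n + 2)
        snps.append(
            SnpRecord(
                position_label=label,
                column_index=col,
                ref_allele=ref,
                alt_allele=alt,
                region=region,
                effect=effect,
                carriers=carriers,
                per_population_counts=per_pop,
            )
        )
    return snps


def allele_frequency_matrix(
    snps: list[SnpRecord], localities: list
) -> FrequencyMatrix:
    """Population x SNP alt-allele frequency matrix.

    ``freq[pop, snp] = alt_count / (2 * genotyped diploids)``; populations
    with no genotyped specimen at a column get NaN.
    """
    pop_ids = [loc.id for loc in localities]
    known = set(pop_ids)
    for snp in snps:
        unknown = set(snp.per_population_counts) - known
        if unknown:
            raise InputError(
                f"SNP{snp.position_label}: unknown locality ids {sorted(unknown)}"
            )
    labels = [snp.position_label for snp in snps]
    freq = pd.DataFrame(np.nan, index=pop_ids, columns=labels, dtype=float)
    sample_n = pd.DataFrame(0, index=pop_ids, columns=labels, dtype=int)
    for snp in snps:
        for pop, (alt_n, tot_n) in snp.per_population_counts.items():
            if tot_n > 0:
                freq.loc[pop, snp.position_label] = alt_n / tot_n
                sample_n.loc[pop, snp.position_label] = tot_n // 2
    return FrequencyMatrix(freq=freq, sample_n=sample_n)


def genotype_dosage_matrix(
    alignment: list[SpecimenSequence], snps: list[SnpRecord]
) -> pd.DataFrame:
    """Specimen x SNP alt-allele dosage matrix (0/1/2, NaN = missing)."""
    idx = [s.specimen_id for s in alignment]
    data = np.full((len(alignment), len(snps)), np.nan)
    for j, snp in enumerate(snps):
        genotypes, _ = genotype_column([s.seq[snp.column_index]
                                        for s in alignment])
        for i, g in enumerate(genotypes):
            if g is not None:
                data[i, j] = g.count(snp.alt_allele)
    return pd.DataFrame(data, index=idx,
                        columns=[s.position_label for s in snps])


def snp_table(snps: list[SnpRecord]) -> pd.DataFrame:
    """Tidy per-SNP summary table."""
    return pd.DataFrame(
        {
            "position_label": [s.position_label for s in snps],
            "column_index": [s.column_index for s in snps],
            "ref": [s.ref_allele for s in snps],
            "alt": [s.alt_allele for s in snps],
            "region": [s.region.value for s in snps],
            "effect": [s.effect.value for s in snps],
            "carriers": [s.carriers for s in snps],
        }
    )
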