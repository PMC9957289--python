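import math

import numpy as np
import pytest

from photocline.types import (
    FragmentAnnotation,
    Lineage,
    Locality,
    MonthlyTemperatureSeries,
    SpecimenSequence,
)


@pytest.fixture
def locality():
    return Locality(id="L1", name="site", latitude=52.0, longitude=5.0,
                    altitude=10.0, lineage=Lineage.WEST, n_specimens=6)


@pytest.fixture
def sinusoid_series():
    """Monthly means of T(d) = 10 - 10*cos(2*pi*(d-15)/365), sampled at the
    mid-month anchor days."""
    from photocline.climate import MONTH_ANCHOR_DAYS
    temps = tuple(10 - 10 * math.cos(2 * math.pi * (d - 15) / 365.0)
                  for d in MONTH_ANCHOR_DAYS)
    return MonthlyTemperatureSeries(locality_id="L1", temps=temps)


def make_annotation(intron_len=10, exon_len=12, frame=0, seq=None, rng=None):
    if seq is None:
        rng = rng or np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=intron_len + exon_len))
    return FragmentAnnotation(intron_len=intron_len, exon_len=exon_len,
                              cds_frame_offset=frame, reference_seq=seq)


def make_alignment(columns, pops, annotation):
    """Build SpecimenSequence records from per-column symbol strings.

    ``columns``: dict column_index -> string of one symbol per specimen;
    all other columns are the reference base. ``pops``: locality id per
    specimen.
    """
    n = len(pops)
    ref = annotation.reference_seq
    rows = [[ref[c] for c in range(len(ref))] for _ in range(n)]
    for col, syms in columns.items():
        assert len(syms) == n
        for i, sym in enumerate(syms):
            rows[i][col] = sym
    return [
        SpecimenSequence(specimen_id=f"s{i}", locality_id=pops[i],
                         seq="".join(row))
        for i, row in enumerate(rows)
    ]
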