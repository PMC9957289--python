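"""Readers and writers for the pipeline's plain-text interchange formats.

Locality table: CSV ``id,name,latitude,longitude,altitude,lineage,n_specimens``.
Temperature table: CSV ``id,jan,...,dec`` (degC monthly means).
Alignment: FASTA with headers ``specimen_id|locality_id``.
Annotation: YAML (intron_len, exon_len, cds_frame_offset, reference fasta
path or inline sequence).
"""

from __future__ import annotations

import pathlib

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    FormatError,
    FragmentAnnotation,
    InputError,
    Lineage,
    Locality,
    MonthlyTemperatureSeries,
)

MONTHS = ("jan", "feb", "mar", "apr", "may", "jun",
          "jul", "aug", "sep", "oct", "nov", "dec")


def read_localities(path) -> list[Locality]:
    df = pd.read_csv(path)
    required = {"id", "name", "latitude", "longitude", "altitude",
                "lineage", "n_specimens"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"locality table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        try:
            lineage = Lineage(str(row.lineage).upper())
        except ValueError:
            raise FormatError(f"unknown lineage {row.lineage!r} for {row.id!r}")
        out.append(Locality(
            id=str(row.id), name=str(row.name), latitude=float(row.latitude),
            longitude=float(row.longitude), altitude=float(row.altitude),
            lineage=lineage, n_specimens=int(row.n_specimens),
        ))
    return out


def write_localities(localities, path) -> None:
    pd.DataFrame({
        "id": [l.id for l in localities],
        "name": [l.name for l in localities],
        "latitude": [l.latitude for l in localities],
        "longitude": [l.longitude for l in localities],
        "altitude": [l.altitude for l in localities],
        "lineage": [l.lineage.value for l in localities],
        "n_specimens": [l.n_specimens for l in localities],
    }).to_csv(path, index=False)


def read_temperatures(path) -> dict:
    df = pd.read_csv(path)
    missing = ({"id"} | set(MONTHS)) - set(df.columns)
    if missing:
        raise FormatError(f"temperature table missing columns {sorted(missing)}")
    return {
        str(row["id"]): MonthlyTemperatureSeries(
            locality_id=str(row["id"]),
            temps=tuple(float(row[m]) for m in MONTHS),
        )
        for _, row in df.iterrows()
    }


def write_temperatures(series_by_id: dict, path) -> None:
    rows = [{"id": k, **dict(zip(MONTHS, s.temps))}
            for k, s in series_by_id.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_alignment(alignment, path) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=f"{s.specimen_id}|{s.locality_id}",
                  description="")
        for s in alignment
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotation(path) -> FragmentAnnotation:
    """YAML with keys intron_len, exon_len, cds_frame_offset and either
    ``reference_seq`` (inline) or ``reference_fasta`` (path, relative to
    the YAML file)."""
    path = pathlib.Path(path)
    meta = yaml.safe_load(path.read_text())
    if "reference_seq" in meta:
        ref = str(meta["reference_seq"]).upper()
    elif "reference_fasta" in meta:
        fasta = path.parent / meta["reference_fasta"]
        recs = list(SeqIO.parse(str(fasta), "fasta"))
        if len(recs) != 1:
            raise FormatError(f"expected one reference record in {fasta}")
        ref = str(recs[0].seq).upper()
    else:
        raise FormatError("annotation needs reference_seq or reference_fasta")
    return FragmentAnnotation(
        intron_len=int(meta["intron_len"]),
        exon_len=int(meta["exon_len"]),
        cds_frame_offset=int(meta.get("cds_frame_offset", 0)),
        reference_seq=ref,
    )


def write_annotation(annotation: FragmentAnnotation, path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump({
        "intron_len": annotation.intron_len,
        "exon_len": annotation.exon_len,
        "cds_frame_offset": annotation.cds_frame_offset,
        "reference_seq": annotation.reference_seq,
    }, sort_keys=False))


def pcpp_table(pcpps: list) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [p.locality_id for p in pcpps],
        "threshold_c": [p.threshold_c for p in pcpps],
        "crossing_day": [round(p.crossing_day, 3) for p in pcpps],
        "pcpp_h": [round(p.pcpp_h, 4) for p in pcpps],
    })


def validate_inputs(localities, series_by_id, alignment=None) -> list[str]:
    """Cross-file consistency diagnostics; empty list = clean."""
    diags = []
    loc_ids = {l.id for l in localities}
    for lid in loc_ids:
        if lid not in series_by_id:
            diags.append(f"locality {lid!r} has no temperature series")
    for sid in series_by_id:
        if sid not in loc_ids:
            diags.append(f"temperature series {sid!r} matches no locality")
    if alignment is not None:
        for spec in alignment:
            if spec.locality_id not in loc_ids:
                diags.append(
                    f"specimen {spec.specimen_id!r} references unknown "
                    f"locality {spec.locality_id!r}"
                )
    return diags
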