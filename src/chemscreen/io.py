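"""Plain-text (TSV) readers and writers for every pipeline interface.

Formats are deliberately simple long-format tables:

* plate reader: well, time_min, od600
* plate map: well, strain, medium, compound, dose_mm
* intensities: tag_id, array_id, intensity (+ array metadata table:
  array_id, role, compound, dose_mm, generations)
* tag map: strain, up_tag, down_tag
* gene coordinates: TSV (gene_id, chromosome, start, end, strand,
  on_array) or a GFF3 subset with ID= and on_array= attributes
* double-mutant fitness: gene_x, gene_y, orientation, condition, W
* annotation: term_id, gene_id
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .growth import Condition, ODTimeSeries
from .screen import ArraySample, TagMap
from .simulate import GenomeLayout

__all__ = [
    "read_plate_reader",
    "write_plate_reader",
    "read_plate_map",
    "write_plate_map",
    "read_curves",
    "read_arrays",
    "write_arrays",
    "read_tag_map",
    "write_tag_map",
    "read_gene_coords",
    "read_double_mutants",
    "write_double_mutants",
    "read_single_fitness",
    "read_annotation",
]


def read_plate_reader(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"well", "time_min", "od600"}
    if not need <= set(df.columns):
        raise ValueError(f"plate-reader TSV needs columns {sorted(need)}")
    return df


def write_plate_reader(series_list: Sequence[ODTimeSeries], path) -> None:
    rows = []
    for s in series_list:
        for t, od in zip(s.times, s.readings):
            rows.append({"well": s.well, "time_min": t, "od600": od})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_plate_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"well", "strain", "medium", "compound", "dose_mm"}
    if not need <= set(df.columns):
        raise ValueError(f"plate-map TSV needs columns {sorted(need)}")
    return df


def write_plate_map(series_list: Sequence[ODTimeSeries], path) -> None:
    rows = [
        {
            "well": s.well,
            "strain": s.strain,
            "medium": s.condition.medium,
            "compound": s.condition.compound or "",
            "dose_mm": s.condition.dose_mm,
        }
        for s in series_list
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_curves(reader_path, map_path) -> list[ODTimeSeries]:
    """Join a plate-reader table with its plate map into ODTimeSeries."""
    od = read_plate_reader(reader_path)
    pm = read_plate_map(map_path).set_index("well")
    out = []
    for well, sub in od.groupby("well"):
        sub = sub.sort_values("time_min")
        meta = pm.loc[well]
        compound = meta["compound"] if isinstance(meta["compound"], str) and meta["compound"] else None
        out.append(
            ODTimeSeries(
                well=str(well),
                strain=str(meta["strain"]),
                condition=Condition(
                    medium=str(meta["medium"]),
                    compound=compound,
                    dose_mm=float(meta["dose_mm"]),
                ),
                times=sub["time_min"].to_numpy(),
                readings=sub["od600"].to_numpy(),
            )
        )
    return out


def read_arrays(intensity_path, metadata_path) -> list[ArraySample]:
    inten = pd.read_csv(intensity_path, sep="\t")
    meta = pd.read_csv(metadata_path, sep="\t").set_index("array_id")
    out = []
    for array_id, sub in inten.groupby("array_id"):
        m = meta.loc[array_id]
        out.append(
            ArraySample(
                array_id=str(array_id),
                role=str(m["role"]),
                intensities=sub.set_index("tag_id")["intensity"]
                .rename_axis(None)
                .rename(None),
                compound=str(m.get("compound", "")) or None,
                dose_mm=float(m.get("dose_mm", 0.0)),
                generations=float(m.get("generations", 20.0)),
            )
        )
    return out


def write_arrays(samples: Sequence[ArraySample], intensity_path, metadata_path) -> None:
    rows = []
    meta = []
    for s in samples:
        for tag, v in s.intensities.items():
            rows.append({"tag_id": tag, "array_id": s.array_id, "intensity": v})
        meta.append(
            {
                "array_id": s.array_id,
                "role": s.role,
                "compound": s.compound or "",
                "dose_mm": s.dose_mm,
                "generations": s.generations,
            }
        )
    pd.DataFrame(rows).to_csv(intensity_path, sep="\t", index=False)
    pd.DataFrame(meta).to_csv(metadata_path, sep="\t", index=False)


def read_tag_map(path) -> TagMap:
    df = pd.read_csv(path, sep="\t")
    return TagMap(
        {
            str(r.strain): (
                str(r.up_tag) if pd.notna(r.up_tag) else None,
                str(r.down_tag) if pd.notna(r.down_tag) else None,
            )
            for r in df.itertuples()
        }
    )


def write_tag_map(tag_map: TagMap, path) -> None:
    rows = [
        {"strain": s, "up_tag": up or "", "down_tag": dn or ""}
        for s, (up, dn) in tag_map.tags.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", attrs.get("gene_id", "")),
                    "chromosome": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "on_array": attrs.get("on_array", "1") not in ("0", "false", "False"),
                }
            )
    return pd.DataFrame(rows)


def read_gene_coords(path) -> GenomeLayout:
    """Gene coordinates from a flat TSV or a GFF3 subset (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        df = _parse_gff3(path)
    else:
        df = pd.read_csv(path, sep="\t")
        if "on_array" in df.columns:
            df["on_array"] = df["on_array"].astype(bool)
        else:
            df["on_array"] = True
    return GenomeLayout.from_frame(df)


def read_double_mutants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_x", "gene_y", "orientation", "condition", "W"}
    if not need <= set(df.columns):
        raise ValueError(f"double-mutant TSV needs columns {sorted(need)}")
    return df


def write_double_mutants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_single_fitness(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "condition", "W"}
    if not need <= set(df.columns):
        raise ValueError(f"single-mutant fitness TSV needs columns {sorted(need)}")
    return df


def read_annotation(path):
    """(term_id, gene_id) TSV → AnnotationMap with the annotated universe."""
    from .enrich import AnnotationMap

    df = pd.read_csv(path, sep="\t")
    need = {"term_id", "gene_id"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation TSV needs columns {sorted(need)}")
    return AnnotationMap.from_pairs(
        (str(r.term_id), str(r.gene_id)) for r in df.itertuples()
    )
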