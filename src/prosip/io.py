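"""File formats: coverage/marker/report TSVs, GFF3 gene coordinates, flat
key-value configs.

FASTA goes through Biopython (:mod:`prosip.chem`), MGF through pyteomics
(:mod:`prosip.search`); tables are plain TSV via pandas.  GFF3 carries the
gene -> protein link in a ``protein_id`` attribute.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .binning import Gene, Scaffold


def write_coverage(coverage: pd.DataFrame, path) -> None:
    coverage.to_csv(path, sep="\t", index_label="scaffold_id")


def read_coverage(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="scaffold_id")


def write_gff3(scaffolds: Sequence[Scaffold], path) -> None:
    """Gene coordinates as GFF3; attributes link each gene to its protein."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for scaffold in scaffolds:
            for gene in scaffold.genes:
                attrs = f"ID={gene.gene_id};protein_id={gene.protein_id}"
                handle.write(
                    "\t".join(
                        [
                            scaffold.scaffold_id,
                            "prosip",
                            "CDS",
                            str(gene.start),
                            str(gene.end),
                            ".",
                            gene.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gff3(path) -> dict[str, list[Gene]]:
    """Parse GFF3 gene records back into per-scaffold gene lists."""
    genes: dict[str, list[Gene]] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            genes.setdefault(fields[0], []).append(
                Gene(
                    gene_id=attrs.get("ID", ""),
                    protein_id=attrs.get("protein_id", ""),
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6],
                )
            )
    return genes


def write_markers(scaffolds: Sequence[Scaffold], path) -> None:
    rows = []
    for scaffold in scaffolds:
        for marker_id, taxonomy in scaffold.marker_hits:
            rows.append((scaffold.scaffold_id, marker_id, taxonomy))
    pd.DataFrame(rows, columns=["scaffold_id", "marker_id", "taxonomy"]).to_csv(
        path, sep="\t", index=False
    )


def read_markers(path) -> dict[str, list[tuple[str, str]]]:
    table = pd.read_csv(path, sep="\t")
    hits: dict[str, list[tuple[str, str]]] = {}
    for row in table.itertuples():
        hits.setdefault(row.scaffold_id, []).append((row.marker_id, row.taxonomy))
    return hits


def write_config(config: Mapping[str, object], path) -> None:
    """Flat ``key = value`` configuration file."""
    with open(path, "w") as handle:
        for key in sorted(config):
            handle.write(f"{key} = {config[key]}\n")


def read_config(path) -> dict[str, str]:
    config: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, value = line.split("=", 1)
            config[key.strip()] = value.strip()
    return config


def psms_to_frame(psms) -> pd.DataFrame:
    rows = []
    for m in psms:
        rows.append(
            {
                "spectrum_id": m.spectrum_id,
                "sample_id": m.sample_id,
                "replicate_id": m.replicate_id,
                "sequence": m.sequence,
                "mods": ";".join(f"{p}:{name}" for p, name in m.mods),
                "protein_ids": ";".join(m.protein_ids),
                "is_decoy": m.is_decoy,
                "atom_percent": m.atom_percent,
                "score": m.score,
                "parent_offset_da": m.parent_offset_da,
                "precursor_charge": m.precursor_charge,
                "peak_area": m.peak_area,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "spectrum_id",
            "sample_id",
            "replicate_id",
            "sequence",
            "mods",
            "protein_ids",
            "is_decoy",
            "atom_percent",
            "score",
            "parent_offset_da",
            "precursor_charge",
            "peak_area",
        ],
    )


def frame_to_psms(table: pd.DataFrame):
    from .search import PeptideSpectrumMatch

    psms = []
    for row in table.itertuples():
        mods = tuple(
            (int(item.split(":")[0]), item.split(":")[1])
            for item in str(row.mods).split(";")
            if item and item != "nan"
        )
        psms.append(
            PeptideSpectrumMatch(
                spectrum_id=row.spectrum_id,
                sample_id=str(row.sample_id),
                replicate_id=str(row.replicate_id),
                sequence=row.sequence,
                mods=mods,
                protein_ids=tuple(str(row.protein_ids).split(";")),
                is_decoy=bool(row.is_decoy),
                atom_percent=float(row.atom_percent),
                score=float(row.score),
                parent_offset_da=int(row.parent_offset_da),
                precursor_charge=int(row.precursor_charge),
                peak_area=float(row.peak_area),
            )
        )
    return psms
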