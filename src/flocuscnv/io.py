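"""Plain-text output formats: FASTA, GFF3, BED, bedGraph-style TSV, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus_model import LocusAnnotation, SyntheticLocus

# GFF3 column-9 source tag
_SOURCE = "flocuscnv"

# internal feature type -> GFF3 type
_GFF_TYPES = {
    "gene": "gene",
    "promoter_proximal": "region",
    "promoter_distal": "region",
    "junction": "region",
    "repeat_unit": "region",
    "flank": "region",
    "primer_site": "primer_binding_site",
}


def write_fasta(locus: SyntheticLocus, path: str | Path) -> None:
    rec = SeqRecord(Seq(locus.sequence), id=locus.annotation.seq_id,
                    description=f"synthetic F-locus haplotype {locus.haplotype}")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")  # biopython wraps at 60 columns


def write_gff3(annotation: LocusAnnotation, path: str | Path) -> None:
    """GFF3 with 1-based inclusive coordinates (internal are 0-based half-open)."""
    lines = ["##gff-version 3",
             f"##sequence-region {annotation.seq_id} 1 {annotation.seq_length}"]
    for f in annotation.features:
        attrs = [f"ID={f.feature_id}", f"flocus_type={f.type}"]
        name = f.attributes.get("name")
        if name:
            attrs.append(f"Name={name}")
        tss = f.attributes.get("tss_offset")
        if tss:
            attrs.append(f"tss_offset={tss[0]}..{tss[1]}")
        lines.append("\t".join([
            annotation.seq_id, _SOURCE, _GFF_TYPES.get(f.type, "region"),
            str(f.start + 1), str(f.end), ".", f.strand, ".", ";".join(attrs),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_unit_bed(annotation: LocusAnnotation, path: str | Path) -> None:
    """Repeat-unit intervals as BED (0-based half-open, as BED requires)."""
    rows = []
    for f in annotation.of_type("repeat_unit"):
        rows.append(f"{annotation.seq_id}\t{f.start}\t{f.end}"
                    f"\t{f.feature_id}:{f.attributes.get('variant', '?')}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonable) + "\n")


def _jsonable(o):
    if hasattr(o, "item"):
        return o.item()
    if hasattr(o, "tolist"):
        return o.tolist()
    return str(o)
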