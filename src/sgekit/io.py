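"""File IO: FASTA/FASTQ, design configs and TSV tables.

Standard formats go through Biopython; tables are plain TSV so every
artifact stays inspectable with command-line tools.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO

from sgekit.caller import FastqRead
from sgekit.design import AmpliconDesign


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> str:
    """First record of a FASTA file as an uppercase string."""
    with _open_text(path) as fh:
        record = next(SeqIO.parse(fh, "fasta"), None)
    if record is None:
        raise ValueError(f"no FASTA records in {path}")
    return str(record.seq).upper()


def read_fastq(path) -> list[FastqRead]:
    with _open_text(path) as fh:
        return [
            FastqRead(r.id, str(r.seq).upper(),
                      tuple(r.letter_annotations["phred_quality"]))
            for r in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def load_design(path) -> AmpliconDesign:
    """Amplicon design from a YAML document.

    Expected keys: ``amplicon_id``, ``reference`` (inline sequence) or
    ``reference_fasta`` (path, relative to the YAML file), ``exons``
    (list of [start, end]), ``cdna_offset``, ``cut_sites``,
    ``marker_edits`` (list of [position, ref, alt]), ``target_region``.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "reference" in doc:
        ref = str(doc["reference"]).upper()
    elif "reference_fasta" in doc:
        ref = read_fasta(path.parent / doc["reference_fasta"])
    else:
        raise ValueError("design needs 'reference' or 'reference_fasta'")
    return AmpliconDesign(
        amplicon_id=doc["amplicon_id"],
        reference_seq=ref,
        exon_intervals=[tuple(iv) for iv in doc["exons"]],
        cdna_offset=int(doc["cdna_offset"]),
        cut_sites=list(doc["cut_sites"]),
        marker_edits=[tuple(e) for e in doc.get("marker_edits", [])],
        target_region=tuple(doc["target_region"]),
        cds_frame_offset=doc.get("cds_frame_offset"),
    )


def save_design(design: AmpliconDesign, path) -> None:
    """Serialize a design to the YAML layout :func:`load_design` reads."""
    doc = {
        "amplicon_id": design.amplicon_id,
        "reference": design.reference_seq,
        "exons": [list(iv) for iv in design.exon_intervals],
        "cdna_offset": design.cdna_offset,
        "cut_sites": list(design.cut_sites),
        "marker_edits": [list(e) for e in design.marker_edits],
        "target_region": list(design.target_region),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def load_supplementary_scores(path) -> pd.DataFrame:
    """Load a re-exported supplementary function-score table (TSV).

    The published per-variant workbooks, saved as TSV, are expected to
    carry at least: ``variant`` (HGVS c.), ``fs_DMSO``, ``fs_cisplatin``,
    ``fs_olaparib`` and a ``label`` column marking the control classes
    ("functional"/"non_functional", empty for experimental variants);
    optional columns (``clinvar``, ``pif``, ``category``, predictor
    scores) are passed through unchanged.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "fs_DMSO", "fs_cisplatin", "fs_olaparib"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"supplementary table lacks columns: {sorted(missing)}")
    return df.set_index("variant")
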