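"""Sequence records and the plain-text input formats of the pipeline.

A :class:`ProteinRecord` ties together an amino-acid sequence, its gene-family
label, its habitat of origin (microbial mat / sediment / water by default) and,
optionally, the coding nucleotide sequence used by the dN/dS stage.

Inputs are protein FASTA + tab-separated metadata (``id<TAB>family<TAB>habitat``)
+ optional coding-sequence FASTA, all keyed by sequence id.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import translate_cds

#: the habitats sampled at the spring, in the fixed round-robin order
DEFAULT_HABITATS: tuple[str, ...] = ("mat", "sediment", "water")

METADATA_COLUMNS = ("id", "family", "habitat")


@dataclass
class ProteinRecord:
    """One protein sequence with family/habitat annotation.

    ``cds_seq``, when present, must be exactly 3x the protein length and
    translate to ``aa_seq`` under the standard genetic code.
    """

    id: str
    family: str
    habitat: str
    aa_seq: str
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"record {self.id!r}: empty amino-acid sequence")

    def validate(self) -> None:
        """Check the CDS/protein consistency invariant; raise ValueError if broken."""
        if self.cds_seq is None:
            return
        if len(self.cds_seq) != 3 * len(self.aa_seq):
            raise ValueError(
                f"record {self.id!r}: CDS length {len(self.cds_seq)} is not "
                f"3 x protein length {len(self.aa_seq)}"
            )
        if translate_cds(self.cds_seq) != self.aa_seq:
            raise ValueError(
                f"record {self.id!r}: CDS does not translate to the protein sequence"
            )

    def __len__(self) -> int:
        return len(self.aa_seq)


def check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


def write_fasta(path: str | os.PathLike, records: Iterable[ProteinRecord], *, cds: bool = False) -> None:
    seqs = []
    for r in records:
        if cds:
            if r.cds_seq is None:
                raise ValueError(f"record {r.id!r} has no coding sequence")
            seqs.append(SeqRecord(Seq(r.cds_seq), id=r.id, description=""))
        else:
            seqs.append(SeqRecord(Seq(r.aa_seq), id=r.id, description=""))
    SeqIO.write(seqs, os.fspath(path), "fasta")


def write_metadata(path: str | os.PathLike, records: Iterable[ProteinRecord]) -> None:
    df = pd.DataFrame(
        [(r.id, r.family, r.habitat) for r in records], columns=list(METADATA_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
    return df


def read_records(
    protein_fasta: str | os.PathLike,
    metadata: str | os.PathLike,
    cds_fasta: str | os.PathLike | None = None,
) -> list[ProteinRecord]:
    """Load records from FASTA + metadata (+ optional CDS FASTA), keyed by id.

    Every protein sequence must have a metadata row; CDS sequences are attached
    where present and checked for translation consistency.
    """
    meta = read_metadata(metadata).set_index("id")
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate metadata ids: {dupes[:5]}")
    cds_map: dict[str, str] = {}
    if cds_fasta is not None:
        cds_map = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(os.fspath(cds_fasta), "fasta")
        }
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(os.fspath(protein_fasta), "fasta"):
        if rec.id not in meta.index:
            raise ValueError(f"sequence {rec.id!r} present in FASTA but not in metadata")
        row = meta.loc[rec.id]
        pr = ProteinRecord(
            id=rec.id,
            family=str(row["family"]),
            habitat=str(row["habitat"]),
            aa_seq=str(rec.seq).upper(),
            cds_seq=cds_map.get(rec.id),
        )
        pr.validate()
        records.append(pr)
    check_unique_ids(records)
    return records
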