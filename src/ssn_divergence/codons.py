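"""Standard genetic code tables shared by the simulator and the dN/dS estimator.

Built once from Biopython's standard codon table (NCBI table 1).
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"

#: every codon -> amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: the 61 sense codons of the standard code, in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)
)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard code.

    Raises ``ValueError`` on length not divisible by 3 or unknown codons.
    Stop codons translate to ``*`` (the simulator never emits them).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"coding sequence length {len(cds)} not a multiple of 3")
    try:
        return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown codon {exc.args[0]!r}") from exc
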