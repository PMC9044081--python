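"""All-vs-all local protein alignment with Karlin-Altschul statistics.

Optimal Smith-Waterman alignment with affine gaps (BLOSUM62, open 11 /
extend 1 by default; the first gap position is charged open+extend) computed
through Biopython's ``PairwiseAligner``. Raw scores are converted to bitscores
and E-values with the classical Karlin-Altschul parameters for gapped BLOSUM62
searches (lambda = 0.267, K = 0.041), using ``len(a) * len(b)`` as the search
space for a pair. Hits are read and written in the standard 12-column tabular
hit format (qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .records import ProteinRecord, check_unique_ids

#: the 20 standard residues plus the ambiguity code X
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    kappa: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)

    def aligner(self, mode: str = "local") -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.substitution_matrix = self.matrix()
        aligner.mode = mode
        # first gap position costs open+extend, as in BLAST's affine model
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentHit:
    """Best local alignment for one ordered sequence pair."""

    query_id: str
    subject_id: str
    raw_score: int
    pct_identity: float
    aln_len: int
    n_mismatch: int
    n_gap_opens: int
    q_start: int  # 1-based inclusive
    q_end: int
    s_start: int
    s_end: int
    evalue: float = math.nan
    bitscore: float = math.nan


def _validate_seq(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"{label}: invalid characters {sorted(bad)}")


def local_align(
    a: str,
    b: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns ``None`` when no alignment scores above zero. Identity is
    the percentage of alignment columns (gap columns included in the
    denominator) whose residues are identical.
    """
    a, b = a.upper(), b.upper()
    _validate_seq(a, "query")
    _validate_seq(b, "subject")
    aligner = scheme.aligner("local")
    score = aligner.score(a, b)
    if score <= 0:
        return None
    aln = aligner.align(a, b)[0]
    blocks = aln.aligned  # [[q blocks], [s blocks]]
    q_blocks, s_blocks = blocks[0], blocks[1]
    matches = 0
    aligned_cols = 0
    gap_cols = 0
    gap_opens = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        aligned_cols += qe - qs
        matches += sum(1 for x, y in zip(a[qs:qe], b[ss:se]) if x == y)
    for ((_, qe0), (qs1, _)), ((_, se0), (ss1, _)) in zip(
        zip(q_blocks, s_blocks), zip(q_blocks[1:], s_blocks[1:])
    ):
        dq, ds = qs1 - qe0, ss1 - se0
        if dq > 0:
            gap_cols += dq
            gap_opens += 1
        if ds > 0:
            gap_cols += ds
            gap_opens += 1
    aln_len = aligned_cols + gap_cols
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=int(round(score)),
        pct_identity=100.0 * matches / aln_len,
        aln_len=aln_len,
        n_mismatch=aligned_cols - matches,
        n_gap_opens=gap_opens,
        q_start=int(q_blocks[0][0]) + 1,
        q_end=int(q_blocks[-1][1]),
        s_start=int(s_blocks[0][0]) + 1,
        s_end=int(s_blocks[-1][1]),
    )


def attach_evalue(
    hit: AlignmentHit, len_a: int, len_b: int, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentHit:
    """Fill in bitscore and E-value from the raw score.

    bitscore = (lambda * S - ln K) / ln 2 ; E = len_a * len_b * 2**(-bitscore).
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    bitscore = (scheme.lam * hit.raw_score - math.log(scheme.kappa)) / math.log(2)
    evalue = len_a * len_b * 2.0 ** (-bitscore)
    return replace(hit, bitscore=bitscore, evalue=evalue)


def all_vs_all(
    records: Sequence[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_length_ratio: float | None = None,
) -> list[AlignmentHit]:
    """Best alignment per unordered pair, with E-values attached.

    Self-pairs are excluded; pairs without a positive-scoring alignment
    yield no hit. The output is sorted by (query_id, subject_id) with
    query_id < subject_id, so it is invariant to input order.

    ``max_length_ratio`` optionally skips pairs whose lengths differ by more
    than that factor (a cheap prefilter; off by default).
    """
    check_unique_ids(records)
    ordered = sorted(records, key=lambda r: r.id)
    hits: list[AlignmentHit] = []
    for i, ra in enumerate(ordered):
        for rb in ordered[i + 1 :]:
            if max_length_ratio is not None:
                lo, hi = sorted((len(ra), len(rb)))
                if hi > max_length_ratio * lo:
                    continue
            hit = local_align(ra.aa_seq, rb.aa_seq, scheme, ra.id, rb.id)
            if hit is not None:
                hits.append(attach_evalue(hit, len(ra), len(rb), scheme))
    return hits


_HIT_COLUMNS = 12


def write_hits(hits: Iterable[AlignmentHit], path: str | os.PathLike) -> None:
    """Write hits in 12-column tabular format (no header)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_len),
                        str(h.n_mismatch),
                        str(h.n_gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def read_hits(path: str | os.PathLike) -> list[AlignmentHit]:
    """Parse a 12-column tabular hit file; raw scores are not recoverable
    from the format and are set to 0."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _HIT_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pct_identity=float(parts[2]),
                        aln_len=int(parts[3]),
                        n_mismatch=int(parts[4]),
                        n_gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                        raw_score=0,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return hits
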