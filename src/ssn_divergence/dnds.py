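"""Pairwise dN/dS by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

For each codon, synonymous and nonsynonymous *sites* are counted by examining
the nine single-nucleotide mutations; mutations creating stop codons are
counted as neither and the remaining mutations at that position are
renormalised (so every sense codon still contributes exactly 3 sites).
Codon *differences* are classified directly for single-difference pairs; for
two- and three-difference pairs the counts are averaged over all orderings of
single steps whose intermediates avoid stop codons (falling back to all
orderings when none survive).

Proportions p = diffs / sites are corrected for multiple hits with
Jukes-Cantor, d = -(3/4) ln(1 - 4p/3); omega = dN/dS. Pairs with dS = 0 or a
saturated proportion (p >= 3/4) are flagged rather than given an arbitrary
omega.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx

from .align import DEFAULT_SCHEME, ScoringScheme
from .codons import CODON_TO_AA, NUCLEOTIDES, is_stop
from .records import ProteinRecord

SATURATION = 0.75  # Jukes-Cantor domain boundary: p >= 3/4 is uncorrectable


@dataclass
class NGCounts:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    codons_compared: int


@dataclass
class DnDsEstimate:
    counts: NGCounts
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float  # nan unless status == "ok"
    status: str  # ok | dS_zero | saturated


@lru_cache(maxsize=None)
def ng_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position the synonymous fraction is the share of synonymous changes
    among the non-stop single-nucleotide changes; the three positions sum to
    exactly 3 sites.
    """
    codon = codon.upper()
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            n_valid += 1
            if CODON_TO_AA[mutant] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def ng_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Multi-difference pairs average over mutational pathways; pathways passing
    through stop codons are excluded when any stop-free pathway exists.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if is_stop(c):
            raise ValueError(f"stop codon {c!r} in comparison")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (syn, nonsyn, stop_free)
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0.0
        stop_free = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt):
                stop_free = False
            if CODON_TO_AA.get(nxt, "*") == CODON_TO_AA[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((syn, nonsyn, stop_free))
    usable = [p for p in paths if p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def codon_pairs(
    rec_a: ProteinRecord,
    rec_b: ProteinRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[tuple[str, str]]:
    """Aligned codon pairs of two coding sequences.

    The proteins are aligned globally (end gaps free, same scoring scheme as
    the similarity search) and the alignment is back-mapped to codons;
    columns with a gap in either sequence are dropped. Equal-length gap-free
    pairs reduce to positional pairing.
    """
    for rec in (rec_a, rec_b):
        if rec.cds_seq is None:
            raise ValueError(f"record {rec.id!r} has no coding sequence")
        rec.validate()
    if len(rec_a.aa_seq) == len(rec_b.aa_seq):
        idx_pairs = [(i, i) for i in range(len(rec_a.aa_seq))]
        if rec_a.aa_seq != rec_b.aa_seq:
            # only shortcut when a global alignment could not do better than
            # the positional pairing; for simulated (indel-free) data it cannot
            idx_pairs = None if _has_gap_benefit(rec_a, rec_b, scheme) else idx_pairs
    else:
        idx_pairs = None
    if idx_pairs is None:
        aligner = scheme.aligner("global")
        aligner.end_gap_score = 0.0
        aln = aligner.align(rec_a.aa_seq, rec_b.aa_seq)[0]
        q_blocks, s_blocks = aln.aligned
        idx_pairs = [
            (qi, si)
            for (qs, qe), (ss, _) in zip(q_blocks, s_blocks)
            for qi, si in zip(range(qs, qe), range(ss, ss + (qe - qs)))
        ]
    pairs = []
    for qi, si in idx_pairs:
        ca = rec_a.cds_seq[3 * qi : 3 * qi + 3]
        cb = rec_b.cds_seq[3 * si : 3 * si + 3]
        pairs.append((ca, cb))
    return pairs


def _has_gap_benefit(rec_a: ProteinRecord, rec_b: ProteinRecord, scheme: ScoringScheme) -> bool:
    """True when the end-gap-free global alignment beats ungapped pairing."""
    aligner = scheme.aligner("global")
    aligner.end_gap_score = 0.0
    matrix = scheme.matrix()
    ungapped = sum(
        matrix[x, y] for x, y in zip(rec_a.aa_seq, rec_b.aa_seq)
    )
    return aligner.score(rec_a.aa_seq, rec_b.aa_seq) > ungapped


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; inf at or beyond the p = 3/4 boundary."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= SATURATION:
        return math.inf
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def dnds_pair(
    rec_a: ProteinRecord,
    rec_b: ProteinRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_codons: int = 10,
) -> DnDsEstimate:
    """NG86 dN/dS estimate for one pair of coding sequences."""
    pairs = codon_pairs(rec_a, rec_b, scheme)
    pairs = [
        (ca, cb) for ca, cb in pairs if not is_stop(ca) and not is_stop(cb)
    ]
    if len(pairs) < min_codons:
        raise ValueError(
            f"only {len(pairs)} comparable codons between {rec_a.id!r} and "
            f"{rec_b.id!r}; need >= {min_codons}"
        )
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in pairs:
        sa, na = ng_sites(ca)
        sb, nb = ng_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        dsd, dnd = ng_differences(ca, cb)
        sd += dsd
        nd += dnd
    counts = NGCounts(
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        codons_compared=len(pairs),
    )
    pS = sd / s_sites if s_sites > 0 else 0.0
    pN = nd / n_sites if n_sites > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if pS >= SATURATION or pN >= SATURATION:
        status, omega = "saturated", math.nan
    elif dS == 0.0:
        status, omega = "dS_zero", math.nan
    else:
        status, omega = "ok", dN / dS
    return DnDsEstimate(counts=counts, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega, status=status)


@dataclass
class HabitatPairResult:
    """All cross-habitat estimates for one family and habitat pair."""

    family: str
    habitat_a: str
    habitat_b: str
    pairs: list[tuple[str, str, DnDsEstimate]]

    @property
    def omega_range(self) -> tuple[float, float] | None:
        """(min, max) over status-ok estimates, or None when there are none."""
        ok = [e.omega for _, _, e in self.pairs if e.status == "ok"]
        if not ok:
            return None
        return min(ok), max(ok)


def habitat_dnds(
    records: Sequence[ProteinRecord],
    core_components: Iterable[set],
    habitat_pair: tuple[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_codons: int = 10,
) -> HabitatPairResult:
    """dN/dS over every cross-habitat sequence pair within core components.

    Pairs whose alignment leaves fewer than ``min_codons`` comparable codons
    are skipped. An empty result signals an absent habitat or no core cluster.
    """
    ha, hb = habitat_pair
    by_id = {r.id: r for r in records}
    family = records[0].family if records else ""
    out: list[tuple[str, str, DnDsEstimate]] = []
    for comp in core_components:
        ids_a = sorted(i for i in comp if i in by_id and by_id[i].habitat == ha)
        ids_b = sorted(i for i in comp if i in by_id and by_id[i].habitat == hb)
        for ia in ids_a:
            for ib in ids_b:
                if ia == ib:
                    continue
                try:
                    est = dnds_pair(by_id[ia], by_id[ib], scheme, min_codons)
                except ValueError:
                    continue
                out.append((ia, ib, est))
    return HabitatPairResult(family=family, habitat_a=ha, habitat_b=hb, pairs=out)
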