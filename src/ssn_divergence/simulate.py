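"""Synthetic codon-family simulator.

Generates gene families on small phylogenies under a mutation-acceptance codon
process: along each branch, single-nucleotide changes are proposed at a Poisson
rate and accepted with probability 1 if synonymous and min(omega, 1) if
nonsynonymous (for omega > 1 the synonymous acceptance is scaled to 1/omega so
that the nonsynonymous:synonymous acceptance odds equal omega). Proposals that
create stop codons are rejected outright. This is exactly the quantity the
Nei-Gojobori counting estimator measures, which makes the simulator a clean
oracle for omega recovery and for the conserved/diversifying/diverged network
archetypes.

Branch lengths are expected substitution *attempts* per nucleotide site, so a
branch of length t over L codons draws Poisson(3*L*t) proposal events.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .codons import CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS, is_stop
from .records import (
    DEFAULT_HABITATS,
    ProteinRecord,
    read_records,
    write_fasta,
    write_metadata,
)

Archetype = Literal["conserved", "diversifying", "diverged"]
ARCHETYPES: tuple[Archetype, ...] = ("conserved", "diversifying", "diverged")

# Divergence regimes of the three family archetypes (tree heights in expected
# substitution attempts per nucleotide site; see docs/methods.md).
ARCHETYPE_DEFAULTS: dict[str, dict] = {
    "conserved": {"n_subfamilies": 1, "tree_height": 0.05, "omega": 0.2},
    "diversifying": {"n_subfamilies": 3, "tree_height": 0.8, "omega": 0.5},
    "diverged": {"n_subfamilies": 0, "tree_height": 2.0, "omega": 1.0},  # 0 -> one per taxon
}

#: within-subfamily tree height for multi-subfamily families
WITHIN_SUBFAMILY_HEIGHT = 0.05


@dataclass
class Phylogeny:
    """Rooted tree with named nodes; ``branch_length[n]`` is the edge above ``n``."""

    root: str
    children: dict[str, list[str]]
    branch_length: dict[str, float]

    @property
    def taxa(self) -> list[str]:
        return [n for n in self._preorder() if not self.children.get(n)]

    def _preorder(self) -> list[str]:
        order, stack = [], [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(reversed(self.children.get(n, [])))
        return order

    def depth(self, node: str) -> float:
        parent = {c: p for p, cs in self.children.items() for c in cs}
        d = 0.0
        while node != self.root:
            d += self.branch_length[node]
            node = parent[node]
        return d


@dataclass
class FamilyConfig:
    family_name: str
    archetype: Archetype
    n_per_habitat: int = 3
    seq_len_codons: int = 250
    omega: float = 0.2
    tree_height: float = 0.05
    n_subfamilies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.seq_len_codons < 10:
            raise ValueError("seq_len_codons must be >= 10")
        if self.n_per_habitat < 1:
            raise ValueError("n_per_habitat must be >= 1")
        if self.n_subfamilies < 1:
            raise ValueError("n_subfamilies must be >= 1")

    @property
    def n_taxa(self) -> int:
        return self.n_per_habitat * len(DEFAULT_HABITATS)


@dataclass
class SimulatedFamily:
    config: FamilyConfig
    tree: Phylogeny
    records: list[ProteinRecord]
    #: per-branch (child-node keyed) counts of accepted events
    event_log: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_syn_events(self) -> int:
        return sum(e["syn"] for e in self.event_log.values())

    @property
    def n_nonsyn_events(self) -> int:
        return sum(e["nonsyn"] for e in self.event_log.values())


def archetype_config(
    family_name: str,
    archetype: Archetype,
    seed: int,
    *,
    n_per_habitat: int = 3,
    seq_len_codons: int = 250,
) -> FamilyConfig:
    """A FamilyConfig preset for one of the three divergence archetypes."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    preset = dict(ARCHETYPE_DEFAULTS[archetype])
    n_sub = preset.pop("n_subfamilies")
    if n_sub == 0:
        n_sub = n_per_habitat * len(DEFAULT_HABITATS)
    return FamilyConfig(
        family_name=family_name,
        archetype=archetype,
        n_per_habitat=n_per_habitat,
        seq_len_codons=seq_len_codons,
        n_subfamilies=n_sub,
        seed=seed,
        **preset,
    )


def default_configs(seed: int = 0, *, n_per_habitat: int = 3, seq_len_codons: int = 250) -> list[FamilyConfig]:
    """The default 15-family study set: 5 families per archetype.

    Family names follow the sulfur-cycle gene set (sulfate reduction and
    sulfide oxidation); DsrAB is the canonical conserved family.
    """
    names = {
        "conserved": ["DsrAB", "AprA", "AprB", "SoxB", "CysNC"],
        "diversifying": ["Sat", "CysH", "CysI", "SoxX", "SoxY"],
        "diverged": ["CysJ", "AsrAB", "AsrC", "SoxA", "SoxZ"],
    }
    configs = []
    i = 0
    for archetype in ARCHETYPES:
        for name in names[archetype]:
            configs.append(
                archetype_config(
                    name,
                    archetype,
                    seed=_family_seed(seed, i),
                    n_per_habitat=n_per_habitat,
                    seq_len_codons=seq_len_codons,
                )
            )
            i += 1
    return configs


def _family_seed(root_seed: int, index: int) -> int:
    # fixed arithmetic fan-out; keeps every derived seed below 2**31
    return (root_seed * 7919 + 104729 * (index + 1)) % (2**31)


def simulate_tree(
    n_taxa: int, height: float, mode: Literal["star", "yule"] = "yule", seed: int = 0
) -> Phylogeny:
    """Simulate a rooted ultrametric tree with all leaves at depth ``height``.

    ``star`` hangs every leaf directly off the root; ``yule`` draws a random
    bifurcating pure-birth topology and rescales node times so every
    root-to-leaf path sums exactly to ``height``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if height < 0:
        raise ValueError("height must be >= 0")
    if mode == "star":
        leaves = [f"t{i}" for i in range(n_taxa)]
        return Phylogeny(
            root="root",
            children={"root": leaves},
            branch_length={leaf: height for leaf in leaves},
        )
    if mode != "yule":
        raise ValueError(f"unknown tree mode {mode!r}")

    rng = np.random.default_rng(seed)
    # forward pure-birth: split a random active lineage at exponential waits
    node_time = {"root": 0.0}
    children: dict[str, list[str]] = {"root": []}
    active = ["root"]
    t = 0.0
    counter = 0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        kids = [f"n{counter}", f"n{counter + 1}"]
        counter += 2
        for k in kids:
            node_time[k] = t
            children[k] = []
        children[parent] = kids
        active.extend(kids)
    total = t + rng.exponential(1.0 / n_taxa)
    scale = height / total if total > 0 else 0.0
    # rename active lineages to leaf labels and set all leaves to depth=height
    leaf_names = {node: f"t{i}" for i, node in enumerate(active)}
    children = {leaf_names.get(p, p): [leaf_names.get(c, c) for c in cs] for p, cs in children.items()}
    node_time = {leaf_names.get(n, n): tt for n, tt in node_time.items()}
    for leaf in leaf_names.values():
        node_time[leaf] = total
    parent_of = {c: p for p, cs in children.items() for c in cs}
    branch_length = {
        n: (node_time[n] - node_time[parent_of[n]]) * scale for n in parent_of
    }
    return Phylogeny(root="root", children=children, branch_length=branch_length)


def _subfamily_tree(config: FamilyConfig, rng: np.random.Generator) -> Phylogeny:
    """Tree for a multi-subfamily family: deep star over subfamily ancestors,
    shallow yule subtrees within each subfamily."""
    n = config.n_taxa
    k = config.n_subfamilies
    if k > n:
        raise ValueError("n_subfamilies cannot exceed taxon count")
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    children: dict[str, list[str]] = {"root": []}
    branch_length: dict[str, float] = {}
    leaf_counter = 0
    for i, size in enumerate(sizes):
        anc = f"sub{i}"
        if size == 1:
            # the subfamily ancestor is itself a leaf
            anc = f"t{leaf_counter}"
            leaf_counter += 1
            children["root"].append(anc)
            children[anc] = []
            branch_length[anc] = config.tree_height
            continue
        children["root"].append(anc)
        branch_length[anc] = config.tree_height
        if size == 2:
            sub = simulate_tree(2, WITHIN_SUBFAMILY_HEIGHT, "star", seed=int(rng.integers(2**31)))
        else:
            sub = simulate_tree(size, WITHIN_SUBFAMILY_HEIGHT, "yule", seed=int(rng.integers(2**31)))
        rename = {sub.root: anc}
        for node in sub.children:
            if node == sub.root:
                continue
            rename.setdefault(node, f"{anc}_{node}")
        for leaf in sub.taxa:
            rename[leaf] = f"t{leaf_counter}"
            leaf_counter += 1
        for p, cs in sub.children.items():
            children[rename[p]] = [rename[c] for c in cs]
        for c, bl in sub.branch_length.items():
            branch_length[rename[c]] = bl
    return Phylogeny(root="root", children=children, branch_length=branch_length)


def _random_root(seq_len_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(len(SENSE_CODONS), size=seq_len_codons)
    return [SENSE_CODONS[i] for i in idx]


def _evolve_branch(
    codons: list[str], branch_length: float, omega: float, rng: np.random.Generator
) -> tuple[list[str], dict[str, int]]:
    """Evolve a codon list along one branch; returns (new codons, event counts)."""
    codons = list(codons)
    n_codons = len(codons)
    p_syn = 1.0 if omega <= 1 else 1.0 / omega
    p_nonsyn = min(omega, 1.0)
    n_attempts = rng.poisson(3.0 * n_codons * branch_length)
    events = {"syn": 0, "nonsyn": 0}
    for _ in range(n_attempts):
        site = int(rng.integers(3 * n_codons))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        old = codon[pos]
        new = NUCLEOTIDES[int(rng.integers(4))]
        while new == old:
            new = NUCLEOTIDES[int(rng.integers(4))]
        cand = codon[:pos] + new + codon[pos + 1 :]
        if is_stop(cand):
            continue
        if CODON_TO_AA[cand] == CODON_TO_AA[codon]:
            if rng.random() < p_syn:
                codons[ci] = cand
                events["syn"] += 1
        else:
            if rng.random() < p_nonsyn:
                codons[ci] = cand
                events["nonsyn"] += 1
    return codons, events


def evolve_family(config: FamilyConfig) -> SimulatedFamily:
    """Simulate one gene family on its archetype tree.

    Leaves are assigned habitats round-robin (mat, sediment, water, mat, ...)
    in leaf-name order, so every family spans all three habitats.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_subfamilies > 1:
        tree = _subfamily_tree(config, rng)
    elif config.n_taxa == 2:
        tree = simulate_tree(2, config.tree_height, "star", seed=int(rng.integers(2**31)))
    else:
        tree = simulate_tree(
            config.n_taxa, config.tree_height, "yule", seed=int(rng.integers(2**31))
        )
    root_codons = _random_root(config.seq_len_codons, rng)
    seqs: dict[str, list[str]] = {tree.root: root_codons}
    event_log: dict[str, dict[str, int]] = {}
    for node in tree._preorder():
        for child in tree.children.get(node, []):
            seqs[child], event_log[child] = _evolve_branch(
                seqs[node], tree.branch_length[child], config.omega, rng
            )
    leaves = sorted(tree.taxa, key=lambda s: int(s[1:]))
    records = []
    for i, leaf in enumerate(leaves):
        cds = "".join(seqs[leaf])
        records.append(
            ProteinRecord(
                id=f"{config.family_name}_{i:03d}",
                family=config.family_name,
                habitat=DEFAULT_HABITATS[i % len(DEFAULT_HABITATS)],
                aa_seq="".join(CODON_TO_AA[c] for c in seqs[leaf]),
                cds_seq=cds,
            )
        )
    return SimulatedFamily(config=config, tree=tree, records=records, event_log=event_log)


def make_dataset(
    configs: Sequence[FamilyConfig], seed: int | None = None
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Simulate all families and return (records, metadata table).

    When ``seed`` is given it re-derives each family's seed by fixed
    arithmetic, overriding the per-config seeds, so one root seed determines
    the whole dataset.
    """
    names = [c.family_name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate family names")
    records: list[ProteinRecord] = []
    for i, config in enumerate(configs):
        if seed is not None:
            config = FamilyConfig(**{**config.__dict__, "seed": _family_seed(seed, i)})
        fam = evolve_family(config)
        records.extend(fam.records)
    metadata = pd.DataFrame(
        [(r.id, r.family, r.habitat) for r in records], columns=["id", "family", "habitat"]
    )
    return records, metadata


def simulate_codon_pair(
    omega: float, n_codons: int, divergence: float, seed: int
) -> tuple[ProteinRecord, ProteinRecord]:
    """Two sequences separated by total path length ``divergence`` (attempts
    per nucleotide site), for omega-recovery experiments."""
    config = FamilyConfig(
        family_name="pair",
        archetype="conserved",
        n_per_habitat=1,
        seq_len_codons=n_codons,
        omega=omega,
        tree_height=divergence / 2.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    root = _random_root(n_codons, rng)
    recs = []
    for i in range(2):
        codons, _ = _evolve_branch(root, divergence / 2.0, omega, rng)
        recs.append(
            ProteinRecord(
                id=f"pair_{i}",
                family="pair",
                habitat=DEFAULT_HABITATS[i],
                aa_seq="".join(CODON_TO_AA[c] for c in codons),
                cds_seq="".join(codons),
            )
        )
    return recs[0], recs[1]


def write_inputs(
    records: Sequence[ProteinRecord],
    metadata: pd.DataFrame,
    out_dir: str | os.PathLike,
) -> dict[str, Path]:
    """Write protein FASTA, CDS FASTA and metadata TSV; returns the paths."""
    if not records:
        raise ValueError("no records to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_fasta": out / "proteins.faa",
        "cds_fasta": out / "cds.fna",
        "metadata": out / "metadata.tsv",
    }
    write_fasta(paths["protein_fasta"], records, cds=False)
    if all(r.cds_seq is not None for r in records):
        write_fasta(paths["cds_fasta"], records, cds=True)
    else:
        paths.pop("cds_fasta")
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    return paths
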