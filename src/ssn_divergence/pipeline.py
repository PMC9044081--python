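"""End-to-end orchestration: simulate/load -> align -> network -> family
analysis -> dN/dS, with tabular outputs and a run log.

Outputs written to the configured directory:

    edges.tsv             thresholded SSN edge list
    network.graphml       SSN with family/habitat node attributes
    global_metrics.tsv    whole-network topology summary
    family_attributes.tsv per-family attribute table
    classification.tsv    family -> conserved/diversifying/diverged
    curves.tsv            topology-vs-degree curves
    powerlaw.tsv          power-law fits of the curves
    dnds.tsv              per-pair dN/dS rows (family x habitat pair)
    run.log               every parameter and stage count actually applied
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import align as align_mod
from . import dnds as dnds_mod
from . import families as fam_mod
from . import network as net_mod
from .align import ScoringScheme
from .records import DEFAULT_HABITATS, ProteinRecord, read_records
from .simulate import FamilyConfig, default_configs, make_dataset

logger = logging.getLogger("ssn_divergence")

OUTPUT_FILES = (
    "edges.tsv",
    "network.graphml",
    "global_metrics.tsv",
    "family_attributes.tsv",
    "classification.tsv",
    "curves.tsv",
    "powerlaw.tsv",
    "dnds.tsv",
)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of (``protein_fasta`` + ``metadata``) or ``simulate`` must be
    set. ``hits_path`` skips the internal aligner and ingests a 12-column
    tabular hit file instead.
    """

    out_dir: str = "ssn_out"
    protein_fasta: str | None = None
    cds_fasta: str | None = None
    metadata: str | None = None
    hits_path: str | None = None
    simulate: list[FamilyConfig] | None = None
    evalue_threshold: float = 1e-30
    min_length_aa: int = 150
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    identity_cluster: float | None = None  # off by default
    isolated_fraction_threshold: float = 0.5
    min_codons: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.protein_fasta is not None and self.metadata is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise ValueError(
                "exactly one of (protein_fasta + metadata) or simulate must be set"
            )
        if not (0 < self.evalue_threshold):
            raise ValueError("evalue_threshold must be positive")
        if self.min_length_aa < 0:
            raise ValueError("min_length_aa must be >= 0")

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "scheme" in raw and isinstance(raw["scheme"], dict):
            raw["scheme"] = ScoringScheme(**raw["scheme"])
        sim = raw.get("simulate")
        if sim == "default":
            raw["simulate"] = default_configs(int(raw.get("seed", 0)))
        elif isinstance(sim, list):
            raw["simulate"] = [
                fc if isinstance(fc, FamilyConfig) else FamilyConfig(**fc) for fc in sim
            ]
        return cls(**raw)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(records: Sequence[ProteinRecord]) -> ValidationReport:
    """Consistency checks on loaded records.

    Hard errors: duplicate ids, CDS/protein translation mismatches.
    Warnings: families missing a habitat (their dN/dS output will be empty).
    """
    report = ValidationReport()
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            report.errors.append(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)
        try:
            r.validate()
        except ValueError as exc:
            report.errors.append(str(exc))
    habitats_present = {r.habitat for r in records}
    by_family: dict[str, set[str]] = {}
    for r in records:
        by_family.setdefault(r.family, set()).add(r.habitat)
    for fam, habs in sorted(by_family.items()):
        missing = habitats_present - habs
        if missing:
            report.warnings.append(
                f"family {fam!r} lacks habitat(s) {sorted(missing)}; "
                "its cross-habitat dN/dS will be empty"
            )
    return report


@dataclass
class RunReport:
    n_records_in: int
    n_records_filtered: int
    n_hits: int
    n_edges: int
    n_components: int
    n_families: int
    global_topology: net_mod.GlobalTopology
    classifications: dict[str, str]
    warnings: list[str]
    out_dir: str


def _load_records(config: PipelineConfig) -> list[ProteinRecord]:
    if config.simulate is not None:
        records, _ = make_dataset(config.simulate, seed=config.seed)
        return records
    return read_records(config.protein_fasta, config.metadata, config.cds_fasta)


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> RunReport:
    logger.info(
        "parameters: evalue_threshold=%g min_length_aa=%d matrix=%s gap=%d/%d "
        "lambda=%g K=%g identity_cluster=%s seed=%d",
        config.evalue_threshold,
        config.min_length_aa,
        config.scheme.matrix_name,
        config.scheme.gap_open,
        config.scheme.gap_extend,
        config.scheme.lam,
        config.scheme.kappa,
        config.identity_cluster,
        config.seed,
    )

    records = _load_records(config)
    logger.info("stage records: %d sequences loaded", len(records))
    report = validate_inputs(records)
    for w in report.warnings:
        logger.warning(w)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.errors))

    filtered = net_mod.length_filter(records, config.min_length_aa)
    logger.info(
        "stage length_filter: %d/%d sequences > %d aa",
        len(filtered),
        len(records),
        config.min_length_aa,
    )

    if config.hits_path is not None:
        hits = align_mod.read_hits(config.hits_path)
        ids = {r.id for r in filtered}
        hits = [h for h in hits if h.query_id in ids and h.subject_id in ids]
        logger.info("stage align: %d hits read from %s", len(hits), config.hits_path)
    else:
        hits = align_mod.all_vs_all(filtered, config.scheme)
        logger.info("stage align: %d positive-scoring pairs", len(hits))

    if config.identity_cluster is not None:
        assignment = net_mod.greedy_cluster(filtered, hits, config.identity_cluster)
        reps = {rep for rep in assignment.values()}
        filtered = [r for r in filtered if r.id in reps]
        hits = [h for h in hits if h.query_id in reps and h.subject_id in reps]
        logger.info(
            "stage cluster: %d representatives at %.1f%% identity",
            len(reps),
            config.identity_cluster,
        )

    net = net_mod.build_network(filtered, hits, config.evalue_threshold)
    logger.info(
        "stage network: %d nodes, %d edges at threshold %g",
        net.number_of_nodes(),
        net.number_of_edges(),
        config.evalue_threshold,
    )
    net_mod.write_edges(net, out / "edges.tsv")
    net_mod.write_graphml(net, out / "network.graphml")

    topo = net_mod.global_topology(net)
    pd.DataFrame([dataclasses.asdict(topo)]).to_csv(
        out / "global_metrics.tsv", sep="\t", index=False, float_format="%.6g"
    )
    logger.info(
        "stage topology: %d components, %d isolated, avg degree %.2f",
        topo.n_components,
        topo.n_isolated,
        topo.avg_degree,
    )

    habitats = [h for h in DEFAULT_HABITATS if any(r.habitat == h for r in filtered)]
    extra = sorted({r.habitat for r in filtered} - set(habitats))
    habitats += extra

    table = fam_mod.family_table(
        net, habitats, isolated_fraction_threshold=config.isolated_fraction_threshold
    )

    metrics = net_mod.node_metrics(net)
    curves = fam_mod.topology_curves(metrics)
    curves.to_csv(out / "curves.tsv", sep="\t", float_format="%.6g")
    fits = fam_mod.curve_power_laws(curves)
    fits.to_csv(out / "powerlaw.tsv", sep="\t", float_format="%.6g")

    # dN/dS on cross-habitat pairs within each family's core clusters
    dnds_rows = []
    ranges: dict[str, str] = {}
    subnets = fam_mod.family_subnetworks(net)
    have_cds = all(r.cds_seq is not None for r in filtered)
    if have_cds:
        by_family: dict[str, list[ProteinRecord]] = {}
        for r in filtered:
            by_family.setdefault(r.family, []).append(r)
        for fam, sub in subnets.items():
            cores = fam_mod.core_clusters(sub, habitats)
            fam_records = by_family.get(fam, [])
            omegas = []
            for ha, hb in [
                (a, b) for i, a in enumerate(habitats) for b in habitats[i + 1 :]
            ]:
                result = dnds_mod.habitat_dnds(
                    fam_records, cores, (ha, hb), config.scheme, config.min_codons
                )
                for ia, ib, est in result.pairs:
                    dnds_rows.append(
                        {
                            "family": fam,
                            "habitat_pair": f"{ha}-{hb}",
                            "id_a": ia,
                            "id_b": ib,
                            "codons": est.counts.codons_compared,
                            "Sd": est.counts.syn_diffs,
                            "Nd": est.counts.nonsyn_diffs,
                            "S_sites": est.counts.syn_sites,
                            "N_sites": est.counts.nonsyn_sites,
                            "dS": est.dS,
                            "dN": est.dN,
                            "omega": est.omega,
                            "status": est.status,
                        }
                    )
                    if est.status == "ok":
                        omegas.append(est.omega)
            ranges[fam] = (
                f"{min(omegas):.3f}-{max(omegas):.3f}" if omegas else "-"
            )
        logger.info("stage dnds: %d cross-habitat pairs", len(dnds_rows))
    else:
        logger.warning("no coding sequences available; dN/dS stage skipped")
        ranges = {fam: "-" for fam in subnets}

    dnds_df = pd.DataFrame(
        dnds_rows,
        columns=[
            "family",
            "habitat_pair",
            "id_a",
            "id_b",
            "codons",
            "Sd",
            "Nd",
            "S_sites",
            "N_sites",
            "dS",
            "dN",
            "omega",
            "status",
        ],
    )
    dnds_df.to_csv(out / "dnds.tsv", sep="\t", index=False, float_format="%.6g")

    table["dnds_range"] = [ranges.get(fam, "-") for fam in table.index]
    table.to_csv(out / "family_attributes.tsv", sep="\t", float_format="%.6g")
    table[["classification"]].to_csv(out / "classification.tsv", sep="\t")

    classifications = table["classification"].to_dict()
    for fam, cls in classifications.items():
        logger.info("family %s: %s", fam, cls)

    return RunReport(
        n_records_in=len(records),
        n_records_filtered=len(filtered),
        n_hits=len(hits),
        n_edges=net.number_of_edges(),
        n_components=topo.n_components,
        n_families=len(subnets),
        global_topology=topo,
        classifications=classifications,
        warnings=report.warnings,
        out_dir=str(out),
    )
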