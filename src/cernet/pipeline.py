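"""End-to-end pipeline: DE -> pairs -> triplets -> network -> topology ->
RWR -> modules -> enrichment, driven by one config object.

Every stage writes its table into a config-hash-named output directory and
appends an entry (stage, input/output counts, parameters) to a
machine-readable run report, so re-running an identical config reproduces
identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import diffexpr, io, modules, rwr, topology, triplets
from .containers import ExpressionMatrix, ValidationError
from .synthetic import (
    PlantedTriplet,
    SyntheticDataset,
    SyntheticSpec,
    default_planted_triplets,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All paths, thresholds and flags for one pipeline run.

    Input comes either from files (``lncrna_path``/``mirna_path``/
    ``mrna_path`` + ``group_table_path`` + ``interactions_path``) or, when
    ``simulate`` is set, from the synthetic generator.
    """

    out_dir: str = "cernet-out"
    # file inputs
    lncrna_path: Optional[str] = None
    mirna_path: Optional[str] = None
    mrna_path: Optional[str] = None
    group_table_path: Optional[str] = None
    interactions_path: Optional[str] = None
    gmt_path: Optional[str] = None
    input_is_log2: bool = False
    # synthetic input
    simulate: bool = False
    n_case: int = 3
    n_control: int = 3
    n_lncRNA: int = 50
    n_miRNA: int = 20
    n_mRNA: int = 100
    n_planted: int = 5
    effect_size: float = 2.0
    background_noise_sd: float = 0.25
    rng_seed: int = 0
    # thresholds
    fc_threshold_mirna: float = 2.0
    fc_threshold_lncrna: float = 1.5
    fc_threshold_mrna: float = 1.5
    p_threshold: float = 0.05
    pcc_threshold: float = 0.99
    neg_threshold: float = 0.0
    correlate_log2: bool = True
    # network / downstream
    include_lnc_mrna_edges: bool = False
    top_k: int = 20
    restart_prob: float = 0.7
    rwr_seeds: Optional[list[str]] = None
    module_k: int = 2
    module_linkage: str = "average"
    module_distance: str = "correlation"

    def __post_init__(self) -> None:
        for name in ("p_threshold", "pcc_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.restart_prob <= 1:
            raise ValidationError(
                f"restart_prob must be in (0, 1], got {self.restart_prob}"
            )
        if self.top_k < 1:
            raise ValidationError(f"top_k must be >= 1, got {self.top_k}")
        if not self.simulate:
            needed = ("lncrna_path", "mirna_path", "mrna_path",
                      "group_table_path", "interactions_path")
            missing = [n for n in needed if getattr(self, n) is None]
            if missing:
                raise ValidationError(
                    f"file inputs require {missing} (or set simulate: true)"
                )

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        spec = SyntheticSpec(
            n_case=config.n_case,
            n_control=config.n_control,
            n_lncRNA=config.n_lncRNA,
            n_miRNA=config.n_miRNA,
            n_mRNA=config.n_mRNA,
            planted_triplets=default_planted_triplets(
                config.n_planted, config.effect_size
            ),
            background_noise_sd=config.background_noise_sd,
            rng_seed=config.rng_seed,
        )
        ds = simulate_dataset(spec)
        return ds.lncrna, ds.mirna, ds.mrna, ds.interactions
    groups = io.read_group_table(config.group_table_path)
    lnc = io.read_expression(
        config.lncrna_path, "lncRNA", groups=groups, is_log2=config.input_is_log2
    )
    mir = io.read_expression(
        config.mirna_path, "miRNA", groups=groups, is_log2=config.input_is_log2
    )
    mrna = io.read_expression(
        config.mrna_path, "mRNA", groups=groups, is_log2=config.input_is_log2
    )
    pairs = io.read_interactions(config.interactions_path)
    return lnc, mir, mrna, pairs


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage in order; returns the machine-readable report.

    Outputs land in ``<out_dir>/run_<config-hash>/`` so identical configs
    map to the same directory and reproduce identical files.
    """
    run_dir = Path(config.out_dir) / f"run_{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.rng_seed,
        "stages": [],
    }

    def log_stage(stage: str, **counts) -> None:
        report["stages"].append({"stage": stage, **counts})
        logger.info("stage %s: %s", stage, counts)

    lnc, mir, mrna, interactions = _load_inputs(config)
    log_stage(
        "load",
        n_lncRNA=lnc.n_features, n_miRNA=mir.n_features,
        n_mRNA=mrna.n_features, n_samples=lnc.n_samples,
        n_interactions=len(interactions),
    )
    io.write_interactions(interactions, run_dir / "interactions.tsv")

    # differential expression, per class
    de_records = {}
    fc_by_class = {
        "lncRNA": config.fc_threshold_lncrna,
        "miRNA": config.fc_threshold_mirna,
        "mRNA": config.fc_threshold_mrna,
    }
    de_ids = {}
    for cls, matrix in (("lncRNA", lnc), ("miRNA", mir), ("mRNA", mrna)):
        recs = diffexpr.select_de(
            matrix, fc_threshold=fc_by_class[cls], p_threshold=config.p_threshold
        )
        de_records[cls] = recs
        de_ids[cls] = diffexpr.passing_ids(recs)
        diffexpr.de_table(recs).to_csv(
            run_dir / f"de_{cls}.tsv", sep="\t", index=False
        )
        log_stage(
            f"de_{cls}", n_tested=len(recs), n_passing=len(de_ids[cls]),
            fc_threshold=fc_by_class[cls], p_threshold=config.p_threshold,
        )

    # correlated lncRNA-mRNA pairs
    pairs = triplets.select_lnc_mrna_pairs(
        lnc, mrna,
        de_lnc=de_ids["lncRNA"], de_mrna=de_ids["mRNA"],
        pcc_threshold=config.pcc_threshold, p_threshold=config.p_threshold,
        use_log2=config.correlate_log2,
    )
    pd.DataFrame(
        [(l, m, c.r, c.p_value) for l, m, c in pairs],
        columns=["lncrna_id", "mrna_id", "r", "p_value"],
    ).to_csv(run_dir / "lnc_mrna_pairs.tsv", sep="\t", index=False)
    log_stage(
        "pairs",
        n_candidates=len(de_ids["lncRNA"]) * len(de_ids["mRNA"]),
        n_retained=len(pairs), pcc_threshold=config.pcc_threshold,
    )

    # triplets
    trip = triplets.build_triplets(
        pairs, interactions, mir, lnc, mrna,
        neg_threshold=config.neg_threshold, p_threshold=config.p_threshold,
        use_log2=config.correlate_log2, de_mirna=de_ids["miRNA"],
    )
    triplets.triplet_table(trip).to_csv(
        run_dir / "triplets.tsv", sep="\t", index=False
    )
    log_stage("triplets", n_pairs_in=len(pairs), n_triplets=len(trip))

    # network + topology
    report["network"] = {}
    if trip:
        net = topology.assemble_network(
            trip, include_lnc_mrna_edges=config.include_lnc_mrna_edges
        )
        io.write_network(net, run_dir / "network.sif", dialect="SIF")
        io.write_network(net, run_dir / "network.graphml", dialect="GraphML")
        metrics = topology.node_metrics(net)
        topology.metrics_table(metrics).to_csv(
            run_dir / "node_metrics.tsv", sep="\t", index=False
        )
        ranking = topology.rank_top(metrics, k=config.top_k)
        (run_dir / "top_nodes.json").write_text(
            json.dumps(ranking, indent=2, sort_keys=True)
        )
        counts = [
            topology.count_pairs(net, l) for l in net.nodes("lncRNA")
        ]
        pd.DataFrame(
            [(c.lncrna_id, c.n_first, c.n_secondary, c.total) for c in counts],
            columns=["lncrna_id", "lnc_mir_pairs", "mir_mrna_pairs", "total"],
        ).sort_values(
            ["total", "lncrna_id"], ascending=[False, True]
        ).to_csv(run_dir / "pair_counts.tsv", sep="\t", index=False)
        log_stage(
            "network",
            **{f"n_{k}": v for k, v in net.class_counts().items()},
            n_edges=net.n_edges,
        )
        report["network"] = {
            "class_counts": net.class_counts(),
            "n_edges": net.n_edges,
            "top": ranking,
        }

        # RWR from configured seeds (default: every lncRNA node)
        seeds = config.rwr_seeds or net.nodes("lncRNA")
        profile = rwr.random_walk_restart(
            net, seeds, restart_prob=config.restart_prob
        )
        profile.ranked().rename("probability").to_csv(
            run_dir / "rwr.tsv", sep="\t", index_label="node_id"
        )
        log_stage(
            "rwr", n_seeds=len(seeds), iterations=profile.iterations_used,
            restart_prob=config.restart_prob,
        )
    else:
        log_stage("network", skipped="no triplets")

    # co-expression modules over the DE lncRNA + mRNA log2 expression
    de_lm = de_ids["lncRNA"] + de_ids["mRNA"]
    if len(de_lm) >= 2:
        expr = pd.concat(
            [lnc.to_log2().values.loc[de_ids["lncRNA"]],
             mrna.to_log2().values.loc[de_ids["mRNA"]]]
        )
        try:
            rows, cols = modules.bicluster(
                expr,
                linkage=config.module_linkage,
                distance=config.module_distance,
                k=min(config.module_k, expr.shape[0]),
            )
        except ValidationError as exc:
            # degenerate module input (e.g. all-identical DE rows) is
            # reported as skipped rather than aborting the run
            log_stage("modules", skipped=str(exc))
        else:
            pd.DataFrame(
                sorted(rows.labels.items()), columns=["feature_id", "module"]
            ).to_csv(run_dir / "modules.tsv", sep="\t", index=False)
            log_stage(
                "modules", n_features=len(rows.labels), n_modules=rows.n_modules
            )

        if config.gmt_path:
            sets = io.read_gmt(config.gmt_path)
            universe = set(mrna.feature_ids)
            query = set(de_ids["mRNA"]) & universe
            results = modules.enrich(query, sets, universe)
            modules.enrichment_table(results).to_csv(
                run_dir / "enrichment.tsv", sep="\t", index=False
            )
            log_stage("enrich", n_sets=len(sets), n_query=len(query))
    else:
        log_stage("modules", skipped="fewer than 2 DE lncRNA/mRNA features")

    (run_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str)
    )
    report["run_dir"] = str(run_dir)
    return report
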