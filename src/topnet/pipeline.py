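"""End-to-end orchestration: build networks, select genes, null-test, report.

A single YAML config drives the run; every output file embeds the config
hash and global seed so reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .diffexpr import DEGConfig, two_class_test
from .ggin import GGINConfig, aggregate_gene_stats, subsample_ensemble
from .io_formats import (
    ExpressionStudy,
    GeneCatalog,
    PPIGraph,
    read_expression,
    read_gene_list,
    read_ppi,
)
from .nullmodels import (
    SelectionPipelineSpec,
    null_ensemble,
    permutation_p,
    PermutationSummary,
)
from .trend import (
    EarlyMarkerConfig,
    SelectionResult,
    ToPConfig,
    build_trend_records,
    combine_sequences,
    early_markers,
    hit_rate,
    top_select,
    tps_select,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_top_pipeline", "run_null_campaign"]


@dataclass
class RunConfig:
    expression: str = ""
    design: str = ""
    ppi: str = ""
    catalog: str | None = None
    sequences: list[list[str]] = field(default_factory=list)
    ggin: GGINConfig = field(default_factory=GGINConfig)
    top: ToPConfig = field(default_factory=ToPConfig)
    deg: DEGConfig = field(default_factory=DEGConfig)
    early: EarlyMarkerConfig = field(default_factory=EarlyMarkerConfig)
    selection_mode: str = "tps"
    out_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, typ in (
            ("ggin", GGINConfig),
            ("top", ToPConfig),
            ("deg", DEGConfig),
            ("early", EarlyMarkerConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        cfg = cls(**kwargs)
        for p in (cfg.expression, cfg.design, cfg.ppi, cfg.catalog):
            if p and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # where outputs land is not semantic
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    per_sequence: dict[tuple[str, ...], dict]
    combined: SelectionResult | None
    funnel: list[dict]
    markers: dict[str, SelectionResult]
    summary: dict


def _run_sequence(
    study: ExpressionStudy,
    ppi: PPIGraph,
    sequence: tuple[str, ...],
    config: RunConfig,
    catalog: GeneCatalog | None,
) -> tuple[dict, list[dict]]:
    """One sequence end to end; returns artifacts and funnel rows."""
    universe = sorted(set(study.genes) & ppi.nodes)
    funnel = [
        {"sequence": "-".join(sequence), "stage": "measured", "n": study.n_genes},
        {"sequence": "-".join(sequence), "stage": "in_ppi", "n": len(universe)},
    ]
    ggin_cfg = replace(config.ggin, seed=config.seed)
    stats_by_state = {}
    for st in sequence:
        ensemble = subsample_ensemble(study, st, ppi, ggin_cfg)
        stats_by_state[st] = aggregate_gene_stats(
            ensemble, universe, aggregate=ggin_cfg.aggregate
        )
    records = build_trend_records(stats_by_state, sequence, universe)
    in_net = sum(1 for r in records if any(d > 0 for d in r.D))
    funnel.append({"sequence": "-".join(sequence), "stage": "in_network", "n": in_net})

    top_result = top_select(records, config.top)
    funnel.append(
        {"sequence": "-".join(sequence), "stage": "top", "n": len(top_result)}
    )
    artifacts = {"records": records, "top": top_result, "stats": stats_by_state}

    first, mid, final = sequence[0], sequence[1], sequence[-1]
    deg_mid = two_class_test(
        study, study.state_samples(mid), study.state_samples(first), config=config.deg
    )
    deg_final = two_class_test(
        study, study.state_samples(final), study.state_samples(first), config=config.deg
    )
    artifacts["deg_mid"], artifacts["deg_final"] = deg_mid, deg_final
    if config.selection_mode == "tps":
        tps_result = tps_select(top_result, deg_mid, deg_final, config.deg)
        funnel.append(
            {"sequence": "-".join(sequence), "stage": "tps", "n": len(tps_result)}
        )
        artifacts["selected"] = tps_result
    else:
        artifacts["selected"] = top_result
    if catalog is not None and len(artifacts["selected"]) > 0:
        artifacts["selected"].summary["hit_rate"] = hit_rate(
            artifacts["selected"], catalog
        )
    for row in funnel:
        logger.info("funnel %(sequence)s %(stage)s: %(n)d", row)
    return artifacts, funnel


def run_top_pipeline(
    config: RunConfig,
    inputs: tuple[ExpressionStudy, PPIGraph, GeneCatalog | None] | None = None,
) -> PipelineResult:
    """Run the full selection for every configured sequence.

    ``inputs`` bypasses file loading (study, ppi, catalog); otherwise the
    paths in the config are read. Stages abort with the stage name in the
    exception context.
    """
    if inputs is not None:
        study, ppi, catalog = inputs
    else:
        study = read_expression(config.expression, config.design)
        ppi = read_ppi(config.ppi)
        catalog = read_gene_list(config.catalog) if config.catalog else None
    if not config.sequences:
        raise ValueError("no state sequences configured")
    for seq in config.sequences:
        unknown = [s for s in seq if s not in study.states]
        if unknown:
            raise ValueError(f"sequence states not in design: {unknown}")

    per_sequence: dict[tuple[str, ...], dict] = {}
    funnel: list[dict] = []
    for seq in config.sequences:
        seq = tuple(seq)
        try:
            artifacts, rows = _run_sequence(study, ppi, seq, config, catalog)
        except Exception as err:
            raise RuntimeError(f"sequence {'-'.join(seq)} failed: {err}") from err
        per_sequence[seq] = artifacts
        funnel.extend(rows)

    combined: SelectionResult | None = None
    if len(per_sequence) >= 2:
        seqs = list(per_sequence)
        combined = combine_sequences(
            per_sequence[seqs[0]]["selected"], per_sequence[seqs[1]]["selected"]
        )
        if catalog is not None and len(combined) > 0:
            combined.summary["hit_rate"] = hit_rate(combined, catalog)

    markers: dict[str, SelectionResult] = {}
    seqs = list(per_sequence)
    for i, seq in enumerate(seqs):
        mid = seq[1]
        other = seqs[1 - i] if len(seqs) == 2 else None
        deg_other = per_sequence[other]["deg_mid"] if other else None
        markers[mid] = early_markers(
            per_sequence[seq]["selected"],
            {r.gene: r for r in per_sequence[seq]["records"]},
            per_sequence[seq]["deg_mid"],
            deg_other,
            config.early,
            state=mid,
            deg_config=config.deg,
        )

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_selected": {
            "-".join(seq): len(art["selected"]) for seq, art in per_sequence.items()
        },
        "n_markers": {st: len(res) for st, res in markers.items()},
    }
    if combined is not None:
        summary["combined"] = dict(combined.summary)
    result = PipelineResult(
        per_sequence=per_sequence,
        combined=combined,
        funnel=funnel,
        markers=markers,
        summary=summary,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config.config_hash()} seed={config.seed}\n"
    with open(out / "funnel.tsv", "w") as fh:
        fh.write(header)
        fh.write("sequence\tstage\tn\n")
        for row in result.funnel:
            fh.write(f"{row['sequence']}\t{row['stage']}\t{row['n']}\n")
    for seq, art in result.per_sequence.items():
        name = "-".join(seq)
        sel: SelectionResult = art["selected"]
        with open(out / f"selected_{name}.tsv", "w") as fh:
            fh.write(header)
            fh.write("gene\t" + "\t".join(f"D_{s}" for s in seq))
            fh.write("\t" + "\t".join(f"C_{s}" for s in seq) + "\n")
            for gene in sorted(sel.genes):
                rec = sel.records.get(gene)
                ds = "\t".join(f"{d:.4g}" for d in rec.D) if rec else ""
                cs = "\t".join(f"{c:.4g}" for c in rec.C) if rec else ""
                fh.write(f"{gene}\t{ds}\t{cs}\n")
    with open(out / "summary.yaml", "w") as fh:
        fh.write(header)
        yaml.safe_dump(result.summary, fh, sort_keys=True)


def run_null_campaign(
    config: RunConfig,
    observed: PipelineResult,
    rand_type: str = "type2",
    n_replicates: int = 100,
    inputs: tuple[ExpressionStudy, PPIGraph, GeneCatalog | None] | None = None,
) -> dict[str, PermutationSummary]:
    """Permutation summaries (selection size, hit rate) for the first
    configured sequence against ``n_replicates`` randomized reruns."""
    if observed is None:
        raise ValueError("missing observed pipeline run")
    if inputs is not None:
        study, ppi, catalog = inputs
    else:
        study = read_expression(config.expression, config.design)
        ppi = read_ppi(config.ppi)
        catalog = read_gene_list(config.catalog) if config.catalog else None
    seq = tuple(config.sequences[0])
    spec = SelectionPipelineSpec(
        study=study,
        ppi=ppi,
        sequence=seq,
        ggin_config=replace(config.ggin, seed=config.seed),
        top_config=config.top,
        deg_config=config.deg,
        selection_mode=config.selection_mode,
        catalog=catalog,
        aggregate=config.ggin.aggregate,
    )
    runs = null_ensemble(spec, rand_type, n_replicates, seed=config.seed)
    sel_obs = observed.per_sequence[seq]["selected"]
    summaries = {
        "n_selected": permutation_p(
            len(sel_obs), [r.n_selected for r in runs], direction="greater"
        )
    }
    if catalog is not None and len(sel_obs) > 0:
        null_rates = [r.hit_rate if r.hit_rate is not None else 0.0 for r in runs]
        summaries["hit_rate"] = permutation_p(
            sel_obs.summary.get("hit_rate", hit_rate(sel_obs, catalog)),
            null_rates,
            direction="greater",
        )
    return summaries
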