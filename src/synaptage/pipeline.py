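"""End-to-end orchestration: ingest -> normalize -> filter -> cluster ->
profiles -> subtraction -> candidates -> (optional) upstream regulators.

A single :class:`PipelineConfig` drives the run: either a simulation block or
per-region input paths, plus the stage parameter sets. All intermediate
artifacts are written under the output directory, a plain-text log records
one line per stage, and the machine-readable :class:`RunSummary` (JSON)
echoes the configuration so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .filtering import FilterParams, anova_by_age, apply_filters, stats_to_frame
from .network import MclParams, build_graph, mcl_cluster, write_edgelist
from .profiles import (
    CHANGING_CLASSES,
    CandidateParams,
    ClassParams,
    candidates_to_frame,
    classify_profile,
    classify_proteins,
    cluster_mean_profiles,
    select_candidates,
    subtract_analogous,
)
from .regulators import RegulatorNetwork, activation_zscore, observed_directions, scores_to_frame
from .simulate import RegulatorSpec, SimConfig, simulate_dataset, write_truth
from .tables import arcsinh_normalize, read_abundance


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Exactly one of ``simulate`` / ``input_paths`` selects the data source."""

    simulate: SimConfig | None = None
    input_paths: dict | None = None  # region -> path
    input_normalized: bool = False
    filter_params: FilterParams = field(default_factory=FilterParams)
    r_threshold: float = 0.95
    mcl_params: MclParams = field(default_factory=MclParams)
    class_params: ClassParams = field(default_factory=ClassParams)
    candidate_params: CandidateParams = field(default_factory=CandidateParams)
    regulator_network: str | RegulatorNetwork | None = None
    universe_size: int | None = None
    outdir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_paths is None):
            raise ValueError("provide exactly one of simulate / input_paths")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and isinstance(d["simulate"], dict):
            sim = dict(d["simulate"])
            if "regulator_spec" in sim:
                sim["regulator_spec"] = [
                    RegulatorSpec(**r) if isinstance(r, dict) else r
                    for r in sim["regulator_spec"]
                ]
            if "regions" in sim:
                sim["regions"] = tuple(sim["regions"])
            d["simulate"] = SimConfig(**sim)
        for key, typ in (
            ("filter_params", FilterParams),
            ("mcl_params", MclParams),
            ("class_params", ClassParams),
            ("candidate_params", CandidateParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def echo(self) -> dict:
        d = asdict(self)
        if isinstance(self.regulator_network, RegulatorNetwork):
            d["regulator_network"] = "<in-memory network>"
        if self.simulate is not None:
            d["simulate"]["class_fractions"] = {
                getattr(k, "value", k): v for k, v in d["simulate"]["class_fractions"].items()
            }
        return d


@dataclass
class RunSummary:
    """Per-region counts, subtraction and candidate results, config echo."""

    version: str
    seed: int | None
    regions: list[str]
    n_proteins: int
    per_region: dict  # region -> {kept, dropped, clusters, class_histogram, ...}
    subtraction: dict  # unique_a / unique_b / removed counts
    n_candidates: int
    candidates: list[str]
    regulator_states: dict  # regulator -> {z, state}
    config: dict

    def to_json(self, **kw) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, **kw)


def run_pipeline(config: PipelineConfig):
    """Execute the full analysis; returns (RunSummary, CandidateReport list).

    Stages fail loudly: any error is re-raised as :class:`PipelineError`
    naming the stage, and if an output directory is set a ``FAILED`` marker
    file records the stage so partial artifacts are recognizable.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    times: dict[str, float] = {}

    def log(msg: str) -> None:
        log_lines.append(msg)

    stage = "ingest"
    try:
        t0 = time.perf_counter()
        truth = None
        if config.simulate is not None:
            sim = config.simulate
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=config.seed)
            table, truth = simulate_dataset(sim)
            if outdir:
                table.to_tsv(outdir / "abundance.tsv")
                write_truth(truth, outdir / "truth.tsv")
        else:
            tables = {
                region: read_abundance(path, normalized=config.input_normalized)
                for region, path in config.input_paths.items()
            }
            table = merge_regions(tables)
        regions = table.regions
        log(f"ingest: {len(table.protein_ids)} proteins, {len(table.values.columns)} samples, "
            f"regions {regions}")
        times[stage] = time.perf_counter() - t0

        stage = "normalize"
        t0 = time.perf_counter()
        if not table.normalized:
            table = arcsinh_normalize(table)
            log("normalize: Arc-Sinh applied")
        else:
            log("normalize: input already normalized, skipped")
        times[stage] = time.perf_counter() - t0

        per_region: dict = {}
        kept_ids: dict = {}
        changing: dict = {}
        for region in regions:
            stage = f"filter[{region}]"
            t0 = time.perf_counter()
            stats_list = anova_by_age(table, region)
            kept, dropped = apply_filters(stats_list, config.filter_params)
            kept_ids[region] = [s.protein for s in kept]
            if outdir:
                stats_to_frame(stats_list).to_csv(outdir / f"stats_{region}.tsv", sep="\t")
            log(f"filter[{region}]: kept {len(kept)} / dropped {len(dropped)}")
            times[stage] = time.perf_counter() - t0

            stage = f"cluster[{region}]"
            t0 = time.perf_counter()
            if kept_ids[region]:
                graph = build_graph(
                    table, kept_ids[region], r_threshold=config.r_threshold, region=region
                )
                clusters = mcl_cluster(graph, config.mcl_params)
                n_graph = graph.number_of_nodes()
            else:
                graph, clusters, n_graph = None, None, 0
            cluster_profiles = (
                cluster_mean_profiles(clusters, table, region) if clusters else []
            )
            histogram: dict = {}
            for prof in cluster_profiles:
                c = classify_profile(prof, config.class_params).value
                histogram[c] = histogram.get(c, 0) + 1
            if outdir and clusters:
                write_edgelist(graph, outdir / f"edges_{region}.tsv")
                clusters.to_frame().to_csv(outdir / f"clusters_{region}.tsv", sep="\t")
            log(
                f"cluster[{region}]: {len(clusters) if clusters else 0} clusters "
                f"({len(clusters.non_singletons) if clusters else 0} non-singleton), "
                f"graph nodes {n_graph}"
            )
            times[stage] = time.perf_counter() - t0

            stage = f"profiles[{region}]"
            t0 = time.perf_counter()
            classes = {
                p: c
                for p, c in classify_proteins(table, region, config.class_params).items()
                if p in set(kept_ids[region])
            }
            # subtraction works on every filtered protein with its exact class;
            # the changing-class count is reported for orientation
            changing[region] = classes
            per_region[region] = {
                "ingested": len(table.protein_ids),
                "kept": len(kept_ids[region]),
                "dropped": len(table.protein_ids) - len(kept_ids[region]),
                "graph_nodes": n_graph,
                "graph_excluded_constant": len(kept_ids[region]) - n_graph,
                "clusters": len(clusters) if clusters else 0,
                "non_singleton_clusters": len(clusters.non_singletons) if clusters else 0,
                "cluster_class_histogram": histogram,
                "changing_proteins": sum(1 for c in classes.values() if c in CHANGING_CLASSES),
                "mcl_converged": bool(clusters.converged) if clusters else None,
            }
            times[stage] = time.perf_counter() - t0

        stage = "subtraction"
        t0 = time.perf_counter()
        ra, rb = regions[0], regions[1]
        unique_a, unique_b, removed = subtract_analogous(changing[ra], changing[rb])
        subtraction = {
            "region_a": ra,
            "region_b": rb,
            "unique_a": len(unique_a),
            "unique_b": len(unique_b),
            "removed": len(removed),
        }
        if outdir:
            _write_subtraction(outdir / "subtraction.tsv", ra, rb, unique_a, unique_b, removed,
                               changing)
        log(f"subtraction: unique[{ra}]={len(unique_a)} unique[{rb}]={len(unique_b)} "
            f"removed={len(removed)}")
        times[stage] = time.perf_counter() - t0

        stage = "candidates"
        t0 = time.perf_counter()
        survivors = sorted(set(unique_a) | set(unique_b))
        reports = select_candidates(
            survivors, table, config.candidate_params, regions=(ra, rb),
            class_params=config.class_params,
        )
        hits = [r for r in reports if r.verdict]
        if outdir and reports:
            candidates_to_frame(reports).to_csv(outdir / "candidates.tsv", sep="\t")
        log(f"candidates: {len(hits)} of {len(reports)} tested")
        times[stage] = time.perf_counter() - t0

        stage = "upstream"
        t0 = time.perf_counter()
        regulator_states: dict = {}
        network = config.regulator_network
        if network is None and truth is not None and truth.network:
            network = RegulatorNetwork.from_edges(truth.network)
        elif isinstance(network, (str, Path)):
            network = RegulatorNetwork.from_tsv(network)
        if network is not None and kept_ids[ra]:
            # directions come from the vulnerable region's differential set
            observed = observed_directions(table, ra, kept_ids[ra])
            if observed:
                universe = config.universe_size or len(table.protein_ids)
                scores = activation_zscore(network, observed, universe)
                regulator_states = {
                    s.regulator: {"z": s.z, "p": s.overlap_p, "state": s.state} for s in scores
                }
                if outdir:
                    scores_to_frame(scores).to_csv(outdir / "regulators.tsv", sep="\t")
                log(f"upstream: scored {len(scores)} regulators")
        times[stage] = time.perf_counter() - t0
    except Exception as exc:
        if outdir:
            (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
            (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    summary = RunSummary(
        version=__version__,
        seed=config.seed if config.seed is not None else (
            config.simulate.seed if config.simulate else None
        ),
        regions=list(regions),
        n_proteins=len(table.protein_ids),
        per_region=per_region,
        subtraction=subtraction,
        n_candidates=len(hits),
        candidates=[r.protein for r in hits],
        regulator_states=regulator_states,
        config=config.echo(),
    )
    if outdir:
        for name, secs in times.items():
            log_lines.append(f"time[{name}]: {secs:.3f}s")
        (outdir / "summary.json").write_text(summary.to_json() + "\n")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary, reports


def merge_regions(tables: dict):
    """Combine per-region tables on their shared proteins (inner join)."""
    import pandas as pd
    import warnings as _w
    from .tables import AbundanceTable

    items = list(tables.items())
    shared = set(items[0][1].protein_ids)
    for _, t in items[1:]:
        shared &= set(t.protein_ids)
    dropped = sum(len(t.protein_ids) for _, t in items) - len(shared) * len(items)
    if dropped:
        _w.warn(f"merge_regions: dropping {dropped} region-specific protein rows", stacklevel=2)
    order = [p for p in items[0][1].protein_ids if p in shared]
    values = pd.concat([t.values.loc[order] for _, t in items], axis=1)
    samples = pd.concat([t.samples for _, t in items], axis=0)
    return AbundanceTable(
        values=values,
        samples=samples,
        unique_peptides=items[0][1].unique_peptides.loc[order],
        normalized=items[0][1].normalized,
    )


def _write_subtraction(path, ra, rb, unique_a, unique_b, removed, changing) -> None:
    import pandas as pd

    rows = []
    for p in unique_a:
        rows.append((p, "unique_" + ra, changing[ra][p].value, ""))
    for p in unique_b:
        rows.append((p, "unique_" + rb, "", changing[rb][p].value))
    for p in removed:
        rows.append((p, "removed", changing[ra][p].value, changing[rb][p].value))
    pd.DataFrame(rows, columns=["protein_id", "status", f"class_{ra}", f"class_{rb}"]).to_csv(
        path, sep="\t", index=False
    )
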