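"""End-to-end experiment: generate -> construct -> profile -> evolve -> classify.

A single master seed propagates to every stochastic stage, so identical
configs give byte-identical result files. Stage order and the group-mean
convention (per-subject metrics first, means after) mirror the analysis the
package implements.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as bio
from .atlas import RegionAtlas, generate_atlas
from .classification import FEATURES, accuracy_table, build_training_set, train_and_classify
from .construction import BinaryNetwork, ThresholdGrid, pearson_matrix, threshold_sweep
from .errors import InvalidArgumentError
from .evolution import EvolutionParams, EvolutionTrace, evolve_group
from .metrics import TopologyProfile, group_mean_profiles, topology_profile
from .synthetic import AD, EVOLVED, HEALTHY, SyntheticCohortConfig, sample_cohort

log = logging.getLogger("brainevo")


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)
    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    write_timeseries: bool = False
    write_plots: bool = False

    def with_seed(self, seed: int) -> "ExperimentConfig":
        """Propagate one master seed into every stochastic block."""
        return dataclasses.replace(
            self,
            seed=seed,
            cohort=dataclasses.replace(self.cohort, seed=seed),
            evolution=dataclasses.replace(self.evolution, seed=seed + 1),
        )

    def to_dict(self) -> dict:
        return {
            "cohort": dataclasses.asdict(self.cohort),
            "grid": dataclasses.asdict(self.grid),
            "evolution": dataclasses.asdict(self.evolution),
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "write_timeseries": self.write_timeseries,
            "write_plots": self.write_plots,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "cohort" in kwargs:
            kwargs["cohort"] = SyntheticCohortConfig(**kwargs["cohort"])
        if "grid" in kwargs:
            kwargs["grid"] = ThresholdGrid(**kwargs["grid"])
        if "evolution" in kwargs:
            kwargs["evolution"] = EvolutionParams(**kwargs["evolution"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ExperimentResult:
    atlas: RegionAtlas
    profiles: list[TopologyProfile]  # healthy + ad + evolved, all thresholds
    traces: dict[tuple[str, float], EvolutionTrace]
    accuracy: "object"  # pandas DataFrame, 11 thresholds + average x 4 features
    group_means: list[TopologyProfile]
    out_files: list[Path] = field(default_factory=list)


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Execute every stage in order and write the result tables.

    Any stage error is re-raised annotated with the stage name and the
    offending subject/threshold.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.grid.values()

    stage = "generate"
    try:
        atlas = generate_atlas(config.cohort.n_regions, seed=config.seed)
        subjects, truths = sample_cohort(config.cohort, atlas)
        log.info("generated %d subjects (%d regions, T=%d)", len(subjects),
                 config.cohort.n_regions, config.cohort.n_timepoints)

        stage = "construct"
        networks: dict[tuple[str, float], BinaryNetwork] = {}
        for ts in subjects:
            corr = pearson_matrix(ts)
            for net in threshold_sweep(corr, config.grid):
                networks[(ts.subject_id, net.threshold)] = net

        stage = "metrics"
        profiles = [topology_profile(net, atlas) for net in networks.values()]

        stage = "evolve"
        healthy_ids = [ts.subject_id for ts in subjects if ts.group == HEALTHY]
        traces: dict[tuple[str, float], EvolutionTrace] = {}
        for tau in thresholds:
            nets = [networks[(sid, tau)] for sid in healthy_ids]
            seed = int(
                np.random.SeedSequence([config.evolution.seed, int(round(tau * 100))])
                .generate_state(1)[0] % 2**31
            )
            params = dataclasses.replace(config.evolution, seed=seed)
            for sid, trace in zip(healthy_ids, evolve_group(nets, atlas, params)):
                traces[(sid, tau)] = trace
        evolved_profiles = [
            topology_profile(tr.final, atlas) for tr in traces.values()
        ]
        profiles = profiles + evolved_profiles

        stage = "classify"
        reports = []
        for tau in thresholds:
            evolved_at_tau = [p for p in profiles if p.group == EVOLVED and p.threshold == tau]
            for feature in FEATURES:
                train = build_training_set(profiles, feature, tau)
                values = [getattr(p, feature) for p in evolved_at_tau]
                reports.append(train_and_classify(train, values))
        table = accuracy_table(reports)

        stage = "report"
        group_means = [
            group_mean_profiles(profiles, g, tau)
            for g in (HEALTHY, AD, EVOLVED)
            for tau in thresholds
        ]
        out_files = _write_outputs(out, config, atlas, subjects, profiles, group_means,
                                   traces, table)
    except Exception as exc:
        raise type(exc)(f"[stage={stage}] {exc}") from exc

    return ExperimentResult(
        atlas=atlas,
        profiles=profiles,
        traces=traces,
        accuracy=table,
        group_means=group_means,
        out_files=out_files,
    )


def _write_outputs(out, config, atlas, subjects, profiles, group_means, traces, table):
    files: list[Path] = []

    def reg(path) -> Path:
        files.append(Path(path))
        return Path(path)

    bio.write_atlas(reg(out / "atlas.tsv"), atlas)
    bio.write_profiles(reg(out / "profiles.csv"), profiles)
    bio.write_profiles(reg(out / "group_means.csv"), group_means)
    table.to_csv(reg(out / "accuracy.csv"), float_format="%.2f")

    trace_dir = out / "traces"
    trace_dir.mkdir(exist_ok=True)
    for (sid, tau), trace in traces.items():
        path = reg(trace_dir / f"trace_{sid}_tau{tau:.2f}.csv")
        with path.open("w") as fh:
            fh.write("step,global_efficiency,clustering_coefficient,edge_count,transitivity\n")
            for i, p in enumerate(trace.per_step_profiles, start=1):
                fh.write(
                    f"{i},{p.global_efficiency:.17g},{p.clustering_coefficient:.17g},"
                    f"{p.edge_count},{p.transitivity:.17g}\n"
                )
        bio.write_network(reg(trace_dir / f"final_{sid}_tau{tau:.2f}.tsv"), trace.final)

    if config.write_timeseries:
        manifest = bio.write_cohort(out / "cohort", subjects)
        files.extend(sorted((out / "cohort").glob("*.tsv")))

    if config.write_plots:
        from .plots import plot_group_curves

        for feature in FEATURES + ("long_distance_edge_count",):
            reg(plot_group_curves(group_means, feature, out / f"fig_{feature}.png"))

    with (out / "provenance.json").open("w") as fh:
        json.dump(
            {"config": config.to_dict(), "config_hash": config.config_hash(),
             "seed": config.seed},
            fh, indent=2, sort_keys=True,
        )
    files.append(out / "provenance.json")
    bio.write_output_manifest(out, files)
    return files


def default_config() -> ExperimentConfig:
    return ExperimentConfig()
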