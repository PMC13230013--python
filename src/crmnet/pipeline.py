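"""Configuration and one-command orchestration of the full simulator.

The pipeline mirrors the module chain: generate (or load) a signed
interaction network, translate it into consumer-resource parameters,
integrate the community to steady state, perturb the environment to
produce biological samples, sequence them into a count table and,
optionally, run the inference benchmark against the ground truth. All
randomness derives from one master seed through named per-stage streams,
so every output file is reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benchmark as bm
from . import micrm, net2micrm, netgen, samples, seqsim
from ._rng import stream

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger("crmnet")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one simulated dataset."""

    # network stage
    adjacency_file: str | None = None  # user-supplied A (taxa only) wins
    topology: str = "er"
    S: int = 50
    p: float | None = 0.1
    k: int | None = None
    nneg: float = 0.1
    # translation stage
    sampling_target: str = "D_columns"
    sampling_distribution: str = "binary"
    sampling_params: dict = field(default_factory=dict)
    # dynamics stage
    micrm: dict = field(default_factory=dict)  # MiCRMParams overrides
    fr: float = 0.5
    init_spec: str | float = "lognormal"
    init_meanlog: float = 0.0
    init_sdlog: float = 2.0
    # perturbation stage
    B: int = 30
    fp: object = (0.0, 1.0)  # float or (low, high)
    ps: object = (2.0, 10.0)
    perturbation_mode: str = "constant"
    # sequencing stage
    library_mode: str = "lognormal"
    library_value: int = 50_000
    library_values: list = field(default_factory=list)
    library_meanlog: float = float(np.log(5e4))
    library_sdlog: float = 0.3
    pool_scale: object = "auto"  # abundances are much smaller than read depths
    # benchmark stage
    run_benchmark: bool = False
    n_perm: int = 1000
    alpha: float = 0.05
    correction: str = "fdr_bh"
    # provenance
    seed: int = 0
    outdir: str = "crmnet_out"

    def micrm_params(self) -> micrm.MiCRMParams:
        kwargs = dict(self.micrm)
        kwargs.setdefault("fr", self.fr)
        return micrm.MiCRMParams(**kwargs)

    def netgen_params(self) -> netgen.NetworkGenParams:
        return netgen.NetworkGenParams(
            topology=self.topology, S=self.S, p=self.p, k=self.k,
            nneg=self.nneg, seed=None,
        )

    def sampling_spec(self) -> net2micrm.WeightSamplingSpec | None:
        if self.sampling_distribution == "binary":
            return None
        return net2micrm.WeightSamplingSpec(
            target=self.sampling_target,
            distribution=self.sampling_distribution,
            seed=int(stream(self.seed, "weights").integers(2**31)),
            **self.sampling_params,
        )

    def library_spec(self) -> seqsim.LibrarySizeSpec:
        return seqsim.LibrarySizeSpec(
            mode=self.library_mode, value=self.library_value,
            values=list(self.library_values),
            meanlog=self.library_meanlog, sdlog=self.library_sdlog,
        )


def load_config(path) -> PipelineConfig:
    """Read a nested-key YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if "fp" in raw and isinstance(raw["fp"], list):
        cfg.fp = tuple(raw["fp"])
    if "ps" in raw and isinstance(raw["ps"], list):
        cfg.ps = tuple(raw["ps"])
    return cfg


def _dump_config(cfg: PipelineConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    for key in ("fp", "ps"):
        if isinstance(d[key], tuple):
            d[key] = list(d[key])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PipelineResult:
    net_taxa: netgen.InteractionNetwork
    net_aug: netgen.InteractionNetwork
    system: net2micrm.MicrmSystem
    supply: micrm.Supply
    steady: micrm.SteadyState
    sample_abund: samples.SampleAbundances
    counts: seqsim.CountTable
    inferred: bm.InferredNetwork | None
    mcc: float | None
    outdir: Path


class StageError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("network")
def stage_network(cfg: PipelineConfig) -> tuple:
    if cfg.adjacency_file:
        raw = netgen.read_adjacency_csv(cfg.adjacency_file)
        if raw.has_env:
            raise ValueError("user adjacency must not contain an ENV node")
    else:
        params = cfg.netgen_params()
        params.seed = int(stream(cfg.seed, "network").integers(2**31))
        raw = netgen.generate_network(params)
        raw = netgen.assign_competitions(
            raw, cfg.nneg, stream(cfg.seed, "competitions")
        )
    net_taxa = netgen.disambiguate_competitor_outputs(raw)
    net_aug = netgen.augment_environment(net_taxa)
    return net_taxa, net_aug


@_stage("interpret")
def stage_interpret(cfg: PipelineConfig, net_aug) -> net2micrm.MicrmSystem:
    return net2micrm.interpret_network(net_aug, cfg.sampling_spec())


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, system) -> tuple:
    params = cfg.micrm_params()
    supplied = micrm.choose_supplied_set(
        system.M, system.w_index, params.fr, stream(cfg.seed, "supply")
    )
    supply = micrm.make_supply(params, supplied, system.M, system.w_index)
    state0 = micrm.init_community(
        system.C, params, supply, init_spec=cfg.init_spec,
        seed=stream(cfg.seed, "init"),
        meanlog=cfg.init_meanlog, sdlog=cfg.init_sdlog,
    )
    steady = micrm.integrate_to_steady_state(state0, system.C, system.D, params, supply)
    if not steady.converged:
        log.warning("base community did not converge within t_max")
    log.info(
        "steady state: %d/%d survivors after t=%.0f",
        steady.survivors.size, system.C.shape[0], steady.t_elapsed,
    )
    return params, supply, steady


@_stage("perturb")
def stage_perturb(cfg, system, params, supply, steady) -> samples.SampleAbundances:
    perturbable = (
        supply.supplied_set
        if cfg.perturbation_mode == "constant"
        else np.where(steady.Rss > 0)[0]
    )
    design = samples.design_perturbations(
        perturbable, cfg.B, seed=stream(cfg.seed, "perturb"),
        fp_dist=cfg.fp, ps_dist=cfg.ps, mode=cfg.perturbation_mode,
    )
    return samples.generate_samples(steady, design, system.C, system.D, params, supply)


@_stage("sequence")
def stage_sequence(cfg, system, sample_abund) -> seqsim.CountTable:
    return seqsim.simulate_counts(
        sample_abund.X, cfg.library_spec(), pool_scale=cfg.pool_scale,
        seed=stream(cfg.seed, "sequence"), taxa=system.taxa,
    )


@_stage("benchmark")
def stage_benchmark(cfg, net_taxa, counts) -> tuple:
    inferred = bm.infer_pearson_network(
        counts.Y, n_perm=cfg.n_perm, alpha=cfg.alpha,
        correction=cfg.correction, seed=stream(cfg.seed, "benchmark"),
    )
    truth = bm.to_undirected_truth(net_taxa)
    score = bm.mcc(inferred.adjacency, truth)
    return inferred, truth, score


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _dump_config(cfg, outdir / "config.yaml")

    net_taxa, net_aug = stage_network(cfg)
    netgen.write_adjacency_csv(net_taxa, outdir / "A_taxa.csv")
    netgen.write_adjacency_csv(net_aug, outdir / "A_augmented.csv")
    netgen.write_edgelist_tsv(net_aug, outdir / "edges.tsv")

    system = stage_interpret(cfg, net_aug)
    met = net2micrm.metabolite_labels(system.M)
    net2micrm.write_matrix_csv(system.C, outdir / "C.csv", system.taxa, met)
    net2micrm.write_matrix_csv(system.D, outdir / "D.csv", met, met)
    net2micrm.write_matrix_csv(
        system.Me, outdir / "Me.csv", net_aug.labels, net_aug.labels
    )

    params, supply, steady = stage_simulate(cfg, system)
    micrm.write_steady_state_tsv(steady, system.taxa, outdir / "steady_state.tsv")
    micrm.write_resources_tsv(steady, met, outdir / "resources.tsv")
    pd.DataFrame(
        {"metabolite": [met[m] for m in supply.supplied_set],
         "kappa": supply.kappa0[supply.supplied_set]}
    ).to_csv(outdir / "supply.tsv", sep="\t", index=False)

    sample_abund = stage_perturb(cfg, system, params, supply, steady)
    samples.write_abundance_tsv(sample_abund, system.taxa, outdir / "X.tsv")
    samples.write_sample_metadata_tsv(sample_abund, outdir / "samples_meta.tsv")

    counts = stage_sequence(cfg, system, sample_abund)
    seqsim.write_count_table_tsv(
        counts, outdir / "Y.tsv", outdir / "library_sizes.tsv"
    )

    inferred = None
    score = None
    if cfg.run_benchmark:
        inferred, truth, score = stage_benchmark(cfg, net_taxa, counts)
        bm.write_inferred_edges_tsv(
            inferred, system.taxa, outdir / "inferred_edges.tsv"
        )
        report_path = outdir / "metrics.tsv"
        report_path.write_text(f"mcc\t{score}\n")
        bm.write_topology_report(
            bm.topology_metrics(truth), report_path, prefix="truth_"
        )
        bm.write_topology_report(
            bm.topology_metrics(inferred.adjacency), report_path, prefix="inferred_"
        )

    return PipelineResult(
        net_taxa=net_taxa, net_aug=net_aug, system=system, supply=supply,
        steady=steady, sample_abund=sample_abund, counts=counts,
        inferred=inferred, mcc=score, outdir=outdir,
    )
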