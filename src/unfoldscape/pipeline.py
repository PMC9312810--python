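"""End-to-end unfolding analysis.

`UnfoldingAnalysis` is the model object: it is built from a trajectory, a
native structure and a configuration, and ``fit()`` runs the full chain --
pairwise-RMSD embedding, step vectors, native-exit detection, statistical
free-energy landscape, reaction path with barrier/channel statistics and
TST rate, contact series, molten-globule classification, transition-state
demarcation and (optionally) phi-values -- returning an
`UnfoldingResults` with a ``summary()`` table. ``run_pipeline`` wraps the
pair with artifact output; ``run_replicates`` aggregates fits over
independently seeded synthetic replicates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as cts
from . import landscape as lsc
from . import phi as phimod
from . import rmsd_space as rsp
from .core import Trajectory, load_structure, load_trajectory, write_table
from .synthetic import UnfoldingScenario, make_toy_native, make_unfolding_trajectory

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "UnfoldingAnalysis", "UnfoldingResults",
           "run_pipeline", "run_replicates"]


@dataclass
class PipelineConfig:
    """All pipeline knobs, centralized so docs and code cannot drift.

    Paths may be None when the analysis objects are supplied in memory
    (e.g. synthetic runs). Temperature defaults to the thermal-unfolding
    protocol value of 498 K.
    """

    trajectory: str | None = None
    topology: str | None = None
    native: str | None = None
    native_model: int = 0
    output_dir: str = "unfoldscape_run"
    temperature: float = 498.0
    stride: int = 1
    frame_interval: float = 1.0
    embedding_k: int = 3
    grid_bins: int = 50
    exit_c: float = 5.0
    exit_m: int = 10
    exit_window: int | None = None        # frames; None -> first 5%
    exit_radius_scale: float = 1.5
    contact_cutoff: float = 8.0
    contact_min_separation: int = 3
    mg_q_lo: float = 0.6
    mg_expansion_min: float = 1.05
    mg_q_floor: float = 0.3
    mg_q_hi: float = 0.8
    mg_gap_tolerance: int = 10
    tst_prefactor: float = 1e6
    phi_manifest: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self, require_paths: bool = True) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if require_paths:
            for name in ("trajectory", "native"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config path '{name}' missing: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class UnfoldingResults:
    """Fitted quantities of one unfolding analysis, with a summary table."""

    config: PipelineConfig
    distance_matrix: rsp.DistanceMatrix
    embedding: rsp.Embedding
    steps: rsp.StepVectorSeries
    exit: rsp.NativeExit
    grid: lsc.LandscapeGrid
    path: lsc.ReactionPath
    deltaF_activation: float
    channel_index: float
    intermediates: list
    rate: lsc.RateEstimate
    contact_series: cts.ContactSeries
    ss_timeline: cts.SecondaryStructureTimeline
    classes: np.ndarray
    transition: cts.TransitionEnsemble
    phi_results: list = field(default_factory=list)

    def summary(self) -> str:
        c = self.config
        te = self.transition
        dt = self.steps.frame_interval
        lines = [
            "Unfolding trajectory analysis",
            "=" * 46,
            f"frames analysed            {self.steps.terminals.shape[0]}",
            f"embedding axes (k)         {self.embedding.k}",
            f"explained fraction         {self.embedding.explained_fraction:.3f}",
            f"native exit frame          {self.exit.exit_frame}",
            f"native exit time (ns)      "
            + (f"{self.exit.exit_time:.3f}" if self.exit.found else "no exit"),
            f"activation dF (kcal/mol)   {self.deltaF_activation:.3f}",
            f"channel index              {self.channel_index:.3f}",
            f"stable intermediates       "
            f"{sum(1 for i in self.intermediates if i['stable'])}",
            f"TST k_u (s^-1)             {self.rate.k_u:.4g} "
            f"(prefactor {self.rate.prefactor:.1g}, T = {c.temperature:g} K)",
            f"transition frames          [{te.frame_range[0]}, {te.frame_range[1]}]",
            f"transition window (ns)     "
            f"[{te.frame_range[0] * dt:.2f}, {te.frame_range[1] * dt:.2f}]",
            f"mean transition Rg ratio   "
            + (f"{np.mean(self.contact_series.rg_ratio[self.transition.member_frames]):.3f}"
               if not te.empty else "n/a"),
        ]
        if self.phi_results:
            lines.append(f"phi-values computed        {len(self.phi_results)}")
        return "\n".join(lines)

    def class_table(self) -> pd.DataFrame:
        s = self.contact_series
        return pd.DataFrame({
            "frame": np.arange(len(s.Q)),
            "time_ns": np.arange(len(s.Q)) * self.steps.frame_interval,
            "Q": s.Q, "total": s.total, "q_fraction": s.q_fraction,
            "Rg": s.Rg, "rg_ratio": s.rg_ratio, "class": self.classes,
        })


class UnfoldingAnalysis:
    """Model object: trajectory + native structure + configuration.

    Build directly from in-memory objects, or with :meth:`from_files` /
    :meth:`from_scenario`; ``fit()`` returns :class:`UnfoldingResults`.
    """

    def __init__(self, traj: Trajectory, native_coords: np.ndarray,
                 config: PipelineConfig | None = None):
        self.traj = traj
        self.native_coords = np.asarray(native_coords, dtype=float)
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(cls, config: PipelineConfig) -> "UnfoldingAnalysis":
        config.validate(require_paths=True)
        top_path = config.topology or config.native
        top, _ = load_structure(top_path)
        ntop, native = load_structure(config.native, model=config.native_model)
        traj = load_trajectory(config.trajectory, top, stride=config.stride,
                               frame_interval=config.frame_interval)
        return cls(traj, native, config)

    @classmethod
    def from_scenario(cls, scenario: UnfoldingScenario,
                      config: PipelineConfig | None = None):
        """Synthetic end-to-end demo: generate, then analyse.

        Returns ``(analysis, ground_truth)``.
        """
        top, native, segments = make_toy_native(scenario.n_residues,
                                                seed=scenario.seed)
        traj, truth = make_unfolding_trajectory(native, top, scenario, segments)
        config = config or PipelineConfig()
        config.frame_interval = scenario.frame_interval
        if config.exit_window is None:
            config.exit_window = scenario.exit_frame
        analysis = cls(traj, native, config)
        analysis.ground_truth = truth
        return analysis, truth

    def fit(self) -> UnfoldingResults:
        c = self.config
        c.validate(require_paths=False)
        logger.info("analysis constants: T = %g K, R = %g kcal/(mol K), "
                    "TST prefactor = %g s^-1", c.temperature,
                    lsc.GAS_CONSTANT_KCAL, c.tst_prefactor)
        traj = self.traj
        defn = cts.ContactDefinition(c.contact_cutoff, c.contact_min_separation)

        D = rsp.pairwise_rmsd_matrix(traj)
        emb = rsp.classical_mds(D, k=c.embedding_k)
        steps = rsp.step_vectors(emb, traj.frame_interval)
        window = (0, c.exit_window) if c.exit_window else None
        exit = rsp.detect_native_exit(steps, reference_window=window,
                                      c=c.exit_c, m=c.exit_m,
                                      radius_scale=c.exit_radius_scale)

        grid = lsc.population_grid(steps.terminals, axes=(0, 1),
                                   n_bins=c.grid_bins)
        grid = lsc.free_energy(grid, c.temperature)
        # anchor the path in the dominant basin complex: the briefly
        # sampled native cluster can be disconnected after a precipitous
        # exit, which would leave a trivial single-cluster path
        start = lsc.dominant_component_modal_bin(grid)
        path = lsc.extract_reaction_path(grid, start_bin=start)
        dF, channel_index, intermediates = lsc.barrier_stats(path)
        rate = lsc.tst_rate(dF, c.temperature, prefactor=c.tst_prefactor)

        native_set = cts.native_contacts(self.native_coords, traj.topology, defn)
        series = cts.contact_timeseries(traj, native_set, defn,
                                        native_frame=self.native_coords)
        ss = cts.secondary_structure_timeline(traj, self.native_coords)
        classes = cts.classify_molten_globule(series, ss, q_lo=c.mg_q_lo,
                                              expansion_min=c.mg_expansion_min,
                                              q_floor=c.mg_q_floor,
                                              q_hi=c.mg_q_hi)
        if exit.found:
            transition = cts.demarcate_transition(exit, classes,
                                                  gap_tolerance=c.mg_gap_tolerance)
        else:
            transition = cts.TransitionEnsemble((0, 0), np.array([], dtype=int),
                                                {"exit_frame": None})
        phi_results = []
        if c.phi_manifest:
            phi_results = self._phi_from_manifest(native_set, defn)
        return UnfoldingResults(c, D, emb, steps, exit, grid, path, dF,
                                channel_index, intermediates, rate, series,
                                ss, classes, transition, phi_results)

    def _phi_from_manifest(self, native_set, defn):
        with open(self.config.phi_manifest) as fh:
            manifest = json.load(fh)
        top, _ = load_structure(manifest["topology"]) if "topology" in manifest \
            else (self.traj.topology, None)

        def ens(paths):
            return {k: load_trajectory(p, top).calpha_coords()
                    for k, p in paths.items()}

        wt = ens(manifest["wild_type"])
        mutants = {mid: ens(paths) for mid, paths in manifest["mutants"].items()}
        return phimod.phi_batch(wt, mutants, native_set, defn)


def run_pipeline(config: PipelineConfig,
                 analysis: UnfoldingAnalysis | None = None) -> UnfoldingResults:
    """Fit and persist every stage artifact plus a run manifest.

    Stage failures abort with the stage name; artifacts completed before
    the failure are kept on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if analysis is None:
        analysis = UnfoldingAnalysis.from_files(config)
    stage = "fit"
    artifacts = {}
    try:
        res = analysis.fit()
        stage = "write-distance-matrix"
        np.savetxt(out / "distance_matrix.csv", res.distance_matrix.values,
                   delimiter=",", fmt="%.12g")
        artifacts["distance_matrix"] = "distance_matrix.csv"
        stage = "write-embedding"
        emb_df = pd.DataFrame(res.embedding.coords,
                              columns=[f"axis_{i}" for i in range(res.embedding.k)])
        write_table(emb_df, out / "embedding.csv")
        artifacts["embedding"] = "embedding.csv"
        stage = "write-steps"
        step_df = pd.DataFrame({"frame": np.arange(1, len(res.steps.norms) + 1),
                                "step_norm": res.steps.norms})
        write_table(step_df, out / "step_norms.csv")
        artifacts["step_norms"] = "step_norms.csv"
        stage = "write-exit"
        with open(out / "native_exit.json", "w") as fh:
            json.dump({"exit_frame": res.exit.exit_frame,
                       "exit_time_ns": res.exit.exit_time,
                       "threshold": res.exit.threshold,
                       "cluster_radius": res.exit.cluster_radius,
                       "reference_window": list(res.exit.reference_window),
                       "persistence": res.exit.persistence}, fh, indent=1)
        artifacts["native_exit"] = "native_exit.json"
        stage = "write-landscape"
        np.savetxt(out / "landscape_counts.csv", res.grid.counts,
                   delimiter=",", fmt="%d")
        artifacts["landscape_counts"] = "landscape_counts.csv"
        stage = "write-path"
        path_df = pd.DataFrame({"arc_length": res.path.arc_length,
                                "deltaF": res.path.profile})
        write_table(path_df, out / "reaction_path.csv")
        artifacts["reaction_path"] = "reaction_path.csv"
        stage = "write-barrier"
        with open(out / "barrier.json", "w") as fh:
            json.dump({"deltaF_activation_kcal_mol": res.deltaF_activation,
                       "channel_index": res.channel_index,
                       "intermediates": res.intermediates,
                       "k_u_per_s": res.rate.k_u,
                       "prefactor_per_s": res.rate.prefactor,
                       "temperature_K": res.rate.temperature}, fh, indent=1)
        artifacts["barrier"] = "barrier.json"
        stage = "write-contacts"
        write_table(res.class_table(), out / "contact_series.csv")
        artifacts["contact_series"] = "contact_series.csv"
        stage = "write-transition"
        with open(out / "transition_ensemble.json", "w") as fh:
            json.dump({"frame_range": list(res.transition.frame_range),
                       "n_members": int(len(res.transition.member_frames)),
                       "criteria": res.transition.criteria}, fh, indent=1)
        artifacts["transition_ensemble"] = "transition_ensemble.json"
        if res.phi_results:
            stage = "write-phi"
            write_table(phimod.phi_table(res.phi_results), out / "phi_values.csv")
            artifacts["phi_values"] = "phi_values.csv"
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    manifest = {"config": dataclasses.asdict(config),
                "artifacts": artifacts,
                "constants": {"R_kcal_mol_K": lsc.GAS_CONSTANT_KCAL,
                              "temperature_K": config.temperature,
                              "tst_prefactor_per_s": config.tst_prefactor}}
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "summary.txt", "w") as fh:
        fh.write(res.summary() + "\n")
    return res


def run_replicates(scenario: UnfoldingScenario, config: PipelineConfig,
                   n_replicates: int = 5) -> pd.DataFrame:
    """Fit independently seeded synthetic replicates and aggregate.

    Per-replicate seeds derive deterministically from ``config.seed``;
    returns a table of exit times, activation free energies and channel
    indices with a trailing mean/SD row. Individual replicate failures
    are recorded and aggregation proceeds with the survivors.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_replicates)]
    rows = []
    for r, seed in enumerate(seeds):
        sc = dataclasses.replace(scenario, seed=seed)
        try:
            analysis, truth = UnfoldingAnalysis.from_scenario(
                sc, dataclasses.replace(config))
            res = analysis.fit()
            rows.append({"replicate": r, "seed": seed,
                         "exit_frame": res.exit.exit_frame,
                         "exit_time_ns": res.exit.exit_time,
                         "deltaF_activation": res.deltaF_activation,
                         "channel_index": res.channel_index,
                         "failed": False})
        except Exception as err:
            logger.warning("replicate %d failed: %s", r, err)
            rows.append({"replicate": r, "seed": seed, "exit_frame": None,
                         "exit_time_ns": np.nan, "deltaF_activation": np.nan,
                         "channel_index": np.nan, "failed": True})
    df = pd.DataFrame(rows)
    ok = df[~df["failed"]]
    agg = {"replicate": "aggregate", "seed": config.seed,
           "exit_frame": ok["exit_frame"].mean(),
           "exit_time_ns": ok["exit_time_ns"].mean(),
           "deltaF_activation": ok["deltaF_activation"].mean(),
           "channel_index": ok["channel_index"].mean(), "failed": False}
    sd = {"replicate": "sd", "seed": config.seed,
          "exit_frame": ok["exit_frame"].std(),
          "exit_time_ns": ok["exit_time_ns"].std(),
          "deltaF_activation": ok["deltaF_activation"].std(),
          "channel_index": ok["channel_index"].std(), "failed": False}
    return pd.concat([df, pd.DataFrame([agg, sd])], ignore_index=True)
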