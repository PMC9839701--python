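"""End-to-end orchestration: simulate/read -> filter -> networks -> modules
-> hubs -> cohesion -> keystones -> stats, with a manifest for exact
reproduction.  The CLI in :mod:`gutnet.cli` is a thin wrapper around
:func:`run`."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as gio
from . import simulate as gsim
from .cohesion import cohesion, connectedness, keystone_scan
from .community import centralities, identify_hubs, spinglass_modules
from .network import filter_species, subset_networks

__all__ = ["PipelineConfig", "run", "ALL_STAGES"]

ALL_STAGES = ("simulate", "network", "modules", "hubs", "cohesion",
              "keystones", "stats")


@dataclass
class PipelineConfig:
    """Everything a run needs; serialised verbatim into the manifest."""

    # inputs: either file paths or a synthetic cohort
    abundance_path: str | None = None
    metadata_path: str | None = None
    pathway_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    # thresholds (field defaults follow the standard workflow)
    min_abundance_pct: float = 0.3
    min_prevalence: float = 0.05
    q_max: float = 0.05
    rho_min: float = 0.3
    keystone_cut: float = 50.0

    # spin-glass parameters
    spins: int = 25
    gamma_pos: float = 1.0
    gamma_neg: float = 1.0
    t_start: float = 1.0
    t_stop: float = 0.01
    cooling: float = 0.99

    # one-sided alternatives per parameter per group for the t-test stage
    alternatives: dict = field(default_factory=dict)

    outdir: str = "gutnet_run"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.keystone_cut < 100.0:
            raise ValueError("keystone_cut must be in (0, 100)")
        for name in ("min_abundance_pct", "min_prevalence", "q_max",
                     "rho_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (self.abundance_path is None) != (self.metadata_path is None):
            raise ValueError("abundance_path and metadata_path go together")


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, **kwargs) -> None:
    """TSV with a seed-stamped comment header for provenance."""
    with open(path, "w") as fh:
        fh.write(f"# gutnet {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", **kwargs)


def run(config: PipelineConfig, stages=ALL_STAGES) -> Path:
    """Execute the pipeline and write all outputs under ``config.outdir``.

    ``stages`` selects which outputs to write; prerequisite computations are
    performed in memory regardless.  Re-running with the same config and
    seed reproduces every output bit-identically.
    """
    stages = set(stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- inputs -----------------------------------------------------------
    if config.abundance_path is not None:
        table = gio.read_metaphlan_table(config.abundance_path)
        metadata = gio.read_metadata(config.metadata_path)
        truth = None
    else:
        syn = gsim.default_config(seed=seed)
        if config.synthetic:
            base = asdict(syn)
            # overriding the block layout invalidates the default planted
            # structure that references it; reset unless explicitly given
            if "blocks" in config.synthetic:
                base["antagonist_pairs"] = ()
                base["keystone_spec"] = ()
                base["group_effects"] = {}
            base.update(config.synthetic)
            base["blocks"] = tuple(
                b if isinstance(b, gsim.BlockSpec)
                else gsim.BlockSpec(**b) if isinstance(b, dict)
                else gsim.BlockSpec(*b)
                for b in base["blocks"])
            base["antagonist_pairs"] = tuple(
                tuple(p) for p in base["antagonist_pairs"])
            base["keystone_spec"] = tuple(
                tuple(k) for k in base["keystone_spec"])
            base["group_effects"] = {
                tuple(k) if not isinstance(k, tuple) else k: v
                for k, v in base["group_effects"].items()}
            syn = gsim.SyntheticConfig(**base)
        table, metadata, truth = gsim.generate_cohort(syn)
    gio.check_samples_match(table, metadata)

    if "simulate" in stages and truth is not None:
        gio.write_metaphlan_table(table, outdir / "abundance.tsv")
        _write_tsv(metadata, outdir / "metadata.tsv", seed)
        _write_tsv(gsim.ground_truth_frame(truth, list(table.columns)),
                   outdir / "ground_truth.tsv", seed)

    # --- networks ---------------------------------------------------------
    kw = dict(min_abundance_pct=config.min_abundance_pct,
              min_prevalence=config.min_prevalence,
              q_max=config.q_max, rho_min=config.rho_min)
    global_net = subset_networks(table, metadata, "global", **kw)[0]
    group_nets = subset_networks(table, metadata, "per_group", **kw)
    local_nets = subset_networks(table, metadata, "per_group_timepoint", **kw)

    # --- modules on the global network ------------------------------------
    sg_kw = dict(spins=config.spins, gamma_pos=config.gamma_pos,
                 gamma_neg=config.gamma_neg, t_start=config.t_start,
                 t_stop=config.t_stop, cooling=config.cooling)
    global_part = spinglass_modules(global_net, seed=seed, **sg_kw)
    global_net.set_modules(global_part.labels)

    if "network" in stages:
        netdir = outdir / "networks"
        netdir.mkdir(exist_ok=True)
        for net in [global_net, *group_nets, *local_nets]:
            gio.write_network(net, netdir / f"{net.name}.edges.tsv", "tsv")
            gio.write_network(net, netdir / f"{net.name}.graphml", "graphml")

    if "modules" in stages:
        frame = global_part.as_frame()
        frame["modularity"] = global_part.modularity
        _write_tsv(frame, outdir / "modules_global.tsv", seed)

    # --- local-network topology, hubs, cohesion ---------------------------
    panel_rows = []
    hubs_frames = []
    cohesion_frames = []
    keystone_frames = []
    filtered = filter_species(table, config.min_abundance_pct,
                              config.min_prevalence)
    for i, net in enumerate(local_nets):
        part = spinglass_modules(net, seed=seed + 1 + i, **sg_kw)
        net.set_modules(part.labels)
        profile = identify_hubs(centralities(net))
        hub_tab = profile.table.copy()
        hub_tab.insert(0, "network", net.name)
        hubs_frames.append(hub_tab)

        conn = connectedness(net)
        sub = filtered.loc[list(net.samples)]
        coh = cohesion(sub, conn)
        ps = coh.per_sample.copy()
        ps.insert(0, "network", net.name)
        cohesion_frames.append(ps)
        group, tp = net.name.rsplit("_", 1)
        panel_rows.append((net.name, group, tp, part.modularity,
                           coh.total_cohesion, coh.np_ratio))

        if "keystones" in stages and coh.total_cohesion > 0:
            ks = keystone_scan(sub, q_max=config.q_max,
                               rho_min=config.rho_min,
                               keystone_cut=config.keystone_cut)
            ks.insert(0, "network", net.name)
            keystone_frames.append(ks)

    panel = pd.DataFrame(
        panel_rows,
        columns=["network", "group", "timepoint", "modularity",
                 "total_cohesion", "np_ratio"]).set_index("network")

    if "hubs" in stages:
        _write_tsv(pd.concat(hubs_frames), outdir / "hubs_local.tsv", seed)
    if "cohesion" in stages:
        _write_tsv(pd.concat(cohesion_frames),
                   outdir / "cohesion_per_sample.tsv", seed)
        _write_tsv(panel, outdir / "network_params.tsv", seed)
    if "keystones" in stages and keystone_frames:
        _write_tsv(pd.concat(keystone_frames), outdir / "keystones.tsv", seed)

    # --- statistics -------------------------------------------------------
    if "stats" in stages:
        from .stats import network_param_tests, pathway_screen, shannon
        div = pd.DataFrame({
            "shannon": [shannon(table.loc[s]) for s in table.index]},
            index=table.index)
        div = div.join(metadata[["group", "timepoint"]])
        _write_tsv(div, outdir / "shannon.tsv", seed)

        tests = network_param_tests(
            panel[["group", "modularity", "total_cohesion", "np_ratio"]],
            config.alternatives, drop_nonfinite=True)
        _write_tsv(tests, outdir / "network_param_tests.tsv", seed,
                   index=False)

        if config.pathway_path is not None:
            pw = gio.read_pathway_table(config.pathway_path, normalize=True)
            screen = pathway_screen(pw.loc[table.index], metadata)
            _write_tsv(screen, outdir / "pathway_screen.tsv", seed)

    config_record = asdict(config)
    config_record.pop("outdir")  # path choice must not affect run identity
    manifest = {
        "package": "gutnet",
        "version": __version__,
        "seed": seed,
        "config": config_record,
        "stages": sorted(stages),
        "n_samples": len(table.index),
        "n_species": len(table.columns),
        "n_species_filtered": filtered.shape[1],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str) + "\n")
    return outdir
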