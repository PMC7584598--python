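"""End-to-end orchestration of study-style comparisons (WT / HT / FM systems).

``run_analysis`` executes, per group: SASA profile of residue 465, the
interface catalog with areas and residue occupancy, hydrogen-bond and
salt-bridge counts (full-atom inputs), G-BSE / BSE-stalk angle series and
G-G asymmetry, helix parameters and per-tetramer radius of gyration; then
group statistics on the per-monomer (per-tetramer, per-frame) summaries.
Everything is written as UTF-8 CSV with one header row plus a run log; a
stage failure is logged and the remaining stages still run.

Statistical units are window means per monomer/tetramer/pair, not raw
frames.  Groups holding both genotypes (the hetero helix) are split into
``<group>.WT`` and ``<group>.MUT`` for angle and SASA comparisons, the way
the study plots them.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DynhelixError
from .geometry import (
    angle_series,
    bse_stalk_definition,
    g_bse_definition,
    gg_asymmetry,
)
from .helix import fit_axis, helix_params_series, tetramer_rg_series
from .interfaces import (
    IF2,
    InterfaceConfig,
    catalog_interfaces,
    count_hbonds,
    count_salt_bridges,
    instances_to_frame,
    occupancy,
    residue465_bse_interaction,
)
from .io import read_structure
from .sasa import SasaConfig, sasa_profile
from .stats import ANOVA_TUKEY, KW_DUNN, compare_groups
from .structures import (
    COARSE_GRAINED,
    LAST_T_NS,
    R465W,
    DomainMap,
    Trajectory,
    WindowSpec,
    select_window,
)
from .topology import assign_topology

log = logging.getLogger(__name__)

DEFAULT_STATS_METHODS = {
    "g_bse_deg": KW_DUNN,
    "bse_stalk_deg": KW_DUNN,
    "tetramer_rg_A": KW_DUNN,
    "sasa465_normalized": ANOVA_TUKEY,
    "if2_area_A2": KW_DUNN,
    "helix_angle_deg": KW_DUNN,
    "n_hbonds": ANOVA_TUKEY,
    "n_salt_bridges": ANOVA_TUKEY,
}


@dataclass
class RunConfig:
    groups: dict  # group name -> Trajectory or structure-file path
    output_dir: str | Path = "dynhelix_out"
    domain_map: DomainMap = field(default_factory=DomainMap)
    window_helix: WindowSpec = field(default_factory=lambda: WindowSpec(LAST_T_NS, 500.0))
    window_dimer: WindowSpec = field(default_factory=lambda: WindowSpec(LAST_T_NS, 10.0))
    interface_config: InterfaceConfig = field(default_factory=InterfaceConfig)
    sasa_config: SasaConfig = field(default_factory=SasaConfig)
    stats_methods: dict = field(default_factory=lambda: dict(DEFAULT_STATS_METHODS))
    #: compute interface catalogs every k-th window frame (areas are costly)
    interface_stride: int = 5
    compute_areas: bool = True
    #: which stages to run (subset of: angles, sasa465, helix, rg, interfaces, bonds)
    stages: tuple = ("angles", "sasa465", "helix", "rg", "interfaces", "bonds")
    tetramer_size: int = 4
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise DynhelixError("run config needs at least one group")
        for metric, method in self.stats_methods.items():
            if method not in (ANOVA_TUKEY, KW_DUNN):
                raise DynhelixError(f"unsupported stats method {method!r} for {metric}")


@dataclass
class RunResult:
    output_dir: Path
    tables: dict  # name -> DataFrame
    comparisons: dict  # metric -> GroupComparison
    errors: list

    @property
    def ok(self) -> bool:
        return not self.errors


def _load(group, source) -> Trajectory:
    if isinstance(source, Trajectory):
        return source
    return read_structure(source)


def _split_by_genotype(means: pd.DataFrame, group: str, value_col: str) -> dict:
    """Group label per unit: plain group name, or group.WT / group.MUT if mixed."""
    out = {}
    genotypes = set(means.genotype)
    if len(genotypes) > 1:
        for geno, sub in means.groupby("genotype"):
            label = f"{group}.{'MUT' if geno == R465W else 'WT'}"
            out[label] = sub[value_col].to_list()
    else:
        out[group] = means[value_col].to_list()
    return out


def _windowed(traj: Trajectory, config: RunConfig) -> Trajectory:
    spec = config.window_helix if traj.resolution == COARSE_GRAINED else config.window_dimer
    try:
        return select_window(traj, spec)
    except DynhelixError as exc:
        log.warning("window %s not applicable (%s); using all frames", spec, exc)
        return traj


def run_analysis(config: RunConfig) -> RunResult:
    """Execute all stages for every group, then cross-group statistics."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dynhelix")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    errors: list[str] = []
    tables: dict[str, list[pd.DataFrame]] = {}
    metric_groups: dict[str, dict] = {}

    log.info("dynhelix %s run starting; groups: %s", __version__, list(config.groups))
    log.info("config: %s", {k: str(v) for k, v in vars(config).items() if k != "groups"})

    for group, source in config.groups.items():
        try:
            traj = _load(group, source)
        except DynhelixError as exc:
            errors.append(f"{group}: {exc}")
            log.error("group %s failed to load: %s", group, exc)
            continue
        win = _windowed(traj, config)
        log.info("group %s: %d monomers, %d frames in window, %s",
                 group, len(win.monomer_ids), len(win), win.resolution)
        _analyze_group(group, win, config, tables, metric_groups, errors)

    comparisons = {}
    rows = []
    for metric, groups in metric_groups.items():
        usable = {g: v for g, v in groups.items() if len(v) >= 3}
        if len(usable) < 2:
            log.info("metric %s: only %d usable group(s); summaries only", metric, len(usable))
            continue
        method = config.stats_methods.get(metric, KW_DUNN)
        cmp_ = compare_groups(usable, method=method, metric=metric)
        comparisons[metric] = cmp_
        for _, r in cmp_.pairwise.iterrows():
            rows.append((metric, method, cmp_.omnibus_p, r.group_a, r.group_b, r.p_adjusted))
    if rows:
        tables.setdefault("comparisons", []).append(
            pd.DataFrame(
                rows,
                columns=["metric", "method", "omnibus_p", "group_a", "group_b", "p_adjusted"],
            )
        )

    final_tables = {}
    for name, parts in tables.items():
        df = pd.concat(parts, ignore_index=True)
        df.to_csv(outdir / f"{name}.csv", index=False)
        final_tables[name] = df
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "groups": {g: str(s) for g, s in config.groups.items()},
                "seed": config.seed,
                "interface_stride": config.interface_stride,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    if errors:
        log.error("run finished with %d stage error(s)", len(errors))
    root.removeHandler(handler)
    handler.close()
    return RunResult(output_dir=outdir, tables=final_tables, comparisons=comparisons, errors=errors)


def _analyze_group(group, win, config, tables, metric_groups, errors):
    dmap = config.domain_map

    def stage(name, fn):
        try:
            fn()
        except DynhelixError as exc:
            errors.append(f"{group}/{name}: {exc}")
            log.error("group %s stage %s failed: %s", group, name, exc)

    def add_table(name, df):
        df = df.copy()
        df.insert(0, "group", group)
        tables.setdefault(name, []).append(df)

    def add_metric(metric, labelled_values):
        metric_groups.setdefault(metric, {}).update(labelled_values)

    topo = None
    if win.resolution == COARSE_GRAINED and len(win.monomer_ids) >= 8:
        def _topo():
            nonlocal topo
            _, axis = fit_axis(win.frames[0])
            topo = assign_topology(
                win.frames[0],
                axis,
                config.tetramer_size,
                contact_cutoff=config.interface_config.contact_cutoff,
                domain_map=dmap,
            )
        stage("topology", _topo)

    enabled = set(config.stages)

    # angles (anchor ranges may be absent from reduced full-atom systems)
    for definition in (g_bse_definition(dmap), bse_stalk_definition(dmap)) if "angles" in enabled else ():
        def _angles(definition=definition):
            series = angle_series(win, definition)
            add_table("angles", series.data)
            means = series.window_means()
            add_table("angle_window_means", means)
            add_metric(
                f"{definition.name}_deg", _split_by_genotype(means, group, "degrees")
            )
            if definition.name == "g_bse" and topo is not None and topo.gg_partners:
                records, summary = gg_asymmetry(series, topo)
                df = pd.DataFrame(
                    [(r.pair[0], r.pair[1], r.delta_deg) for r in records],
                    columns=["monomer_a", "monomer_b", "delta_deg"],
                )
                add_table("gg_asymmetry", df)
                log.info(
                    "group %s G-G asymmetry: %.2f +/- %.2f deg (n=%d)",
                    group, summary["mean_delta_deg"], summary["sem_delta_deg"],
                    summary["n_pairs"],
                )
        stage(f"angles_{definition.name}", _angles)

    # SASA of residue 465
    def _sasa465():
        prof = sasa_profile(win, ("all", dmap.mutation_site), config.sasa_config)
        add_table("sasa465", prof)
        means = prof[prof.frame_index == -1].copy()
        genotype_of = {m.monomer_id: m.genotype for m in win.frames[0].monomers}
        means["genotype"] = means.monomer_id.map(genotype_of)
        add_metric("sasa465_normalized", _split_by_genotype(means, group, "normalized"))
    if "sasa465" in enabled:
        stage("sasa465", _sasa465)

    if topo is not None:
        def _helix():
            hp = helix_params_series(win, topo)
            add_table("helix", hp)
            add_metric("helix_angle_deg", {group: hp.helix_angle_deg.to_list()})
        if "helix" in enabled:
            stage("helix_params", _helix)

        def _rg():
            rg = tetramer_rg_series(win, topo)
            add_table("tetramer_rg", rg)
            means = rg[rg.frame_index == -1]
            add_metric("tetramer_rg_A", {group: means.rg_A.to_list()})
        if "rg" in enabled:
            stage("tetramer_rg", _rg)

        def _interfaces():
            instances = []
            for frame in win.frames[:: config.interface_stride]:
                instances.extend(
                    catalog_interfaces(
                        frame, topo, dmap, config.interface_config,
                        config.sasa_config, compute_area=config.compute_areas,
                    )
                )
                instances.extend(
                    residue465_bse_interaction(
                        frame, topo, dmap, config.interface_config,
                        config.sasa_config, compute_area=config.compute_areas,
                    )
                )
            add_table("interfaces", instances_to_frame(instances))
            occ = occupancy([i for i in instances if i.residues_a])
            add_table("occupancy", occ.to_frame())
            if config.compute_areas:
                if2 = [i for i in instances if i.itype == IF2]
                add_metric("if2_area_A2", {group: [i.area_A2 for i in if2]})
        if "interfaces" in enabled:
            stage("interfaces", _interfaces)

    if win.resolution != COARSE_GRAINED and len(win.monomer_ids) == 2:
        def _bonds():
            pair = tuple(win.monomer_ids)
            rows = []
            for frame in win.frames:
                rows.append(
                    (
                        pair[0],
                        pair[1],
                        frame.frame_index,
                        count_hbonds(frame, pair),
                        count_salt_bridges(frame, pair),
                    )
                )
            df = pd.DataFrame(
                rows,
                columns=["monomer_a", "monomer_b", "frame_index", "n_hbonds", "n_salt_bridges"],
            )
            add_table("bonds", df)
            add_metric("n_hbonds", {group: df.n_hbonds.to_list()})
            add_metric("n_salt_bridges", {group: df.n_salt_bridges.to_list()})
        if "bonds" in enabled:
            stage("bonds", _bonds)


# ---------------------------------------------------------------------------
# figures (optional; never required by any downstream step)
# ---------------------------------------------------------------------------

def render_reports(result: RunResult, formats=("png",)) -> list[Path]:
    """Deterministic figure files from a run's tables (skips empty metrics)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = result.output_dir
    written = []

    means = result.tables.get("angle_window_means")
    if means is not None and not means.empty:
        for angle, sub in means.groupby("angle_name"):
            fig, ax = plt.subplots(figsize=(6, 4))
            labels, data = [], []
            for (grp, geno), gsub in sub.groupby(["group", "genotype"]):
                labels.append(f"{grp}\n{geno}")
                data.append(gsub.degrees.to_numpy())
            ax.violinplot(data, showmedians=True)
            ax.boxplot(data, widths=0.15)
            ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
            ax.set_ylabel(f"{angle} angle (deg)")
            fig.tight_layout()
            for fmt in formats:
                p = outdir / f"{angle}_violin.{fmt}"
                fig.savefig(p, dpi=120)
                written.append(p)
            plt.close(fig)

    occ = result.tables.get("occupancy")
    if occ is not None and not occ.empty:
        pivot = occ.pivot_table(
            index="residue_number", columns=["group", "itype"], values="fraction", fill_value=0.0
        )
        fig, ax = plt.subplots(figsize=(6, max(3, 0.12 * len(pivot))))
        im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_yticks(range(len(pivot)), pivot.index, fontsize=6)
        ax.set_xticks(range(pivot.shape[1]),
                      ["/".join(map(str, c)) for c in pivot.columns], rotation=90, fontsize=6)
        fig.colorbar(im, ax=ax, label="occupancy")
        fig.tight_layout()
        for fmt in formats:
            p = outdir / f"occupancy_heatmap.{fmt}"
            fig.savefig(p, dpi=120)
            written.append(p)
        plt.close(fig)

    hel = result.tables.get("helix")
    if hel is not None and not hel.empty:
        fig, axes = plt.subplots(3, 1, figsize=(6, 7), sharex=True)
        for grp, sub in hel.groupby("group"):
            axes[0].plot(sub.frame_index, sub.diameter_A, label=grp)
            axes[1].plot(sub.frame_index, sub.pitch_A, label=grp)
            axes[2].plot(sub.frame_index, sub.helix_angle_deg, label=grp)
        for ax, lab in zip(axes, ("diameter (A)", "pitch (A)", "helix angle (deg)")):
            ax.set_ylabel(lab)
        axes[0].legend(fontsize=8)
        axes[2].set_xlabel("frame")
        fig.tight_layout()
        for fmt in formats:
            p = outdir / f"helix_params.{fmt}"
            fig.savefig(p, dpi=120)
            written.append(p)
        plt.close(fig)
    return written
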