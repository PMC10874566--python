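"""End-to-end orchestration: generate -> detect -> coloc -> zones -> profiles -> stats.

One YAML config drives every stage; all intermediate artifacts are written
into the run directory together with the effective config and a provenance
log, and a rerun with the same config is bit-identical for tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import DEFAULT_MATCH_RADIUS_UM, cfos_activation, coloc_table
from .detect import CellSet, DetectionConfig, count_summary, detect_cells
from .profiles import AxisSpec, profile_axis, realign_and_average, zscore
from .stack_io import max_project, read_stack
from .stats import anova_bonferroni, significance_stars, unpaired_t
from .synthgen import ClaustrumGeometry, GeneratorConfig, generate_cohort
from .zones import ZoneConfig, delineate_devoid_zone, delineate_enriched_zone, overlay_cohort

log = logging.getLogger("claumap")

__all__ = ["RunConfig", "run", "report"]


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    zone: ZoneConfig = field(default_factory=ZoneConfig)
    axis_strip_width_um: float = 100.0
    axis_bin_um: float = 20.0
    axis_extent_um: float = 400.0
    channel_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("retro", "nurr1"), ("retro", "nr2f2"), ("retro", "tle4")]
    )
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM
    reference_channel: str = "retro"
    devoid_channel: str = "tle4"
    profile_channels: list[str] = field(default_factory=lambda: ["retro", "nurr1", "tle4"])
    conditions: dict = field(
        default_factory=lambda: {"naive": {"n_mice": 2, "coloc_overrides": {}}}
    )
    slices_per_subdivision: int = 2
    output_dir: str = "claumap_run"
    master_seed: int = 1

    def __post_init__(self) -> None:
        self.channel_pairs = [tuple(p) for p in self.channel_pairs]
        chans = set(self.generator.channels)
        for a, b in self.channel_pairs:
            if a not in chans or b not in chans:
                raise ValueError(f"channel pair ({a}, {b}) not in generator channels {sorted(chans)}")
        for ch in [self.reference_channel, self.devoid_channel, *self.profile_channels]:
            if ch not in chans:
                raise ValueError(f"channel {ch!r} not in generator channels {sorted(chans)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "generator" in kw:
            g = dict(kw["generator"])
            if "zone_geometry" in g:
                g["zone_geometry"] = ClaustrumGeometry(
                    **{k: tuple(v) if isinstance(v, list) else v for k, v in g["zone_geometry"].items()}
                )
            if "coloc_fractions" in g:
                g["coloc_fractions"] = {
                    tuple(k.split("|")): v for k, v in g["coloc_fractions"].items()
                }
            kw["generator"] = GeneratorConfig(**g)
        if "detection" in kw:
            kw["detection"] = DetectionConfig(**kw["detection"])
        if "zone" in kw:
            kw["zone"] = ZoneConfig(**kw["zone"])
        return cls(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["coloc_fractions"] = {
            f"{a}|{b}": v for (a, b), v in self.generator.coloc_fractions.items()
        }
        return d


def _condition_config(base: GeneratorConfig, overrides: dict) -> GeneratorConfig:
    fr = dict(base.coloc_fractions)
    for k, v in (overrides or {}).items():
        key = tuple(k.split("|")) if isinstance(k, str) else tuple(k)
        fr[key] = float(v)
    return dataclasses.replace(base, coloc_fractions=fr)


def run(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    artifacts: dict = {"conditions": {}, "package_version": __version__}
    stage = "generate"
    try:
        slice_manifests = []
        for cond, spec in config.conditions.items():
            gcfg = _condition_config(config.generator, spec.get("coloc_overrides", {}))
            cohort_dir = out / f"cohort_{cond}"
            log.info("generate: condition=%s n_mice=%d", cond, spec.get("n_mice", 1))
            manifest = generate_cohort(
                gcfg,
                n_mice=int(spec.get("n_mice", 1)),
                slices_per_subdivision=config.slices_per_subdivision,
                out_dir=cohort_dir,
                condition=cond,
                master_seed=config.master_seed,
            )
            manifest["cohort_dir"] = str(cohort_dir)
            slice_manifests.append(manifest)
            artifacts["conditions"][cond] = {"cohort_dir": str(cohort_dir)}
        manifest = pd.concat(slice_manifests, ignore_index=True)

        stage = "detect"
        det_dir = out / "cellsets"
        det_dir.mkdir(exist_ok=True)
        slice_sets: list[dict[str, CellSet]] = []
        cellsets_flat: list[CellSet] = []
        for _, row in manifest.iterrows():
            vol = read_stack(Path(row["cohort_dir"]) / row["stack_path"])
            sets = {}
            for ch in config.generator.channels:
                cs = detect_cells(max_project(vol, ch), config.detection)
                cs.to_csv(det_dir / f"{row['slice_id']}_{ch}.csv")
                sets[ch] = cs
                cellsets_flat.append(cs)
            slice_sets.append(sets)
        counts = count_summary(cellsets_flat)
        counts.to_csv(out / "cell_counts.csv", index=False)
        artifacts["cell_counts"] = "cell_counts.csv"

        stage = "coloc"
        pairs = list(config.channel_pairs)
        cfos_pairs = []
        if len(config.conditions) > 1 and "cfos" in config.generator.channels:
            for marker in ("nurr1", "tle4"):
                if marker in config.generator.channels:
                    cfos_pairs.append((marker, "cfos"))
        slice_tab, summary_tab = coloc_table(
            slice_sets, pairs + cfos_pairs, config.match_radius_um
        )
        slice_tab.to_csv(out / "coloc_slices.csv", index=False)
        summary_tab.to_csv(out / "coloc_summary.csv", index=False)
        artifacts["coloc_slices"] = "coloc_slices.csv"
        artifacts["coloc_summary"] = "coloc_summary.csv"

        stage = "zones"
        zone_dir = out / "zones"
        zone_dir.mkdir(exist_ok=True)
        zone_records = []
        per_mouse_first: dict[tuple[str, str], tuple] = {}
        for (_, row), sets in zip(manifest.iterrows(), slice_sets):
            sid = row["slice_id"]
            try:
                ref_poly = delineate_enriched_zone(sets[config.reference_channel], config.zone)
            except ValueError as e:
                log.warning("zones: skip %s (%s)", sid, e)
                continue
            ref_poly.to_geojson(zone_dir / f"{sid}_{config.reference_channel}_enriched.geojson")
            partner_polys = {}
            for ch in ("nr2f2", "nurr1"):
                if ch in sets and len(sets[ch]) >= 10:
                    try:
                        p = delineate_enriched_zone(sets[ch], config.zone)
                    except ValueError as e:
                        log.warning("zones: no %s enriched zone for %s (%s)", ch, sid, e)
                        continue
                    p.to_geojson(zone_dir / f"{sid}_{ch}_enriched.geojson")
                    partner_polys[ch] = p
            try:
                dev = delineate_devoid_zone(
                    sets[config.devoid_channel], tuple(ref_poly.centroid), config.zone
                )
                dev.to_geojson(zone_dir / f"{sid}_{config.devoid_channel}_devoid.geojson")
                partner_polys[config.devoid_channel] = dev
            except ValueError as e:
                log.warning("zones: no devoid zone for %s (%s)", sid, e)
            zone_records.append(
                {"slice_id": sid, "centroid_x_um": ref_poly.centroid[0],
                 "centroid_y_um": ref_poly.centroid[1],
                 "contained_fraction": ref_poly.contained_fraction}
            )
            key = (row["mouse_id"], row["subdivision"])
            if key not in per_mouse_first:  # one slice per mouse per subdivision
                per_mouse_first[key] = (ref_poly, partner_polys)
        pd.DataFrame(zone_records).to_csv(out / "zones_summary.csv", index=False)
        artifacts["zones_summary"] = "zones_summary.csv"
        overlays = {}
        for partner_ch in ("nr2f2", config.devoid_channel):
            for subdivision in ("anterior", "middle", "posterior"):
                sel = [
                    (ref, partners[partner_ch])
                    for (m, s), (ref, partners) in per_mouse_first.items()
                    if s == subdivision and partner_ch in partners
                ]
                if not sel:
                    continue
                ov = overlay_cohort(sel, subdivision, grid_um=config.zone.grid_um)
                np.savetxt(
                    zone_dir / f"overlay_{partner_ch}_{subdivision}.csv",
                    ov.occupancy_partner,
                    fmt="%d",
                    delimiter=",",
                )
                overlays[f"{partner_ch}:{subdivision}"] = str(
                    zone_dir / f"overlay_{partner_ch}_{subdivision}.csv"
                )
        artifacts["overlays"] = overlays

        stage = "profiles"
        prof_rows = []
        slice_profiles = []
        for (_, row), sets in zip(manifest.iterrows(), slice_sets):
            sid = row["slice_id"]
            try:
                anchor_poly = delineate_enriched_zone(sets[config.reference_channel], config.zone)
            except ValueError:
                continue
            origin = tuple(anchor_poly.centroid)
            vol = read_stack(Path(row["cohort_dir"]) / row["stack_path"])
            ax1 = AxisSpec(
                origin_um=origin,
                direction_deg=float(row["orientation_deg"]),
                strip_width_um=config.axis_strip_width_um,
                bin_um=config.axis_bin_um,
                extent_um=config.axis_extent_um,
            )
            for ax_name, ax in (("parallel", ax1), ("perpendicular", ax1.perpendicular())):
                by_ch = {}
                for ch in config.profile_channels:
                    p = zscore(profile_axis(max_project(vol, ch), ax))
                    by_ch[ch] = p
                    for pos, v in zip(p.positions_mm, p.values):
                        prof_rows.append(
                            {"slice_id": sid, "axis": ax_name, "channel": ch,
                             "position_mm": pos, "zscore": v}
                        )
                if ax_name == "perpendicular":
                    slice_profiles.append(by_ch)
        pd.DataFrame(prof_rows).to_csv(out / "profiles_slices.csv", index=False)
        artifacts["profiles_slices"] = "profiles_slices.csv"
        if slice_profiles:
            env = realign_and_average(slice_profiles, config.reference_channel)
            env.to_csv(out / "profiles_envelope.csv", index=False)
            artifacts["profiles_envelope"] = "profiles_envelope.csv"

        stage = "stats"
        stats_rows = []
        if not slice_tab.empty:
            pooled = slice_tab.assign(subdivision="all")
            per_mouse = (
                pd.concat([slice_tab, pooled], ignore_index=True)
                .groupby(["pair", "subdivision", "mouse_id"], as_index=False)
                .agg(frac=("frac_ab_of_a", "mean"))
            )
            for pair, sub in per_mouse[per_mouse["subdivision"] != "all"].groupby("pair"):
                groups = [
                    g["frac"].dropna().to_numpy()
                    for _, g in sub.groupby("subdivision")
                ]
                if len(groups) >= 3 and all(len(g) >= 2 for g in groups):
                    try:
                        res = anova_bonferroni(groups)
                    except ValueError:
                        continue
                    stats_rows.append(
                        {"comparison": f"{pair} across subdivisions", "test": "anova",
                         "stat": res.F, "df1": res.df_between, "df2": res.df_within,
                         "p": res.p, "stars": significance_stars(res.p)}
                    )
        if len(config.conditions) > 1 and cfos_pairs:
            act = cfos_activation(slice_tab)
            act.to_csv(out / "cfos_activation.csv", index=False)
            artifacts["cfos_activation"] = "cfos_activation.csv"
            for _, r in act.iterrows():
                if np.isfinite(r["p"]):
                    stats_rows.append(
                        {"comparison": f"cfos in {r['marker']}+: naive vs of", "test": "t",
                         "stat": r["t"], "df1": r["df"], "df2": np.nan, "p": r["p"],
                         "stars": significance_stars(r["p"])}
                    )
            for marker in ("nurr1", "tle4"):
                cnt = counts[(counts["channel"] == marker) & (counts["subdivision"] == "all")]
                cnt = cnt.merge(
                    manifest[["mouse_id", "condition"]].drop_duplicates(), on="mouse_id"
                )
                g = {
                    c: cnt.loc[cnt["condition"] == c, "mean_cells"].to_numpy()
                    for c in config.conditions
                }
                vals = list(g.values())
                if len(vals) == 2 and all(len(v) >= 2 for v in vals):
                    res = unpaired_t(vals[0], vals[1])
                    stats_rows.append(
                        {"comparison": f"{marker}+ cell count between conditions", "test": "t",
                         "stat": res.t, "df1": res.df, "df2": np.nan, "p": res.p,
                         "stars": significance_stars(res.p)}
                    )
        pd.DataFrame(stats_rows).to_csv(out / "stats.csv", index=False)
        artifacts["stats"] = "stats.csv"
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    artifacts["config_digest"] = config.generator.digest()
    artifacts["master_seed"] = config.master_seed
    artifacts["elapsed_s"] = round(time.time() - t0, 2)
    (out / "run_manifest.json").write_text(json.dumps(artifacts, indent=2, sort_keys=True))
    log.info("run complete in %.1fs", artifacts["elapsed_s"])
    return artifacts


def report(run_dir: str | Path, figures: bool = True) -> Path:
    """Render a summary document (markdown + PNG figures) from a finished run."""
    run_dir = Path(run_dir)
    man_path = run_dir / "run_manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"{run_dir} has no run_manifest.json (incomplete run?)")
    manifest = json.loads(man_path.read_text())
    lines = ["# claumap run report", ""]
    lines.append(f"Package version {manifest.get('package_version')}, "
                 f"config digest {manifest.get('config_digest')}, "
                 f"master seed {manifest.get('master_seed')}.")
    summary_path = run_dir / "coloc_summary.csv"
    if summary_path.exists():
        df = pd.read_csv(summary_path)
        lines += ["", "## Colocalization (Venn) summary, mean ± SD across mice", ""]
        if not df.empty:
            lines.append("| pair | subdivision | n_A | n_B | n_A∩B | frac(A∩B of A) |")
            lines.append("|---|---|---|---|---|---|")
            for _, r in df.iterrows():
                lines.append(
                    f"| {r['pair']} | {r['subdivision']} | "
                    f"{r['mean_n_a']:.1f} ± {r['sd_n_a']:.1f} | "
                    f"{r['mean_n_b']:.1f} ± {r['sd_n_b']:.1f} | "
                    f"{r['mean_n_ab']:.1f} ± {r['sd_n_ab']:.1f} | "
                    f"{r['mean_frac']:.3f} ± {r['sd_frac']:.3f} |"
                )
    act_path = run_dir / "cfos_activation.csv"
    if act_path.exists():
        df = pd.read_csv(act_path)
        lines += ["", "## c-Fos activation (open field vs naive)", ""]
        for _, r in df.iterrows():
            lines.append(
                f"- {r['marker']}: {r['naive_pct']:.1f}% → {r['of_pct']:.1f}% c-Fos+ "
                f"({r['upregulation_points']:+.1f} points; t({r['df']:.0f}) = {r['t']:.2f}, "
                f"p = {r['p']:.2g} {significance_stars(min(max(r['p'], 0), 1))})"
            )
    stats_path = run_dir / "stats.csv"
    if stats_path.exists():
        df = pd.read_csv(stats_path)
        if not df.empty:
            lines += ["", "## Group statistics", ""]
            for _, r in df.iterrows():
                lines.append(
                    f"- {r['comparison']}: {r['test']} stat = {r['stat']:.3f}, "
                    f"p = {r['p']:.3g} {r['stars']}"
                )
    if figures:
        _report_figures(run_dir, lines)
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out


def _report_figures(run_dir: Path, lines: list[str]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    env_path = run_dir / "profiles_envelope.csv"
    if env_path.exists():
        env = pd.read_csv(env_path)
        if not env.empty:
            fig, ax = plt.subplots(figsize=(6, 4))
            for ch, sub in env.groupby("channel"):
                sub = sub.sort_values("position_mm")
                ax.plot(sub["position_mm"], sub["mean"], label=ch)
                ax.fill_between(
                    sub["position_mm"], sub["mean"] - sub["sd"], sub["mean"] + sub["sd"], alpha=0.2
                )
            ax.axvline(0.0, color="k", lw=0.5)
            ax.set_xlabel("position along axis (mm, 0 = retro peak)")
            ax.set_ylabel("fluorescence (z-score)")
            ax.legend()
            fig.tight_layout()
            fig.savefig(run_dir / "profiles_envelope.png", dpi=120)
            plt.close(fig)
            lines += ["", "![profile envelopes](profiles_envelope.png)"]
    for f in sorted((run_dir / "zones").glob("overlay_*.csv")) if (run_dir / "zones").exists() else []:
        occ = np.loadtxt(f, delimiter=",")
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(occ, origin="upper", cmap="viridis")
        fig.colorbar(im, ax=ax, label="mice covering point")
        ax.set_title(f.stem)
        fig.tight_layout()
        fig.savefig(f.with_suffix(".png"), dpi=120)
        plt.close(fig)
        lines += ["", f"![{f.stem}](zones/{f.stem}.png)"]
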