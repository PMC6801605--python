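"""End-to-end orchestration: simulate a two-arm section/cohort study, analyze it.

``cmd_simulate`` emulates the study's sampling design — 2 groups × 3 tumors ×
10 sections (30 profile units per group) plus a two-arm growth/survival
cohort — writing TIFF sections with JSON sidecars and cohort CSVs.

``cmd_analyze`` runs segmentation → edge/vessel profiling → AUC →
accumulation → growth/KM/log-rank → group comparisons over such a bundle and
writes result CSVs, plots and a JSON summary.  Every output embeds the seed
and a hash of the configuration (CSV ``#`` comment header / JSON field), and
identical config + seed reproduce identical result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import efficacy as eff
from . import io as mio
from . import microdistribution as md
from . import segmentation as seg
from . import synthetic as syn
from .exceptions import ConfigError, EmptyVesselMaskWarning

log = logging.getLogger("mabpen")

GROUPS = ("SD", "FD")


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    groups: tuple[str, ...] = GROUPS
    n_tumors: int = 3
    n_sections_per_tumor: int = 10
    section: syn.SyntheticSectionParams = field(default_factory=syn.SyntheticSectionParams)
    group_section_overrides: dict = field(default_factory=dict)  # group -> {param: value}
    cohort: syn.SyntheticCohortParams = field(default_factory=syn.SyntheticCohortParams)
    segmentation: seg.SegmentationParams = field(default_factory=seg.SegmentationParams)
    profile: md.ProfileParams = field(default_factory=md.ProfileParams)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.n_tumors < 1 or self.n_sections_per_tumor < 1:
            raise ConfigError("n_tumors and n_sections_per_tumor must be >= 1")
        if len(self.groups) < 1:
            raise ConfigError("at least one group required")
        for g in self.group_section_overrides:
            if g not in self.groups:
                raise ConfigError(f"override for unknown group {g!r}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def metadata_comment(self) -> str:
        return f"mabpen config_hash={self.config_hash()} seed={self.seed}"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs: dict = {}
        for key in ("outdir", "seed", "n_tumors", "n_sections_per_tumor", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "groups" in raw:
            kwargs["groups"] = tuple(raw["groups"])
        if "group_section_overrides" in raw:
            kwargs["group_section_overrides"] = dict(raw["group_section_overrides"])
        for key, klass in (("section", syn.SyntheticSectionParams),
                           ("cohort", syn.SyntheticCohortParams),
                           ("segmentation", seg.SegmentationParams),
                           ("profile", md.ProfileParams)):
            if key in raw:
                sub = dict(raw[key])
                if "image_shape" in sub:
                    sub["image_shape"] = tuple(sub["image_shape"])
                kwargs[key] = klass(**sub)
        return cls(**kwargs)


def _setup_logging(config: RunConfig, outdir: Path) -> None:
    log.setLevel(config.log_level.upper())
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(sh)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def _section_seed(base: int, group_i: int, tumor: int, section: int) -> int:
    h = hashlib.sha256(f"{base}:{group_i}:{tumor}:{section}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


def cmd_simulate(config: RunConfig) -> dict:
    """Generate the synthetic study bundle.  Returns a manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    secdir = outdir / "sections"
    secdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config, outdir)
    log.info("simulate: %d groups x %d tumors x %d sections",
             len(config.groups), config.n_tumors, config.n_sections_per_tumor)

    section_files: list[str] = []
    for gi, group in enumerate(config.groups):
        params = config.section.replace(**config.group_section_overrides.get(group, {}))
        for t in range(1, config.n_tumors + 1):
            for s in range(1, config.n_sections_per_tumor + 1):
                p = params.replace(seed=_section_seed(config.seed, gi, t, s))
                sid = f"{group}_t{t:02d}_s{s:02d}"
                section, truth = syn.generate_section(
                    p, section_id=sid, tumor_id=f"{group}_t{t:02d}", group=group)
                path = secdir / f"{sid}.tif"
                mio.write_section(section, path, metadata={
                    "seed": p.seed, "config_hash": config.config_hash(),
                    "params": dataclasses.asdict(p)})
                mio.write_mask(mio.Mask(truth.tumor_mask, "tumor"),
                               secdir / f"{sid}_tumor_mask.tif")
                mio.write_mask(mio.Mask(truth.vessel_mask, "vessel"),
                               secdir / f"{sid}_vessel_mask.tif")
                section_files.append(str(path))

    cohort = config.cohort.replace(
        seed=_section_seed(config.seed, 99, 0, 0),
        growth_rate={g: config.cohort.growth_rate.get(g, next(iter(config.cohort.growth_rate.values())))
                     for g in config.groups})
    growth, survival = syn.generate_cohort(cohort)
    comment = config.metadata_comment()
    mio.write_results(eff.growth_to_frame(growth).to_dict("records"),
                      outdir / "growth.csv", metadata_comment=comment)
    mio.write_results(eff.survival_to_frame(survival).to_dict("records"),
                      outdir / "survival.csv", metadata_comment=comment)

    manifest = {"sections": section_files, "growth": str(outdir / "growth.csv"),
                "survival": str(outdir / "survival.csv"),
                "config_hash": config.config_hash(), "seed": config.seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("simulate: wrote %d sections to %s", len(section_files), secdir)
    return manifest


def analyze_section(section: mio.SectionImage, config: RunConfig) -> dict:
    """Segment one section and compute its profiles, AUCs and accumulation."""
    tumor, contour = seg.segment_tumor(section, config.segmentation)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", EmptyVesselMaskWarning)
        vessels = seg.segment_vessels(section, tumor, config.segmentation)
    edge = md.edge_profiles(section, tumor, contour, config.profile)
    vessel = (md.vessel_profiles(section, tumor, vessels, config.profile)
              if vessels.pixels.any() else [])
    acc = md.total_accumulation(section, tumor)
    out = {"section": section, "tumor": tumor, "contour": contour,
           "vessels": vessels, "edge_profiles": edge, "vessel_profiles": vessel,
           "accumulation": acc}
    for source, profs in (("edge", edge), ("vessel", vessel)):
        if profs:
            mp = md.aggregate_profiles(profs, config.profile, group=section.group)
            out[f"{source}_mean_profile"] = mp
            out[f"{source}_auc"] = md.profile_auc(mp, config.profile)
    return out


def cmd_analyze(config: RunConfig, make_plots: bool = True) -> dict:
    """Analyze a simulated (or imported) bundle under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    _setup_logging(config, outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"no manifest.json under {outdir}; run simulate first")
    manifest = json.loads(manifest_path.read_text())
    comment = config.metadata_comment()

    log.info("analyze: segmentation + profiling over %d sections", len(manifest["sections"]))
    per_section: list[dict] = []
    profile_rows: list[dict] = []
    auc_rows: list[dict] = []
    acc_rows: list[dict] = []
    group_profiles: dict[tuple[str, str], list[md.LineProfile]] = {}
    for path in manifest["sections"]:
        section = mio.read_section(path)
        res = analyze_section(section, config)
        per_section.append(res)
        for source in ("edge", "vessel"):
            for p in res[f"{source}_profiles"]:
                for d, v in zip(p.distances, p.intensities):
                    profile_rows.append({"section_id": p.section_id, "group": section.group,
                                         "source": source, "anchor_row": p.anchor[0],
                                         "anchor_col": p.anchor[1], "region": p.region,
                                         "distance_um": d, "intensity": v})
                group_profiles.setdefault((section.group, source), []).append(p)
            auc = res.get(f"{source}_auc")
            if auc is not None:
                auc_rows.append({"level": "section", "section_id": section.section_id,
                                 "group": section.group, "source": source,
                                 "auc_raw": auc.auc_raw, "auc_norm": auc.auc,
                                 "n_profiles": len(res[f"{source}_profiles"])})
        a = res["accumulation"]
        acc_rows.append({"section_id": a.section_id, "group": a.group,
                         "total_intensity": a.total_intensity,
                         "tumor_area_um2": a.tumor_area, "accumulation": a.accumulation})

    # pooled-group AUC (all profiles together) alongside the per-section mean
    mean_rows: list[dict] = []
    for (group, source), profs in sorted(group_profiles.items()):
        mp = md.aggregate_profiles(profs, config.profile, group=group)
        auc = md.profile_auc(mp, config.profile)
        auc_rows.append({"level": "group_pooled", "section_id": "", "group": group,
                         "source": source, "auc_raw": auc.auc_raw, "auc_norm": auc.auc,
                         "n_profiles": len(profs)})
        for c, m, s, n in zip(mp.bin_centers, mp.mean, mp.sd, mp.n):
            mean_rows.append({"group": group, "source": source, "distance_um": c,
                              "mean_intensity": m, "sd": s, "n": int(n)})

    auc_frame = pd.DataFrame(auc_rows)
    acc_frame = pd.DataFrame(acc_rows)

    log.info("analyze: efficacy stage")
    growth = mio.read_results(manifest["growth"])
    survival = mio.read_results(manifest["survival"])
    gsum = eff.growth_summary(growth, groups=config.groups)
    km_rows: list[dict] = []
    for g in config.groups:
        times, surv = eff.km_estimate(survival, g)
        for t, sv in zip(times, surv):
            km_rows.append({"group": g, "time_days": t, "survival": sv})

    comparisons: list[eff.ComparisonResult] = []
    ga, gb = config.groups[0], config.groups[1] if len(config.groups) > 1 else config.groups[0]
    if len(config.groups) > 1:
        sec_auc = auc_frame[auc_frame["level"] == "section"]
        for source in ("edge", "vessel"):
            va = sec_auc[(sec_auc.group == ga) & (sec_auc.source == source)]["auc_raw"]
            vb = sec_auc[(sec_auc.group == gb) & (sec_auc.source == source)]["auc_raw"]
            if len(va) >= 2 and len(vb) >= 2:
                comparisons.append(eff.compare_groups(va, vb, kind=f"auc_{source}",
                                                      group_a=ga, group_b=gb))
        acc_a = acc_frame[acc_frame.group == ga]["accumulation"]
        acc_b = acc_frame[acc_frame.group == gb]["accumulation"]
        if len(acc_a) >= 2 and len(acc_b) >= 2:
            comparisons.append(eff.compare_groups(acc_a, acc_b, kind="accumulation",
                                                  group_a=ga, group_b=gb))
        final_day = int(growth["day"].max())
        last = growth[growth["day"] == final_day]
        va = last[last.group == ga]["volume_mm3"]
        vb = last[last.group == gb]["volume_mm3"]
        if len(va) >= 2 and len(vb) >= 2:
            comparisons.append(eff.compare_groups(va, vb, kind=f"volume_day{final_day}",
                                                  group_a=ga, group_b=gb))
        if survival["event"].sum() > 0:
            comparisons.append(eff.logrank_test(survival, ga, gb))

    mio.write_results(profile_rows, outdir / "profiles.csv", metadata_comment=comment)
    mio.write_results(mean_rows, outdir / "mean_profiles.csv", metadata_comment=comment)
    mio.write_results(auc_rows, outdir / "auc.csv", metadata_comment=comment)
    mio.write_results(acc_rows, outdir / "accumulation.csv", metadata_comment=comment)
    mio.write_results(gsum.to_dict("records"), outdir / "growth_summary.csv",
                      metadata_comment=comment)
    mio.write_results(km_rows, outdir / "km_curves.csv", metadata_comment=comment)
    if comparisons:
        mio.write_results(comparisons, outdir / "comparisons.csv", metadata_comment=comment)

    summary = {
        "seed": config.seed, "config_hash": config.config_hash(),
        "n_sections": len(manifest["sections"]),
        "group_auc": {f"{g}/{s}": round(float(
            auc_frame[(auc_frame.level == "section") & (auc_frame.group == g)
                      & (auc_frame.source == s)]["auc_raw"].mean()), 6)
            for g in config.groups for s in ("edge", "vessel")},
        "group_accumulation": {g: round(float(
            acc_frame[acc_frame.group == g]["accumulation"].mean()), 6)
            for g in config.groups},
        "comparisons": {c.name: {"statistic": c.statistic, "p_value": c.p_value}
                        for c in comparisons},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    if make_plots:
        _write_plots(outdir, pd.DataFrame(mean_rows), gsum, pd.DataFrame(km_rows))
    log.info("analyze: done (%d comparisons)", len(comparisons))
    return {"summary": summary, "auc": auc_frame, "accumulation": acc_frame,
            "comparisons": comparisons, "per_section": per_section,
            "growth_summary": gsum, "km": pd.DataFrame(km_rows)}


def _write_plots(outdir: Path, mean_profiles: pd.DataFrame,
                 growth: pd.DataFrame, km: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not mean_profiles.empty:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
        for ax, source in zip(axes, ("edge", "vessel")):
            sub = mean_profiles[mean_profiles.source == source]
            for g, gsub in sub.groupby("group"):
                ax.errorbar(gsub.distance_um, gsub.mean_intensity, yerr=gsub.sd,
                            label=g, capsize=2, lw=1)
            ax.set_xlabel("distance (µm)")
            ax.set_title(f"from {source}")
        axes[0].set_ylabel("intensity (a.u.)")
        axes[0].legend()
        fig.tight_layout()
        fig.savefig(outdir / "mean_profiles.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for g, gsub in growth.groupby("group"):
        ax.errorbar(gsub.day, gsub.mean_volume_mm3, yerr=gsub.sd_volume_mm3,
                    label=g, capsize=2, marker="o", ms=3, lw=1)
    ax.set_xlabel("day")
    ax.set_ylabel("tumor volume (mm³)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "growth.png", dpi=120)
    plt.close(fig)

    if not km.empty:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for g, gsub in km.groupby("group"):
            ax.step(gsub.time_days, gsub.survival, where="post", label=g)
        ax.set_xlabel("day")
        ax.set_ylabel("survival fraction")
        ax.set_ylim(0, 1.05)
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "km.png", dpi=120)
        plt.close(fig)


def cmd_report(config: RunConfig) -> str:
    """Render a short plain-text report from an analyzed bundle."""
    outdir = Path(config.outdir)
    summary_path = outdir / "summary.json"
    if not summary_path.exists():
        raise ConfigError(f"no summary.json under {outdir}; run analyze first")
    s = json.loads(summary_path.read_text())
    lines = [f"mabpen run {s['config_hash']} (seed {s['seed']}): "
             f"{s['n_sections']} sections"]
    lines.append("mean per-section AUC_raw (a.u.·µm):")
    for key, val in s["group_auc"].items():
        lines.append(f"  {key}: {val:.2f}")
    lines.append("mean accumulation (a.u./µm²):")
    for key, val in s["group_accumulation"].items():
        lines.append(f"  {key}: {val:.4f}")
    lines.append("two-group comparisons:")
    for name, c in s["comparisons"].items():
        verdict = "significant" if c["p_value"] < 0.05 else "not significant"
        lines.append(f"  {name}: stat={c['statistic']:.3f} p={c['p_value']:.3f} ({verdict})")
    return "\n".join(lines)
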