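"""End-to-end orchestration: simulate a cohort, run first-level GLMs, group
statistics, variance decomposition, map/region concordance, pseudo-rest dual
regression and tSNR/CNR metrics, writing one artifact tree.

Stages are idempotent: a stage whose marker file exists is skipped unless
forced.  Every stochastic stage derives its seeds from the single global
seed by fixed arithmetic, so any run is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import firstlevel as fl
from . import grouplevel as gl
from . import metrics as mx
from . import pseudorest as pr
from . import sequences as sq
from . import simulate as sim
from . import varcomp as vc
from .core import StatMap, VolumeSeries, load_series, save_map

log = logging.getLogger("mbfmri")

STAGES = ["simulate", "firstlevel", "group", "varcomp", "concordance",
          "pseudorest", "metrics", "report"]


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    out_dir: str = "mbfmri_out"
    sequence_table: str | None = None       # None -> bundled five schemes
    n_subjects: int = 23
    grid_shape: tuple[int, int, int] = (32, 38, 32)
    voxel_size: float = 3.0
    n_activation_blobs: int = 5
    mean_effect: float = 1.0
    noise: dict = dataclasses.field(default_factory=dict)
    hrf_variant: str = "canonical"
    whitening: str = "exp-basis"
    highpass_cutoff: float = 128.0
    smooth_fwhm: float = 6.0
    q: float = 0.05
    cluster_k: int = 50
    connectivity: int = 18
    reference_sequence: str = "MB1S22.7iso2.45"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.q < 1):
            raise ValueError("q must be in (0, 1)")
        if self.cluster_k < 0:
            raise ValueError("cluster_k must be >= 0")
        if self.sequence_table is not None and not Path(self.sequence_table).exists():
            raise FileNotFoundError(self.sequence_table)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def specs(self) -> list[sq.SequenceSpec]:
        if self.sequence_table is None:
            return sq.default_sequence_table()
        return sq.load_sequence_table(self.sequence_table)


def _marker(out: Path, stage: str) -> Path:
    return out / stage / ".complete"


def _done(out: Path, stage: str) -> bool:
    return _marker(out, stage).exists()


def _finish(out: Path, stage: str, info: dict) -> None:
    d = out / stage
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "summary.json", "w") as fh:
        json.dump(info, fh, indent=2, default=str)
    _marker(out, stage).touch()


def _load_phantom(out: Path) -> sim.Phantom:
    z = np.load(out / "simulate" / "phantom.npz")
    return sim.Phantom(
        grid_shape=tuple(int(v) for v in z["grid_shape"]),
        voxel_size=float(z["voxel_size"]), affine=z["affine"],
        brain_mask=z["brain_mask"].astype(bool),
        gm_mask=z["gm_mask"].astype(bool), wm_mask=z["wm_mask"].astype(bool),
        csf_mask=z["csf_mask"].astype(bool), atlas_labels=z["atlas_labels"],
        activation_truth=z["activation_truth"], rsn_templates=z["rsn_templates"],
        artefactual_networks=tuple(int(v) for v in z["artefactual"]),
        seed=int(z["seed"]))


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    phantom = sim.generate_phantom(
        grid_shape=cfg.grid_shape, voxel_size=cfg.voxel_size,
        n_activation_blobs=cfg.n_activation_blobs,
        seed=sim.expand_seed(cfg.seed, 0))
    noise = sim.NoiseModel(**cfg.noise) if cfg.noise else sim.NoiseModel()
    sim_dir = out / "simulate"
    sim_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        sim_dir / "phantom.npz", grid_shape=phantom.grid_shape,
        voxel_size=phantom.voxel_size, affine=phantom.affine,
        brain_mask=phantom.brain_mask, gm_mask=phantom.gm_mask,
        wm_mask=phantom.wm_mask, csf_mask=phantom.csf_mask,
        atlas_labels=phantom.atlas_labels,
        activation_truth=phantom.activation_truth,
        rsn_templates=phantom.rsn_templates,
        artefactual=np.asarray(phantom.artefactual_networks), seed=phantom.seed)
    manifest = sim.simulate_cohort(
        phantom, cfg.specs(), n_subjects=cfg.n_subjects, noise=noise,
        out_dir=sim_dir, mean_effect=cfg.mean_effect, seed=cfg.seed)
    log.info("simulate: %d runs, seed %d", len(manifest), cfg.seed)
    _finish(out, "simulate", {"n_runs": len(manifest), "seed": cfg.seed})


def _first_level_one(row, phantom: sim.Phantom, cfg: PipelineConfig):
    """First-level analysis of one run: returns (con, tmap, fit, residuals)."""
    series = load_series(row.bold_path, mask=phantom.brain_mask)
    events = pd.read_csv(row.events_path, sep="\t")
    design_t = sim.TaskDesign.from_events_frame(
        events, session_duration=row.session_duration)
    motion = np.loadtxt(row.motion_path)
    spec = next(s for s in cfg.specs() if s.name == row.sequence)
    cc_wm = fl.compcor_regressors(series, phantom.wm_mask, k=5)
    cc_csf = fl.compcor_regressors(series, phantom.csf_mask, k=5)
    X = fl.build_design(design_t, spec, motion=motion,
                        compcor=np.column_stack([cc_csf, cc_wm]),
                        hrf_variant=cfg.hrf_variant,
                        highpass_cutoff=cfg.highpass_cutoff)
    smoothed = fl.gaussian_smooth(series, cfg.smooth_fwhm)
    fit = fl.fit_glm(smoothed, X, whitening=cfg.whitening,
                     pool_mask=phantom.gm_mask)
    con_c = fl.Contrast.from_names(X, "task_CA", "task_CC", name="CA-CC")
    tmap, con = fl.contrast_tmap(fit, con_c)
    resid = fl.residualize_for_rest(series, X)   # unsmoothed input
    return con, tmap, fit, resid


def stage_firstlevel(cfg: PipelineConfig, out: Path) -> None:
    phantom = _load_phantom(out)
    manifest = pd.read_csv(out / "simulate" / "manifest.csv")
    fl_dir = out / "firstlevel"
    fl_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in manifest.itertuples(index=False):
        con, tmap, fit, resid = _first_level_one(row, phantom, cfg)
        stem = f"sub-{row.subject:02d}_seq-{row.sequence}"
        np.save(fl_dir / f"{stem}_con.npy", con.astype(np.float32))
        np.save(fl_dir / f"{stem}_t.npy", tmap.values.astype(np.float32))
        np.save(fl_dir / f"{stem}_resms.npy", fit.resms.astype(np.float32))
        np.save(fl_dir / f"{stem}_pseudorest.npy",
                resid.data.astype(np.float32))
        fit.design.to_frame().to_csv(fl_dir / f"{stem}_design.tsv",
                                     sep="\t", index=False)
        raw = load_series(row.bold_path, mask=phantom.brain_mask)
        ts = mx.tsnr_maps(raw, fit=fit, mask=phantom.brain_mask)
        rows.append(dict(subject=row.subject, sequence=row.sequence,
                         dof=fit.dof,
                         tsnr_raw=float(ts.raw[ts.mask].mean()),
                         tsnr_eff=float(ts.effective[ts.mask].mean()),
                         tsnr_put=float(ts.per_unit_time[ts.mask].mean()),
                         cnr=mx.gm_wm_cnr(raw, phantom.gm_mask, phantom.wm_mask)))
    pd.DataFrame(rows).to_csv(fl_dir / "runs.tsv", sep="\t", index=False)
    _finish(out, "firstlevel", {"n_runs": len(rows)})


def _group_for_sequence(out: Path, seq: str, phantom: sim.Phantom,
                        cfg: PipelineConfig) -> gl.GroupResult:
    fl_dir = out / "firstlevel"
    cons = np.stack([np.load(p) for p in sorted(fl_dir.glob(f"*_seq-{seq}_con.npy"))])
    g = gl.rfx_ttest(cons, phantom.brain_mask)
    return gl.threshold_group(g, q=cfg.q, k=cfg.cluster_k,
                              connectivity=cfg.connectivity)


def stage_group(cfg: PipelineConfig, out: Path) -> None:
    phantom = _load_phantom(out)
    gdir = out / "group"
    gdir.mkdir(parents=True, exist_ok=True)
    names = [s.name for s in cfg.specs()]
    info = {}
    for seq in names:
        g = _group_for_sequence(out, seq, phantom, cfg)
        save_map(StatMap(values=g.tmap.values, kind="t", affine=phantom.affine),
                 gdir / f"seq-{seq}_group_t.nii.gz")
        save_map(StatMap(values=g.sig_mask.astype(float), kind="mask",
                         affine=phantom.affine),
                 gdir / f"seq-{seq}_sig_mask.nii.gz")
        np.save(gdir / f"seq-{seq}_resms_rfx.npy", g.resms_rfx)
        counts, edges = gl.t_histogram(g, bins=np.linspace(0, 15, 31))
        pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                      "count": counts}).to_csv(
            gdir / f"seq-{seq}_t_hist.tsv", sep="\t", index=False)
        info[seq] = dict(n_sig=int(g.sig_mask.sum()), t_at_q=g.t_at_q)
    _finish(out, "group", info)


def stage_varcomp(cfg: PipelineConfig, out: Path) -> None:
    phantom = _load_phantom(out)
    manifest = pd.read_csv(out / "simulate" / "manifest.csv")
    vdir = out / "varcomp"
    vdir.mkdir(parents=True, exist_ok=True)
    info = {}
    for seq in manifest["sequence"].unique():
        sub = manifest[manifest["sequence"] == seq]
        series_list, design_list, con_list = [], [], []
        for row in sub.itertuples(index=False):
            series = load_series(row.bold_path, mask=phantom.brain_mask)
            events = pd.read_csv(row.events_path, sep="\t")
            design_t = sim.TaskDesign.from_events_frame(
                events, session_duration=row.session_duration)
            motion = np.loadtxt(row.motion_path)
            spec = next(s for s in cfg.specs() if s.name == seq)
            cc = np.column_stack([
                fl.compcor_regressors(series, phantom.csf_mask, k=5),
                fl.compcor_regressors(series, phantom.wm_mask, k=5)])
            X = fl.build_design(design_t, spec, motion=motion, compcor=cc,
                                hrf_variant=cfg.hrf_variant,
                                highpass_cutoff=cfg.highpass_cutoff)
            series_list.append(fl.gaussian_smooth(series, cfg.smooth_fwhm))
            design_list.append(X)
            con_list.append(fl.Contrast.from_names(X, "task_CA", "task_CC"))
        ffx = vc.fit_fixed_effects(series_list, design_list, con_list,
                                   phantom.brain_mask, whitening=cfg.whitening,
                                   pool_mask=phantom.gm_mask)
        sigma2 = vc.intra_subject_variance(ffx)
        resms_rfx = np.load(out / "group" / f"seq-{seq}_resms_rfx.npy")
        vm = vc.inter_subject_variance(resms_rfx, sigma2, phantom.brain_mask)
        save_map(StatMap(values=vm.intra, kind="var", affine=phantom.affine),
                 vdir / f"seq-{seq}_sigma2.nii.gz")
        save_map(StatMap(values=vm.inter, kind="var", affine=phantom.affine),
                 vdir / f"seq-{seq}_Sigma2.nii.gz")
        centers = vc.phantom_roi_centers(phantom.activation_truth,
                                         phantom.affine)
        roi = vc.roi_sphere_summary(vm.inter, phantom.affine,
                                    phantom.brain_mask, centers_mm=centers)
        roi["measure"] = "inter"
        roi2 = vc.roi_sphere_summary(vm.intra, phantom.affine,
                                     phantom.brain_mask, centers_mm=centers)
        roi2["measure"] = "intra"
        pd.concat([roi, roi2]).to_csv(vdir / f"seq-{seq}_roi.tsv",
                                      sep="\t", index=False)
        info[seq] = dict(negative_fraction=vm.negative_fraction)
    _finish(out, "varcomp", info)


def stage_concordance(cfg: PipelineConfig, out: Path) -> None:
    phantom = _load_phantom(out)
    cdir = out / "concordance"
    cdir.mkdir(parents=True, exist_ok=True)
    names = [s.name for s in cfg.specs()]
    groups = {seq: _group_for_sequence(out, seq, phantom, cfg) for seq in names}
    auc = pd.DataFrame(index=names, columns=names, dtype=float)
    hit = pd.DataFrame(index=names, columns=names, dtype=float)
    fa = pd.DataFrame(index=names, columns=names, dtype=float)
    for ref_name in names:
        for test_name in names:
            if ref_name == test_name:
                continue
            try:
                r = conc.roc_between_maps(
                    groups[test_name].tmap, groups[ref_name],
                    phantom.brain_mask,
                    test_sig_mask=groups[test_name].sig_mask,
                    test_name=test_name, reference_name=ref_name)
            except ValueError:      # reference found nothing significant
                log.warning("concordance %s vs %s: empty reference mask",
                            test_name, ref_name)
                continue
            auc.loc[test_name, ref_name] = r.auc
            hit.loc[test_name, ref_name] = r.hit_rate
            fa.loc[test_name, ref_name] = r.fa_rate
    auc.to_csv(cdir / "auc_matrix.tsv", sep="\t")
    hit.to_csv(cdir / "hit_matrix.tsv", sep="\t")
    fa.to_csv(cdir / "fa_matrix.tsv", sep="\t")
    tables = {}
    for seq in names:
        rt = conc.region_activation_table(groups[seq].sig_mask,
                                          phantom.atlas_labels,
                                          phantom.brain_mask)
        rt.table.to_csv(cdir / f"seq-{seq}_regions.tsv", sep="\t", index=False)
        tables[seq] = rt
    rows = []
    for a_name in names:
        for b_name in names:
            if a_name >= b_name:
                continue
            try:
                d = conc.table_concordance(tables[a_name], tables[b_name])
            except ValueError:
                continue
            rows.append(dict(a=a_name, b=b_name, **d))
    pd.DataFrame(rows).to_csv(cdir / "table_concordance.tsv", sep="\t",
                              index=False)
    _finish(out, "concordance", {"n_pairs": len(rows)})


def stage_pseudorest(cfg: PipelineConfig, out: Path) -> None:
    phantom = _load_phantom(out)
    manifest = pd.read_csv(out / "simulate" / "manifest.csv")
    pdir = out / "pseudorest"
    pdir.mkdir(parents=True, exist_ok=True)
    fl_dir = out / "firstlevel"
    subject_maps: dict[str, np.ndarray] = {}
    for seq in manifest["sequence"].unique():
        sub = manifest[manifest["sequence"] == seq]
        per_subj = []
        for row in sub.itertuples(index=False):
            stem = f"sub-{row.subject:02d}_seq-{row.sequence}"
            spec = next(s for s in cfg.specs() if s.name == seq)
            resid = VolumeSeries(
                data=np.load(fl_dir / f"{stem}_pseudorest.npy"),
                affine=phantom.affine, tr=spec.tr, mask=phantom.brain_mask)
            sm = fl.gaussian_smooth(resid, cfg.smooth_fwhm)
            tc = pr.spatial_glm_timecourses(sm, phantom.rsn_templates,
                                            phantom.brain_mask,
                                            subject=str(row.subject),
                                            sequence=seq)
            motion = np.loadtxt(row.motion_path)
            full = load_series(row.bold_path, mask=phantom.brain_mask)
            full_sm = fl.gaussian_smooth(full, cfg.smooth_fwhm)
            betas, _ = pr.network_subject_maps(
                full_sm, tc, nuisance=motion, whitening=cfg.whitening,
                pool_mask=phantom.gm_mask,
                highpass_cutoff=cfg.highpass_cutoff)
            per_subj.append(betas)
        subject_maps[seq] = np.stack(per_subj)
    table, results = pr.network_group_counts(
        subject_maps, phantom.brain_mask, q=cfg.q, k=cfg.cluster_k,
        connectivity=cfg.connectivity, reference=cfg.reference_sequence)
    table.to_csv(pdir / "network_counts.tsv", sep="\t", index=False)
    curves = pr.cumulative_curves(results, cfg.reference_sequence,
                                  phantom.brain_mask)
    rows = [dict(network=c.network_id, sequence=c.sequence, x=x, y=y)
            for c in curves for x, y in zip(c.x, c.y)]
    pd.DataFrame(rows).to_csv(pdir / "cumulative_curves.tsv", sep="\t",
                              index=False)
    _finish(out, "pseudorest", {
        "mean_counts": table.groupby("sequence")["n_significant"]
        .mean().to_dict()})


def stage_metrics(cfg: PipelineConfig, out: Path) -> None:
    mdir = out / "metrics"
    mdir.mkdir(parents=True, exist_ok=True)
    runs = pd.read_csv(out / "firstlevel" / "runs.tsv", sep="\t")
    summary = runs.groupby("sequence")[
        ["tsnr_raw", "tsnr_eff", "tsnr_put", "cnr"]].mean()
    summary.to_csv(mdir / "tsnr_cnr_summary.tsv", sep="\t")
    power_rows = [dict(n=n, detectable_d=mx.detectable_effect_size(n))
                  for n in (3, 14, 23)]
    pd.DataFrame(power_rows).to_csv(mdir / "power_table.tsv", sep="\t",
                                    index=False)
    _finish(out, "metrics", {"sequences": summary.index.tolist()})


def make_report(out: Path) -> Path:
    """Assemble a markdown report from the artifact tree."""
    required = {
        "group": out / "group" / "summary.json",
        "concordance": out / "concordance" / "auc_matrix.tsv",
        "metrics": out / "metrics" / "tsnr_cnr_summary.tsv",
    }
    missing = [k for k, p in required.items() if not p.exists()]
    lines = ["# Sequence-comparison report", ""]
    if missing == list(required):
        raise FileNotFoundError(
            f"no artifacts to report on; missing: {missing}")
    if missing:
        lines += [f"**Missing stages:** {', '.join(missing)}", ""]
    if required["group"].exists():
        info = json.loads(required["group"].read_text())
        lines += ["## Group activation (CA-CC)", "",
                  "| sequence | significant voxels | t at q |",
                  "|---|---|---|"]
        for seq, d in info.items():
            t_at_q = d["t_at_q"]
            t_str = f"{t_at_q:.2f}" if t_at_q is not None else "-"
            lines.append(f"| {seq} | {d['n_sig']} | {t_str} |")
        lines.append("")
        for p in sorted((out / "group").glob("*_t_hist.tsv")):
            hist = pd.read_csv(p, sep="\t")
            lines += [f"### t histogram: {p.stem}", "",
                      hist.to_markdown(index=False), ""]
    if required["concordance"].exists():
        auc = pd.read_csv(required["concordance"], sep="\t", index_col=0)
        lines += ["## Concordance (AUC matrix)", "", auc.to_markdown(), ""]
    if required["metrics"].exists():
        s = pd.read_csv(required["metrics"], sep="\t", index_col=0)
        lines += ["## tSNR / CNR", "", s.to_markdown(), ""]
    curves_p = out / "pseudorest" / "network_counts.tsv"
    if curves_p.exists():
        t = pd.read_csv(curves_p, sep="\t")
        means = t.groupby("sequence")[["n_significant", "pct_change_vs_ref"]].mean()
        lines += ["## Pseudo-rest network counts", "", means.to_markdown(), ""]
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report


_STAGE_FN = {
    "simulate": stage_simulate,
    "firstlevel": stage_firstlevel,
    "group": stage_group,
    "varcomp": stage_varcomp,
    "concordance": stage_concordance,
    "pseudorest": stage_pseudorest,
    "metrics": stage_metrics,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None,
                 force: bool = False) -> Path:
    """Execute the requested stages in dependency order."""
    cfg.validate()
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh)
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "report":
            make_report(out)
            continue
        if _done(out, stage) and not force:
            log.info("stage %s: complete, skipping", stage)
            continue
        t0 = time.time()
        _STAGE_FN[stage](cfg, out)
        log.info("stage %s: %.1f s", stage, time.time() - t0)
    return out
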