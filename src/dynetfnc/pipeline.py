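"""Pipeline orchestration: simulate -> gica -> tdfnc -> iva -> sdfnc -> stats.

Each stage reads its inputs from the output directory (or from configured
paths), persists every intermediate it produces, and can therefore run as a
standalone subcommand; running the stages separately is byte-identical to
running them in one go.  A manifest records config, seed, and version.  All
stage randomness derives from one global seed fanned out to per-stage
substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imageio import BoldSeries, load_masked_series
from . import gica as _gica
from . import iva as _iva
from . import sdfnc as _sdfnc
from . import stats as _stats
from . import synthdata as _synth
from . import tdfnc as _tdfnc

log = logging.getLogger("dynetfnc")

STAGES = ["simulate", "gica", "tdfnc", "iva", "sdfnc", "stats"]


@dataclass
class SimulateParams:
    n_subjects: int = 24
    T: int = 192
    grid_shape: tuple = (12, 12, 12)
    n_sources: int = 4
    k_states: int = 3
    snr: float = 5.0
    spatial_jitter: float = 0.15
    tr_seconds: float = 2.0
    group_state: int | None = 2
    group_edge: tuple | None = (0, 1)
    group_delta_r: float = 0.5
    clinical_state: int | None = 1
    clinical_edge: tuple | None = (0, 2)
    clinical_r: float = 0.7


@dataclass
class GicaParams:
    n_components: int = 100
    n_subject_pcs: int = 120
    n_group_pcs: int = 100
    icasso_runs: int = 100
    min_cluster: int = 80
    artifact_r: float = 0.2


@dataclass
class TdfncParams:
    width_trs: int = 18
    step_trs: int = 1
    k: object = "auto"
    min_windows: int = 10


@dataclass
class IvaParams:
    window_trs: int = 48
    overlap: float = 0.5
    n_components: int = 20
    keep_sdcs: int = 9


@dataclass
class StatsParams:
    alpha: float = 0.05
    fdr_family: str = "state"


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults are the study's stated settings."""

    out_dir: str = "dynetfnc_out"
    volumes: list = field(default_factory=list)  # per-subject 4-D NIfTI paths
    mask: str | None = None
    clinical_csv: str | None = None
    templates: str | None = None  # NIfTI of template maps (4th axis = template)
    seed: int = 0
    simulate: SimulateParams = field(default_factory=SimulateParams)
    gica: GicaParams = field(default_factory=GicaParams)
    tdfnc: TdfncParams = field(default_factory=TdfncParams)
    iva: IvaParams = field(default_factory=IvaParams)
    stats: StatsParams = field(default_factory=StatsParams)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        for name, sub in [
            ("simulate", SimulateParams), ("gica", GicaParams),
            ("tdfnc", TdfncParams), ("iva", IvaParams), ("stats", StatsParams),
        ]:
            if name in kw and isinstance(kw[name], dict):
                kw[name] = sub(**kw[name])
        cfg = cls(**kw)
        for attr in ("grid_shape", "group_edge", "clinical_edge"):
            v = getattr(cfg.simulate, attr)
            if isinstance(v, list):
                setattr(cfg.simulate, attr, tuple(v))
        return cfg

    def validate(self) -> None:
        if not self.volumes and self.simulate is None:
            raise ValueError("no input volumes and no simulation configured")
        for p in self.volumes:
            if not Path(p).exists():
                raise FileNotFoundError(f"volume not found: {p}")
        if self.volumes and (self.mask is None or not Path(self.mask).exists()):
            raise FileNotFoundError(f"mask not found: {self.mask}")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream of the global seed."""
    return int(np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def _sim_dir(out: Path) -> Path:
    return out / "simulate"


def _load_series(cfg: PipelineConfig, out: Path):
    if cfg.volumes:
        vols, mask = cfg.volumes, cfg.mask
    else:
        sim = _sim_dir(out)
        vols = sorted(sim.glob("sub-*_bold.nii.gz"))
        mask = sim / "mask.nii.gz"
        if not vols:
            raise FileNotFoundError(f"no volumes configured and none in {sim}")
    return [
        load_masked_series(v, mask, subject_id=Path(v).name.split("_")[0])
        for v in vols
    ]


def _load_clinical(cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    path = cfg.clinical_csv or _sim_dir(out) / "clinical.csv"
    return pd.read_csv(path)


def _load_templates(cfg: PipelineConfig, out: Path):
    """Template maps as {name: (V,) array}; synthetic runs fall back to the
    ground-truth source maps."""
    if cfg.templates:
        import nibabel as nib

        from .imageio import load_component_maps, mask_to_indices

        mask = np.asanyarray(nib.load(str(cfg.mask)).dataobj)
        maps = load_component_maps(cfg.templates, mask_to_indices(mask))
        return {f"template_{i:02d}": maps[i] for i in range(maps.shape[0])}
    gt_path = _sim_dir(out) / "ground_truth.npz"
    if gt_path.exists():
        src = np.load(gt_path)["spatial_sources"]
        return {f"source_{i:02d}": src[i] for i in range(src.shape[0])}
    return None


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    p = cfg.simulate
    effects = _synth.PlantedEffects(
        group_state=p.group_state, group_edge=p.group_edge, group_delta_r=p.group_delta_r,
        clinical_state=p.clinical_state, clinical_edge=p.clinical_edge,
        clinical_r=p.clinical_r,
    )
    series, truth = _synth.generate_dataset(
        n_subjects=p.n_subjects, T=p.T, grid_shape=p.grid_shape,
        n_sources=p.n_sources, k_states=p.k_states, snr=p.snr,
        spatial_jitter=p.spatial_jitter, planted_effects=effects,
        seed=stage_seed(cfg.seed, "simulate"), tr_seconds=p.tr_seconds,
        iva_window_trs=cfg.iva.window_trs,
    )
    _synth.write_dataset(series, truth, _sim_dir(out))


def stage_gica(cfg: PipelineConfig, out: Path) -> None:
    series = _load_series(cfg, out)
    g = cfg.gica
    n_sub_pcs = min(g.n_subject_pcs, min(s.n_timepoints for s in series),
                    min(s.n_voxels for s in series))
    n_grp_pcs = min(g.n_group_pcs, n_sub_pcs * len(series))
    Y, ops = _gica.reduce_and_concat(series, n_sub_pcs, n_grp_pcs)
    comps = _gica.icasso_select(
        Y, g.n_components, n_runs=g.icasso_runs, min_cluster_size=g.min_cluster,
        seed=stage_seed(cfg.seed, "gica"),
    )
    templates = _load_templates(cfg, out)
    if templates:
        comps = _gica.label_components(comps, templates, artifact_r_threshold=g.artifact_r)
    subject_sets = _gica.back_reconstruct(comps, ops, series)

    d = out / "gica"
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        d / "group_components.npz",
        spatial_maps=comps.spatial_maps, stability_iq=comps.stability_iq,
        unstable=comps.unstable,
        time_courses=np.stack([cs.time_courses for cs in subject_sets]),
        subject_maps=np.stack([cs.spatial_maps for cs in subject_sets]),
        subject_ids=np.array([s.subject_id for s in series]),
    )
    rows = []
    for i in range(comps.n_components):
        lab = comps.labels[i] if comps.labels else ""
        tr = comps.template_correlations[i][0] if comps.template_correlations else np.nan
        rows.append((i, lab, tr, comps.stability_iq[i]))
    pd.DataFrame(rows, columns=["component", "label", "template_r", "iq"]).to_csv(
        d / "components.csv", index=False
    )


def _non_artifact_indices(out: Path):
    df = pd.read_csv(out / "gica" / "components.csv")
    keep = df.index[(df["label"].fillna("") != "artifact")].to_numpy()
    return keep if keep.size else df.index.to_numpy()


def stage_tdfnc(cfg: PipelineConfig, out: Path) -> None:
    z = np.load(out / "gica" / "group_components.npz")
    tcs = z["time_courses"]  # (M, T, N)
    sids = [str(s) for s in z["subject_ids"]]
    keep = _non_artifact_indices(out)
    t = cfg.tdfnc
    wfnc = {
        sid: _tdfnc.sliding_window_fnc(tcs[m][:, keep], t.width_trs, t.step_trs)
        for m, sid in enumerate(sids)
    }
    model = _tdfnc.cluster_states(wfnc, k=t.k, seed=stage_seed(cfg.seed, "tdfnc"))
    d = out / "tdfnc"
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        d / "state_model.npz",
        centroids=model.centroids, k=model.k, kept_components=keep,
        **{f"assign_{sid}": a for sid, a in model.assignments.items()},
    )
    arows = [
        (sid, w, int(s))
        for sid in sids
        for w, s in enumerate(model.assignments[sid])
    ]
    pd.DataFrame(arows, columns=["subject_id", "window_index", "state"]).to_csv(
        d / "assignments.csv", index=False
    )
    mrows = []
    for sid in sids:
        metrics = _tdfnc.state_metrics(
            model.assignments[sid], min_windows=t.min_windows, states=range(model.k)
        )
        for s, (n, member, dwell) in metrics.items():
            mrows.append((sid, s, n, member, dwell))
    pd.DataFrame(
        mrows, columns=["subject_id", "state", "n_windows", "member", "mean_dwell"]
    ).to_csv(d / "state_metrics.csv", index=False)
    # static FNC per subject on the same kept components
    static = np.stack([_tdfnc.static_fnc(tcs[m][:, keep]) for m in range(len(sids))])
    np.savez_compressed(d / "static_fnc.npz", matrices=static, subject_ids=np.array(sids))


def stage_iva(cfg: PipelineConfig, out: Path) -> None:
    series = _load_series(cfg, out)
    p = cfg.iva
    segs = [_iva.segment_windows(s, p.window_trs, p.overlap) for s in series]
    n_comp = min(p.n_components, p.window_trs, min(s.n_voxels for s in series))
    scv = _iva.iva_gl(segs, n_components=n_comp, seed=stage_seed(cfg.seed, "iva"))
    templates = _load_templates(cfg, out)
    if templates and p.keep_sdcs < scv.n_components:
        scv = _iva.screen_sdcs(scv, templates, keep=p.keep_sdcs)
    d = out / "iva"
    d.mkdir(parents=True, exist_ok=True)
    M, L = scv.n_subjects, scv.n_windows
    np.savez_compressed(
        d / "scvset.npz",
        sources=np.stack([scv.sources[k] for k in scv.dataset_keys]).reshape(
            M, L, scv.n_components, -1
        ),
        n_components=scv.n_components, n_subjects=M, n_windows=L,
        subject_ids=np.array([s.subject_id for s in series]),
    )


def stage_sdfnc(cfg: PipelineConfig, out: Path) -> None:
    z = np.load(out / "iva" / "scvset.npz")
    src = z["sources"]  # (M, L, P, V)
    M, L, P, V = src.shape
    sources = {(m, l): src[m, l] for m in range(M) for l in range(L)}
    scv = _iva.SCVSet(demixing={}, sources=sources, n_components=P,
                      n_subjects=M, n_windows=L)
    stack = _sdfnc.mi_connectivity(scv)
    clin = _load_clinical(cfg, out)
    sids = [str(s) for s in z["subject_ids"]]
    groups = dict(zip(clin["subject_id"], clin["group"]))
    var = _sdfnc.edge_variability(stack, groups={m: groups[sids[m]] for m in range(M)})
    d = out / "sdfnc"
    d.mkdir(parents=True, exist_ok=True)
    stack.to_frame(subject_ids=sids).to_csv(d / "mi_connectivity.csv", index=False)
    np.savez_compressed(
        d / "edge_variability.npz", std_per_edge=var.std_per_edge,
        **{f"group_{g}": v for g, v in var.group_mean_std.items()},
    )
    rows = []
    for m, sid in enumerate(sids):
        for i in range(P):
            for j in range(i + 1, P):
                rows.append((sid, i, j, var.std_per_edge[m, i, j]))
    pd.DataFrame(rows, columns=["subject_id", "component_i", "component_j", "std"]).to_csv(
        d / "mi_std.csv", index=False
    )


def stage_stats(cfg: PipelineConfig, out: Path) -> None:
    alpha = cfg.stats.alpha
    clin = _load_clinical(cfg, out)
    groups = dict(zip(clin["subject_id"], clin["group"]))
    glabels = list(dict.fromkeys(clin["group"]))
    d = out / "stats"
    d.mkdir(parents=True, exist_ok=True)

    # --- temporal: per-state dynamic FNC ---
    z = np.load(out / "gica" / "group_components.npz")
    tcs = z["time_courses"]
    sids = [str(s) for s in z["subject_ids"]]
    sz = np.load(out / "tdfnc" / "state_model.npz")
    keep = sz["kept_components"]
    t = cfg.tdfnc
    wfnc = {
        sid: _tdfnc.sliding_window_fnc(tcs[m][:, keep], t.width_trs, t.step_trs)
        for m, sid in enumerate(sids)
    }
    model = _tdfnc.StateModel(
        k=int(sz["k"]), centroids=sz["centroids"],
        assignments={sid: sz[f"assign_{sid}"] for sid in sids},
    )
    results, skipped = _stats.compare_state_fnc(
        model, wfnc, groups, min_windows=t.min_windows, alpha=alpha,
        fdr_family=cfg.stats.fdr_family,
    )
    for s, reason in skipped.items():
        log.info("stats: %s", reason)
    frames = [res.to_frame(state=s) for s, res in sorted(results.items())]
    dyn = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["state", "component_i", "component_j", "statistic", "p", "q", "significant"]
    )
    dyn.to_csv(d / "dynamic_fnc_tests.csv", index=False)

    # --- temporal: static FNC ---
    st = np.load(out / "tdfnc" / "static_fnc.npz")
    svecs = _tdfnc.fisher_z(_tdfnc.vectorize_fnc(st["matrices"]))
    N = st["matrices"].shape[1]
    iu = np.triu_indices(N, 1)
    edges = list(zip(iu[0].tolist(), iu[1].tolist()))
    ga = [m for m, sid in enumerate(sids) if groups[sid] == glabels[0]]
    gb = [m for m, sid in enumerate(sids) if groups[sid] == glabels[1]]
    res_static = _stats.compare_edge_matrix(svecs[ga], svecs[gb], alpha=alpha, edges=edges)
    res_static.to_frame(state=-1).to_csv(d / "static_fnc_tests.csv", index=False)

    # --- spatial: Mann-Whitney on MI STD ---
    ev = np.load(out / "sdfnc" / "edge_variability.npz")
    std = ev["std_per_edge"]  # (M, P, P)
    P = std.shape[1]
    iuP = np.triu_indices(P, 1)
    stdv = std[:, iuP[0], iuP[1]]
    edgesP = list(zip(iuP[0].tolist(), iuP[1].tolist()))
    res_mi = _stats.compare_edge_matrix(
        stdv[ga], stdv[gb], alpha=alpha, test="mannwhitney", edges=edgesP
    )
    res_mi.to_frame(state=-1).to_csv(d / "mi_std_tests.csv", index=False)

    # --- clinical correlation on significant features ---
    crows = []
    score = clin.set_index("subject_id")
    for _, row in dyn[dyn["significant"]].iterrows():
        s, i, j = int(row["state"]), int(row["component_i"]), int(row["component_j"])
        feats, ys, yd = [], [], []
        for sid in sids:
            sv = _stats.subject_state_fnc(wfnc[sid], model.assignments[sid], t.min_windows)
            if s in sv:
                e = edges.index((i, j))
                feats.append(sv[s][e])
                ys.append(score.loc[sid, "score"])
                yd.append(score.loc[sid, "duration_months"])
        if len(feats) >= 3:
            for sname, yv in [("score", ys), ("duration_months", yd)]:
                try:
                    c = _stats.correlate_clinical(
                        feats, yv, feature_name=f"state{s}_edge{i}-{j}", score_name=sname
                    )
                    crows.append((c.feature, c.score, c.r, c.p, c.n))
                except ValueError:
                    pass
    mi_df = res_mi.to_frame(state=-1)
    mean_mi = None
    for _, row in mi_df[mi_df["significant"]].iterrows():
        i, j = int(row["component_i"]), int(row["component_j"])
        if mean_mi is None:
            mi_stack = pd.read_csv(out / "sdfnc" / "mi_connectivity.csv")
            mean_mi = mi_stack.groupby(["subject_id", "component_i", "component_j"])[
                "value"
            ].mean()
        feats = [mean_mi.loc[(sid, i, j)] for sid in sids]
        for sname in ("score", "duration_months"):
            try:
                c = _stats.correlate_clinical(
                    feats, [score.loc[sid, sname] for sid in sids],
                    feature_name=f"mi_edge{i}-{j}", score_name=sname,
                )
                crows.append((c.feature, c.score, c.r, c.p, c.n))
            except ValueError:
                pass
    pd.DataFrame(crows, columns=["feature", "score", "r", "p", "n"]).to_csv(
        d / "clinical_correlations.csv", index=False
    )


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "gica": stage_gica,
    "tdfnc": stage_tdfnc,
    "iva": stage_iva,
    "sdfnc": stage_sdfnc,
    "stats": stage_stats,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> Path:
    """Run the requested stages (default: all) and write a manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    if cfg.volumes and "simulate" in stages:
        stages = [s for s in stages if s != "simulate"]
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "stages": {},
    }
    for name in stages:
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            STAGE_FUNCS[name](cfg, out)
        except Exception:
            log.error("stage %s: FAILED", name)
            manifest["stages"][name] = "failed"
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise
        dt = time.perf_counter() - t0
        manifest["stages"][name] = f"ok ({dt:.1f}s)"
        log.info("stage %s: done in %.1fs", name, dt)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    return d
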