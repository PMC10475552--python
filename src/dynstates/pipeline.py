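"""End-to-end orchestration: QC -> group ICA -> component selection ->
static FC -> dynamic FC states -> temporal metrics -> clinical correlations.

Each stage communicates through files (TSV tables, NIfTI volumes, JSON
manifests) so the per-stage CLI subcommands and the full pipeline share one
implementation.  All randomness flows from named seeds in the run
configuration; a run manifest records the resolved configuration, per-stage
outputs, hashes, warnings and timings.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .dynamic_fc import (WindowSpec, cluster_states, group_centroids,
                         make_windows, select_k, state_edge_ttest, top_edges,
                         windowed_fc)
from .ica import back_reconstruct, stability_aggregate, two_stage_pca
from .metrics import compare_metrics, duration_correlation, metrics_table
from .motion import apply_exclusion, compare_group_fd, discard_initial, \
    load_motion_trace
from .selection import clean_timecourse, friston24_regressors, \
    spectral_artifact_flag, template_match
from .static_fc import edge_glm, edge_pairs, network_pair_summary, \
    static_matrix, vectorize_edges

DEFAULTS = {
    "n_discard": 10,
    "tr_seconds": 2.0,
    "n_components": 26,
    "subj_pca_dim": 40,
    "n_ica_runs": 20,
    "template_threshold": 0.2,
    "band_hz": [0.01, 0.1],
    "window_width": 30,
    "window_step": 1,
    "k": None,              # None -> silhouette selection over k_range
    "k_range": [2, 10],
    "n_init": 100,
    "select_k_n_init": 20,
    "distance": "sqeuclidean",
    "alpha_edges": 0.01,
    "alpha_metrics": 0.05,
    "seed": 0,
    "robustness": False,
    "robustness_width": 40,
    "keep_components": [],
    "drop_components": [],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_cohort_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "age_months", "sex"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"cohort sheet missing columns: {sorted(missing)}")
    return sheet


def _load_image_matrix(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else None
    X = data.reshape(-1, data.shape[-1]).T   # (T, V)
    return X, tr


def run_pipeline(config: dict, out_dir) -> dict:
    """Run every stage on a cohort of NIfTI images + motion traces.

    ``config`` must provide ``images`` (subject_id -> path), ``motion``
    (subject_id -> path), ``template`` (path) and ``sheet`` (path); all
    other keys default to the study parameters in ``DEFAULTS``.
    Returns the run manifest (also written to ``manifest.json``).
    """
    cfg = {**DEFAULTS, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg["seed"])
    manifest = {"version": __version__, "config": {
        k: v for k, v in cfg.items() if k not in ("images", "motion")},
        "stages": {}, "warnings": []}
    t0 = time.time()

    def _stage_done(name, outputs):
        manifest["stages"][name] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "hashes": {k: _sha256(Path(v)) for k, v in outputs.items()
                       if Path(v).is_file()},
            "elapsed_s": round(time.time() - t0, 2),
        }

    sheet = load_cohort_sheet(cfg["sheet"])
    ids = list(sheet["subject_id"])

    # ---- Stage 1: motion QC --------------------------------------------
    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")
        traces = {sid: load_motion_trace(cfg["motion"][sid]) for sid in ids}
        reports = {sid: apply_exclusion(traces[sid], subject_id=sid)
                   for sid in ids}
        qc = pd.DataFrame([reports[sid].to_dict() for sid in ids])
        groups01 = (sheet["group"] == "patient").astype(int).to_numpy()
        t_fd, df_fd, p_fd = compare_group_fd(
            qc["mean_fd"].to_numpy(), groups01)
        qc_path = out / "qc_report.tsv"
        qc.to_csv(qc_path, sep="\t", index=False)
        with open(out / "qc_report.json", "w") as fh:
            json.dump({"per_subject": qc.to_dict(orient="records"),
                       "group_fd_welch": {"t": t_fd, "df": df_fd, "p": p_fd}},
                      fh, indent=2)
    manifest["warnings"] += [str(w.message) for w in wlog]
    _stage_done("qc", {"report_tsv": qc_path, "report_json": out / "qc_report.json"})

    kept_ids = [sid for sid in ids if not reports[sid].excluded]
    if len(kept_ids) < 2:
        raise RuntimeError("qc: fewer than 2 subjects survive motion exclusion")
    sheet = sheet[sheet["subject_id"].isin(kept_ids)].reset_index(drop=True)
    groups01 = (sheet["group"] == "patient").astype(int).to_numpy()

    # ---- Stage 2: load, discard initial volumes, group ICA -------------
    n_discard = cfg["n_discard"]
    subject_data = []
    tr = cfg["tr_seconds"]
    for sid in kept_ids:
        X, tr_hdr = _load_image_matrix(cfg["images"][sid])
        if tr_hdr and tr_hdr > 0:
            tr = tr_hdr
        subject_data.append(discard_initial(X, n_discard, time_axis=0))
    mask = np.ones(subject_data[0].shape[1], dtype=bool)
    for X in subject_data:
        mask &= X.std(axis=0) > 0
    subject_data = [X[:, mask] for X in subject_data]

    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")
        _, reduced = two_stage_pca(subject_data, cfg["subj_pca_dim"],
                                   cfg["n_components"])
        comps = stability_aggregate(reduced, n_runs=cfg["n_ica_runs"],
                                    seed=int(rng.integers(2**31)))
        tcs, smaps = back_reconstruct(subject_data, comps.group_maps)
    manifest["warnings"] += [str(w.message) for w in wlog]
    comps.subject_timecourses = tcs
    comps.subject_maps = smaps

    tmpl_img = nib.load(str(cfg["template"]))
    tmpl_labels = np.asarray(tmpl_img.dataobj).ravel()[mask]
    grid_shape = tuple(tmpl_img.shape)
    full_maps = np.zeros((comps.n_components, mask.size))
    full_maps[:, mask] = comps.group_maps
    maps_img = nib.Nifti1Image(
        full_maps.T.reshape(grid_shape + (comps.n_components,)).astype(np.float32),
        affine=tmpl_img.affine)
    maps_path = out / "group_ic_maps.nii.gz"
    nib.save(maps_img, maps_path)
    stab_path = out / "ic_stability.tsv"
    pd.DataFrame({"ic": np.arange(comps.n_components),
                  "stability": comps.stability_index}).to_csv(
        stab_path, sep="\t", index=False)
    _stage_done("ica", {"group_maps": maps_path, "stability": stab_path})

    # ---- Stage 3: component selection + cleaning ------------------------
    labels_df = template_match(comps.group_maps, tmpl_labels,
                               cfg["template_threshold"])
    high_frac = np.zeros(comps.n_components)
    for ic in range(comps.n_components):
        fracs = []
        for tc in tcs:
            _, frac, _ = spectral_artifact_flag(tc[:, ic], tr)
            fracs.append(frac)
        high_frac[ic] = np.nanmean(fracs)
    labels_df["high_freq_fraction"] = high_frac
    labels_df["spectral_flag"] = high_frac > 0.5
    labels_df["retained"] = (labels_df["retained"]
                             & ~labels_df["spectral_flag"])
    for ic in cfg["keep_components"]:
        labels_df.loc[labels_df["ic"] == ic, "retained"] = True
    for ic in cfg["drop_components"]:
        labels_df.loc[labels_df["ic"] == ic, "retained"] = False
    labels_path = out / "ic_labels.tsv"
    labels_df.to_csv(labels_path, sep="\t", index=False)
    retained = labels_df.loc[labels_df["retained"], "ic"].to_numpy()
    if retained.size < 2:
        raise RuntimeError("select: fewer than 2 components retained")
    networks = list(labels_df.loc[labels_df["retained"], "network"])

    cleaned = []
    for i, sid in enumerate(kept_ids):
        trace = discard_initial(traces[sid], n_discard, time_axis=0)
        reg = friston24_regressors(trace)
        sub = np.column_stack([
            clean_timecourse(tcs[i][:, ic], reg, tr, tuple(cfg["band_hz"]))
            for ic in retained
        ])
        cleaned.append(sub)
        np.savetxt(out / f"tc_clean_{sid}.tsv", sub, delimiter="\t", fmt="%.6f")
    _stage_done("select", {"labels": labels_path})

    # ---- Stage 4: static FC ---------------------------------------------
    z_edges = np.array([vectorize_edges(static_matrix(tc)) for tc in cleaned])
    for i, sid in enumerate(kept_ids):
        np.savetxt(out / f"sfc_{sid}.tsv", static_matrix(cleaned[i]),
                   delimiter="\t", fmt="%.6f")
    contrast = edge_glm(z_edges, groups01, sheet["age_months"], sheet["sex"],
                        alpha=cfg["alpha_edges"], fdr=True)
    pairs = edge_pairs(len(retained))
    contrast["ic_i"] = [retained[i] for i, _ in pairs]
    contrast["ic_j"] = [retained[j] for _, j in pairs]
    contrast["net_i"] = [networks[i] for i, _ in pairs]
    contrast["net_j"] = [networks[j] for _, j in pairs]
    sfc_path = out / "sfc_edge_contrast.tsv"
    contrast.to_csv(sfc_path, sep="\t", index=False)
    summary = network_pair_summary(contrast, networks)
    summary_path = out / "sfc_network_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    _stage_done("sfc", {"edges": sfc_path, "summary": summary_path})

    # ---- Stage 5 + 6: dynamic FC states + temporal metrics --------------
    def _dfc(width, tag):
        wspec = WindowSpec(width=width, step=cfg["window_step"])
        windows = make_windows(cleaned[0].shape[0], wspec)
        W = np.stack([windowed_fc(tc, windows) for tc in cleaned])
        flat = W.reshape(-1, W.shape[-1])
        if cfg["k"] is None:
            k_opt, curve = select_k(flat, range(cfg["k_range"][0],
                                               cfg["k_range"][1] + 1),
                                    n_init=cfg["select_k_n_init"],
                                    seed=int(rng.integers(2**31)),
                                    distance=cfg["distance"])
        else:
            k_opt, curve = int(cfg["k"]), None
        model = cluster_states(W, k_opt, n_init=cfg["n_init"],
                               seed=int(rng.integers(2**31)),
                               distance=cfg["distance"],
                               silhouette_curve=curve)
        assign = pd.DataFrame(
            [(sid, w, int(model.assignments[i, w]))
             for i, sid in enumerate(kept_ids)
             for w in range(model.assignments.shape[1])],
            columns=["subject_id", "window", "state"])
        assign.to_csv(out / f"state_assignments{tag}.tsv", sep="\t", index=False)
        if curve is not None:
            pd.DataFrame(sorted(curve.items()),
                         columns=["k", "silhouette"]).to_csv(
                out / f"silhouette{tag}.tsv", sep="\t", index=False)
        for s in range(model.k):
            np.savetxt(out / f"centroid_state{s + 1}{tag}.tsv",
                       model.centroids[s], delimiter="\t", fmt="%.6f")
            te = top_edges(model.centroids[s])
            pd.DataFrame({
                "edge": te,
                "ic_i": [retained[pairs[e][0]] for e in te],
                "ic_j": [retained[pairs[e][1]] for e in te],
                "value": model.centroids[s][te],
            }).to_csv(out / f"top_edges_state{s + 1}{tag}.tsv",
                      sep="\t", index=False)
        gcent, gcounts = group_centroids(model, W, sheet["group"].to_numpy())
        ttests = state_edge_ttest(model, W, groups01, alpha=cfg["alpha_edges"])
        for s, res in ttests.items():
            if res.get("skipped"):
                continue
            df = pd.DataFrame({"edge": np.arange(len(res["t"])),
                               "t": res["t"], "p": res["p"],
                               "sig": res["sig"],
                               "direction": res["direction"]})
            df.to_csv(out / f"dfc_ttest_state{s}{tag}.tsv", sep="\t", index=False)
        met = metrics_table(model.assignments, kept_ids, k=model.k)
        met.to_csv(out / f"temporal_metrics{tag}.tsv", sep="\t", index=False)
        comp = compare_metrics(met, groups01, sheet["age_months"], sheet["sex"],
                               alpha=cfg["alpha_metrics"])
        comp.to_csv(out / f"metrics_comparison{tag}.tsv", sep="\t", index=False)
        pat = sheet["group"].to_numpy() == "patient"
        if pat.sum() >= 5 and "duration_months" in sheet.columns:
            corr = duration_correlation(
                met.iloc[np.flatnonzero(pat)].reset_index(drop=True),
                sheet["duration_months"].to_numpy(dtype=float)[pat],
                sheet["age_months"].to_numpy()[pat],
                sheet["sex"].to_numpy()[pat], alpha=cfg["alpha_metrics"])
            corr.to_csv(out / f"duration_correlation{tag}.tsv", sep="\t",
                        index=False)
        return model, gcent, gcounts

    model, _, _ = _dfc(cfg["window_width"], "")
    _stage_done("dfc", {"assignments": out / "state_assignments.tsv"})
    _stage_done("metrics", {"metrics": out / "temporal_metrics.tsv"})
    if cfg["robustness"]:
        _dfc(cfg["robustness_width"], f"_w{cfg['robustness_width']}")
        _stage_done("robustness", {
            "assignments": out / f"state_assignments_w{cfg['robustness_width']}.tsv"})

    manifest["n_subjects"] = len(kept_ids)
    manifest["n_retained_components"] = int(retained.size)
    manifest["k"] = int(model.k)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
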