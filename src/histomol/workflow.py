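"""End-to-end orchestration of the two classification tracks.

``run_msi_track`` renders a phantom imaging cohort, preprocesses every
section (baseline, TIC, dense binning onto the 700–2500 Da / 0.25 Da grid),
segments it with spatial shrunken centroids, extracts the tumor clusters
against the reference annotation, and runs leave-one-patient-out PLS-DA to
produce per-patient median-score calls with the margin rule.

``run_prot_track`` generates the extraction-spot protein table, applies the
flag/log/valid-value/ANOVA chain, imputes, fits the PCA prediction
ellipses, and cross-validates the one-vs-rest SVM; per-patient calls are
majority votes over the patient's extraction spots.

``run_benchmark`` runs both tracks on the synthetic cohort and integrates
the calls into the final diagnosis table.  Every run writes a manifest
(config hash, master seed, library versions, output listing); reruns with
the same config are bit-identical for the manifest and all outputs.

A single master seed deterministically derives per-stage seeds, so the two
tracks can be re-run in isolation without disturbing each other's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import msi_classify, msi_preprocess, msi_segmentation, synthetic_data
from .integration import (ModalityCall, flag_irregular_msi,
                          flag_irregular_proteomics, integrate)
from .proteomics_classify import CVConfig, CVReport, svm_cv
from .proteomics_pipeline import (anova_bh, filter_flags, filter_valid,
                                  impute_normal, log_transform,
                                  pca_with_ellipses, prediction_ellipse)

__all__ = ["RunConfig", "stage_seed", "run_msi_track", "run_prot_track",
           "run_benchmark"]


@dataclass
class RunConfig:
    """All knobs of the end-to-end benchmark, with workflow defaults."""

    out_dir: str | Path = "histomol_run"
    seed: int = 0
    # MSI track
    msi_patients: Mapping[str, int] = field(
        default_factory=lambda: {"ccRCC": 9, "RO": 9, "ChRCC": 5})
    grid: int = 14
    patient_cv: float = 0.25
    ro_chrcc_overlap: float = 0.0
    sarcomatoid_patient: bool = False
    mz_min: float = 700.0
    mz_max: float = 2500.0
    mz_step: float = 0.25
    baseline_half_window: float = 25.0
    segmentation_k: int = 4
    segmentation_r: int = 1
    segmentation_s: float = 3.0
    n_components: int = 5
    max_components: int = 34
    margin: float = 0.10
    # proteomics track
    proteome_design: Mapping = field(default_factory=dict)
    min_valid: float = 0.70
    fdr: float = 0.01
    k: int = 5
    kernel: str = "rbf"
    svm_cost: float = 10.0
    imputation_width: float = 0.3
    imputation_downshift: float = 1.8

    def __post_init__(self) -> None:
        if not 0 < self.margin < 1:
            raise ValueError("margin must be in (0, 1)")
        if not 0 < self.min_valid <= 1:
            raise ValueError("min_valid must be in (0, 1]")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.n_components < 1 or self.max_components < 1:
            raise ValueError("component counts must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        d["msi_patients"] = dict(d["msi_patients"])
        d["proteome_design"] = dict(d["proteome_design"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    rng = np.random.default_rng([int(master), zlib.crc32(stage.encode())])
    return int(rng.integers(2**31 - 1))


def _write_manifest(config: RunConfig, out_dir: Path, outputs: list[str],
                    stage: str) -> Path:
    import sklearn

    manifest = {
        "stage": stage,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "outputs": sorted(outputs),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _call_to_dict(call: ModalityCall) -> dict:
    return {"winner": call.winner, "ambiguous_with": sorted(call.ambiguous_with),
            "irregular": call.irregular, "reason": call.reason,
            "label": call.label}


# ---------------------------------------------------------------------------
# MSI track


def run_msi_track(config: RunConfig) -> dict:
    """Phantom cohort -> preprocess -> segment -> tumor pixels -> LOPO PLS-DA.

    Returns a dict with the per-patient :class:`ModalityCall`s, the raw
    pixel-level CV result, pathology labels, and per-class pixel accuracy.
    Outputs (score maps TSV, calls JSON, manifest) land in ``out_dir/msi``.
    """
    out_dir = Path(config.out_dir) / "msi"
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = synthetic_data.msi_cohort_specs(
        dict(config.msi_patients), seed=stage_seed(config.seed, "msi_cohort"),
        grid=config.grid, patient_cv=config.patient_cv,
        ro_chrcc_overlap=config.ro_chrcc_overlap,
        sarcomatoid_patient=config.sarcomatoid_patient,
    )
    matrices, labels_truth = [], {}
    for pid, cls, spec in specs:
        phantom = synthetic_data.generate_msi_phantom(spec)
        phantom.metadata.update(patient_id=pid, condition=cls)
        truth = synthetic_data.ground_truth(phantom)
        prep = msi_preprocess.tic_normalize(
            msi_preprocess.subtract_baseline_dataset(
                phantom, config.baseline_half_window))
        binned = msi_preprocess.bin_resample(prep, config.mz_min, config.mz_max,
                                             config.mz_step)
        seg = msi_segmentation.spatial_shrunken_centroids(
            binned, params=msi_segmentation.SegmentationParams(
                k_init=config.segmentation_k, r=config.segmentation_r,
                s=config.segmentation_s,
                seed=stage_seed(config.seed, f"segment_{pid}")))
        tumor_truth = {c for c, l in truth.items() if l in synthetic_data.CLASSES}
        tumor_px = msi_segmentation.select_tumor_clusters(
            seg, tumor_truth, threshold=0.5, criterion="containment")
        if not tumor_px:  # fall back to the annotation itself
            tumor_px = tumor_truth
        keep = [i for i, c in enumerate(binned.row_meta[["x", "y"]]
                                        .itertuples(index=False, name=None))
                if c in tumor_px]
        sub = msi_preprocess.FeatureMatrix(
            binned.values[keep], binned.feature_axis,
            binned.row_meta.iloc[keep].reset_index(drop=True))
        matrices.append(sub)
        labels_truth[pid] = cls

    combined = msi_preprocess.FeatureMatrix.concat(matrices)
    cv = msi_classify.loo_patient_cv(
        combined.values, combined.row_meta["condition"].to_numpy(),
        combined.row_meta["patient_id"].to_numpy(),
        n_components=config.n_components,
        coords=list(zip(combined.row_meta["x"], combined.row_meta["y"])))
    patient_calls = cv.patient_calls(config.margin)

    calls: dict[str, ModalityCall] = {}
    for pid, pc in patient_calls.items():
        irregular, reason = flag_irregular_msi(pc)
        calls[pid] = ModalityCall(pc.winner, set(pc.ambiguous_with),
                                  irregular, reason)

    cv.pixels.to_csv(out_dir / "pixel_scores.tsv", sep="\t", index=False)
    calls_json = {pid: _call_to_dict(c) for pid, c in sorted(calls.items())}
    (out_dir / "patient_calls.json").write_text(
        json.dumps(calls_json, indent=2, sort_keys=True) + "\n")
    manifest = _write_manifest(config, out_dir,
                               ["pixel_scores.tsv", "patient_calls.json"], "msi")
    return {
        "calls": calls,
        "cv": cv,
        "truth": labels_truth,
        "pixel_accuracy": cv.pixel_accuracy(),
        "patient_accuracy": float(np.mean(
            [calls[p].winner == labels_truth[p] for p in labels_truth])),
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# Proteomics track


def run_prot_track(config: RunConfig) -> dict:
    """Protein table -> filter/log/valid/ANOVA -> impute -> PCA + SVM CV.

    Per-patient calls are majority votes over the patient's extraction-spot
    predictions; the PCA-ellipse rule sets the irregularity flag.  The
    sarcomatoid-analog patient (when designed in) is excluded from
    classifier training and testing but still screened by the ellipse rule.
    """
    out_dir = Path(config.out_dir) / "proteomics"
    out_dir.mkdir(parents=True, exist_ok=True)
    design = synthetic_data.ProteomeDesign(
        seed=stage_seed(config.seed, "proteome"), **dict(config.proteome_design))
    table = synthetic_data.generate_protein_table(design)
    truth = synthetic_data.ground_truth(table)

    processed = filter_valid(log_transform(filter_flags(table)), config.min_valid)
    diff = anova_bh(processed, fdr=config.fdr)
    selected = processed.subset_rows(diff.significant) \
        if diff.significant.sum() >= 10 else processed
    imputed = impute_normal(selected, config.imputation_width,
                            config.imputation_downshift,
                            seed=stage_seed(config.seed, "impute"))

    scores, evr, ellipses = pca_with_ellipses(imputed.intensities,
                                              imputed.classes)
    meta = imputed.sample_meta
    outlier_pid = truth.outlier_patient_id
    train_mask = (meta["patient_id"] != outlier_pid).to_numpy() \
        if outlier_pid else np.ones(len(meta), dtype=bool)

    X = imputed.intensities.T
    report = svm_cv(X[train_mask], meta["class"].to_numpy()[train_mask],
                    CVConfig(k=config.k, kernel=config.kernel,
                             cost=config.svm_cost,
                             seed=stage_seed(config.seed, "svm")),
                    sample_ids=meta["sample_id"].to_numpy()[train_mask])

    predicted = dict(zip(report.samples["sample_id"], report.samples["predicted"]))

    def _screen_ellipses(pid: str) -> dict:
        """Class ellipses with the screened patient held out (the prediction
        region is for a *new* observation, so the patient under scrutiny must
        not inform its own reference)."""
        out = {}
        for cls in pd.unique(meta["class"]):
            ref = ((meta["class"] == cls) & (meta["patient_id"] != pid)).to_numpy()
            if ref.sum() >= 3:
                out[cls] = prediction_ellipse(scores[ref, :2], cls)
        return out

    calls: dict[str, ModalityCall] = {}
    for pid, grp in meta.groupby("patient_id", sort=False):
        idx = grp.index.to_numpy()
        if outlier_pid and pid == outlier_pid:
            # screened but excluded from classifier training/testing
            assigned = grp["class"].iloc[0]
            irregular, reason = flag_irregular_proteomics(
                scores[idx, :2], assigned, _screen_ellipses(pid))
            calls[pid] = ModalityCall(assigned, set(), irregular,
                                      reason or "excluded from classification")
            continue
        votes = pd.Series([predicted[s] for s in grp["sample_id"]])
        winner = votes.mode().iloc[0]
        irregular, reason = flag_irregular_proteomics(
            scores[idx, :2], winner, _screen_ellipses(pid))
        calls[pid] = ModalityCall(winner, set(), irregular, reason)

    report.samples.to_csv(out_dir / "cv_report.tsv", sep="\t", index=False)
    (out_dir / "patient_calls.json").write_text(json.dumps(
        {pid: _call_to_dict(c) for pid, c in sorted(calls.items())},
        indent=2, sort_keys=True) + "\n")
    manifest = _write_manifest(config, out_dir,
                               ["cv_report.tsv", "patient_calls.json"],
                               "proteomics")
    truth_classes = {pid: grp["class"].iloc[0]
                     for pid, grp in meta.groupby("patient_id", sort=False)}
    return {
        "calls": calls,
        "report": report,
        "table": table,
        "diff": diff,
        "ellipses": ellipses,
        "pca_scores": scores,
        "explained_variance": evr,
        "truth": truth_classes,
        "outlier_patient": outlier_pid,
        "error_rate": report.error_rate,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# Full benchmark


def run_benchmark(config: RunConfig) -> dict:
    """Both tracks on the synthetic cohort, integrated per patient.

    MSI and proteomics cohorts are generated patient-for-patient from the
    same design (classes aligned by patient index within class), so the two
    tracks describe the same virtual patients.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    prot_design = dict(config.proteome_design)
    prot_design.setdefault("patients_per_class", dict(config.msi_patients))
    if config.sarcomatoid_patient:
        prot_design.setdefault("outlier_patient",
                               ("ChRCC", {"ChRCC": 0.5, "ccRCC": 0.5}))
    cfg = dataclasses.replace(config, proteome_design=prot_design)

    msi = run_msi_track(cfg)
    prot = run_prot_track(cfg)

    # align patient ids across the tracks by (class, index-within-class)
    def _by_class(truth: Mapping[str, str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid in sorted(truth):
            out.setdefault(truth[pid], []).append(pid)
        return out

    msi_ids = _by_class(msi["truth"])
    prot_ids = _by_class(prot["truth"])
    rows = []
    for cls, pids in msi_ids.items():
        for i, pid in enumerate(pids):
            prot_pid = prot_ids[cls][i] if i < len(prot_ids[cls]) else None
            if prot_pid is None:
                continue
            diag = integrate(msi["calls"][pid], prot["calls"][prot_pid], pid)
            rows.append({
                "patient": pid,
                "pathology": cls,
                "msi_diagnosis": diag.msi_call.label,
                "lcms_diagnosis": diag.lcms_call.label,
                "conclusion": diag.conclusion,
            })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "integrated_diagnoses.tsv", sep="\t", index=False)
    manifest = _write_manifest(config, out_dir, ["integrated_diagnoses.tsv"],
                               "benchmark")
    return {"msi": msi, "proteomics": prot, "table": table, "manifest": manifest}
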