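"""Synthetic MSI phantoms and protein quantification tables with known truth.

Two generators emulate the two data modalities of the renal-tumor workflow:

* :func:`generate_msi_phantom` builds an imaging dataset on a pixel grid —
  spatially contiguous tissue regions (tumor of a given subtype, stroma,
  background), each with Gaussian peaks at class-specific signature m/z
  values, a shared tissue signature, an exponentially decaying chemical
  baseline, per-pixel total-ion-current (TIC) variation and additive noise.
  The default subtype signatures sit at the discriminating m/z values
  reported for the three renal tumor classes: 723.5 / 704.5 (ccRCC),
  806.5 / 1640.0 (RO) and 1169.5 / 1039.5 (ChRCC).

* :func:`generate_protein_table` builds a MaxQuant-style label-free protein
  table: log-normal protein abundances with class-specific protein blocks,
  a patient/extraction-spot hierarchy (2–6 spots per patient), logistic
  intensity-dependent (MNAR) missingness, decoy/contaminant rows, and
  optionally one "sarcomatoid-like" outlier patient whose profile is a
  convex mixture of two class profiles.

Every generated object carries its ground truth (region labels, per-protein
true effects, per-sample classes), retrievable via :func:`ground_truth`.
Random streams are split per pixel / per patient with seed sequences, so
subsetting a design leaves the remaining draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .msi_io import MSIDataset
from .proteomics_pipeline import ProteinQuantTable

__all__ = [
    "CLASSES",
    "SIGNATURE_PEAKS",
    "MsiPhantomSpec",
    "ProteomeDesign",
    "generate_msi_phantom",
    "generate_protein_table",
    "ground_truth",
    "ellipse_mask",
    "default_phantom_spec",
    "msi_cohort_specs",
    "write_ground_truth_mask",
]

CLASSES = ("ccRCC", "RO", "ChRCC")

#: Discriminating m/z per tumor subtype: (m/z [Da], mean intensity [a.u.], CV).
SIGNATURE_PEAKS: dict[str, list[tuple[float, float, float]]] = {
    "ccRCC": [(723.5, 100.0, 0.3), (704.5, 80.0, 0.3)],
    "RO": [(806.5, 100.0, 0.3), (1640.0, 80.0, 0.3)],
    "ChRCC": [(1169.5, 100.0, 0.3), (1039.5, 80.0, 0.3)],
}

#: Peaks common to all tissue (tumor and stroma alike).
SHARED_PEAKS: list[tuple[float, float, float]] = [
    (900.0, 70.0, 0.3),
    (1200.5, 50.0, 0.3),
    (2000.5, 35.0, 0.3),
]

#: Stroma-only signature, so segmentation has something to separate.
STROMA_PEAKS: list[tuple[float, float, float]] = [
    (750.5, 90.0, 0.3),
    (1500.5, 70.0, 0.3),
]


# ---------------------------------------------------------------------------
# MSI phantom


@dataclass
class MsiPhantomSpec:
    """Full description of one synthetic MSI tissue section."""

    grid_width: int
    grid_height: int
    regions: list[tuple[frozenset, str]]  # (pixel mask, region class)
    class_signature_peaks: Mapping[str, list[tuple[float, float, float]]]
    shared_peaks: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(SHARED_PEAKS))
    peak_width_fwhm: float = 1.0
    baseline_amplitude: float = 20.0
    baseline_decay: float = 0.002
    noise_sd: float = 2.0
    tic_variation_cv: float = 0.2
    mz_range: tuple[float, float] = (600.0, 3500.0)
    mz_step: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must satisfy min < max")
        if min(self.noise_sd, self.tic_variation_cv, self.peak_width_fwhm) < 0:
            raise ValueError("noise_sd, tic_variation_cv, fwhm must be >= 0")
        for cls, peaks in self.class_signature_peaks.items():
            for mz, _mean, cv in peaks:
                if not lo <= mz <= hi:
                    raise ValueError(f"signature m/z {mz} outside mz_range for {cls}")
                if cv < 0:
                    raise ValueError("peak CV must be >= 0")
        grid = {(x, y) for x in range(1, self.grid_width + 1)
                for y in range(1, self.grid_height + 1)}
        claimed: dict[tuple[int, int], str] = {}
        for mask, cls in self.regions:
            if not set(mask) <= grid:
                raise ValueError("region mask extends outside the grid")
            for px in mask:
                if px in claimed and claimed[px] != cls:
                    raise ValueError(
                        f"pixel {px} claimed by both {claimed[px]!r} and {cls!r}")
                claimed[px] = cls


def ellipse_mask(cx: float, cy: float, rx: float, ry: float,
                 grid_width: int, grid_height: int) -> frozenset:
    """Pixels of the grid inside an axis-aligned ellipse (1-based coords)."""
    pts = [(x, y)
           for x in range(1, grid_width + 1)
           for y in range(1, grid_height + 1)
           if ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0]
    return frozenset(pts)


def _peak_profile(mz_axis: np.ndarray, mz0: float, amplitude: float,
                  sigma: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((mz_axis - mz0) / sigma) ** 2)


def generate_msi_phantom(spec: MsiPhantomSpec) -> MSIDataset:
    """Render the phantom spec into a continuous-mode :class:`MSIDataset`.

    Each pixel's spectrum is (signature + shared Gaussian peaks) x per-pixel
    TIC factor + exponential baseline + Gaussian noise, clipped at zero.
    Pixels not covered by any region are background (baseline + noise only).
    Deterministic given ``spec.seed``; the random stream is split per pixel.
    """
    lo, hi = spec.mz_range
    n_points = int(round((hi - lo) / spec.mz_step)) + 1
    mz_axis = lo + spec.mz_step * np.arange(n_points)
    sigma = spec.peak_width_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    baseline = spec.baseline_amplitude * np.exp(-spec.baseline_decay * (mz_axis - lo))

    label_of: dict[tuple[int, int], str] = {}
    for mask, cls in spec.regions:
        for px in mask:
            label_of[px] = cls

    coords: list[tuple[int, int]] = []
    intensities: list[np.ndarray] = []
    truth: dict[tuple[int, int], str] = {}
    tic_factors: dict[tuple[int, int], float] = {}

    for y in range(1, spec.grid_height + 1):
        for x in range(1, spec.grid_width + 1):
            cls = label_of.get((x, y), "background")
            rng = np.random.default_rng([spec.seed, x, y])
            peaks: list[tuple[float, float, float]] = []
            if cls != "background":
                peaks.extend(spec.class_signature_peaks.get(cls, []))
                peaks.extend(spec.shared_peaks)
            if spec.tic_variation_cv > 0:
                tic = float(np.exp(rng.normal(0.0, spec.tic_variation_cv)))
            else:
                tic = 1.0
            signal = np.zeros_like(mz_axis)
            for mz0, mean, cv in peaks:
                amp = mean * max(0.0, 1.0 + cv * rng.standard_normal()) if cv > 0 else mean
                signal += _peak_profile(mz_axis, mz0, amp, sigma)
            spectrum = signal * tic + baseline
            if spec.noise_sd > 0:
                spectrum = spectrum + rng.normal(0.0, spec.noise_sd, size=n_points)
            spectrum = np.maximum(spectrum, 0.0).astype(np.float32)
            coords.append((x, y))
            intensities.append(spectrum)
            truth[(x, y)] = cls
            tic_factors[(x, y)] = tic

    dataset = MSIDataset(
        coordinates=coords,
        mz_axes=[mz_axis] * len(coords),
        intensities=intensities,
        mode="continuous",
        metadata={
            "ground_truth": truth,
            "tic_factors": tic_factors,
            "synthetic": True,
            "mz_range": spec.mz_range,
        },
    )
    return dataset


def default_phantom_spec(tumor_class: str, seed: int, grid: int = 14,
                         signature_scale: Mapping[str, float] | None = None,
                         mix_with: str | None = None, mix_weight: float = 0.5,
                         **overrides) -> MsiPhantomSpec:
    """Spec for one patient section: central tumor blob + stroma ring.

    ``signature_scale`` multiplies per-peak mean intensities (patient-level
    heterogeneity); ``mix_with`` blends a second subtype's signature into the
    tumor region (the sarcomatoid-like mixed phenotype).
    """
    if tumor_class not in CLASSES:
        raise ValueError(f"tumor_class must be one of {CLASSES}")
    c = (grid + 1) / 2.0
    tumor = ellipse_mask(c, c, grid * 0.30, grid * 0.30, grid, grid)
    stroma = ellipse_mask(c, c, grid * 0.45, grid * 0.45, grid, grid) - tumor

    sig = {cls: [list(p) for p in peaks] for cls, peaks in SIGNATURE_PEAKS.items()}
    if signature_scale:
        for cls, factor in signature_scale.items():
            for p in sig[cls]:
                p[1] *= factor
    tumor_peaks = [tuple(p) for p in sig[tumor_class]]
    if mix_with is not None:
        tumor_peaks = (
            [(mz, m * (1 - mix_weight), cv) for mz, m, cv in tumor_peaks]
            + [(mz, m * mix_weight, cv) for mz, m, cv in
               (tuple(p) for p in sig[mix_with])]
        )
    signature = {tumor_class: tumor_peaks, "stroma": list(STROMA_PEAKS)}
    return MsiPhantomSpec(
        grid_width=grid, grid_height=grid,
        regions=[(tumor, tumor_class), (stroma, "stroma")],
        class_signature_peaks=signature,
        seed=seed,
        **overrides,
    )


def msi_cohort_specs(n_per_class: Mapping[str, int] | None = None, seed: int = 0,
                     grid: int = 14, patient_cv: float = 0.25,
                     ro_chrcc_overlap: float = 0.0,
                     sarcomatoid_patient: bool = False,
                     **overrides) -> list[tuple[str, str, MsiPhantomSpec]]:
    """Cohort of per-patient phantom specs with patient-level heterogeneity.

    Defaults reproduce the reference imaging cohort design:
    9 ccRCC, 9 RO and 5 ChRCC patients.  ``patient_cv`` is the log-normal CV
    of per-patient signature intensity.  ``ro_chrcc_overlap`` in [0, 1)
    blends the RO and ChRCC signatures into each other (0 = fully distinct),
    emulating the spectral similarity of these two subtypes.  With
    ``sarcomatoid_patient`` the last ChRCC patient's tumor mixes ChRCC and
    ccRCC signatures half/half.

    Returns a list of (patient_id, pathology label, spec).
    """
    if n_per_class is None:
        n_per_class = {"ccRCC": 9, "RO": 9, "ChRCC": 5}
    out: list[tuple[str, str, MsiPhantomSpec]] = []
    rng = np.random.default_rng([seed, 815])
    idx = 0
    for cls in CLASSES:
        for k in range(n_per_class.get(cls, 0)):
            idx += 1
            pid = f"P{idx:03d}"
            scale = {c: float(np.exp(rng.normal(0.0, patient_cv))) for c in CLASSES}
            mix_with = None
            mix_weight = 0.5
            is_sarc = (sarcomatoid_patient and cls == "ChRCC"
                       and k == n_per_class[cls] - 1)
            if is_sarc:
                mix_with = "ccRCC"
                # a convex mixture of the two class *mean* profiles: one
                # common patient factor, not independent per-class factors
                scale = {c: scale[cls] for c in CLASSES}
            elif ro_chrcc_overlap > 0 and cls in ("RO", "ChRCC"):
                mix_with = "ChRCC" if cls == "RO" else "RO"
                mix_weight = ro_chrcc_overlap / 2.0
                # blended signatures share one patient factor so the overlap
                # itself, not per-class scaling, drives the score geometry
                scale[mix_with] = scale[cls]
            spec = default_phantom_spec(
                cls, seed=int(rng.integers(2**31 - 1)), grid=grid,
                signature_scale=scale, mix_with=mix_with, mix_weight=mix_weight,
                **overrides,
            )
            out.append((pid, cls, spec))
    return out


def write_ground_truth_mask(dataset: MSIDataset, path: str | Path) -> Path:
    """Write the per-pixel ground-truth labels as a (x, y, label) TSV."""
    truth = ground_truth(dataset)
    path = Path(path)
    rows = [(x, y, truth[(x, y)]) for (x, y) in dataset.coordinates]
    pd.DataFrame(rows, columns=["x", "y", "label"]).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Protein quantification tables


@dataclass
class ProteomeDesign:
    """Generative design for a label-free protein quantification table.

    Defaults mirror the reference microproteomics cohort design:
    12 ccRCC / 11 RO / 5 ChRCC patients, 2–6 extraction spots each, with 10
    class-specific proteins per class among 400 total.  Intensities are
    log2-normal; class effects shift a class's specific block by
    ``class_effect_log2fc`` log2 units; missingness follows a logistic
    model in the true log2 intensity (low abundance more often missing).
    """

    n_proteins_total: int = 400
    n_class_specific_per_class: int = 10
    patients_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"ccRCC": 12, "RO": 11, "ChRCC": 5})
    spots_per_patient_range: tuple[int, int] = (2, 6)
    base_log_intensity_mean: float = 25.0
    base_log_intensity_sd: float = 1.5
    class_effect_log2fc: float = 2.0
    spot_noise_sd: float = 0.5
    patient_noise_sd: float = 0.4
    missingness_model: tuple[float, float] = (18.0, -0.8)  # logit = a + b * log2 intensity
    n_contaminant_rows: int = 5
    n_reverse_rows: int = 5
    outlier_patient: tuple[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins_total, self.n_class_specific_per_class,
               self.n_contaminant_rows, self.n_reverse_rows) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_class_specific_per_class * len(CLASSES) > self.n_proteins_total:
            raise ValueError("class-specific blocks exceed total protein count")
        lo, hi = self.spots_per_patient_range
        if not (1 <= lo <= hi <= 10):
            raise ValueError("spots_per_patient_range must lie within [1, 10]")
        for cls in CLASSES:
            if self.patients_per_class.get(cls, 0) <= 0:
                raise ValueError(f"class {cls} needs at least one patient")
        if self.outlier_patient is not None:
            _label, weights = self.outlier_patient
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError("outlier mixture weights must sum to 1")


@dataclass
class ProteomeTruth:
    """Ground truth of a generated table."""

    protein_effects: pd.DataFrame  # per protein: specific_class, log2fc per class
    sample_classes: pd.Series  # sample_id -> class
    outlier_patient_id: str | None
    true_log_intensity: pd.DataFrame  # noise-free log2 means, protein x sample


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def generate_protein_table(design: ProteomeDesign) -> ProteinQuantTable:
    """Sample a raw-scale :class:`ProteinQuantTable` from the design.

    Rows = proteins (plus flagged contaminant / reverse rows), columns =
    extraction-spot samples grouped by patient.  The returned table's
    ``ground_truth`` attribute is a :class:`ProteomeTruth`.
    """
    rng = np.random.default_rng([design.seed, 1])
    P, C = design.n_proteins_total, len(CLASSES)
    k = design.n_class_specific_per_class

    base = rng.normal(design.base_log_intensity_mean,
                      design.base_log_intensity_sd, size=P)
    specific = np.full(P, "", dtype=object)
    effect = np.zeros((P, C))
    for ci, cls in enumerate(CLASSES):
        block = slice(ci * k, (ci + 1) * k)
        specific[block] = cls
        effect[block, ci] = design.class_effect_log2fc
    class_profiles = {cls: base + effect[:, ci] for ci, cls in enumerate(CLASSES)}

    # patient / spot hierarchy
    sample_ids: list[str] = []
    patient_ids: list[str] = []
    classes: list[str] = []
    spot_ids: list[str] = []
    patients: list[tuple[str, str]] = []
    idx = 0
    for cls in CLASSES:
        for _ in range(design.patients_per_class[cls]):
            idx += 1
            patients.append((f"P{idx:03d}", cls))
    outlier_pid = None
    if design.outlier_patient is not None:
        label, _weights = design.outlier_patient
        for pid, cls in reversed(patients):
            if cls == label:
                outlier_pid = pid
                break
        if outlier_pid is None:
            raise ValueError(f"no patient of class {label!r} for outlier assignment")

    lo, hi = design.spots_per_patient_range
    columns: list[np.ndarray] = []
    true_means: list[np.ndarray] = []
    for pid, cls in patients:
        prng = np.random.default_rng([design.seed, 2, int(pid[1:])])
        n_spots = int(prng.integers(lo, hi + 1))
        if pid == outlier_pid:
            _label, weights = design.outlier_patient
            profile = sum(w * class_profiles[c] for c, w in weights.items())
        else:
            profile = class_profiles[cls]
        patient_shift = prng.normal(0.0, design.patient_noise_sd, size=P)
        for s in range(n_spots):
            mu = profile + patient_shift
            vals = mu + prng.normal(0.0, design.spot_noise_sd, size=P)
            a, b = design.missingness_model
            p_miss = _sigmoid(a + b * vals)
            vals[prng.random(P) < p_miss] = np.nan
            sid = f"{pid}_s{s + 1}"
            sample_ids.append(sid)
            patient_ids.append(pid)
            classes.append(cls)
            spot_ids.append(f"s{s + 1}")
            columns.append(vals)
            true_means.append(mu)

    log_matrix = np.column_stack(columns)
    raw = np.power(2.0, log_matrix)

    # decoy / contaminant rows: moderate random intensities, flags set
    n_extra = design.n_contaminant_rows + design.n_reverse_rows
    if n_extra:
        erng = np.random.default_rng([design.seed, 3])
        extra = np.power(2.0, erng.normal(design.base_log_intensity_mean - 2.0, 1.0,
                                          size=(n_extra, raw.shape[1])))
        raw = np.vstack([raw, extra])

    protein_ids = [f"PROT{i + 1:04d}" for i in range(P)]
    protein_ids += [f"CON__C{i + 1}" for i in range(design.n_contaminant_rows)]
    protein_ids += [f"REV__R{i + 1}" for i in range(design.n_reverse_rows)]
    flags = pd.DataFrame(False, index=range(len(protein_ids)),
                         columns=["contaminant", "reverse", "only_by_site"])
    flags.loc[P:P + design.n_contaminant_rows - 1, "contaminant"] = True
    flags.loc[P + design.n_contaminant_rows:, "reverse"] = True

    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": patient_ids,
        "class": classes,
        "spot_id": spot_ids,
    })
    truth = ProteomeTruth(
        protein_effects=pd.DataFrame(
            {"specific_class": specific,
             **{f"log2fc_{cls}": effect[:, ci] for ci, cls in enumerate(CLASSES)}},
            index=protein_ids[:P]),
        sample_classes=pd.Series(classes, index=sample_ids, name="class"),
        outlier_patient_id=outlier_pid,
        true_log_intensity=pd.DataFrame(np.column_stack(true_means),
                                        index=protein_ids[:P], columns=sample_ids),
    )
    return ProteinQuantTable(
        protein_ids=protein_ids,
        intensities=raw,
        sample_meta=meta,
        flags=flags,
        scale="raw",
        ground_truth=truth,
    )


def ground_truth(obj):
    """Return the ground truth attached to a generated dataset or table."""
    if isinstance(obj, MSIDataset):
        truth = obj.metadata.get("ground_truth")
        if truth is None:
            raise ValueError("dataset was not produced by the synthetic generator")
        return truth
    if isinstance(obj, ProteinQuantTable):
        if obj.ground_truth is None:
            raise ValueError("table was not produced by the synthetic generator")
        return obj.ground_truth
    raise TypeError(f"no ground truth for objects of type {type(obj).__name__}")
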