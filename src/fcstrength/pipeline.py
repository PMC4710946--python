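"""End-to-end orchestration of the FCS analysis on a synthetic cohort.

``run_full_analysis`` chains every stage in the analysis order: cohort
generation, temporal preprocessing, FCS mapping, covariate-adjusted group
inference with Monte-Carlo cluster-extent correction, the converter
comparison, seed-based connectivity from the converter-deficit clusters,
behavior association maps, leave-one-out SVM discrimination, and the
robustness suite.  Every artifact is written under the configured output
directory and listed, with its SHA-256 hash, in ``manifest.json``.

Stage seeds are split from the master seed via ``numpy.random.SeedSequence``
children in a fixed order (cohort, cluster null simulation, FWE
calibration), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .classify import extract_features, loocv_svm
from .clusters import estimate_cluster_extent_threshold, extract_clusters
from .cohort import CohortSpec, generate_cohort, anatomy_masks
from .connectivity import compute_fcs, seed_fc_map, seed_timecourse
from .inference import ancova_f_map, behavior_association_map, posthoc_t_map
from .preprocess import clean_subject, framewise_displacement, group_gm_mask
from .validation import run_validation_suite

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_full_analysis", "demo_config"]


@dataclass
class AnalysisConfig:
    """All knobs of one analysis run; serializes round-trip stable to YAML."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    low_hz: float = 0.01
    high_hz: float = 0.08
    gm_cutoff: float = 0.2
    r_threshold: float = 0.2
    fcs_mode: str = "zsum"
    gsr: bool = True
    voxel_p: float = 0.05
    alpha: float = 0.05
    cluster_iterations: int = 500
    connectivity: int = 18
    smoothing_fwhm_mm: float = 4.0
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    master_seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        for name in ("gm_cutoff", "r_threshold", "voxel_p", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError("need 0 <= low_hz < high_hz")

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.master_seed)
        children = ss.spawn(3)
        names = ["cohort", "cluster_null", "fwe_calibration"]
        return {
            name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for name, child in zip(names, children)
        }

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"]["network_rois"] = [
            {"name": r["name"], "voxels": [list(v) for v in r["voxels"]]}
            for r in d["cohort"]["network_rois"]
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        from .cohort import NetworkROI

        d = yaml.safe_load(Path(path).read_text())
        c = d.pop("cohort")
        c["grid_dims"] = tuple(c["grid_dims"])
        c["voxel_size_mm"] = tuple(c["voxel_size_mm"])
        c["band_hz"] = tuple(c["band_hz"])
        c["network_rois"] = tuple(
            NetworkROI(r["name"], tuple(tuple(v) for v in r["voxels"]))
            for r in c["network_rois"]
        )
        return cls(cohort=CohortSpec(**c), **d)


def demo_config(out_dir: str = "results/demo", master_seed: int = 0) -> AnalysisConfig:
    """Desk-scale configuration: small grid, 26 subjects, fast MC correction."""
    spec = CohortSpec(
        grid_dims=(16, 16, 12),
        n_per_group={"AD": 6, "MCI": 12, "NC": 8},
        n_converters=7,
        n_timepoints=100,
        seed=0,
    )
    return AnalysisConfig(cohort=spec, cluster_iterations=200,
                          master_seed=master_seed, out_dir=out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and return the manifest dictionary."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    vox = config.cohort.voxel_size_mm
    artifacts: list[Path] = []

    def save_vol(data: np.ndarray, name: str) -> None:
        p = out / name
        fio.save_volume(data, p, voxel_size_mm=vox)
        artifacts.append(p)

    # --- stage 1: cohort -------------------------------------------------
    logger.info("stage cohort: generating synthetic cohort")
    spec = config.cohort.replace(seed=seeds["cohort"])
    cohort = generate_cohort(spec)
    table = cohort.subject_table()
    fio.save_subject_table(table, out / "subjects.tsv")
    artifacts.append(out / "subjects.tsv")

    # --- stage 2: preprocessing ------------------------------------------
    logger.info("stage preprocess: temporal cleaning of %d subjects", len(cohort))
    gm = group_gm_mask(cohort.gm_probability_maps, cutoff=config.gm_cutoff)
    compartments = anatomy_masks(spec)
    conf_masks = {"global": gm.include, "wm": compartments["wm"],
                  "csf": compartments["csf"]}
    cleaned = [
        clean_subject(b, m, conf_masks, config.low_hz, config.high_hz, gsr=config.gsr)
        for _, b, m in cohort
    ]
    mean_fd = np.array([framewise_displacement(m).mean_fd_mm for m in cohort.motions])
    save_vol(gm.include.astype(np.float32), "gm_mask.nii")

    # --- stage 3: FCS maps ------------------------------------------------
    logger.info("stage fcs: voxelwise connectivity strength (r > %.2f)",
                config.r_threshold)
    fcs_maps = [
        compute_fcs(b, gm, r_threshold=config.r_threshold, mode=config.fcs_mode)
        for b in cleaned
    ]
    groups = [s.group for s in cohort.subjects]
    for g in ("AD", "MCI", "NC"):
        mean_map = np.mean(
            [m.values for m, s in zip(fcs_maps, cohort.subjects) if s.group == g],
            axis=0,
        )
        save_vol(mean_map, f"fcs_mean_{g}.nii")

    # --- stage 4: group inference + cluster correction --------------------
    logger.info("stage stats: ANCOVA and cluster-extent correction")
    age = table["age"].to_numpy()
    sex = (table["sex"] == "M").to_numpy(float)
    covariates = np.column_stack([age, sex])
    f_map = ancova_f_map(fcs_maps, groups, covariates, mask=gm.include)
    save_vol(f_map.values, "ancova_f.nii")
    extent = estimate_cluster_extent_threshold(
        gm.include, fwhm_mm=config.smoothing_fwhm_mm, voxel_p=config.voxel_p,
        alpha=config.alpha, n_iterations=config.cluster_iterations,
        connectivity=config.connectivity, seed=seeds["cluster_null"],
        voxel_size_mm=vox[0],
    )
    f_thr = f_map.threshold_value(config.voxel_p)
    f_clusters = extract_clusters(
        f_map.values, f_thr, extent.min_extent_voxels, config.connectivity,
        voxel_volume_mm3=float(np.prod(vox)), mask=gm.include,
    )
    group_effect_mask = np.zeros(spec.grid_dims, bool)
    for c in f_clusters.clusters:
        group_effect_mask |= c["voxel_mask"]

    def subset(group: str):
        return [m for m, s in zip(fcs_maps, cohort.subjects) if s.group == group], \
               covariates[[s.group == group for s in cohort.subjects]]

    posthoc_mask = group_effect_mask if group_effect_mask.any() else gm.include
    posthoc = {}
    for a, b in (("AD", "NC"), ("MCI", "NC"), ("AD", "MCI")):
        ma, ca = subset(a)
        mb, cb = subset(b)
        tmap = posthoc_t_map(ma, mb, np.vstack([ca, cb]), posthoc_mask)
        posthoc[f"{a}_vs_{b}"] = tmap
        save_vol(tmap.values, f"t_{a}_vs_{b}.nii")

    # converter comparison, restricted to the AD-vs-control significant mask
    ad_nc = posthoc["AD_vs_NC"]
    ad_thr = ad_nc.threshold_value(config.voxel_p)
    ad_clusters = extract_clusters(np.abs(ad_nc.values), ad_thr,
                                   extent.min_extent_voxels, config.connectivity,
                                   voxel_volume_mm3=float(np.prod(vox)),
                                   mask=posthoc_mask)
    conv_restrict = np.zeros(spec.grid_dims, bool)
    for c in ad_clusters.clusters:
        conv_restrict |= c["voxel_mask"]
    if not conv_restrict.any():
        logger.warning("no AD-vs-NC clusters survive; converter comparison on full GM")
        conv_restrict = gm.include
    is_mci = np.array([s.group == "MCI" for s in cohort.subjects])
    is_conv = np.array([s.is_converter for s in cohort.subjects])
    mci_c = [m for m, c, g in zip(fcs_maps, is_conv, is_mci) if g and c]
    mci_nc = [m for m, c, g in zip(fcs_maps, is_conv, is_mci) if g and not c]
    cov_mci = np.vstack([covariates[is_mci & is_conv], covariates[is_mci & ~is_conv]])
    conv_map = posthoc_t_map(mci_c, mci_nc, cov_mci, conv_restrict)
    save_vol(conv_map.values, "t_converter_vs_nonconverter.nii")
    conv_thr = conv_map.threshold_value(config.voxel_p)
    conv_clusters = extract_clusters(np.abs(conv_map.values), conv_thr,
                                     extent.min_extent_voxels, config.connectivity,
                                     voxel_volume_mm3=float(np.prod(vox)),
                                     mask=conv_restrict)

    # --- stage 5: seed-based connectivity ---------------------------------
    logger.info("stage seedfc: seed maps from converter-deficit clusters")
    if len(conv_clusters) >= 1:
        seed_masks = {f"cluster_{c['id']}": c["voxel_mask"]
                      for c in conv_clusters.clusters[:2]}
    else:
        logger.warning("no converter clusters survive; seeding from planted ROIs")
        seed_masks = {r.name: r.mask(spec.grid_dims) for r in spec.network_rois}
    seed_t_maps = {}
    for name, smask in seed_masks.items():
        zc = [seed_fc_map(b, seed_timecourse(b, smask), gm, seed_name=name)
              for b, g in zip(cleaned, is_mci) if g]
        z_conv = [m.values for m, c in zip(zc, is_conv[is_mci]) if c]
        z_nonc = [m.values for m, c in zip(zc, is_conv[is_mci]) if not c]
        positive_any = np.zeros(spec.grid_dims, bool)
        for group_maps in (z_conv, z_nonc):
            positive_any |= np.mean(group_maps, axis=0) > 0
        positive_any &= gm.include
        tmap = posthoc_t_map(z_conv, z_nonc, cov_mci, positive_any)
        seed_t_maps[name] = tmap
        save_vol(tmap.values, f"seedfc_t_{name}.nii")

    # --- stage 6: behavior association -------------------------------------
    logger.info("stage behavior: score association maps")
    patient = np.array([s.group in ("AD", "MCI") for s in cohort.subjects])
    behavior_mask = posthoc_mask
    for score_name in ("MMSE", "MoCA", "AVLT_I", "AVLT_D", "AVLT_R"):
        scores = table.loc[patient, score_name].to_numpy(float)
        maps_p = [m for m, p in zip(fcs_maps, patient) if p]
        bmap = behavior_association_map(maps_p, scores, covariates[patient],
                                        behavior_mask)
        save_vol(bmap.values, f"behavior_t_{score_name}.nii")

    # --- stage 7: discrimination -------------------------------------------
    logger.info("stage classify: LOOCV SVM on significant voxels")
    sig_mask = np.zeros(spec.grid_dims, bool)
    for c in conv_clusters.clusters:
        sig_mask |= c["voxel_mask"]
    if not sig_mask.any():
        logger.warning("no significant converter voxels; features from planted ROIs")
        for r in spec.network_rois:
            sig_mask |= r.mask(spec.grid_dims)
    feats = extract_features([m.values for m, g in zip(fcs_maps, is_mci) if g], sig_mask)
    labels = is_conv[is_mci].astype(int)
    clf = loocv_svm(feats, labels, kernel=config.svm_kernel, C=config.svm_C)

    # --- stage 8: validation suite -----------------------------------------
    logger.info("stage validate: robustness suite")
    report = run_validation_suite(cohort, gm_cutoff=config.gm_cutoff,
                                  band_hz=(config.low_hz, config.high_hz),
                                  fcs_mode=config.fcs_mode)
    report.to_frame().to_csv(out / "validation.tsv", sep="\t", index=False)
    artifacts.append(out / "validation.tsv")

    results = {
        "cluster_extent": {
            "min_extent_voxels": extent.min_extent_voxels,
            "min_extent_mm3": extent.min_extent_mm3,
            "voxel_p": extent.voxel_p,
            "alpha": extent.alpha,
        },
        "n_group_effect_clusters": len(f_clusters),
        "n_converter_clusters": len(conv_clusters),
        "classification": {
            "confusion": dataclasses.asdict(clf.confusion),
            "accuracy": clf.accuracy,
            "sensitivity": clf.sensitivity,
            "specificity": clf.specificity,
        },
        "mean_fd_mm": float(mean_fd.mean()),
    }
    fio.save_json(results, out / "results.json")
    artifacts.append(out / "results.json")
    # the saved config is location-independent so manifests of identical
    # runs hash identically wherever they were written
    dataclasses.replace(config, out_dir=".").to_yaml(out / "config.yaml")
    artifacts.append(out / "config.yaml")

    manifest = {
        "seeds": seeds,
        "master_seed": config.master_seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    fio.save_json(manifest, out / "manifest.json")
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return {"manifest": manifest, "results": results}
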