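"""Synthetic study generator for the CBTC-circuit pipeline.

Emulates the structure of a stroke case-control resting-state study so every
downstream stage (parcellation, FC extraction, group statistics,
classification, behavior prediction) is exercisable without imaging data:

* region BOLD-like series drawn from a multivariate normal whose correlation
  matrix places ``rho0`` on every manifest loop edge, lowered by ``delta`` on
  designated ipsilesional edges in patients (the group effect);
* Upper Extremity Fugl-Meyer scores (integers in [0, 66]) affinely coupled to
  the Fisher-z FC of designated behavior edges plus Gaussian noise;
* subcortical voxel connectivity profiles drawn from target-peaked Dirichlet
  distributions with planted subdivision labels, for the winner-take-all
  parcellation stage.

Across-subject FC variability arises from finite-length sampling of the
shared group correlation matrix; ages and sexes are cosmetic covariates.
All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fc as _fc
from .regions import (
    CORTICAL,
    HEMISPHERES,
    LoopManifest,
    SubjectRecord,
    default_manifest,
)

#: edges reported attenuated in the affected (R, ipsilesional) hemisphere
DEFAULT_AFFECTED_EDGES = (
    "long:R:DLPFC-THA_DLPFC",
    "short:R:CAU_M1-M1",
    "short:R:DLPFC-PUT_DLPFC",
)

#: (edge key, weight) pairs coupling FC to the motor score
DEFAULT_BEHAVIOR_EDGES = (
    ("short:R:CAU_M1-M1", 1.0),
    ("short:R:M1-PUT_M1", 1.0),
    ("short:L:DLPFC-PUT_DLPFC", 1.0),
    ("short:L:CAU_MPFC-MPFC", -1.0),
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the modelled study: 64 patients / 64 controls, baseline
    loop-edge correlation rho0 = 0.4 with a 0.15 ipsilesional decrement in
    patients on the three attenuated edges, and motor scores coupled to the
    four behavior edges (three positive, one negative).
    """

    n_patients: int = 64
    n_controls: int = 64
    n_timepoints: int = 200
    rho0: float = 0.4
    affected_edges: tuple[str, ...] = DEFAULT_AFFECTED_EDGES
    delta: float = 0.15
    behavior_edges: tuple[tuple[str, float], ...] = DEFAULT_BEHAVIOR_EDGES
    behavior_noise_sd: float = 4.0
    behavior_offset: float = -7.0
    behavior_scale: float = 40.0
    profile_concentration: float = 50.0
    voxels_per_subdivision: int = 40
    prob_lesion_left: float = 15 / 64  # left-lesion fraction in the modelled cohort
    seed: int = 0

    def validate(self, manifest: LoopManifest) -> None:
        if not (0 < self.rho0 < 1):
            raise ValueError("rho0 must be in (0, 1)")
        if not (0 <= self.delta < self.rho0):
            raise ValueError("delta must satisfy 0 <= delta < rho0")
        if self.profile_concentration <= 0:
            raise ValueError("profile_concentration must be positive")
        known = {e.key for e in manifest.edges}
        for key in list(self.affected_edges) + [k for k, _ in self.behavior_edges]:
            if key not in known:
                raise ValueError(f"edge {key!r} not in manifest")


@dataclass
class SyntheticDataset:
    subjects: list[SubjectRecord]
    series: dict[str, pd.DataFrame]                 # id -> regions x time
    profiles: dict[str, "ProfileSet"]               # "hemi:structure" -> profiles
    truth: SimulationConfig
    repair_perturbation: dict[str, float] = field(default_factory=dict)


@dataclass
class ProfileSet:
    """Voxel connectivity profiles for one subcortical structure with planted labels."""

    structure: str
    hemisphere: str
    targets: tuple[str, ...]
    probs: np.ndarray          # voxels x targets, rows sum to 1
    true_labels: np.ndarray    # voxel -> target index


def nearest_psd_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues and renormalise the diagonal to 1.

    Returns the repaired matrix and the largest absolute entry change.
    """
    sym = (mat + mat.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eig_floor:
        return sym, 0.0
    vals = np.clip(vals, eig_floor, None)
    rep = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(rep))
    rep = rep / np.outer(d, d)
    np.fill_diagonal(rep, 1.0)
    return rep, float(np.abs(rep - sym).max())


def build_target_correlation(manifest: LoopManifest, rho0: float, group: str,
                             affected_edges=(), delta: float = 0.0,
                             ) -> tuple[pd.DataFrame, float]:
    """Region correlation matrix with rho0 on loop edges, attenuated in patients.

    The matrix is indexed by region series keys (cortical + subdivision rows
    of both hemispheres).  Entries off the loop manifest are zero; the result
    is repaired to the nearest positive semidefinite correlation matrix.
    Returns (matrix, repair perturbation).
    """
    if not (0 < rho0 < 1):
        raise ValueError("rho0 must be in (0, 1)")
    regions = manifest.regions(("cortical", "subdivision"))
    keys = [_fc.region_series_key(r) for r in regions]
    idx = {k: i for i, k in enumerate(keys)}
    corr = np.eye(len(keys))
    affected = set(affected_edges)
    # a region pair shared by both loops has one physical correlation: if any
    # loop edge on the pair is designated affected, the pair is attenuated
    attenuated_pairs = {
        frozenset((_fc.region_series_key(e.a), _fc.region_series_key(e.b)))
        for e in manifest.edges_for("loops") if e.key in affected
    }
    for e in manifest.edges_for("loops"):
        pair = frozenset((_fc.region_series_key(e.a), _fc.region_series_key(e.b)))
        r = rho0 - delta if (group == "patient" and pair in attenuated_pairs) else rho0
        i, j = idx[_fc.region_series_key(e.a)], idx[_fc.region_series_key(e.b)]
        corr[i, j] = corr[j, i] = r
    target = corr.copy()
    repaired, perturb = nearest_psd_correlation(corr)
    edge_mask = target != np.eye(len(keys))
    if edge_mask.any():
        edge_shift = float(np.abs(repaired - target)[edge_mask].max())
        if edge_shift > 0.05:
            raise ValueError(
                f"PSD repair moved a targeted correlation by {edge_shift:.3f} (> 0.05); "
                "lower rho0 or sparsify the manifest"
            )
    return pd.DataFrame(repaired, index=keys, columns=keys), perturb


def simulate_timeseries(corr: pd.DataFrame | np.ndarray, n_timepoints: int,
                        seed: int | np.random.Generator) -> np.ndarray:
    """Regions x time draw from N(0, corr); deterministic under seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = np.asarray(corr, dtype=float)
    vals, vecs = np.linalg.eigh((c + c.T) / 2)
    if vals.min() < -1e-8:
        raise ValueError("correlation matrix is not positive semidefinite")
    root = vecs * np.sqrt(np.clip(vals, 0, None))
    white = rng.standard_normal((c.shape[0], n_timepoints))
    return root @ white


def simulate_behavior(fc_vector: pd.Series, behavior_edges, noise_sd: float,
                      offset: float, scale: float,
                      seed: int | np.random.Generator) -> int:
    """UE-FMA score: affine map of weighted edge z values plus noise, in [0, 66]."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signal = sum(w * fc_vector[key] for key, w in behavior_edges)
    raw = offset + scale * signal + rng.normal(0.0, noise_sd)
    return int(np.clip(np.round(raw), 0, 66))


def simulate_voxel_profiles(structure: str, cortical_targets, voxels_per_subdivision: int,
                            kappa: float, seed: int | np.random.Generator,
                            hemisphere: str = "R") -> ProfileSet:
    """Dirichlet voxel profiles with one planted subdivision per cortical target.

    Voxels of subdivision t are drawn from Dirichlet(alpha) with alpha_t =
    kappa and alpha_other = 1: large kappa concentrates probability mass on
    the true target, kappa = 1 is uninformative.
    """
    if kappa <= 0:
        raise ValueError("profile concentration kappa must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = tuple(cortical_targets)
    blocks, labels = [], []
    for t_idx, _ in enumerate(targets):
        alpha = np.ones(len(targets))
        alpha[t_idx] = kappa
        blocks.append(rng.dirichlet(alpha, size=voxels_per_subdivision))
        labels.extend([t_idx] * voxels_per_subdivision)
    return ProfileSet(structure, hemisphere, targets,
                      np.vstack(blocks), np.asarray(labels))


def simulate_cohort(config: SimulationConfig | None = None,
                    manifest: LoopManifest | None = None) -> SyntheticDataset:
    """Generate a full synthetic study: phenotypes, series, behavior, profiles."""
    config = config or SimulationConfig()
    manifest = manifest or default_manifest()
    config.validate(manifest)
    rng = np.random.default_rng(config.seed)

    corr_control, pert_c = build_target_correlation(
        manifest, config.rho0, "control", config.affected_edges, config.delta)
    corr_patient, pert_p = build_target_correlation(
        manifest, config.rho0, "patient", config.affected_edges, config.delta)
    keys = list(corr_control.index)
    behavior_edge_objs = [e for e in manifest.edges_for("loops")
                          if e.key in {k for k, _ in config.behavior_edges}]

    subjects: list[SubjectRecord] = []
    series: dict[str, pd.DataFrame] = {}
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    for i, group in enumerate(groups):
        sid = f"{'pat' if group == 'patient' else 'ctl'}{i:03d}"
        age = float(np.clip(rng.normal(57, 12), 30, 80))
        sex = "male" if rng.random() < 0.55 else "female"
        corr = corr_patient if group == "patient" else corr_control
        mat = simulate_timeseries(corr.to_numpy(), config.n_timepoints, rng)
        df = pd.DataFrame(mat, index=keys)
        series[sid] = df
        if group == "patient":
            lesion = "L" if rng.random() < config.prob_lesion_left else "R"
            # series are generated directly in the flipped frame (ipsilesional = R)
            zvec = _fc.fc_vector(df, behavior_edge_objs)
            fma = simulate_behavior(zvec, config.behavior_edges,
                                    config.behavior_noise_sd, config.behavior_offset,
                                    config.behavior_scale, rng)
            subjects.append(SubjectRecord(sid, "patient", age, sex, lesion_side=lesion,
                                          ue_fma=fma, flipped=(lesion == "L")))
        else:
            subjects.append(SubjectRecord(sid, "control", age, sex))

    profiles: dict[str, ProfileSet] = {}
    for hemi in HEMISPHERES:
        for structure in ("CAU", "PUT", "PAL", "THA"):
            profiles[f"{hemi}:{structure}"] = simulate_voxel_profiles(
                structure, CORTICAL, config.voxels_per_subdivision,
                config.profile_concentration, rng, hemisphere=hemi)

    return SyntheticDataset(subjects, series, profiles, replace(config),
                            repair_perturbation={"control": pert_c, "patient": pert_p})
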