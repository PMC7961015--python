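"""Synthetic DCIS cohort generator.

Emulates the statistical structure of a multiplexed-immunofluorescence DCIS
study cohort: 51 patients (13 with a later breast cancer event, BCE),
~1,500 segmented epithelial cells per patient drawn from six phenotype
archetypes over ER/HER2/cMET/SLC7A5, group-conditional patient cluster
profiles, slide batch effects, per-round exposure variation, and the QC
artifacts the filtering stage exists to remove (multi-nucleate cells,
out-of-range compartment areas, misregistered cells, low-DCIS fields of
view).

Raw linear intensities are synthesised by inverting the preprocessing chain
(z-space -> log2 intensity -> undo log2 -> undo exposure correction), so
running the preprocessing forward on generator output recovers the
generator's latent values exactly (up to tail capping and slide-median
centring), which makes preprocessing testable against ground truth.

Every random draw flows from the single ``seed`` via a
``numpy.random.Generator``; there is no hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .errors import ConfigurationError
from .preprocess import (MarkerPanel, default_panel, CLUSTERING_MARKERS,
                         NUCLEAR_MARKERS)

# ---------------------------------------------------------------------------
# archetypes


@dataclass(frozen=True)
class ClusterArchetype:
    """One cell-phenotype archetype in standardised marker space.

    ``mean_z``/``sd_z`` are over (ER, HER2, cMET, SLC7A5), in z-units of the
    standardised clustering matrix.
    """

    label: int
    mean_z: tuple[float, float, float, float]
    sd_z: tuple[float, float, float, float]

    def __post_init__(self):
        if len(self.mean_z) != 4 or len(self.sd_z) != 4:
            raise ConfigurationError("archetype mean_z/sd_z must be 4-vectors")
        if any(s <= 0 for s in self.sd_z):
            raise ConfigurationError("archetype sd_z must be strictly positive")


def default_archetypes(sd: float = 0.5) -> list[ClusterArchetype]:
    """Six archetypes over (ER, HER2, cMET, SLC7A5).

    1: all markers low. 2: ER high, rest low. 3: SLC7A5 high, HER2 low.
    4: ER and cMET high, HER2/SLC7A5 low. 5: HER2 and SLC7A5 high,
    cMET low-moderate, ER low. 6: HER2 high, rest low.
    """
    sds = (sd, sd, sd, sd)
    means = {
        1: (-1.0, -1.0, -1.0, -1.0),
        2: (1.5, -1.0, -1.0, -1.0),
        3: (0.0, -1.0, 0.0, 1.5),
        4: (1.5, -1.0, 1.5, -1.0),
        5: (-1.0, 1.5, -0.3, 1.5),
        6: (-1.0, 1.5, -1.0, -1.0),
    }
    archetypes = [ClusterArchetype(lab, means[lab], sds) for lab in sorted(means)]
    signs = [tuple(1 if m > 0.25 else (-1 if m < -0.25 else 0) for m in a.mean_z)
             for a in archetypes]
    if len(set(signs)) != len(signs):
        raise ConfigurationError("archetype high/low patterns are not distinct")
    return archetypes


#: Group-conditional expected cluster proportions (clusters 1..6).
#: Clusters 2/4/5/6 follow the reported group percentages; the remaining
#: mass is split equally between clusters 1 and 3, whose group shares were
#: not reported.
BCE_PROFILE_MEAN = (0.166, 0.030, 0.166, 0.063, 0.245, 0.330)
NON_BCE_PROFILE_MEAN = (0.230, 0.176, 0.230, 0.165, 0.085, 0.114)


@dataclass
class ArtifactRates:
    """Per-cell / per-FOV artifact injection probabilities."""

    multinucleate: float = 0.02
    bad_area: float = 0.02
    misregistered: float = 0.03
    low_dcis_fov: float = 0.10


@dataclass
class FollowupModel:
    """Follow-up time distributions (years).

    Non-BCE patients: Uniform(nonbce_min, nonbce_max).  BCE patients:
    Weibull(shape) scaled so the median event time is ``bce_median_years``,
    resampled to stay below ``bce_max_years``.
    """

    nonbce_min: float = 3.0
    nonbce_max: float = 17.0
    bce_median_years: float = 2.5
    bce_shape: float = 1.5
    bce_max_years: float = 10.0


@dataclass
class SimulationConfig:
    """Generator settings; defaults encode the study conditions."""

    n_patients: int = 51
    bce_fraction: float = 13 / 51
    cells_per_patient_mean: float = 2200.0
    #: negative-binomial dispersion (size); ``None`` = constant cell count
    cells_per_patient_dispersion: float | None = 5.0
    group_profile_means: tuple = (BCE_PROFILE_MEAN, NON_BCE_PROFILE_MEAN)
    profile_concentration: float = 1.0
    outcome_mode: str = "group_conditional"  # or "logistic"
    #: (intercept, slope on %C5&6, slope on %C2&4); percentage scale 0-100
    logistic_params: tuple[float, float, float] = (-15.0, 1.77, -2.78)
    n_slides: int = 8
    #: per-slide additive log2 shifts; ``None`` = drawn N(0, 0.25)
    slide_offsets: tuple | None = None
    #: actual-vs-reference exposure log-sd (per slide and round)
    exposure_jitter_sd: float = 0.15
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    followup: FollowupModel = field(default_factory=FollowupModel)
    n_background_markers: int = 4
    stromal_fraction: float = 0.2
    n_fovs_per_patient: int = 3
    cores_per_patient: int = 1
    archetype_sd: float = 0.5
    #: z -> log2-intensity mapping: log2 = log2_mean + log2_scale * z
    log2_mean: float = 8.0
    log2_scale: float = 1.0
    er_pr_correlation: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not 0.0 <= self.bce_fraction <= 1.0:
            raise ConfigurationError("bce_fraction must be in [0, 1]")
        if self.cells_per_patient_mean < 1:
            raise ConfigurationError("cells_per_patient_mean must be >= 1")
        gm = np.asarray(self.group_profile_means, dtype=float)
        if gm.shape != (2, 6):
            raise ConfigurationError("group_profile_means must be 2 rows of 6")
        if np.any(gm < 0) or np.any(np.abs(gm.sum(axis=1) - 1.0) > 1e-9):
            raise ConfigurationError(
                "group_profile_means rows must be nonnegative and sum to 1")
        if self.profile_concentration <= 0:
            raise ConfigurationError("profile_concentration must be > 0")
        if self.outcome_mode not in ("group_conditional", "logistic"):
            raise ConfigurationError(
                f"outcome_mode {self.outcome_mode!r} is not a valid mode")
        for name in ("multinucleate", "bad_area", "misregistered", "low_dcis_fov"):
            rate = getattr(self.artifact_rates, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"artifact_rates.{name} must be in [0, 1]")
        if not 0.0 <= self.stromal_fraction < 1.0:
            raise ConfigurationError("stromal_fraction must be in [0, 1)")
        if self.n_slides < 1:
            raise ConfigurationError("n_slides must be >= 1")
        if self.slide_offsets is not None and len(self.slide_offsets) != self.n_slides:
            raise ConfigurationError("slide_offsets length must equal n_slides")
        if self.cores_per_patient < 1:
            raise ConfigurationError("cores_per_patient must be >= 1")
        if not -1.0 < self.er_pr_correlation < 1.0:
            raise ConfigurationError("er_pr_correlation must be in (-1, 1)")
        if self.archetype_sd <= 0:
            raise ConfigurationError("archetype_sd must be > 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "artifact_rates" in d and isinstance(d["artifact_rates"], dict):
            d["artifact_rates"] = ArtifactRates(**d["artifact_rates"])
        if "followup" in d and isinstance(d["followup"], dict):
            d["followup"] = FollowupModel(**d["followup"])
        for key in ("group_profile_means", "logistic_params", "slide_offsets"):
            if d.get(key) is not None:
                d[key] = tuple(tuple(v) if isinstance(v, list) else v
                               for v in d[key])
        return cls(**d)


def logistic_mode_config(**overrides) -> SimulationConfig:
    """Preset for the logistic outcome mode.

    Profiles are drawn from a pooled Dirichlet whose concentration keeps a
    usable fraction of patients near the decision boundary (otherwise the
    steep published slopes make almost every outcome deterministic and the
    slopes are not statistically recoverable); the intercept is set for a
    roughly 25% event rate at that spread.
    """
    defaults = dict(outcome_mode="logistic", profile_concentration=1500.0,
                    logistic_params=(-11.4, 1.77, -2.78))
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class TruthRecord:
    """Ground truth stored alongside a generated cohort."""

    cell_clusters: pd.Series  # 1..6 for epithelial, 0 otherwise
    patient_profiles: pd.DataFrame  # patients x 6, true Dirichlet draws
    outcomes: pd.Series  # patient -> bool BCE
    slide_offsets: np.ndarray
    artifact_flags: pd.DataFrame  # per-cell booleans
    true_log2: pd.DataFrame  # latent log2 value per analysis marker
    true_z: pd.DataFrame  # archetype-space draws, clustering markers


@dataclass
class Cohort:
    cells: pd.DataFrame
    patients: pd.DataFrame
    fovs: pd.DataFrame
    truth: TruthRecord
    panel: MarkerPanel
    config: SimulationConfig

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "cells.csv", index=False)
        self.patients.to_csv(outdir / "patients.csv", index=False)
        self.fovs.to_csv(outdir / "fovs.csv", index=False)
        self.panel.to_csv(outdir / "panel.csv")
        self.config.to_yaml(outdir / "config.yaml")
        truth_cells = pd.DataFrame({
            "cell_id": self.cells["cell_id"],
            "true_cluster": self.truth.cell_clusters.to_numpy(),
        })
        truth_cells.to_csv(outdir / "truth_cells.csv", index=False)
        self.truth.patient_profiles.to_csv(outdir / "truth_profiles.csv")
        with open(outdir / "truth.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({
                "slide_offsets": [float(v) for v in self.truth.slide_offsets],
                "outcomes": {k: bool(v)
                             for k, v in self.truth.outcomes.items()},
                "seed": self.config.seed,
            }, fh)


# ---------------------------------------------------------------------------
# patient-level sampling


def _draw_outcomes(rng, n: int, fraction: float) -> np.ndarray:
    """BCE indicator per patient.

    When ``n * fraction`` is integral the split is exact (a random subset of
    that size), matching a cohort recruited to a fixed group design;
    otherwise outcomes are i.i.d. Bernoulli.
    """
    expected = n * fraction
    if abs(expected - round(expected)) < 1e-9:
        k = int(round(expected))
        outcome = np.zeros(n, dtype=bool)
        outcome[rng.choice(n, size=k, replace=False)] = True
        return outcome
    return rng.random(n) < fraction


def sample_patient_profiles(config: SimulationConfig,
                            rng: np.random.Generator | None = None):
    """Draw per-patient outcomes and true cluster profiles (no cells).

    Returns ``(profiles (n, 6), outcomes (n,) bool)``.  In
    ``group_conditional`` mode the outcome is drawn first and the profile
    from the outcome group's Dirichlet; in ``logistic`` mode profiles come
    from the pooled Dirichlet and outcomes from
    ``Bernoulli(expit(b0 + b1 * %C5&6 + b2 * %C2&4))``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    gm = np.asarray(config.group_profile_means, dtype=float)
    conc = config.profile_concentration
    if config.outcome_mode == "group_conditional":
        outcomes = _draw_outcomes(rng, n, config.bce_fraction)
        profiles = np.empty((n, 6))
        for grp, mean in ((True, gm[0]), (False, gm[1])):
            mask = outcomes == grp
            if mask.any():
                profiles[mask] = rng.dirichlet(conc * mean, size=int(mask.sum()))
    else:
        pooled = gm.mean(axis=0)
        profiles = rng.dirichlet(conc * pooled, size=n)
        b0, b1, b2 = config.logistic_params
        x1 = 100.0 * (profiles[:, 4] + profiles[:, 5])
        x2 = 100.0 * (profiles[:, 1] + profiles[:, 3])
        outcomes = rng.random(n) < expit(b0 + b1 * x1 + b2 * x2)
    return profiles, outcomes


def _draw_followup(rng, outcomes: np.ndarray, fm: FollowupModel) -> np.ndarray:
    n = len(outcomes)
    followup = rng.uniform(fm.nonbce_min, fm.nonbce_max, size=n)
    n_bce = int(outcomes.sum())
    if n_bce:
        scale = fm.bce_median_years / np.log(2.0) ** (1.0 / fm.bce_shape)
        times = scale * rng.weibull(fm.bce_shape, size=n_bce)
        # resample the rare draws at/over the event-time cap
        for _ in range(1000):
            bad = times >= fm.bce_max_years
            if not bad.any():
                break
            times[bad] = scale * rng.weibull(fm.bce_shape, size=int(bad.sum()))
        times = np.clip(times, 0.05, fm.bce_max_years - 1e-6)
        followup[outcomes] = times
    return followup


# ---------------------------------------------------------------------------
# full cohort


def generate_cohort(config: SimulationConfig,
                    panel: MarkerPanel | None = None,
                    archetypes: list[ClusterArchetype] | None = None) -> Cohort:
    """Generate a full synthetic cohort (cells, patients, FOVs, truth).

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = default_panel(config.n_background_markers)
    if archetypes is None:
        archetypes = default_archetypes(config.archetype_sd)
    if len(archetypes) != 6:
        raise ConfigurationError("generator requires exactly 6 archetypes")

    n_pat = config.n_patients
    patient_ids = np.array([f"P{i + 1:03d}" for i in range(n_pat)])
    profiles, outcomes = sample_patient_profiles(config, rng)
    followup = _draw_followup(rng, outcomes, config.followup)
    slides = np.arange(n_pat) % config.n_slides
    slide_ids = np.array([f"S{s + 1}" for s in range(config.n_slides)])

    if config.slide_offsets is None:
        slide_offsets = rng.normal(0.0, 0.25, size=config.n_slides)
    else:
        slide_offsets = np.asarray(config.slide_offsets, dtype=float)

    rounds = panel.rounds
    ref_exposure = {r: panel.reference_exposure(r) for r in rounds}
    # actual exposure per (slide, round): reference x lognormal jitter
    expo_factor = np.exp(rng.normal(0.0, config.exposure_jitter_sd,
                                    size=(config.n_slides, len(rounds))))
    actual_exposure = {r: ref_exposure[r] * expo_factor[:, j]
                       for j, r in enumerate(rounds)}

    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "bce": outcomes,
        "followup_years": followup,
        "hormone_therapy": rng.random(n_pat) < 0.56,
        "radiotherapy": rng.random(n_pat) < 0.74,
        "surgery": True,
        "age": rng.integers(34, 76, size=n_pat),
        "grade": rng.integers(1, 4, size=n_pat),
        "slide_id": slide_ids[slides],
    })

    # ---- FOVs
    fov_rows = []
    for i, pid in enumerate(patient_ids):
        for j in range(config.n_fovs_per_patient):
            low = rng.random() < config.artifact_rates.low_dcis_fov
            pct_dcis = rng.uniform(5.0, 45.0) if low else rng.uniform(55.0, 95.0)
            fov_rows.append((f"{pid}_F{j + 1}", pid, slide_ids[slides[i]],
                             pct_dcis, 100.0 - pct_dcis, True, low))
    fovs = pd.DataFrame(fov_rows, columns=[
        "fov_id", "patient_id", "slide_id", "pct_dcis", "pct_normal",
        "manual_quality_pass", "is_low_dcis_truth"])

    # ---- cells
    mean = config.cells_per_patient_mean
    disp = config.cells_per_patient_dispersion
    if disp is None or not np.isfinite(disp):
        counts = np.full(n_pat, int(round(mean)))
    else:
        p = disp / (disp + mean)
        counts = np.maximum(rng.negative_binomial(disp, p, size=n_pat), 1)
    n_cells = int(counts.sum())
    pat_idx = np.repeat(np.arange(n_pat), counts)

    epithelial = rng.random(n_cells) >= config.stromal_fraction
    # true cluster per epithelial cell from the patient's profile
    cum = np.cumsum(profiles, axis=1)
    u = rng.random(n_cells)
    clusters = 1 + (u[:, None] > cum[pat_idx]).sum(axis=1)
    clusters = np.minimum(clusters, 6)
    clusters[~epithelial] = 0

    arch_means = np.array([a.mean_z for a in archetypes])
    arch_sds = np.array([a.sd_z for a in archetypes])
    z = np.where(epithelial[:, None],
                 arch_means[np.maximum(clusters - 1, 0)], -1.0)
    sd = np.where(epithelial[:, None],
                  arch_sds[np.maximum(clusters - 1, 0)], 0.5)
    z = z + sd * rng.standard_normal((n_cells, 4))

    # latent log2 values per analysis marker
    clus_idx = {m: i for i, m in enumerate(CLUSTERING_MARKERS)}
    log2_vals = {}
    rho = config.er_pr_correlation
    for spec in panel:
        if spec.role == "segmentation_only":
            continue
        if spec.name in clus_idx:
            zz = z[:, clus_idx[spec.name]]
        elif spec.name == "PR":
            zz = rho * z[:, clus_idx["ER"]] + np.sqrt(1 - rho ** 2) \
                * rng.standard_normal(n_cells)
        else:
            # background marker: lognormal intensity with patient-level shift
            shift = rng.normal(0.0, 0.5, size=n_pat)
            zz = shift[pat_idx] + 0.7 * rng.standard_normal(n_cells)
        log2_vals[spec.name] = config.log2_mean + config.log2_scale * zz
    log2_df = pd.DataFrame(log2_vals)
    # slide batch effect: additive log2 shift, all markers alike
    log2_df = log2_df.add(slide_offsets[slides[pat_idx]], axis=0)

    # artifact flags
    ar = config.artifact_rates
    multinuc = rng.random(n_cells) < ar.multinucleate
    bad_area = rng.random(n_cells) < ar.bad_area
    misreg = rng.random(n_cells) < ar.misregistered

    n_nuclei = 1 + (rng.random(n_cells) < 0.15).astype(int)
    n_nuclei[multinuc] = rng.integers(3, 6, size=int(multinuc.sum()))

    areas = {}
    for comp in ("nucleus", "membrane", "cytoplasm"):
        a = np.exp(rng.normal(np.log(250.0), 0.35, size=n_cells))
        areas[comp] = np.clip(a, 15.0, 1400.0)
    # out-of-range artifact: one random compartment goes tiny or huge
    comp_pick = rng.integers(0, 3, size=n_cells)
    too_small = rng.random(n_cells) < 0.5
    for ci, comp in enumerate(("nucleus", "membrane", "cytoplasm")):
        hit = bad_area & (comp_pick == ci)
        vals = areas[comp]
        vals[hit & too_small] = rng.uniform(1.0, 10.0, size=int((hit & too_small).sum()))
        vals[hit & ~too_small] = rng.uniform(1500.0, 3000.0,
                                             size=int((hit & ~too_small).sum()))

    qc = {r: np.ones(n_cells) for r in rounds}
    round_pick = rng.integers(0, len(rounds), size=n_cells)
    for j, r in enumerate(rounds):
        hit = misreg & (round_pick == j)
        qc[r][hit] = rng.uniform(0.2, 0.95, size=int(hit.sum()))

    # FOV assignment within patient, core label(s)
    fov_j = rng.integers(0, config.n_fovs_per_patient, size=n_cells)
    core_j = rng.integers(0, config.cores_per_patient, size=n_cells)

    cells = pd.DataFrame({
        "cell_id": [f"{patient_ids[p]}_C{i:06d}"
                    for i, p in enumerate(pat_idx)],
        "patient_id": patient_ids[pat_idx],
        "slide_id": slide_ids[slides[pat_idx]],
        "fov_id": [f"{patient_ids[p]}_F{f + 1}"
                   for p, f in zip(pat_idx, fov_j)],
        "core_id": [f"{patient_ids[p]}-{chr(ord('A') + c)}"
                    for p, c in zip(pat_idx, core_j)],
        "tissue_class": np.where(epithelial, "epithelial", "stromal"),
        "n_nuclei": n_nuclei,
        "area_nucleus_px": areas["nucleus"],
        "area_membrane_px": areas["membrane"],
        "area_cytoplasm_px": areas["cytoplasm"],
    })
    for r in rounds:
        cells[f"qc_score_r{r}"] = qc[r]
        cells[f"exposure_r{r}_ms"] = actual_exposure[r][slides[pat_idx]]

    # raw intensities: invert log2 then invert exposure correction
    for spec in panel:
        if spec.name not in log2_df.columns:
            continue
        v = log2_df[spec.name].to_numpy()
        corrected = np.maximum(np.exp2(v) - 1.0, 0.0)
        raw = corrected * actual_exposure[spec.round][slides[pat_idx]] \
            / ref_exposure[spec.round]
        primary = "nuclear" if spec.summarization == "nuclear_median" else "cell"
        secondary = "cell" if primary == "nuclear" else "nuclear"
        cells[f"{spec.name}_{primary}_median"] = raw
        # the unused compartment readout: correlated but noisier
        v2 = v + 0.3 * rng.standard_normal(n_cells)
        cells[f"{spec.name}_{secondary}_median"] = \
            np.maximum(np.exp2(v2) - 1.0, 0.0) \
            * actual_exposure[spec.round][slides[pat_idx]] / ref_exposure[spec.round]

    cell_index = pd.Index(cells["cell_id"])
    low_fovs = set(fovs.loc[fovs["is_low_dcis_truth"], "fov_id"])
    truth = TruthRecord(
        cell_clusters=pd.Series(clusters, index=cell_index, name="true_cluster"),
        patient_profiles=pd.DataFrame(
            profiles, index=pd.Index(patient_ids, name="patient_id"),
            columns=[f"cluster_{c}" for c in range(1, 7)]),
        outcomes=pd.Series(outcomes, index=patient_ids, name="bce"),
        slide_offsets=slide_offsets,
        artifact_flags=pd.DataFrame({
            "multinucleate": multinuc,
            "bad_area": bad_area,
            "misregistered": misreg,
            "low_dcis_fov": cells["fov_id"].isin(low_fovs).to_numpy(),
            "stromal": ~epithelial,
        }, index=cell_index),
        true_log2=log2_df.set_index(cell_index),
        true_z=pd.DataFrame(z, index=cell_index, columns=list(CLUSTERING_MARKERS)),
    )
    return Cohort(cells=cells, patients=patients, fovs=fovs, truth=truth,
                  panel=panel, config=config)


# ---------------------------------------------------------------------------
# nuclear patches for registration scoring


def generate_nuclear_patches(cell_ids, offsets, seed: int,
                             patch_size: int = 32, n_rounds: int = 1,
                             noise_sd: float = 0.0):
    """Paired baseline/round DAPI-like patches per cell.

    For each cell a smooth random intensity field is synthesised; the
    baseline patch and each round patch are windows of that field displaced
    by the cell's misregistration ``offset`` (pixels).  Offset 0 yields
    identical patches; larger offsets yield lower correlation on average.

    Returns ``{cell_id: (baseline, [round patches])}``.
    """
    from scipy.ndimage import gaussian_filter

    offsets = np.asarray(offsets, dtype=int)
    if np.any(offsets < 0):
        raise ConfigurationError("misregistration offsets must be >= 0")
    if offsets.shape == ():
        offsets = np.full(len(cell_ids), int(offsets))
    if len(offsets) != len(cell_ids):
        raise ConfigurationError("offsets must match cell_ids in length")
    rng = np.random.default_rng(seed)
    out = {}
    for cid, off in zip(cell_ids, offsets):
        canvas = rng.standard_normal((patch_size + int(off),) * 2)
        canvas = gaussian_filter(canvas, sigma=2.5)
        baseline = canvas[:patch_size, :patch_size].copy()
        rounds = []
        for _ in range(n_rounds):
            patch = canvas[off:off + patch_size, off:off + patch_size].copy()
            if noise_sd > 0:
                patch = patch + noise_sd * rng.standard_normal(patch.shape)
            rounds.append(patch)
        out[cid] = (baseline, rounds)
    return out
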