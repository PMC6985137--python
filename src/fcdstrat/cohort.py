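"""Seeded synthetic cohort with the statistical structure the analysis assumes.

The generator emulates a four-site premanifest Huntington's disease (pre-HD)
imaging study: ~150 subjects in two groups (gene carriers before motor
diagnosis, and controls), two resting-state imaging visits each, and a
battery of 10 cognitive/motor tasks with 2-7 yearly scores per subject whose
longitudinal slopes covary through a latent decline factor.  BOLD series are
linear mixtures of shared network latents, subject-stable fingerprint
latents, a decline-linked hub latent whose loading breadth grows with the
latent decline factor, a site-specific latent, a motion-locked artifact and
white noise, plus a small set of high-variance physiological-noise voxels
for tCompCor to find.  Grey-matter-concentration (GMC) maps carry an
optional decline-linked atrophy effect.

Every generator is a pure function of (config, seed); the latent decline
factor is emitted only as ground truth and never consumed by analysis
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fcd import BoldSeries

__all__ = [
    "TaskSpec",
    "CohortConfig",
    "SubjectRecord",
    "CohortStructure",
    "default_tasks",
    "compute_cap",
    "generate_cohort",
    "generate_task_scores",
    "generate_bold",
    "iter_bold",
    "generate_gmc",
    "cohort_structure",
]

# CAG-age product, normalized so that expected motor onset sits near 100.
CAP_OFFSET = 35.5
CAP_DENOM = 627.0


def compute_cap(age: float, cag: int | float) -> float:
    """Disease-burden score: 100 * age * (CAG - 35.5) / 627."""
    return 100.0 * age * (cag - CAP_OFFSET) / CAP_DENOM


@dataclass(frozen=True)
class TaskSpec:
    """Generative model of one cognitive/motor task.

    Scores follow ``baseline + slope * t + noise`` per subject, with
    ``slope = decline_sign * (aging_slope + sex_offset * is_male +
    loading_on_latent * latent_decline)`` in the task's raw units.
    ``decline_sign`` records the orientation convention: after multiplying
    slopes by it, a negative slope indicates decline for every task.
    """

    name: str
    loading_on_latent: float = -1.0      # oriented units/yr per unit latent
    aging_slope_per_year: float = -0.05  # oriented units/yr
    sex_offset: float = 0.0              # oriented units/yr, added for males
    noise_sd: float = 1.0                # observation noise, raw units
    baseline_mean: float = 50.0
    baseline_sd: float = 8.0
    decline_sign: int = 1
    visit_count_range: tuple[int, int] = (2, 7)

    def __post_init__(self):
        lo, hi = self.visit_count_range
        if not (2 <= lo <= hi <= 7):
            raise ValueError("visit_count_range must lie within [2, 7]")


def default_tasks() -> list[TaskSpec]:
    """The 10-task battery, with decline sensitivity concentrated in the
    timed symbol/attention tasks and two error-count measures that grow
    (rather than shrink) as performance deteriorates."""
    return [
        TaskSpec("sdmt", loading_on_latent=-2.0, aging_slope_per_year=-0.30,
                 noise_sd=1.2, baseline_mean=50, baseline_sd=8),
        TaskSpec("cancelation", loading_on_latent=-1.6, aging_slope_per_year=-0.25,
                 noise_sd=1.2, baseline_mean=40, baseline_sd=6),
        TaskSpec("paced_tapping", loading_on_latent=-1.4, aging_slope_per_year=-0.10,
                 noise_sd=1.3, baseline_mean=30, baseline_sd=5),
        TaskSpec("stroop", loading_on_latent=-1.2, aging_slope_per_year=-0.35,
                 noise_sd=1.4, baseline_mean=100, baseline_sd=12),
        # error-count measures: raw scores rise as performance worsens
        # (decline_sign = -1); loadings are in oriented units, so they are
        # negative here like every other task
        TaskSpec("indirect_circle_trace", loading_on_latent=-1.0,
                 aging_slope_per_year=-0.10, noise_sd=1.5, baseline_mean=10,
                 baseline_sd=3, decline_sign=-1),
        TaskSpec("grip_variability", loading_on_latent=-0.8,
                 aging_slope_per_year=-0.05, sex_offset=-0.05, noise_sd=1.6,
                 baseline_mean=5, baseline_sd=1.5, decline_sign=-1),
        TaskSpec("map_search", loading_on_latent=-0.7, aging_slope_per_year=-0.20,
                 noise_sd=1.6, baseline_mean=60, baseline_sd=9),
        TaskSpec("spot_change", loading_on_latent=-0.6, aging_slope_per_year=-0.15,
                 noise_sd=1.7, baseline_mean=20, baseline_sd=4),
        TaskSpec("mental_rotation", loading_on_latent=-0.5,
                 aging_slope_per_year=-0.15, sex_offset=0.05, noise_sd=1.7,
                 baseline_mean=25, baseline_sd=5),
        TaskSpec("count_backwards", loading_on_latent=-0.4,
                 aging_slope_per_year=-0.10, noise_sd=1.8, baseline_mean=15,
                 baseline_sd=4),
    ]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort."""

    n_controls: int = 79
    n_prehd: int = 74
    n_sites: int = 4
    seed: int = 0

    # demographics (cohort-level targets)
    control_age_mean: float = 49.0
    control_age_sd: float = 11.0
    prehd_age_mean: float = 42.0
    prehd_age_sd: float = 10.0
    age_range: tuple[float, float] = (23.0, 65.0)
    control_female_frac: float = 30 / 79
    prehd_female_frac: float = 34 / 74
    cag_mean: float = 43.0
    cag_sd: float = 2.0
    cag_range: tuple[int, int] = (39, 50)

    # latent decline factor (pre-HD only; controls are 0)
    latent_mean: float = 1.0
    latent_sd: float = 0.5
    latent_cap_coupling: float = 0.3
    n_latent_factors: int = 1   # extra orthogonal decline factors if > 1

    # effect scales
    site_effect_scale: float = 0.4
    motion_effect_scale: float = 0.5
    # mild by default: grey-matter maps alone should carry little group
    # signal, mirroring the weak atrophy-only discrimination seen in early
    # premanifest cohorts
    atrophy_effect_scale: float = 0.02
    fingerprint_strength: float = 0.6
    group_effect_strength: float = 0.5
    decline_hub_strength: float = 1.0

    # BOLD geometry
    n_voxels: int = 1000
    n_frames: int = 165          # raw frames, before trimming
    tr_seconds: float = 3.0
    n_networks: int = 5
    hub_fraction: float = 0.10
    noise_voxel_fraction: float = 0.03
    network_amplitude: float = 2.0
    hub_base_loading: float = 0.6
    physio_leak: float = 0.3
    # physiological (CSF-like) voxels must stay the highest-variance
    # compartment so the tCompCor variance mask isolates them and not the
    # neural hub signal
    noise_voxel_sd: float = 5.0

    # motion
    fd_mean_log: float = float(np.log(0.12))
    fd_log_sd: float = 0.4

    tasks: list[TaskSpec] = field(default_factory=default_tasks)

    def __post_init__(self):
        if min(self.n_controls, self.n_prehd, self.n_sites) <= 0:
            raise ValueError("counts must be positive")
        for name in ("site_effect_scale", "motion_effect_scale",
                     "atrophy_effect_scale", "fingerprint_strength",
                     "group_effect_strength", "decline_hub_strength"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_voxels < 50:
            raise ValueError("n_voxels too small (need >= 50)")
        if self.n_frames < 25:
            raise ValueError("n_frames too small (need >= 25)")
        if not (0 < self.control_female_frac < 1 and 0 < self.prehd_female_frac < 1):
            raise ValueError("female fractions must lie in (0, 1)")
        if self.cag_sd <= 0 or self.control_age_sd <= 0 or self.prehd_age_sd <= 0:
            raise ValueError("distribution scales must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        side = int(np.ceil(self.n_voxels ** (1.0 / 3.0)))
        return (side, side, int(np.ceil(self.n_voxels / side**2)))


@dataclass
class SubjectRecord:
    subject_id: str
    site: int
    group: str                   # "control" | "preHD"
    sex: str                     # "F" | "M"
    age: float                   # years at first functional image
    cag: int | None              # pre-HD only
    cap: float | None
    latent_decline: float        # ground truth, never an analysis input
    extra_latents: tuple = ()    # additional orthogonal decline factors
    fd_mean: dict = field(default_factory=dict)  # visit -> mm/frame

    @property
    def is_prehd(self) -> bool:
        return self.group == "preHD"


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Draw demographics, genetics, latent decline and per-visit motion."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records: list[SubjectRecord] = []
    n_total = config.n_controls + config.n_prehd
    # Balanced random site assignment across the whole cohort.
    sites = np.concatenate([np.arange(config.n_sites)] *
                           int(np.ceil(n_total / config.n_sites)))[:n_total]
    rng.shuffle(sites)

    idx = 0
    for group, n, age_mu, age_sd, f_frac in (
        ("control", config.n_controls, config.control_age_mean,
         config.control_age_sd, config.control_female_frac),
        ("preHD", config.n_prehd, config.prehd_age_mean,
         config.prehd_age_sd, config.prehd_female_frac),
    ):
        for _ in range(n):
            age = float(np.clip(rng.normal(age_mu, age_sd), *config.age_range))
            sex = "F" if rng.random() < f_frac else "M"
            if group == "preHD":
                cag = int(np.clip(round(rng.normal(config.cag_mean, config.cag_sd)),
                                  *config.cag_range))
                cap = compute_cap(age, cag)
            else:
                cag, cap = None, None
            fd = {v: float(np.exp(rng.normal(config.fd_mean_log, config.fd_log_sd)))
                  for v in (1, 2)}
            records.append(SubjectRecord(
                subject_id=f"sub-{idx:03d}", site=int(sites[idx]), group=group,
                sex=sex, age=age, cag=cag, cap=cap, latent_decline=0.0,
                fd_mean=fd,
            ))
            idx += 1

    # Latent decline for pre-HD, partially coupled to disease burden (CAP).
    prehd_idx = [i for i, r in enumerate(records) if r.is_prehd]
    caps = np.array([records[i].cap for i in prehd_idx])
    z_cap = (caps - caps.mean()) / caps.std() if caps.std() > 0 else np.zeros(len(prehd_idx))
    rho = config.latent_cap_coupling
    for j, i in enumerate(prehd_idx):
        eps = rng.normal()
        latent = config.latent_mean + config.latent_sd * (
            rho * z_cap[j] + np.sqrt(max(0.0, 1 - rho**2)) * eps)
        extras = tuple(rng.normal(0.0, config.latent_sd)
                       for _ in range(max(0, config.n_latent_factors - 1)))
        records[i] = replace(records[i], latent_decline=float(latent),
                             extra_latents=extras)
    return records


def generate_task_scores(cohort: list[SubjectRecord], config: CohortConfig,
                         seed: int) -> pd.DataFrame:
    """Long-format task panel: one row per subject/task/visit.

    Visit counts are drawn uniformly from each task's ``visit_count_range``
    per subject-task; visit times are yearly from the first visit.  Raw
    scores carry the task's native orientation (``decline_sign`` flips
    error-count tasks where deterioration raises the score).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    rows = []
    t0 = pd.Timestamp("2010-01-01")
    for r in cohort:
        male = 1.0 if r.sex == "M" else 0.0
        for task in config.tasks:
            lo, hi = task.visit_count_range
            k = int(rng.integers(lo, hi + 1))
            baseline = rng.normal(task.baseline_mean, task.baseline_sd)
            oriented_slope = (task.aging_slope_per_year
                              + task.sex_offset * male
                              + task.loading_on_latent * r.latent_decline)
            for visit in range(k):
                t = float(visit)
                score = (baseline
                         + task.decline_sign * oriented_slope * t
                         + rng.normal(0.0, task.noise_sd))
                rows.append({
                    "subject_id": r.subject_id, "site": r.site,
                    "group": r.group, "sex": r.sex, "age": r.age,
                    "cag": r.cag if r.cag is not None else np.nan,
                    "task": task.name,
                    "visit_date": (t0 + pd.Timedelta(days=round(t * 365.25))
                                   ).strftime("%Y-%m-%d"),
                    "time_years": t,
                    "score": float(score),
                })
    return pd.DataFrame(rows)


@dataclass
class CohortStructure:
    """Fixed spatial ground truth shared by all scans of a cohort."""

    coords: np.ndarray
    shape: tuple[int, int, int]
    network_of_voxel: np.ndarray   # -1 where not in a shared network
    hub_voxels: np.ndarray         # indices of the decline-linked hub set
    hub_breadth: np.ndarray        # per-hub-voxel loading multiplier
    hub_onset: np.ndarray          # per-hub-voxel latent level that recruits it
    group_voxels: np.ndarray       # pre-HD signature set (pallidal analogue)
    noise_voxels: np.ndarray       # physiological high-variance set
    site_pattern: np.ndarray       # per-voxel site-latent loading shape
    motion_pattern: np.ndarray     # per-voxel motion-artifact loading
    atrophy_voxels: np.ndarray     # GMC decline-linked region
    fingerprint_loadings: dict = field(default_factory=dict)  # subject -> (V,)


def cohort_structure(cohort: list[SubjectRecord], config: CohortConfig,
                     seed: int) -> CohortStructure:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    V = config.n_voxels
    shape = config.grid_shape
    full = np.indices(shape).reshape(3, -1).T
    coords = full[:V]

    perm = rng.permutation(V)
    n_noise = max(1, int(round(config.noise_voxel_fraction * V)))
    n_hub = max(2, int(round(config.hub_fraction * V)))
    n_group = max(2, int(round(0.05 * V)))
    noise_voxels = np.sort(perm[:n_noise])
    hub_voxels = np.sort(perm[n_noise:n_noise + n_hub])
    group_voxels = np.sort(perm[n_noise + n_hub:n_noise + n_hub + n_group])
    rest = np.sort(perm[n_noise + n_hub + n_group:])

    network_of_voxel = np.full(V, -1, dtype=int)
    net_ids = np.arange(len(rest)) % config.n_networks
    rng.shuffle(net_ids)
    network_of_voxel[rest] = net_ids

    hub_breadth = rng.uniform(0.5, 1.5, size=n_hub)
    # Recruitment thresholds: the number of hub voxels with decline-driven
    # loading grows with the latent factor (loading *breadth*, not just
    # amplitude, scales with decline), so the planted effect does not
    # saturate once pairwise correlations cross the link threshold.
    hub_onset = rng.uniform(0.0, 2.5, size=n_hub)
    site_pattern = rng.normal(0.0, 1.0, size=V)
    motion_pattern = np.abs(rng.normal(0.0, 1.0, size=V))
    # Atrophy region overlaps the hub set plus surrounding voxels.
    atrophy_voxels = np.union1d(hub_voxels, rng.choice(rest, size=n_hub, replace=False))

    fingerprints = {r.subject_id: rng.normal(0.0, 1.0, size=V) for r in cohort}
    return CohortStructure(
        coords=coords, shape=shape, network_of_voxel=network_of_voxel,
        hub_voxels=hub_voxels, hub_breadth=hub_breadth, hub_onset=hub_onset,
        group_voxels=group_voxels, noise_voxels=noise_voxels,
        site_pattern=site_pattern, motion_pattern=motion_pattern,
        atrophy_voxels=atrophy_voxels, fingerprint_loadings=fingerprints,
    )


def _scan_rng(seed: int, subject_index: int, visit: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, 4, subject_index, visit]))


def _simulate_scan(record: SubjectRecord, subject_index: int, visit: int,
                   structure: CohortStructure, config: CohortConfig,
                   seed: int) -> BoldSeries:
    rng = _scan_rng(seed, subject_index, visit)
    V, T = config.n_voxels, config.n_frames
    X = rng.normal(0.0, 1.0, size=(V, T))          # white noise floor

    def latent() -> np.ndarray:
        return rng.normal(0.0, 1.0, size=T)

    # Shared networks: disjoint voxel sets driven by common time courses.
    for k in range(config.n_networks):
        members = structure.network_of_voxel == k
        if members.any():
            X[members] += config.network_amplitude * latent()

    # Physiological nuisance: strong in designated noise voxels, leaking
    # weakly everywhere (this is what tCompCor is meant to remove).
    physio = latent()
    X += config.physio_leak * physio
    X[structure.noise_voxels] += config.noise_voxel_sd * physio[None, :]
    X[structure.noise_voxels] += rng.normal(
        0.0, config.noise_voxel_sd, size=(len(structure.noise_voxels), T))

    # Subject-stable fingerprint: loadings fixed across visits.
    fp = structure.fingerprint_loadings[record.subject_id]
    X += config.fingerprint_strength * np.outer(fp, latent())

    # Decline-linked hub: voxels are recruited once the latent decline
    # factor passes their onset level, so the *breadth* of strongly-loaded
    # hub voxels grows with decline and the planted effect stays graded
    # even when recruited pairs saturate the link threshold.
    # per-voxel loading saturates (cap at 1 unit of excess): the decline
    # effect is carried by recruitment breadth, and hub variance stays
    # below the physiological-noise compartment that tCompCor masks out
    excess = np.clip(record.latent_decline - structure.hub_onset, 0.0, 1.0)
    w = (config.hub_base_loading
         + config.decline_hub_strength * excess * structure.hub_breadth)
    X[structure.hub_voxels] += np.outer(w, latent())

    # Pre-HD group signature independent of decline rate.
    if record.is_prehd and config.group_effect_strength > 0:
        X[structure.group_voxels] += (
            (1.0 + config.group_effect_strength) * latent()[None, :])
    elif config.group_effect_strength > 0:
        X[structure.group_voxels] += 1.0 * latent()[None, :]

    # Site latent with per-site gain.
    gains = np.linspace(0.5, 1.5, config.n_sites)
    X += (config.site_effect_scale * gains[record.site]
          * np.outer(structure.site_pattern, latent()))

    # Motion-locked artifact scaled by the visit's mean FD.
    fd = record.fd_mean.get(visit, 0.1)
    motion_tc = np.cumsum(rng.normal(0.0, 1.0, size=T))
    motion_tc = (motion_tc - motion_tc.mean()) / (motion_tc.std() + 1e-12)
    X += (config.motion_effect_scale * (fd / 0.1)
          * np.outer(structure.motion_pattern, motion_tc))

    # Unsteady initial frames: decaying global offset over the first 5.
    n_unsteady = min(5, T)
    X[:, :n_unsteady] += 5.0 * np.exp(-np.arange(n_unsteady))

    return BoldSeries(data=X, tr=config.tr_seconds, coords=structure.coords,
                      shape=structure.shape, subject_id=record.subject_id,
                      visit=visit)


def iter_bold(cohort: list[SubjectRecord], config: CohortConfig, seed: int,
              visits: tuple[int, ...] = (1, 2), structure: CohortStructure | None = None):
    """Yield ``(record, BoldSeries)`` per subject-visit, deterministically.

    The per-scan random stream depends only on (seed, subject index, visit),
    so any subset of scans can be regenerated independently.
    """
    if structure is None:
        structure = cohort_structure(cohort, config, seed)
    for i, record in enumerate(cohort):
        for visit in visits:
            yield record, _simulate_scan(record, i, visit, structure, config, seed)


def generate_bold(cohort: list[SubjectRecord], config: CohortConfig, seed: int,
                  visits: tuple[int, ...] = (1, 2)
                  ) -> tuple[list[BoldSeries], CohortStructure]:
    """Materialize all BOLD scans plus the ground-truth spatial structure."""
    structure = cohort_structure(cohort, config, seed)
    series = [s for _, s in iter_bold(cohort, config, seed, visits, structure)]
    return series, structure


def generate_motion_trace(record: SubjectRecord, config: CohortConfig,
                          seed: int, visit: int = 1,
                          subject_index: int | None = None) -> np.ndarray:
    """Per-frame framewise displacement (mm) consistent with fd_mean."""
    if subject_index is None:
        subject_index = int(record.subject_id.split("-")[-1])
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, 5, subject_index, visit]))
    fd_mean = record.fd_mean.get(visit, 0.1)
    # Gamma frames with the target mean; shape 2 keeps >0.6 mm frames rare
    # at typical means (~0.12 mm).
    fd = rng.gamma(shape=2.0, scale=fd_mean / 2.0, size=config.n_frames - 1)
    return fd


def generate_gmc(cohort: list[SubjectRecord], config: CohortConfig,
                 seed: int) -> np.ndarray:
    """Grey-matter-concentration maps, subjects x voxels, clipped to [0, 1].

    With a positive ``atrophy_effect_scale``, GMC in the atrophy region
    decreases with the latent decline factor.
    """
    structure = cohort_structure(cohort, config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    V = config.n_voxels
    base = np.clip(rng.normal(0.6, 0.12, size=V), 0.15, 0.95)
    atrophy_mask = np.zeros(V)
    atrophy_mask[structure.atrophy_voxels] = 1.0
    maps = np.empty((len(cohort), V))
    for i, r in enumerate(cohort):
        noise = rng.normal(0.0, 0.05, size=V)
        maps[i] = base + noise - (config.atrophy_effect_scale
                                  * max(0.0, r.latent_decline) * atrophy_mask)
    return np.clip(maps, 0.0, 1.0)
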