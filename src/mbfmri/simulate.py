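"""Synthetic multi-subject, multi-sequence BOLD cohort generator.

The generator emulates the structure of a block-design action-observation
cohort scanned repeatedly under several acquisition schemes: 26 seven-second
movie blocks (13 per condition, conditions CA and CC) separated by 8-12 s
rest intervals in an ~8 min run, acquired by each subject once per scheme
with freshly randomized block order.

Signal model per voxel v at volume time t:

    y(v, t) = B(v) * [ 1
                       + (effect/100) * A(v) * (h * box_CA)(t)
                       + sum_k (a_k/100) * R_k(v) * c_k(t)
                       + physio(v, t)/100 + drift(t)/100 ]
              + thermal(v, t)

where B is the tissue baseline (proton density x spoiled-GRE steady-state
signal at the scheme's TR, so grey-white contrast shrinks as TR shortens),
A the spatial CA-CC effect map (unit peak), h the canonical HRF, R_k the 20
planted network templates with time courses c_k, and thermal an AR(phi)
process whose stationary SD is sigma0 * g(v) * (V_ref / V_voxel) percent of
the local baseline -- the g-factor map carries the spatially varying noise
penalty of multiband/SENSE acceleration and V_ref/V_voxel the thermal-noise
cost of smaller voxels.  Sinusoidal respiratory/cardiac components are
sampled at the volume times, so they alias naturally at long TRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import VolumeSeries, save_series
from .sequences import SequenceSpec, TissueRelaxation, steady_state_signal

__all__ = [
    "TaskDesign",
    "Phantom",
    "NoiseModel",
    "GFactorMap",
    "generate_task_design",
    "generate_phantom",
    "synthesize_gfactor",
    "simulate_subject",
    "simulate_cohort",
]

#: Reference voxel volume (mm^3) at which thermal_sd_ref is defined;
#: the 2.7 mm isotropic schemes' voxel volume.
REFERENCE_VOXEL_VOLUME = 2.7 ** 3

#: Reference total acceleration below which no g-factor penalty applies
#: (the MB1 SENSE-2 scheme).
REFERENCE_ACCELERATION = 2.0

CONDITIONS = ("CA", "CC")


@dataclass(frozen=True)
class TaskDesign:
    """Block timing of one run: 13 CA + 13 CC blocks of 7 s, ISI 8-12 s."""

    onsets: tuple[float, ...]
    durations: tuple[float, ...]
    conditions: tuple[str, ...]
    session_duration: float
    seed: int

    def __post_init__(self) -> None:
        n = len(self.onsets)
        if not (len(self.durations) == len(self.conditions) == n):
            raise ValueError("onsets/durations/conditions length mismatch")
        ends = np.asarray(self.onsets) + np.asarray(self.durations)
        if np.any(np.asarray(self.onsets)[1:] < ends[:-1]):
            raise ValueError("blocks overlap")
        if ends[-1] > self.session_duration:
            raise ValueError("blocks exceed session duration")

    def onsets_for(self, condition: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        return np.asarray([self.onsets[i] for i in idx])

    def durations_for(self, condition: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.conditions) if c == condition]
        return np.asarray([self.durations[i] for i in idx])

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {"onset": self.onsets, "duration": self.durations,
             "trial_type": self.conditions}
        )

    @classmethod
    def from_events_frame(cls, df: pd.DataFrame, session_duration: float,
                          seed: int = 0) -> "TaskDesign":
        return cls(
            onsets=tuple(float(x) for x in df["onset"]),
            durations=tuple(float(x) for x in df["duration"]),
            conditions=tuple(str(x) for x in df["trial_type"]),
            session_duration=float(session_duration),
            seed=seed,
        )

    def truncated(self, max_time: float) -> "TaskDesign":
        """Keep only blocks falling wholly before ``max_time``."""
        keep = [i for i, (o, d) in enumerate(zip(self.onsets, self.durations))
                if o + d <= max_time]
        return TaskDesign(
            onsets=tuple(self.onsets[i] for i in keep),
            durations=tuple(self.durations[i] for i in keep),
            conditions=tuple(self.conditions[i] for i in keep),
            session_duration=min(self.session_duration, max_time),
            seed=self.seed,
        )


def generate_task_design(seed: int, n_per_condition: int = 13,
                         block_s: float = 7.0,
                         isi_range: tuple[float, float] = (8.0, 12.0),
                         lead_in_s: float = 10.0) -> TaskDesign:
    """Randomized block design: ``n_per_condition`` blocks per condition.

    Condition order is a random permutation; inter-block intervals are drawn
    uniformly on ``isi_range``.  Deterministic under a fixed seed.
    """
    if n_per_condition < 1 or block_s <= 0 or lead_in_s < 0:
        raise ValueError("design parameters must be positive")
    if not (0 < isi_range[0] <= isi_range[1]):
        raise ValueError("isi_range must be ordered and positive")
    rng = np.random.default_rng(seed)
    conditions = np.repeat(CONDITIONS, n_per_condition)
    rng.shuffle(conditions)
    n_blocks = 2 * n_per_condition
    isis = rng.uniform(isi_range[0], isi_range[1], size=n_blocks - 1)
    onsets = [lead_in_s]
    for isi in isis:
        onsets.append(onsets[-1] + block_s + isi)
    session = onsets[-1] + block_s + lead_in_s
    return TaskDesign(
        onsets=tuple(onsets),
        durations=(block_s,) * n_blocks,
        conditions=tuple(conditions),
        session_duration=session,
        seed=seed,
    )


@dataclass
class Phantom:
    """Digital head phantom: tissue masks, atlas, effect map, 20 network maps."""

    grid_shape: tuple[int, int, int]
    voxel_size: float
    affine: np.ndarray
    brain_mask: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    atlas_labels: np.ndarray
    activation_truth: np.ndarray
    rsn_templates: np.ndarray  # (20, x, y, z), unit peak each
    artefactual_networks: tuple[int, ...] = ()
    seed: int = 0

    @property
    def n_networks(self) -> int:
        return self.rsn_templates.shape[0]


def _radial_profile(shape: tuple[int, int, int]) -> np.ndarray:
    """Normalized squared elliptic radius; 0 at grid centre, 1 on the box edge."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return xx ** 2 + yy ** 2 + zz ** 2


def generate_phantom(grid_shape: tuple[int, int, int] = (32, 38, 32),
                     voxel_size: float = 3.0,
                     n_activation_blobs: int = 5,
                     n_networks: int = 20,
                     n_atlas_regions: int = 12,
                     n_artefactual: int = 3,
                     blob_sigma_vox: float = 1.6,
                     seed: int = 0) -> Phantom:
    """Build the synthetic head on a regular grid.

    Concentric ellipsoids define CSF (core), white matter (inner shell) and
    grey matter (outer shell); a Voronoi tessellation of random grey-matter
    seeds yields >= 10 atlas regions; the activation map has exactly
    ``n_activation_blobs`` connected Gaussian blobs confined to grey matter;
    the 20 network templates are smooth multi-blob random fields with unit
    peak, the last ``n_artefactual`` of them placed deep (white matter/CSF
    neighbourhood) to mimic artefactual or deep components.
    """
    if min(grid_shape) < 16:
        raise ValueError("grid_shape must be >= 16 per axis")
    rng = np.random.default_rng(seed)
    r2 = _radial_profile(grid_shape)
    brain = r2 <= 0.81          # ellipsoid at 90% of half-extent
    csf = r2 <= 0.02            # central ventricle analogue
    wm = (r2 <= 0.30) & ~csf
    gm = brain & ~wm & ~csf

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -voxel_size * (np.asarray(grid_shape) - 1) / 2.0

    # atlas: Voronoi of random GM seed voxels, labels only inside GM
    gm_idx = np.argwhere(gm)
    seeds = gm_idx[rng.choice(len(gm_idx), size=n_atlas_regions, replace=False)]
    grid = np.indices(grid_shape).reshape(3, -1).T
    d2 = ((grid[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels = (np.argmin(d2, axis=1) + 1).reshape(grid_shape)
    atlas = np.where(gm, labels, 0).astype(np.int32)

    def _blob(center: np.ndarray, sigma: float) -> np.ndarray:
        dist2 = ((grid - center) ** 2).sum(axis=1).reshape(grid_shape)
        return np.exp(-dist2 / (2.0 * sigma ** 2))

    # activation truth: well-separated GM blobs, hard support cut keeps the
    # requested number of connected components
    truth = np.zeros(grid_shape)
    if n_activation_blobs > 0:
        centers = _spread_points(gm_idx, n_activation_blobs, rng,
                                 min_dist=4.0 * blob_sigma_vox)
        if len(centers) < n_activation_blobs:
            raise ValueError("grid too small to host the requested blobs")
        for c in centers:
            b = _blob(c, blob_sigma_vox)
            truth = np.maximum(truth, np.where(b >= 0.30, b, 0.0))
        truth *= gm
        if truth.max() > 0:
            truth /= truth.max()

    # network templates
    templates = np.zeros((n_networks, *grid_shape))
    artefactual = tuple(range(n_networks - n_artefactual, n_networks))
    deep_idx = np.argwhere(wm | csf)
    for k in range(n_networks):
        pool = deep_idx if k in artefactual else gm_idx
        centers = pool[rng.choice(len(pool), size=3, replace=False)]
        t = np.zeros(grid_shape)
        for c in centers:
            t = np.maximum(t, _blob(c, 2.0))
        t *= brain
        templates[k] = t / t.max()

    return Phantom(
        grid_shape=tuple(grid_shape), voxel_size=voxel_size, affine=affine,
        brain_mask=brain, gm_mask=gm, wm_mask=wm, csf_mask=csf,
        atlas_labels=atlas, activation_truth=truth, rsn_templates=templates,
        artefactual_networks=artefactual, seed=seed,
    )


def _spread_points(candidates: np.ndarray, n: int, rng: np.random.Generator,
                   min_dist: float) -> np.ndarray:
    """Greedy max-min selection of ``n`` well-separated points."""
    order = rng.permutation(len(candidates))
    chosen: list[np.ndarray] = []
    for i in order:
        p = candidates[i]
        if all(np.linalg.norm(p - q) >= min_dist for q in chosen):
            chosen.append(p)
            if len(chosen) == n:
                break
    return np.asarray(chosen)


@dataclass(frozen=True)
class NoiseModel:
    """Noise parameters of the simulator.

    Amplitudes are in percent of the local baseline signal except
    ``thermal_sd_ref`` which is the stationary SD (percent of baseline) of
    the AR-coloured thermal noise at the reference voxel volume and g = 1.
    """

    ar_coefficient: float = 0.35
    thermal_sd_ref: float = 2.0
    physio_respiratory_hz: float = 0.3
    physio_cardiac_hz: float = 1.0
    physio_amplitudes: tuple[float, float] = (0.4, 0.3)
    drift_amplitude: float = 1.0
    between_subject_sd: float = 0.3
    motion_signal_pct: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.thermal_sd_ref < 0 or self.drift_amplitude < 0:
            raise ValueError("noise SDs must be >= 0")
        if any(a < 0 for a in self.physio_amplitudes) or self.between_subject_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class GFactorMap:
    """Spatial noise-amplification map of a parallel-imaging scheme (>= 1)."""

    values: np.ndarray
    mb_factor: int
    sense_factor: float

    def __post_init__(self) -> None:
        if self.values.min() < 1.0 - 1e-9:
            raise ValueError("g-factor must be >= 1 everywhere")


def synthesize_gfactor(phantom: Phantom, mb_factor: int, sense_factor: float,
                       center_penalty: float = 0.25) -> GFactorMap:
    """Model g-factor map: unity at the reference acceleration, centrally
    peaked inflation growing linearly with total acceleration beyond it.

    ``g(v) = 1 + center_penalty * (mb*sense - 2)/2 * w(v)`` with ``w`` a
    centrally peaked profile in [0, 1] — unfolding is hardest far from the
    receive coils, i.e. at the head centre.
    """
    if mb_factor < 1 or sense_factor <= 0:
        raise ValueError("acceleration factors must be >= 1 (mb) and > 0 (sense)")
    total = mb_factor * sense_factor
    g = np.ones(phantom.grid_shape)
    if total > REFERENCE_ACCELERATION:
        w = np.exp(-_radial_profile(phantom.grid_shape) / (2 * 0.35 ** 2))
        excess = (total - REFERENCE_ACCELERATION) / REFERENCE_ACCELERATION
        g = 1.0 + center_penalty * excess * w
    return GFactorMap(values=g, mb_factor=mb_factor, sense_factor=sense_factor)


# ---------------------------------------------------------------------------
# subject-level simulation

def _baseline_map(phantom: Phantom, spec: SequenceSpec,
                  tissue: TissueRelaxation) -> np.ndarray:
    """Tissue baseline: proton density x steady-state signal, scaled to ~100."""
    t1_csf, pd_csf = 4.0, 1.0
    base = np.zeros(phantom.grid_shape)
    base[phantom.gm_mask] = (tissue.proton_density_grey
                             * steady_state_signal(spec.tr, tissue.t1_grey))
    base[phantom.wm_mask] = (tissue.proton_density_white
                             * steady_state_signal(spec.tr, tissue.t1_white))
    base[phantom.csf_mask] = pd_csf * steady_state_signal(spec.tr, t1_csf)
    other = phantom.brain_mask & ~(phantom.gm_mask | phantom.wm_mask | phantom.csf_mask)
    base[other] = (tissue.proton_density_grey
                   * steady_state_signal(spec.tr, tissue.t1_grey))
    return 100.0 * base


def _hrf_convolved_regressor(onsets: np.ndarray, durations: np.ndarray,
                             tr: float, n_volumes: int,
                             oversample: int = 16) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, sampled at volume times."""
    from .firstlevel import canonical_hrf

    dt = tr / oversample
    n_fine = n_volumes * oversample
    box = np.zeros(n_fine)
    tt = np.arange(n_fine) * dt
    for o, d in zip(onsets, durations):
        box[(tt >= o) & (tt < o + d)] = 1.0
    kern = canonical_hrf(dt)
    conv = np.convolve(box, kern)[:n_fine] * dt
    return conv[oversample // 2::oversample][:n_volumes]


def _smooth_timecourse(n: int, tr: float, rng: np.random.Generator,
                       cutoff_hz: float = 0.08) -> np.ndarray:
    """Unit-variance low-frequency random time course (network dynamics)."""
    x = rng.standard_normal(n)
    sigma_samples = max(1.0 / (2.0 * math.pi * cutoff_hz * tr), 0.5)
    x = ndimage.gaussian_filter1d(x, sigma_samples, mode="reflect")
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar_noise(shape_vt: tuple[int, int], phi: float,
              rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise along the last axis with stationary SD 1."""
    innov = rng.standard_normal(shape_vt)
    if phi == 0:
        return innov
    out = signal.lfilter([1.0], [1.0, -phi], innov, axis=-1)
    return out * math.sqrt(1.0 - phi ** 2)


def _motion_table(n_volumes: int, tr: float, rng: np.random.Generator,
                  n_jerks: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Six realignment-parameter columns: smooth drifts plus step jerks.

    Returns the table and the jerk step regressor (sum over jerks) used to
    inject spatially structured signal changes.
    """
    cols = {}
    t = np.arange(n_volumes) * tr
    jerk_times = rng.uniform(0.15, 0.85, size=n_jerks) * t[-1] if n_volumes > 1 else []
    step = np.zeros(n_volumes)
    for jt in np.atleast_1d(jerk_times):
        step += (t >= jt).astype(float) * rng.uniform(-1.0, 1.0)
    names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    for i, name in enumerate(names):
        scale = 0.15 if i < 3 else 0.05          # mm vs degrees
        drift = ndimage.gaussian_filter1d(
            np.cumsum(rng.standard_normal(n_volumes)) * 0.02, 8.0, mode="nearest")
        cols[name] = scale * (drift + step * rng.uniform(0.5, 1.5))
    return pd.DataFrame(cols), step


def simulate_subject(phantom: Phantom, design: TaskDesign, spec: SequenceSpec,
                     noise: NoiseModel, subject_effect: float = 1.0,
                     seed: int = 0,
                     tissue: TissueRelaxation | None = None,
                     gfactor: GFactorMap | None = None,
                     rsn_amplitudes: np.ndarray | None = None,
                     ) -> tuple[VolumeSeries, pd.DataFrame]:
    """Simulate one run of one subject under one acquisition scheme.

    ``subject_effect`` is the subject's CA-CC amplitude in percent signal
    change at the activation peak.  Returns the 4D series and the 6-column
    motion-parameter table.
    """
    n_vol, tr = spec.n_volumes, spec.tr
    if design.onsets and design.onsets[-1] + design.durations[-1] > n_vol * tr + 1e-6:
        raise ValueError("task design does not fit within the acquisition")
    tissue = tissue or TissueRelaxation()
    if gfactor is None:
        gfactor = synthesize_gfactor(phantom, spec.mb_factor, spec.sense_factor)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    base = _baseline_map(phantom, spec, tissue)
    brain = phantom.brain_mask
    n_brain = int(brain.sum())
    t = np.arange(n_vol) * tr

    rel = np.zeros((n_brain, n_vol))            # relative (fractional) signal

    # task: CA carries the effect, CC is the matched control
    ca = _hrf_convolved_regressor(design.onsets_for("CA"),
                                  design.durations_for("CA"), tr, n_vol)
    truth_b = phantom.activation_truth[brain]
    rel += (subject_effect / 100.0) * truth_b[:, None] * ca[None, :]

    # planted network fluctuations
    if rsn_amplitudes is None:
        rsn_amplitudes = np.full(phantom.n_networks, 1.0)
        for k in phantom.artefactual_networks:
            rsn_amplitudes[k] = 0.3
    for k in range(phantom.n_networks):
        if rsn_amplitudes[k] == 0:
            continue
        tc = _smooth_timecourse(n_vol, tr, rng)
        rel += (rsn_amplitudes[k] / 100.0) * phantom.rsn_templates[k][brain][:, None] * tc[None, :]

    # physiological sinusoids, sampled at volume times (alias at long TR)
    amp_r, amp_c = noise.physio_amplitudes
    if amp_r > 0:
        phase = rng.uniform(0, 2 * math.pi)
        wmap = 1.0 + 2.0 * phantom.csf_mask[brain]
        rel += (amp_r / 100.0) * wmap[:, None] * np.sin(
            2 * math.pi * noise.physio_respiratory_hz * t + phase)[None, :]
    if amp_c > 0:
        phase = rng.uniform(0, 2 * math.pi)
        wmap = 0.5 + 2.5 * phantom.csf_mask[brain]
        rel += (amp_c / 100.0) * wmap[:, None] * np.sin(
            2 * math.pi * noise.physio_cardiac_hz * t + phase)[None, :]

    # slow drift: linear + one slow cosine, random sign/phase per voxel block
    if noise.drift_amplitude > 0:
        lin = (t / t[-1] - 0.5) if n_vol > 1 else np.zeros(1)
        cosine = np.cos(2 * math.pi * t / max(t[-1], 1.0) * rng.uniform(0.5, 1.5))
        w1, w2 = rng.standard_normal(2)
        rel += (noise.drift_amplitude / 100.0) * (w1 * lin + w2 * cosine)[None, :]

    # motion table + spatially structured jerk signal
    motion, step = _motion_table(n_vol, tr, rng)
    if noise.motion_signal_pct > 0 and np.any(step != 0):
        grad_z = np.gradient(base, axis=2)[brain]
        gz = grad_z / (np.abs(grad_z).max() + 1e-12)
        rel += (noise.motion_signal_pct / 100.0) * gz[:, None] * step[None, :]

    y = base[brain][:, None] * (1.0 + rel)

    # AR-coloured thermal noise, SD scaled by g-factor and voxel volume
    if noise.thermal_sd_ref > 0:
        sd_map = (noise.thermal_sd_ref / 100.0) * base[brain] \
            * gfactor.values[brain] * (REFERENCE_VOXEL_VOLUME / spec.voxel_volume)
        y += sd_map[:, None] * _ar_noise((n_brain, n_vol), noise.ar_coefficient, rng)

    data = np.zeros((*phantom.grid_shape, n_vol), dtype=np.float32)
    data[brain] = y
    series = VolumeSeries(data=data, affine=phantom.affine, tr=tr,
                          mask=brain, name=spec.name)
    return series, motion


def expand_seed(global_seed: int, *key: int) -> int:
    """Deterministic per-stage seed expansion (single reproducible stream)."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, np.uint32)[0])


def simulate_cohort(phantom: Phantom, spec_list: list[SequenceSpec],
                    n_subjects: int = 23,
                    noise: NoiseModel | None = None,
                    out_dir: str | Path = "cohort",
                    mean_effect: float = 1.0,
                    seed: int = 0,
                    tissue: TissueRelaxation | None = None) -> pd.DataFrame:
    """Simulate and write a full cohort: ``n_subjects`` x ``len(spec_list)`` runs.

    Each subject draws one CA-CC amplitude (mean ``mean_effect`` percent, SD
    ``noise.between_subject_sd``) shared across schemes; each run gets a fresh
    randomized block order.  Writes 4D NIfTI, BIDS-style events TSV and
    motion text per run plus a manifest CSV; returns the manifest.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    noise = noise or NoiseModel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
    effects = mean_effect + noise.between_subject_sd * rng.standard_normal(n_subjects)

    rows = []
    for si in range(n_subjects):
        for qi, spec in enumerate(spec_list):
            run_seed = expand_seed(seed, si, qi)
            design = generate_task_design(expand_seed(seed, si, qi, 1))
            series, motion = simulate_subject(
                phantom, design, spec, noise, subject_effect=effects[si],
                seed=run_seed, tissue=tissue)
            stem = f"sub-{si + 1:02d}_seq-{spec.name}"
            bold_p = out_dir / f"{stem}_bold.nii.gz"
            events_p = out_dir / f"{stem}_events.tsv"
            motion_p = out_dir / f"{stem}_motion.txt"
            save_series(series, bold_p)
            design.to_events_frame().to_csv(events_p, sep="\t", index=False)
            np.savetxt(motion_p, motion.to_numpy(), fmt="%.6f")
            rows.append(dict(subject=si + 1, sequence=spec.name,
                             bold_path=str(bold_p), events_path=str(events_p),
                             motion_path=str(motion_p),
                             session_duration=design.session_duration,
                             subject_effect=effects[si], seed=run_seed))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
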