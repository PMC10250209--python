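"""Seeded generators for every input the analysis pipeline consumes.

These emulate the statistical structure of DNA-tightrope single-molecule
experiments and the accompanying gel assays:

* exponentially distributed residence times, right-censored at the end
  of a 300 s movie, with an optional competitor-concentration-dependent
  facilitated-dissociation term in the effective off-rate;
* 1D anomalous diffusion along the DNA as fractional Brownian motion
  (fBm) with MSD(t) = 2 D t^alpha, plus Gaussian localization noise
  per frame — fBm is the standard single-particle-tracking stand-in
  when the true generative model of motion is unknown;
* dual-color particle placements on a lesion array (one abasic site
  every 2 kb) with ground-truth pairing for co-localization validation;
* quadratic tight-binding isotherms at fixed DNA concentration;
* pseudo-first-order excision time courses;
* rendered kymograph images (per-frame Gaussian spot plus noise) for
  round-tripping the tracking code.

Every generator takes an explicit seed (or a config carrying one);
identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import IsothermData, fraction_bound_model
from .errors import InvalidParameterError
from .excision import TimeCourse
from .kymo import BP_PER_MICRON, KymographImage, Trajectory
from .residence import DwellRecord, ParticleDetection


@dataclass(frozen=True)
class SimulationConfig:
    """Imaging and unit conventions shared by the generators.

    frame_interval : s/frame, default 0.08 (12.5 fps; movies in these
        experiments run at ~11-12.5 fps).
    observation_window : movie length in seconds (default 300 = 5 min).
    localization_sd : per-frame localization noise, microns (default
        0.04, typical for quantum-dot tracking).
    pixel_size : microns per pixel for rendered kymographs.
    bp_per_micron : DNA contour conversion, default 2941 bp/um
        (0.34 nm/bp B-DNA rise).
    """

    frame_interval: float = 0.08
    observation_window: float = 300.0
    localization_sd: float = 0.04
    pixel_size: float = 0.1
    bp_per_micron: float = BP_PER_MICRON
    seed: int | None = None

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.observation_window <= 0:
            raise InvalidParameterError("observation_window must be > 0")
        if self.localization_sd < 0:
            raise InvalidParameterError("localization_sd must be >= 0")
        if self.pixel_size <= 0 or self.bp_per_micron <= 0:
            raise InvalidParameterError("pixel_size and bp_per_micron must be > 0")

    def rng(self, seed=None) -> np.random.Generator:
        s = seed if seed is not None else self.seed
        return np.random.default_rng(s)


@dataclass(frozen=True)
class FacilitatedDissociationParams:
    """Mechanistic stand-in for competitor-driven displacement.

    The effective off-rate is k_eff = k_intrinsic + k_fd * [competitor]:
    a protein leaves either spontaneously or because a competitor
    (UV-DDB in the motivating experiments) displaces it, at a rate
    proportional to competitor concentration.
    """

    k_intrinsic: float            # 1/s
    k_fd: float = 0.0             # 1/(s*nM)
    competitor_conc: float = 0.0  # nM

    def __post_init__(self):
        if self.k_intrinsic < 0 or self.k_fd < 0 or self.competitor_conc < 0:
            raise InvalidParameterError("rates and concentrations must be >= 0")

    @property
    def k_eff(self) -> float:
        return self.k_intrinsic + self.k_fd * self.competitor_conc


def simulate_dwell_times(k_eff: float, n: int, window: float | None = None,
                         cfg: SimulationConfig | None = None,
                         seed=None, condition: str = "",
                         motile_fraction: float = 0.0) -> list[DwellRecord]:
    """Draw residence times from Exponential(k_eff), right-censoring at
    ``window`` (seconds; ``np.inf`` disables censoring; defaults to the
    config's observation window)."""
    cfg = cfg or SimulationConfig()
    if k_eff <= 0:
        raise InvalidParameterError("k_eff must be > 0")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if window is None:
        window = cfg.observation_window
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    rng = cfg.rng(seed)
    raw = rng.exponential(1.0 / k_eff, size=n)
    motile = rng.random(n) < motile_fraction
    out = []
    for i, t in enumerate(raw):
        cens = t > window
        out.append(DwellRecord(
            particle_id=f"d{i}", duration=float(min(t, window)),
            censored=bool(cens), motile=bool(motile[i]), condition=condition))
    return out


# ---------------------------------------------------------------------------
# fractional Brownian motion

def _fgn_exact(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """n unit-variance fractional Gaussian noise increments.

    Davies-Harte circulant embedding (exact covariance, O(n log n));
    falls back to a Cholesky factorization of the exact covariance
    matrix if the embedding is not nonnegative definite.
    """
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma[: n + 1], gamma[n - 1:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() >= -1e-10 * max(lam.max(), 1.0):
        lam = np.clip(lam, 0.0, None)
        m = 2 * n
        z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        f = np.fft.fft(z * np.sqrt(lam / m))
        return f.real[:n]
    # rare at high Hurst / tiny n: exact covariance Cholesky
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov = gamma[idx]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return chol @ rng.standard_normal(n)


def simulate_trajectory(diff_coeff: float, alpha: float,
                        cfg: SimulationConfig | None = None,
                        duration: float | None = None, seed=None,
                        start_um: float = 0.0,
                        particle_id: str = "sim0") -> Trajectory:
    """Simulate 1D motion along the DNA as fractional Brownian motion.

    The true (noise-free) MSD is 2 * diff_coeff * t^alpha with t in
    seconds, so for alpha = 1 a linear MSD fit recovers ``diff_coeff``
    in um^2/s; for alpha != 1 ``diff_coeff`` is the generalized
    coefficient in um^2/s^alpha. Independent Gaussian localization
    noise (cfg.localization_sd) is added to every frame.
    """
    cfg = cfg or SimulationConfig()
    if diff_coeff < 0:
        raise InvalidParameterError("diff_coeff must be >= 0")
    if not (0 < alpha <= 2):
        raise InvalidParameterError("alpha must lie in (0, 2]")
    if duration is None:
        duration = cfg.observation_window
    n_frames = int(round(duration / cfg.frame_interval)) + 1
    if n_frames < 2:
        raise InvalidParameterError("duration shorter than one frame")
    rng = cfg.rng(seed)
    if diff_coeff == 0:
        x = np.full(n_frames, start_um)
    else:
        increment_sd = np.sqrt(2.0 * diff_coeff * cfg.frame_interval ** alpha)
        inc = increment_sd * _fgn_exact(n_frames - 1, alpha / 2.0, rng)
        x = start_um + np.concatenate([[0.0], np.cumsum(inc)])
    if cfg.localization_sd > 0:
        x = x + rng.normal(0.0, cfg.localization_sd, n_frames)
    traj = Trajectory.from_positions(particle_id, x, cfg.frame_interval,
                                     source="synthetic")
    traj.positions_kb = traj.positions_um * cfg.bp_per_micron / 1000.0
    return traj


def simulate_two_color_particles(n_a: int, n_b: int, n_shared: int,
                                 array_spacing_kb: float = 2.0,
                                 cfg: SimulationConfig | None = None,
                                 seed=None, substrate_kb: float = 40.0):
    """Place particles of two channels on a lesion-array substrate.

    Lesions sit at multiples of ``array_spacing_kb`` along a
    ``substrate_kb``-long DNA. ``n_shared`` particles (counted inside
    both channel totals) occupy identical lesions; all remaining
    particles get distinct lesions. Returns (channel_a, channel_b,
    ground_truth_pairs).
    """
    cfg = cfg or SimulationConfig()
    if min(n_a, n_b, n_shared) < 0:
        raise InvalidParameterError("counts must be >= 0")
    if n_shared > min(n_a, n_b):
        raise InvalidParameterError("n_shared cannot exceed either channel total")
    n_lesions_needed = n_a + n_b - n_shared
    lesions = np.arange(array_spacing_kb, substrate_kb + 1e-9, array_spacing_kb)
    if n_lesions_needed > lesions.size:
        raise InvalidParameterError(
            f"{n_lesions_needed} distinct lesions needed but only {lesions.size} "
            f"fit on a {substrate_kb} kb substrate")
    rng = cfg.rng(seed)
    chosen = rng.choice(lesions, size=n_lesions_needed, replace=False)
    n_frames = int(round(cfg.observation_window / cfg.frame_interval))

    def make(channel, idx, pos):
        return ParticleDetection(
            particle_id=f"{channel}_{idx}", channel=channel,
            position_kb=float(pos), first_frame=0, last_frame=n_frames - 1)

    a, b, pairs = [], [], []
    for i in range(n_shared):
        pa = make("605", i, chosen[i])
        pb = make("705", i, chosen[i])
        a.append(pa)
        b.append(pb)
        pairs.append((pa, pb))
    k = n_shared
    for i in range(n_a - n_shared):
        a.append(make("605", n_shared + i, chosen[k]))
        k += 1
    for i in range(n_b - n_shared):
        b.append(make("705", n_shared + i, chosen[k]))
        k += 1
    return a, b, pairs


def simulate_isotherm(kd: float, dna_conc: float, protein_concs,
                      noise_sd: float = 5.0, replicates: int = 3,
                      seed=None) -> IsothermData:
    """Quadratic-model percent bound plus additive Gaussian noise
    (percentage points), clipped to [0, 100]."""
    if kd <= 0 or dna_conc <= 0:
        raise InvalidParameterError("kd and dna_conc must be > 0")
    concs = np.asarray(protein_concs, dtype=float)
    if np.any(concs < 0):
        raise InvalidParameterError("protein concentrations must be >= 0")
    if noise_sd < 0 or replicates < 1:
        raise InvalidParameterError("noise_sd >= 0 and replicates >= 1 required")
    rng = np.random.default_rng(seed)
    truth = fraction_bound_model(concs, dna_conc, kd)
    y = np.tile(truth, (replicates, 1))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.clip(y, 0.0, 100.0)
    return IsothermData(protein_concs=concs, pct_bound=y, dna_conc_total=dna_conc)


def simulate_excision_timecourse(k_obs: float, amplitude: float, times,
                                 noise_sd: float = 1.0, seed=None,
                                 condition: str = "") -> TimeCourse:
    """Pseudo-first-order product formation
    A*(1 - exp(-k_obs t)) + noise, clipped to [0, 100]."""
    if k_obs < 0:
        raise InvalidParameterError("k_obs must be >= 0")
    if not (0 <= amplitude <= 100):
        raise InvalidParameterError("amplitude must lie in [0, 100]")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    y = amplitude * (1.0 - np.exp(-k_obs * t))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    y = np.clip(y, 0.0, 100.0)
    return TimeCourse(times=t, product_pct=y, condition=condition)


def render_kymograph(traj: Trajectory, psf_sigma_px: float = 1.5,
                     amplitude: float = 200.0, background: float = 20.0,
                     noise_model: str = "poisson",
                     cfg: SimulationConfig | None = None, seed=None,
                     n_rows: int | None = None,
                     origin_um: float | None = None) -> KymographImage:
    """Render a trajectory as a kymograph image.

    One column per frame; each column holds a Gaussian spot of width
    ``psf_sigma_px`` centered at the particle position, on a constant
    background, with per-pixel Poisson or Gaussian noise (or none).
    If ``n_rows``/``origin_um`` are given and any frame's spot center
    falls outside the image, an error lists the offending frames;
    otherwise the image is sized to the trajectory with a margin.
    """
    cfg = cfg or SimulationConfig()
    if psf_sigma_px <= 0:
        raise InvalidParameterError("psf_sigma_px must be > 0")
    if noise_model not in ("poisson", "gaussian", "none"):
        raise InvalidParameterError(f"unknown noise_model {noise_model!r}")
    margin_px = 5.0 * psf_sigma_px
    if origin_um is None:
        origin_um = float(traj.positions_um.min() - margin_px * cfg.pixel_size)
    rows_f = (traj.positions_um - origin_um) / cfg.pixel_size
    if n_rows is None:
        n_rows = int(np.ceil(rows_f.max() + margin_px)) + 1
    bad = np.flatnonzero((rows_f < 0) | (rows_f > n_rows - 1))
    if bad.size:
        raise InvalidParameterError(
            f"trajectory outside image bounds at frames {traj.frames[bad].tolist()}")
    rr = np.arange(n_rows, dtype=float)
    img = background + amplitude * np.exp(
        -0.5 * ((rr[:, None] - rows_f[None, :]) / psf_sigma_px) ** 2)
    rng = cfg.rng(seed)
    if noise_model == "poisson":
        img = rng.poisson(img).astype(float)
    elif noise_model == "gaussian":
        img = np.clip(img + rng.normal(0.0, np.sqrt(background), img.shape), 0.0, None)
    return KymographImage(pixels=img, pixel_size=cfg.pixel_size,
                          frame_interval=traj.frame_interval, origin_um=origin_um)


__all__ = [
    "SimulationConfig", "FacilitatedDissociationParams", "simulate_dwell_times",
    "simulate_trajectory", "simulate_two_color_particles", "simulate_isotherm",
    "simulate_excision_timecourse", "render_kymograph",
]
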