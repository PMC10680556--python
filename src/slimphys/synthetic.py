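"""Ground-truthed simulators for Slimfield stacks, photobleaching traces
and PAM/ECS time series.

The image model: each complex carries ``k * unit_size`` tag sites of
which a binomial fraction are fluorescent; every live, non-dark molecule
deposits an integrated 2-D Gaussian PSF of expected total ``brightness``
photoelectrons per frame at the complex position; pixel values are
Poisson about (signal + background) plus Gaussian read noise, clipped at
zero and quantized to uint16.  Molecules bleach irreversibly with a
per-frame probability and may blink reversibly.  Motion is 2-D Brownian,
reflected at the ROI bounding box.

Defaults mirror the acquisition that motivated the model: 53 nm/pixel,
10 ms exposure, 56 photoelectrons/frame/molecule.  The source's quoted
"10 ms exposure/frame at 180 frames/s" is internally inconsistent
(180 fps implies a 5.6 ms period); we default to a 10 ms frame period
(100 fps equivalent) and leave both configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import erf

from .io import ImageStack, ROIMask


class ConfigurationError(ValueError):
    """Raised for non-finite, negative or inconsistent simulation settings."""


def _check_prob(name: str, value: float) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be a probability in [0, 1]; got {value}")


def _check_pos(name: str, value: float, strict: bool = True) -> None:
    if not np.isfinite(value) or (value <= 0 if strict else value < 0):
        op = ">" if strict else ">="
        raise ConfigurationError(f"{name} must be {op} 0 and finite; got {value}")


@dataclass
class SlimfieldSimConfig:
    """Settings for :func:`simulate_image_stack`.

    ``multiple_weights`` maps the multiplier ``k`` (complex carries
    ``k * unit_size`` tag sites) to its probability; weights must sum
    to 1.  ``roi`` may be ``None`` (whole frame is ROI 1), a label
    array, or an axis-aligned rectangle ``(r0, c0, r1, c1)`` (half-open).
    """

    unit_size: int = 5
    multiple_weights: Mapping[int, float] = field(default_factory=lambda: {1: 1.0})
    maturation_prob: float = 0.75
    brightness: float = 56.0
    bleach_prob: float = 0.03
    blink_off_prob: float = 0.0
    blink_on_prob: float = 0.0
    n_complexes: int = 10
    diffusion_coeff: float = 0.05  # px^2 / frame
    psf_sigma: float = 1.5  # px; ~0.21 * 585 nm / 1.49 NA at 53 nm/px
    frame_count: int = 300
    frame_interval: float = 0.010
    exposure: float = 0.010
    pixel_size: float = 53.0
    image_shape: tuple[int, int] = (64, 64)
    roi: object = None
    background_rate: float = 10.0  # photoelectrons / pixel / frame
    read_noise_sd: float = 3.0
    shot_noise: bool = True  # False: deterministic expected counts (oracle runs)
    placement: str = "uniform"  # or "grid" (jittered grid, well-separated)
    seed: int | None = None

    def __post_init__(self) -> None:
        if int(self.unit_size) < 1:
            raise ConfigurationError(f"unit_size must be >= 1; got {self.unit_size}")
        weights = dict(self.multiple_weights)
        total = sum(weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"multiple_weights must sum to 1; got {total}")
        if any(k < 1 or w < 0 for k, w in weights.items()):
            raise ConfigurationError("multiple_weights needs k >= 1 and weights >= 0")
        for name in ("maturation_prob", "bleach_prob", "blink_off_prob", "blink_on_prob"):
            _check_prob(name, getattr(self, name))
        _check_pos("brightness", self.brightness)
        _check_pos("psf_sigma", self.psf_sigma)
        _check_pos("frame_interval", self.frame_interval)
        _check_pos("exposure", self.exposure)
        _check_pos("pixel_size", self.pixel_size)
        _check_pos("background_rate", self.background_rate, strict=False)
        _check_pos("read_noise_sd", self.read_noise_sd, strict=False)
        _check_pos("diffusion_coeff", self.diffusion_coeff, strict=False)
        if self.n_complexes < 0 or self.frame_count < 1:
            raise ConfigurationError("n_complexes >= 0 and frame_count >= 1 required")
        if self.placement not in ("uniform", "grid"):
            raise ConfigurationError(f"unknown placement '{self.placement}'")


@dataclass
class GroundTruthTable:
    """Per-complex truth emitted alongside a simulated stack.

    ``trajectories[i]`` is an ``(n_frames, 2)`` array of sub-pixel
    ``(row, col)`` positions; ``bleach_frames[i]`` holds one entry per
    fluorescent molecule (first frame in which it no longer emits; -1 if
    it never bleaches); ``live_counts[i]`` is the per-frame number of
    emitting molecules.
    """

    complex_ids: np.ndarray
    true_subunits: np.ndarray
    true_fluorophores: np.ndarray
    trajectories: list[np.ndarray]
    bleach_frames: list[np.ndarray]
    live_counts: list[np.ndarray]

    def __post_init__(self) -> None:
        if np.any(self.true_fluorophores > self.true_subunits):
            raise ValueError("true_fluorophores must be <= true_subunits")

    @property
    def n_complexes(self) -> int:
        return len(self.complex_ids)

    def to_frame(self):
        """Long-format table: one row per complex per frame."""
        import pandas as pd

        rows = []
        for i, cid in enumerate(self.complex_ids):
            traj = self.trajectories[i]
            live = self.live_counts[i]
            for f in range(traj.shape[0]):
                rows.append((cid, f, traj[f, 0], traj[f, 1], live[f]))
        return pd.DataFrame(
            rows, columns=["complex_id", "frame", "row", "col", "live_molecules"]
        )

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "complex_id": self.complex_ids,
                "true_subunits": self.true_subunits,
                "true_fluorophores": self.true_fluorophores,
            }
        )


def _resolve_roi(cfg: SlimfieldSimConfig) -> np.ndarray:
    shape = tuple(cfg.image_shape)
    if cfg.roi is None:
        return np.ones(shape, dtype=np.int32)
    if isinstance(cfg.roi, np.ndarray):
        if cfg.roi.shape != shape:
            raise ConfigurationError(
                f"roi shape {cfg.roi.shape} does not match image_shape {shape}"
            )
        return cfg.roi.astype(np.int32)
    if isinstance(cfg.roi, (tuple, list)) and len(cfg.roi) == 4:
        r0, c0, r1, c1 = cfg.roi
        labels = np.zeros(shape, dtype=np.int32)
        labels[int(r0) : int(r1), int(c0) : int(c1)] = 1
        return labels
    raise ConfigurationError(f"cannot interpret roi spec {cfg.roi!r}")


def _roi_bbox(labels: np.ndarray) -> tuple[float, float, float, float]:
    rows, cols = np.nonzero(labels > 0)
    if rows.size == 0:
        raise ConfigurationError("ROI mask is empty but n_complexes > 0")
    # pixel-area bounds: pixel center i covers [i-0.5, i+0.5)
    return rows.min() - 0.5, cols.min() - 0.5, rows.max() + 0.5, cols.max() + 0.5


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    if span <= 0:
        return np.full_like(x, lo)
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _initial_positions(
    cfg: SlimfieldSimConfig, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    r0, c0, r1, c1 = _roi_bbox(labels)
    n = cfg.n_complexes
    if cfg.placement == "grid":
        # jittered grid inside the bbox keeps complexes resolvable
        margin = 3.0 * cfg.psf_sigma
        rows = max(1, int(math.ceil(math.sqrt(n))))
        cols = max(1, int(math.ceil(n / rows)))
        rr = np.linspace(r0 + margin, r1 - margin, rows)
        cc = np.linspace(c0 + margin, c1 - margin, cols)
        grid = np.array([(a, b) for a in rr for b in cc])[:n]
        jitter = rng.uniform(-0.5, 0.5, size=grid.shape)
        return grid + jitter
    pos = np.empty((n, 2))
    for i in range(n):
        for _ in range(1000):
            r = rng.uniform(r0, r1)
            c = rng.uniform(c0, c1)
            if labels[int(round(r)) % labels.shape[0], int(round(c)) % labels.shape[1]] > 0:
                pos[i] = (r, c)
                break
        else:
            raise ConfigurationError("could not place complex inside ROI")
    return pos


def _psf_window(
    pos: tuple[float, float], sigma: float, shape: tuple[int, int], half: int
):
    """Integrated-Gaussian pixel weights on a clipped window around pos.

    The integral of the PSF over pixel (i, j) separates into a product
    of 1-D erf differences, so we return the window slice plus the outer
    product of the two 1-D weight vectors.
    """
    r, c = pos
    ri0 = max(0, int(math.floor(r)) - half)
    ri1 = min(shape[0], int(math.floor(r)) + half + 1)
    ci0 = max(0, int(math.floor(c)) - half)
    ci1 = min(shape[1], int(math.floor(c)) + half + 1)
    if ri0 >= ri1 or ci0 >= ci1:
        return None
    denom = sigma * math.sqrt(2.0)
    rows = np.arange(ri0, ri1)
    cols = np.arange(ci0, ci1)
    wr = 0.5 * (erf((rows + 0.5 - r) / denom) - erf((rows - 0.5 - r) / denom))
    wc = 0.5 * (erf((cols + 0.5 - c) / denom) - erf((cols - 0.5 - c) / denom))
    return (slice(ri0, ri1), slice(ci0, ci1)), np.outer(wr, wc)


def simulate_image_stack(
    cfg: SlimfieldSimConfig,
) -> tuple[ImageStack, ROIMask, GroundTruthTable]:
    """Simulate a photoelectron-calibrated Slimfield movie.

    Returns the stack, the ROI label mask used, and the ground truth.
    Identical config + seed gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = _resolve_roi(cfg)
    shape = tuple(cfg.image_shape)
    n_frames = cfg.frame_count
    half = max(3, int(math.ceil(6.0 * cfg.psf_sigma)))

    if cfg.n_complexes == 0:
        signal = np.full((n_frames, *shape), cfg.background_rate, dtype=np.float64)
        truth = GroundTruthTable(
            complex_ids=np.array([], dtype=int),
            true_subunits=np.array([], dtype=int),
            true_fluorophores=np.array([], dtype=int),
            trajectories=[],
            bleach_frames=[],
            live_counts=[],
        )
        return _finish_stack(signal, cfg, rng), ROIMask(labels), truth

    ks = sorted(cfg.multiple_weights)
    probs = np.array([cfg.multiple_weights[k] for k in ks], dtype=float)
    probs = probs / probs.sum()
    multipliers = rng.choice(ks, size=cfg.n_complexes, p=probs)
    subunits = multipliers * int(cfg.unit_size)
    fluors = rng.binomial(subunits, cfg.maturation_prob)

    positions = _initial_positions(cfg, labels, rng)
    r0, c0, r1, c1 = _roi_bbox(labels)
    step_sd = math.sqrt(2.0 * cfg.diffusion_coeff)

    trajectories: list[np.ndarray] = []
    for i in range(cfg.n_complexes):
        steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2)) if n_frames > 1 else np.empty((0, 2))
        path = positions[i] + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        path[:, 0] = _reflect(path[:, 0], r0, r1)
        path[:, 1] = _reflect(path[:, 1], c0, c1)
        trajectories.append(path)

    bleach_frames: list[np.ndarray] = []
    live_counts: list[np.ndarray] = []
    signal = np.full((n_frames, *shape), cfg.background_rate, dtype=np.float64)
    for i in range(cfg.n_complexes):
        m = int(fluors[i])
        # per-molecule state paths: emitting iff not bleached and not dark
        bleached = np.zeros(m, dtype=bool)
        dark = np.zeros(m, dtype=bool)
        bframes = np.full(m, -1, dtype=int)
        live = np.zeros(n_frames, dtype=int)
        for f in range(n_frames):
            emitting = ~bleached & ~dark
            live[f] = int(emitting.sum())
            if live[f] > 0:
                win = _psf_window(tuple(trajectories[i][f]), cfg.psf_sigma, shape, half)
                if win is not None:
                    sl, w = win
                    signal[f][sl] += live[f] * cfg.brightness * w
            # state transitions applied after the frame's emission
            if cfg.bleach_prob > 0:
                newly = emitting & (rng.random(m) < cfg.bleach_prob)
                bleached |= newly
                bframes[newly] = f + 1
            if cfg.blink_off_prob > 0:
                dark |= (~bleached) & ~dark & (rng.random(m) < cfg.blink_off_prob)
            if cfg.blink_on_prob > 0:
                recover = (~bleached) & dark & (rng.random(m) < cfg.blink_on_prob)
                dark &= ~recover
        bleach_frames.append(bframes)
        live_counts.append(live)

    truth = GroundTruthTable(
        complex_ids=np.arange(cfg.n_complexes),
        true_subunits=subunits,
        true_fluorophores=fluors,
        trajectories=trajectories,
        bleach_frames=bleach_frames,
        live_counts=live_counts,
    )
    return _finish_stack(signal, cfg, rng), ROIMask(labels), truth


def _finish_stack(
    signal: np.ndarray, cfg: SlimfieldSimConfig, rng: np.random.Generator
) -> ImageStack:
    if cfg.shot_noise:
        counts = rng.poisson(signal).astype(np.float64)
    else:
        counts = signal.copy()
    if cfg.read_noise_sd > 0:
        counts += rng.normal(0.0, cfg.read_noise_sd, size=counts.shape)
    pixels = np.clip(np.rint(counts), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return ImageStack(
        pixels=pixels,
        pixel_size=cfg.pixel_size,
        frame_interval=cfg.frame_interval,
        exposure=cfg.exposure,
    )


def expected_noiseless_frame(
    cfg: SlimfieldSimConfig, truth: GroundTruthTable, frame: int
) -> np.ndarray:
    """Expected photoelectrons per pixel for one frame (no noise draw)."""
    shape = tuple(cfg.image_shape)
    half = max(3, int(math.ceil(6.0 * cfg.psf_sigma)))
    signal = np.full(shape, cfg.background_rate, dtype=np.float64)
    for i in range(truth.n_complexes):
        live = truth.live_counts[i][frame]
        if live == 0:
            continue
        win = _psf_window(tuple(truth.trajectories[i][frame]), cfg.psf_sigma, shape, half)
        if win is not None:
            sl, w = win
            signal[sl] += live * cfg.brightness * w
    return signal


def simulate_bleach_traces(
    n_traces: int,
    brightness: float = 56.0,
    bleach_prob: float = 0.05,
    noise_sd: float = 9.0,
    initial_molecules: int | tuple[int, int] | Sequence[int] = 1,
    seed: int | None = None,
    n_frames: int = 500,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Direct trace-level photobleaching generator (bypasses imaging).

    Each trace is ``I(t) = brightness * m(t) + N(0, noise_sd)`` where
    ``m(t)`` is a non-increasing integer path from the trace's initial
    molecule count down to 0 (each molecule bleaches independently with
    per-frame probability ``bleach_prob``).

    ``initial_molecules`` may be a single count, an inclusive
    ``(low, high)`` range drawn uniformly per trace, or a sequence of
    per-trace counts.  Returns ``(traces, molecule_paths)``.
    """
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0; got {noise_sd}")
    _check_pos("brightness", brightness)
    _check_prob("bleach_prob", bleach_prob)
    rng = np.random.default_rng(seed)

    if isinstance(initial_molecules, (int, np.integer)):
        counts = np.full(n_traces, int(initial_molecules))
    elif isinstance(initial_molecules, tuple) and len(initial_molecules) == 2:
        lo, hi = initial_molecules
        counts = rng.integers(int(lo), int(hi) + 1, size=n_traces)
    else:
        counts = np.asarray(list(initial_molecules), dtype=int)
        if counts.size != n_traces:
            raise ConfigurationError(
                f"initial_molecules sequence length {counts.size} != n_traces {n_traces}"
            )
    if np.any(counts < 1):
        raise ConfigurationError("initial_molecules must be >= 1")

    traces: list[np.ndarray] = []
    paths: list[np.ndarray] = []
    for m0 in counts:
        if bleach_prob > 0:
            # geometric lifetimes: molecule emits in frames [0, life)
            lifetimes = rng.geometric(bleach_prob, size=int(m0))
        else:
            lifetimes = np.full(int(m0), n_frames + 1)
        m_t = (lifetimes[None, :] > np.arange(n_frames)[:, None]).sum(axis=1)
        trace = brightness * m_t.astype(float)
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
        traces.append(trace)
        paths.append(m_t.astype(int))
    return traces, paths


@dataclass
class PAMSimConfig:
    """Settings for :func:`simulate_pam_trace`.

    ``npq_schedule`` is a callable ``t -> NPQ(t)`` or a list of
    ``(time, npq)`` breakpoints interpreted as a step function.
    Saturating-pulse maxima are ``Fm / (1 + NPQ(t))`` so quenching
    metrics round-trip exactly.
    """

    Fo: float = 0.2
    Fm: float = 1.0
    npq_schedule: Callable[[float], float] | Sequence[tuple[float, float]] = ()
    pulse_times: Sequence[float] = ()
    light_on: float = 0.0
    light_off: float = 300.0
    duration: float = 600.0
    sample_interval: float = 0.1
    pulse_width: float = 0.3
    stationary_fraction: float = 0.5  # F between pulses, as a fraction of Fm'
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.Fm > self.Fo > 0):
            raise ConfigurationError(f"need Fm > Fo > 0; got Fm={self.Fm}, Fo={self.Fo}")
        if any(t < 0 for t in self.pulse_times):
            raise ConfigurationError("pulse times must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def npq_at(self, t: float) -> float:
        sched = self.npq_schedule
        if callable(sched):
            value = float(sched(t))
        else:
            value = 0.0
            for t0, npq in sorted(sched):
                if t >= t0:
                    value = float(npq)
        if value < 0:
            raise ConfigurationError(f"npq_schedule gave NPQ < 0 at t={t}")
        return value


def simulate_pam_trace(cfg: PAMSimConfig):
    """Simulate a PAM chlorophyll-fluorescence record.

    Between pulses the fluorescence sits at ``stationary_fraction *
    Fm'(t)`` (``Fo`` in darkness before light-on); during a saturating
    pulse it jumps to ``Fm' = Fm / (1 + NPQ(t))``.
    """
    from .photophys import PAMTrace

    rng = np.random.default_rng(cfg.seed)
    time = np.arange(0.0, cfg.duration, cfg.sample_interval)
    fluor = np.empty_like(time)
    pulses = np.sort(np.asarray(cfg.pulse_times, dtype=float))
    for j, t in enumerate(time):
        fm_prime = cfg.Fm / (1.0 + cfg.npq_at(t))
        in_pulse = np.any((pulses <= t) & (t < pulses + cfg.pulse_width))
        if in_pulse:
            fluor[j] = fm_prime
        elif cfg.light_on <= t < cfg.light_off:
            fluor[j] = cfg.stationary_fraction * fm_prime
        else:
            fluor[j] = cfg.Fo
    if cfg.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, cfg.noise_sd, size=fluor.size)
    return PAMTrace(
        time=time,
        fluorescence=fluor,
        pulse_times=pulses,
        light_on=cfg.light_on,
        light_off=cfg.light_off,
        Fm=cfg.Fm,
        Fo=cfg.Fo,
    )


@dataclass
class ECSSimConfig:
    """Settings for :func:`simulate_ecs_trace`.

    The normalized dual-wavelength signal is ``pmf_amplitude`` during
    illumination, then ``offset + pmf_amplitude * exp(-(t - light_off)
    / tau)`` after light-off.  The raw 520 nm channel carries the signal
    scaled by ``ecs_st``; the 545 nm channel carries only noise.
    """

    pmf_amplitude: float = 1.0
    tau: float = 0.05
    ecs_st: float = 1.0
    light_off_time: float = 1.0
    duration: float = 2.0
    sample_interval: float = 0.001
    offset: float = 0.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_pos("tau", self.tau)
        _check_pos("ecs_st", self.ecs_st)
        if self.sample_interval > 0.005:
            raise ConfigurationError(
                "sample_interval must be <= 0.005 s so >= 20 samples fall in the "
                f"100 ms decay-fit window; got {self.sample_interval}"
            )
        if not 0 < self.light_off_time < self.duration:
            raise ConfigurationError("light_off_time must lie inside the record")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def simulate_ecs_trace(cfg: ECSSimConfig):
    from .photophys import ECSTrace

    rng = np.random.default_rng(cfg.seed)
    time = np.arange(0.0, cfg.duration, cfg.sample_interval)
    normalized = np.where(
        time < cfg.light_off_time,
        cfg.pmf_amplitude,
        cfg.offset + cfg.pmf_amplitude * np.exp(-(time - cfg.light_off_time) / cfg.tau),
    )
    a520 = normalized * cfg.ecs_st
    a545 = np.zeros_like(time)
    if cfg.noise_sd > 0:
        a520 = a520 + rng.normal(0.0, cfg.noise_sd * cfg.ecs_st, size=time.size)
        a545 = a545 + rng.normal(0.0, cfg.noise_sd * cfg.ecs_st, size=time.size)
    return ECSTrace(
        time=time,
        a520=a520,
        a545=a545,
        ecs_st=cfg.ecs_st,
        light_off_time=cfg.light_off_time,
    )
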