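"""Synthetic plantar tactile sequences for five walking states.

The generator emulates the acquisition protocol of a plantar tactile
study: 50 Hz sampling, 50-frame collections, forces within the sensor's
0-60 N range, five states (normal walking plus falls forward, backward,
left, right), and ground-condition variants.

The waveform model: during each gait cycle the load progresses
heel -> metatarsals -> toes, so every unit's normal force is a periodic
Gaussian bump centred at its region's phase in the cycle, scaled by a
per-region peak force.  Tangential channels are proportional to the
signed time derivative of the normal channel (f_y tracks the
antero-posterior progression; f_x carries the medio-lateral asymmetry
with opposite sign on medial and lateral sensors).  A fall linearly
blends the periodic gait into a sustained directional loading pattern
over a short transition window: the centre of pressure freezes on the
regions the body tips toward (forward: toes and metatarsals; backward:
heels; left: medial regions; right: lateral regions), with a
progressive f_x sign shift for the sideways falls.

This is a phenomenological stand-in, not a biomechanical simulation;
every shape parameter is exposed so the generator can be re-targeted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .layout import N_UNITS, SensorUnit, default_layout, sensor_ids

FS_HZ = 50.0
FRAMES_PER_COLLECTION = 50
FORCE_MAX_N = 60.0
TANGENTIAL_MAX_N = 12.0  # |tangential| <= 0.2 * 60 N

STATE_NAMES = ("normal", "forward", "backward", "left", "right")

# regions: 0 toe, 1 first metatarsal, 2 third-fifth metatarsal,
#          3 medial heel, 4 lateral heel
# Walking loads on a nursing-aid sole are light (the user steadies, not
# stands, on it); a fall collapses body weight onto it, driving the
# recipient regions toward the sensor's 60 N ceiling.  That contrast is
# what makes the five states recoverable from force magnitude + pattern.
_REGION_PHASE = np.array([0.72, 0.50, 0.45, 0.08, 0.12])
_REGION_PEAK_N = np.array([10.0, 14.0, 13.0, 18.0, 16.0])
_SIDE_SIGN = np.array([0.5, 1.0, -1.0, 1.0, -1.0])  # medial +, lateral -

# sustained post-fall loading, as a fraction of FORCE_MAX_N per region
# (toe, first met, third-fifth met, medial heel, lateral heel)
_FALL_PATTERN = {
    1: np.array([0.80, 0.70, 0.70, 0.05, 0.05]),  # forward: onto forefoot
    2: np.array([0.02, 0.05, 0.05, 0.85, 0.85]),  # backward: onto heels
    3: np.array([0.30, 0.75, 0.05, 0.75, 0.10]),  # left: onto medial edge
    4: np.array([0.30, 0.05, 0.75, 0.10, 0.75]),  # right: onto lateral edge
}


class SimulationError(ValueError):
    pass


@dataclass
class GaitParams:
    """Shape of the periodic walking waveform."""

    cadence: float = 0.9                     # strides / second (~1 m/s walk)
    region_peak_n: np.ndarray = field(
        default_factory=lambda: _REGION_PEAK_N.copy()
    )
    region_phase: np.ndarray = field(
        default_factory=lambda: _REGION_PHASE.copy()
    )
    bump_width: float = 0.12                 # cycle fraction (Gaussian sd)
    tangential_ratio: float = 0.2            # |f_x|,|f_y| cap as f_z fraction
    noise_sd: float = 0.5                    # newtons
    initial_phase: float = 0.0               # cycle fraction at frame 0

    def validate(self) -> None:
        peaks = np.asarray(self.region_peak_n, dtype=float)
        phases = np.asarray(self.region_phase, dtype=float)
        if peaks.shape != (5,) or phases.shape != (5,):
            raise SimulationError("region arrays must have length 5")
        if np.any(peaks <= 0) or np.any(peaks > FORCE_MAX_N):
            raise SimulationError("region peaks must lie in (0, 60] N")
        if np.any((phases < 0) | (phases >= 1)):
            raise SimulationError("region phases must lie in [0, 1)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.cadence <= 0 or self.bump_width <= 0:
            raise SimulationError("cadence and bump_width must be > 0")


@dataclass
class FallSpec:
    """A directional fall injected into an otherwise normal sequence."""

    direction: str                  # forward | backward | left | right
    onset_frame: int = 25
    transition_frames: int = 3      # 60 ms at 50 Hz: an abrupt impact
    intensity: float = 1.0          # 0..1 amplitude-transfer magnitude

    @property
    def class_index(self) -> int:
        try:
            return STATE_NAMES.index(self.direction)
        except ValueError:
            raise SimulationError(
                f"unknown fall direction {self.direction!r}"
            ) from None

    def validate(self, t_frames: int) -> None:
        if self.direction not in STATE_NAMES[1:]:
            raise SimulationError(f"unknown fall direction {self.direction!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise SimulationError("intensity must lie in [0, 1]")
        if self.onset_frame < 0 or (
            self.onset_frame + self.transition_frames > t_frames
        ):
            raise SimulationError(
                "onset + transition must fit inside the sequence"
            )


@dataclass(frozen=True)
class GroundCondition:
    """Ground type / morphology preset modulating the waveform."""

    name: str
    noise_multiplier: float = 1.0
    amplitude_scale: float = 1.0
    phase_jitter_sd: float = 0.0   # per-region random phase jitter (cycles)
    phase_shift: float = 0.0       # systematic phase offset (cycles)
    pattern_blend: float = 0.0     # 0..1: dilute directional fall signature

    def validate(self) -> None:
        if self.noise_multiplier <= 0 or self.amplitude_scale <= 0:
            raise SimulationError("condition multipliers must be > 0")
        if not 0.0 <= self.pattern_blend < 1.0:
            raise SimulationError("pattern_blend must lie in [0, 1)")


def condition_presets() -> dict[str, GroundCondition]:
    """Named ground presets.  Ceramic is the reference; wood and cement
    raise noise and damp amplitude; stairs and slope additionally shift
    the phase profile (a distribution shift relative to flat ground)."""
    return {
        "ceramic": GroundCondition("ceramic"),
        "wood": GroundCondition("wood", noise_multiplier=2.0,
                                amplitude_scale=0.92, pattern_blend=0.35),
        "cement": GroundCondition("cement", noise_multiplier=3.0,
                                  amplitude_scale=0.85, pattern_blend=0.45),
        "stairs": GroundCondition("stairs", noise_multiplier=2.5,
                                  amplitude_scale=0.85,
                                  phase_jitter_sd=0.08, phase_shift=0.10,
                                  pattern_blend=0.60),
        "slope": GroundCondition("slope", noise_multiplier=2.0,
                                 amplitude_scale=0.88,
                                 phase_jitter_sd=0.06, phase_shift=-0.08,
                                 pattern_blend=0.50),
    }


@dataclass
class SimulatedSequence:
    forces: np.ndarray   # (T, 40, 3) newtons, axes (f_x, f_y, f_z)
    labels: np.ndarray   # (T,) class indices
    meta: dict


def _wrap_phase(d: np.ndarray) -> np.ndarray:
    """Signed circular distance in cycle fractions, range [-0.5, 0.5)."""
    return (d + 0.5) % 1.0 - 0.5


# fixed per-unit amplitude taper so the eight units of one sensor differ
_UNIT_FACTOR = 0.85 + 0.3 * (np.arange(8) / 7.0)


def simulate_sequence(
    gait: GaitParams | None = None,
    fall: FallSpec | None = None,
    condition: GroundCondition | None = None,
    t_frames: int = FRAMES_PER_COLLECTION,
    seed: int = 0,
    units: list[SensorUnit] | None = None,
) -> SimulatedSequence:
    """Generate one labelled tactile sequence; deterministic given seed."""
    gait = gait or GaitParams()
    condition = condition or condition_presets()["ceramic"]
    gait.validate()
    condition.validate()
    if fall is not None:
        fall.validate(t_frames)
    units = units or default_layout()
    sid = sensor_ids(units)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    phases = np.asarray(gait.region_phase, float) + condition.phase_shift
    if condition.phase_jitter_sd > 0:
        phases = phases + rng.normal(0, condition.phase_jitter_sd, size=5)
    phases = phases % 1.0

    t = np.arange(t_frames) / FS_HZ
    cycle = (gait.initial_phase + t * gait.cadence) % 1.0  # (T,)

    unit_phase = phases[sid]                           # (40,)
    unit_peak = (
        np.asarray(gait.region_peak_n, float)[sid]
        * _UNIT_FACTOR[np.arange(N_UNITS) % 8]
        * condition.amplitude_scale
    )
    d = _wrap_phase(cycle[:, None] - unit_phase[None, :])   # (T, 40)
    base = np.exp(-0.5 * (d / gait.bump_width) ** 2)        # (T, 40)
    fz = unit_peak[None, :] * base

    labels = np.zeros(t_frames, dtype=np.int8)
    ramp = np.zeros(t_frames)
    if fall is not None:
        k = fall.class_index
        after = np.arange(t_frames) - fall.onset_frame
        if fall.transition_frames > 0:
            ramp = np.clip(after / fall.transition_frames, 0.0, 1.0)
        else:
            ramp = (after >= 0).astype(float)
        ramp *= fall.intensity
        pattern = _FALL_PATTERN[k]
        if condition.pattern_blend > 0:
            # ground morphology changes fall biomechanics: the regional
            # impact signature drifts toward a direction-neutral mix
            mean_pattern = np.mean(list(_FALL_PATTERN.values()), axis=0)
            pattern = ((1.0 - condition.pattern_blend) * pattern
                       + condition.pattern_blend * mean_pattern)
        static = (
            pattern[sid]
            * FORCE_MAX_N
            * _UNIT_FACTOR[np.arange(N_UNITS) % 8]
            * condition.amplitude_scale
        )  # (40,)
        fz = (1.0 - ramp)[:, None] * fz + ramp[:, None] * static[None, :]
        labels[fall.onset_frame:] = k

    # tangential channels from the signed slope of the (noise-free) load
    dfz = np.gradient(fz, 1.0 / FS_HZ, axis=0)
    denom = np.maximum(np.abs(dfz).max(axis=0, keepdims=True), 1e-9)
    slope = dfz / denom                                  # (T, 40) in [-1, 1]
    fy = gait.tangential_ratio * unit_peak[None, :] * slope
    fx = 0.5 * gait.tangential_ratio * unit_peak[None, :] * slope \
        * _SIDE_SIGN[sid][None, :]
    if fall is not None and fall.direction == "left":
        fx = fx * (1.0 - 2.0 * ramp)[:, None]   # progressive sign flip
    elif fall is not None and fall.direction == "right":
        fx = fx * (1.0 + ramp)[:, None]         # mirrored: same-sign boost

    noise_sd = gait.noise_sd * condition.noise_multiplier
    if noise_sd > 0:
        fz = fz + rng.normal(0, noise_sd, fz.shape)
        fy = fy + rng.normal(0, 0.5 * noise_sd, fy.shape)
        fx = fx + rng.normal(0, 0.5 * noise_sd, fx.shape)

    fz = np.clip(fz, 0.0, FORCE_MAX_N)
    fx = np.clip(fx, -TANGENTIAL_MAX_N, TANGENTIAL_MAX_N)
    fy = np.clip(fy, -TANGENTIAL_MAX_N, TANGENTIAL_MAX_N)

    forces = np.stack([fx, fy, fz], axis=-1)
    meta = {
        "seed": int(seed),
        "fs": FS_HZ,
        "condition": condition.name,
        "state": STATE_NAMES[fall.class_index] if fall else "normal",
        "onset_frame": fall.onset_frame if fall else None,
    }
    return SimulatedSequence(forces=forces, labels=labels, meta=meta)


def _state_counts(n: int, mix: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n sequences over 5 states."""
    exact = n * mix
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:short]] += 1
    return counts


def sequence_seed(master_seed: int, index: int) -> int:
    """Per-sequence seed so any single sequence can be regenerated."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_collection(
    master_seed: int,
    index: int,
    state: int,
    condition: GroundCondition,
    base_gait: GaitParams,
    t_frames: int = FRAMES_PER_COLLECTION,
    units: list[SensorUnit] | None = None,
) -> SimulatedSequence:
    """One dataset entry: per-sequence gait variation + optional fall."""
    seed = sequence_seed(master_seed, index)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    gait = replace(
        base_gait,
        cadence=base_gait.cadence * rng.uniform(0.9, 1.1),
        region_peak_n=np.clip(
            np.asarray(base_gait.region_peak_n)
            * rng.uniform(0.9, 1.1, size=5),
            1.0, FORCE_MAX_N,
        ),
        initial_phase=rng.uniform(0.0, 1.0),
    )
    fall = None
    if state != 0:
        fall = FallSpec(
            direction=STATE_NAMES[state],
            onset_frame=int(rng.integers(20, 31)),
            transition_frames=3,
            intensity=1.0,
        )
    seq = simulate_sequence(
        gait, fall, condition, t_frames=t_frames, seed=seed, units=units
    )
    seq.meta["index"] = index
    return seq


def simulate_dataset(
    n_sequences: int = 5000,
    state_mix: np.ndarray | None = None,
    condition: GroundCondition | str = "ceramic",
    split: tuple[int, int] = (4000, 1000),
    seed: int = 0,
    t_frames: int = FRAMES_PER_COLLECTION,
    gait: GaitParams | None = None,
    units: list[SensorUnit] | None = None,
):
    """Generate a labelled synthetic dataset with a train/test split.

    Returns ``(train, test, manifest)`` where train/test are
    :class:`~plantargait.datasets.TactileDataset` and the manifest
    records counts per state, the condition and the master seed.  Every
    sequence is regenerable in isolation from ``sequence_seed(seed, i)``.
    """
    from .datasets import TactileDataset

    if sum(split) != n_sequences:
        raise SimulationError(
            f"split {split} does not sum to n_sequences {n_sequences}"
        )
    mix = (np.full(5, 0.2) if state_mix is None
           else np.asarray(state_mix, dtype=float))
    if not np.isclose(mix.sum(), 1.0):
        raise SimulationError("state_mix must sum to 1")
    if isinstance(condition, str):
        condition = condition_presets()[condition]
    gait = gait or GaitParams()

    counts = _state_counts(n_sequences, mix)
    states = np.repeat(np.arange(5), counts)
    np.random.default_rng(np.random.SeedSequence([seed, 999])).shuffle(states)

    forces = np.empty((n_sequences, t_frames, N_UNITS, 3), dtype=np.float32)
    labels = np.empty((n_sequences, t_frames), dtype=np.int8)
    units = units or default_layout()
    for i in range(n_sequences):
        seq = simulate_collection(
            seed, i, int(states[i]), condition, gait,
            t_frames=t_frames, units=units,
        )
        forces[i] = seq.forces
        labels[i] = seq.labels

    n_train = split[0]
    meta = {"seed": int(seed), "fs": FS_HZ, "condition": condition.name,
            "generator_version": 1}
    train = TactileDataset(forces=forces[:n_train], labels=labels[:n_train],
                           meta=dict(meta, split="train"))
    test = TactileDataset(forces=forces[n_train:], labels=labels[n_train:],
                          meta=dict(meta, split="test"))
    manifest = {
        "n_sequences": int(n_sequences),
        "n_train": int(n_train),
        "n_test": int(split[1]),
        "frames_per_collection": int(t_frames),
        "fs_hz": FS_HZ,
        "condition": condition.name,
        "seed": int(seed),
        "generator_version": 1,
        "counts_per_state": {
            STATE_NAMES[s]: int(c) for s, c in enumerate(counts)
        },
    }
    return train, test, manifest
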