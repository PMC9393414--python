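"""Synthetic hypnograms, stage-conditioned movement, and toy sleep video.

No public pediatric sleep-video dataset exists, so the pipeline is
exercised on simulated recordings built from three layers:

1. a Markov-chain hypnogram whose stationary stage proportions follow an
   age-group preset, with a mild drift that makes Deep more likely early in
   the night and REM late;
2. a stage-conditioned movement model: movement bouts arrive within each
   30 s epoch at a stage-specific rate, with log-normal pixel-count
   magnitudes (counts are positive and right-skewed); the slow channel sees
   each bout smeared over the bout duration plus the slow-lag span;
3. optionally, a rendered toy video: a bright rectangular "child" blob that
   makes stage-conditioned random jumps over a static dark bed, so the full
   video -> rectification -> differencing path can be tested end to end.

Every simulator output is a pure function of (model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .classify import STAGES, Hypnogram, Recording
from .features import compute_features, default_k, standardize
from .movement import MovementSeries
from .video import FrameSequence, GeometryError

#: Default pixel count of the rectified ROI assumed by the movement model.
DEFAULT_ROI_AREA = 10_000

#: Frames per 30 s epoch at 2 fps.
SAMPLES_PER_EPOCH = 60

AGE_GROUPS = ("group_0_2", "group_3_6")


def load_presets() -> dict:
    """Parse the packaged calibration presets (age groups, movement, blob)."""
    text = resources.files("somnocam").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def normalize_age_group(name: str) -> str:
    """Accept '0-2', '3-6', 'group_0_2', 'group_3_6' spellings."""
    key = name.strip().lower().replace("-", "_").replace("group_", "")
    if key in ("0_2", "02"):
        return "group_0_2"
    if key in ("3_6", "36"):
        return "group_3_6"
    raise ValueError(f"unknown age group: {name!r} (expected 0-2 or 3-6)")


@dataclass
class HypnogramModel:
    """Markov model of nightly sleep-stage succession.

    ``transition`` rows (one per stage, ordered as :data:`STAGES`) must each
    sum to 1.  ``time_inhomogeneity`` shifts the Deep logit up by that
    amount at lights-off and down at wake-up time (and the REM logit the
    opposite way), linearly across the night.
    """

    initial: np.ndarray
    transition: np.ndarray
    time_inhomogeneity: float = 0.0

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.initial.shape != (4,) or self.transition.shape != (4, 4):
            raise ValueError("initial must be length 4 and transition 4x4")
        if (self.transition < 0).any() or (self.initial < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")

    @classmethod
    def from_proportions(
        cls,
        proportions: dict[str, float],
        stickiness: float = 0.85,
        time_inhomogeneity: float = 0.0,
    ) -> "HypnogramModel":
        """Sticky chain with a prescribed stationary distribution.

        The transition matrix mixes staying put (weight ``stickiness``) with
        an independent redraw from ``proportions``; its stationary
        distribution is exactly ``proportions``.
        """
        pi = np.array([proportions[s] for s in STAGES], dtype=float)
        pi = pi / pi.sum()
        if not 0 <= stickiness < 1:
            raise ValueError("stickiness must lie in [0, 1)")
        transition = stickiness * np.eye(4) + (1 - stickiness) * np.tile(pi, (4, 1))
        return cls(initial=pi, transition=transition, time_inhomogeneity=time_inhomogeneity)

    def row_at(self, state: int, fraction: float) -> np.ndarray:
        """Transition row from ``state`` at night fraction ``fraction`` in [0, 1]."""
        row = self.transition[state].copy()
        a = self.time_inhomogeneity
        if a == 0.0:
            return row
        shift = np.zeros(4)
        shift[STAGES.index("Deep")] = a * (1.0 - 2.0 * fraction)
        shift[STAGES.index("REM")] = -a * (1.0 - 2.0 * fraction)
        with np.errstate(divide="ignore"):
            logits = np.where(row > 0, np.log(row), -np.inf) + shift
        shifted = np.exp(logits - logits.max())
        return shifted / shifted.sum()


def simulate_hypnogram(model: HypnogramModel, n_epochs: int, seed: int) -> Hypnogram:
    """Sample a night of 30 s stage labels from the Markov model."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    states = np.empty(n_epochs, dtype=int)
    states[0] = rng.choice(4, p=model.initial)
    denom = max(n_epochs - 1, 1)
    for t in range(1, n_epochs):
        row = model.row_at(states[t - 1], fraction=t / denom)
        states[t] = rng.choice(4, p=row)
    return Hypnogram([STAGES[s] for s in states])


@dataclass
class StageBouts:
    """Movement-bout statistics for one stage.

    ``event_rate`` is the expected bout count per 30 s epoch,
    ``magnitude_mean`` the mean bout pixel count (log-normal with shape
    ``magnitude_dispersion``), ``duration`` the bout length in 0.5 s samples.
    """

    event_rate: float
    magnitude_mean: float
    magnitude_dispersion: float = 0.5
    duration: int = 3

    def __post_init__(self) -> None:
        if min(self.event_rate, self.magnitude_mean, self.magnitude_dispersion) < 0:
            raise ValueError("rates and magnitudes must be non-negative")
        if self.duration < 1:
            raise ValueError("duration must be >= 1 sample")

    @property
    def mean_per_sample(self) -> float:
        """Analytic per-sample mean contribution to the fast channel."""
        return self.event_rate * self.magnitude_mean * self.duration / SAMPLES_PER_EPOCH


@dataclass
class StageMovementModel:
    """Per-stage bout models plus the still-period noise floor (Poisson mean)."""

    stages: dict[str, StageBouts]
    noise_floor: float = 3.0

    def __post_init__(self) -> None:
        missing = set(STAGES) - set(self.stages)
        if missing:
            raise ValueError(f"missing stage models: {sorted(missing)}")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")


def default_movement_model() -> StageMovementModel:
    """Movement model from the packaged presets (well-separated stages)."""
    cfg = load_presets()["movement"]
    return StageMovementModel(
        stages={s: StageBouts(**cfg["stages"][s]) for s in STAGES},
        noise_floor=float(cfg["noise_floor"]),
    )


def stage_independent_model(reference_stage: str = "Light") -> StageMovementModel:
    """Null-control model: every stage shares one bout distribution.

    Movement then carries no stage information, so any classifier working
    from movement features alone should perform at chance.
    """
    base = default_movement_model()
    shared = base.stages[reference_stage]
    return StageMovementModel(
        stages={s: shared for s in STAGES}, noise_floor=base.noise_floor
    )


def simulate_movement(
    hypnogram: Hypnogram,
    model: StageMovementModel,
    seed: int,
    roi_area: int = DEFAULT_ROI_AREA,
    slow_lag: int = 6,
) -> MovementSeries:
    """Generate the fast/slow movement series implied by a hypnogram.

    Within each epoch, a Poisson number of bouts arrive at uniform times;
    each bout adds its log-normal magnitude to the fast channel for
    ``duration`` samples and to the slow channel for ``duration + slow_lag``
    samples (a slow-lag difference stays large until the lagged frame has
    also moved past the event).  Poisson noise is added everywhere, and
    counts are clipped to the ROI area.
    """
    rng = np.random.default_rng(seed)
    n = SAMPLES_PER_EPOCH * len(hypnogram)
    fast = np.zeros(n)
    slow = np.zeros(n)
    for e, stage in enumerate(hypnogram.stages):
        bouts = model.stages[stage]
        count = rng.poisson(bouts.event_rate)
        if count == 0:
            continue
        starts = SAMPLES_PER_EPOCH * e + rng.integers(0, SAMPLES_PER_EPOCH, count)
        sigma = bouts.magnitude_dispersion
        mu = np.log(bouts.magnitude_mean) - sigma**2 / 2 if bouts.magnitude_mean > 0 else -np.inf
        magnitudes = rng.lognormal(mu, sigma, count) if bouts.magnitude_mean > 0 else np.zeros(count)
        for start, mag in zip(starts, magnitudes):
            fast[start : start + bouts.duration] += mag
            slow[start : start + bouts.duration + slow_lag] += mag
    if model.noise_floor > 0:
        fast += rng.poisson(model.noise_floor, n)
        slow += rng.poisson(model.noise_floor, n)
    fast = np.clip(np.rint(fast), 0, roi_area).astype(np.int64)
    slow = np.clip(np.rint(slow), 0, roi_area).astype(np.int64)
    return MovementSeries(fast, slow, sample_interval=0.5, roi_area=roi_area)


@dataclass
class BlobSpec:
    """Rendering parameters of the toy 'sleeping child' blob.

    ``stage_params`` maps each stage to (jump probability per frame, maximum
    jump step in pixels).  Contrast between ``foreground`` and
    ``background`` must exceed the binarization threshold used downstream.
    """

    width: int = 8
    height: int = 8
    background: int = 20
    foreground: int = 220
    stage_params: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stage_params:
            cfg = load_presets()["blob"]["stages"]
            self.stage_params = {s: (cfg[s]["jump_prob"], cfg[s]["step"]) for s in STAGES}


def render_video(
    hypnogram: Hypnogram,
    blob: BlobSpec,
    frame_size: tuple[int, int],
    seed: int,
) -> FrameSequence:
    """Render toy sleep video: 60 frames per epoch at 0.5 s spacing.

    The blob starts at the frame center and, on each frame, jumps with its
    stage's probability by a uniform step of up to the stage's step size in
    each axis, clipped to the frame.
    """
    height, width = frame_size
    if blob.height > height or blob.width > width:
        raise GeometryError(
            f"blob {blob.width}x{blob.height} does not fit in frame {width}x{height}"
        )
    rng = np.random.default_rng(seed)
    n = SAMPLES_PER_EPOCH * len(hypnogram)
    frames = np.full((n, height, width), blob.background, dtype=np.uint8)
    y = (height - blob.height) // 2
    x = (width - blob.width) // 2
    for i in range(n):
        stage = hypnogram.stages[i // SAMPLES_PER_EPOCH]
        jump_prob, step = blob.stage_params[stage]
        if i > 0 and step > 0 and rng.random() < jump_prob:
            x += int(rng.integers(-step, step + 1))
            y += int(rng.integers(-step, step + 1))
            x = int(np.clip(x, 0, width - blob.width))
            y = int(np.clip(y, 0, height - blob.height))
        frames[i, y : y + blob.height, x : x + blob.width] = blob.foreground
    return FrameSequence(frames, sample_interval=0.5)


def hypnogram_model_for(age_group: str) -> HypnogramModel:
    """Hypnogram model from the packaged age-group preset."""
    cfg = load_presets()["hypnogram"][normalize_age_group(age_group)]
    return HypnogramModel.from_proportions(
        cfg["stage_proportions"],
        stickiness=cfg["stickiness"],
        time_inhomogeneity=cfg["time_inhomogeneity"],
    )


def make_cohort(
    n_recordings: int,
    age_group: str = "group_0_2",
    n_epochs: int = 900,
    seed: int = 0,
    movement_model: StageMovementModel | None = None,
    stage_independent: bool = False,
    roi_area: int = DEFAULT_ROI_AREA,
    out_dir: str | Path | None = None,
) -> list[Recording]:
    """Simulate a cohort of nights ready for leave-one-night-out evaluation.

    Per-recording seeds are derived from the master seed, so the cohort is
    reproducible as a whole.  With ``out_dir`` set, movement CSVs, feature
    CSVs, hypnogram CSVs and a cohort YAML manifest are written there.
    """
    if n_recordings < 2:
        raise ValueError("a cohort needs at least 2 recordings for leave-one-out use")
    age_group = normalize_age_group(age_group)
    if movement_model is None:
        movement_model = (
            stage_independent_model() if stage_independent else default_movement_model()
        )
    hyp_model = hypnogram_model_for(age_group)
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_recordings) % (2**31)

    recordings = []
    for r in range(n_recordings):
        rec_id = f"{age_group}_rec{r + 1:02d}"
        hyp = simulate_hypnogram(hyp_model, n_epochs, seed=int(child_seeds[2 * r]))
        series = simulate_movement(
            hyp, movement_model, seed=int(child_seeds[2 * r + 1]), roi_area=roi_area
        )
        feats = standardize(
            compute_features(series, k=default_k(roi_area), recording_id=rec_id)
        )
        recordings.append(
            Recording(recording_id=rec_id, age_group=age_group, features=feats, hypnogram=hyp)
        )

    if out_dir is not None:
        from .cohort import write_cohort

        write_cohort(recordings, out_dir)
    return recordings
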