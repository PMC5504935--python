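"""Synthetic scenes and synthetic oddball EEG sessions.

Stands in for camera photographs and human recordings: cluttered
multi-blob scenes whose blob colors sit near the trained seed pixels and
whose global illumination is a multiplicative channel scale, and speller
EEG sessions where every flash covering the attended target carries a
positive P300-like half-cosine deflection at 300 ms over Gaussian
background noise, spread over the 30 channels by a fixed posterior-weighted
topography.

Everything is bit-reproducible under a fixed ``rng_seed``; ground-truth
blob masks are recorded before jitter and clutter are applied so
intersection-over-union against extracted masks is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from . import eeg_pipeline as ep
from .p300_speller import (
    REPETITION_MS,
    RepetitionSchedule,
    SeedDatasetEntry,
    SpellerLayout,
    build_schedule,
    default_dataset,
)
from .segmentation import GrowthConfig, extract_object

__all__ = [
    "BlobSpec",
    "SceneSpec",
    "ERPSpec",
    "EndToEndReport",
    "default_scene_spec",
    "single_object_scene_spec",
    "make_scene",
    "make_eeg_session",
    "mask_iou",
    "run_end_to_end",
]

#: Uniform background far (in vector angle) from every trained seed color.
BACKGROUND_RGB = (180, 40, 170)

PRE_MS = 500  # quiet lead-in before the first flash (filter warm-up)
INTER_TRIAL_MS = 1000  # pause between trials; also covers the last epoch
TAIL_MS = 1200


@dataclass(frozen=True)
class BlobSpec:
    """One colored object blob on the canvas."""

    object_id: str
    seed: tuple[int, int, int]
    top_left: tuple[int, int]
    size: tuple[int, int] = (24, 24)
    shape: str = "rect"  # "rect" | "ellipse"
    jitter_sd: float = 3.0  # per-channel Gaussian sensor noise, 8-bit counts

    def __post_init__(self) -> None:
        if self.shape not in ("rect", "ellipse"):
            raise ValueError(f"shape must be 'rect' or 'ellipse', got {self.shape!r}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """A cluttered scene under a multiplicative illumination scale."""

    shape: tuple[int, int] = (120, 160)
    blobs: tuple[BlobSpec, ...] = ()
    n_clutter: int = 40
    clutter_margin: int = 2  # speckles keep this many px clear of blobs
    illumination: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.illumination <= 0:
            raise ValueError("illumination must be > 0")
        if self.n_clutter < 0 or self.clutter_margin < 0:
            raise ValueError("clutter counts/margins must be >= 0")


def default_scene_spec(
    illumination: float = 1.0, rng_seed: int = 0, dataset: dict[str, SeedDatasetEntry] | None = None
) -> SceneSpec:
    """Seven blobs (one per trained object) on a 120x160 canvas."""
    dataset = dataset or default_dataset()
    anchors = [(8, 10), (8, 66), (8, 122), (54, 10), (54, 66), (54, 122), (92, 10)]
    shapes = ("rect", "ellipse", "rect", "ellipse", "rect", "ellipse", "rect")
    blobs = tuple(
        BlobSpec(object_id=oid, seed=dataset[oid].seed, top_left=anchors[i], shape=shapes[i])
        for i, oid in enumerate(sorted(dataset))
    )
    return SceneSpec(blobs=blobs, illumination=illumination, rng_seed=rng_seed)


def single_object_scene_spec(
    object_id: str,
    illumination: float = 1.0,
    rng_seed: int = 0,
    dataset: dict[str, SeedDatasetEntry] | None = None,
) -> SceneSpec:
    """One dominant blob of the requested object plus clutter speckles.

    The well-posed world for gate-free extraction: with the squared-RGB
    distance gate disabled, objects whose trained fuzzy ranges accept each
    other's seed color (the published parameter rows contain such pairs)
    cannot coexist in one scene, so illumination-robustness is stated on a
    scene dominated by the single object of interest.
    """
    dataset = dataset or default_dataset()
    blob = BlobSpec(
        object_id=object_id, seed=dataset[object_id].seed, top_left=(30, 50), size=(40, 48)
    )
    return SceneSpec(blobs=(blob,), illumination=illumination, rng_seed=rng_seed)


def _blob_mask(blob: BlobSpec, shape: tuple[int, int]) -> np.ndarray:
    M, N = shape
    mask = np.zeros((M, N), dtype=bool)
    m0, n0 = blob.top_left
    h, w = blob.size
    m1, n1 = min(M, m0 + h), min(N, n0 + w)
    if blob.shape == "rect":
        mask[m0:m1, n0:n1] = True
    else:
        mm, nn = np.mgrid[m0:m1, n0:n1]
        cm, cn = m0 + (h - 1) / 2.0, n0 + (w - 1) / 2.0
        mask[m0:m1, n0:n1] = ((mm - cm) / (h / 2.0)) ** 2 + ((nn - cn) / (w / 2.0)) ** 2 <= 1.0
    return mask


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render a scene; returns (uint8 image, ground-truth masks by object).

    Blob interiors are the seed color plus per-pixel channel jitter;
    clutter speckles of random color are scattered off-blob; the
    multiplicative illumination scale is applied last and the result
    clipped to 8 bits.  Masks are recorded before jitter and clutter.
    """
    rng = np.random.default_rng(spec.rng_seed)
    M, N = spec.shape
    base = np.empty((M, N, 3), dtype=float)
    base[:] = BACKGROUND_RGB

    masks: dict[str, np.ndarray] = {}
    union = np.zeros((M, N), dtype=bool)
    for blob in spec.blobs:
        mask = _blob_mask(blob, spec.shape)
        masks[blob.object_id] = mask
        union |= mask
        n_px = int(mask.sum())
        jitter = rng.normal(0.0, blob.jitter_sd, size=(n_px, 3))
        base[mask] = np.clip(np.asarray(blob.seed, dtype=float) + jitter, 0.0, 255.0)

    keep_out = binary_dilation(union, iterations=spec.clutter_margin) if union.any() else union
    placed = 0
    while placed < spec.n_clutter:
        m = int(rng.integers(0, M))
        n = int(rng.integers(0, N))
        h = int(rng.integers(1, 4))
        w = int(rng.integers(1, 4))
        color = rng.integers(0, 256, size=3)
        m1, n1 = min(M, m + h), min(N, n + w)
        if keep_out[m:m1, n:n1].any():
            placed += 1  # skip but keep the draw count deterministic
            continue
        base[m:m1, n:n1] = color
        placed += 1

    image = np.clip(np.rint(base * spec.illumination), 0, 255).astype(np.uint8)
    return image, masks


# ---------------------------------------------------------------------------
# synthetic EEG

@dataclass(frozen=True)
class ERPSpec:
    """Parametric P300 surrogate: a positive half-cosine deflection.

    ``amplitude`` (uV) at ``latency_ms`` after target-covering flashes,
    ``width_ms`` wide, on Gaussian noise of ``noise_sd`` uV.  Defaults are
    the high-SNR regime used for pipeline validation; real EEG background
    is substantially noisier than the evoked response.
    """

    amplitude: float = 5.0
    latency_ms: int = 300
    width_ms: int = 300
    noise_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.latency_ms < ep.EPOCH_MS:
            raise ValueError("latency must fall inside the 800 ms epoch")
        if self.noise_sd < 0 or self.width_ms <= 0:
            raise ValueError("noise_sd must be >= 0 and width_ms > 0")


def _topography(n_channels: int = ep.N_CHANNELS) -> np.ndarray:
    """Fixed smooth posterior-weighted channel gain (front -> back ramp)."""
    return 0.25 + 0.75 * np.arange(n_channels) / (n_channels - 1)


def _bump(width_ms: int) -> np.ndarray:
    t = np.arange(-(width_ms // 2), width_ms // 2 + 1)
    return np.cos(np.pi * t / width_ms)


def make_eeg_session(
    schedule,
    true_targets: list[str],
    spec: ERPSpec,
    layout: SpellerLayout | None = None,
) -> ep.RawEEG:
    """Simulate one speller session (one trial per true target).

    ``schedule`` is either one list of :class:`RepetitionSchedule` reused
    for every trial, or one such list per trial.  Flashes covering the
    trial's attended target receive the deflection; everything rides on
    i.i.d. Gaussian channel noise.  Bit-reproducible from ``spec.rng_seed``.
    """
    layout = layout or SpellerLayout()
    if schedule and isinstance(schedule[0], RepetitionSchedule):
        per_trial = [list(schedule)] * len(true_targets)
    else:
        per_trial = [list(s) for s in schedule]
    if len(per_trial) != len(true_targets):
        raise ValueError(
            f"{len(per_trial)} trial schedules for {len(true_targets)} targets"
        )

    trial_ms = [len(reps) * REPETITION_MS + INTER_TRIAL_MS for reps in per_trial]
    n_samples = PRE_MS + int(sum(trial_ms)) + TAIL_MS
    rng = np.random.default_rng(spec.rng_seed)
    data = rng.normal(0.0, spec.noise_sd, size=(ep.N_CHANNELS, n_samples))

    topo = _topography()
    bump = _bump(spec.width_ms)
    half = len(bump) // 2

    rows = []
    t0 = PRE_MS
    for trial, (reps, target) in enumerate(zip(per_trial, true_targets)):
        pos = layout.position(target)
        for rep_i, rep in enumerate(reps):
            for ev in rep.events:
                onset = t0 + rep_i * REPETITION_MS + ev.onset_ms
                is_target = ev.covers(pos)
                rows.append(
                    {
                        "sample": onset,
                        "kind": ev.kind,
                        "index": ev.index,
                        "trial": trial,
                        "repetition": rep_i,
                        "is_target": is_target,
                    }
                )
                if is_target and spec.amplitude != 0.0:
                    c = onset + spec.latency_ms
                    lo, hi = c - half, c + half + 1
                    data[:, lo:hi] += spec.amplitude * topo[:, None] * bump[None, :]
        t0 += len(reps) * REPETITION_MS + INTER_TRIAL_MS

    events = pd.DataFrame(rows)
    return ep.RawEEG(data=data, events=events, true_targets=tuple(true_targets))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(a) != 0
    b = np.asarray(b) != 0
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# end-to-end simulation

@dataclass
class EndToEndReport:
    """Outcome of a simulated select-then-extract run."""

    selection_accuracy: float
    results: list[tuple[str, str]]  # (predicted, true) per selection
    iou: dict[str, float]
    masks: dict[str, np.ndarray]
    rng_seed: int


def _simulate_block(
    targets: list[str],
    n_repetitions: int,
    erp_spec: ERPSpec,
    layout: SpellerLayout,
    sched_seed: int,
    noise_seed: int,
) -> ep.RawEEG:
    schedules = [
        build_schedule(n_repetitions, sched_seed + i) for i in range(len(targets))
    ]
    spec = ERPSpec(
        amplitude=erp_spec.amplitude,
        latency_ms=erp_spec.latency_ms,
        width_ms=erp_spec.width_ms,
        noise_sd=erp_spec.noise_sd,
        rng_seed=noise_seed,
    )
    return make_eeg_session(schedules, targets, spec, layout)


def run_end_to_end(
    scene_spec: SceneSpec | None = None,
    erp_spec: ERPSpec | None = None,
    n_selections: int = 18,
    rng_seed: int = 0,
    layout: SpellerLayout | None = None,
    dataset: dict[str, SeedDatasetEntry] | None = None,
    n_train_trials: int = 18,
    growth_cfg: GrowthConfig | None = None,
    extract_masks: bool = True,
    chunk_trials: int = 27,
) -> EndToEndReport:
    """Offline training, online selection, then object extraction.

    Trains the FLDA on a simulated offline session (``n_train_trials``
    trials of 6 repetitions, targets cycling over the full grid), runs
    ``n_selections`` online selections (3 repetitions each, majority vote),
    and, for every trained object in the scene, feeds its dataset
    parameters to the extractor and scores the mask against ground truth.
    """
    layout = layout or SpellerLayout()
    dataset = dataset or default_dataset()
    erp_spec = erp_spec or ERPSpec()
    master = np.random.default_rng(rng_seed)

    def next_seed() -> int:
        return int(master.integers(0, 2**31 - 1))

    # --- offline training session: 6 repetitions per trial
    train_targets = [layout.targets[i % 9] for i in range(n_train_trials)]
    raw = _simulate_block(train_targets, 6, erp_spec, layout, next_seed(), next_seed())
    X, y = ep.training_set(ep.bandpass_filter(raw), layout)
    model = ep.train_flda(X, y)

    # --- online selections: 3 repetitions, vote; chunked to bound memory
    online_targets = [layout.targets[i % 9] for i in range(n_selections)]
    results: list[tuple[str, str]] = []
    for start in range(0, n_selections, chunk_trials):
        block = online_targets[start : start + chunk_trials]
        raw_online = _simulate_block(block, 3, erp_spec, layout, next_seed(), next_seed())
        preds = ep.predict_session(model, ep.bandpass_filter(raw_online), layout, mode="online")
        results.extend(zip(preds, block))
    accuracy = ep.session_accuracy(results)

    # --- extraction on the synthetic scene
    iou: dict[str, float] = {}
    masks: dict[str, np.ndarray] = {}
    if extract_masks:
        scene_spec = scene_spec or default_scene_spec(rng_seed=next_seed(), dataset=dataset)
        image, truth = make_scene(scene_spec)
        for oid, gt_mask in truth.items():
            if oid not in dataset:
                continue
            mask = extract_object(image, dataset[oid], growth_cfg)
            masks[oid] = mask
            iou[oid] = mask_iou(mask, gt_mask)

    return EndToEndReport(
        selection_accuracy=accuracy, results=results, iou=iou, masks=masks, rng_seed=rng_seed
    )
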