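"""Task paradigm generators: Sternberg working-memory and relevance-modulation (RM).

Both tasks are event trains with block structure and embedded rest phases from
which baseline entropy and oscillatory amplitude are measured downstream.

Sternberg: each trial presents two 600 ms *example* stimuli with onsets 1 s
apart, a 6 s maintenance period, and a 3 s *probe* that matches one of the
examples with probability 0.5.  A block is three trials followed by 36 s rest.

RM: blocks of 40 alternating 800 ms stimuli (butterflies / ladybirds) with
jittered inter-stimulus gaps (mean 1.92 s, SD 0.08 s), one stimulus category
task-relevant per block; blocks run BF, LB, LB, BF, LB, BF, BF, LB and last
120 s, the remainder after the final stimulus being a rest phase.  Rare
(p = 0.05) target stimuli are flagged and excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Event",
    "ParadigmSpec",
    "generate_sternberg_paradigm",
    "generate_rm_paradigm",
]

# Sternberg timing (seconds)
STERN_EXAMPLE_DURATION = 0.6
STERN_EXAMPLE_SOA = 1.0          # onset-to-onset spacing of the two examples
STERN_MAINTENANCE = 6.0
STERN_PROBE_ONSET = 8.0          # relative to first example onset
STERN_PROBE_DURATION = 3.0
STERN_TRIAL_WINDOW = (0.0, 12.0)  # trial-average window, from first example onset
STERN_TRIALS_PER_BLOCK = 3
STERN_REST_DURATION = 36.0
STERN_MATCH_PROB = 0.5

# RM timing (seconds)
RM_STIM_DURATION = 0.8
RM_ISI_MEAN = 1.92               # offset-to-onset gap
RM_ISI_SD = 0.08
RM_ISI_TRUNC_SD = 3.0            # truncation of the jitter distribution, in SDs
RM_STIMS_PER_BLOCK = 40
RM_BLOCK_DURATION = 120.0
RM_TARGET_PROB = 0.05
RM_BLOCK_ORDER = ("BF", "LB", "LB", "BF", "LB", "BF", "BF", "LB")
RM_TRIAL_WINDOW = (0.0, 2.0)


@dataclass(frozen=True)
class Event:
    """A single stimulus event."""

    onset: float          # seconds from recording start
    duration: float       # seconds
    label: str            # e.g. "example", "probe_match", "relevant", ...
    block: int            # 0-based block index
    excluded: bool = False  # flagged targets are excluded from trial averaging


@dataclass
class ParadigmSpec:
    """Full timing description of a generated task run.

    ``trial_onsets`` are the anchors of the per-trial averaging windows
    (first-example onsets for Sternberg, stimulus onsets for RM) and
    ``trial_window`` is the (start, end) averaging window in seconds relative
    to each anchor.
    """

    task_name: str
    events: list[Event]
    block_boundaries: list[tuple[float, float, str]]
    rest_windows: list[tuple[float, float]]
    total_duration: float
    sampling_rate: float
    trial_onsets: list[float] = field(default_factory=list)
    trial_window: tuple[float, float] = (0.0, 2.0)
    isi_values: list[float] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        for e in self.events:
            if e.onset < 0 or e.onset + e.duration > self.total_duration + 1e-9:
                raise ValueError(f"event at {e.onset:.3f}s outside [0, total_duration]")
        for rs, re_ in self.rest_windows:
            for e in self.events:
                if e.onset < re_ and e.onset + e.duration > rs:
                    raise ValueError("rest windows must be disjoint from stimulus events")

    @property
    def included_trial_onsets(self) -> list[float]:
        """Trial anchors with excluded (target) trials removed."""
        excluded = {e.onset for e in self.events if e.excluded}
        return [t for t in self.trial_onsets if t not in excluded]

    def event_labels(self) -> set[str]:
        return {e.label for e in self.events}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["events"] = [asdict(e) for e in self.events]
        return d


def generate_sternberg_paradigm(
    n_blocks: int = 15,
    seed: int = 0,
    sampling_rate: float = 600.0,
) -> ParadigmSpec:
    """Generate a Sternberg working-memory run.

    Each block holds three 12 s trials followed by a 36 s rest window; the
    probe matches one of the two examples with probability 0.5 and is labelled
    ``probe_match`` / ``probe_nonmatch`` accordingly.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    rng = np.random.default_rng(seed)
    trial_len = STERN_TRIAL_WINDOW[1]  # 12 s
    block_len = STERN_TRIALS_PER_BLOCK * trial_len + STERN_REST_DURATION

    events: list[Event] = []
    rest_windows: list[tuple[float, float]] = []
    block_boundaries: list[tuple[float, float, str]] = []
    trial_onsets: list[float] = []
    for b in range(n_blocks):
        t0 = b * block_len
        block_boundaries.append((t0, t0 + block_len, "sternberg"))
        for k in range(STERN_TRIALS_PER_BLOCK):
            tt = t0 + k * trial_len
            trial_onsets.append(tt)
            events.append(Event(tt, STERN_EXAMPLE_DURATION, "example", b))
            events.append(Event(tt + STERN_EXAMPLE_SOA, STERN_EXAMPLE_DURATION, "example", b))
            match = bool(rng.random() < STERN_MATCH_PROB)
            label = "probe_match" if match else "probe_nonmatch"
            events.append(Event(tt + STERN_PROBE_ONSET, STERN_PROBE_DURATION, label, b))
        rest_start = t0 + STERN_TRIALS_PER_BLOCK * trial_len
        rest_windows.append((rest_start, rest_start + STERN_REST_DURATION))

    return ParadigmSpec(
        task_name="sternberg",
        events=events,
        block_boundaries=block_boundaries,
        rest_windows=rest_windows,
        total_duration=n_blocks * block_len,
        sampling_rate=sampling_rate,
        trial_onsets=trial_onsets,
        trial_window=STERN_TRIAL_WINDOW,
        seed=seed,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      trunc_sd: float, size: int) -> np.ndarray:
    # rejection sampling; acceptance probability ~0.997 so a few rounds suffice
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size - n)
        ok = np.abs(draw - mean) <= trunc_sd * sd
        kept = draw[ok]
        out[n:n + kept.size] = kept
        n += kept.size
    return out


def generate_rm_paradigm(
    n_blocks: int = 8,
    seed: int = 0,
    sampling_rate: float = 600.0,
) -> ParadigmSpec:
    """Generate a relevance-modulation run.

    Blocks cycle through the fixed BF/LB relevance order.  Stimuli alternate
    butterfly/ladybird; the category matching the block type is labelled
    ``relevant``, the other ``irrelevant``.  Targets (p = 0.05) are flagged
    ``excluded`` so trial averaging skips them.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    rng = np.random.default_rng(seed)

    events: list[Event] = []
    rest_windows: list[tuple[float, float]] = []
    block_boundaries: list[tuple[float, float, str]] = []
    trial_onsets: list[float] = []
    isi_values: list[float] = []
    for b in range(n_blocks):
        block_type = RM_BLOCK_ORDER[b % len(RM_BLOCK_ORDER)]
        t0 = b * RM_BLOCK_DURATION
        block_boundaries.append((t0, t0 + RM_BLOCK_DURATION, block_type))
        isis = _truncated_normal(rng, RM_ISI_MEAN, RM_ISI_SD, RM_ISI_TRUNC_SD,
                                 RM_STIMS_PER_BLOCK - 1)
        onset = t0
        for k in range(RM_STIMS_PER_BLOCK):
            category = "BF" if k % 2 == 0 else "LB"
            label = "relevant" if category == block_type else "irrelevant"
            is_target = bool(rng.random() < RM_TARGET_PROB)
            events.append(Event(onset, RM_STIM_DURATION, label, b, excluded=is_target))
            trial_onsets.append(onset)
            if k < RM_STIMS_PER_BLOCK - 1:
                isi_values.append(float(isis[k]))
                onset = onset + RM_STIM_DURATION + isis[k]
        last_offset = onset + RM_STIM_DURATION
        rest_windows.append((last_offset, t0 + RM_BLOCK_DURATION))

    return ParadigmSpec(
        task_name="rm",
        events=events,
        block_boundaries=block_boundaries,
        rest_windows=rest_windows,
        total_duration=n_blocks * RM_BLOCK_DURATION,
        sampling_rate=sampling_rate,
        trial_onsets=trial_onsets,
        trial_window=RM_TRIAL_WINDOW,
        isi_values=isi_values,
        seed=seed,
    )
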