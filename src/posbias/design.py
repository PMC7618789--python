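"""Task designs: the facial expression recognition task (FERT) trial layout
and the emotional-faces fMRI block schedule.

The FERT presents brief emotional faces that the participant classifies into
one of seven categories (happy, surprise, anger, fear, sadness, disgust,
neutral).  Each non-neutral emotion appears at 10 morph intensities acted by
4 actors (40 trials per emotion); 10 neutral faces complete a 250-trial
session split into four blocks of 62/62/63/63 trials.

The fMRI task is a gender-discrimination paradigm with passive emotional
processing: 4 blocks of happy faces and 4 blocks of fearful faces (30 faces
per block, 100 ms each; 120 faces per emotion), interleaved with 9 fixation
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EMOTIONS: tuple[str, ...] = (
    "happy", "surprise", "anger", "fear", "sadness", "disgust", "neutral",
)
NON_NEUTRAL: tuple[str, ...] = EMOTIONS[:-1]
POSITIVE_EMOTIONS: tuple[str, ...] = ("happy", "surprise")
NEGATIVE_EMOTIONS: tuple[str, ...] = ("fear", "sadness", "anger", "disgust")

N_INTENSITIES = 10
N_ACTORS = 4
N_NEUTRAL = 10
N_TRIALS = 250
BLOCK_SIZES = (62, 62, 63, 63)

EMOTION_INDEX = {e: i for i, e in enumerate(EMOTIONS)}


def build_fert_design(seed: int) -> pd.DataFrame:
    """Build one FERT session design as a trial table.

    The stimulus set is fixed (40 trials per non-neutral emotion as
    4 actors x 10 intensities, plus 10 neutral faces); the trial order is a
    seeded permutation, after which trials are assigned to the four blocks
    in order.

    Returns a DataFrame with columns ``stimulus_id``, ``true_emotion``,
    ``intensity`` (1-10; 0 for neutral), ``actor`` and ``block``.
    """
    rng = np.random.default_rng(seed)
    df = _stimulus_set().iloc[rng.permutation(N_TRIALS)].reset_index(drop=True)
    df["block"] = np.repeat(np.arange(1, 5), BLOCK_SIZES)
    return df


_STIMULUS_SET: pd.DataFrame | None = None


def _stimulus_set() -> pd.DataFrame:
    """The fixed 250-stimulus set (cached; order is canonical, not shuffled)."""
    global _STIMULUS_SET
    if _STIMULUS_SET is None:
        rows = []
        for emo in NON_NEUTRAL:
            for actor in range(1, N_ACTORS + 1):
                for intensity in range(1, N_INTENSITIES + 1):
                    rows.append((f"{emo}_a{actor}_i{intensity:02d}", emo, intensity, actor))
        for j in range(1, N_NEUTRAL + 1):
            actor = (j - 1) % N_ACTORS + 1
            rows.append((f"neutral_{j:02d}", "neutral", 0, actor))
        _STIMULUS_SET = pd.DataFrame(
            rows, columns=["stimulus_id", "true_emotion", "intensity", "actor"])
    return _STIMULUS_SET


# --- fMRI block schedule ---------------------------------------------------

N_TASK_BLOCKS_PER_EMOTION = 4
N_FIXATION_BLOCKS = 9
FACES_PER_BLOCK = 30
FACES_PER_EMOTION = 120
FACE_DURATION_S = 0.1


@dataclass
class EventSchedule:
    """Event timing of one fMRI run.

    ``events`` holds one row per event (BIDS-style: onset, duration,
    trial_type); face presentations and fixation blocks both appear as
    events.  ``tr`` and ``n_volumes`` fix the sampling grid of the run.
    """

    events: pd.DataFrame
    tr: float
    n_volumes: int

    def face_events(self, condition: str | None = None) -> pd.DataFrame:
        ev = self.events[self.events.trial_type.isin(("happy", "fearful"))]
        if condition is not None:
            ev = ev[ev.trial_type == condition]
        return ev

    @property
    def n_fixation_blocks(self) -> int:
        return int((self.events.trial_type == "fixation").sum())

    def validate(self) -> None:
        end = (self.events.onset + self.events.duration).max()
        if (self.events.onset < 0).any():
            raise ValueError("negative event onset")
        if end > self.n_volumes * self.tr + 1e-9:
            raise ValueError("events extend beyond the run")


def build_event_schedule(
    tr: float = 2.0,
    block_duration: float = 30.0,
    fixation_duration: float = 15.0,
    face_soa: float = 1.0,
    first_condition: str = "happy",
) -> EventSchedule:
    """Build the emotional-faces run: 4 happy + 4 fearful task blocks
    interleaved by 9 fixation blocks, 30 faces of 100 ms per task block.

    The run starts and ends with fixation; happy and fearful blocks
    alternate, starting with ``first_condition``.
    """
    other = "fearful" if first_condition == "happy" else "happy"
    order = [first_condition, other] * N_TASK_BLOCKS_PER_EMOTION
    rows = []
    t = 0.0
    rows.append((t, fixation_duration, "fixation"))
    t += fixation_duration
    for cond in order:
        for i in range(FACES_PER_BLOCK):
            rows.append((t + i * face_soa, FACE_DURATION_S, cond))
        t += block_duration
        rows.append((t, fixation_duration, "fixation"))
        t += fixation_duration
    events = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    n_volumes = int(np.ceil(t / tr))
    sched = EventSchedule(events=events, tr=tr, n_volumes=n_volumes)
    sched.validate()
    return sched
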