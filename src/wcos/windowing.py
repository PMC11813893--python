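"""Sliding-window sample construction and normal-only-training fold plans.

Records are cut into fixed-length windows of ``window_frames`` frames
(default 10 frames of 0.5 s) advanced by ``hop_frames``; a window inherits the
abnormal label whenever it overlaps a murmur interval by any positive duration.
Cross-validation splits are built at the *record* level so that overlapping
windows of the same record can never straddle the train/test boundary, and
training folds contain normal samples only (the semi-supervised contract).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio import AudioSignal

NORMAL = "normal"
ABNORMAL = "abnormal"


@dataclass(frozen=True)
class FrameConfig:
    """Frame length (s), frames per window, and hop in frames."""

    frame_len_s: float = 0.5
    window_frames: int = 10
    hop_frames: int = 5

    def __post_init__(self) -> None:
        if self.window_frames < 1:
            raise ValueError("window_frames must be >= 1")
        if not (1 <= self.hop_frames <= self.window_frames):
            raise ValueError("hop_frames must satisfy 1 <= hop <= window_frames")
        if self.frame_len_s <= 0:
            raise ValueError("frame_len_s must be positive")

    @property
    def window_len_s(self) -> float:
        return self.window_frames * self.frame_len_s


@dataclass
class LabeledRecord:
    """A whole recording with its label and ground-truth murmur intervals."""

    signal: AudioSignal
    label: str
    murmur_intervals: list[tuple[float, float]]
    record_id: str

    def __post_init__(self) -> None:
        if self.label not in (NORMAL, ABNORMAL):
            raise ValueError(f"label must be {NORMAL!r} or {ABNORMAL!r}")


@dataclass
class Sample:
    """One fixed-length labeled window cut from a record."""

    values: np.ndarray
    label: str
    record_id: str
    start_s: float


@dataclass
class FoldPlan:
    """Per-(repeat, fold) train/test index assignments over a sample list.

    ``assignments[(repeat, fold)] -> (train_idx, test_idx)``; train indices
    reference normal samples only.
    """

    k: int
    repeats: int
    assignments: dict[tuple[int, int], tuple[list[int], list[int]]]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "assignments": {
                f"{r},{f}": {"train": tr, "test": te}
                for (r, f), (tr, te) in self.assignments.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def slice_windows(record: LabeledRecord, config: FrameConfig = FrameConfig()) -> list[Sample]:
    """Cut a record into hop-strided windows with interval-overlap labels.

    The window count is ``floor((F - W)/H) + 1`` with ``F`` whole frames in the
    record, ``W`` frames per window and ``H`` the hop. A window is abnormal iff
    it overlaps any murmur interval by a positive duration.
    """
    fs = record.signal.sample_rate
    frame_n = int(round(config.frame_len_s * fs))
    total_frames = len(record.signal) // frame_n
    if total_frames < config.window_frames:
        raise ValueError(
            f"record {record.record_id!r} has {total_frames} frames, "
            f"shorter than one window of {config.window_frames}"
        )
    n_windows = (total_frames - config.window_frames) // config.hop_frames + 1
    window_n = config.window_frames * frame_n
    samples = []
    for w in range(n_windows):
        start_frame = w * config.hop_frames
        start_s = start_frame * config.frame_len_s
        end_s = start_s + config.window_len_s
        i0 = start_frame * frame_n
        overlaps = any(
            min(end_s, b) - max(start_s, a) > 0 for a, b in record.murmur_intervals
        )
        samples.append(
            Sample(
                values=record.signal.samples[i0 : i0 + window_n].copy(),
                label=ABNORMAL if overlaps else NORMAL,
                record_id=record.record_id,
                start_s=start_s,
            )
        )
    return samples


def make_folds(
    dataset: list[Sample], k: int = 5, repeats: int = 10, seed: int = 0
) -> FoldPlan:
    """Build k-fold, normal-only-training splits grouped by record.

    All windows of one record are assigned to the same fold (overlapping
    windows are near-duplicates; splitting them across folds would leak).
    Fold ``j`` of a repeat trains on the normal records of the other k-1 folds
    and tests on normal fold ``j`` plus abnormal fold ``j``. Within a repeat,
    the test sets partition the whole dataset. Fully reproducible from
    ``seed``.
    """
    by_record: dict[str, str] = {}
    for s in dataset:
        prev = by_record.setdefault(s.record_id, s.label)
        # a record containing any abnormal window is grouped with abnormals
        if s.label == ABNORMAL and prev == NORMAL:
            by_record[s.record_id] = ABNORMAL
    normal_recs = sorted(r for r, lab in by_record.items() if lab == NORMAL)
    abnormal_recs = sorted(r for r, lab in by_record.items() if lab == ABNORMAL)
    if len(normal_recs) < k or len(abnormal_recs) < k:
        raise ValueError(
            f"need at least k={k} normal and abnormal records, "
            f"got {len(normal_recs)} normal / {len(abnormal_recs)} abnormal"
        )
    rec_windows: dict[str, list[int]] = {}
    for i, s in enumerate(dataset):
        rec_windows.setdefault(s.record_id, []).append(i)

    assignments: dict[tuple[int, int], tuple[list[int], list[int]]] = {}
    root = np.random.SeedSequence([int(seed), 3])
    for rep, child in enumerate(root.spawn(repeats)):
        rng = np.random.default_rng(child)
        norm_perm = list(np.array(normal_recs)[rng.permutation(len(normal_recs))])
        abn_perm = list(np.array(abnormal_recs)[rng.permutation(len(abnormal_recs))])
        norm_folds = [list(a) for a in np.array_split(norm_perm, k)]
        abn_folds = [list(a) for a in np.array_split(abn_perm, k)]
        for j in range(k):
            train_recs = [r for jj in range(k) if jj != j for r in norm_folds[jj]]
            test_recs = list(norm_folds[j]) + list(abn_folds[j])
            train_idx = [
                i
                for r in train_recs
                for i in rec_windows[r]
                if dataset[i].label == NORMAL
            ]
            test_idx = [i for r in test_recs for i in rec_windows[r]]
            assignments[(rep, j)] = (sorted(train_idx), sorted(test_idx))
    return FoldPlan(k=k, repeats=repeats, assignments=assignments, seed=int(seed))
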