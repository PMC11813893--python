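"""Control-group pipelines, grids, and the cross-validated evaluation protocol.

Six control groups factor the full pipeline (wavelet denoising x representation):

    1  OCSVM            raw windows (decimated to 512) -> one-class SVM
    2  TF24-OCSVM       24 statistical descriptors -> one-class SVM
    3  CAE-OCSVM        autoencoder latents -> one-class SVM
    4  WR-OCSVM         wavelet-denoised, then as group 1
    5  WR-TF24-OCSVM    wavelet-denoised, then as group 2
    6  WR-CAE-OCSVM     wavelet-denoised, then as group 3 (the full framework)

Every configuration is evaluated with k-fold cross-validation repeated
``repeats`` times; training folds contain normal samples only, and any
fold-dependent fitting (autoencoder, TF24 standardization, rbf width) uses the
fold's training data alone. The noise-robustness study repeats the protocol
with Gaussian noise of each sigma added to the raw records before any
denoising or windowing.
"""

from __future__ import annotations

import ast
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import resample_poly
from math import gcd

from .synthetic import PCGSpec, NoiseSpec, generate_pcg, add_gaussian_noise, murmur_intervals
from .wavelet import WaveletSpec, denoise
from .windowing import (
    ABNORMAL,
    NORMAL,
    FoldPlan,
    FrameConfig,
    LabeledRecord,
    Sample,
    make_folds,
    slice_windows,
)
from .features import tf24
from .cae import CAE, CAEConfig, CHANNEL_GRID, train_cae
from . import ocsvm as oc
from .evaluation import AUCSummary, auc, relative_change, summarize

RAW_DIM = 512
_KERNEL_ORDER = {"linear": 0, "poly": 1, "rbf": 2, "sigmoid": 3}


@dataclass(frozen=True)
class ControlGroupSpec:
    """One of the six pipeline variants."""

    id: int
    denoise: bool
    representation: str  # raw | tf24 | cae

    def __post_init__(self) -> None:
        if self.id not in range(1, 7):
            raise ValueError("control group id must be 1..6")
        expected = CONTROL_GROUPS[self.id]
        if (self.denoise, self.representation) != (expected.denoise, expected.representation):
            raise ValueError(
                f"group {self.id} must have denoise={expected.denoise}, "
                f"representation={expected.representation!r}"
            )

    @property
    def name(self) -> str:
        rep = {"raw": "", "tf24": "TF24-", "cae": "CAE-"}[self.representation]
        return ("WR-" if self.denoise else "") + rep + "OCSVM"


CONTROL_GROUPS: dict[int, "ControlGroupSpec"] = {}
for _id, (_dn, _rep) in enumerate(
    [(False, "raw"), (False, "tf24"), (False, "cae"), (True, "raw"), (True, "tf24"), (True, "cae")],
    start=1,
):
    g = object.__new__(ControlGroupSpec)
    object.__setattr__(g, "id", _id)
    object.__setattr__(g, "denoise", _dn)
    object.__setattr__(g, "representation", _rep)
    CONTROL_GROUPS[_id] = g


def control_group(group_id: int) -> ControlGroupSpec:
    if group_id not in CONTROL_GROUPS:
        raise ValueError(f"unknown control group id {group_id}")
    return CONTROL_GROUPS[group_id]


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter search grids (defaults are the study's grids)."""

    C_grid: tuple[float, ...] = (1e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1)
    kernel_grid: tuple[str, ...] = ("linear", "poly", "rbf", "sigmoid")
    channel_grid: tuple[tuple[int, int], ...] = CHANNEL_GRID


@dataclass(frozen=True)
class NoiseGrid:
    """Ambient-noise levels of the robustness study."""

    sigmas: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5)


@dataclass(frozen=True)
class PipelineConfig:
    """One grid cell: OCSVM settings plus (for CAE groups) channel pair."""

    ocsvm: oc.OCSVMConfig = field(default_factory=oc.OCSVMConfig)
    channels: tuple[int, int] | None = None

    def key(self) -> tuple:
        return (self.ocsvm.kernel.kind, self.ocsvm.C, self.channels)

    def label(self) -> str:
        s = f"{self.ocsvm.kernel.kind}-C{self.ocsvm.C:g}"
        if self.channels is not None:
            s += f"-ch{self.channels[0]}x{self.channels[1]}"
        return s


def configs_for_group(group: ControlGroupSpec, grid: GridSpec = GridSpec()):
    """Enumerate the grid cells of one group (C x kernel, x channels for CAE)."""
    channel_options = grid.channel_grid if group.representation == "cae" else (None,)
    for C, kind, ch in itertools.product(grid.C_grid, grid.kernel_grid, channel_options):
        yield PipelineConfig(ocsvm=oc.OCSVMConfig(C=C, kernel=oc.KernelSpec(kind=kind)), channels=ch)


@dataclass
class RunResult:
    """Long-format AUC records plus run provenance (seeds, settings)."""

    records: pd.DataFrame
    provenance: dict

    def summary(self) -> pd.DataFrame:
        """Table-style mean/sd/variance per (group, config, sigma), pooling
        all fold x repeat values."""
        rows = []
        for (gid, label, sigma), sub in self.records.groupby(["group", "config", "sigma"]):
            s = summarize(sub["auc"].to_numpy())
            rows.append(
                {
                    "group": gid,
                    "model": control_group(int(gid)).name,
                    "config": label,
                    "sigma": sigma,
                    "auc_mean": s.mean,
                    "auc_sd": s.sd,
                    "auc_variance": s.variance,
                    "n_values": len(s.values),
                }
            )
        return pd.DataFrame(rows).sort_values(["group", "config", "sigma"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------

def make_dataset(
    n_normal: int = 100,
    n_abnormal: int = 20,
    murmur_rel_amplitude: float = 0.8,
    duration_s: float = 10.0,
    sample_rate: int = 4000,
    heart_rate_bpm: float = 70.0,
    cycle_jitter_frac: float = 0.02,
    seed: int = 0,
) -> list[LabeledRecord]:
    """Generate an imbalanced synthetic cohort (abnormal = murmur minority)."""
    records = []
    root = np.random.SeedSequence([int(seed), 6])
    seeds = root.generate_state(n_normal + n_abnormal) % (2**31)
    for i in range(n_normal + n_abnormal):
        abnormal = i >= n_normal
        spec = PCGSpec(
            duration_s=duration_s,
            sample_rate=sample_rate,
            heart_rate_bpm=heart_rate_bpm,
            murmur_present=abnormal,
            murmur_rel_amplitude=murmur_rel_amplitude,
            cycle_jitter_frac=cycle_jitter_frac,
            seed=int(seeds[i]),
        )
        records.append(
            LabeledRecord(
                signal=generate_pcg(spec),
                label=ABNORMAL if abnormal else NORMAL,
                murmur_intervals=murmur_intervals(spec),
                record_id=f"{'abn' if abnormal else 'nrm'}{i:04d}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# representations
# ---------------------------------------------------------------------------

def _decimate_to_raw(values: np.ndarray) -> np.ndarray:
    """Polyphase-resample each window to a fixed RAW_DIM-length vector."""
    L = values.shape[-1]
    if L == RAW_DIM:
        return values.copy()
    g = gcd(L, RAW_DIM)
    return resample_poly(values, RAW_DIM // g, L // g, axis=-1)


def build_representation(
    group: ControlGroupSpec,
    samples: list[Sample],
    sample_rate: int,
    train_idx: list[int],
    cae_config: CAEConfig | None = None,
) -> tuple[np.ndarray, CAE | None]:
    """Feature matrix for every sample, fitted on the training subset only.

    raw  -> each window decimated to RAW_DIM values;
    tf24 -> 24-vector per window, z-scored with training-fold statistics;
    cae  -> latents from an autoencoder trained on the fold's normal windows.

    Returns (features, fitted_cae_or_None).
    """
    X = np.stack([s.values for s in samples])
    if group.representation == "raw":
        return _decimate_to_raw(X), None
    if group.representation == "tf24":
        F = np.stack([tf24(x, sample_rate) for x in X])
        mu = F[train_idx].mean(axis=0)
        sd = F[train_idx].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return (F - mu) / sd, None
    if group.representation == "cae":
        if cae_config is None:
            cae_config = CAEConfig()
        train_samples = [samples[i] for i in train_idx]
        model, _ = train_cae(train_samples, cae_config)
        _, latents = model.encode(X)
        return latents, model
    raise ValueError(f"unknown representation {group.representation!r}")


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------

def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_experiment(
    dataset: list[LabeledRecord],
    groups: list[int] | None = None,
    grid: dict[int, list[PipelineConfig]] | None = None,
    k: int = 5,
    repeats: int = 2,
    noise_grid: NoiseGrid = NoiseGrid(sigmas=(0.0,)),
    seed: int = 0,
    frame_config: FrameConfig = FrameConfig(),
    wavelet_spec: WaveletSpec = WaveletSpec(),
    cae_base: CAEConfig | None = None,
) -> RunResult:
    """Run the full protocol: noise -> (denoise) -> window -> represent ->
    one-class SVM -> AUC, for every (group, config, sigma, repeat, fold).

    ``grid`` maps group id -> configs to evaluate; by default each group gets a
    single sensible cell (rbf, C=1e-3, default channels). Per-fold training
    never sees an abnormal sample; folds are shared across groups and configs
    within one (sigma, repeat) so comparisons are paired.
    """
    if groups is None:
        groups = [1, 2, 3, 4, 5, 6]
    group_specs = [control_group(g) for g in groups]
    if grid is None:
        grid = {}
    if cae_base is None:
        cae_base = CAEConfig(epochs=20)
    configs = {
        g.id: grid.get(
            g.id,
            [
                PipelineConfig(
                    ocsvm=oc.OCSVMConfig(C=1e-3, kernel=oc.KernelSpec(kind="rbf")),
                    channels=cae_base.channels if g.representation == "cae" else None,
                )
            ],
        )
        for g in group_specs
    }
    fs = dataset[0].signal.sample_rate
    rows = []
    for sigma in noise_grid.sigmas:
        for rep in range(repeats):
            noisy = [
                LabeledRecord(
                    signal=add_gaussian_noise(
                        r.signal, NoiseSpec(sigma, seed=_derive_seed(seed, 7, rep, ri))
                    ),
                    label=r.label,
                    murmur_intervals=r.murmur_intervals,
                    record_id=r.record_id,
                )
                for ri, r in enumerate(dataset)
            ]
            need_denoise = any(g.denoise for g in group_specs)
            denoised = (
                [
                    LabeledRecord(
                        signal=denoise(r.signal, wavelet_spec),
                        label=r.label,
                        murmur_intervals=r.murmur_intervals,
                        record_id=r.record_id,
                    )
                    for r in noisy
                ]
                if need_denoise
                else None
            )
            windows = {False: [s for r in noisy for s in slice_windows(r, frame_config)]}
            if denoised is not None:
                windows[True] = [s for r in denoised for s in slice_windows(r, frame_config)]
            plan = make_folds(windows[False], k=k, repeats=1, seed=_derive_seed(seed, 8, rep))
            for g in group_specs:
                samples = windows[g.denoise]
                labels = np.array([s.label for s in samples])
                for cfg in configs[g.id]:
                    for fold in range(k):
                        train_idx, test_idx = plan.assignments[(0, fold)]
                        cae_cfg = None
                        if g.representation == "cae":
                            cae_cfg = replace(
                                cae_base,
                                channels=cfg.channels or cae_base.channels,
                                seed=_derive_seed(seed, 9, rep, fold, g.id),
                            )
                        feats, _ = build_representation(g, samples, fs, train_idx, cae_cfg)
                        model = oc.fit(feats[train_idx], cfg.ocsvm)
                        scores = oc.anomaly_score(model, feats[test_idx])
                        rows.append(
                            {
                                "group": g.id,
                                "model": g.name,
                                "config": cfg.label(),
                                "kernel": cfg.ocsvm.kernel.kind,
                                "C": cfg.ocsvm.C,
                                "channels": str(cfg.channels),
                                "sigma": sigma,
                                "repeat": rep,
                                "fold": fold,
                                "auc": auc(scores, labels[test_idx]),
                            }
                        )
    records = pd.DataFrame(rows)
    provenance = {
        "seed": int(seed),
        "k": k,
        "repeats": repeats,
        "sigmas": list(noise_grid.sigmas),
        "groups": list(groups),
        "n_records": len(dataset),
        "frame_config": {
            "frame_len_s": frame_config.frame_len_s,
            "window_frames": frame_config.window_frames,
            "hop_frames": frame_config.hop_frames,
        },
    }
    return RunResult(records=records, provenance=provenance)


def hyperparameter_search(result: RunResult) -> dict[int, dict]:
    """Best grid cell per group by mean AUC.

    Ties break deterministically: smaller C, then kernel order
    linear < poly < rbf < sigmoid, then smaller channel pair.
    """
    if result.records.empty:
        raise ValueError("empty run result")
    best: dict[int, dict] = {}
    for gid, sub in result.records.groupby("group"):
        cells = []
        for (label, kind, C, ch), cell in sub.groupby(["config", "kernel", "C", "channels"]):
            chans = ast.literal_eval(ch) if ch != "None" else None  # stored as str repr
            cells.append(
                {
                    "config": label,
                    "kernel": kind,
                    "C": C,
                    "channels": chans,
                    "mean_auc": float(cell["auc"].mean()),
                }
            )
        cells.sort(
            key=lambda c: (
                -c["mean_auc"],
                c["C"],
                _KERNEL_ORDER[c["kernel"]],
                c["channels"] if c["channels"] is not None else (0, 0),
            )
        )
        best[int(gid)] = cells[0]
    return best


def compare_models(summary_a: AUCSummary, summary_b: AUCSummary, decimals: int = 1) -> dict:
    """Relative percent changes (a vs b) of mean, sd and variance."""
    return {
        "mean_pct": relative_change(summary_a.mean, summary_b.mean, decimals),
        "sd_pct": relative_change(summary_a.sd, summary_b.sd, decimals),
        "variance_pct": relative_change(summary_a.variance, summary_b.variance, decimals),
    }
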