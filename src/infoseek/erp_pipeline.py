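"""Preprocessing, epoching, condition binning and component measurement.

The chain mirrors a conventional feedback-ERP workflow: linear detrend,
0.1-70 Hz zero-phase band-pass, 45-55 Hz band-stop, mastoid-average
re-reference; epochs from -1000 to +1000 ms around events with a 100 ms
pre-stimulus baseline; +/-200 microvolt amplitude screening; condition
binning by prediction-error sign; and window-mean component amplitudes
(FRN 200-350 ms frontocentral, N1 150-200 ms, LPP 400-700 ms
centroparietal).  Participants enter an analysis only when every
condition bin retains at least 20 artifact-free epochs.

Time conventions: windows are closed on the left and open on the right;
the sample at t=0 belongs to the post-stimulus side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic_eeg import (
    COMPONENT_WINDOWS,
    CENTROPARIETAL,
    FRONTOCENTRAL,
    MASTOIDS,
    N1_CHANNELS,
    Recording,
)

logger = logging.getLogger(__name__)

COMPONENT_CHANNELS = {
    "FRN": FRONTOCENTRAL,
    "N1": N1_CHANNELS,
    "LPP": CENTROPARIETAL,
}

DEFAULT_WINDOW = (-1.0, 1.0)
DEFAULT_BASELINE = (-0.1, 0.0)
REJECTION_THRESHOLD_UV = 200.0
MIN_EPOCHS = 20


def preprocess(
    recording: Recording,
    l_freq: float = 0.1,
    h_freq: float = 70.0,
    notch: tuple[float, float] = (45.0, 55.0),
    detrend: bool = True,
    rereference: bool = True,
    filter_order: int = 4,
) -> Recording:
    """Detrend, band-pass, band-stop and mastoid-re-reference a recording.

    Filters are Butterworth, applied forward-backward (zero phase); the
    high- and low-pass edges are applied as separate sections for
    numerical stability given the extreme 0.1/70 Hz edge ratio.  Filter
    transients are confined to the recording edges; synthesis leaves a
    lead-in/lead-out outside any analysis window.
    """
    fs = recording.sample_rate
    if fs <= 2 * h_freq:
        raise ValueError(
            f"sample rate {fs} Hz too low for a {h_freq} Hz low-pass"
        )
    if rereference:
        for m in MASTOIDS:
            if m not in recording.channels:
                raise ValueError(f"mastoid channel {m} missing: cannot re-reference")
    data = recording.data.astype(float, copy=True)
    if detrend:
        # closed-form linear detrend per channel (cheaper than lstsq)
        x = np.arange(data.shape[1], dtype=float)
        x -= x.mean()
        slope = (data @ x) / (x @ x)
        data -= data.mean(axis=1, keepdims=True) + slope[:, None] * x[None, :]
    sos_hp = signal.butter(filter_order, l_freq, btype="highpass", fs=fs, output="sos")
    sos_lp = signal.butter(filter_order, h_freq, btype="lowpass", fs=fs, output="sos")
    sos_stop = signal.butter(filter_order, notch, btype="bandstop", fs=fs, output="sos")
    # generous reflect-padding keeps the slow high-pass edge transient small
    pad = min(data.shape[1] - 1, int(10 * fs))
    data = signal.sosfiltfilt(sos_hp, data, axis=1, padlen=pad)
    data = signal.sosfiltfilt(sos_lp, data, axis=1, padlen=pad)
    data = signal.sosfiltfilt(sos_stop, data, axis=1, padlen=pad)
    if rereference:
        ref = data[[recording.channel_index(m) for m in MASTOIDS]].mean(axis=0)
        data = data - ref
    return Recording(fs, recording.channels, data, recording.events.copy())


@dataclass(frozen=True)
class EpochSet:
    """Epoch tensor (epochs x channels x samples) with per-epoch labels."""

    data: np.ndarray
    sample_rate: float
    channels: tuple[str, ...]
    window: tuple[float, float]
    baseline: tuple[float, float]
    labels: pd.DataFrame
    rejected: np.ndarray  # bool per epoch

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        w0, w1 = self.window
        start = int(round(w0 * self.sample_rate))
        return (start + np.arange(self.data.shape[2])) / self.sample_rate

    @property
    def good(self) -> np.ndarray:
        return ~self.rejected

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def time_mask(self, lo: float, hi: float) -> np.ndarray:
        t = self.times
        return (t >= lo) & (t < hi)


def epoch_and_baseline(
    recording: Recording,
    window: tuple[float, float] = DEFAULT_WINDOW,
    baseline: tuple[float, float] = DEFAULT_BASELINE,
    events: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut one epoch per event and subtract the per-channel baseline mean.

    Events whose window does not fit inside the recording are skipped
    with a logged warning.
    """
    events = recording.events if events is None else events
    fs = recording.sample_rate
    w0, w1 = window
    start_off = int(round(w0 * fs))
    stop_off = int(round(w1 * fs))
    n_samp = stop_off - start_off
    times = (start_off + np.arange(n_samp)) / fs
    b_mask = (times >= baseline[0]) & (times < baseline[1])
    if not b_mask.any():
        raise ValueError("baseline window contains no samples")
    samples = events["sample"].to_numpy(int)
    lo = samples + start_off
    hi = samples + stop_off
    keep = (lo >= 0) & (hi <= recording.n_samples)
    for s0 in samples[~keep]:
        logger.warning("event at sample %d skipped: window out of bounds", s0)
    chunks = [recording.data[:, a:b] for a, b in zip(lo[keep], hi[keep])]
    if chunks:
        data = np.stack(chunks)
        data -= data[:, :, b_mask].mean(axis=2, keepdims=True)
    else:
        data = np.empty((0, len(recording.channels), n_samp))
    labels = events.loc[keep].reset_index(drop=True)
    return EpochSet(
        data=data,
        sample_rate=fs,
        channels=tuple(recording.channels),
        window=window,
        baseline=baseline,
        labels=labels,
        rejected=np.zeros(len(labels), dtype=bool),
    )


def reject_artifacts(
    epochs: EpochSet,
    threshold: float = REJECTION_THRESHOLD_UV,
    channels: Sequence[str] | None = None,
) -> EpochSet:
    """Flag epochs whose absolute amplitude exceeds ``threshold`` (in
    microvolts) on any analysis channel (all non-mastoid channels by
    default)."""
    if channels is None:
        channels = [ch for ch in epochs.channels if ch not in MASTOIDS]
    idx = [epochs.channel_index(ch) for ch in channels]
    if epochs.n_epochs == 0:
        return epochs
    peak = np.abs(epochs.data[:, idx, :]).max(axis=(1, 2))
    return replace(epochs, rejected=epochs.rejected | (peak > threshold))


#: Binning schemes: (label column, event class, level filter or None for all
#: levels, stimulus-kind filter).  ``None`` levels mean "pos and neg only".
_SCHEMES: Mapping[str, tuple[str, str, tuple[str, ...], str | None]] = {
    "rpe_sign": ("rpe_sign", "card", ("pos", "neg"), "informative"),
    "ipe_sign": ("ipe_sign", "card", ("pos", "neg"), "informative"),
    "ipe_sign_with_zero": ("ipe_sign", "card", ("pos", "neg", "zero"), "informative"),
    "info_sign": ("info_sign", "card", ("pos", "neg"), "informative"),
    "pseudo_rpe_sign": ("pseudo_rpe_sign", "card", ("pos", "neg"), "non_informative"),
    "pseudo_ipe_sign": ("pseudo_ipe_sign", "card", ("pos", "neg"), "non_informative"),
    "pseudo_info_sign": ("pseudo_info_sign", "card", ("pos", "neg"), "non_informative"),
    "outcome": ("outcome", "outcome_screen", ("win", "loss"), None),
    "outcome_after_informative": (
        "outcome", "outcome_screen", ("win", "loss"), "informative",
    ),
    "outcome_after_non_informative": (
        "outcome", "outcome_screen", ("win", "loss"), "non_informative",
    ),
}

BINNING_SCHEMES = tuple(_SCHEMES)


def bin_epochs(epochs: EpochSet, scheme: str) -> dict[str, np.ndarray]:
    """Map each condition of a binning scheme to its good-epoch indices.

    Zero-labelled epochs are excluded except in the explicitly
    zero-inclusive scheme; rejected epochs never enter a bin.
    """
    if scheme not in _SCHEMES:
        raise ValueError(
            f"unknown binning scheme {scheme!r}; known: {sorted(_SCHEMES)}"
        )
    column, event_class, levels, kind = _SCHEMES[scheme]
    lab = epochs.labels
    base = (lab["event_class"] == event_class).to_numpy() & epochs.good
    if kind is not None:
        base &= (lab["stimulus_kind"] == kind).to_numpy()
    return {
        level: np.flatnonzero(base & (lab[column] == level).to_numpy())
        for level in levels
    }


def bin_counts(epochs: EpochSet, scheme: str) -> pd.DataFrame:
    """Per-participant epoch counts for every condition of a scheme."""
    bins = bin_epochs(epochs, scheme)
    rows = []
    for level, idx in bins.items():
        for participant, n in (
            epochs.labels.loc[idx, "participant"].value_counts().items()
        ):
            rows.append({"participant": participant, "condition": level, "n": n})
    return pd.DataFrame(rows, columns=["participant", "condition", "n"])


def include_by_epoch_count(
    counts_or_epochs, scheme: str | None = None, min_epochs: int = MIN_EPOCHS
) -> list[str]:
    """Participants for whom every condition bin has >= ``min_epochs``.

    Accepts either an :class:`EpochSet` plus scheme, or a tidy counts
    frame with columns (participant, condition, n).
    """
    if isinstance(counts_or_epochs, EpochSet):
        if scheme is None:
            raise ValueError("scheme required when passing an EpochSet")
        epochs = counts_or_epochs
        bins = bin_epochs(epochs, scheme)
        participants = sorted(epochs.labels["participant"].unique())
        included = []
        for p in participants:
            ok = True
            for idx in bins.values():
                n = int((epochs.labels.loc[idx, "participant"] == p).sum())
                if n < min_epochs:
                    ok = False
                    break
            if ok:
                included.append(p)
        return included
    counts = counts_or_epochs
    n_conditions = counts["condition"].nunique()
    by = counts.groupby("participant")
    return sorted(
        p
        for p, g in by
        if len(g) == n_conditions and (g["n"] >= min_epochs).all()
    )


def measure_component(
    epochs: EpochSet,
    component: str,
    bins: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Window-mean amplitude per participant x condition x electrode.

    Measured on the per-condition average waveform; for equally weighted
    epoch means this is identical to averaging single-epoch window means.
    """
    if component not in COMPONENT_WINDOWS:
        raise ValueError(f"unknown component {component!r}")
    channels = COMPONENT_CHANNELS[component]
    missing = [ch for ch in channels if ch not in epochs.channels]
    if missing:
        raise ValueError(f"channels missing for {component}: {missing}")
    lo, hi = COMPONENT_WINDOWS[component]
    t_mask = epochs.time_mask(lo, hi)
    ch_idx = {ch: epochs.channel_index(ch) for ch in channels}
    rows = []
    for condition, idx in bins.items():
        by_participant = epochs.labels.loc[idx].groupby("participant").groups
        for participant, rows_idx in by_participant.items():
            sel = idx[np.isin(idx, np.asarray(rows_idx))]
            avg = epochs.data[sel][:, :, t_mask].mean(axis=(0, 2))
            for ch, ci in ch_idx.items():
                rows.append(
                    {
                        "participant": participant,
                        "condition": condition,
                        "electrode": ch,
                        "component": component,
                        "mean_amplitude": float(avg[ci]),
                        "n_epochs": int(len(sel)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "condition", "electrode", "component",
            "mean_amplitude", "n_epochs",
        ],
    )


def grand_average(
    epochs: EpochSet, bins: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Condition -> channels x samples grand-average waveform."""
    return {
        cond: epochs.data[idx].mean(axis=0)
        for cond, idx in bins.items()
        if len(idx)
    }


def difference_wave(
    epochs: EpochSet, bins: Mapping[str, np.ndarray],
    minuend: str = "neg", subtrahend: str = "pos",
) -> np.ndarray:
    """Negative-minus-positive grand-average difference (channels x samples)."""
    ga = grand_average(epochs, bins)
    return ga[minuend] - ga[subtrahend]


def plot_difference_wave(
    epochs: EpochSet,
    bins: Mapping[str, np.ndarray],
    channel: str,
    path,
    component: str = "FRN",
) -> None:
    """Save a grand-average + difference-wave figure for one channel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ga = grand_average(epochs, bins)
    ci = epochs.channel_index(channel)
    t = epochs.times * 1000.0
    fig, ax = plt.subplots(figsize=(7, 4))
    for cond, wave in ga.items():
        ax.plot(t, wave[ci], label=cond)
    if "neg" in ga and "pos" in ga:
        ax.plot(t, ga["neg"][ci] - ga["pos"][ci], "k--", label="neg - pos")
    lo, hi = COMPONENT_WINDOWS[component]
    ax.axvspan(lo * 1000, hi * 1000, alpha=0.15, color="teal")
    ax.axvline(0, color="grey", lw=0.5)
    ax.invert_yaxis()  # negative up, ERP convention
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (microvolts)")
    ax.set_title(f"{channel}: {component} window")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def save_epochs(epochs: EpochSet, prefix) -> dict:
    """Binary epochs container: float32 tensor + JSON sidecar + labels TSV."""
    prefix = Path(prefix)
    dat = prefix.with_suffix(".dat")
    epochs.data.astype("<f4").tofile(dat)
    labels_tsv = prefix.with_name(prefix.name + "_labels.tsv")
    labels = epochs.labels.assign(rejected=epochs.rejected)
    labels.to_csv(labels_tsv, sep="\t", index=False, na_rep="n/a")
    meta = {
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "order": "epoch-major C order (epochs x channels x samples)",
        "sample_rate": epochs.sample_rate,
        "channels": list(epochs.channels),
        "window": list(epochs.window),
        "baseline": list(epochs.baseline),
        "units": "microvolts",
        "labels": labels_tsv.name,
        "data": dat.name,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return meta


def load_epochs(prefix) -> EpochSet:
    """Load an epochs container written by :func:`save_epochs`."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    data = np.fromfile(prefix.parent / meta["data"], dtype="<f4").reshape(
        meta["shape"]
    ).astype(float)
    labels = pd.read_csv(
        prefix.parent / meta["labels"], sep="\t", na_values=["n/a"],
        keep_default_na=False,
    )
    rejected = labels.pop("rejected").astype(bool).to_numpy()
    return EpochSet(
        data=data,
        sample_rate=meta["sample_rate"],
        channels=tuple(meta["channels"]),
        window=tuple(meta["window"]),
        baseline=tuple(meta["baseline"]),
        labels=labels,
        rejected=rejected,
    )
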