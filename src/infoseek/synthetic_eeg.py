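"""Synthetic multichannel EEG with known event-related components.

Each card and outcome-screen event adds parametric FRN, N1 and LPP
deflections whose amplitudes depend on the event's prediction-error sign
labels, on top of per-channel pink + white noise.  Templates are scaled
so that a coefficient of c microvolts produces exactly a c-microvolt
mean over the component's measurement window in the noiseless forward
model, which makes parameter-recovery targets explicit.

There is no volume-conduction model: topographies are fixed per-channel
gain tables, and the mastoid references receive (near-)zero component
gain so that mastoid re-referencing behaves realistically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task_simulator import Session, TimingSpec, session_events

#: 10-20 labels used by the component analyses, plus mastoid references.
DEFAULT_MONTAGE = (
    "Fpz", "AFz", "Fz", "FCz", "Cz",
    "F3", "F4", "C3", "C4",
    "CPz", "CP1", "CP2", "Pz",
    "M1", "M2",
)

MASTOIDS = ("M1", "M2")

FRONTOCENTRAL = ("Fpz", "AFz", "Fz", "FCz", "Cz")
N1_CHANNELS = ("Fz", "F3", "F4", "Cz", "C3", "C4")
CENTROPARIETAL = ("Cz", "CPz", "CP1", "CP2", "Pz")

#: Measurement windows in seconds post-stimulus (closed left, open right).
COMPONENT_WINDOWS = {
    "FRN": (0.200, 0.350),
    "N1": (0.150, 0.200),
    "LPP": (0.400, 0.700),
}


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG in microvolts with an event table."""

    sample_rate: float
    channels: tuple[str, ...]
    data: np.ndarray  # channels x samples, microvolts
    events: pd.DataFrame  # must contain a 'sample' column

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples")
        samples = self.events["sample"].to_numpy()
        if len(samples) and not np.all(np.diff(samples) > 0):
            raise ValueError("event latencies must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def validate_spacing(self, half_width_s: float = 1.0) -> None:
        """Check inter-event spacing against an epoch half-width."""
        samples = self.events["sample"].to_numpy()
        min_gap = half_width_s * self.sample_rate
        if len(samples) > 1 and np.min(np.diff(samples)) < min_gap:
            raise ValueError(
                f"inter-event spacing below {half_width_s} s epoch half-width"
            )


@dataclass(frozen=True)
class ComponentSpec:
    """Parametric ERP component.

    ``modulation`` maps ``(label_column, level)`` pairs (e.g.
    ``("ipe_sign", "neg")``) to amplitude offsets in microvolts added to
    ``base_amplitude`` whenever the event's label matches.
    """

    name: str
    peak_s: float
    width_s: float  # Gaussian sd, or boxcar edge-smoothing sd
    shape: str  # "gaussian" or "boxcar"
    base_amplitude: float  # microvolts (signed)
    topography: Mapping[str, float]
    modulation: Mapping[tuple[str, str], float] = field(default_factory=dict)
    window: tuple[float, float] | None = None  # boxcar support, seconds

    def waveform(self, times: np.ndarray) -> np.ndarray:
        """Unit template on a time grid, normalised so its mean over the
        component's measurement window equals 1."""
        if self.shape == "gaussian":
            w = np.exp(-0.5 * ((times - self.peak_s) / self.width_s) ** 2)
        elif self.shape == "boxcar":
            lo, hi = self.window or COMPONENT_WINDOWS[self.name]
            from scipy.special import erf

            s = self.width_s * np.sqrt(2.0)
            w = 0.5 * (erf((times - lo) / s) - erf((times - hi) / s))
        else:
            raise ValueError(f"unknown template shape {self.shape!r}")
        lo, hi = COMPONENT_WINDOWS.get(self.name, (self.peak_s - 0.05, self.peak_s + 0.05))
        mask = (times >= lo) & (times < hi)
        norm = float(w[mask].mean()) if mask.any() else float(w.max())
        return w / norm


def _gain_table(full: Sequence[str], others: float = 0.25) -> dict[str, float]:
    gains = {ch: others for ch in DEFAULT_MONTAGE}
    for ch in full:
        gains[ch] = 1.0
    for ch in MASTOIDS:
        gains[ch] = 0.0
    return gains


def default_component_specs(
    frn_rpe: float = -1.4,
    frn_ipe: float = -2.1,
    n1_rpe: float = -1.3,
    n1_ipe: float = -1.1,
    lpp_ipe: float = 0.0,
    frn_outcome_loss: float = -0.8,
) -> tuple[ComponentSpec, ...]:
    """Component set with sign-bin modulations.

    Defaults approximate the reported negative-minus-positive condition
    differences (about 1.4 to 2 microvolts); a coefficient on
    ``("ipe_sign", "neg")`` shifts the window-mean amplitude of negative
    IPE events by that many microvolts.  The same coefficients are applied
    to the pseudo sign labels so that non-informative stimuli can carry
    (smaller, configurable) effects; by default only true labels modulate.
    """
    frn_mod = {
        ("rpe_sign", "neg"): frn_rpe,
        ("ipe_sign", "neg"): frn_ipe,
        ("outcome", "loss"): frn_outcome_loss,
    }
    n1_mod = {("rpe_sign", "neg"): n1_rpe, ("ipe_sign", "neg"): n1_ipe}
    lpp_mod = {("ipe_sign", "neg"): lpp_ipe}
    return (
        ComponentSpec(
            name="FRN", peak_s=0.275, width_s=0.040, shape="gaussian",
            base_amplitude=4.0, topography=_gain_table(FRONTOCENTRAL),
            modulation=frn_mod,
        ),
        ComponentSpec(
            name="N1", peak_s=0.175, width_s=0.015, shape="gaussian",
            base_amplitude=-1.0, topography=_gain_table(N1_CHANNELS),
            modulation=n1_mod,
        ),
        ComponentSpec(
            name="LPP", peak_s=0.550, width_s=0.030, shape="boxcar",
            base_amplitude=3.0, topography=_gain_table(CENTROPARIETAL),
            modulation=lpp_mod, window=(0.400, 0.700),
        ),
    )


def null_component_specs() -> tuple[ComponentSpec, ...]:
    """Components with every sign modulation set to zero."""
    return default_component_specs(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def scaled_component_specs(effect: float) -> tuple[ComponentSpec, ...]:
    """All sign effects set to the same (signed) microvolt value."""
    return default_component_specs(effect, effect, effect, effect, 0.0, effect)


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise model (per-sample microvolts)."""

    white_sd: float = 8.0
    pink_scale: float = 8.0
    participant_sd: float = 1.0  # random intercept per component, per recording
    trial_sd: float = 1.0  # per-event amplitude jitter


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def synthesize_recording(
    session: Session,
    specs: Sequence[ComponentSpec] | None = None,
    noise: NoiseParams | None = None,
    timing: TimingSpec | None = None,
    montage: Sequence[str] = DEFAULT_MONTAGE,
    sample_rate: float = 512.0,
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Forward-model a session into a continuous Recording.

    Every card and outcome-screen event contributes each component's
    template x topography x (base + modulation + participant intercept +
    trial jitter); pink and white noise are added per channel.
    """
    specs = default_component_specs() if specs is None else tuple(specs)
    noise = noise or NoiseParams()
    timing = timing or TimingSpec()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for spec in specs:
        missing = [ch for ch in montage if ch not in spec.topography]
        if missing:
            raise ValueError(
                f"component {spec.name}: channels missing from topography: {missing}"
            )
    events = session_events(session, timing)
    events = events.assign(
        sample=np.round(events["onset"].to_numpy() * sample_rate).astype(int)
    )
    n_samples = int(
        round((events["onset"].iloc[-1] + timing.lead_out + 1.5) * sample_rate)
    )
    n_ch = len(montage)
    data = np.zeros((n_ch, n_samples))

    # support grid for templates: -0.2 .. +1.0 s around each event
    t0, t1 = -0.2, 1.0
    offsets = np.arange(int(round(t0 * sample_rate)), int(round(t1 * sample_rate)))
    times = offsets / sample_rate
    gains = {
        spec.name: np.array([spec.topography[ch] for ch in montage])
        for spec in specs
    }
    waves = {spec.name: spec.waveform(times) for spec in specs}
    intercepts = {
        spec.name: noise.participant_sd * rng.standard_normal() for spec in specs
    }
    samples = events["sample"].to_numpy(int)
    for spec in specs:
        amps = np.full(
            len(events), spec.base_amplitude + intercepts[spec.name]
        )
        amps += noise.trial_sd * rng.standard_normal(len(events))
        for (column, level), coeff in spec.modulation.items():
            if column in events.columns:
                amps += coeff * (events[column].to_numpy() == level)
        gain, wave = gains[spec.name], waves[spec.name]
        width = len(offsets)
        for amp, s0 in zip(amps, samples):
            lo = s0 + offsets[0]
            if 0 <= lo and lo + width <= n_samples:
                data[:, lo : lo + width] += (amp * gain)[:, None] * wave
            else:  # clipped at a recording edge
                idx = s0 + offsets
                ok = (idx >= 0) & (idx < n_samples)
                data[:, idx[ok]] += amp * np.outer(gain, wave[ok])
    for c in range(n_ch):
        if noise.pink_scale > 0:
            data[c] += noise.pink_scale * pink_noise(n_samples, rng)
        if noise.white_sd > 0:
            data[c] += noise.white_sd * rng.standard_normal(n_samples)
    events.insert(0, "participant", session.participant)
    return Recording(
        sample_rate=sample_rate,
        channels=tuple(montage),
        data=data,
        events=events.reset_index(drop=True),
    )


def inject_artifacts(
    recording: Recording,
    rate: float,
    amplitude: float = 400.0,
    duration_s: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> tuple[Recording, list[int]]:
    """Add high-amplitude transients at a fraction of the events.

    Returns the contaminated recording and the indices (row positions in
    the event table) of the events whose epochs received an artifact, for
    cross-checking against the rejection stage.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    data = recording.data.copy()
    contaminated: list[int] = []
    n = int(round(duration_s * recording.sample_rate))
    bump = amplitude * np.sin(np.linspace(0, np.pi, n))
    for i, s0 in enumerate(recording.events["sample"].to_numpy()):
        if rng.random() >= rate:
            continue
        start = int(s0 + rng.uniform(-0.2, 0.5) * recording.sample_rate)
        start = max(0, min(start, recording.n_samples - n))
        data[:, start : start + n] += bump
        contaminated.append(i)
    return (
        Recording(
            recording.sample_rate, recording.channels, data,
            recording.events.copy(),
        ),
        contaminated,
    )


def save_recording(recording: Recording, prefix) -> dict:
    """Write the raw binary container: little-endian float32 samples,
    channel-multiplexed (frame by frame), plus JSON sidecar and events TSV."""
    prefix = Path(prefix)
    dat = prefix.with_suffix(".dat")
    sidecar = prefix.with_suffix(".json")
    events_tsv = prefix.with_name(prefix.name + "_events.tsv")
    recording.data.T.astype("<f4").tofile(dat)
    recording.events.to_csv(events_tsv, sep="\t", index=False, na_rep="n/a")
    meta = {
        "channels": list(recording.channels),
        "sample_rate": recording.sample_rate,
        "n_samples": recording.n_samples,
        "units": "microvolts",
        "dtype": "<f4",
        "order": "sample-major (channel-multiplexed frames)",
        "events": events_tsv.name,
        "data": dat.name,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return meta


def load_recording(prefix) -> Recording:
    """Load a recording written by :func:`save_recording`."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        meta = json.load(fh)
    raw = np.fromfile(prefix.parent / meta["data"], dtype="<f4")
    data = raw.reshape(meta["n_samples"], len(meta["channels"])).T.astype(float)
    events = pd.read_csv(
        prefix.parent / meta["events"], sep="\t", na_values=["n/a"],
        keep_default_na=False,
    )
    return Recording(
        sample_rate=meta["sample_rate"],
        channels=tuple(meta["channels"]),
        data=data,
        events=events,
    )
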