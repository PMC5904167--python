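"""End-to-end cohort workflows: simulate behaviour and EEG, preprocess,
epoch, reject, bin, measure, and run the condition ANOVA.

These functions chain the public module surfaces and are used by the
command-line interface and the Monte-Carlo parameter-recovery studies.
Monte-Carlo studies run at reduced sizes (lower sampling rate, the
component's own electrode subset) chosen to keep a simulation study on a
single CPU practical; the event structure, filters, windows, inclusion
rules and statistics are the full-scale ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import erp_pipeline as erp
from . import stats
from . import synthetic_eeg as seeg
from . import task_simulator as sim

#: Reduced montage for FRN-focused simulation studies.
FRN_MONTAGE = seeg.FRONTOCENTRAL + seeg.MASTOIDS


@dataclass(frozen=True)
class CohortConfig:
    """Knobs for a simulated cohort run."""

    n_participants: int = 20
    task: sim.TaskParams = sim.TaskParams()
    agent: sim.AgentParams = sim.AgentParams()
    info_value_sd: float = 0.75
    sample_rate: float = 512.0
    montage: tuple[str, ...] = seeg.DEFAULT_MONTAGE
    noise: seeg.NoiseParams = seeg.NoiseParams()
    component: str = "FRN"
    scheme: str = "ipe_sign"
    min_epochs: int = erp.MIN_EPOCHS
    rejection_threshold: float = erp.REJECTION_THRESHOLD_UV


@dataclass(frozen=True)
class CohortResult:
    amplitude_table: pd.DataFrame
    anova: list
    participant_differences: pd.DataFrame  # neg - pos per participant
    n_included: int
    n_cohort: int


def participant_amplitudes(
    session: sim.Session,
    specs,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame | None:
    """Run one participant through the full chain; None if excluded."""
    rec = seeg.synthesize_recording(
        session,
        specs=specs,
        noise=cfg.noise,
        montage=cfg.montage,
        sample_rate=cfg.sample_rate,
        seed=rng,
    )
    rec = erp.preprocess(rec)
    epochs = erp.epoch_and_baseline(rec)
    epochs = erp.reject_artifacts(epochs, threshold=cfg.rejection_threshold)
    bins = erp.bin_epochs(epochs, cfg.scheme)
    if any(
        len(idx) < cfg.min_epochs for idx in bins.values()
    ):
        return None
    return erp.measure_component(epochs, cfg.component, bins)


def run_cohort(
    specs, cfg: CohortConfig | None = None, seed: int = 0
) -> CohortResult:
    """Simulate and analyse one cohort; ANOVA is condition x electrode."""
    cfg = cfg or CohortConfig()
    ss = np.random.SeedSequence(seed)
    tables = []
    for i, child in enumerate(ss.spawn(cfg.n_participants)):
        rng = np.random.default_rng(child)
        agent = replace(
            cfg.agent,
            info_value=cfg.agent.info_value
            + cfg.info_value_sd * rng.standard_normal(),
        )
        session = sim.simulate_session(
            participant=f"sub-{i + 1:02d}", agent=agent, task=cfg.task, seed=rng
        )
        table = participant_amplitudes(session, specs, cfg, rng)
        if table is not None:
            tables.append(table)
    if len(tables) < 2:
        raise ValueError("fewer than 2 participants met the epoch-count rule")
    amp = pd.concat(tables, ignore_index=True)
    anova = stats.rm_anova(
        amp, dv="mean_amplitude", within=["condition", "electrode"],
        subject="participant",
    )
    per_cond = (
        amp.groupby(["participant", "condition"])["mean_amplitude"]
        .mean()
        .unstack("condition")
    )
    diffs = (per_cond["neg"] - per_cond["pos"]).rename("difference").reset_index()
    return CohortResult(
        amplitude_table=amp,
        anova=anova,
        participant_differences=diffs,
        n_included=per_cond.shape[0],
        n_cohort=cfg.n_participants,
    )


def noiseless_effect(
    specs, cfg: CohortConfig | None = None, seed: int = 12345
) -> float:
    """Condition difference (neg - pos) the pipeline measures with all
    noise sources off: the forward-model truth for parameter recovery."""
    cfg = cfg or CohortConfig()
    quiet = replace(
        cfg,
        noise=seeg.NoiseParams(
            white_sd=0.0, pink_scale=0.0, participant_sd=0.0, trial_sd=0.0
        ),
        n_participants=1,
        min_epochs=1,
    )
    rng = np.random.default_rng(seed)
    # informative-preferring agent so both sign bins are populated
    agent = replace(quiet.agent, info_value=10.0)
    session = sim.simulate_session("sub-fm", agent=agent, task=quiet.task, seed=rng)
    table = participant_amplitudes(session, specs, quiet, rng)
    if table is None:
        raise RuntimeError("forward-model session produced empty bins")
    per_cond = table.groupby("condition")["mean_amplitude"].mean()
    return float(per_cond["neg"] - per_cond["pos"])


def difference_ci(diffs: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for the mean condition difference."""
    from scipy import stats as sps

    x = np.asarray(diffs, float)
    n = x.size
    se = x.std(ddof=1) / np.sqrt(n)
    half = sps.t.ppf(0.5 + level / 2, n - 1) * se
    mean = x.mean()
    return float(mean - half), float(mean + half)
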