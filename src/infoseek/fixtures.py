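"""One-command generation of the canonical synthetic fixture set.

Builds a desk-scale cohort (behaviour + EEG) at the task's default
parameters in three variants: ``default`` (literature-scale component
effects), ``null`` (no sign effects) and ``strong`` (-3 microvolt sign
effects).  Behaviour is written for every participant; epoch containers
are written for a small number of participants and one continuous
recording is kept to exercise the preprocessing stage, which keeps the
fixture directory light.  The manifest records seeds, parameters and a
SHA-256 checksum per file: rebuilding from the same configuration
reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import erp_pipeline as erp
from . import synthetic_eeg as seeg
from . import task_simulator as sim


@dataclass(frozen=True)
class FixtureConfig:
    n_participants: int = 20
    n_eeg_epoch_participants: int = 2
    sample_rate: float = 512.0
    seed: int = 2018
    task: sim.TaskParams = sim.TaskParams()
    agent: sim.AgentParams = sim.AgentParams()
    info_value_sd: float = 0.75
    noise: seeg.NoiseParams = seeg.NoiseParams()
    variants: tuple[str, ...] = ("default", "null", "strong")


@dataclass
class FixtureManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _variant_specs(variant: str):
    if variant == "default":
        return seeg.default_component_specs()
    if variant == "null":
        return seeg.null_component_specs()
    if variant == "strong":
        return seeg.scaled_component_specs(-3.0)
    raise ValueError(f"unknown fixture variant {variant!r}")


def build_fixtures(config: FixtureConfig | None = None, out_dir="fixtures") -> FixtureManifest:
    """Write the fixture set and its manifest; returns the manifest."""
    cfg = config or FixtureConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = FixtureManifest(
        config={
            "n_participants": cfg.n_participants,
            "n_eeg_epoch_participants": cfg.n_eeg_epoch_participants,
            "sample_rate": cfg.sample_rate,
            "seed": cfg.seed,
            "task": dataclasses.asdict(cfg.task),
            "agent": dataclasses.asdict(cfg.agent),
            "info_value_sd": cfg.info_value_sd,
            "noise": dataclasses.asdict(cfg.noise),
            "variants": list(cfg.variants),
        }
    )
    root_ss = np.random.SeedSequence(cfg.seed)
    variant_seeds = {
        v: int(child.generate_state(1)[0] % (2**31))
        for v, child in zip(cfg.variants, root_ss.spawn(len(cfg.variants)))
    }
    manifest.seeds = variant_seeds
    written: list[Path] = []
    for variant in cfg.variants:
        vdir = out / variant
        vdir.mkdir(exist_ok=True)
        specs = _variant_specs(variant)
        sessions = sim.simulate_cohort(
            n_participants=cfg.n_participants,
            seed=variant_seeds[variant],
            agent=cfg.agent,
            task=cfg.task,
            info_value_sd=cfg.info_value_sd,
        )
        sessions = sim.apply_attention_exclusion(sessions)
        for s in sessions:
            tsv = vdir / f"{s.participant}_events.tsv"
            sidecar = vdir / f"{s.participant}_session.json"
            sim.write_bids_events(s, tsv, sidecar)
            written += [tsv, sidecar]
        eeg_ss = np.random.SeedSequence(variant_seeds[variant] + 1)
        for s, child in zip(
            sessions[: cfg.n_eeg_epoch_participants],
            eeg_ss.spawn(cfg.n_eeg_epoch_participants),
        ):
            rec = seeg.synthesize_recording(
                s, specs=specs, noise=cfg.noise,
                sample_rate=cfg.sample_rate, seed=np.random.default_rng(child),
            )
            rec = erp.preprocess(rec)
            epochs = erp.epoch_and_baseline(rec)
            epochs = erp.reject_artifacts(epochs)
            prefix = vdir / f"{s.participant}_epochs"
            erp.save_epochs(epochs, prefix)
            written += [
                prefix.with_suffix(".dat"),
                prefix.with_suffix(".json"),
                prefix.with_name(prefix.name + "_labels.tsv"),
            ]
        if variant == "default":
            raw_rng = np.random.default_rng(
                np.random.SeedSequence(variant_seeds[variant] + 2)
            )
            rec = seeg.synthesize_recording(
                sessions[0], specs=specs, noise=cfg.noise,
                sample_rate=cfg.sample_rate, seed=raw_rng,
            )
            prefix = vdir / f"{sessions[0].participant}_raw"
            seeg.save_recording(rec, prefix)
            written += [
                prefix.with_suffix(".dat"),
                prefix.with_suffix(".json"),
                prefix.with_name(prefix.name + "_events.tsv"),
            ]
    for path in written:
        manifest.files[str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
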