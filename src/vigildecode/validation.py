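"""Calibration experiments for the statistical machinery.

Two study-level soundness checks, run at reduced spatial/temporal scale
so they complete on a single CPU:

* chance-level control: the full pipeline on synthetic epochs with zero
  planted class effect must produce group-mean temporal-generalization
  accuracy at the balanced-design chance level of 50%;
* false-discovery control: across many seeded global-null repetitions,
  the fraction of runs in which the Mann-Whitney + Benjamini-Hochberg
  procedure declares any cell significant at q = 0.01 must stay at or
  below the nominal level (within Monte-Carlo error).

Also provides reduced-scale planted-effect configurations used to check
that the pipeline recovers a shared NREM pattern and the
polarity-reversal signature.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .containers import ChannelLayout, STATES
from .decoding import ClassifierSpec, permute_labels, prepare_for_decoding, within_state_tgm
from .group_stats import mass_univariate
from .pipeline import RunConfig, derive_seed, run_full_analysis
from .preprocess import PreprocessingParams, preprocess
from .simulate import EffectSpec, NoiseSpec, SimulationConfig, default_noise_specs, simulate_epochs

__all__ = [
    "null_chance_config",
    "chance_level_experiment",
    "reduced_scale_config",
    "fdr_null_experiment",
    "planted_effect_config",
]


def _null_effects() -> dict:
    return {"VOICE": EffectSpec(amplitude=0.0)}


def null_chance_config(
    seed: int,
    states: tuple[str, ...] = ("N2",),
    n_subjects: int = 16,
    n_channels: int = 8,
    n_epochs: int = 100,
) -> RunConfig:
    """Study-scale null configuration: full 250 Hz preprocessing chain,
    100 balanced epochs per condition, zero planted effect."""
    sim = SimulationConfig(
        n_subjects=n_subjects,
        states=tuple(states),
        n_epochs_per_condition={s: n_epochs for s in states},
        layout=ChannelLayout.default(n_channels),
        effects=_null_effects(),
        noise={s: default_noise_specs()[s] for s in states},
        seed=seed,
    )
    return RunConfig(
        simulation=sim,
        preprocessing=PreprocessingParams(n_balance=n_epochs),
        contrasts=("VOICE",),
        states=tuple(states),
        master_seed=seed,
    )


def chance_level_experiment(
    seed: int,
    states: tuple[str, ...] = ("N2",),
    n_subjects: int = 16,
    n_channels: int = 8,
    n_epochs: int = 100,
) -> dict:
    """Run the full pipeline on null data; report the grand mean
    accuracy (percent) over all TGM cells, subjects and state pairs.

    The 3-binomial-SE band uses the per-subject test-trial count
    (2 * n_epochs trials scored across the two folds), not the cell
    count, since neighbouring cells are strongly correlated.
    """
    config = null_chance_config(seed, states, n_subjects, n_channels, n_epochs)
    grid = run_full_analysis(config)
    all_scores = []
    per_pair = {}
    for key, res in grid.entries.items():
        scores = np.stack([t.scores for t in res.subject_tgms])
        per_pair[f"{key[0]}->{key[1]}"] = 100.0 * float(scores.mean())
        all_scores.append(scores)
    grand = float(np.mean([s.mean() for s in all_scores]))
    n_test = 2 * n_epochs
    se = np.sqrt(0.25 / n_test) / np.sqrt(n_subjects)
    return {
        "value": 100.0 * grand,
        "n": n_subjects,
        "per_pair_pct": per_pair,
        "chance_pct": 50.0,
        "band_3se_pct": 100.0 * 3 * se,
        "n_cells": int(all_scores[0].shape[1] * all_scores[0].shape[2]),
    }


def reduced_scale_config(
    seed: int,
    states: tuple[str, ...] = ("N2",),
    n_subjects: int = 8,
    n_channels: int = 8,
    n_epochs: int = 20,
    effects: Optional[dict] = None,
) -> RunConfig:
    """Desk-scale configuration: 50 Hz acquisition, 1-7 Hz band-pass,
    decimation x3 (21 samples between -0.2 and 1.0 s, a ~21x21 TGM).

    The decode-time low-pass is dropped because the reduced sampling
    rate already confines the spectrum well below 25 Hz.
    """
    sim = SimulationConfig(
        n_subjects=n_subjects,
        states=tuple(states),
        n_epochs_per_condition={s: n_epochs for s in states},
        sfreq=50.0,
        layout=ChannelLayout.default(n_channels),
        effects=effects if effects is not None else _null_effects(),
        noise={s: default_noise_specs()[s] for s in states},
        seed=seed,
    )
    return RunConfig(
        simulation=sim,
        preprocessing=PreprocessingParams(
            bandpass=(1.0, 7.0), decim=3, lowpass=None, n_balance=n_epochs
        ),
        contrasts=tuple(effects.keys()) if effects else ("VOICE",),
        states=tuple(states),
        master_seed=seed,
    )


def _single_null_run(config: RunConfig) -> bool:
    """One global-null repetition: per-subject observed and
    label-permuted TGMs, Mann-Whitney per cell, BH per matrix.
    Returns True when any cell is declared significant.

    Filtering/cropping/decimation act independently on every trial, so
    all subjects are conditioned in one stacked call (identical numbers,
    one FIR design) before the per-subject balance/decode steps.
    """
    from .preprocess import balance_epochs, bandpass_filter, crop, decimate

    state = config.states[0]
    spec = config.classifier
    params = config.preprocessing
    sim = config.simulation
    blocks = [
        simulate_epochs(sim, subject, state, "VOICE")
        for subject in range(sim.n_subjects)
    ]
    stacked = blocks[0].evolve(
        data=np.concatenate([b.data for b in blocks]),
        labels=np.concatenate([b.labels for b in blocks]),
    )
    stacked = decimate(
        crop(bandpass_filter(stacked, *params.bandpass), params.crop_window),
        params.decim,
    )
    n_per = blocks[0].n_trials
    obs, null = [], []
    for subject in range(sim.n_subjects):
        sl = slice(subject * n_per, (subject + 1) * n_per)
        ep = stacked.evolve(
            data=stacked.data[sl], labels=stacked.labels[sl], subject=subject
        )
        ep = balance_epochs(
            ep, params.n_balance, derive_seed(config.master_seed, 1, 0, subject, 0)
        )
        ep = prepare_for_decoding(ep, lowpass=params.lowpass)
        fold_seed = derive_seed(config.master_seed, 3, 0, subject, 0)
        perm = permute_labels(
            ep, derive_seed(config.master_seed, 2, 0, subject, 0)
        )
        obs.append(within_state_tgm(ep, spec, seed=fold_seed))
        null.append(within_state_tgm(perm, spec, seed=fold_seed))
    stat = mass_univariate(obs, null, q=config.q)
    return bool(stat.mask.any())


def fdr_null_experiment(
    seed: int,
    n_runs: int = 500,
    n_subjects: int = 8,
    n_channels: int = 8,
    n_epochs: int = 20,
    q: float = 0.01,
) -> dict:
    """Empirical any-rejection rate of the group-level procedure over
    seeded global-null repetitions at reduced scale."""
    n_any = 0
    for r in range(n_runs):
        config = reduced_scale_config(
            derive_seed(seed, 7, r), ("N2",), n_subjects, n_channels, n_epochs
        )
        # accuracy scoring is insensitive to optimizer tolerance at this
        # scale; a looser tol keeps the many-repetition loop fast
        config = dataclasses.replace(
            config, q=q, classifier=ClassifierSpec(tol=1e-4)
        )
        n_any += _single_null_run(config)
    frac = n_any / n_runs
    mc_se = float(np.sqrt(q * (1 - q) / n_runs))
    return {
        "value": frac,
        "n": n_runs,
        "n_any_rejection": n_any,
        "q": q,
        "bound_3se": q + 3 * mc_se,
    }


def planted_effect_config(
    seed: int,
    shared_states: frozenset = frozenset({"N2", "N3"}),
    states: tuple[str, ...] = ("WAKE", "N2", "N3", "REM"),
    amplitude: Optional[float] = None,
    n_subjects: int = 16,
    n_channels: int = 8,
    n_epochs: int = 30,
) -> RunConfig:
    """Reduced-scale configuration with a strong fronto-central pattern
    planted in ``shared_states`` only (the shared-NREM-code scenario).

    By default the planted amplitude is 3x the largest per-sample
    background SD among the carrying states — the detectability
    condition under which the group-level machinery is expected to have
    power (N3's large in-band slow-wave noise sets the scale).
    """
    from .simulate import state_noise_sd

    if amplitude is None:
        noise = default_noise_specs()
        amplitude = 3.0 * max(state_noise_sd(noise[s]) for s in shared_states)
    effects = {
        "VOICE": EffectSpec(amplitude=amplitude,
                            shared_states=frozenset(shared_states))
    }
    return reduced_scale_config(
        seed, states, n_subjects, n_channels, n_epochs, effects=effects
    )
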