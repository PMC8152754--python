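"""End-to-end orchestration: simulate (or load) -> preprocess -> decode
all state pairs -> forward-model topographies -> group statistics ->
serialized results, tables and figures.

Every random element (balancing draw, CV fold split, label
permutation) is seeded from one master seed through per-(contrast,
subject, state) substreams, so a run is fully reproducible and
independent of subject execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as vio
from .containers import STATES, EpochSet
from .decoding import (
    ClassifierSpec,
    TemporalGeneralizationMatrix,
    cross_state_tgm,
    peak_window_summary,
    permute_labels,
    prepare_for_decoding,
    within_state_tgm,
)
from .forward_model import TopographyMap, mean_topography, pattern_timecourse
from .group_stats import StatResult, mass_univariate
from .preprocess import PreprocessingParams, preprocess
from .simulate import (
    EffectSpec,
    NoiseSpec,
    SimulationConfig,
    default_noise_specs,
    simulate_epochs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PairResult",
    "CrossGeneralizationGrid",
    "derive_seed",
    "run_full_analysis",
    "summarize",
]


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic substream seed (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed for one full analysis run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    contrasts: tuple[str, ...] = ("VOICE", "NAME")
    states: tuple[str, ...] = STATES
    q: float = 0.01
    peak_window: tuple[float, float] = (0.25, 0.40)
    output_dir: Optional[Path] = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        for s in self.states:
            if s not in self.simulation.states:
                raise ValueError(f"state {s!r} missing from simulation config")
        for c in self.contrasts:
            if c not in self.simulation.effects:
                raise ValueError(f"contrast {c!r} missing from simulation config")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.get("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            from .containers import ChannelLayout

            n_ch = sim.pop("n_channels", None)
            if n_ch is not None:
                sim["layout"] = ChannelLayout.default(int(n_ch))
            if "effects" in sim:
                sim["effects"] = {
                    k: EffectSpec(**{
                        **v,
                        **({"shared_states": frozenset(v["shared_states"])}
                           if "shared_states" in v else {}),
                        **({"topography_center": tuple(v["topography_center"])}
                           if "topography_center" in v else {}),
                        **({"peak_window": tuple(v["peak_window"])}
                           if "peak_window" in v else {}),
                    })
                    for k, v in sim["effects"].items()
                }
            if "noise" in sim:
                base = default_noise_specs()
                for s, kw in sim["noise"].items():
                    base[s] = dataclasses.replace(base[s], **kw)
                sim["noise"] = base
            if "states" in sim:
                sim["states"] = tuple(sim["states"])
            if "epoch_window" in sim:
                sim["epoch_window"] = tuple(sim["epoch_window"])
            sim = SimulationConfig(**sim)
        pp = d.get("preprocessing", {})
        if isinstance(pp, dict):
            pp = dict(pp)
            for key in ("bandpass", "crop_window"):
                if key in pp:
                    pp[key] = tuple(pp[key])
            pp = PreprocessingParams(**pp)
        clf = d.get("classifier", {})
        if isinstance(clf, dict):
            clf = ClassifierSpec(**clf)
        out = d.get("output_dir")
        return cls(
            simulation=sim,
            preprocessing=pp,
            classifier=clf,
            contrasts=tuple(d.get("contrasts", ("VOICE", "NAME"))),
            states=tuple(d.get("states", sim.states)),
            q=float(d.get("q", 0.01)),
            peak_window=tuple(d.get("peak_window", (0.25, 0.40))),
            output_dir=Path(out) if out else None,
            master_seed=int(d.get("master_seed", 0)),
        )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        return enc(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PairResult:
    """Group-level result for one (train-state, test-state, contrast)."""

    group_mean: TemporalGeneralizationMatrix
    stat: StatResult
    subject_tgms: list[TemporalGeneralizationMatrix]
    null_tgms: list[TemporalGeneralizationMatrix]


@dataclass
class CrossGeneralizationGrid:
    """The full array of state-pair results plus topographies."""

    states: tuple[str, ...]
    contrasts: tuple[str, ...]
    entries: dict[tuple[str, str, str], PairResult]
    topographies: dict[tuple[str, str], TopographyMap]
    peak_window: tuple[float, float]
    master_seed: int
    config_hash: str


def _prepare_subject_state(
    config: RunConfig, subject: int, state: str, contrast: str,
    provider=None, preprocessed: bool = False,
) -> tuple[EpochSet, EpochSet]:
    """Condition, balance and standardize one block, plus its
    label-permuted twin (the within-subject null).

    ``provider(subject, state, contrast)`` supplies the raw (or, with
    ``preprocessed=True``, already conditioned and balanced) EpochSet;
    by default epochs are simulated from the run's SimulationConfig.
    """
    ci = list(config.contrasts).index(contrast)
    si = list(config.states).index(state)
    if provider is None:
        ep = simulate_epochs(config.simulation, subject, state, contrast)
    else:
        ep = provider(subject, state, contrast)
    params = config.preprocessing
    if not preprocessed:
        params = dataclasses.replace(
            params, seed=derive_seed(config.master_seed, 1, ci, subject, si)
        )
        ep = preprocess(ep, params)
    ep = prepare_for_decoding(ep, lowpass=params.lowpass)
    perm = permute_labels(ep, derive_seed(config.master_seed, 2, ci, subject, si))
    return ep, perm


def run_full_analysis(
    config: RunConfig, provider=None, preprocessed: bool = False
) -> CrossGeneralizationGrid:
    """Decode every (train-state, test-state) pair for every contrast.

    Diagonal entries are two-fold cross-validated within-state results
    (with fold-averaged forward-model topographies); off-diagonal
    entries are cross-state transfer results.  Each subject also
    contributes one label-permuted null TGM per pair, the second sample
    of the group-level Mann-Whitney test.
    """
    entries: dict[tuple[str, str, str], PairResult] = {}
    topographies: dict[tuple[str, str], TopographyMap] = {}
    n_subj = config.simulation.n_subjects
    for contrast in config.contrasts:
        ci = list(config.contrasts).index(contrast)
        per_pair: dict[tuple[str, str], list] = {
            (a, b): [] for a, b in product(config.states, config.states)
        }
        per_pair_null: dict[tuple[str, str], list] = {
            (a, b): [] for a, b in product(config.states, config.states)
        }
        subject_topos: dict[str, list[TopographyMap]] = {s: [] for s in config.states}
        for subject in range(n_subj):
            prepared = {}
            for state in config.states:
                prepared[state] = _prepare_subject_state(
                    config, subject, state, contrast,
                    provider=provider, preprocessed=preprocessed,
                )
            for train_state, test_state in product(config.states, config.states):
                ep_train, ep_train_perm = prepared[train_state]
                ep_test, _ = prepared[test_state]
                si = list(config.states).index(train_state)
                fold_seed = derive_seed(config.master_seed, 3, ci, subject, si)
                if train_state == test_state:
                    tgm, decoders = within_state_tgm(
                        ep_train, config.classifier, seed=fold_seed,
                        return_decoders=True, estimate_covariance=True,
                    )
                    null_tgm = within_state_tgm(
                        ep_train_perm, config.classifier, seed=fold_seed
                    )
                    subject_topos[train_state].append(
                        mean_topography([pattern_timecourse(d) for d in decoders])
                    )
                else:
                    tgm = cross_state_tgm(ep_train, ep_test, config.classifier)
                    null_tgm = cross_state_tgm(
                        ep_train_perm, ep_test, config.classifier
                    )
                per_pair[(train_state, test_state)].append(tgm)
                per_pair_null[(train_state, test_state)].append(null_tgm)
            logger.info("decoded subject %d / %d (%s)", subject + 1, n_subj, contrast)
        for pair, tgms in per_pair.items():
            null_tgms = per_pair_null[pair]
            stat = mass_univariate(tgms, null_tgms, q=config.q)
            group_mean = TemporalGeneralizationMatrix(
                scores=np.mean([t.scores for t in tgms], axis=0),
                train_times=tgms[0].train_times,
                test_times=tgms[0].test_times,
                train_state=pair[0], test_state=pair[1],
                subject=-1, n_folds=tgms[0].n_folds, contrast=contrast,
            )
            entries[(pair[0], pair[1], contrast)] = PairResult(
                group_mean=group_mean, stat=stat,
                subject_tgms=tgms, null_tgms=null_tgms,
            )
        for state in config.states:
            topographies[(state, contrast)] = mean_topography(subject_topos[state])
    grid = CrossGeneralizationGrid(
        states=tuple(config.states), contrasts=tuple(config.contrasts),
        entries=entries, topographies=topographies,
        peak_window=tuple(config.peak_window), master_seed=config.master_seed,
        config_hash=config.config_hash(),
    )
    if config.output_dir is not None:
        write_grid(grid, config)
    return grid


def summarize(grid: CrossGeneralizationGrid) -> pd.DataFrame:
    """Peak-window accuracy (% mean ± SD across subjects), significant
    cell count, and the latency of the maximal group-mean accuracy,
    per state pair and contrast."""
    rows = []
    for (train_state, test_state, contrast), res in grid.entries.items():
        per_subj = np.array([
            peak_window_summary(t, grid.peak_window) for t in res.subject_tgms
        ])
        if per_subj.size < 2:
            logger.warning(
                "single subject for %s->%s (%s); SD reported as 0",
                train_state, test_state, contrast,
            )
            sd = 0.0
        else:
            sd = float(per_subj.std(ddof=1))
        gm = res.group_mean
        i, j = np.unravel_index(np.argmax(gm.scores), gm.scores.shape)
        rows.append({
            "contrast": contrast,
            "train_state": train_state,
            "test_state": test_state,
            "peak_window_mean_pct": 100.0 * float(per_subj.mean()),
            "peak_window_sd_pct": 100.0 * sd,
            "n_significant_cells": int(res.stat.mask.sum()),
            "max_accuracy_pct": 100.0 * float(gm.scores[i, j]),
            "max_accuracy_train_time_s": float(gm.train_times[i]),
            "max_accuracy_test_time_s": float(gm.test_times[j]),
        })
    return pd.DataFrame(rows)


def write_grid(grid: CrossGeneralizationGrid, config: RunConfig) -> None:
    """Serialize all grid artifacts below config.output_dir."""
    out = Path(config.output_dir)
    (out / "tgms").mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)
    (out / "topographies").mkdir(exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    for (a, b, c), res in grid.entries.items():
        stem = f"{c}_{a}_to_{b}"
        vio.save_tgm(res.group_mean, out / "tgms" / f"{stem}_groupmean")
        np.savez_compressed(
            out / "tgms" / f"{stem}_subjects.npz",
            scores=np.stack([t.scores for t in res.subject_tgms]),
            null_scores=np.stack([t.scores for t in res.null_tgms]),
            train_times=res.group_mean.train_times,
            test_times=res.group_mean.test_times,
        )
        vio.save_stat_result(res.stat, out / "stats" / stem)
    for (state, c), topo in grid.topographies.items():
        vio.save_topography(topo, out / "topographies" / f"{c}_{state}")
    summary = summarize(grid)
    summary.to_csv(out / "summary.csv", index=False)
    (out / "run_config.json").write_text(json.dumps({
        "config": config.to_dict(), "config_hash": grid.config_hash,
    }, indent=1))
    try:
        from .plots import plot_grid, plot_topography

        for c in grid.contrasts:
            plot_grid(grid, c, out / "figures" / f"grid_{c}.png")
            for state in grid.states:
                plot_topography(
                    grid.topographies[(state, c)],
                    out / "figures" / f"topo_{c}_{state}.png",
                )
    except Exception:  # plotting must never sink an analysis run
        logger.exception("figure rendering failed; numeric outputs are complete")
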