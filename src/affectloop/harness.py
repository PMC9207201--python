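"""Desk-scale replications of the two study designs.

* Method comparison: leave-one-subject-out emotion prediction on a
  synthetic cohort.  For each target participant, the remaining
  participants are split into a pre-training pool and a validation pool;
  methods A (meta-learned initialisation), B (pooled initialisation) and
  C (scratch) are fine-tuned on 5/9/13/25 training pieces and scored by
  per-piece RMSE on the 16 held-out test pieces.  The fusion network
  (CNN + generator inputs) is trained on top of the method-A CNN.

* Policy comparison: per target participant, a CNN is fine-tuned on the
  13-piece training set and a fusion network on top, then the three
  music-update policies each run one closed-loop session per induction
  target; the score is the final target-to-prediction distance.

Results are emitted as long-format tables (one row per participant x
condition x axis/metric); summaries are always derived, never stored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import metalearn as ml
from .cohort import (
    PopulationPrior, TaskDataset, build_cohort, generate_trial,
    sample_participant, stimulus_grid, test_pieces,
)
from .controller import POLICIES, ModelPredictor, run_session

__all__ = [
    "METHOD_COMPARISON_PRIOR",
    "MethodComparisonConfig", "PolicyComparisonConfig",
    "replicate_method_comparison", "replicate_policy_comparison",
    "summarize", "significance_tests",
]

# Cohort prior of the method-comparison experiment.  The comparison is
# only meaningful on a cohort with real between-subject heterogeneity
# (otherwise pooled training is optimal) and an EEG SNR regime in which
# the CNN's error leaves room for the generator inputs to help, so this
# prior widens the subject-level affect response and EEG gain spread and
# adds trial-level log-variance noise that the 20 windows of a trial
# cannot average away.
METHOD_COMPARISON_PRIOR = replace(
    PopulationPrior(),
    affect_gain_sd=0.35,
    affect_offset_sd=0.25,
    gain_individual_sd=1.5,
    noise_scale=0.5,
)


@dataclass(frozen=True)
class MethodComparisonConfig:
    """Problem sizes and seeds of the method-comparison replication.

    Each master seed builds a fresh cohort of ``n_participants``;
    ``targets_per_seed`` participants per seed serve as the left-out
    target (rotating across seeds, so no participant index is favoured)."""

    n_participants: int = 20
    n_seeds: int = 10
    targets_per_seed: int = 1
    n_pretrain: int = 10
    n_val: int = 9
    sizes: tuple = (5, 9, 13, 25)
    methods: tuple = ("A", "B", "C")
    include_fusion: bool = True
    fs: float = 100.0
    base_seed: int = 0
    prior: PopulationPrior = field(default_factory=lambda: METHOD_COMPARISON_PRIOR)
    maml_cfg: ml.MamlConfig = field(default_factory=ml.MamlConfig)
    pooled_cfg: ml.PooledConfig = field(default_factory=ml.PooledConfig)


@dataclass(frozen=True)
class PolicyComparisonConfig:
    """Problem sizes and seeds of the policy-comparison replication.

    Target participants' resting emotions are spread around neutral
    (``rest_sd``), giving the silent-state prediction a real signal to
    recover — the situation the iso principle is designed for.

    ``n_seeds`` replicates the whole design (cohort, pre-training,
    participants); ``session_replicates`` repeats each participant x
    policy x target session with fresh EEG noise under derived seeds."""

    n_targets: int = 10
    n_seeds: int = 1
    session_replicates: int = 10
    n_pretrain: int = 10
    n_val: int = 10
    training_pieces: int = 13
    policies: tuple = POLICIES
    fs: float = 100.0
    base_seed: int = 0
    prior: PopulationPrior = field(default_factory=PopulationPrior)
    rest_sd: float = 0.15
    maml_cfg: ml.MamlConfig = field(default_factory=ml.MamlConfig)


def _featurize_cohort(tasks):
    return [ml.featurize_task(t) for t in tasks]


def replicate_method_comparison(cfg: MethodComparisonConfig | None = None) -> pd.DataFrame:
    """Long-format RMSE table over seeds x targets x methods x sizes.

    Columns: master_seed, participant, method, model, pieces, axis, rmse.
    ``model`` is "cnn" for the plain CNN, "fusion" for CNN + generator
    inputs (method A only) and "geninput" for the generator-input-only
    reference predictor.
    """
    cfg = cfg or MethodComparisonConfig()
    if cfg.n_participants < 20:
        raise ValueError("the method comparison is defined for cohorts of >= 20")
    if 1 + cfg.n_pretrain + cfg.n_val > cfg.n_participants:
        raise ValueError("pretrain + validation pools exceed the cohort")
    test = test_pieces()
    rows = []
    for rep in range(cfg.n_seeds):
        seed_seq = np.random.SeedSequence([cfg.base_seed, rep])
        cohort_seed, split_seed, train_seed = (int(s) for s in seed_seq.generate_state(3))
        cohort = build_cohort(
            cfg.n_participants, "full41", fs=cfg.fs, seed=cohort_seed, prior=cfg.prior
        )
        tasks = _featurize_cohort(cohort)
        target_ids = [
            (rep * cfg.targets_per_seed + k) % cfg.n_participants
            for k in range(cfg.targets_per_seed)
        ]
        rng = np.random.default_rng(split_seed)
        for target_id in target_ids:
            others = [i for i in range(cfg.n_participants) if i != target_id]
            rng.shuffle(others)
            pre_ids = others[: cfg.n_pretrain]
            val_ids = others[cfg.n_pretrain: cfg.n_pretrain + cfg.n_val]
            assert target_id not in pre_ids and target_id not in val_ids
            pretrain = [tasks[i] for i in pre_ids]
            val = [tasks[i] for i in val_ids]
            tgt = tasks[target_id]

            maml_params, _ = ml.maml_pretrain(
                pretrain, val, replace(cfg.maml_cfg, seed=train_seed + target_id)
            )
            pooled_params, _ = ml.pooled_pretrain(
                pretrain, val, replace(cfg.pooled_cfg, seed=train_seed + target_id)
            )

            def emit(method, model, pieces, rv, ra):
                for axis, r in (("valence", rv), ("arousal", ra)):
                    rows.append({
                        "master_seed": rep, "participant": tgt.participant_id,
                        "method": method, "model": model, "pieces": pieces,
                        "axis": axis, "rmse": r,
                    })

            gv, ga = ml.generator_input_rmse(tgt, test)
            emit("-", "geninput", 0, gv, ga)
            for pieces in cfg.sizes:
                for method in cfg.methods:
                    cnn = ml.train_method(
                        method, tgt, pieces,
                        maml_init=maml_params, pooled_init=pooled_params,
                        seed=train_seed + target_id,
                    )
                    rv, ra = ml.evaluate_rmse(cnn, tgt, test)
                    emit(method, "cnn", pieces, rv, ra)
                    if method == "A" and cfg.include_fusion:
                        fus = ml.train_fusion(
                            cnn, tgt, pieces, seed=train_seed + target_id
                        )
                        rv2, ra2 = ml.evaluate_rmse((cnn, fus), tgt, test)
                        emit(method, "fusion", pieces, rv2, ra2)
    return pd.DataFrame(rows)


def replicate_policy_comparison(cfg: PolicyComparisonConfig | None = None) -> pd.DataFrame:
    """Long-format induction-distance table over seeds x targets x policies.

    Columns: master_seed, replicate, participant, policy, target_valence,
    target_arousal, distance.
    """
    cfg = cfg or PolicyComparisonConfig()
    targets = stimulus_grid("targets5")
    rows = []
    for rep in range(cfg.n_seeds):
        seed_seq = np.random.SeedSequence([cfg.base_seed, 101, rep])
        cohort_seed, part_seed, train_seed, sess_seed = (
            int(s) for s in seed_seq.generate_state(4)
        )
        cohort = build_cohort(
            cfg.n_pretrain + cfg.n_val, "full41", fs=cfg.fs,
            seed=cohort_seed, prior=cfg.prior,
        )
        tasks = _featurize_cohort(cohort)
        maml_params, _ = ml.maml_pretrain(
            tasks[: cfg.n_pretrain], tasks[cfg.n_pretrain:],
            replace(cfg.maml_cfg, seed=train_seed),
        )
        # fresh participants, never in the pre-training pools
        target_prior = replace(cfg.prior, rest_sd=cfg.rest_sd)
        part_rng = np.random.SeedSequence(part_seed).generate_state(cfg.n_targets)
        for j in range(cfg.n_targets):
            participant = sample_participant(
                target_prior, int(part_rng[j]), participant_id=f"target-{rep}-{j:02d}"
            )
            stims = stimulus_grid(f"train{cfg.training_pieces}")
            t_ss = np.random.SeedSequence([train_seed, rep, j]).generate_state(len(stims))
            trials = [
                generate_trial(participant, s, fs=cfg.fs, seed=int(t_ss[k]))
                for k, s in enumerate(stims)
            ]
            ftask = ml.featurize_task(TaskDataset(participant=participant, trials=trials))
            cnn = ml.finetune(
                maml_params, ftask, cfg.training_pieces,
                n_iter=ml.FINETUNE_ITERS["A"], seed=train_seed + j,
            )
            fusion = ml.train_fusion(cnn, ftask, cfg.training_pieces, seed=train_seed + j)
            predictor = ModelPredictor(cnn, fusion, fs=cfg.fs)
            for k, (policy, target) in enumerate(
                itertools.product(cfg.policies, targets)
            ):
                for r in range(cfg.session_replicates):
                    res = run_session(
                        participant, predictor, policy, target,
                        seed=(sess_seed + 100000 * r + 1000 * j + k) % (2**31),
                    )
                    rows.append({
                        "master_seed": rep, "replicate": r,
                        "participant": participant.participant_id,
                        "policy": policy, "target_valence": target.valence,
                        "target_arousal": target.arousal,
                        "distance": res.final_distance,
                    })
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, group_keys, value: str | None = None) -> pd.DataFrame:
    """Mean and SD (population SD, so a single record has SD 0) by group."""
    if len(table) == 0:
        raise ValueError("empty results table")
    if value is None:
        value = "rmse" if "rmse" in table.columns else "distance"
    out = (
        table.groupby(list(group_keys))[value]
        .agg(mean="mean", sd=lambda s: float(np.std(s, ddof=0)), n="count")
        .reset_index()
    )
    return out


def significance_tests(table: pd.DataFrame, condition: str, value: str,
                       subject_keys=("master_seed", "participant")) -> dict:
    """Friedman test across conditions plus pairwise Wilcoxon signed-rank
    tests with Bonferroni correction, on subject-wise means."""
    pivot = (
        table.groupby(list(subject_keys) + [condition])[value].mean().unstack(condition)
    ).dropna()
    conds = list(pivot.columns)
    out = {"friedman_p": float(stats.friedmanchisquare(*[pivot[c] for c in conds]).pvalue)}
    pairs = list(itertools.combinations(conds, 2))
    for a, b in pairs:
        diff = pivot[a] - pivot[b]
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(pivot[a], pivot[b]).pvalue)
        out[f"wilcoxon_{a}_vs_{b}_p_bonferroni"] = min(1.0, p * len(pairs))
    return out
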