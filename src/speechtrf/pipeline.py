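"""Config-driven orchestration of the full analysis graph.

Order of stages mirrors the method: preprocess EEG -> tune lambda on the
combined attended+ignored word+phoneme model -> channel selection from the
grand-average accuracy topography -> three onset models (each with and
without the envelope regressor) per attention condition -> duration-
preserving permutation null -> group statistics (rank-sum vs chance,
attend-ignore cluster test on difference TRFs, signed-rank model
comparisons with Benjamini-Yekutieli correction).

Synthetic mode regenerates subjects deterministically from the seed at
every stage, so stages are resumable without binary intermediates; real
mode loads the documented containers. All randomness flows from named
sub-seeds of the master seed, and every stage's outputs are plain TSV/JSON
files registered (with hashes) in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as stio
from .features import extract_envelope, read_annotations
from .permutation import build_chance_distribution
from .stats import (
    ChannelSelection,
    cluster_permutation_test,
    compare_models,
    select_channels,
    test_vs_chance,
)
from .synthetic import (
    ATTEND,
    CONDITIONS,
    IGNORE,
    SimulationConfig,
    SubjectData,
    simulate_dataset,
)
from .trf import (
    DEFAULT_LAMBDA_GRID,
    CrossValResult,
    LagSpec,
    crossval_submodels,
    preprocess_eeg,
    tune_lambda,
)

logger = logging.getLogger(__name__)

BASE_MODELS: dict[str, list[str]] = {
    "word": ["word_onset"],
    "phoneme": ["phoneme_onset"],
    "word_phoneme": ["word_onset", "phoneme_onset"],
}


def model_id(base: str, with_envelope: bool) -> str:
    return f"{base}+env" if with_envelope else base


def expand_models(
    bases: Sequence[str], envelope_settings: Sequence[bool]
) -> dict[str, list[str]]:
    """Model-id -> feature-name map over base models x envelope settings."""
    out: dict[str, list[str]] = {}
    for base in bases:
        for env in envelope_settings:
            feats = list(BASE_MODELS[base]) + (["envelope"] if env else [])
            out[model_id(base, env)] = feats
    return out


@dataclass
class RunConfig:
    """Everything a run needs; defaults follow the reference analysis
    (0-500 ms lags, lambda grid 1e-6..1e6, 100 regressor permutations,
    cluster-forming and corrected alpha 0.001) at desk scale."""

    mode: str = "synthetic"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    real_subjects: list[dict] = field(default_factory=list)
    lag_min_ms: float = 0.0
    lag_max_ms: float = 500.0
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    fixed_lambda: float | None = None  # skip tuning when set
    models: tuple[str, ...] = ("word", "phoneme", "word_phoneme")
    envelope_settings: tuple[bool, ...] = (False, True)
    n_perm: int = 100
    n_perm_cluster: int = 2000
    cluster_forming_alpha: float = 0.001
    corrected_alpha: float = 0.001
    k_channels: int = 12
    symmetric_channels: bool = True
    cluster_model: str = "word_phoneme"
    cluster_with_envelope: bool = True
    seed: int = 0
    out_dir: str = "speechtrf_out"

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("model list must be nonempty")
        unknown = set(self.models) - set(BASE_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)

    @property
    def lag_spec(self) -> LagSpec:
        fs = self.sim.fs if self.mode == "synthetic" else self._real_fs()
        return LagSpec(fs=fs, lag_min_ms=self.lag_min_ms, lag_max_ms=self.lag_max_ms)

    def _real_fs(self) -> float:
        if not self.real_subjects:
            raise ValueError("real mode needs real_subjects entries")
        return float(self.real_subjects[0].get("fs", 500.0))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def register(self, stage: str, paths: Sequence[Path], seconds: float) -> None:
        self.stages[stage] = {
            "wall_clock_s": round(seconds, 3),
            "outputs": [str(p) for p in paths],
        }
        for p in paths:
            self.outputs[str(p)] = _sha256(p)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "stages": self.stages, "outputs": self.outputs}, indent=1, default=str,
        ))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# subject loading
# ---------------------------------------------------------------------------

def load_subjects(config: RunConfig) -> list[SubjectData]:
    if config.mode == "synthetic":
        return simulate_dataset(config.sim)
    return [_load_real_subject(entry, i, config) for i, entry in enumerate(config.real_subjects)]


def _load_real_subject(entry: dict, idx: int, config: RunConfig) -> SubjectData:
    """Load one recorded subject from containers declared in the config.

    Expected entry keys: ``eeg`` (container prefix or .edf path), optional
    ``n_trials`` to split a continuous EDF, and per condition a list of
    annotation TSV paths plus optional ``wav``/``envelope`` sources.
    """
    from .features import feature_set_from_tiers

    eeg_path = Path(entry["eeg"])
    if eeg_path.suffix == ".edf":
        eeg = stio.read_edf(eeg_path)
        if entry.get("n_trials", 1) > 1:
            eeg = stio.split_trials(eeg, int(entry["n_trials"]))
    else:
        eeg = stio.read_eeg_container(eeg_path)
    feats: dict[str, list] = {}
    tiers: dict[str, list] = {}
    for cond in CONDITIONS:
        feats[cond] = []
        tiers[cond] = []
        for ti, ann_path in enumerate(entry["annotations"][cond]):
            tier_list = read_annotations(ann_path, dialect=entry.get("dialect", "tsv"))
            by_name = {t.tier_name: t for t in tier_list}
            word, phon = by_name["word"], by_name["phoneme"]
            n = eeg.trials[ti].shape[1]
            env = None
            wavs = entry.get("wav", {}).get(cond)
            if wavs:
                from scipy.io import wavfile

                audio_fs, audio = wavfile.read(wavs[ti])
                env = extract_envelope(audio.astype(float), audio_fs, eeg.fs)[:n]
            feats[cond].append(
                feature_set_from_tiers(word, phon, eeg.fs, n, envelope=env, trial_id=ti)
            )
            tiers[cond].append((word, phon))
    return SubjectData(
        subject_id=idx, eeg=eeg, features=feats, tiers=tiers,
        attended_stream=int(entry.get("attended_stream", 1)), kernels=None,
    )


# ---------------------------------------------------------------------------
# fitting stages
# ---------------------------------------------------------------------------

def combined_attention_features(subj: SubjectData) -> list[dict[str, np.ndarray]]:
    """Per-trial word+phoneme regressors of both conditions in one design,
    used for lambda tuning and channel selection so neither is biased by
    the attention contrast."""
    out = []
    for att, ign in zip(subj.features[ATTEND], subj.features[IGNORE]):
        out.append({
            "attend_word_onset": att.features["word_onset"],
            "attend_phoneme_onset": att.features["phoneme_onset"],
            "ignore_word_onset": ign.features["word_onset"],
            "ignore_phoneme_onset": ign.features["phoneme_onset"],
        })
    return out


def tune_subject_lambda(subj: SubjectData, config: RunConfig) -> float:
    if config.fixed_lambda is not None:
        return float(config.fixed_lambda)
    lam, _ = tune_lambda(
        combined_attention_features(subj), subj.eeg, config.lambda_grid,
        config.lag_spec,
    )
    return lam


def channel_selection_stage(
    subjects: Sequence[SubjectData], lambdas: Sequence[float], config: RunConfig
) -> ChannelSelection:
    """Grand-average accuracy per channel from the combined model, top-k."""
    per_subject = []
    for subj, lam in zip(subjects, lambdas):
        feats = combined_attention_features(subj)
        names = list(feats[0])
        res = crossval_submodels(
            feats, subj.eeg, lam, config.lag_spec, {"combined": names}
        )["combined"]
        per_subject.append(np.nanmean(res.accuracy.r, axis=0))
    grand = np.mean(per_subject, axis=0)
    layout = subjects[0].eeg.layout
    k = min(config.k_channels, len(grand))
    symmetric = config.symmetric_channels and layout is not None and k % 2 == 0
    return select_channels(
        grand, k, symmetry_required=symmetric, layout=layout,
        labels=subjects[0].eeg.channel_labels,
    )


def fit_subject_models(
    subj: SubjectData, lam: float, config: RunConfig
) -> dict[str, dict[str, CrossValResult]]:
    """All (model x envelope) fits for each condition, via shared covariance."""
    models = expand_models(config.models, config.envelope_settings)
    union = ["word_onset", "phoneme_onset"] + (
        ["envelope"] if any(config.envelope_settings) else []
    )
    out: dict[str, dict[str, CrossValResult]] = {}
    for cond in CONDITIONS:
        feats = [f.subset(union) for f in subj.features[cond]]
        out[cond] = crossval_submodels(
            feats, subj.eeg, lam, config.lag_spec, models, condition=cond
        )
    return out


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunManifest:
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_dict(config), version=__version__)

    t0 = time.time()
    logger.info("stage=load loading/generating subjects")
    subjects = load_subjects(config)
    for subj in subjects:
        subj.eeg = preprocess_eeg(subj.eeg)
    lag_spec = config.lag_spec

    logger.info("stage=lambda tuning per-subject ridge parameter")
    lambdas = [tune_subject_lambda(s, config) for s in subjects]

    logger.info("stage=channels grand-average accuracy channel selection")
    selection = channel_selection_stage(subjects, lambdas, config)
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    (fits_dir / "lambda.json").write_text(json.dumps(
        {f"s{subj.subject_id:02d}": lam for subj, lam in zip(subjects, lambdas)},
        indent=1,
    ))
    (fits_dir / "channels.json").write_text(json.dumps({
        "selected": selection.selected,
        "labels": selection.labels,
        "ranking_statistic": selection.ranking_statistic.tolist(),
        "k": selection.k,
        "symmetry": selection.symmetry_required,
    }, indent=1))

    logger.info("stage=fit %d models x %d conditions x %d subjects",
                len(config.models) * len(config.envelope_settings), 2, len(subjects))
    all_fits = [fit_subject_models(s, lam, config) for s, lam in zip(subjects, lambdas)]
    models = expand_models(config.models, config.envelope_settings)
    chans = selection.selected

    acc_rows = []
    for subj, fits in zip(subjects, all_fits):
        for cond in CONDITIONS:
            for mid, res in fits[cond].items():
                acc_rows.append((
                    subj.subject_id, mid, cond,
                    res.accuracy.grand_mean(chans),
                    res.accuracy.grand_mean(None),
                    res.mse,
                ))
    acc_df = pd.DataFrame(acc_rows, columns=[
        "subject", "model", "condition", "r_selected", "r_all", "mse",
    ])
    acc_df.to_csv(fits_dir / "accuracy_summary.tsv", sep="\t", index=False)

    trf_rows = []
    for mid, feat_names in models.items():
        for cond in CONDITIONS:
            stack = np.stack([
                fits[cond][mid].model.weights[:, :, chans].mean(axis=2)
                for fits in all_fits
            ])
            grand = stack.mean(axis=0)
            for fi, fname in enumerate(feat_names):
                for li, t_ms in enumerate(lag_spec.lag_times_ms):
                    trf_rows.append((mid, cond, fname, t_ms, grand[fi, li]))
    pd.DataFrame(trf_rows, columns=["model", "condition", "feature", "lag_ms", "weight"]) \
        .to_csv(fits_dir / "trf_grand.tsv", sep="\t", index=False)
    manifest.register("fit", sorted(fits_dir.glob("*")), time.time() - t0)

    t0 = time.time()
    logger.info("stage=permute %d duration-preserving permutations", config.n_perm)
    chance = build_chance_distribution(
        subjects, models, lambdas, lag_spec, channels=chans,
        n_perm=config.n_perm, seed=config.seed + 1,
    )
    chance_dir = out / "chance"
    chance_dir.mkdir(exist_ok=True)
    ch_rows = [
        (p, m, c, chance.accuracies[(m, c)][p])
        for (m, c) in chance.accuracies for p in range(chance.n_perm)
    ]
    pd.DataFrame(ch_rows, columns=["perm", "model", "condition", "accuracy"]) \
        .to_csv(chance_dir / "chance_accuracy.tsv", sep="\t", index=False)
    ctrf_rows = []
    for (m, c), arr in chance.trfs.items():
        for p in range(chance.n_perm):
            for fi, fname in enumerate(chance.feature_names[m]):
                for li, t_ms in enumerate(lag_spec.lag_times_ms):
                    ctrf_rows.append((p, m, c, fname, t_ms, arr[p, fi, li]))
    pd.DataFrame(ctrf_rows, columns=["perm", "model", "condition", "feature", "lag_ms", "weight"]) \
        .to_csv(chance_dir / "chance_trf.tsv", sep="\t", index=False)
    meta = {"envelope_permuted": False, "n_perm": config.n_perm, "seed": config.seed + 1}
    (chance_dir / "chance_meta.json").write_text(json.dumps(meta, indent=1))
    manifest.register("permute", sorted(chance_dir.glob("*")), time.time() - t0)

    t0 = time.time()
    logger.info("stage=stats group statistics")
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    _stats_stage(config, subjects, all_fits, chance, chans, lag_spec, stats_dir)
    manifest.register("stats", sorted(stats_dir.glob("*")), time.time() - t0)

    manifest.write(out / "manifest.json")
    manifest.outputs[str(out / "manifest.json")] = "self"
    return manifest


def _stats_stage(config, subjects, all_fits, chance, chans, lag_spec, stats_dir):
    models = expand_models(config.models, config.envelope_settings)

    # observed accuracies vs chance (rank-sum, per-subject observed values)
    vs_rows = []
    for mid in models:
        for cond in CONDITIONS:
            observed = np.array([
                fits[cond][mid].accuracy.grand_mean(chans) for fits in all_fits
            ])
            z, p = test_vs_chance(observed, chance.accuracies[(mid, cond)])
            vs_rows.append((mid, cond, float(observed.mean()),
                            float(chance.accuracies[(mid, cond)].mean()), z, p))
    pd.DataFrame(vs_rows, columns=[
        "model", "condition", "observed_mean", "chance_mean", "z", "p",
    ]).to_csv(stats_dir / "vs_chance.tsv", sep="\t", index=False)

    # attend-ignore cluster test on difference TRFs, per onset feature
    cmid = model_id(
        config.cluster_model,
        config.cluster_with_envelope and True in config.envelope_settings,
    )
    cl_rows = []
    if cmid in models:
        feat_names = models[cmid]
        for fi, fname in enumerate(feat_names):
            if not fname.endswith("_onset"):
                continue
            subj_diff = np.stack([
                fits[ATTEND][cmid].model.weights[fi, :, chans].mean(axis=0)
                - fits[IGNORE][cmid].model.weights[fi, :, chans].mean(axis=0)
                for fits in all_fits
            ])
            chance_diff = (
                chance.trfs[(cmid, ATTEND)][:, fi, :]
                - chance.trfs[(cmid, IGNORE)][:, fi, :]
            )
            result = cluster_permutation_test(
                subj_diff, chance_diff,
                cluster_forming_alpha=config.cluster_forming_alpha,
                corrected_alpha=config.corrected_alpha,
                n_perm=config.n_perm_cluster,
                seed=config.seed + 2,
                lag_times_ms=lag_spec.lag_times_ms,
            )
            for cl in result.clusters:
                cl_rows.append((
                    fname, cl.lag_start_ms, cl.lag_end_ms, cl.t_sum,
                    cl.p_value, cl.sign, cl.significant,
                ))
    pd.DataFrame(cl_rows, columns=[
        "feature", "lag_start_ms", "lag_end_ms", "t_sum", "p", "sign", "significant",
    ]).to_csv(stats_dir / "clusters.tsv", sep="\t", index=False)

    # signed-rank comparisons with BY correction, one family per envelope setting
    comp_rows = []
    for env in config.envelope_settings:
        ids = {b: model_id(b, env) for b in config.models}
        per_subj = {
            (b, cond): np.array([
                fits[cond][ids[b]].accuracy.grand_mean(chans) for fits in all_fits
            ])
            for b in config.models for cond in CONDITIONS
        }
        att_vs_ign = {
            f"{b}:attend_vs_ignore": (per_subj[(b, ATTEND)], per_subj[(b, IGNORE)])
            for b in config.models
        }
        ordering = {}
        if {"word", "phoneme"} <= set(config.models):
            for cond in CONDITIONS:
                ordering[f"word_vs_phoneme:{cond}"] = (
                    per_subj[("word", cond)], per_subj[("phoneme", cond)],
                )
        if {"phoneme", "word_phoneme"} <= set(config.models):
            for cond in CONDITIONS:
                ordering[f"phoneme_vs_word_phoneme:{cond}"] = (
                    per_subj[("phoneme", cond)], per_subj[("word_phoneme", cond)],
                )
        for family_name, family in (
            ("attend_vs_ignore", att_vs_ign), ("model_ordering", ordering),
        ):
            if not family:
                continue
            if len(all_fits) < 5:
                logger.warning(
                    "stage=stats skipping %s comparisons: %d subjects < 5",
                    family_name, len(all_fits),
                )
                continue
            result = compare_models(family)
            for comp in result.comparisons:
                comp_rows.append((
                    "env" if env else "noenv", family_name, comp.name,
                    comp.z, comp.p_raw, comp.p_adjusted, comp.n, comp.missing,
                ))
    pd.DataFrame(comp_rows, columns=[
        "envelope", "family", "comparison", "z", "p_raw", "p_adjusted", "n", "missing",
    ]).to_csv(stats_dir / "comparisons.tsv", sep="\t", index=False)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["sim"] = asdict(config.sim)
    d["sim"]["phonemes_per_word"] = {
        str(k): v for k, v in config.sim.phonemes_per_word.items()
    }
    return d


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report_summary(out_dir) -> tuple[str, bool]:
    """Human-readable summary tables; returns (text, complete_flag)."""
    out = Path(out_dir)
    lines = []
    complete = True

    acc_path = out / "fits" / "accuracy_summary.tsv"
    chance_path = out / "chance" / "chance_accuracy.tsv"
    if acc_path.exists():
        acc = pd.read_csv(acc_path, sep="\t")
        table = acc.groupby(["model", "condition"])["r_selected"].mean().unstack()
        if chance_path.exists():
            ch = pd.read_csv(chance_path, sep="\t")
            q95 = ch.groupby(["model", "condition"])["accuracy"].quantile(0.95).unstack()
            q95.columns = [f"chance95_{c}" for c in q95.columns]
            table = table.join(q95)
        else:
            complete = False
            lines.append("[gap] chance distribution missing")
        lines.append("Prediction accuracy (mean over subjects, selected channels):")
        lines.append(table.round(4).to_string())
    else:
        complete = False
        lines.append("[gap] model fits missing")

    cl_path = out / "stats" / "clusters.tsv"
    if cl_path.exists():
        cl = pd.read_csv(cl_path, sep="\t")
        lines.append("")
        if len(cl):
            sig = cl[cl["significant"]]
            lines.append("Significant attend-vs-ignore cluster windows (ms):")
            if len(sig):
                for _, row in sig.iterrows():
                    lines.append(
                        f"  {row['feature']}: {row['lag_start_ms']:.0f}-"
                        f"{row['lag_end_ms']:.0f} ms (t_sum={row['t_sum']:.1f}, "
                        f"p={row['p']:.4g})"
                    )
            else:
                lines.append("  none")
        else:
            lines.append("No clusters formed.")
    else:
        complete = False
        lines.append("[gap] cluster test results missing")

    comp_path = out / "stats" / "comparisons.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t")
        lines.append("")
        lines.append("Model comparisons (Wilcoxon signed-rank, BY-adjusted):")
        lines.append(comp.round(4).to_string(index=False))
    else:
        complete = False
        lines.append("[gap] model comparisons missing")

    return "\n".join(lines), complete
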