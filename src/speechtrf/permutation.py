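"""Duration-preserving permutation null for onset regressors.

The shuffle rebuilds the word-onset grid from a uniform random permutation
of the original inter-onset intervals and assigns word units -- each
carrying its duration and its internal phoneme-onset offsets -- to the new
slots by an independent uniform permutation. This preserves, exactly and
per permutation: the word count, phoneme count, multiset of word
durations, multiset of word inter-onset intervals, and the multiset of
within-word phoneme onset offsets -- the word and phoneme rate statistics
are identical to the original regressors' while the onset times themselves
are rearranged.

A permuted long word placed before a short interval may extend past the
next slot onset (or the trial end); that is permitted because only onset
impulses enter the model.

:func:`build_chance_distribution` refits every subject on permuted onset
regressors (envelope intact, lambda and channel selection frozen) and
averages across subjects, yielding the chance-level TRFs and accuracies
for all group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .features import AnnotationTier, Event, StimulusFeatureSet
from .synthetic import CONDITIONS, SubjectData
from .trf import LagSpec, crossval_submodels

DEFAULT_N_PERM = 100


@dataclass
class PermutationSet:
    """Per-permutation shuffled tier pairs for one (word, phoneme) stream."""

    permutations: list[tuple[AnnotationTier, AnnotationTier]]
    orderings: list[tuple[int, ...]]
    seed: int
    source_id: str = ""

    @property
    def n_perm(self) -> int:
        return len(self.permutations)


@dataclass
class ChanceDistribution:
    """Null distributions of grand-average TRFs and accuracies.

    ``accuracies[(model, condition)]`` is an (n_perm,) array of
    subject-averaged accuracies; ``trfs[(model, condition)]`` is
    (n_perm, n_features, n_lags), channel-averaged over the selected
    channels and grand-averaged over subjects.
    """

    accuracies: dict[tuple[str, str], np.ndarray]
    trfs: dict[tuple[str, str], np.ndarray]
    feature_names: dict[str, list[str]]
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        for key, acc in self.accuracies.items():
            if len(acc) != self.n_perm or not np.all(np.isfinite(acc)):
                raise ValueError(f"bad chance accuracy entries for {key}")


# ---------------------------------------------------------------------------
# the shuffle
# ---------------------------------------------------------------------------

def _word_units(word_tier: AnnotationTier, phoneme_tier: AnnotationTier):
    """Decompose into (duration, label, [(rel_on, rel_off, label), ...]) units."""
    units = []
    phon_iter = iter(phoneme_tier.events)
    buckets: list[list[Event]] = [[] for _ in word_tier.events]
    onsets = word_tier.onsets
    for p in phoneme_tier.events:
        wi = int(np.searchsorted(onsets, p.onset, side="right") - 1)
        buckets[wi].append(p)
    for w, bucket in zip(word_tier.events, buckets):
        rel = [(p.onset - w.onset, p.offset - w.onset, p.label) for p in bucket]
        units.append((w.duration, w.label, rel))
    return units


def apply_word_permutation(
    word_tier: AnnotationTier,
    phoneme_tier: AnnotationTier,
    order: Sequence[int],
    ioi_order: Sequence[int] | None = None,
) -> tuple[AnnotationTier, AnnotationTier]:
    """Place word unit ``order[k]`` at the k-th slot of the permuted grid.

    The slot grid starts at the original first word onset and advances by
    the original inter-onset intervals taken in ``ioi_order`` (identity
    when omitted, which keeps the original grid). The identity permutation
    of both sequences reproduces the input exactly.
    """
    onsets = word_tier.onsets
    n = len(onsets)
    if ioi_order is None or _is_identity(ioi_order):
        slots = onsets
    else:
        iois = np.diff(onsets)
        slots = np.concatenate([[onsets[0]], onsets[0] + np.cumsum(iois[list(ioi_order)])])
    if _is_identity(order) and slots is onsets:
        return word_tier, phoneme_tier
    units = _word_units(word_tier, phoneme_tier)
    words: list[Event] = []
    phons: list[Event] = []
    for slot, ui in zip(slots, order):
        dur, label, rel = units[ui]
        words.append(Event(slot, slot + dur, label))
        for r_on, r_off, p_label in rel:
            phons.append(Event(slot + r_on, slot + r_off, p_label))
    phons.sort(key=lambda e: e.onset)
    sid = word_tier.source_id
    # permuted words may overlap following slots by construction: skip validation
    return (
        AnnotationTier("word", words, source_id=sid, validate=False),
        AnnotationTier("phoneme", phons, source_id=sid, validate=False),
    )


def _is_identity(order: Sequence[int]) -> bool:
    return all(int(o) == i for i, o in enumerate(order))


def _draw_orders(n: int, rng: np.random.Generator):
    return rng.permutation(n), rng.permutation(n - 1)


def shuffle_onsets(
    word_tier: AnnotationTier,
    phoneme_tier: AnnotationTier,
    seed: int | np.random.Generator,
) -> tuple[AnnotationTier, AnnotationTier]:
    """One uniform-random rearrangement of word units and onset intervals."""
    if len(word_tier) < 2:
        raise ValueError("need at least 2 words to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order, ioi_order = _draw_orders(len(word_tier), rng)
    return apply_word_permutation(word_tier, phoneme_tier, order, ioi_order)


def generate_permutation_set(
    word_tier: AnnotationTier,
    phoneme_tier: AnnotationTier,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PermutationSet:
    """``n_perm`` unique orderings (rejection-sampled by hashing the order)."""
    n = len(word_tier)
    if n < 2:
        raise ValueError("need at least 2 words to permute")
    if n <= 20 and n_perm > math.factorial(n):
        raise ValueError(
            f"{n_perm} unique permutations requested but only {math.factorial(n)} exist"
        )
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    perms, orders = [], []
    attempts = 0
    while len(perms) < n_perm:
        attempts += 1
        if attempts > 100 * n_perm + 1000:
            raise RuntimeError("could not find enough unique permutations")
        raw_order, ioi_order = _draw_orders(n, rng)
        order = tuple(int(i) for i in raw_order)
        if order in seen:
            continue
        seen.add(order)
        perms.append(apply_word_permutation(word_tier, phoneme_tier, order, ioi_order))
        orders.append(order)
    return PermutationSet(
        permutations=perms, orderings=orders, seed=seed,
        source_id=word_tier.source_id,
    )


def permuted_feature_set(
    original: StimulusFeatureSet,
    word_tier: AnnotationTier,
    phoneme_tier: AnnotationTier,
    rng: np.random.Generator,
) -> tuple[StimulusFeatureSet, tuple[int, ...]]:
    """Feature set with shuffled onset trains; the envelope is left intact."""
    from .features import build_onset_regressor  # local to avoid cycle noise

    raw_order, ioi_order = _draw_orders(len(word_tier), rng)
    order = tuple(int(i) for i in raw_order)
    w_perm, p_perm = apply_word_permutation(word_tier, phoneme_tier, order, ioi_order)
    feats = dict(original.features)
    feats["word_onset"] = build_onset_regressor(
        w_perm, original.fs, original.n_samples, clip=True
    )
    feats["phoneme_onset"] = build_onset_regressor(
        p_perm, original.fs, original.n_samples, clip=True
    )
    return (
        StimulusFeatureSet(
            fs=original.fs, n_samples=original.n_samples, features=feats,
            stream_id=original.stream_id, trial_id=original.trial_id,
        ),
        order,
    )


# ---------------------------------------------------------------------------
# chance distributions
# ---------------------------------------------------------------------------

def build_chance_distribution(
    subjects: Sequence[SubjectData],
    models: Mapping[str, Sequence[str]],
    lam_per_subject: Sequence[float],
    lag_spec: LagSpec,
    channels: Sequence[int] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    conditions: Sequence[str] = CONDITIONS,
    per_feature_standardize: bool = True,
) -> ChanceDistribution:
    """Refit every subject on permuted onset regressors, n_perm times.

    For each permutation, each subject's per-trial word/phoneme trains are
    rearranged with the duration-preserving shuffle (envelope untouched),
    the frozen per-subject lambda is reused, and the resulting accuracies
    and channel-averaged TRFs are grand-averaged across subjects.
    Uniqueness across permutations is enforced by hashing the orderings of
    the first subject's trials and rejection-resampling collisions.
    """
    if not subjects:
        raise ValueError("no subjects given")
    n_words_first = len(subjects[0].tiers[conditions[0]][0][0])
    if n_words_first >= 2 and n_words_first <= 20 and n_perm > math.factorial(n_words_first):
        raise ValueError("n_perm exceeds the number of distinct orderings")

    acc: dict[tuple[str, str], list[float]] = {
        (m, c): [] for m in models for c in conditions
    }
    trf: dict[tuple[str, str], list[np.ndarray]] = {
        (m, c): [] for m in models for c in conditions
    }
    seen: set[tuple] = set()
    salt = 0
    p = 0
    while p < n_perm:
        rng = np.random.default_rng(np.random.SeedSequence([seed, p, salt]))
        sub_acc: dict[tuple[str, str], list[float]] = {k: [] for k in acc}
        sub_trf: dict[tuple[str, str], list[np.ndarray]] = {k: [] for k in trf}
        signature: list[tuple] = []
        for si, subj in enumerate(subjects):
            for cond in conditions:
                perm_feats = []
                for ti, (fset, (w, ph)) in enumerate(
                    zip(subj.features[cond], subj.tiers[cond])
                ):
                    pf, order = permuted_feature_set(fset, w, ph, rng)
                    perm_feats.append(pf)
                    if si == 0:
                        signature.append(order)
                results = crossval_submodels(
                    perm_feats, subj.eeg, lam_per_subject[si], lag_spec, models,
                    per_feature_standardize=per_feature_standardize,
                    condition=cond,
                )
                for m, res in results.items():
                    sub_acc[(m, cond)].append(res.accuracy.grand_mean(channels))
                    w_sel = (
                        res.model.weights if channels is None
                        else res.model.weights[:, :, list(channels)]
                    )
                    sub_trf[(m, cond)].append(w_sel.mean(axis=2))
        sig = tuple(signature)
        if sig in seen:
            salt += 1
            continue
        seen.add(sig)
        for k in acc:
            acc[k].append(float(np.mean(sub_acc[k])))
            trf[k].append(np.mean(sub_trf[k], axis=0))
        p += 1

    return ChanceDistribution(
        accuracies={k: np.asarray(v) for k, v in acc.items()},
        trfs={k: np.asarray(v) for k, v in trf.items()},
        feature_names={m: list(f) for m, f in models.items()},
        n_perm=n_perm,
        seed=seed,
    )
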