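"""Verification protocol: splitting, pair generation, threshold calibration,
decision making and biometric metrics.

The protocol follows the standard one-to-one verification design: the
manifest is split 50/50 *by individual* (no animal contributes images to
both halves), labelled genuine/imposter image pairs are generated at a
target genuine fraction ``r``, the accept threshold is calibrated on the
training pairs as the lowest score that produces zero false matches, and
the held-out pairs are scored against that threshold.  Rates follow the
ISO/IEC 19795 orientation: FMR is the fraction of imposter pairs accepted,
FNMR the fraction of genuine pairs rejected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, EvaluationError, MuzzleIdError, PairGenerationError


@dataclass(frozen=True)
class ImagePair:
    path_a: str
    path_b: str
    individual_a: str
    individual_b: str
    label: str  # "genuine" | "imposter"

    def __post_init__(self):
        if self.path_a == self.path_b:
            raise PairGenerationError("self-pairs are not allowed")
        expected = "genuine" if self.individual_a == self.individual_b else "imposter"
        if self.label != expected:
            raise PairGenerationError(
                f"label {self.label!r} inconsistent with identities "
                f"{self.individual_a!r}/{self.individual_b!r}"
            )


@dataclass
class PairSet:
    pairs: list[ImagePair]
    r: float
    generation_seed: int

    @property
    def n_genuine(self) -> int:
        return sum(p.label == "genuine" for p in self.pairs)

    @property
    def n_imposter(self) -> int:
        return sum(p.label == "imposter" for p in self.pairs)


@dataclass(frozen=True)
class DecisionThreshold:
    """Accept iff score >= t_star; delta is the score resolution used."""

    t_star: float
    delta: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int  # genuine accepted
    fp: int  # imposter accepted
    tn: int  # imposter rejected
    fn: int  # genuine rejected

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Biometric rates for one evaluation category, as percentages.

    Rates with an empty denominator (no genuine or no imposter pairs) are
    ``None`` — undefined, never silently zero.
    """

    accuracy: float
    tmr: float | None
    tnmr: float | None
    fmr: float | None
    fnmr: float | None
    fta: float | None = None
    category_label: str = ""
    counts: ConfusionCounts | None = None


# ---------------------------------------------------------------------------
# Splitting and pair generation
# ---------------------------------------------------------------------------

def split_database(
    manifest: pd.DataFrame,
    fraction: float = 0.5,
    split_seed: int = 0,
    by: str = "individual",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/test split with no individual crossover.

    ``by='individual'`` (default) assigns whole animals to one side, so no
    identity contributes images to both halves; ``by='image'`` is available
    for sensitivity analysis only.
    """
    if by == "image":
        idx = np.arange(len(manifest))
        np.random.default_rng(split_seed).shuffle(idx)
        k = int(round(fraction * len(idx)))
        return (
            manifest.iloc[np.sort(idx[:k])].reset_index(drop=True),
            manifest.iloc[np.sort(idx[k:])].reset_index(drop=True),
        )
    if by != "individual":
        raise MuzzleIdError(f"unknown split unit {by!r}")
    individuals = sorted(manifest["individual_id"].unique())
    if len(individuals) < 2:
        raise MuzzleIdError("database split needs at least 2 individuals")
    order = np.array(individuals, dtype=object)
    np.random.default_rng(split_seed).shuffle(order)
    k = int(round(fraction * len(order)))
    train_ids = set(order[:k])
    train = manifest[manifest["individual_id"].isin(train_ids)].reset_index(drop=True)
    test = manifest[~manifest["individual_id"].isin(train_ids)].reset_index(drop=True)
    return train, test


def genuine_pool(manifest: pd.DataFrame) -> list[tuple[int, int]]:
    """All within-individual image pairs (row-index pairs, a < b)."""
    pool = []
    for _, grp in manifest.groupby("individual_id", sort=True):
        for i, j in itertools.combinations(sorted(grp.index), 2):
            pool.append((i, j))
    return pool


def imposter_pool_size(manifest: pd.DataFrame) -> int:
    n = len(manifest)
    same = sum(
        len(g) * (len(g) - 1) // 2 for _, g in manifest.groupby("individual_id")
    )
    return n * (n - 1) // 2 - same


def generate_pairs(
    manifest: pd.DataFrame,
    r: float,
    max_pairs: int | None = None,
    pair_seed: int = 0,
) -> PairSet:
    """Build a labelled pair set with genuine fraction ``r``.

    All within-individual pairs form the genuine pool (subsampled only if
    ``max_pairs`` requires it); imposter pairs are sampled uniformly without
    replacement across distinct individuals.  The realized genuine fraction
    satisfies ``|n_genuine/total - r| <= 1/total``.
    """
    if not (0.0 < r < 1.0):
        raise PairGenerationError(f"genuine-pair fraction must be in (0,1), got {r}")
    manifest = manifest.reset_index(drop=True)
    gpool = genuine_pool(manifest)
    if not gpool:
        raise PairGenerationError(
            "no genuine pairs constructible: no individual has two or more images"
        )
    rng = np.random.default_rng(pair_seed)
    if max_pairs is not None:
        n_g = min(len(gpool), max(1, round(r * max_pairs)))
    else:
        n_g = len(gpool)
    total = max(n_g + 1, round(n_g / r))
    n_i = total - n_g

    if n_g < len(gpool):
        sel = rng.choice(len(gpool), size=n_g, replace=False)
        gpool = [gpool[k] for k in sorted(sel)]

    # sample imposter pairs without replacement across distinct individuals
    ids = manifest["individual_id"].to_numpy()
    n_rows = len(manifest)
    avail = imposter_pool_size(manifest)
    if n_i > avail:
        raise PairGenerationError(
            f"requested {n_i} imposter pairs but only {avail} are constructible"
        )
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_i:
        i, j = rng.integers(0, n_rows, size=2)
        if i == j or ids[i] == ids[j]:
            continue
        key = (int(min(i, j)), int(max(i, j)))
        chosen.add(key)

    def mk(i: int, j: int) -> ImagePair:
        return ImagePair(
            path_a=str(manifest.at[i, "image_path"]),
            path_b=str(manifest.at[j, "image_path"]),
            individual_a=str(ids[i]),
            individual_b=str(ids[j]),
            label="genuine" if ids[i] == ids[j] else "imposter",
        )

    pairs = [mk(i, j) for i, j in gpool] + [mk(i, j) for i, j in sorted(chosen)]
    ps = PairSet(pairs=pairs, r=r, generation_seed=pair_seed)
    assert abs(ps.n_genuine / len(pairs) - r) <= 1.0 / len(pairs) + 1e-12
    return ps


# ---------------------------------------------------------------------------
# Threshold calibration and decisions
# ---------------------------------------------------------------------------

def score_resolution(scores: Sequence[float]) -> float:
    """Smallest positive gap between distinct observed scores.

    Integer-valued score sets (e.g. raw key-point counts) resolve to 1; a
    set with fewer than two distinct values falls back to 1e-6.
    """
    arr = np.asarray(sorted(set(float(s) for s in scores)))
    if len(arr) and np.all(arr == np.round(arr)):
        return 1.0
    gaps = np.diff(arr)
    gaps = gaps[gaps > 0]
    return float(gaps.min()) if len(gaps) else 1e-6


def calibrate_threshold(
    scores: Sequence[float],
    labels: Sequence[str],
    delta: float | None = None,
) -> DecisionThreshold:
    """Lowest accept threshold with zero false matches on the calibration set.

    With the rule "accept iff score >= t_star" and
    ``t_star = max(imposter scores) + delta``, imposter acceptance on the
    calibration set is exactly zero by construction, and ``t_star`` is the
    smallest such threshold at the observed score resolution.
    """
    scores = [float(s) for s in scores]
    imposter = [s for s, l in zip(scores, labels) if l == "imposter"]
    if not imposter:
        raise CalibrationError("cannot calibrate without imposter scores")
    if delta is None:
        delta = score_resolution(scores)
    if delta <= 0:
        raise CalibrationError(f"score resolution must be positive, got {delta}")
    return DecisionThreshold(t_star=max(imposter) + delta, delta=delta)


def evaluate_scores(
    scores: Sequence[float], labels: Sequence[str], threshold: DecisionThreshold
) -> ConfusionCounts:
    """Tally the confusion table under "accept iff score >= t_star"."""
    tp = fp = tn = fn = 0
    for s, l in zip(scores, labels):
        accept = float(s) >= threshold.t_star
        if l == "genuine":
            tp += accept
            fn += not accept
        elif l == "imposter":
            fp += accept
            tn += not accept
        else:
            raise EvaluationError(f"unknown pair label {l!r}")
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def score_pairs(
    pair_set: PairSet,
    matcher: Callable,
    image_provider: Callable[[str], np.ndarray],
    score_channel: str = "similarity",
    cache: dict | None = None,
) -> pd.DataFrame:
    """Score every pair; returns a (pair_id, label, score) frame.

    ``image_provider`` maps an image path to its canonical matcher input
    (and should cache).  ``score_channel`` selects which MatchResult field
    feeds thresholding: the normalized ``similarity`` (default) or the raw
    inlier key-point count (``keypoints``).
    """
    if score_channel not in ("similarity", "keypoints"):
        raise EvaluationError(f"unknown score channel {score_channel!r}")
    rows = []
    for k, pair in enumerate(pair_set.pairs):
        key = (min(pair.path_a, pair.path_b), max(pair.path_a, pair.path_b), score_channel)
        if cache is not None and key in cache:
            score = cache[key]
        else:
            res = matcher(image_provider(pair.path_a), image_provider(pair.path_b))
            score = res.similarity if score_channel == "similarity" else res.n_keypoints
            if cache is not None:
                cache[key] = score
        rows.append({"pair_id": k, "label": pair.label, "score": float(score)})
    return pd.DataFrame(rows)


def evaluate_pairs(
    pair_set: PairSet,
    matcher: Callable,
    threshold: DecisionThreshold,
    image_provider: Callable[[str], np.ndarray],
    score_channel: str = "similarity",
    cache: dict | None = None,
    quality: dict[str, str] | None = None,
) -> ConfusionCounts:
    """Score a pair set and tally decisions against ground truth.

    If a path-to-quality map is supplied, encountering an ``unusable``
    record raises: such captures must be filtered upstream and counted
    toward the fail-to-acquire rate instead of being matched.
    """
    if quality is not None:
        for pair in pair_set.pairs:
            for p in (pair.path_a, pair.path_b):
                if quality.get(p) == "unusable":
                    raise EvaluationError(
                        f"unusable capture {p} reached evaluation; filter it upstream"
                    )
    frame = score_pairs(pair_set, matcher, image_provider, score_channel, cache)
    return evaluate_scores(frame["score"], frame["label"], threshold)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(counts: ConfusionCounts, category_label: str = "") -> MetricsReport:
    """Accuracy, TMR/FNMR, TNMR/FMR as percentages.

    TMR + FNMR = 100 and TNMR + FMR = 100 hold to machine precision; rates
    over an empty class are reported as ``None`` (undefined).
    """
    if counts.total == 0:
        raise EvaluationError("cannot compute metrics over zero pairs")
    n_gen = counts.tp + counts.fn
    n_imp = counts.fp + counts.tn
    tmr = 100.0 * counts.tp / n_gen if n_gen else None
    fnmr = 100.0 * counts.fn / n_gen if n_gen else None
    tnmr = 100.0 * counts.tn / n_imp if n_imp else None
    fmr = 100.0 * counts.fp / n_imp if n_imp else None
    accuracy = 100.0 * (counts.tp + counts.tn) / counts.total
    return MetricsReport(
        accuracy=accuracy, tmr=tmr, tnmr=tnmr, fmr=fmr, fnmr=fnmr,
        category_label=category_label, counts=counts,
    )


def compute_fta(n_unusable: int, n_attempts: int) -> float:
    """Fail-to-acquire rate: percentage of attempts yielding unusable images."""
    if n_attempts <= 0:
        raise EvaluationError("fail-to-acquire rate needs at least one attempt")
    if not (0 <= n_unusable <= n_attempts):
        raise EvaluationError(
            f"unusable count {n_unusable} outside [0, {n_attempts}]"
        )
    return 100.0 * n_unusable / n_attempts


# ---------------------------------------------------------------------------
# Score cache persistence
# ---------------------------------------------------------------------------

def save_scores(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=["pair_id", "label", "score"])


def load_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
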