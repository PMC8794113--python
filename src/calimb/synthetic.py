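"""Synthetic, imbalance-controlled classifier scores with known ground truth.

The generator stands in for the test/validation predictions of a trained
binary classifier.  It produces

1. binary labels at a controlled positive:negative ratio,
2. latent *perfectly calibrated* posterior probabilities from a
   Gaussian-latent generative model (the Bayes posterior of two unit-variance
   normals separated by an effect size ``d`` is logistic, so the reference
   probabilities are calibrated by construction), and
3. a parametric, strictly monotone miscalibration distortion applied on top,
   including a degenerate "majority collapse" regime in which every
   disease-positive sample scores below 0.5.

Because each distortion family is the inverse of a parametric calibration
map, fitting the matching calibrator to distorted scores recovers the
generating parameters — the core self-consistency property of the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit, logit

from .exceptions import InvalidDistortionError, InvalidSpecError

#: Symmetric probability clip applied before any logit/log transform.
EPS = 1e-6

_FAMILIES = ("identity", "beta_family", "platt_family", "majority_collapse")


def positive_count(n_negative: int, ratio: float) -> int:
    """Number of positives for a given negative count and imbalance ratio.

    Uses round-half-to-even on ``ratio * n_negative``.
    """
    return int(round(ratio * n_negative))


@dataclass(frozen=True)
class DatasetSpec:
    """Sizes, imbalance ratio and seed for one synthetic study design.

    ``n_negative``/``ratio`` describe the calibration-fit partition;
    ``test_negative``/``test_ratio`` describe the held-out test partition.
    ``test_ratio`` may be the string ``"match"`` to mirror the fit ratio
    (default is a fixed balanced test set).
    """

    n_negative: int
    ratio: float
    seed: int = 0
    test_negative: int = 0
    test_ratio: float | str = 1.0

    def __post_init__(self) -> None:
        if self.n_negative < 1:
            raise InvalidSpecError(f"n_negative must be >= 1, got {self.n_negative}")
        if not (0.0 < self.ratio <= 1.0):
            raise InvalidSpecError(f"ratio must be in (0, 1], got {self.ratio}")
        if self.n_positive < 1:
            raise InvalidSpecError(
                f"round(ratio * n_negative) = {self.n_positive} must be >= 1"
            )
        if self.test_negative < 0:
            raise InvalidSpecError("test_negative must be >= 0")
        if isinstance(self.test_ratio, str):
            if self.test_ratio != "match":
                raise InvalidSpecError(
                    f"test_ratio must be a float or 'match', got {self.test_ratio!r}"
                )
        elif not (0.0 < self.test_ratio <= 1.0):
            raise InvalidSpecError(f"test_ratio must be in (0, 1], got {self.test_ratio}")

    @property
    def n_positive(self) -> int:
        return positive_count(self.n_negative, self.ratio)

    def resolved_test_ratio(self) -> float:
        return self.ratio if self.test_ratio == "match" else float(self.test_ratio)


@dataclass(frozen=True)
class DistortionSpec:
    """A parametric miscalibration distortion.

    family
        ``identity`` (no params), ``beta_family`` (``a, b > 0``, ``c``),
        ``platt_family`` (``alpha``, ``beta > 0``) or ``majority_collapse``
        (``delta > 0`` or ``"auto"``).
    separability
        Effect size ``d >= 0`` of the Gaussian-latent model controlling class
        overlap of the *true* probabilities.
    """

    family: str = "identity"
    params: Mapping[str, float | str] = field(default_factory=dict)
    separability: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidDistortionError(
                f"unknown distortion family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.separability < 0:
            raise InvalidDistortionError("separability must be >= 0")
        p = dict(self.params)
        if self.family == "identity":
            if p:
                raise InvalidDistortionError("identity distortion takes no params")
        elif self.family == "beta_family":
            a, b = p.get("a", 1.0), p.get("b", 1.0)
            if not (a > 0 and b > 0):
                raise InvalidDistortionError(f"beta_family needs a, b > 0, got a={a}, b={b}")
        elif self.family == "platt_family":
            if not p.get("beta", 1.0) > 0:
                raise InvalidDistortionError("platt_family needs beta > 0")
        elif self.family == "majority_collapse":
            delta = p.get("delta", "auto")
            if delta != "auto" and not float(delta) > 0:
                raise InvalidDistortionError("majority_collapse needs delta > 0 or 'auto'")


@dataclass
class ScoreSet:
    """Labels plus positive-class scores for one split, with provenance.

    ``true_probs`` holds the latent calibrated posterior and is present only
    for synthetic data.
    """

    ids: np.ndarray
    labels: np.ndarray
    scores: np.ndarray
    true_probs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.labels = np.asarray(self.labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.true_probs is not None:
            self.true_probs = np.asarray(self.true_probs, dtype=float)
        n = len(self.labels)
        if not (len(self.ids) == len(self.scores) == n) or (
            self.true_probs is not None and len(self.true_probs) != n
        ):
            raise InvalidSpecError("ids, labels, scores (and true_probs) must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise InvalidSpecError("labels must be binary in {0, 1}")
        if np.isnan(self.scores).any() or (self.scores < 0).any() or (self.scores > 1).any():
            raise InvalidSpecError("scores must lie in [0, 1] and be finite")

    def __len__(self) -> int:
        return len(self.labels)


def make_imbalanced_labels(spec: DatasetSpec) -> np.ndarray:
    """Return ``spec.n_negative`` zeros and ``spec.n_positive`` ones, shuffled.

    Deterministic given ``spec.seed``.
    """
    labels = np.concatenate(
        [np.zeros(spec.n_negative, dtype=int), np.ones(spec.n_positive, dtype=int)]
    )
    rng = np.random.default_rng(spec.seed)
    return rng.permutation(labels)


def generate_latent_scores(
    labels: np.ndarray,
    separability: float,
    prevalence: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw perfectly calibrated posterior probabilities for given labels.

    Each sample gets a latent ``x | y ~ Normal(+/- d/2, 1)`` and the returned
    probability is the exact Bayes posterior
    ``p = logistic(d * x + log(pi / (1 - pi)))`` of that generative model, so
    the output is calibrated by construction.  ``d = 0`` returns the
    prevalence for every sample.
    """
    labels = np.asarray(labels, dtype=int)
    d = float(separability)
    if d < 0:
        raise InvalidSpecError("separability must be >= 0")
    pi = float(np.mean(labels)) if prevalence is None else float(prevalence)
    if not (0.0 < pi < 1.0):
        raise InvalidSpecError(f"prevalence must be in (0, 1), got {pi}")
    if abs(pi - np.mean(labels)) > 0.5 / max(len(labels), 1):
        raise InvalidSpecError("prevalence must equal the label vector's positive fraction")
    rng = np.random.default_rng(rng)
    x = rng.normal(loc=np.where(labels == 1, d / 2.0, -d / 2.0), scale=1.0)
    return expit(d * x + logit(pi))


def _invert_beta_map(p: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    # Solve c + a*ln(z) - b*ln(1-z) = logit(p) for z by bisection; the left
    # side is strictly increasing in z for a, b > 0.
    target = logit(np.clip(p, EPS, 1.0 - EPS))
    lo = np.full_like(target, EPS)
    hi = np.full_like(target, 1.0 - EPS)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val = c + a * np.log(mid) - b * np.log1p(-mid)
        below = val < target
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def distort_scores(
    true_probs: np.ndarray,
    distortion: DistortionSpec,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Apply a strictly increasing miscalibration map to calibrated probabilities.

    Each family inverts the corresponding calibration map, so that fitting the
    matching calibrator on the output can recover the generating parameters:

    * ``identity`` — exact passthrough.
    * ``platt_family`` — solves ``p = logistic(alpha + beta * z)`` for ``z``
      (affine on the logit scale).  Solutions falling outside ``[0, 1]`` are
      clipped with a warning; clipping introduces boundary ties.
    * ``beta_family`` — numerical inverse of the three-parameter beta map.
    * ``majority_collapse`` — downward logit shift ``z = logistic(logit(p) - delta)``.
      With ``delta="auto"`` (requires ``labels``) the shift is chosen so every
      positive-class score lands strictly below 0.5.
    """
    p = np.clip(np.asarray(true_probs, dtype=float), EPS, 1.0 - EPS)
    fam = distortion.family
    params = dict(distortion.params)
    if fam == "identity":
        return np.asarray(true_probs, dtype=float).copy()
    if fam == "platt_family":
        alpha, beta = float(params.get("alpha", 0.0)), float(params.get("beta", 1.0))
        if beta <= 0:
            raise InvalidDistortionError("platt_family needs beta > 0")
        z = (logit(p) - alpha) / beta
        n_out = int(np.sum((z < 0) | (z > 1)))
        if n_out:
            warnings.warn(
                f"platt_family inversion left [0, 1] for {n_out}/{z.size} samples; "
                "clipping (introduces boundary ties)",
                stacklevel=2,
            )
        return np.clip(z, 0.0, 1.0)
    if fam == "beta_family":
        a, b, c = (float(params.get(k, v)) for k, v in (("a", 1.0), ("b", 1.0), ("c", 0.0)))
        if a <= 0 or b <= 0:
            raise InvalidDistortionError("beta_family needs a, b > 0 to be invertible")
        return _invert_beta_map(p, a, b, c)
    if fam == "majority_collapse":
        delta = params.get("delta", "auto")
        if delta == "auto":
            if labels is None:
                raise InvalidDistortionError("delta='auto' requires labels")
            delta = collapse_delta(p, labels)
        delta = float(delta)
        if delta <= 0:
            raise InvalidDistortionError("majority_collapse needs delta > 0")
        return expit(logit(p) - delta)
    raise InvalidDistortionError(f"unknown family {fam!r}")  # pragma: no cover


def collapse_delta(true_probs: np.ndarray, labels: np.ndarray, margin: float = 0.5) -> float:
    """Smallest-plus-margin logit shift pushing all positive-class scores below 0.5."""
    labels = np.asarray(labels, dtype=int)
    pos = np.clip(np.asarray(true_probs, dtype=float)[labels == 1], EPS, 1.0 - EPS)
    if pos.size == 0:
        raise InvalidSpecError("collapse_delta requires at least one positive sample")
    return float(max(logit(pos.max()), 0.0) + margin)


def check_majority_collapse(scores: np.ndarray, labels: np.ndarray) -> None:
    """Post-generation invariant: every positive-class score must be < 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    bad = scores[labels == 1] >= 0.5
    if bad.any():
        raise InvalidDistortionError(
            f"majority_collapse violated: {int(bad.sum())} positive-class scores >= 0.5"
        )


def _ids(prefix: str, n: int) -> np.ndarray:
    width = max(len(str(n)), 4)
    return np.array([f"{prefix}{i:0{width}d}" for i in range(n)])


def make_score_set(
    spec: DatasetSpec,
    distortion: DistortionSpec,
    rng: np.random.Generator | int | None = None,
    split: str = "cal",
) -> ScoreSet:
    """Generate one labelled score split: labels -> latent posteriors -> distortion."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    labels = rng.permutation(
        np.concatenate([np.zeros(spec.n_negative, dtype=int), np.ones(spec.n_positive, dtype=int)])
    )
    true_probs = generate_latent_scores(labels, distortion.separability, rng=rng)
    scores = distort_scores(true_probs, distortion, labels=labels)
    if distortion.family == "majority_collapse":
        check_majority_collapse(scores, labels)
    return ScoreSet(
        ids=_ids(f"{split}_", len(labels)),
        labels=labels,
        scores=scores,
        true_probs=true_probs,
        meta={"spec": spec, "distortion": distortion, "split": split},
    )


def build_study_sets(
    base: DatasetSpec,
    ratios: list[float],
    distortion: DistortionSpec,
) -> dict[float, tuple[ScoreSet, ScoreSet]]:
    """Build (calibration-fit, test) score-set pairs for a sweep of imbalance ratios.

    Test partitions keep the template's fixed (by default balanced) class
    sizes while only the fit partition's positive count varies with the
    ratio.  Per-ratio and per-split seeds are spawned deterministically from
    ``base.seed`` (children ``3i``, ``3i+1`` of the master ``SeedSequence``
    for the i-th ratio's fit and test splits; ``3i+2`` is reserved for
    downstream fitting), so the same master seed yields bit-identical output.
    """
    ratios = list(ratios)
    if not ratios:
        raise InvalidSpecError("ratios must be non-empty")
    if base.test_negative < 1:
        raise InvalidSpecError("build_study_sets needs test_negative >= 1")
    children = np.random.SeedSequence(base.seed).spawn(3 * len(ratios))
    out: dict[float, tuple[ScoreSet, ScoreSet]] = {}
    for i, ratio in enumerate(ratios):
        cal_spec = replace(base, ratio=ratio)
        test_spec = DatasetSpec(
            n_negative=base.test_negative,
            ratio=cal_spec.resolved_test_ratio(),
            seed=base.seed,
        )
        cal_rng = np.random.default_rng(children[3 * i])
        test_rng = np.random.default_rng(children[3 * i + 1])
        if distortion.family == "majority_collapse" and dict(distortion.params).get(
            "delta", "auto"
        ) == "auto":
            # Share one delta across both splits so the fitted calibration
            # map transfers exactly; derive it from both splits' positives.
            cal_labels = cal_rng.permutation(
                np.concatenate(
                    [np.zeros(cal_spec.n_negative, dtype=int), np.ones(cal_spec.n_positive, dtype=int)]
                )
            )
            test_labels = test_rng.permutation(
                np.concatenate(
                    [np.zeros(test_spec.n_negative, dtype=int), np.ones(test_spec.n_positive, dtype=int)]
                )
            )
            cal_p = generate_latent_scores(cal_labels, distortion.separability, rng=cal_rng)
            test_p = generate_latent_scores(test_labels, distortion.separability, rng=test_rng)
            delta = max(
                collapse_delta(cal_p, cal_labels), collapse_delta(test_p, test_labels)
            )
            fixed = DistortionSpec(
                family="majority_collapse",
                params={"delta": delta},
                separability=distortion.separability,
            )
            pair = []
            for split, labels, probs in (
                ("cal", cal_labels, cal_p),
                ("test", test_labels, test_p),
            ):
                scores = distort_scores(probs, fixed, labels=labels)
                check_majority_collapse(scores, labels)
                pair.append(
                    ScoreSet(
                        ids=_ids(f"{split}_", len(labels)),
                        labels=labels,
                        scores=scores,
                        true_probs=probs,
                        meta={
                            "spec": cal_spec if split == "cal" else test_spec,
                            "distortion": fixed,
                            "split": split,
                        },
                    )
                )
            out[ratio] = (pair[0], pair[1])
        else:
            out[ratio] = (
                make_score_set(cal_spec, distortion, rng=cal_rng, split="cal"),
                make_score_set(test_spec, distortion, rng=test_rng, split="test"),
            )
    return out


def sample_family_scores(
    distortion: DistortionSpec, n: int, rng: np.random.Generator | int | None = None
) -> ScoreSet:
    """Draw scores exactly well-specified for the matching calibrator.

    Raw scores are uniform on (0, 1); true probabilities are the *forward*
    calibration map of the distortion family applied to them, and labels are
    Bernoulli draws from those probabilities.  Fitting the matching
    calibrator on (scores, labels) is then a correctly specified maximum
    likelihood problem, which is the cleanest parameter-recovery setup (the
    Gaussian-latent route can push platt_family inversions outside [0, 1]).
    """
    from .calibrators import BetaParams, PlattParams, apply_beta, apply_platt

    rng = np.random.default_rng(rng)
    z = rng.uniform(EPS, 1.0 - EPS, size=n)
    params = dict(distortion.params)
    if distortion.family == "platt_family":
        p = apply_platt(
            PlattParams(float(params.get("alpha", 0.0)), float(params.get("beta", 1.0))), z
        )
    elif distortion.family == "beta_family":
        p = apply_beta(
            BetaParams(
                float(params.get("a", 1.0)),
                float(params.get("b", 1.0)),
                float(params.get("c", 0.0)),
            ),
            z,
        )
    elif distortion.family == "identity":
        p = z.copy()
    else:
        raise InvalidDistortionError(
            f"sample_family_scores supports identity/platt_family/beta_family, got {distortion.family}"
        )
    labels = (rng.uniform(size=n) < p).astype(int)
    return ScoreSet(
        ids=_ids("fam_", n),
        labels=labels,
        scores=z,
        true_probs=p,
        meta={"distortion": distortion, "split": "family_sample"},
    )
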