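"""Bootstrap-embedded recursive feature elimination and the one-SE rule.

Two rankings drive the elimination: boosting impurity importance (``BSTsel``)
and L1-logistic-regression coefficient magnitude (``L1LRsel``).  Each
patient-wise bootstrap resample fits the ranking model on the in-bag
patients' segments, iteratively drops the least important feature down to a
single one, and scores every subset size on the out-of-bag patients.  The
subset size K_s is the smallest whose mean out-of-bag BER is within one
standard error of the minimum, and the final subset collects the K_s features
most often retained across resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifiers import ModelSpec, TrainedModel, fit, predict
from .evaluation import MetricSet, PairedComparison, metrics, paired_compare
from .features import FeatureDataset
from .records import NSH, SH

log = logging.getLogger(__name__)

#: ranking-model hyperparameters reused across resamples (tuned once
#: globally or left at these defaults; per-resample retuning is out of scope)
DEFAULT_RANKER_HP = {
    "BSTsel": {"depth": 1, "M": 50},
    "L1LRsel": {"lam": 0.05},
}
_METHOD_TO_ALG = {"BSTsel": "BST", "L1LRsel": "L1LR"}


@dataclass
class RfeResult:
    """Per-resample elimination paths and out-of-bag BER curves."""

    method: str
    feature_names: list[str]
    #: B x K; column k-1 holds the out-of-bag BER at subset size k, percent
    ber: np.ndarray
    #: B x K elimination orders (feature indices, first-dropped first)
    elimination: np.ndarray
    B: int
    seed: int
    n_redraws: int = 0

    @property
    def K(self) -> int:
        return len(self.feature_names)

    def mean_curve(self) -> np.ndarray:
        """Mean BER by subset size (index k-1 <-> size k)."""
        return self.ber.mean(axis=0)

    def selection_counts(self, k: int) -> np.ndarray:
        """Times each feature survives into the size-k subset, over resamples."""
        surviving = self.elimination[:, self.K - k :]
        counts = np.zeros(self.K, dtype=int)
        for row in surviving:
            counts[row] += 1
        return counts

    def mean_elimination_step(self) -> np.ndarray:
        """Mean position in the elimination order (higher = dropped later =
        more important); the secondary tie-break for the final subset."""
        order = np.argsort(self.elimination, axis=1)
        return order.mean(axis=0)


@dataclass
class SelectionResult:
    """One-SE subset choice on top of an RFE run."""

    method: str
    mean_ber: np.ndarray
    se: float
    k_min: int
    k_s: int
    counts: np.ndarray
    subset: list[str]
    rfe: RfeResult = field(repr=False, default=None)

    @property
    def threshold(self) -> float:
        return float(self.mean_ber[self.k_min - 1] + self.se)


def rfe_bootstrap(
    train: FeatureDataset,
    method: str,
    B: int = 500,
    seed: int = 0,
    ranker_hp: dict | None = None,
    max_redraws: int = 200,
) -> RfeResult:
    """Run the bootstrap recursive elimination.

    A resample whose in-bag or out-of-bag patients miss a class is redrawn
    (and logged); ``max_redraws`` caps the total across the run.
    """
    if method not in _METHOD_TO_ALG:
        raise ValueError(f"method must be one of {sorted(_METHOD_TO_ALG)}")
    hp = dict(DEFAULT_RANKER_HP[method], **(ranker_hp or {}))
    spec = ModelSpec(_METHOD_TO_ALG[method])
    pids = np.unique(train.patients)
    if pids.size < 2:
        raise ValueError("need at least 2 training patients")
    K = len(train.feature_names)
    Xall = train.X.to_numpy()
    y = train.y
    seg_idx = {pid: np.flatnonzero(train.patients == pid) for pid in pids}

    streams = np.random.SeedSequence(seed).spawn(B + max_redraws)
    ber = np.empty((B, K))
    elimination = np.empty((B, K), dtype=int)
    b = 0
    redraws = 0
    stream_i = 0
    while b < B:
        if stream_i >= len(streams):
            raise RuntimeError("exceeded redraw budget; classes too imbalanced")
        rng = np.random.default_rng(streams[stream_i])
        stream_i += 1
        draw = pids[rng.integers(0, pids.size, size=pids.size)]
        oob = np.setdiff1d(pids, draw)
        in_idx = np.concatenate([seg_idx[p] for p in draw])
        if oob.size == 0:
            redraws += 1
            log.info("resample redrawn: empty out-of-bag")
            continue
        oob_idx = np.concatenate([seg_idx[p] for p in oob])
        if (
            not ((y[in_idx] == SH).any() and (y[in_idx] == NSH).any())
            or not ((y[oob_idx] == SH).any() and (y[oob_idx] == NSH).any())
        ):
            redraws += 1
            log.info("resample redrawn: missing class in bag or out-of-bag")
            continue
        ber[b], elimination[b] = _rfe_path(
            spec, hp, Xall, y, in_idx, oob_idx, train.feature_names,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        b += 1
    return RfeResult(
        method=method,
        feature_names=list(train.feature_names),
        ber=ber,
        elimination=elimination,
        B=B,
        seed=seed,
        n_redraws=redraws,
    )


def _rfe_path(spec, hp, X, y, in_idx, oob_idx, names, seed):
    """One resample: eliminate the least important feature down to k=1,
    scoring each subset size on the out-of-bag rows."""
    K = len(names)
    active = list(range(K))
    ber_by_size = np.empty(K)
    order = np.empty(K, dtype=int)
    from .classifiers import _make_estimator

    for k in range(K, 0, -1):
        est = _make_estimator(spec.algorithm, hp, spec.n_trees, seed)
        est.fit(X[np.ix_(in_idx, active)], y[in_idx])
        pred = est.predict(X[np.ix_(oob_idx, active)])
        ber_by_size[k - 1] = metrics(y[oob_idx], pred).ber
        if spec.algorithm == "L1LR":
            attribution = np.abs(est.coef_.ravel())
        else:
            attribution = np.asarray(est.feature_importances_)
        drop = int(np.argmin(attribution))
        order[K - k] = active[drop]
        del active[drop]
    return ber_by_size, order


def one_se_size(mean_ber: np.ndarray, se: float) -> int:
    """Smallest subset size whose mean BER is within one standard error of
    the minimum.  ``mean_ber`` is indexed by size (element 0 <-> size 1)."""
    mean_ber = np.asarray(mean_ber, dtype=float)
    k_min = int(np.argmin(mean_ber)) + 1
    threshold = mean_ber[k_min - 1] + se
    for k in range(1, mean_ber.size + 1):
        if mean_ber[k - 1] <= threshold + 1e-12:
            return k
    return k_min


def one_se_subset(rfe: RfeResult, se_rule: str = "sd") -> SelectionResult:
    """Apply the one-SE rule and assemble the final subset.

    ``se_rule`` picks the dispersion used as the band: ``"sd"`` (the SD of
    the B out-of-bag BER values at the minimizing size, matching per-size
    error bars) or ``"sd/sqrtB"`` (the standard error of the mean).  The
    final subset holds the K_s features with the highest selection counts at
    size K_s; ties break by mean elimination step (later is better), then by
    name.
    """
    mean_ber = rfe.mean_curve()
    k_min = int(np.argmin(mean_ber)) + 1
    sd = float(np.std(rfe.ber[:, k_min - 1], ddof=1)) if rfe.B > 1 else 0.0
    if se_rule == "sd":
        se = sd
    elif se_rule in ("sd/sqrtB", "sem"):
        se = sd / np.sqrt(rfe.B)
    else:
        raise ValueError("se_rule must be 'sd' or 'sd/sqrtB'")
    k_s = one_se_size(mean_ber, se)
    counts = rfe.selection_counts(k_s)
    steps = rfe.mean_elimination_step()
    names = rfe.feature_names
    ranked = sorted(
        range(len(names)), key=lambda j: (-counts[j], -steps[j], names[j])
    )
    subset = [names[j] for j in ranked[:k_s]]
    return SelectionResult(
        method=rfe.method,
        mean_ber=mean_ber,
        se=se,
        k_min=k_min,
        k_s=k_s,
        counts=counts,
        subset=subset,
        rfe=rfe,
    )


@dataclass
class SubsetEvaluation:
    subset_metrics: MetricSet
    all_metrics: MetricSet
    comparison: PairedComparison
    model_subset: TrainedModel
    model_all: TrainedModel


def evaluate_subset(
    train: FeatureDataset,
    test: FeatureDataset,
    subset: list[str],
    spec: ModelSpec,
    hyperparams: dict,
    B: int = 500,
    seed: int = 0,
) -> SubsetEvaluation:
    """Refit on the subset columns and compare against the all-features model
    with a paired bootstrap on shared test resamples."""
    if len(subset) == 0:
        raise ValueError("empty feature subset")
    unknown = set(subset) - set(train.feature_names)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    model_all = fit(spec, hyperparams, train, seed=seed)
    model_sub = fit(spec, hyperparams, train.subset_features(subset), seed=seed)
    pred_all = predict(model_all, test.X)
    pred_sub = predict(model_sub, test.subset_features(subset).X)
    cmp = paired_compare(
        test.y, pred_sub, pred_all, test.patients, B=B, seed=seed, metric="BER"
    )
    return SubsetEvaluation(
        subset_metrics=metrics(test.y, pred_sub),
        all_metrics=metrics(test.y, pred_all),
        comparison=cmp,
        model_subset=model_sub,
        model_all=model_all,
    )
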