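"""Classification scoring, the adaptive band/m search, kappa and the t-test.

Feature vectors are scored by a support-vector machine (RBF kernel, C = 1,
variance-scaled bandwidth) under repeated stratified k-fold cross-validation
(10 x 10-fold by default).  Standardization is fitted on training folds only.

The adaptive search mirrors the two-stage frequency-band selection: the
alpha (8-13 Hz) and beta (13-30 Hz) bands are scored over every truncation
order m in 1..p first; if alpha wins, it is reported, otherwise the beta
sub-bands beta1 (13-21 Hz) and beta2 (21-30 Hz) are scored as well and the
best of {beta, beta1, beta2} is reported.

Agreement beyond chance is summarized by Cohen's kappa,
``k = (p0 - pe) / (1 - pe)`` with pe = 0.5 for a balanced two-class design,
and two methods' fold accuracies are compared by a pooled-variance
two-sample t-test with a one-sided decision rule at significance 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._exceptions import ValidationError
from .connectivity import compute_adjacency
from .features import feature_vector
from .mvar import fit_mvar, select_order_sbc
from .preprocessing import BANDS, Band, bandpass_filter
from .recording import EpochedRecording

__all__ = [
    "SearchConfig",
    "EvaluationResult",
    "TTestResult",
    "evaluate_features",
    "adaptive_search",
    "kappa",
    "chance_agreement",
    "pooled_t_test",
]


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the adaptive band/m search.

    ``p_max`` caps the SBC order scan per band; ``folds`` x ``repeats``
    define the cross-validation scheme; all randomness derives from
    ``seed``.  ``order_mode`` selects how the common per-band order p is
    chosen from per-trial SBC picks ('median') or from a fit on the
    trial-concatenated signal ('concatenated').
    """

    p_max: int = 5
    folds: int = 10
    repeats: int = 10
    seed: int = 0
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    exclude_self: bool = False
    order_mode: str = "median"

    def __post_init__(self) -> None:
        if self.order_mode not in ("median", "concatenated"):
            raise ValidationError(f"unknown order_mode {self.order_mode!r}")
        if self.folds < 2 or self.repeats < 1 or self.p_max < 1:
            raise ValidationError("folds >= 2, repeats >= 1, p_max >= 1 required")


@dataclass
class EvaluationResult:
    """Outcome of the adaptive search.

    ``table`` maps ``(band_name, m)`` to a dict with keys ``mean_accuracy``
    (percent) and ``per_run`` (accuracy of each repeat, percent);
    ``search_trace`` records the bands scored, in order; ``orders`` the
    SBC-selected p per band.
    """

    table: dict[tuple[str, int], dict]
    best_band: str
    best_m: int
    best_accuracy: float
    kappa: float
    search_trace: list[str] = field(default_factory=list)
    orders: dict[str, int] = field(default_factory=dict)
    config: SearchConfig | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "best_band": self.best_band,
            "best_m": int(self.best_m),
            "best_accuracy": float(self.best_accuracy),
            "kappa": float(self.kappa),
            "search_trace": self.search_trace,
            "orders": {b: int(p) for b, p in self.orders.items()},
            "table": [
                {
                    "band": band,
                    "m": int(m),
                    "mean_accuracy": float(entry["mean_accuracy"]),
                    "std_accuracy": float(np.std(entry["per_run"])),
                    "per_run": [float(a) for a in entry["per_run"]],
                }
                for (band, m), entry in sorted(self.table.items())
            ],
            "config": None if self.config is None else vars(self.config).copy(),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary_tsv(self) -> str:
        """One-line TSV summary (band, m, mean accuracy %) plus header."""
        return (
            "best_band\tbest_m\tmean_accuracy_pct\tkappa\n"
            f"{self.best_band}\t{self.best_m}\t{self.best_accuracy:.2f}\t{self.kappa:.4f}\n"
        )


@dataclass
class TTestResult:
    """Pooled two-sample t-test with one-sided decision at level ``mu``."""

    t_stat: float
    p_value: float
    n_a: int
    n_b: int
    mu: float
    reject: bool


def kappa(accuracy_fraction: float, p_e: float = 0.5) -> float:
    """Cohen's kappa ``(p0 - pe) / (1 - pe)`` of an accuracy fraction p0."""
    p0 = float(accuracy_fraction)
    if not 0.0 <= p0 <= 1.0:
        raise ValidationError(f"accuracy fraction must be in [0, 1], got {p0}")
    if p_e >= 1.0:
        raise ValidationError(f"chance agreement p_e must be < 1, got {p_e}")
    return (p0 - p_e) / (1.0 - p_e)


def chance_agreement(labels: np.ndarray) -> float:
    """Chance agreement pe for a label vector: 0.5 if balanced two-class,
    otherwise the sum of squared class proportions (matched marginals)."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    props = counts / counts.sum()
    if len(props) == 2 and counts[0] == counts[1]:
        return 0.5
    return float((props**2).sum())


def pooled_t_test(acc_a, acc_b, mu: float = 0.05) -> TTestResult:
    """One-sided pooled-variance t-test that ``acc_b`` exceeds ``acc_a``.

    The statistic is t = (mean_b - mean_a) / sqrt(s2_pooled (1/n_a + 1/n_b))
    with s2_pooled the weighted average of the two sample variances and
    df = n_a + n_b - 2; reject the equal-means hypothesis iff the one-sided
    p-value P{T > t} is <= ``mu``.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValidationError("both samples need at least 2 observations")
    diff = b.mean() - a.mean()
    s2 = ((n_b - 1) * b.var(ddof=1) + (n_a - 1) * a.var(ddof=1)) / (n_a + n_b - 2)
    denom = np.sqrt(s2 * (1.0 / n_a + 1.0 / n_b))
    if denom == 0.0:
        # Degenerate: no within-sample variability at all.
        if diff == 0.0:
            t_stat, p = 0.0, 0.5
        else:
            t_stat = np.inf if diff > 0 else -np.inf
            p = 0.0 if diff > 0 else 1.0
    else:
        t_stat = diff / denom
        p = float(stats.t.sf(t_stat, df=n_a + n_b - 2))
    return TTestResult(
        t_stat=float(t_stat), p_value=float(p), n_a=n_a, n_b=n_b, mu=mu,
        reject=bool(p <= mu),
    )


def _svm(config: SearchConfig):
    return make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", C=config.svm_c, gamma=config.svm_gamma),
    )


def evaluate_features(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    config: SearchConfig | None = None,
) -> dict:
    """Repeated stratified k-fold SVM accuracy of a feature matrix.

    Each repeat r uses ``StratifiedKFold`` shuffled with seed ``seed + r``;
    within a fold, features are z-scored on the training split only.
    Returns ``{"mean_accuracy": percent, "per_run": [percent, ...]}``; the
    mean is the average of the per-repeat accuracies.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or len(y) != len(x):
        raise ValidationError("features must be 2-D with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {len(classes)}")
    if counts.min() < folds:
        raise ValidationError(
            f"smallest class has {counts.min()} trials, fewer than {folds} folds"
        )
    if config is None:
        config = SearchConfig(folds=folds, repeats=repeats, seed=seed)
    per_run = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        fold_acc = []
        for train, test in skf.split(x, y):
            clf = _svm(config)
            clf.fit(x[train], y[train])
            fold_acc.append(clf.score(x[test], y[test]))
        per_run.append(100.0 * float(np.mean(fold_acc)))
    return {"mean_accuracy": float(np.mean(per_run)), "per_run": per_run}


def _band_order(band_data: np.ndarray, config: SearchConfig) -> int:
    """Common MVAR order for one band: median of per-trial SBC picks, or an
    SBC pick on the trial-concatenated signal."""
    if config.order_mode == "concatenated":
        return select_order_sbc(np.concatenate(list(band_data), axis=1),
                                p_max=config.p_max)
    picks = [select_order_sbc(trial, p_max=config.p_max) for trial in band_data]
    return int(round(float(np.median(picks))))


def band_feature_table(
    rec: EpochedRecording, band: Band, config: SearchConfig
) -> tuple[int, dict[int, np.ndarray]]:
    """Preprocess ``rec`` to ``band`` and build per-m feature matrices.

    Returns the SBC-selected order p and a map m -> (n_trials, 2N) feature
    matrix for every m in 1..p.  Models are fitted per trial at the common
    order p and reused across m.
    """
    filtered = bandpass_filter(rec, band)
    p = _band_order(filtered.data, config)
    models = []
    for trial in filtered.data:
        model = fit_mvar(trial, p)
        model.fs = rec.fs
        models.append(model)
    tables: dict[int, np.ndarray] = {}
    for m in range(1, p + 1):
        feats = [
            feature_vector(
                compute_adjacency(
                    filtered.data[i], band, m, model=models[i],
                    channels=filtered.channels,
                    exclude_self=config.exclude_self,
                )
            )
            for i in range(filtered.n_trials)
        ]
        tables[m] = np.asarray(feats)
    return p, tables


def _best_entry(table: dict, bands: list[str]) -> tuple[str, int, float]:
    candidates = [
        (band, m, entry["mean_accuracy"])
        for (band, m), entry in table.items()
        if band in bands
    ]
    # Highest accuracy first.  Exact ties break toward the smaller m and
    # then the narrower band (fewer grid points, lower f_low): when a wide
    # band and its sub-band score identically, the sub-band is the sharper
    # statement of where the discriminative rhythm lives -- localizing
    # within the wide band is the whole point of the refinement stage.
    def sort_key(c):
        band = BANDS[c[0]]
        return (c[2], -c[1], -band.n_freqs, -band.f_low)

    return max(candidates, key=sort_key)


def adaptive_search(
    rec: EpochedRecording, config: SearchConfig | None = None
) -> EvaluationResult:
    """Two-stage adaptive frequency-band and truncation-order search.

    Stage 1 scores the alpha and beta bands over m = 1..p (p per band by
    SBC).  If the best alpha accuracy is at least the best beta accuracy,
    the alpha winner is reported and the search stops.  Otherwise stage 2
    also scores beta1 and beta2 and reports the best of
    {beta, beta1, beta2}.  ``rec`` must be raw (not yet band-filtered) but
    already referenced/windowed/channel-selected as desired.
    """
    if config is None:
        config = SearchConfig()
    if len(rec.classes()) != 2:
        raise ValidationError(
            f"adaptive search needs exactly two classes, got {rec.classes()}"
        )
    if rec.band_tag is not None:
        raise ValidationError(
            f"recording already band-filtered to {rec.band_tag!r}; "
            "pass the pre-band data"
        )

    table: dict[tuple[str, int], dict] = {}
    orders: dict[str, int] = {}
    trace: list[str] = []

    def run_band(name: str) -> None:
        band = BANDS[name]
        p, tables = band_feature_table(rec, band, config)
        orders[name] = p
        trace.append(name)
        for m, feats in tables.items():
            table[(name, m)] = evaluate_features(
                feats, rec.labels,
                folds=config.folds, repeats=config.repeats, seed=config.seed,
                config=config,
            )

    run_band("alpha")
    run_band("beta")
    best_alpha = max(v["mean_accuracy"] for (b, _), v in table.items() if b == "alpha")
    best_beta = max(v["mean_accuracy"] for (b, _), v in table.items() if b == "beta")
    if best_alpha >= best_beta:
        band, m, acc = _best_entry(table, ["alpha"])
    else:
        run_band("beta1")
        run_band("beta2")
        band, m, acc = _best_entry(table, ["beta", "beta1", "beta2"])

    p_e = chance_agreement(rec.labels)
    return EvaluationResult(
        table=table,
        best_band=band,
        best_m=m,
        best_accuracy=acc,
        kappa=kappa(acc / 100.0, p_e=p_e),
        search_trace=trace,
        orders=orders,
        config=config,
    )
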