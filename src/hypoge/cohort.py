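"""Personal, general and cluster model orchestration.

Three model scopes share one training recipe (30 independent evolutionary
runs on balanced training windows) and differ only in whose data is pooled:

* PM — one suite per patient, trained on that patient's data only;
* GM — one suite trained on all patients pooled;
* CM — one suite per K-means cluster, trained on the cluster's pooled data.

Clustering characterises each patient by the 4-vector of average glucose
rates of change over 30/60/90/120-minute windows (mg/dL per minute) —
``roc(w) = mean over t of (gluc(t) - gluc(t-w)) / w`` over the sample pairs
where both values exist.  Features are standardised before K-means so the
longest window does not dominate distances; k is picked by a combined rank
of the elbow curvature, silhouette and Davies-Bouldin diagnostics, and can
be overridden (the choice is ultimately a judgment call).

Evaluation applies every run's best rule to each relevant patient's
untouched, naturally imbalanced test split and reports the full confusion
metrics per (patient, run).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.preprocessing import StandardScaler

from . import metrics
from .engines import EvolutionConfig, evolve
from .expressions import parse_phenotype
from .glucodata import LabeledDataset
from .grammar import Grammar

__all__ = [
    "ROC_WINDOWS_MIN",
    "ClusterAssignment",
    "ModelSuite",
    "rate_of_change",
    "patient_features",
    "cluster_patients",
    "train_suite",
    "evaluate_suite",
    "summarize_metrics",
]

logger = logging.getLogger(__name__)

ROC_WINDOWS_MIN = (30, 60, 90, 120)


def rate_of_change(series, w: int) -> float:
    """Average glucose rate of change over window ``w`` minutes.

    Mean over valid sample pairs of ``(gluc(t) - gluc(t-w)) / w``; only
    pairs with both values present count.  Invariant to adding a constant
    to all glucose values.
    """
    if w not in ROC_WINDOWS_MIN:
        raise ValueError(f"w must be one of {ROC_WINDOWS_MIN}, got {w}")
    g = series.data["gluc"]
    lagged = g.shift(w // 5)
    diffs = ((g - lagged) / w).dropna()
    if len(diffs) == 0:
        raise ValueError(
            f"no valid (t, t-{w}min) glucose pair for {series.patient_id!r}"
        )
    return float(diffs.mean())


def patient_features(series) -> np.ndarray:
    """The 4-D clustering vector (roc(30), roc(60), roc(90), roc(120))."""
    return np.array([rate_of_change(series, w) for w in ROC_WINDOWS_MIN])


@dataclass
class ClusterAssignment:
    k: int
    labels: dict[str, int]
    diagnostics: pd.DataFrame  # columns: k, inertia, silhouette, davies_bouldin

    @classmethod
    def single_cluster(cls, patient_ids) -> "ClusterAssignment":
        """The trivial assignment: every patient in cluster 0 (CM == GM)."""
        return cls(
            k=1,
            labels={pid: 0 for pid in patient_ids},
            diagnostics=pd.DataFrame(
                columns=["k", "inertia", "silhouette", "davies_bouldin"]
            ),
        )


def cluster_patients(
    features: dict[str, np.ndarray],
    k_range: tuple[int, int] = (2, 7),
    seed: int = 0,
    k_override: int | None = None,
) -> ClusterAssignment:
    """K-means over standardised per-patient roc features, for each k in
    ``k_range`` (inclusive), with diagnostics and an automatic k choice.

    Each candidate k gets an inertia (elbow curve), silhouette and
    Davies-Bouldin score; the chosen k is the smallest k minimising the sum
    of three ranks (elbow curvature descending, silhouette descending,
    Davies-Bouldin ascending).  Pass ``k_override`` to impose a k.
    """
    pids = sorted(features)
    if not pids:
        raise ValueError("no patients")
    X = np.vstack([features[p] for p in pids])
    k_lo, k_hi = k_range
    if k_lo < 2:
        raise ValueError("k must be >= 2 (silhouette undefined for k=1)")
    if k_hi >= len(pids):
        raise ValueError(
            f"max k ({k_hi}) must be below the number of patients"
            f" ({len(pids)}): silhouette needs at least one spare"
        )
    Xs = StandardScaler().fit_transform(X)

    rows = []
    label_sets: dict[int, np.ndarray] = {}
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(Xs)
        label_sets[k] = lab
        rows.append(
            {
                "k": k,
                "inertia": float(km.inertia_),
                "silhouette": float(silhouette_score(Xs, lab)),
                "davies_bouldin": float(davies_bouldin_score(Xs, lab)),
            }
        )
    diag = pd.DataFrame(rows)

    if k_override is not None:
        if not (k_lo <= k_override <= k_hi):
            raise ValueError("k_override outside k_range")
        chosen = k_override
    else:
        chosen = _rank_select_k(diag)
    return ClusterAssignment(
        k=chosen,
        labels={p: int(l) for p, l in zip(pids, label_sets[chosen])},
        diagnostics=diag,
    )


def _rank_select_k(diag: pd.DataFrame) -> int:
    """Smallest k minimising the summed ranks of the three diagnostics.

    Elbow is scored by the discrete curvature of the inertia curve
    (endpoints, which have no curvature, get the worst rank).
    """
    d = diag.sort_values("k").reset_index(drop=True)
    inertia = d["inertia"].to_numpy()
    curvature = np.full(len(d), -np.inf)
    if len(d) >= 3:
        curvature[1:-1] = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
    ranks = (
        pd.Series(-curvature).rank(method="min")
        + pd.Series(-d["silhouette"]).rank(method="min")
        + pd.Series(d["davies_bouldin"]).rank(method="min")
    )
    best = ranks.min()
    return int(d.loc[ranks[ranks == best].index.min(), "k"])


@dataclass
class ModelSuite:
    """Best-of-run rule models for one scope.

    ``models`` maps a target (patient id for PM, ``"GM"``, or a cluster
    index for CM) to one record per run: (run, seed, phenotype,
    train_fitness).  ``train_index`` keeps each patient's training window
    index so evaluation can assert train/test disjointness.
    """

    scope: str
    horizon: int
    models: dict = field(default_factory=dict)
    assignment: ClusterAssignment | None = None
    train_index: dict = field(default_factory=dict)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "scope": self.scope,
                "target": str(target),
                "run": run,
                "seed": seed,
                "best_fitness": fitness,
                "phenotype": phenotype,
            }
            for target, records in self.models.items()
            for (run, seed, phenotype, fitness) in records
        ]
        return pd.DataFrame(rows)


def _pool(parts: dict[str, LabeledDataset]) -> LabeledDataset:
    """Pool per-patient datasets in sorted patient order, tagging the index."""
    pieces = []
    for pid in sorted(parts):
        ds = parts[pid]
        X = ds.X.copy()
        X.index = pd.MultiIndex.from_arrays(
            [[pid] * len(X), X.index], names=["patient", "window"]
        )
        pieces.append(LabeledDataset(X=X, y=ds.y, horizon=ds.horizon))
    return LabeledDataset.concat(pieces)


def train_suite(
    scope: str,
    train_sets: dict[str, LabeledDataset],
    g: Grammar,
    cfg: EvolutionConfig,
    assignment: ClusterAssignment | None = None,
) -> ModelSuite:
    """Train ``cfg.runs`` independent evolutions per scope target.

    ``train_sets`` are per-patient, already balanced training splits;
    pooling happens after balancing so each patient contributes 50/50
    classes.  Run ``r`` uses seed ``cfg.seed + r`` for every target, which
    makes CM with a single all-patient cluster bit-identical to GM.
    """
    scope = scope.upper()
    if scope not in ("PM", "GM", "CM"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "CM":
        if assignment is None:
            raise ValueError("CM training requires a cluster assignment")
        missing = sorted(set(train_sets) - set(assignment.labels))
        if missing:
            raise ValueError(f"patients without a cluster: {missing}")

    horizon = next(iter(train_sets.values())).horizon
    if scope == "PM":
        pooled = {pid: train_sets[pid] for pid in sorted(train_sets)}
    elif scope == "GM":
        pooled = {"GM": _pool(train_sets)}
    else:
        pooled = {}
        for c in sorted(set(assignment.labels.values())):
            members = {
                pid: ds
                for pid, ds in train_sets.items()
                if assignment.labels[pid] == c
            }
            if not members:
                raise ValueError(f"cluster {c} has no training data")
            pooled[c] = _pool(members)

    suite = ModelSuite(
        scope=scope,
        horizon=horizon,
        assignment=assignment,
        train_index={pid: ds.X.index for pid, ds in train_sets.items()},
    )
    for target, ds in pooled.items():
        records = []
        for run in range(cfg.runs):
            run_seed = cfg.seed + run
            run_cfg = EvolutionConfig(
                **{
                    **cfg.__dict__,
                    "seed": run_seed,
                    "crossover_change_prob": cfg.crossover_change_prob,
                }
            )
            best, _trace = evolve(ds, g, run_cfg)
            records.append((run, run_seed, best.phenotype, best.fitness))
            logger.info(
                "%s target=%s run=%d fitness=%.4f",
                scope, target, run, best.fitness,
            )
        suite.models[target] = records
    return suite


def evaluate_suite(
    suite: ModelSuite, test_sets: dict[str, LabeledDataset]
) -> pd.DataFrame:
    """Apply each run's model to each relevant patient's test split.

    Returns one row per (patient, run) with the confusion counts, accuracy,
    precision, recall, F1, WA, fitness, TPR and TNR.  TPR is NaN (with a
    warning in the log) for test sets without positives.
    """
    rows = []
    for pid in sorted(test_sets):
        test = test_sets[pid]
        if pid in suite.train_index:
            overlap = suite.train_index[pid].intersection(test.X.index)
            if len(overlap):
                raise ValueError(
                    f"test set of {pid!r} overlaps its training windows"
                )
        if suite.scope == "PM":
            target = pid
        elif suite.scope == "GM":
            target = "GM"
        else:
            target = suite.assignment.labels[pid]
        if target not in suite.models:
            continue
        data = test.arrays()
        if not test.y.any():
            logger.warning("patient %s: no positives in test; TPR undefined", pid)
        for run, seed, phenotype, train_fitness in suite.models[target]:
            model = parse_phenotype(phenotype)
            rep = metrics.confusion(test.y, model.predict(data))
            rows.append(
                {"patient": pid, "run": run, "seed": seed, **rep.to_dict()}
            )
    return pd.DataFrame(rows)


def summarize_metrics(report: pd.DataFrame) -> pd.DataFrame:
    """Per-patient quartile summaries (for boxplot-style reporting)."""
    cols = ["tpr", "tnr", "wa", "accuracy", "f1"]
    out = (
        report.groupby("patient")[cols]
        .quantile([0.25, 0.5, 0.75])
        .unstack(level=-1)
    )
    out.columns = [f"{m}_q{int(q * 100)}" for m, q in out.columns]
    return out.reset_index()
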