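"""Metric suite and repeated-simulation benchmark runner.

Three metric families assess an integration method through the feature
representation it hands to downstream analysis:

1. pairwise patient similarity — mean Pearson correlation and mean
   Gaussian-kernel similarity of patient pairs, split into within-class
   and between-class averages;
2. class discovery — normalized mutual information between the planted
   classes and a best-of-many-restarts k-means partition;
3. class prediction — leave-one-out cross-validated random-forest
   accuracy on the true labels.

`run_benchmark` repeats a simulation scenario, applies each requested
method and reports mean +/- sd per metric, mirroring the layout of the
published comparison table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import normalized_mutual_info_score

from .core import VARIANTS, _row_correlation, direct_concatenate, ibfe
from .simulate import SimulationOutput, SimulationSpec, simulate

__all__ = [
    "nmi",
    "intra_inter_pcc",
    "intra_inter_similarity",
    "gaussian_kernel_similarity",
    "best_kmeans",
    "loo_rf_accuracy",
    "stable_k",
    "run_benchmark",
    "EvaluationReport",
    "BENCHMARK_METHODS",
]

BENCHMARK_METHODS = ("data1", "data2", "concatenation", "ibfe1", "ibfe2", "ibfe3")

METRICS = (
    "pcc_intraclass",
    "pcc_interclass",
    "sim_intraclass",
    "sim_interclass",
    "nmi_kmeans",
    "acc_rfloo",
)


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    return labels


def nmi(labels_a, labels_b, normalization: str = "sqrt") -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Mutual information is normalized by sqrt(H(A) * H(B)) by default
    (``normalization="max"`` uses max(H(A), H(B)) instead).  If either
    partition has zero entropy the ratio is undefined; by convention the
    value is 1 when the two partitions are identical and 0 otherwise.
    """
    a, b = _check_labels(labels_a), _check_labels(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("label vectors are empty")
    if normalization not in ("sqrt", "max"):
        raise ValueError(f"normalization must be 'sqrt' or 'max', got {normalization!r}")
    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        same = len(np.unique(a)) == 1 and len(np.unique(b)) == 1
        return 1.0 if same else 0.0
    method = "geometric" if normalization == "sqrt" else "max"
    return float(normalized_mutual_info_score(a, b, average_method=method))


def _pair_masks(labels: np.ndarray):
    iu = np.triu_indices(len(labels), k=1)
    same = (labels[:, None] == labels[None, :])[iu]
    return iu, same


def intra_inter_similarity(C, labels) -> tuple[float, float]:
    """Within/between-class means of a precomputed patient-similarity matrix.

    The diagonal is excluded; each unordered patient pair contributes once.
    """
    C = np.asarray(C, dtype=float)
    labels = _check_labels(labels)
    if C.shape != (len(labels), len(labels)):
        raise ValueError("similarity matrix and labels are inconsistent")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    iu, same = _pair_masks(labels)
    vals = C[iu]
    if not same.any():
        raise ValueError("no within-class pair: every class has a single member")
    return float(vals[same].mean()), float(vals[~same].mean())


def intra_inter_pcc(F, labels) -> tuple[float, float]:
    """Mean within/between-class Pearson correlation of patient feature rows."""
    F = np.asarray(F, dtype=float)
    return intra_inter_similarity(_row_correlation(F), labels)


def gaussian_kernel_similarity(F, labels, bandwidth: str | float = "median") -> tuple[float, float]:
    """Mean within/between-class Gaussian-kernel similarity of feature rows.

    sim(a, b) = exp(-d(a, b)^2 / (2 sigma^2)) with d the Euclidean distance
    and sigma either a fixed number or the median off-diagonal pairwise
    distance (the standard heuristic).  If all points coincide sigma is 0;
    similarity is then defined as 1 everywhere and a warning is emitted.
    """
    F = np.asarray(F, dtype=float)
    labels = _check_labels(labels)
    d = pdist(F)
    if bandwidth == "median":
        sigma = float(np.median(d))
    else:
        sigma = float(bandwidth)
        if sigma < 0:
            raise ValueError("bandwidth must be non-negative")
    if sigma == 0:
        warnings.warn("zero kernel bandwidth: all similarities set to 1", RuntimeWarning)
        K = np.ones((len(F), len(F)))
    else:
        K = np.exp(-squareform(d) ** 2 / (2.0 * sigma**2))
    return intra_inter_similarity(K, labels)


def best_kmeans(F, k: int, n_restarts: int = 1000, seed: int = 0, return_inertia: bool = False):
    """Best of ``n_restarts`` randomly initialized k-means runs.

    Every restart draws k initial centroids uniformly from the data points
    and runs Lloyd iterations to convergence; the partition with the
    minimum total point-to-centroid squared distance wins.  Deterministic
    given ``seed``.
    """
    F = np.asarray(F, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k >= len(F):
        raise ValueError(f"k={k} must be smaller than the number of patients {len(F)}")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(F)
    if return_inertia:
        return km.labels_, float(km.inertia_)
    return km.labels_


def loo_rf_accuracy(
    F,
    labels,
    n_estimators: int = 100,
    max_features: str | float = "sqrt",
    seed: int = 0,
) -> float:
    """Leave-one-out cross-validated random-forest accuracy.

    Each patient is predicted by a forest trained on all the others.
    Deterministic given ``seed`` (each fold uses a seed derived from it).
    """
    F = np.asarray(F, dtype=float)
    y = _check_labels(labels)
    if len(F) != len(y):
        raise ValueError("features and labels are inconsistent")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    if len(y) < 10:
        raise ValueError("leave-one-out needs at least 10 patients")
    correct = 0
    idx = np.arange(len(y))
    for i in idx:
        train = idx != i
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=(seed + 7919 * int(i)) % (2**31),
            n_jobs=1,
        )
        clf.fit(F[train], y[train])
        correct += int(clf.predict(F[i : i + 1])[0] == y[i])
    return correct / len(y)


def stable_k(
    F,
    k_range: Sequence[int] = range(2, 11),
    n_restarts: int = 1000,
    n_batches: int = 10,
    subsample: float = 0.8,
    seed: int = 0,
) -> tuple[int, np.ndarray, pd.Series]:
    """Most stable cluster number over a range of k.

    For each k, the full cohort is partitioned with the restart protocol
    and ``n_batches`` random patient subsamples are partitioned the same
    way; stability is the mean NMI between each subsample partition and
    the full partition restricted to the subsampled patients.  A k that
    carves real structure reproduces itself on subsamples; a k that
    merges or splits clusters arbitrarily does not.  The k with the
    highest stability wins, ties favouring the smaller k.

    Returns ``(k, labels, stability_scores)``.
    """
    F = np.asarray(F, dtype=float)
    if F.std() == 0:
        raise ValueError("degenerate features: all patients identical")
    if not 0 < subsample < 1:
        raise ValueError("subsample must be in (0, 1)")
    m = len(F)
    n_sub = max(2, int(round(subsample * m)))
    scores = {}
    full_parts = {}
    ss = np.random.SeedSequence(seed)
    for k in k_range:
        k_child, batch_child = ss.spawn(2)
        k_seed = int(k_child.generate_state(1)[0] % (2**31))
        full = best_kmeans(F, k, n_restarts, k_seed)
        full_parts[k] = full
        batch_scores = []
        for child in batch_child.spawn(n_batches):
            rng = np.random.default_rng(child)
            idx = rng.choice(m, size=n_sub, replace=False)
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            sub = best_kmeans(F[idx], k, n_restarts, sub_seed)
            batch_scores.append(nmi(full[idx], sub))
        scores[k] = float(np.mean(batch_scores))
    stability = pd.Series(scores, name="stability")
    best = max(stability.index, key=lambda k: (stability[k], -k))
    return int(best), full_parts[best], stability


# ---------------------------------------------------------------------------
# benchmark runner


def _representations(method: str, sim: SimulationOutput):
    """Feature matrix and patient-similarity matrix for one method.

    For the raw baselines the features are the (concatenated) data columns
    and the similarity is the Pearson correlation of those rows.  For the
    integrative variants the similarity IS the integrated matrix Z (the
    Pearson correlation of patients in the extracted feature space) and
    the downstream features are the rows of Z.
    """
    ds = sim.datasets
    if method == "data1":
        F = ds[0].to_numpy()
        return F, None
    if method == "data2":
        F = ds[1].to_numpy()
        return F, None
    if method in ("concat", "concatenation"):
        F = direct_concatenate(ds).to_numpy()
        return F, None
    if method in VARIANTS:
        Z = ibfe(ds, variant=method).to_numpy()
        return Z, Z
    raise ValueError(f"unknown method {method!r}; choose from {BENCHMARK_METHODS}")


@dataclass
class EvaluationReport:
    """Benchmark result: per-repeat metric values and their summary."""

    repeats: pd.DataFrame  # columns: repeat, method, metric, value
    config: dict

    @property
    def table(self) -> pd.DataFrame:
        """method x metric table of ``mean +/- sd`` across repeats."""
        g = self.repeats.groupby(["method", "metric"])["value"]
        summary = g.agg(["mean", "std"]).reset_index()
        return summary.pivot(index="method", columns="metric", values="mean")

    def summary(self) -> pd.DataFrame:
        g = self.repeats.groupby(["method", "metric"])["value"]
        return g.agg(["mean", "std", "count"]).reset_index()

    def mean(self, method: str, metric: str) -> float:
        sel = self.repeats[
            (self.repeats["method"] == method) & (self.repeats["metric"] == metric)
        ]["value"]
        if sel.empty:
            raise KeyError(f"no values for method={method!r}, metric={metric!r}")
        return float(sel.mean())

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "summary": self.summary().to_dict(orient="records"),
            "repeats": self.repeats.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def run_benchmark(
    scenario: str,
    methods: Sequence[str] = BENCHMARK_METHODS,
    n_repeats: int = 100,
    seed: int = 0,
    q: float | None = None,
    sigma_pair: tuple[float, float] = (0.5, 2.0),
    realistic: bool = False,
    metrics: Sequence[str] = METRICS,
    n_restarts: int = 1000,
    rf_estimators: int = 100,
    kernel_bandwidth: str | float = "median",
    nmi_normalization: str = "sqrt",
) -> EvaluationReport:
    """Repeat a scenario and score every method with every metric.

    Each repeat draws a fresh simulation (seeded deterministically from
    ``seed``), builds each method's representation and computes the
    requested metrics.  k-means uses k=2 for sd1-sd4 and k=4 for sd5.
    Unclassified patients of realistic draws take part in the
    representations but are excluded from label-dependent scoring.
    """
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}; choose from {METRICS}")
    for m in methods:
        if m not in BENCHMARK_METHODS and m != "concat":
            raise ValueError(f"unknown method {m!r}; choose from {BENCHMARK_METHODS}")
    k = 4 if scenario == "sd5" else 2
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_repeats)):
        sim_seed, km_seed, rf_seed = (int(s % (2**31)) for s in child.generate_state(3))
        sim = simulate(
            SimulationSpec(
                scenario=scenario,
                q=q,
                sigma_pair=sigma_pair,
                realistic=realistic,
                seed=sim_seed,
            )
        )
        classified = (~sim.unclassified_mask).to_numpy()
        truth = sim.true_labels.to_numpy()[classified]
        for method in methods:
            F, C = _representations(method, sim)
            if C is None:
                C = _row_correlation(F)
            values = {}
            if "pcc_intraclass" in metrics or "pcc_interclass" in metrics:
                intra, inter = intra_inter_similarity(
                    C[np.ix_(classified, classified)], truth
                )
                values["pcc_intraclass"], values["pcc_interclass"] = intra, inter
            if "sim_intraclass" in metrics or "sim_interclass" in metrics:
                intra, inter = gaussian_kernel_similarity(
                    F[classified], truth, bandwidth=kernel_bandwidth
                )
                values["sim_intraclass"], values["sim_interclass"] = intra, inter
            if "nmi_kmeans" in metrics:
                pred = best_kmeans(F, k, n_restarts=n_restarts, seed=km_seed)
                values["nmi_kmeans"] = nmi(
                    truth, pred[classified], normalization=nmi_normalization
                )
            if "acc_rfloo" in metrics:
                values["acc_rfloo"] = loo_rf_accuracy(
                    F[classified], truth, n_estimators=rf_estimators, seed=rf_seed
                )
            rows.extend(
                {"repeat": rep, "method": method, "metric": name, "value": val}
                for name, val in values.items()
                if name in metrics
            )
    config = {
        "scenario": scenario,
        "methods": list(methods),
        "n_repeats": n_repeats,
        "seed": seed,
        "q": q,
        "sigma_pair": list(sigma_pair),
        "realistic": realistic,
        "metrics": list(metrics),
        "k": k,
        "n_restarts": n_restarts,
        "rf_estimators": rf_estimators,
        "kernel_bandwidth": kernel_bandwidth,
        "nmi_normalization": nmi_normalization,
    }
    return EvaluationReport(repeats=pd.DataFrame(rows), config=config)
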