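"""Sequential three-test triage cascade over frame embeddings.

Each stage is a linear max-margin (hinge-loss, L2-regularized) classifier on
standardized frame features. Frames of a site are averaged into a site-level
prediction score, and the operating cut-off of each stage is chosen on a
held-out cross-validation split by maximizing Youden's J on the ROC curve.
The fitted cascade then routes every site through the decision tree:

    Test 1 (carcinoma vs rest)        positive -> refer_biopsy_oscc
    Test 2 (dysplasia vs normal/benign) negative -> routine_monitoring
    Test 3 (high- vs low-grade)       positive -> refer_biopsy_hgd
                                      negative -> surveillance_lgd

Splits are by site, never by frame: frames of one site are near-duplicates,
and letting them straddle the split would leak. This is deliberately
stricter than splitting individual images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    CutoffError,
    DomainError,
    StratificationError,
    TrainingError,
)

#: Stage definitions: (positive diagnoses, population diagnoses).
STAGES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "test1_oscc_vs_rest": (
        frozenset({"oscc"}),
        frozenset(
            {"oscc", "mild_dysplasia", "moderate_dysplasia", "severe_dysplasia",
             "normal", "benign"}
        ),
    ),
    "test2_dysplasia_vs_rest": (
        frozenset({"mild_dysplasia", "moderate_dysplasia", "severe_dysplasia"}),
        frozenset(
            {"mild_dysplasia", "moderate_dysplasia", "severe_dysplasia",
             "normal", "benign"}
        ),
    ),
    "test3_hgd_vs_lgd": (
        frozenset({"moderate_dysplasia", "severe_dysplasia"}),
        frozenset(
            {"mild_dysplasia", "moderate_dysplasia", "severe_dysplasia",
             "normal", "benign"}
        ),
    ),
}

TRIAGE_LABELS = (
    "refer_biopsy_oscc",
    "refer_biopsy_hgd",
    "surveillance_lgd",
    "routine_monitoring",
)


def split_train_cv(
    site_labels: pd.Series | dict[str, bool],
    fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Site-level stratified train/cv split.

    ``site_labels`` maps site_id -> binary stage label. Allocation uses
    largest remainders so the train side totals ``round(fraction * n)``
    while every stratum keeps at least one site on each side.
    """
    if not 0 < fraction < 1:
        raise DomainError("fraction must be in (0, 1)")
    labels = pd.Series(site_labels)
    rng = np.random.default_rng(seed)
    strata = {val: list(labels.index[labels == val]) for val in sorted(labels.unique())}
    for val, sites in strata.items():
        if len(sites) < 2:
            raise StratificationError(
                f"stratum {val!r} has {len(sites)} site(s); need >= 2 to split"
            )
    total_train = int(round(fraction * len(labels)))
    quotas = {v: fraction * len(s) for v, s in strata.items()}
    base = {v: min(max(int(np.floor(q)), 1), len(strata[v]) - 1) for v, q in quotas.items()}
    remaining = total_train - sum(base.values())
    order = sorted(quotas, key=lambda v: quotas[v] - np.floor(quotas[v]), reverse=True)
    for v in order:
        if remaining <= 0:
            break
        if base[v] < len(strata[v]) - 1:
            base[v] += 1
            remaining -= 1
    train: list[str] = []
    cv: list[str] = []
    for val, sites in strata.items():
        sites = sorted(sites)
        rng.shuffle(sites)
        k = base[val]
        train.extend(sites[:k])
        cv.extend(sites[k:])
    return sorted(train), sorted(cv)


class StageClassifier(BaseEstimator, ClassifierMixin):
    """Linear hinge-loss (max-margin) classifier over standardized features.

    The decision value ``w . x + b`` is the frame-level prediction score.
    """

    def __init__(self, c: float = 1.0, max_iter: int = 20000):
        self.c = c
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StageClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise TrainingError("training needs both classes present")
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            LinearSVC(C=self.c, loss="hinge", max_iter=self.max_iter),
        )
        self.pipeline_.fit(X, y)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def train_stage(X: np.ndarray, y: np.ndarray, c: float = 1.0) -> StageClassifier:
    """Functional wrapper over :class:`StageClassifier`."""
    return StageClassifier(c=c).fit(X, y)


def site_score(frame_scores: np.ndarray | list[float]) -> float:
    """Site-level prediction score: mean of the frame decision values."""
    arr = np.asarray(frame_scores, dtype=float)
    if arr.size == 0:
        raise DomainError("a site needs at least one frame decision value")
    return float(arr.mean())


def roc_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Youden-optimal cut-off from cv site scores.

    Candidate thresholds are midpoints between adjacent sorted unique scores
    plus +/- infinity; a site is called positive when ``score >= cutoff``.
    Ties in J break to the higher-sensitivity, then the smaller, threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.size != labels.size or scores.size == 0:
        raise DomainError("scores and labels must be non-empty and aligned")
    if labels.all() or not labels.any():
        raise CutoffError("cv labels contain a single class; no ROC exists")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise CutoffError("all cv scores identical; cut-off is undefined")
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None
    for t in candidates:
        called = scores >= t
        sens = (called & labels).sum() / n_pos
        spec = (~called & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


@dataclass
class FittedTest:
    """One cascade stage: trained classifier + ROC-derived cut-off."""

    stage: str
    classifier: StageClassifier
    cutoff: float
    n_train_sites: int
    n_cv_sites: int
    backend: str = "default"
    split_seed: int = 0


@dataclass
class SitePrediction:
    """Per-site cascade outcome."""

    site_id: str
    stage_scores: dict[str, float] = field(default_factory=dict)
    stage_calls: dict[str, bool] = field(default_factory=dict)
    final_label: str = ""


class TriageCascade(BaseEstimator):
    """Fit the three-stage triage cascade on a frame-level feature table.

    The feature table must carry ``site_id``, ``diagnosis`` and ``f###``
    feature columns (one row per frame, or per frame half when the mirror
    convention is on). ``fit`` trains each stage on its own site-stratified
    70/30 train/cv split and stores one :class:`FittedTest` per stage.
    """

    def __init__(
        self,
        train_fraction: float = 0.7,
        c: float = 1.0,
        seed: int = 0,
        backend: str = "default",
    ):
        self.train_fraction = train_fraction
        self.c = c
        self.seed = seed
        self.backend = backend

    @staticmethod
    def _features(table: pd.DataFrame) -> np.ndarray:
        cols = sorted(c for c in table.columns if c.startswith("f") and c[1:].isdigit())
        if not cols:
            raise ConfigurationError("feature table has no f### columns")
        return table[cols].to_numpy(dtype=float)

    def fit(self, table: pd.DataFrame, y: object = None) -> "TriageCascade":
        if "site_id" not in table.columns or "diagnosis" not in table.columns:
            raise ConfigurationError("feature table needs site_id and diagnosis columns")
        self.tests_ = {}
        for stage, (positives, population) in STAGES.items():
            sub = table[table["diagnosis"].isin(population)]
            site_label = (
                sub.groupby("site_id")["diagnosis"]
                .first()
                .isin(positives)
            )
            train_sites, cv_sites = split_train_cv(
                site_label, self.train_fraction, self.seed
            )
            tr = sub[sub["site_id"].isin(train_sites)]
            clf = StageClassifier(c=self.c).fit(
                self._features(tr), tr["diagnosis"].isin(positives).to_numpy()
            )
            cv = sub[sub["site_id"].isin(cv_sites)]
            dec = clf.decision_function(self._features(cv))
            cv_scores = (
                pd.Series(dec, index=cv["site_id"].to_numpy())
                .groupby(level=0)
                .mean()
            )
            cutoff = roc_cutoff(
                cv_scores.to_numpy(), site_label.loc[cv_scores.index].to_numpy()
            )
            self.tests_[stage] = FittedTest(
                stage=stage,
                classifier=clf,
                cutoff=cutoff,
                n_train_sites=len(train_sites),
                n_cv_sites=len(cv_sites),
                backend=self.backend,
                split_seed=self.seed,
            )
        return self

    def stage_site_scores(self, table: pd.DataFrame, stage: str) -> pd.Series:
        test = self.tests_[stage]
        dec = test.classifier.decision_function(self._features(table))
        return pd.Series(dec, index=table["site_id"].to_numpy()).groupby(level=0).mean()

    def predict(self, table: pd.DataFrame) -> list[SitePrediction]:
        """Run the sequential decision tree on every site in the table."""
        return run_cascade(self.tests_, table)


def run_cascade(
    tests: dict[str, FittedTest], table: pd.DataFrame
) -> list[SitePrediction]:
    """Route each site through the three-test decision tree.

    Stages after a decisive call are not evaluated (their scores stay
    absent), mirroring the sequential clinical workflow.
    """
    for stage in STAGES:
        if stage not in tests:
            raise ConfigurationError(f"cascade is missing fitted stage {stage!r}")
    cols = sorted(c for c in table.columns if c.startswith("f") and c[1:].isdigit())
    X = table[cols].to_numpy(dtype=float)
    site_ids = table["site_id"].to_numpy()

    def stage_scores(stage: str) -> pd.Series:
        dec = tests[stage].classifier.decision_function(X)
        return pd.Series(dec, index=site_ids).groupby(level=0).mean()

    s1 = stage_scores("test1_oscc_vs_rest")
    s2 = stage_scores("test2_dysplasia_vs_rest")
    s3 = stage_scores("test3_hgd_vs_lgd")

    out = []
    for sid in s1.index:
        pred = SitePrediction(site_id=str(sid))
        call1 = s1[sid] >= tests["test1_oscc_vs_rest"].cutoff
        pred.stage_scores["test1_oscc_vs_rest"] = float(s1[sid])
        pred.stage_calls["test1_oscc_vs_rest"] = bool(call1)
        if call1:
            pred.final_label = "refer_biopsy_oscc"
            out.append(pred)
            continue
        call2 = s2[sid] >= tests["test2_dysplasia_vs_rest"].cutoff
        pred.stage_scores["test2_dysplasia_vs_rest"] = float(s2[sid])
        pred.stage_calls["test2_dysplasia_vs_rest"] = bool(call2)
        if not call2:
            pred.final_label = "routine_monitoring"
            out.append(pred)
            continue
        call3 = s3[sid] >= tests["test3_hgd_vs_lgd"].cutoff
        pred.stage_scores["test3_hgd_vs_lgd"] = float(s3[sid])
        pred.stage_calls["test3_hgd_vs_lgd"] = bool(call3)
        pred.final_label = "refer_biopsy_hgd" if call3 else "surveillance_lgd"
        out.append(pred)
    return out


@dataclass
class CascadeEvaluation:
    """Per-stage and combined confusion counts of a cascade run."""

    per_stage: dict[str, dict[str, int]]
    combined: dict[str, dict[str, int]]


def evaluate_cascade(
    predictions: list[SitePrediction],
    truth: dict[str, str] | pd.Series,
    or_rule: bool = True,
) -> CascadeEvaluation:
    """Confusion counts per stage (on the population reaching it) + combined.

    Combined sensitivity treats a carcinoma site as detected when ANY stage
    flags it (``or_rule``), and a dysplastic site as detected when Test 1 or
    Test 2 flags it; combined specificity is the fraction of normal/benign
    sites routed to routine monitoring. With ``or_rule=False`` only the
    stage dedicated to each condition counts.
    """
    truth = pd.Series(truth)
    pred_sites = {p.site_id for p in predictions}
    if pred_sites != set(truth.index):
        raise AlignmentError("prediction and truth site sets differ")

    per_stage: dict[str, dict[str, int]] = {}
    for stage, (positives, population) in STAGES.items():
        counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for p in predictions:
            if stage not in p.stage_calls:
                continue  # site never reached this stage
            dx = truth[p.site_id]
            if dx not in population:
                continue
            is_pos = dx in positives
            called = p.stage_calls[stage]
            if is_pos and called:
                counts["TP"] += 1
            elif is_pos:
                counts["FN"] += 1
            elif called:
                counts["FP"] += 1
            else:
                counts["TN"] += 1
        per_stage[stage] = counts

    dysplasias = {"mild_dysplasia", "moderate_dysplasia", "severe_dysplasia"}
    combined: dict[str, dict[str, int]] = {
        "oscc": {"TP": 0, "FP": 0, "TN": 0, "FN": 0},
        "dysplasia": {"TP": 0, "FP": 0, "TN": 0, "FN": 0},
    }
    for p in predictions:
        dx = truth[p.site_id]
        any_flag = p.final_label != "routine_monitoring"
        t1 = p.stage_calls.get("test1_oscc_vs_rest", False)
        t2 = p.stage_calls.get("test2_dysplasia_vs_rest", False)
        oscc_detected = any_flag if or_rule else t1
        dys_detected = (t1 or t2) if or_rule else t2
        if dx == "oscc":
            combined["oscc"]["TP" if oscc_detected else "FN"] += 1
        elif dx in {"normal", "benign"}:
            combined["oscc"]["FP" if oscc_detected else "TN"] += 1
        if dx in dysplasias:
            combined["dysplasia"]["TP" if dys_detected else "FN"] += 1
        elif dx in {"normal", "benign"}:
            combined["dysplasia"]["FP" if dys_detected else "TN"] += 1
    return CascadeEvaluation(per_stage=per_stage, combined=combined)
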