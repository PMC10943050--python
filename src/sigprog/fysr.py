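"""Five-year-survival (FYSR) prediction by repeated-subsampling random forests.

Training samples are the five-year survivors (G1, positive class) and the
under-five-year deaths (G2, negative class); features are the gene-level
CCA scores of the prognosis-related signatures.  Each round draws 95% of
cases without replacement (stratified by class), fits a random forest and
scores it by its out-of-bag AUC.  Rounds clearing the AUC gate (default
0.9) vote for their high-importance features; features voted in more than
half of the passing rounds become the biomarker panel, and a final forest
is refit on all cases with just those features.  Model accuracy is
summarized as ROC/AUC with a bootstrap (or DeLong) 95% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Knobs of the repeated-subsampling selection procedure.

    ``subsample_fraction`` is the share of cases drawn per round (0.95),
    ``auc_gate`` the out-of-bag AUC a round must exceed to vote, and
    ``freq_gate`` the vote frequency a feature must exceed to be selected.
    ``importance_rule`` is "mean" (importance above the round's mean) or
    "top_k" with ``top_k`` features per round.
    """

    subsample_fraction: float = 0.95
    n_rounds: int = 100
    auc_gate: float = 0.9
    freq_gate: float = 0.5
    n_trees: int = 500
    max_depth: int | None = None
    max_features: str | float = "sqrt"
    importance_rule: str = "mean"
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not (0 <= self.freq_gate <= 1):
            raise ValueError("freq_gate must be in [0, 1]")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


@dataclass
class BiomarkerSelection:
    feature_name: str
    selection_count: int
    frequency: float
    selected: bool


@dataclass
class FYSRModel:
    selected_features: list[BiomarkerSelection]
    ensemble: RandomForestClassifier
    config: TrainingConfig
    feature_names: list[str]
    n_passing_rounds: int
    n_rounds: int

    def selection_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": b.feature_name,
                    "count": b.selection_count,
                    "frequency": b.frequency,
                    "selected": b.selected,
                }
                for b in self.selected_features
            ]
        )

    @property
    def biomarkers(self) -> list[str]:
        return [b.feature_name for b in self.selected_features if b.selected]


@dataclass
class ROCSummary:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    method: str = "bootstrap"


def _as_binary(labels) -> np.ndarray:
    """Map labels to {0, 1} with G1 (five-year survivor) as positive."""
    y = pd.Series(labels)
    if y.dtype == object or str(y.dtype).startswith("str"):
        mapping = {"G1": 1, "G2": 0}
        bad = set(y.unique()) - set(mapping)
        if bad:
            raise ValueError(f"labels must be G1/G2 or 0/1, got {sorted(bad)}")
        y = y.map(mapping)
    y = y.astype(int).to_numpy()
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("binary labels must be 0/1")
    return y


def _oob_auc(forest: RandomForestClassifier, y: np.ndarray) -> float:
    proba = forest.oob_decision_function_[:, list(forest.classes_).index(1)]
    ok = ~np.isnan(proba)
    if len(np.unique(y[ok])) < 2:
        return float("nan")
    return float(roc_auc_score(y[ok], proba[ok]))


def train_fysr(
    features: pd.DataFrame,
    labels,
    config: TrainingConfig | None = None,
) -> FYSRModel:
    """Run the repeated-subsampling selection and fit the final forest.

    Each round draws ``subsample_fraction`` of cases without replacement,
    stratified so both classes survive the draw, fits a forest, and — if
    its out-of-bag AUC exceeds ``auc_gate`` — votes for the features whose
    impurity importance clears the round's rule.  Features with vote
    frequency above ``freq_gate`` form the biomarker panel of the final
    forest, refit on all cases.  Fully deterministic given the seed.
    """
    config = config or TrainingConfig()
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes (G1 and G2) must be present for training")
    X = features.astype(float)
    names = list(X.columns)

    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_rounds + 1)
    counts = np.zeros(len(names), dtype=int)
    n_passing = 0
    for r in range(config.n_rounds):
        rs = int(seeds[r] % (2**31 - 1))
        if config.subsample_fraction < 1.0:
            Xs, _, ys, _ = train_test_split(
                X,
                y,
                train_size=config.subsample_fraction,
                stratify=y,
                random_state=rs,
            )
        else:
            Xs, ys = X, y
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_features=config.max_features,
            oob_score=True,
            random_state=rs,
            n_jobs=1,
        )
        forest.fit(Xs, ys)
        round_auc = _oob_auc(forest, ys)
        if not np.isnan(round_auc) and round_auc > config.auc_gate:
            n_passing += 1
            imp = forest.feature_importances_
            if config.importance_rule == "mean":
                chosen = imp > imp.mean()
            elif config.importance_rule == "top_k":
                chosen = np.zeros(len(imp), dtype=bool)
                chosen[np.argsort(-imp, kind="stable")[: config.top_k]] = True
            else:
                raise ValueError("importance_rule must be 'mean' or 'top_k'")
            counts += chosen

    if n_passing == 0:
        raise RuntimeError(
            f"no round reached out-of-bag AUC > {config.auc_gate}; relax "
            "auc_gate or check that the features carry signal"
        )

    freq = counts / n_passing
    selection = [
        BiomarkerSelection(n, int(c), float(f), bool(f > config.freq_gate))
        for n, c, f in zip(names, counts, freq)
    ]
    selected = [b.feature_name for b in selection if b.selected]
    if not selected:
        raise RuntimeError(
            "no feature exceeded the selection-frequency gate; relax freq_gate"
        )

    final_rs = int(seeds[-1] % (2**31 - 1))
    final = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features=config.max_features,
        oob_score=True,
        random_state=final_rs,
        n_jobs=1,
    )
    final.fit(X[selected], y)
    return FYSRModel(
        selected_features=selection,
        ensemble=final,
        config=config,
        feature_names=selected,
        n_passing_rounds=n_passing,
        n_rounds=config.n_rounds,
    )


def predict_fysr(model: FYSRModel, features: pd.DataFrame) -> pd.Series:
    """Score samples with the trained model; returns P(five-year survival).

    Feature columns are reconciled by name with the model's biomarker
    panel; columns the input lacks are zero-filled with a warning.
    """
    X = pd.DataFrame(index=features.index)
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        logger.warning(
            "%d model feature(s) absent from input, zero-filled: %s",
            len(missing),
            missing[:5],
        )
    for c in model.feature_names:
        X[c] = features[c].astype(float) if c in features.columns else 0.0
    pos = list(model.ensemble.classes_).index(1)
    scores = model.ensemble.predict_proba(X)[:, pos]
    return pd.Series(scores, index=features.index, name="fysr_score")


# ---------------------------------------------------------------------------
# ROC / AUC with confidence interval


def _delong_ci(scores: np.ndarray, y: np.ndarray, alpha: float = 0.05):
    """DeLong variance of the AUC via midranks (Sun & Xu fast form)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)

    def midrank(x):
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x))
        sx = x[order]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and sx[j] == sx[i]:
                j += 1
            ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
            i = j
        return ranks

    all_r = midrank(np.concatenate([pos, neg]))
    pos_r = midrank(pos)
    neg_r = midrank(neg)
    auc_val = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (all_r[:m] - pos_r) / n
    v10 = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    se = np.sqrt(max(var, 0.0))
    z = norm.ppf(1 - alpha / 2)
    return float(auc_val), float(auc_val - z * se), float(auc_val + z * se)


def roc_with_ci(
    scores,
    labels,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ROCSummary:
    """Empirical ROC curve and trapezoidal AUC with a 95% CI.

    The default CI is a class-stratified percentile bootstrap; DeLong's
    asymptotic interval is available as ``ci_method="delong"``.  Bounds are
    clipped to [0, 1].
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to compute an ROC")
    fpr, tpr, _ = roc_curve(y, s)
    auc_val = float(_trapezoid_auc(fpr, tpr))

    if ci_method == "delong":
        _, lo, hi = _delong_ci(s, y, alpha)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_i = np.flatnonzero(y == 1)
        neg_i = np.flatnonzero(y == 0)
        stats = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_i, size=len(pos_i), replace=True)
            ni = rng.choice(neg_i, size=len(neg_i), replace=True)
            idx = np.concatenate([pi, ni])
            stats[b] = roc_auc_score(y[idx], s[idx])
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError("ci_method must be 'bootstrap' or 'delong'")

    return ROCSummary(
        auc=auc_val,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        fpr=fpr,
        tpr=tpr,
        method=ci_method,
    )
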