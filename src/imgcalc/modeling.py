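"""Regression machinery for imageability prediction.

Ordinary least squares with classical inference (via statsmodels),
backwards elimination down to a target predictor count, split-half
validation, application of the published coefficient tables to new words,
the CONTEXT/EMOTIONALITY composite scores, and the random-word control
analysis that probes whether arbitrary word sets can stand in for emotion
terms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources as importlib_resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .corpus import CoocSpace
from .features import emotion_similarity_table

logger = logging.getLogger(__name__)


class RankDeficientError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class RegressionModel:
    """An OLS fit: coefficients with inference and fit statistics.

    AIC uses the Gaussian log-likelihood including its constant term, so
    only AIC *differences* between models on the same data are meaningful.
    """

    predictors: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    intercept: float
    intercept_se: float
    r2: float
    aic: float
    n: int
    provenance: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        missing = [p for p in self.predictors if p not in X.columns]
        if missing:
            raise KeyError(f"missing predictor columns: {missing}")
        yhat = np.full(len(X), self.intercept, dtype=float)
        for p in self.predictors:
            yhat += self.coef[p] * X[p].to_numpy(dtype=float)
        return pd.Series(yhat, index=X.index, name="predicted")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RegressionModel":
        return cls(**json.loads(text))


def fit_ols(X: pd.DataFrame, y: pd.Series | np.ndarray,
            provenance: dict | None = None) -> RegressionModel:
    """OLS with intercept, classical SEs and two-sided t tests.

    Raises :class:`RankDeficientError` naming collinear columns when the
    design matrix (with constant) is rank deficient.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values in regression inputs")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        cols: list[np.ndarray] = []
        for name in design.columns:
            trial = np.column_stack(cols + [design[name].to_numpy()])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(name)
            else:
                cols.append(design[name].to_numpy())
        raise RankDeficientError(f"collinear columns: {bad}")
    res = sm.OLS(y, design).fit()
    names = list(X.columns)
    return RegressionModel(
        predictors=names,
        coef={k: float(res.params[k]) for k in names},
        se={k: float(res.bse[k]) for k in names},
        tvalues={k: float(res.tvalues[k]) for k in names},
        pvalues={k: float(res.pvalues[k]) for k in names},
        intercept=float(res.params["const"]),
        intercept_se=float(res.bse["const"]),
        r2=float(res.rsquared),
        aic=float(res.aic),
        n=int(n),
        provenance=provenance or {},
    )


def backwards_eliminate(X: pd.DataFrame, y: pd.Series | np.ndarray,
                        k: int, provenance: dict | None = None
                        ) -> RegressionModel:
    """Backwards stepwise elimination to ``k`` predictors.

    At each step the predictor with the largest p-value is removed
    (p-value ties broken by predictor name, alphabetically last removed
    first) and the model refit.  The removal order is recorded in the
    returned model's provenance under ``elimination_trace``.
    """
    X = pd.DataFrame(X)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must be in [1, {X.shape[1]}], got {k}")
    trace: list[dict] = []
    cols = list(X.columns)
    model = fit_ols(X[cols], y)
    while len(cols) > k:
        # largest p first; ties broken deterministically by name
        worst = max(cols, key=lambda c: (model.pvalues[c], c))
        trace.append({"removed": worst, "p": model.pvalues[worst],
                      "remaining": len(cols) - 1})
        cols.remove(worst)
        model = fit_ols(X[cols], y)
    prov = dict(provenance or {})
    prov["elimination_trace"] = trace
    model.provenance = prov
    return model


def split_half(table: pd.DataFrame, seed: int = 0
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random partition into a test half and a validation half.

    Halves differ in size by at most one row; deterministic under seed.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    cut = len(table) // 2
    test = table.iloc[np.sort(perm[:cut + len(table) % 2])]
    valid = table.iloc[np.sort(perm[cut + len(table) % 2:])]
    return test, valid


# ---------------------------------------------------------------------------
# published coefficient tables


@dataclass(frozen=True)
class PretrainedCoefficients:
    """A published coefficient table: intercept + per-predictor records."""

    name: str
    intercept: float
    coef: dict[str, float]
    se: dict[str, float]
    tvalues: dict[str, float]
    r2: float
    n: int

    @property
    def predictors(self) -> list[str]:
        return list(self.coef)


def _load_pretrained_raw() -> dict:
    ref = (importlib_resources.files("imgcalc.resources")
           / "pretrained_models.json")
    return json.loads(ref.read_text())


def load_pretrained(name: str) -> PretrainedCoefficients:
    """Load one of the published models.

    ``context_density`` (ARC + INV-NCOUNT), ``eight_emotion`` (8 emotion
    terms), or ``full`` (7 emotion terms + density + lexical covariates).
    """
    data = _load_pretrained_raw()
    try:
        m = data["models"][name]
    except KeyError:
        raise KeyError(f"unknown pretrained model {name!r}; "
                       f"choose from {list(data['models'])}") from None
    preds = m["predictors"]
    return PretrainedCoefficients(
        name=name,
        intercept=m["intercept"]["estimate"],
        coef={k: v["estimate"] for k, v in preds.items()},
        se={k: v["se"] for k, v in preds.items()},
        tvalues={k: v["t"] for k, v in preds.items()},
        r2=m["r2"],
        n=m["n"],
    )


def composite_dimension_terms() -> dict[str, list[str]]:
    """Predictor names feeding each composite dimension (context,
    emotionality) of the full published model."""
    return {k: list(v)
            for k, v in _load_pretrained_raw()["composite_dimensions"].items()}


def apply_pretrained(features: pd.DataFrame,
                     model: PretrainedCoefficients) -> pd.Series:
    """Predicted imageability (1-7 judgment scale) per word, unclamped.

    Values outside [1, 7] are kept and logged: the linear score is the
    quantity of interest, not a clamped rating.
    """
    missing = [p for p in model.predictors if p not in features.columns]
    if missing:
        raise KeyError(f"missing predictor columns: {missing}")
    yhat = np.full(len(features), model.intercept, dtype=float)
    for p in model.predictors:
        yhat += model.coef[p] * features[p].to_numpy(dtype=float)
    out = pd.Series(yhat, index=features.index, name="predicted_imageability")
    outside = int(((out < 1) | (out > 7)).sum())
    if outside:
        logger.info("%d predictions fall outside the 1-7 scale (kept)", outside)
    return out


def composite_scores(features: pd.DataFrame,
                     model: PretrainedCoefficients | None = None
                     ) -> pd.DataFrame:
    """CONTEXT and EMOTIONALITY composites with z-scored variants.

    CONTEXT is the β-weighted sum of the density measures (arc,
    inv_ncount); EMOTIONALITY the β-weighted sum of the emotion-term
    similarities, using the full published model's weights by default.
    z-scoring is over the input set and requires nonzero spread.
    """
    model = model or load_pretrained("full")
    dims = composite_dimension_terms()
    out = pd.DataFrame(index=features.index)
    for dim, terms in dims.items():
        terms = [t for t in terms if t in model.coef]
        missing = [t for t in terms if t not in features.columns]
        if missing:
            raise KeyError(f"missing columns for {dim} composite: {missing}")
        score = np.zeros(len(features))
        for t in terms:
            score += model.coef[t] * features[t].to_numpy(dtype=float)
        out[f"{dim}_score"] = score
        sd = out[f"{dim}_score"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(
                f"cannot z-score {dim} composite: zero or undefined spread")
        mean = out[f"{dim}_score"].mean()
        out[f"{dim}_z"] = (out[f"{dim}_score"] - mean) / sd
    return out


# ---------------------------------------------------------------------------
# random-word control


@dataclass
class RandomControlReport:
    """Outcome of the random seed-set control analysis.

    Per sampled set: the test-half and validation-half correlations of the
    selected k-word model.  Pooled across all selected predictors: the
    correlation between their fitted β and a sign-weighted summed
    similarity to the reference emotion terms (the "valence proxy").
    """

    per_set: pd.DataFrame  # columns: set, test_r, validate_r
    beta_proxy_r: float
    betas: pd.DataFrame  # columns: set, word, beta, proxy
    seed: int


def random_control_analysis(space: CoocSpace, norms: pd.DataFrame,
                            emotion_terms: Sequence[str],
                            emotion_weights: dict[str, float] | None = None,
                            n_sets: int = 10, set_size: int = 78, k: int = 8,
                            freq_window: tuple[float, float] = (10.0, 500.0),
                            seed: int = 0) -> RandomControlReport:
    """Can random word sets predict imageability as emotion terms do?

    Samples ``n_sets`` disjoint sets of ``set_size`` words of medium
    frequency (``freq_window`` in occurrences per million), excluding the
    emotion terms and the normed words.  For each set: similarity features
    to the sampled words, backwards elimination to ``k`` on the test half
    of the norms, correlation of predictions with ratings on both halves.
    Finally correlates all selected βs with each word's sign-weighted
    summed similarity to the emotion terms.
    """
    if emotion_weights is None:
        pre = load_pretrained("eight_emotion")
        emotion_weights = pre.coef
    rng = np.random.default_rng(seed)

    total = space.frequency.total
    per_million = {w: c * 1e6 / total for w, c in space.frequency.counts.items()}
    normed = set(norms["word"])
    excluded = set(emotion_terms) | normed
    eligible = [w for w in space.vocabulary
                if w not in excluded
                and freq_window[0] <= per_million.get(w, 0) <= freq_window[1]]
    need = n_sets * set_size
    if len(eligible) < need:
        raise ValueError(
            f"insufficient eligible vocabulary: need {need}, have "
            f"{len(eligible)} in the {freq_window} per-million window")
    chosen = rng.choice(len(eligible), size=need, replace=False)
    sets = [[eligible[i] for i in chosen[s * set_size:(s + 1) * set_size]]
            for s in range(n_sets)]

    usable_emo = [t for t in emotion_weights if t in space]
    signed = {t: np.sign(emotion_weights[t]) for t in usable_emo}

    test, valid = split_half(norms, seed=seed)
    per_set_rows, beta_rows = [], []
    for s, words in enumerate(sets):
        feats_test = emotion_similarity_table(
            space, list(test["word"]), words)
        feats_valid = emotion_similarity_table(
            space, list(valid["word"]), words)
        y_test = test.set_index("word").loc[feats_test.index, "rating"]
        y_valid = valid.set_index("word").loc[feats_valid.index, "rating"]
        model = backwards_eliminate(feats_test, y_test, k=k,
                                    provenance={"set": s, "seed": seed})
        pred_t = model.predict(feats_test)
        pred_v = model.predict(feats_valid[model.predictors])
        test_r = float(np.corrcoef(pred_t, y_test)[0, 1])
        valid_r = float(np.corrcoef(pred_v, y_valid)[0, 1])
        per_set_rows.append((s, test_r, valid_r))

        emo_sims = emotion_similarity_table(space, model.predictors, usable_emo)
        for w in model.predictors:
            proxy = float(sum(signed[t] * emo_sims.loc[w, t]
                              for t in emo_sims.columns))
            beta_rows.append((s, w, model.coef[w], proxy))

    per_set = pd.DataFrame(per_set_rows, columns=["set", "test_r", "validate_r"])
    betas = pd.DataFrame(beta_rows, columns=["set", "word", "beta", "proxy"])
    if len(betas) >= 2 and betas["beta"].std() > 0 and betas["proxy"].std() > 0:
        beta_proxy_r = float(np.corrcoef(betas["beta"], betas["proxy"])[0, 1])
    else:
        beta_proxy_r = float("nan")
    return RandomControlReport(per_set=per_set, beta_proxy_r=beta_proxy_r,
                               betas=betas, seed=seed)
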