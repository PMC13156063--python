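"""Feature fusion and subject-level repeated cross-validated SVM evaluation.

The feature table fuses three blocks per subject: temporal (per-band,
per-channel complexity), frequency (per-band, per-channel power), and
spatial (gated directed connectivity entries plus nodal graph metrics).
Evaluation is stratified subject-level k-fold, repeated, with
standardization fit on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .network_metrics import NODAL_METRICS

BLOCKS = ("T", "F", "S")
POSITIVE_CLASS = "ASD-like"


class AssemblyError(ValueError):
    pass


@dataclass
class CVResult:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    ci: dict[str, tuple[float, float]]
    per_repetition: pd.DataFrame
    config: dict = field(default_factory=dict)


def assemble_features(
    lzc: pd.DataFrame,
    powers: pd.DataFrame,
    conn: pd.DataFrame,
    graph_nodal: pd.DataFrame,
    groups: dict[str, str],
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta"),
) -> pd.DataFrame:
    """Fuse per-subject blocks into one wide table.

    Inputs are long-format frames: lzc (subject, band, channel, lzc), powers
    (subject, band, channel, power), conn (subject, band, source, target,
    value), graph_nodal (subject, band, node, metric, value). With 8
    channels and 4 bands the result has 32 + 32 + 224 + 128 = 416 feature
    columns plus ``subject`` and ``group``.
    """
    subjects = sorted(groups)
    channels = sorted(lzc["channel"].unique())
    channels = [c for c in channels if c != "whole_brain"]

    def block_T(sub: str) -> dict[str, float]:
        d = lzc[(lzc.subject == sub) & (lzc.channel != "whole_brain")]
        out = {}
        for b in bands:
            for ch in channels:
                v = d.loc[(d.band == b) & (d.channel == ch), "lzc"]
                if v.empty:
                    raise AssemblyError(f"subject {sub}: missing T block entry {b}/{ch}")
                out[f"T__{b}__{ch}"] = float(v.iloc[0])
        return out

    def block_F(sub: str) -> dict[str, float]:
        d = powers[powers.subject == sub]
        out = {}
        for b in bands:
            for ch in channels:
                v = d.loc[(d.band == b) & (d.channel == ch), "power"]
                if v.empty:
                    raise AssemblyError(f"subject {sub}: missing F block entry {b}/{ch}")
                out[f"F__{b}__{ch}"] = float(v.iloc[0])
        return out

    def block_S(sub: str) -> dict[str, float]:
        out = {}
        dc = conn[conn.subject == sub]
        for b in bands:
            db = dc[dc.band == b]
            if db.empty:
                raise AssemblyError(f"subject {sub}: missing {b} connectivity block")
            for src in channels:
                for tgt in channels:
                    if src == tgt:
                        continue
                    v = db.loc[(db.source == src) & (db.target == tgt), "value"]
                    if v.empty:
                        raise AssemblyError(
                            f"subject {sub}: missing connectivity {b} {src}->{tgt}"
                        )
                    out[f"S__conn__{b}__{src}__{tgt}"] = float(v.iloc[0])
        dg = graph_nodal[graph_nodal.subject == sub]
        for b in bands:
            for metric in NODAL_METRICS:
                for ch in channels:
                    v = dg.loc[
                        (dg.band == b) & (dg.metric == metric) & (dg.node == ch), "value"
                    ]
                    if v.empty:
                        raise AssemblyError(
                            f"subject {sub}: missing nodal metric {b}/{metric}/{ch}"
                        )
                    out[f"S__graph__{b}__{metric}__{ch}"] = float(v.iloc[0])
        return out

    rows = []
    for sub in subjects:
        row: dict[str, object] = {"subject": sub, "group": groups[sub]}
        row.update(block_T(sub))
        row.update(block_F(sub))
        row.update(block_S(sub))
        rows.append(row)
    df = pd.DataFrame(rows)
    # NaN values (unassigned individualized bands, undefined nodal path
    # lengths on edgeless graphs) become column medians; columns that are
    # entirely undefined fall back to 0.
    feat_cols = [c for c in df.columns if c not in ("subject", "group")]
    df[feat_cols] = df[feat_cols].fillna(df[feat_cols].median()).fillna(0.0)
    return df


def block_columns(features: pd.DataFrame, blocks: tuple[str, ...]) -> list[str]:
    cols = []
    for c in features.columns:
        if c in ("subject", "group"):
            continue
        if c.split("__", 1)[0] in blocks:
            cols.append(c)
    if not cols:
        raise AssemblyError(f"no feature columns for blocks {blocks}")
    return cols


def _metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    pos = y_true == 1
    neg = ~pos
    tp = int((y_pred[pos] == 1).sum())
    tn = int((y_pred[neg] == 0).sum())
    fp = int((y_pred[neg] == 1).sum())
    fn = int((y_pred[pos] == 0).sum())
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    prec = tp / max(tp + fp, 1)
    f1 = 2 * prec * sens / max(prec + sens, 1e-12)
    return dict(
        accuracy=(tp + tn) / len(y_true),
        sensitivity=sens,
        specificity=spec,
        f1=f1,
        auc=roc_auc_score(y_true, scores),
    )


def _t_ci(vals: np.ndarray) -> tuple[float, float]:
    m = vals.mean()
    if len(vals) < 2 or vals.std(ddof=1) == 0:
        return (float(m), float(m))
    half = stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
    return (float(m - half), float(m + half))


def cv_evaluate(
    features: pd.DataFrame,
    blocks: tuple[str, ...] = BLOCKS,
    reps: int = 5,
    folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> CVResult:
    """Stratified subject-level repeated k-fold SVM-RBF evaluation.

    Standardization is fit on training subjects only; predictions are pooled
    per repetition and 95% CIs are t-based across repetitions. Asserts that
    no subject appears in both train and test of any fold.
    """
    cols = feature_cols if feature_cols is not None else block_columns(features, blocks)
    X = features[cols].to_numpy(dtype=np.float64)
    y = (features["group"] == POSITIVE_CLASS).to_numpy(dtype=int)
    subjects = features["subject"].to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} subjects per class for {folds}-fold stratification"
        )
    rep_rows = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        y_true = np.empty_like(y)
        y_pred = np.empty_like(y)
        scores = np.empty(len(y))
        for tr, te in skf.split(X, y):
            assert not set(subjects[tr]) & set(subjects[te]), "subject leakage across folds"
            model = make_pipeline(
                StandardScaler(), SVC(C=C, kernel="rbf", gamma="auto")
            )
            model.fit(X[tr], y[tr])
            y_true[te] = y[te]
            y_pred[te] = model.predict(X[te])
            scores[te] = model.decision_function(X[te])
        rep_rows.append(dict(repetition=rep, **_metrics(y_true, y_pred, scores)))
    per_rep = pd.DataFrame(rep_rows)
    ci = {k: _t_ci(per_rep[k].to_numpy()) for k in
          ("accuracy", "sensitivity", "specificity", "f1", "auc")}
    return CVResult(
        accuracy=float(per_rep.accuracy.mean()),
        sensitivity=float(per_rep.sensitivity.mean()),
        specificity=float(per_rep.specificity.mean()),
        f1=float(per_rep.f1.mean()),
        auc=float(per_rep.auc.mean()),
        ci=ci,
        per_repetition=per_rep,
        config=dict(kernel="rbf", C=C, gamma="auto (1/n_features)",
                    reps=reps, folds=folds, seed=seed, blocks=list(blocks),
                    n_features=len(cols)),
    )


ABLATION_SETS: tuple[tuple[str, ...], ...] = (
    ("T",), ("F",), ("S",), ("T", "F"), ("T", "F", "S")
)


def ablation(
    features: pd.DataFrame,
    block_sets: tuple[tuple[str, ...], ...] = ABLATION_SETS,
    reps: int = 5,
    folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """cv_evaluate per block combination with shared fold seeds."""
    rows = []
    for blocks in block_sets:
        res = cv_evaluate(features, blocks=blocks, reps=reps, folds=folds, C=C, seed=seed)
        rows.append(
            {
                "combination": "+".join(blocks),
                "accuracy": res.accuracy,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "f1": res.f1,
                "auc": res.auc,
            }
        )
    return pd.DataFrame(rows)


def baseline_demographics(
    age: np.ndarray,
    sex: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray | None = None,
    reps: int = 5,
    folds: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> CVResult:
    """Same CV protocol on a 2-column age/sex table."""
    n = len(age)
    if subjects is None:
        subjects = np.array([f"sub-{i:03d}" for i in range(n)])
    df = pd.DataFrame(
        {
            "subject": subjects,
            "group": labels,
            "D__age": np.asarray(age, dtype=np.float64),
            "D__sex": (np.asarray(sex) == "M").astype(float),
        }
    )
    return cv_evaluate(
        df, blocks=("D",), reps=reps, folds=folds, C=C, seed=seed,
        feature_cols=["D__age", "D__sex"],
    )
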