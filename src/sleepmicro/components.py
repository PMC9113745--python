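"""Principal spectral component (PSC) reduction and the joint classifier.

High-dimensional metric grids (e.g. 57 channels × 79 frequency bins of
power) are summarized by the SVD of the column-centered subject × feature
matrix A = U Σ Vᵀ: columns of U are orthogonal component scores, Σ carries
the variance accounted for, and V maps components back to features.
Components explaining at least 1% of total variance are retained, and those
additionally showing a group difference at nominal p < 0.01 (logistic,
age/sex-adjusted, on age/sex-residualized scores) enter a joint logistic
case/control model. New cohorts are projected into the training component
space via U_B = (B − training means) · V · Σ⁻¹, so component k indexes the
same pattern of variability in both cohorts.

Classifier discrimination is reported as the apparent AUC together with a
bootstrap optimism-corrected AUC and Nagelkerke R² (refit on each bootstrap
resample, evaluated on the resample and on the original data; the mean
difference is the optimism subtracted from the apparent values).

Component signs are not identified by the SVD; each component is oriented
so that its largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import _batched_logit_wald

__all__ = [
    "PSCModel",
    "JointModelResult",
    "psc_fit",
    "psc_project",
    "select_components",
    "joint_fit_predict",
    "bootstrap_optimism",
    "save_psc",
    "load_psc",
]


@dataclass
class PSCModel:
    feature_names: list
    column_means: np.ndarray  # (m,)
    singular_values: np.ndarray  # (k,)
    right_vectors: np.ndarray  # V, (m, k)
    variance_explained: np.ndarray  # percent, sums to 100
    scores: np.ndarray  # training U, (n, k)
    retained: np.ndarray  # bool, variance >= threshold

    @property
    def n_components(self) -> int:
        return len(self.singular_values)


@dataclass
class JointModelResult:
    selected: np.ndarray  # component indices
    coef: np.ndarray  # intercept + per-component logistic coefficients
    train_probabilities: np.ndarray
    test_probabilities: np.ndarray | None
    apparent_auc: float
    test_auc: float | None
    flagged: bool = False


def psc_fit(
    feature_matrix: np.ndarray,
    feature_names: list | None = None,
    var_threshold: float = 0.01,
) -> PSCModel:
    """SVD of the column-centered feature matrix.

    Retains the bookkeeping needed for out-of-sample projection (training
    column means, Σ, V). ``retained`` marks components explaining at least
    ``var_threshold`` (default 1%) of total variance.
    """
    a = np.asarray(feature_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 subjects")
    if not np.isfinite(a).all():
        raise ValueError("feature matrix contains non-finite entries; impute upstream")
    means = a.mean(axis=0)
    u, s, vt = np.linalg.svd(a - means, full_matrices=False)
    # drop numerically-null directions (centering removes one rank; keeping
    # them would make out-of-sample projection divide by ~0)
    k = int(np.sum(s > (s[0] if s.size else 0.0) * 1e-8))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    v = vt.T
    # sign convention: largest-magnitude loading of each component positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    u = u * flip
    var = s ** 2
    var_pct = 100.0 * var / var.sum() if var.sum() > 0 else var
    return PSCModel(
        feature_names=list(feature_names) if feature_names is not None
        else list(range(a.shape[1])),
        column_means=means,
        singular_values=s,
        right_vectors=v,
        variance_explained=var_pct,
        scores=u * s,  # score columns on the singular-value scale
        retained=var_pct >= 100.0 * var_threshold,
    )


def psc_project(new_matrix: np.ndarray, model: PSCModel) -> np.ndarray:
    """Project a new cohort into the training component space.

    Centers with the *training* column means, then U_B = B_c · V · Σ⁻¹.
    Scores are returned on the U scale (unit-norm training components), the
    same scale as ``unit_scores``.
    """
    b = np.asarray(new_matrix, dtype=float)
    if b.ndim != 2 or b.shape[1] != len(model.column_means):
        raise ValueError("feature grid mismatch with the fitted model")
    with np.errstate(divide="ignore"):
        inv_s = np.where(model.singular_values > 0, 1.0 / model.singular_values, 0.0)
    return (b - model.column_means) @ model.right_vectors * inv_s


def unit_scores(model: PSCModel) -> np.ndarray:
    """Training scores on the U scale (columns with unit norm)."""
    with np.errstate(divide="ignore"):
        inv_s = np.where(model.singular_values > 0, 1.0 / model.singular_values, 0.0)
    return model.scores * inv_s


def save_psc(model: PSCModel, directory) -> None:
    """Serialize a fitted model: JSON (means, Σ, variance %) + TSV for V."""
    import json
    from pathlib import Path

    import pandas as pd

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "psc_model.json").write_text(json.dumps({
        "feature_names": [str(f) for f in model.feature_names],
        "column_means": model.column_means.tolist(),
        "singular_values": model.singular_values.tolist(),
        "variance_explained": model.variance_explained.tolist(),
        "retained": model.retained.astype(int).tolist(),
    }))
    pd.DataFrame(
        model.right_vectors,
        index=[str(f) for f in model.feature_names],
        columns=[f"PSC{i + 1}" for i in range(model.n_components)],
    ).to_csv(d / "psc_loadings.tsv", sep="\t")


def load_psc(directory) -> PSCModel:
    """Load a model written by :func:`save_psc` (training scores not stored)."""
    import json
    from pathlib import Path

    import pandas as pd

    d = Path(directory)
    meta = json.loads((d / "psc_model.json").read_text())
    v = pd.read_csv(d / "psc_loadings.tsv", sep="\t", index_col=0).to_numpy()
    return PSCModel(
        feature_names=meta["feature_names"],
        column_means=np.asarray(meta["column_means"]),
        singular_values=np.asarray(meta["singular_values"]),
        right_vectors=v,
        variance_explained=np.asarray(meta["variance_explained"]),
        scores=np.zeros((0, v.shape[1])),
        retained=np.asarray(meta["retained"], dtype=bool),
    )


def _residualize(scores: np.ndarray, age: np.ndarray, sex01: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(age), age, sex01])
    beta, *_ = np.linalg.lstsq(x, scores, rcond=None)
    return scores - x @ beta


def _encode_y_sex(group, sex):
    from .stats import _encode

    return _encode(group, sex)


def select_components(
    model: PSCModel,
    group,
    age,
    sex,
    p_threshold: float = 0.01,
) -> np.ndarray:
    """Indices of components with ≥1% variance and group p < threshold.

    Scores are first residualized on age and sex; each candidate is then
    tested with logit(group) ~ score + age + sex (Wald).
    """
    y, s01 = _encode_y_sex(group, sex)
    age = np.asarray(age, dtype=float)
    cand = np.flatnonzero(model.retained)
    if len(cand) == 0:
        return cand
    scores = _residualize(unit_scores(model)[:, cand], age, s01)
    n = len(y)
    x = np.empty((len(cand), n, 4))
    x[:, :, 0] = 1.0
    x[:, :, 1] = scores.T
    x[:, :, 2] = age[None]
    x[:, :, 3] = s01[None]
    p, _, flagged = _batched_logit_wald(y[None], x)
    ok = np.nan_to_num(p[0], nan=1.0) < p_threshold
    return cand[ok & ~flagged[0]]


def _logit_fit(x: np.ndarray, y: np.ndarray):
    """Plain logistic fit returning (coef, probabilities, flagged)."""
    from scipy.special import expit

    beta = np.zeros(x.shape[1])
    flagged = False
    for _ in range(50):
        eta = np.clip(x @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu)
        hess = (x * w[:, None]).T @ x + np.eye(x.shape[1]) * 1e-9
        step = np.linalg.solve(hess, x.T @ (y - mu))
        beta += step
        if np.abs(step).max() < 1e-9:
            break
    if np.abs(beta).max() > 1e3:
        flagged = True
        # ridge-penalized fallback keeps probabilities finite under separation
        beta = np.zeros(x.shape[1])
        for _ in range(100):
            eta = np.clip(x @ beta, -30, 30)
            mu = expit(eta)
            w = mu * (1 - mu)
            hess = (x * w[:, None]).T @ x + np.eye(x.shape[1]) * 1.0
            step = np.linalg.solve(hess, x.T @ (y - mu) - beta)
            beta += step
            if np.abs(step).max() < 1e-9:
                break
    probs = expit(np.clip(x @ beta, -30, 30))
    return beta, probs, flagged


def _auc(y: np.ndarray, scores: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, scores))


def joint_fit_predict(
    train_scores: np.ndarray,
    train_labels,
    test_scores: np.ndarray | None = None,
    test_labels=None,
    selected: np.ndarray | None = None,
) -> JointModelResult:
    """Multivariable logistic case/control model on component scores.

    Fits on the training scores (optionally a column subset ``selected``),
    reports apparent AUC, and — when test scores are given — posterior
    probabilities and AUC in the test cohort using the *training*
    coefficients.
    """
    y = np.asarray(
        [1.0 if g in (1, "case", True) else 0.0 for g in np.asarray(train_labels)]
    )
    xs = np.asarray(train_scores, dtype=float)
    if selected is not None:
        xs = xs[:, selected]
    x = np.column_stack([np.ones(len(y)), xs])
    beta, probs, flagged = _logit_fit(x, y)
    res = JointModelResult(
        selected=np.asarray(selected) if selected is not None
        else np.arange(xs.shape[1]),
        coef=beta,
        train_probabilities=probs,
        test_probabilities=None,
        apparent_auc=_auc(y, probs),
        test_auc=None,
        flagged=flagged,
    )
    if test_scores is not None:
        xt = np.asarray(test_scores, dtype=float)
        if selected is not None:
            xt = xt[:, selected]
        xt = np.column_stack([np.ones(xt.shape[0]), xt])
        from scipy.special import expit

        res.test_probabilities = expit(np.clip(xt @ beta, -30, 30))
        if test_labels is not None:
            yt = np.asarray(
                [1.0 if g in (1, "case", True) else 0.0 for g in np.asarray(test_labels)]
            )
            res.test_auc = _auc(yt, res.test_probabilities)
    return res


def _nagelkerke(y: np.ndarray, probs: np.ndarray) -> float:
    eps = 1e-12
    ll1 = np.sum(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))
    p0 = y.mean()
    ll0 = len(y) * (p0 * np.log(p0 + eps) + (1 - p0) * np.log(1 - p0 + eps))
    n = len(y)
    r2_cs = 1 - np.exp(2 * (ll0 - ll1) / n)
    denom = 1 - np.exp(2 * ll0 / n)
    return float(r2_cs / denom) if denom > 0 else np.nan


def bootstrap_optimism(
    train_scores: np.ndarray,
    train_labels,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Harrell bootstrap optimism correction of AUC and Nagelkerke R².

    For each resample: refit, evaluate on the resample (apparent_b) and on
    the original data (test_b); optimism = mean(apparent_b − test_b),
    clipped at zero, subtracted from the apparent values.
    """
    if n_boot < 1:
        raise ValueError("need at least one bootstrap resample")
    y = np.asarray(
        [1.0 if g in (1, "case", True) else 0.0 for g in np.asarray(train_labels)]
    )
    xs = np.asarray(train_scores, dtype=float)
    x = np.column_stack([np.ones(len(y)), xs])
    beta, probs, _ = _logit_fit(x, y)
    apparent_auc = _auc(y, probs)
    apparent_r2 = _nagelkerke(y, probs)

    rng = np.random.default_rng(seed)
    from scipy.special import expit

    opt_auc, opt_r2 = [], []
    for _ in range(n_boot):
        idx = rng.integers(len(y), size=len(y))
        if len(np.unique(y[idx])) < 2:
            continue
        bb, bp, _ = _logit_fit(x[idx], y[idx])
        orig_p = expit(np.clip(x @ bb, -30, 30))
        opt_auc.append(_auc(y[idx], bp) - _auc(y, orig_p))
        opt_r2.append(_nagelkerke(y[idx], bp) - _nagelkerke(y, orig_p))
    optimism_auc = max(float(np.mean(opt_auc)), 0.0) if opt_auc else 0.0
    optimism_r2 = max(float(np.mean(opt_r2)), 0.0) if opt_r2 else 0.0
    return {
        "apparent_auc": apparent_auc,
        "corrected_auc": apparent_auc - optimism_auc,
        "apparent_r2": apparent_r2,
        "corrected_r2": apparent_r2 - optimism_r2,
        "n_boot_used": len(opt_auc),
    }
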