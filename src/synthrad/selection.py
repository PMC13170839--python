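"""Training-set-only feature selection in two stages.

Stage 1 ranks features by a sparse-representation (L1-path) criterion:
solving ``min_w 0.5||y - Xw||^2 + lambda ||w||_1`` along a decreasing
lambda path, a feature is more important the earlier (larger lambda) its
coefficient first becomes nonzero.

Stage 2 grows subsets along that ranking (sequential forward selection);
each candidate subset is scored by the cross-validated accuracy of a
sparse-representation classifier (SRC): a query is coded as an
L1-sparse combination of training samples and assigned to the class whose
atoms reconstruct it with the smaller residual.

Both stages see training rows only; the test set is applied downstream
with standardization parameters frozen from the training set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import StratifiedKFold

LAMBDA_FRACTION_GRID = (0.01, 0.05, 0.2)  # of lambda_max, for the inner SRC


@dataclass
class SplitPlan:
    """Stratified train/test partition of a cohort at a target ratio."""

    train_ids: list[str]
    test_ids: list[str]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_split(labels: pd.Series | dict, ratio: float = 2.0 / 3.0,
               seed: int = 0) -> SplitPlan:
    """Stratified split with ``round(n * ratio)`` training cases.

    ``labels`` maps case_id -> class label.  Per-class training counts are
    assigned by largest-remainder apportionment so the total is exact
    (e.g. 152 cases at 2:1 give 101 train / 51 test) and every class with
    >= 2 members appears in the training set.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    classes = sorted(labels.unique())
    counts = labels.value_counts()
    if (counts < 1).any() or len(classes) < 2:
        raise ValueError("need at least two non-empty classes to stratify")
    if (counts < 2).any():
        # a singleton class cannot be stratified; it must train
        warnings.warn("class(es) with a single member are forced into the "
                      "training set", stacklevel=2)
    n_train_total = _round_half_up(len(labels) * ratio)
    exact = {c: max(counts[c] * ratio, 1.0 if counts[c] == 1 else 0.0)
             for c in classes}
    base = {c: int(np.floor(exact[c])) if counts[c] > 1 else 1 for c in classes}
    leftover = n_train_total - sum(base.values())
    # largest fractional remainder; ties to the larger class, then name
    order = sorted(classes, key=lambda c: (-(exact[c] - base[c]), -counts[c], c))
    for c in order[:leftover]:
        base[c] += 1
    rng = np.random.default_rng([seed, 330_001])
    train_ids, test_ids = [], []
    for c in classes:
        ids = np.array(sorted(labels.index[labels == c]))
        rng.shuffle(ids)
        k = min(base[c], len(ids))
        train_ids += ids[:k].tolist()
        test_ids += ids[k:].tolist()
    return SplitPlan(sorted(train_ids), sorted(test_ids), ratio=ratio, seed=seed)


# ----------------------------------------------------------------------
# stage 1: sparse-representation ranking


def _check_standardized(X: np.ndarray) -> np.ndarray:
    """Columns must be standardized; zero-variance columns are flagged."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd < 1e-12
    ok = constant | (np.isclose(mu, 0.0, atol=1e-6) & np.isclose(sd, 1.0, atol=1e-4))
    if not ok.all():
        bad = np.where(~ok)[0][:5].tolist()
        raise ValueError(
            f"feature matrix is not standardized (columns {bad}); "
            "standardize on the training set first")
    return constant


def sparse_rank(X, y, lambda_grid: np.ndarray | None = None) -> list:
    """Rank features by the L1 path: earlier activation = more important.

    Parameters
    ----------
    X : (n, p) array or DataFrame, columns standardized on the train set
    y : length-n array of +/-1 (or two-level) labels
    lambda_grid : optional decreasing penalty path; default is the
        automatically scaled 100-point path.

    Returns the full feature ranking (names for DataFrame input, indices
    otherwise); constant columns rank last with a warning.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.shape(X)[1]))
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    uniq = np.unique(ya)
    if uniq.size == 2 and not np.array_equal(np.sort(uniq), [-1.0, 1.0]):
        ya = np.where(ya == uniq[1], 1.0, -1.0)
    constant = _check_standardized(Xa)
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) ranked last",
                      stacklevel=2)
    active = ~constant
    Xs = Xa[:, active]
    kwargs = {}
    if lambda_grid is not None:
        kwargs["alphas"] = np.sort(np.asarray(lambda_grid, dtype=float))[::-1] / len(ya)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, coefs, _ = lasso_path(Xs, ya, eps=1e-4, n_alphas=100, **kwargs)
    # first index along the decreasing path at which each coefficient is nonzero
    nonzero = np.abs(coefs) > 1e-12
    first = np.where(nonzero.any(axis=1), nonzero.argmax(axis=1), np.inf)
    final_mag = np.abs(coefs[:, -1])
    active_names = [n for n, a in zip(names, active) if a]
    order = sorted(range(len(active_names)),
                   key=lambda j: (first[j], -final_mag[j], str(active_names[j])))
    ranking = [active_names[j] for j in order]
    ranking += [n for n, c in zip(names, constant) if c]
    return ranking


# ----------------------------------------------------------------------
# stage 2: sparse-representation classifier


def _src_residuals(train_X: np.ndarray, train_y: np.ndarray,
                   queries: np.ndarray, lam_frac: float) -> pd.DataFrame:
    """Class-wise reconstruction residuals for each query row.

    Atoms (training samples) and queries are L2-normalized; the L1 penalty
    is ``lam_frac * lambda_max`` with ``lambda_max = max|A^T q|`` averaged
    over queries, mapped onto scikit-learn's Lasso scaling.
    """
    A = train_X.T.astype(float)  # (d, n_atoms)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    A = A / norms
    Q = queries.T.astype(float)  # (d, m)
    qn = np.linalg.norm(Q, axis=0)
    qn[qn == 0] = 1.0
    Qn = Q / qn
    d = A.shape[0]
    lam_max = float(np.abs(A.T @ Qn).max())
    lam = max(lam_frac * lam_max, 1e-10)
    # non-negative coding: with standardized two-class data the classes sit
    # in antipodal half-spaces, and signed coefficients would let either
    # class reconstruct any query (flipping an atom's sign), destroying the
    # residual contrast the classifier relies on
    model = Lasso(alpha=lam / d, fit_intercept=False, positive=True,
                  max_iter=5000, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(A, Qn)
    C = np.atleast_2d(model.coef_)  # (m, n_atoms)
    classes = sorted(np.unique(train_y).tolist())
    res = {}
    for c in classes:
        sel = train_y == c
        recon = A[:, sel] @ C[:, sel].T  # (d, m)
        res[c] = np.linalg.norm(Qn - recon, axis=0)
    return pd.DataFrame(res)


def src_classify(train_X, train_y, query_x, lam_frac: float = 0.05):
    """Classify one query by sparse-representation residuals.

    Returns ``(label, residuals)`` where residuals maps class -> L2
    reconstruction error from that class's atoms alone.  Ties go to the
    lexicographically smaller class label.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    q = np.asarray(query_x, dtype=float).ravel()
    if q.size > 1 and np.var(q) == 0.0:
        raise ValueError("zero-variance query cannot be sparsely coded")
    for c in np.unique(train_y):
        if (train_y == c).sum() < 1:
            raise ValueError(f"class {c} has no training samples")
    res = _src_residuals(train_X, train_y, q[None, :], lam_frac).iloc[0]
    label = res.index[np.argmin(res.values)]
    # argmin takes the first (lexicographically smallest, sorted) on ties
    return label, res.to_dict()


def _src_accuracy(train_X, train_y, val_X, val_y, lam_frac: float) -> float:
    res = _src_residuals(train_X, train_y, val_X, lam_frac)
    pred = res.columns.to_numpy()[np.argmin(res.to_numpy(), axis=1)]
    return float((pred == val_y).mean())


# ----------------------------------------------------------------------
# stage 2: sequential forward selection


@dataclass
class SelectionResult:
    """Ranking, chosen prefix subset, and the CV score curve."""

    ranking: list
    chosen_subset: list
    cv_curve: list[float]
    seed: int
    lambda_fractions: dict = field(default_factory=dict)  # per-fold inner choice

    def __post_init__(self) -> None:
        if self.chosen_subset != self.ranking[:len(self.chosen_subset)]:
            raise ValueError("chosen_subset must be a prefix of the ranking")

    def to_json(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return path

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def _standardize_pair(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (other - mu) / sd


def forward_select(ranking: list, X, y, k_max: int, folds: int = 10,
                   seed: int = 0,
                   lambda_fraction_grid=LAMBDA_FRACTION_GRID) -> SelectionResult:
    """Grow subsets along ``ranking``; score each size by ``folds``-fold CV
    accuracy of the SRC classifier; keep the best (smallest on ties).

    The SRC penalty fraction is chosen per outer fold by nested 5-fold CV
    on that fold's training part only.  ``X``/``y`` must be training rows
    only; the interface never sees test cases.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(np.shape(X)[1]))
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    classes, counts = np.unique(ya, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds smallest class count {counts.min()}")
    k_max = min(k_max, len(ranking))
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    col = {n: j for j, n in enumerate(names)}
    rank_idx = [col[r] for r in ranking[:k_max]]

    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_splits = list(outer.split(Xa, ya))

    # nested lambda choice per outer fold, on a pilot prefix of the ranking
    pilot = rank_idx[:min(5, k_max)]
    lam_per_fold: list[float] = []
    for tr, _ in fold_splits:
        Xf, yf = Xa[np.ix_(tr, pilot)], ya[tr]
        inner_n = min(5, np.unique(yf, return_counts=True)[1].min())
        if inner_n < 2 or len(lambda_fraction_grid) == 1:
            lam_per_fold.append(lambda_fraction_grid[0])
            continue
        inner = StratifiedKFold(n_splits=inner_n, shuffle=True, random_state=seed + 1)
        scores = []
        for lf in lambda_fraction_grid:
            accs = []
            for itr, iva in inner.split(Xf, yf):
                a, b = _standardize_pair(Xf[itr], Xf[iva])
                accs.append(_src_accuracy(a, yf[itr], b, yf[iva], lf))
            scores.append(np.mean(accs))
        lam_per_fold.append(lambda_fraction_grid[int(np.argmax(scores))])

    cv_curve: list[float] = []
    for k in range(1, k_max + 1):
        feats = rank_idx[:k]
        accs = []
        for (tr, va), lf in zip(fold_splits, lam_per_fold):
            a, b = _standardize_pair(Xa[np.ix_(tr, feats)], Xa[np.ix_(va, feats)])
            accs.append(_src_accuracy(a, ya[tr], b, ya[va], lf))
        cv_curve.append(float(np.mean(accs)))
    best_k = int(np.argmax(cv_curve)) + 1  # argmax takes smallest on ties
    return SelectionResult(
        ranking=list(ranking), chosen_subset=list(ranking[:best_k]),
        cv_curve=cv_curve, seed=seed,
        lambda_fractions={i: lf for i, lf in enumerate(lam_per_fold)})


def select_features(train_table: pd.DataFrame, label_col: str = "label",
                    k_max: int = 30, folds: int = 10, seed: int = 0,
                    positive_label: str = "fibrous") -> SelectionResult:
    """End-to-end stage 1 + stage 2 on a training feature table.

    Non-feature columns (case_id, modality, label) are excluded; features
    are standardized on the training rows before ranking.
    """
    feat_cols = [c for c in train_table.columns
                 if c not in (label_col, "case_id", "modality")]
    X = train_table[feat_cols].to_numpy(dtype=float)
    y_raw = train_table[label_col].to_numpy()
    y = np.where(y_raw == positive_label, 1.0, -1.0)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = pd.DataFrame((X - mu) / sd_safe, columns=feat_cols)
    Xs.loc[:, sd == 0] = 0.0
    ranking = sparse_rank(Xs, y)
    return forward_select(ranking, Xs, y_raw, k_max=k_max, folds=folds, seed=seed)
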