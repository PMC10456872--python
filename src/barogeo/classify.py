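"""Index screening and kernel-SVM group classification with LOOCV.

Indices are screened by a two-sided Mann–Whitney U test (significant at
p ≤ 0.05); significant, mutually low-correlated indices are paired and
each pair feeds a soft-margin SVM over Gaussian, Laplace and ANOVA
kernels:

    Gaussian  K(x, y) = exp(−‖x−y‖² / 2σ²)
    Laplace   K(x, y) = exp(−‖x−y‖ / σ)
    ANOVA     K(x, y) = [Σ_k exp(−σ (x_k − y_k)²)]^d

Models are validated by leave-one-out cross-validation; feature
standardization (and, in the default honest mode, the screening and
pair/hyperparameter selection themselves) is recomputed inside each
training fold so the held-out subject never influences model choice.
Results are reported as accuracy, sensitivity and specificity in
percent.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRID",
    "KERNELS",
    "mann_whitney",
    "screen",
    "correlation_filter",
    "kernel_matrix",
    "train_svm",
    "classification_metrics",
    "loocv_evaluate",
    "SubspaceClassifier",
    "ClassificationResults",
    "model_search",
]

KERNELS = ("gaussian", "laplace", "anova")

#: default hyperparameter grid, bracketing the optima reported for this
#: family of problems (C around 1–5, σ around 0.8–2)
DEFAULT_GRID: dict[str, tuple] = {
    "C": (0.5, 1.0, 2.2, 5.0, 10.0),
    "sigma": (0.5, 0.8, 1.0, 1.5, 2.0, 3.0),
    "d": (1, 2, 3),
}


# ---------------------------------------------------------------------------
# screening

def mann_whitney(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact enumeration when n_x + n_y ≤ 12 and the pooled sample has no
    ties; otherwise the normal approximation with tie and continuity
    corrections.  Two identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                              use_continuity=True)
    return float(min(res.pvalue, 1.0))


def screen(
    features: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Mann–Whitney screening of every index between two groups.

    Returns a DataFrame indexed by feature name with per-group mean ± SD,
    the two-sided p-value, and a ``significant`` flag (p ≤ ``p_max``).
    Subjects with a missing value are dropped per index; indices with
    fewer than 2 valid subjects in either group get p = NaN.
    """
    cols = [c for c in features.columns if c != "group"]
    ia = labels == group_a
    ib = labels == group_b
    rows = []
    for name in cols:
        xa = features.loc[ia, name].dropna().to_numpy()
        xb = features.loc[ib, name].dropna().to_numpy()
        if xa.size < 2 or xb.size < 2:
            p = float("nan")
            logger.debug("index %s dropped from screening: too few valid values", name)
        else:
            p = mann_whitney(xa, xb)
        rows.append(
            {
                "index": name,
                f"mean_{group_a}": xa.mean() if xa.size else float("nan"),
                f"sd_{group_a}": xa.std(ddof=1) if xa.size > 1 else float("nan"),
                f"mean_{group_b}": xb.mean() if xb.size else float("nan"),
                f"sd_{group_b}": xb.std(ddof=1) if xb.size > 1 else float("nan"),
                "p_value": p,
                "significant": bool(p <= p_max) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows).set_index("index")


def correlation_filter(
    features: pd.DataFrame,
    significant: list[str],
    rho_max: float = 0.7,
) -> list[tuple[str, str]]:
    """Unordered pairs of significant indices with |Spearman ρ| < rho_max.

    Raises
    ------
    ValueError
        If fewer than 2 significant indices are given, or no pair passes
        the correlation cut (the message carries the correlation matrix
        as a diagnostic).
    """
    if len(significant) < 2:
        raise ValueError("need at least 2 significant indices to form pairs")
    sub = features[significant]
    rho = sub.corr(method="spearman")
    pairs = [
        (i, j)
        for i, j in itertools.combinations(significant, 2)
        if np.isfinite(rho.loc[i, j]) and abs(rho.loc[i, j]) < rho_max
    ]
    if not pairs:
        raise ValueError(
            "no admissible index pair below the correlation threshold "
            f"{rho_max}; Spearman matrix:\n{rho.round(3)}"
        )
    return pairs


# ---------------------------------------------------------------------------
# kernels and SVM

def kernel_matrix(
    X: np.ndarray,
    Y: np.ndarray | None = None,
    kernel: str = "gaussian",
    sigma: float = 1.0,
    d: int = 2,
) -> np.ndarray:
    """Gram matrix K(X, Y) for the Gaussian, Laplace or ANOVA kernel."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if kernel == "gaussian":
        sq = cdist(X, Y, "sqeuclidean")
        return np.exp(-sq / (2.0 * sigma**2))
    if kernel == "laplace":
        return np.exp(-cdist(X, Y, "euclidean") / sigma)
    if kernel == "anova":
        diff2 = (X[:, None, :] - Y[None, :, :]) ** 2
        return np.exp(-sigma * diff2).sum(axis=2) ** d
    raise ValueError(f"unknown kernel: {kernel!r}")


@dataclass
class SVMFit:
    """Soft-margin SVM solved on a precomputed Gram matrix."""

    svc: SVC
    train_X: np.ndarray
    kernel: str
    sigma: float
    d: int
    classes: np.ndarray

    @property
    def n_support(self) -> int:
        return int(self.svc.n_support_.sum())

    @property
    def dual_coef(self) -> np.ndarray:
        """α_i·y_i of the support vectors."""
        return self.svc.dual_coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.svc.intercept_[0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """f(x) = Σ α_i y_i K(x_i, x) + b."""
        gram = kernel_matrix(np.atleast_2d(X), self.train_X,
                             self.kernel, self.sigma, self.d)
        return self.svc.decision_function(gram)

    def predict(self, X: np.ndarray) -> np.ndarray:
        gram = kernel_matrix(np.atleast_2d(X), self.train_X,
                             self.kernel, self.sigma, self.d)
        return self.svc.predict(gram)


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    kernel: str = "gaussian",
    sigma: float = 1.0,
    d: int = 2,
) -> SVMFit:
    """Fit a soft-margin SVM with a precomputed kernel on standardized X.

    Raises
    ------
    ValueError
        If fewer than two classes are present or C ≤ 0.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    gram = kernel_matrix(X, X, kernel, sigma, d)
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(gram, y)
    if svc.fit_status_ != 0:  # pragma: no cover - libsvm rarely fails here
        raise ValueError(f"SVM solver did not converge (status {svc.fit_status_})")
    return SVMFit(svc, X, kernel, sigma, d, svc.classes_)


# ---------------------------------------------------------------------------
# metrics and LOOCV

def classification_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from confusion counts."""
    n = tp + fn + tn + fp
    if n == 0:
        raise ValueError("empty confusion table")
    acc = 100.0 * (tp + tn) / n
    sn = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return acc, sn, sp


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive) -> tuple[int, int, int, int]:
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    neg = ~pos
    tn = int(np.sum(neg & (y_pred != positive)))
    fp = int(np.sum(neg & (y_pred == positive)))
    return tp, fn, tn, fp


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scoring with training-fold statistics only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def loocv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    positive,
    C: float = 1.0,
    kernel: str = "gaussian",
    sigma: float = 1.0,
    d: int = 2,
) -> tuple[float, float, float, np.ndarray]:
    """Leave-one-out evaluation of one (pair, kernel, C, σ, d) candidate.

    In each of the n folds the standardization statistics and the SVM
    are fitted on the n−1 training subjects only.  Returns pooled
    (accuracy, sensitivity, specificity) in percent plus the per-fold
    held-out predictions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects for LOOCV")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with at least 2 subjects each")
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            raise ValueError("a training fold contains a single class")
        Xtr, Xte = _standardize(X[mask], X[i:i + 1])
        fit = train_svm(Xtr, y[mask], C=C, kernel=kernel, sigma=sigma, d=d)
        preds[i] = fit.predict(Xte)[0]
    acc, sn, sp = classification_metrics(*_confusion(y, preds, positive))
    return acc, sn, sp, preds


# ---------------------------------------------------------------------------
# model objects

@dataclass
class ClassificationResults:
    """Fitted classification report for one group comparison.

    ``summary()`` renders the screening table and the selected model the
    way the field reports them: index pair, kernel, C/σ(/d), and LOOCV
    accuracy / sensitivity / specificity in percent.
    """

    comparison: tuple[str, str]
    positive: str
    feature_pair: tuple[str, str]
    kernel: str
    C: float
    sigma: float
    d: int | None
    acc: float
    sn: float
    sp: float
    confusion: tuple[int, int, int, int]  # tp, fn, tn, fp
    predictions: pd.Series
    screening: pd.DataFrame
    mode: str = "honest"
    n_excluded: int = 0
    n_candidates: int = 0
    fold_choices: list[dict] | None = None

    def summary(self) -> str:
        a, b = self.comparison
        tp, fn, tn, fp = self.confusion
        lines = [
            f"Comparison {a} vs. {b}   (positive class: {self.positive}, "
            f"mode: {self.mode})",
            f"  feature pair : {self.feature_pair[0]}  +  {self.feature_pair[1]}",
            f"  kernel       : {self.kernel}  (C={self.C:g}, sigma={self.sigma:g}"
            + (f", d={self.d}" if self.kernel == "anova" else "")
            + ")",
            f"  LOOCV        : Acc {self.acc:.1f}%  Sn {self.sn:.1f}%  Sp {self.sp:.1f}%",
            f"  confusion    : TP {tp}  FN {fn}  TN {tn}  FP {fp}"
            + (f"  (excluded {self.n_excluded})" if self.n_excluded else ""),
            "",
            "Significant indices (Mann-Whitney p <= 0.05):",
        ]
        sig = self.screening[self.screening["significant"]].sort_values("p_value")
        if len(sig):
            lines.append(sig.round(4).to_string())
        else:
            lines.append("  (none)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        tp, fn, tn, fp = self.confusion
        return {
            "comparison": list(self.comparison),
            "positive": self.positive,
            "feature_pair": list(self.feature_pair),
            "kernel": self.kernel,
            "C": self.C,
            "sigma": self.sigma,
            "d": self.d,
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
            "mode": self.mode,
            "n_excluded": self.n_excluded,
            "n_candidates": self.n_candidates,
            "predictions": {str(k): str(v) for k, v in self.predictions.items()},
            "screening": {
                name: {k: (None if pd.isna(v) else float(v) if not isinstance(v, bool) else v)
                       for k, v in row.items()}
                for name, row in self.screening.iterrows()
            },
        }


def _grid_candidates(grid: dict[str, tuple], kernels=KERNELS):
    """Deterministic (kernel, C, sigma, d) enumeration; d only for ANOVA."""
    for kernel in kernels:
        ds = grid.get("d", (2,)) if kernel == "anova" else (None,)
        for C in grid["C"]:
            for sigma in grid["sigma"]:
                for d in ds:
                    yield kernel, float(C), float(sigma), d


class SubspaceClassifier:
    """Two-group classifier over a subject × index feature table.

    Statsmodels-style model object: construct from the data, call
    :meth:`fit`, get a :class:`ClassificationResults`.

    Parameters
    ----------
    features : DataFrame
        Subject-indexed feature table (a ``group`` column is ignored).
    groups : Series
        Group label per subject, aligned with ``features``.
    comparison : (str, str)
        The two group labels to contrast, e.g. ``("ICM", "DCM")``.
    positive : str, optional
        Sensitivity class.  Default: the non-control group if one label
        equals ``control_label``, otherwise the second-listed group
        (the convention under which the reference arithmetic of this
        method's published results is consistent).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        groups: pd.Series,
        comparison: tuple[str, str],
        positive: str | None = None,
        control_label: str = "CON",
        p_max: float = 0.05,
        rho_max: float = 0.7,
    ) -> None:
        a, b = comparison
        groups = groups.reindex(features.index)
        keep = groups.isin([a, b])
        if keep.sum() < 4:
            raise ValueError("need at least 4 subjects across the two groups")
        self.features = features.loc[keep].drop(columns="group", errors="ignore")
        self.groups = groups.loc[keep]
        self.comparison = (a, b)
        if positive is None:
            if a == control_label:
                positive = b
            elif b == control_label:
                positive = a
            else:
                positive = b
        self.positive = positive
        self.p_max = p_max
        self.rho_max = rho_max

    # -- selection helpers -------------------------------------------------

    def _screen(self, idx: pd.Index) -> pd.DataFrame:
        return screen(self.features.loc[idx], self.groups.loc[idx],
                      *self.comparison, p_max=self.p_max)

    def _admissible_pairs(
        self, screening: pd.DataFrame, idx: pd.Index, max_pairs: int | None
    ) -> list[tuple[str, str]]:
        sig = screening[screening["significant"]].sort_values("p_value")
        names = list(sig.index)
        if len(names) < 2:
            # fall back to the two lowest-p indices so every fold can predict
            names = list(screening["p_value"].sort_values().index[:2])
            logger.debug("screening found <2 significant indices; using lowest-p fallback")
        try:
            pairs = correlation_filter(self.features.loc[idx], names, self.rho_max)
        except ValueError:
            pairs = [tuple(names[:2])]
            logger.debug("no low-correlation pair; falling back to the two lowest-p indices")
        pval = screening["p_value"]
        pairs.sort(key=lambda ij: (pval[ij[0]] * pval[ij[1]], ij))
        if max_pairs is not None:
            pairs = pairs[:max_pairs]
        return pairs

    def _pair_data(self, pair: tuple[str, str], idx: pd.Index):
        sub = self.features.loc[idx, list(pair)]
        ok = sub.notna().all(axis=1)
        X = sub.loc[ok].to_numpy(dtype=float)
        y = self.groups.loc[idx][ok].to_numpy()
        return X, y, sub.index[ok], int((~ok).sum())

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        mode: str = "honest",
        grid: dict[str, tuple] | None = None,
        kernels: tuple[str, ...] = KERNELS,
        max_pairs: int | None = 10,
    ) -> ClassificationResults:
        """Run screening + pairwise SVM search under LOOCV.

        ``mode="honest"`` (default) repeats screening and pair /
        hyperparameter selection inside every training fold, so the
        held-out subject never informs any selection step.
        ``mode="paper"`` screens once on all subjects and then
        grid-searches candidate pairs by LOOCV accuracy — the protocol
        the original study used, kept for fidelity.
        ``max_pairs`` caps the candidate pairs (ranked by combined
        screening p-value) to keep the search tractable; ``None`` means
        exhaustive.
        """
        grid = dict(DEFAULT_GRID if grid is None else grid)
        if mode == "paper":
            return self._fit_paper(grid, kernels, max_pairs)
        if mode == "honest":
            return self._fit_honest(grid, kernels, max_pairs)
        raise ValueError(f"unknown mode: {mode!r}")

    def _fit_paper(self, grid, kernels, max_pairs) -> ClassificationResults:
        idx = self.features.index
        screening = self._screen(idx)
        pairs = self._admissible_pairs(screening, idx, max_pairs)
        candidates = list(_grid_candidates(grid, kernels))
        best = None
        n_eval = 0
        for pair in pairs:
            X, y, sub_idx, n_excl = self._pair_data(pair, idx)
            classes, counts = np.unique(y, return_counts=True)
            if classes.size < 2 or counts.min() < 2 or X.shape[0] < 4:
                logger.debug("pair %s skipped: too few complete subjects", pair)
                continue
            for kernel, C, sigma, d in candidates:
                acc, sn, sp, preds = loocv_evaluate(
                    X, y, self.positive, C, kernel, sigma, d if d else 2)
                n_eval += 1
                # ties on (acc, sn) break by support-vector count, then names
                if best is not None and (-acc, -sn) > best[0][:2]:
                    continue
                Xs, _ = _standardize(X, X)
                full = train_svm(Xs, y, C=C, kernel=kernel, sigma=sigma,
                                 d=d if d else 2)
                key = (-acc, -sn, full.n_support, pair, kernel, C, sigma)
                if best is None or key < best[0]:
                    best = (key, pair, kernel, C, sigma, d, acc, sn, sp,
                            preds, sub_idx, n_excl)
        if best is None:
            raise ValueError("empty search grid: no evaluable candidate")
        (_, pair, kernel, C, sigma, d, acc, sn, sp, preds, sub_idx, n_excl) = best
        y = self.groups.loc[sub_idx].to_numpy()
        return ClassificationResults(
            self.comparison, self.positive, pair, kernel, C, sigma, d,
            acc, sn, sp, _confusion(y, preds, self.positive),
            pd.Series(preds, index=sub_idx), screening,
            mode="paper", n_excluded=n_excl, n_candidates=n_eval,
        )

    def _fit_honest(self, grid, kernels, max_pairs) -> ClassificationResults:
        idx = self.features.index
        n = len(idx)
        candidates = list(_grid_candidates(grid, kernels))
        preds: dict = {}
        fold_choices: list[dict] = []
        for i in range(n):
            hold = idx[i]
            tr_idx = idx.delete(i)
            scr = self._screen(tr_idx)
            pairs = self._admissible_pairs(scr, tr_idx, max_pairs=1)
            pair = pairs[0]
            X, y, sub_idx, _ = self._pair_data(pair, tr_idx)
            row = self.features.loc[[hold], list(pair)]
            if row.isna().any(axis=None) or np.unique(y).size < 2 or X.shape[0] < 3:
                logger.debug("fold %s skipped: missing features or degenerate training set", hold)
                continue
            Xtr, Xte = _standardize(X, row.to_numpy(dtype=float))
            best = None
            for kernel, C, sigma, d in candidates:
                fit = train_svm(Xtr, y, C=C, kernel=kernel, sigma=sigma,
                                d=d if d else 2)
                tr_acc = float(np.mean(fit.predict(Xtr) == y))
                key = (-tr_acc, fit.n_support, KERNELS.index(kernel), C, sigma)
                if best is None or key < best[0]:
                    best = (key, fit, kernel, C, sigma, d)
            _, fit, kernel, C, sigma, d = best
            preds[hold] = fit.predict(Xte)[0]
            fold_choices.append(
                {"held_out": str(hold), "pair": pair, "kernel": kernel,
                 "C": C, "sigma": sigma, "d": d}
            )
        if not preds:
            raise ValueError("no fold produced a prediction")
        pred_s = pd.Series(preds)
        y_true = self.groups.loc[pred_s.index].to_numpy()
        conf = _confusion(y_true, pred_s.to_numpy(), self.positive)
        acc, sn, sp = classification_metrics(*conf)
        # report the modal fold selection as the model description
        pair_counts = pd.Series([tuple(f["pair"]) for f in fold_choices]).value_counts()
        modal_pair = tuple(pair_counts.index[0])
        modal = [f for f in fold_choices if tuple(f["pair"]) == modal_pair]
        kern_counts = pd.Series([f["kernel"] for f in modal]).value_counts()
        modal_kernel = kern_counts.index[0]
        modal_kc = [f for f in modal if f["kernel"] == modal_kernel]
        C = float(np.median([f["C"] for f in modal_kc]))
        sigma = float(np.median([f["sigma"] for f in modal_kc]))
        ds = [f["d"] for f in modal_kc if f["d"] is not None]
        d = int(np.median(ds)) if ds else None
        screening = self._screen(idx)
        n_excl = len(idx) - len(pred_s)
        return ClassificationResults(
            self.comparison, self.positive, modal_pair, modal_kernel, C, sigma, d,
            acc, sn, sp, conf, pred_s, screening,
            mode="honest", n_excluded=n_excl,
            n_candidates=len(candidates), fold_choices=fold_choices,
        )


def model_search(
    features: pd.DataFrame,
    groups: pd.Series,
    comparison: tuple[str, str],
    mode: str = "honest",
    grid: dict[str, tuple] | None = None,
    kernels: tuple[str, ...] = KERNELS,
    max_pairs: int | None = 10,
    **kwargs,
) -> ClassificationResults:
    """Convenience wrapper: build a :class:`SubspaceClassifier` and fit it."""
    model = SubspaceClassifier(features, groups, comparison, **kwargs)
    return model.fit(mode=mode, grid=grid, kernels=kernels, max_pairs=max_pairs)
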