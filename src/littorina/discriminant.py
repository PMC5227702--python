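"""PLS-DA discrimination with VIP-ranked forward selection and permutation nulls.

The discrimination procedure is: fit a partial-least-squares regression of a
dummy-coded class response on the processed bin matrix; rank bins by Variable
Importance on Projection (VIP); forward-select the smallest VIP prefix with the
lowest cross-validated balanced error rate (venetian-blinds folds, repeated
with re-randomized sample order); and assess significance against a null
distribution of balanced error rates from label permutations, with

    p = #{permuted BER < observed BER} / n_permutations.

The strict-inequality, uncorrected estimator is deliberate; the conventional
(b+1)/(m+1) estimator is available via ``plus_one=True``.  Under each
permutation the whole model-building chain — VIP ranking and forward
selection included — is rerun, so the null distribution reflects the same
selection optimism as the observed error.

The PLS engine is a compact NIPALS implementation (mean-centring, regression
deflation); it matches ``sklearn.cross_decomposition.PLSRegression`` to
numerical precision while being cheap enough for the tens of thousands of
refits a permutation study performs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MAX_COMPONENTS_SEARCHED = 10
DEFAULT_FOLDS = 7
FORWARD_SELECTION_CAP = 50


# ---------------------------------------------------------------------------
# PLS core
# ---------------------------------------------------------------------------


@dataclass
class PlsCore:
    """Mean-centred NIPALS PLS regression (X: n x p, Y: n x m)."""

    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # x weights, p x a
    P: np.ndarray  # x loadings, p x a
    Q: np.ndarray  # y loadings, m x a
    T: np.ndarray  # x scores, n x a
    B: np.ndarray  # regression coefficients, p x m

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def predict_response(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.B + self.y_mean


def pls_fit(X: np.ndarray, Y: np.ndarray, n_components: int,
            max_iter: int = 500, tol: float = 1e-12) -> PlsCore:
    """NIPALS PLS with regression-mode Y deflation.

    Components whose score norm collapses (rank exhausted) end the extraction
    early; the returned model then has fewer components.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    x_scale = float(np.abs(Xc).max()) or 1.0

    Ws, Ps, Qs, Ts = [], [], [], []
    for _ in range(n_components):
        if m == 1:
            w = Xc.T @ Yc[:, 0]
            nw = np.linalg.norm(w)
            if nw < tol * x_scale:
                break
            w /= nw
            t = Xc @ w
        else:
            u = Yc[:, int(np.argmax(Yc.var(axis=0)))]
            w_old = np.zeros(p)
            degenerate = False
            for _ in range(max_iter):
                w = Xc.T @ u
                nw = np.linalg.norm(w)
                if nw < tol * x_scale:
                    degenerate = True
                    break
                w /= nw
                t = Xc @ w
                q = Yc.T @ t / (t @ t)
                u = Yc @ q / (q @ q)
                if np.linalg.norm(w - w_old) < tol:
                    break
                w_old = w
            if degenerate:
                break
        tt = t @ t
        if tt < (tol * x_scale) ** 2:
            break
        pvec = Xc.T @ t / tt
        q = Yc.T @ t / tt
        Xc = Xc - np.outer(t, pvec)
        Yc = Yc - np.outer(t, q)
        Ws.append(w)
        Ps.append(pvec)
        Qs.append(q)
        Ts.append(t)

    if not Ws:
        W = np.zeros((p, 1))
        Pl = np.zeros((p, 1))
        Q = np.zeros((m, 1))
        T = np.zeros((n, 1))
        B = np.zeros((p, m))
    else:
        W = np.column_stack(Ws)
        Pl = np.column_stack(Ps)
        Q = np.column_stack(Qs)
        T = np.column_stack(Ts)
        R = W @ np.linalg.pinv(Pl.T @ W)  # x rotations
        B = R @ Q.T
    return PlsCore(x_mean=x_mean, y_mean=y_mean, W=W, P=Pl, Q=Q, T=T, B=B)


# ---------------------------------------------------------------------------
# PLS-DA wrapper
# ---------------------------------------------------------------------------


@dataclass
class PlsdaModel:
    """A fitted PLS-DA model.

    Two classes are coded as a single 0/1 response with a 0.5 decision
    threshold; more classes use one-hot coding with argmax decision.
    """

    core: PlsCore
    classes: np.ndarray
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        raw = self.core.predict_response(X)
        if len(self.classes) == 2:
            return self.classes[(raw.ravel() >= 0.5).astype(int)]
        return self.classes[np.argmax(raw, axis=1)]


@dataclass
class DiscriminationResult:
    ranking: np.ndarray  # variable indices by decreasing VIP
    selected: np.ndarray  # chosen prefix of the ranking
    n_components: int
    error_curve: np.ndarray  # CV BER per evaluated prefix size
    optimal_ber: float
    permutation_bers: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_value: float | None = None


def _encode(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, codes = np.unique(np.asarray(y), return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if len(classes) == 2:
        Y = codes.astype(float)[:, None]
    else:
        Y = np.eye(len(classes))[codes]
    return classes, Y


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsdaModel:
    """Fit PLS-DA: PLS regression of the dummy-coded response on X.

    ``n_components`` is capped at min(samples - 1, variables) with a warning.
    """
    X = np.asarray(X, dtype=float)
    classes, Y = _encode(y)
    counts = np.bincount(np.searchsorted(classes, np.asarray(y)))
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        warnings.warn(f"reducing n_components {n_components} -> {max_comp}")
        n_components = max_comp
    core = pls_fit(X, Y, n_components)
    return PlsdaModel(core=core, classes=classes, n_components=core.n_components)


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable Importance on Projection.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ) where SS_a
    is the response variance captured by component a (t_a.t_a * ||q_a||^2) and
    p is the number of variables; mean of VIP^2 over variables is exactly 1.
    """
    core = model.core
    W, T, Q = core.W, core.T, core.Q
    p = W.shape[0]
    ss = np.einsum("ia,ia->a", T, T) * np.einsum("ma,ma->a", Q, Q)
    total = ss.sum()
    if total <= 0:
        return np.ones(p)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip2 = p * (W**2 / wnorm2) @ ss / total
    return np.sqrt(vip2)


def balanced_error_rate(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Mean over classes of that class's misclassification fraction.

    For two classes this is the average of the false positive and false
    negative rates; the per-class mean generalizes it to more groups.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("length mismatch")
    rates = []
    for c in np.unique(truth):
        mask = truth == c
        rates.append(np.mean(predicted[mask] != c))
    return float(np.mean(rates))


def _venetian_folds(n: int, k: int) -> list[np.ndarray]:
    order = np.arange(n)
    return [order[i::k] for i in range(k)]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def venetian_blinds_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = DEFAULT_FOLDS,
    n_components: int = 2,
    repeats: int = 1,
    seed: int | np.random.Generator = 0,
    max_retries: int = 20,
) -> tuple[float, np.ndarray]:
    """Cross-validated balanced error rate under the venetian-blinds pattern.

    Each repeat shuffles the sample order with the seeded generator and assigns
    sample i (in shuffled order) to fold i mod k; with k = n this is
    leave-one-out.  A repeat whose training split loses an entire class is
    redrawn (bounded retries).  Returns (mean BER, per-repeat BERs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n samples")
    rng = _as_rng(seed)
    classes = np.unique(y)
    folds = _venetian_folds(n, k)

    bers = np.empty(repeats)
    for r in range(repeats):
        for _ in range(max_retries):
            perm = rng.permutation(n)
            ok = all(
                len(np.unique(y[np.delete(perm, fold)])) == len(classes)
                for fold in folds
            )
            if ok:
                break
            logger.info("fold lost a class; redrawing repeat %d", r)
        else:
            raise RuntimeError("could not draw folds preserving all classes")
        pred = np.empty(n, dtype=y.dtype)
        for fold in folds:
            test = perm[fold]
            train = np.delete(perm, fold)
            model = fit_plsda(X[train], y[train], n_components)
            pred[test] = model.predict(X[test])
        bers[r] = balanced_error_rate(y, pred)
    return float(bers.mean()), bers


def choose_n_components(
    X: np.ndarray,
    y: np.ndarray,
    k: int = DEFAULT_FOLDS,
    max_components: int = MAX_COMPONENTS_SEARCHED,
    repeats: int = 1,
    seed: int | np.random.Generator = 0,
) -> int:
    """Pick the PLS component count minimizing CV BER over 1..min(10, rank)."""
    X = np.asarray(X, dtype=float)
    rng = _as_rng(seed)
    hi = max(1, min(max_components, X.shape[0] - 1 - X.shape[0] // k, X.shape[1]))
    best_a, best_ber = 1, np.inf
    for a in range(1, hi + 1):
        ber, _ = venetian_blinds_cv(
            X, y, k=k, n_components=a, repeats=repeats,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
        if ber < best_ber - 1e-12:
            best_a, best_ber = a, ber
    return best_a


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    vip_ranking: np.ndarray,
    k: int = DEFAULT_FOLDS,
    n_components: int = 2,
    repeats: int = 1,
    seed: int | np.random.Generator = 0,
    max_subset: int | None = FORWARD_SELECTION_CAP,
) -> DiscriminationResult:
    """Smallest VIP-ranking prefix attaining the minimum CV balanced error.

    Prefix sizes 1..min(p, max_subset) are evaluated; the error curve is
    returned alongside the selection.
    """
    X = np.asarray(X, dtype=float)
    vip_ranking = np.asarray(vip_ranking)
    if vip_ranking.size == 0:
        raise ValueError("empty ranking")
    rng = _as_rng(seed)
    p = vip_ranking.size
    cap = p if max_subset is None else min(p, max_subset)
    logger.debug("forward selection over prefix sizes 1..%d", cap)

    curve = np.empty(cap)
    for size in range(1, cap + 1):
        a = min(n_components, size)
        curve[size - 1], _ = venetian_blinds_cv(
            X[:, vip_ranking[:size]], y, k=k, n_components=a, repeats=repeats,
            seed=np.random.default_rng(rng.integers(2**31)),
        )
    best = int(np.argmin(curve))  # argmin returns the first (smallest) prefix
    return DiscriminationResult(
        ranking=vip_ranking,
        selected=vip_ranking[: best + 1],
        n_components=n_components,
        error_curve=curve,
        optimal_ber=float(curve[best]),
    )


def _build_and_score(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    k: int,
    repeats: int,
    rng: np.random.Generator,
    max_subset: int | None,
) -> float:
    """One pass of the model-building chain: fit, VIP-rank, forward-select."""
    model = fit_plsda(X, y, n_components)
    ranking = np.argsort(-vip_scores(model), kind="stable")
    res = forward_select(
        X, y, ranking, k=k, n_components=n_components, repeats=repeats,
        seed=np.random.default_rng(rng.integers(2**31)), max_subset=max_subset,
    )
    return res.optimal_ber


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    observed_ber: float,
    n_components: int,
    n_perm: int = 1000,
    k: int = DEFAULT_FOLDS,
    repeats: int = 1,
    seed: int | np.random.Generator = 0,
    max_subset: int | None = FORWARD_SELECTION_CAP,
    reselect: bool = True,
    selected: np.ndarray | None = None,
    plus_one: bool = False,
) -> tuple[float, np.ndarray]:
    """Permutation null for the optimal model's balanced error rate.

    For each permutation the class labels are shuffled and a PLS-DA model is
    rebuilt and cross-validated under the same settings.  With ``reselect``
    (default) the rebuild repeats VIP ranking and forward selection, so the
    null carries the same selection optimism as the observed error; with
    ``reselect=False`` only the model on ``selected`` variables is re-scored.
    p = #{permuted BER < observed} / n_perm (strict inequality, no +1
    correction unless ``plus_one``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = _as_rng(seed)
    if not reselect:
        if selected is None:
            raise ValueError("reselect=False requires the selected variables")
        Xs = X[:, np.asarray(selected)]

    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        if reselect:
            null[b] = _build_and_score(
                X, y_perm, n_components, k, repeats, rng, max_subset
            )
        else:
            null[b], _ = venetian_blinds_cv(
                Xs, y_perm, k=k, n_components=n_components, repeats=repeats,
                seed=np.random.default_rng(rng.integers(2**31)),
            )
    hits = int(np.sum(null < observed_ber))
    p = (hits + 1) / (n_perm + 1) if plus_one else hits / n_perm
    return float(p), null


def discriminate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = DEFAULT_FOLDS,
    repeats: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    n_components: int | None = None,
    max_subset: int | None = FORWARD_SELECTION_CAP,
) -> DiscriminationResult:
    """Full discrimination pipeline on a processed matrix.

    Fits PLS-DA on all variables, ranks by VIP, forward-selects the optimal
    bin subset, then runs the reselecting permutation test.  ``repeats`` is
    the number of re-randomized venetian-blinds repeats per CV evaluation.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    if n_components is None:
        n_components = choose_n_components(
            X, y, k=k, repeats=repeats, seed=np.random.default_rng(rng.integers(2**31))
        )
    model = fit_plsda(X, y, n_components)
    ranking = np.argsort(-vip_scores(model), kind="stable")
    result = forward_select(
        X, y, ranking, k=k, n_components=n_components, repeats=repeats,
        seed=np.random.default_rng(rng.integers(2**31)), max_subset=max_subset,
    )
    p, null = permutation_test(
        X, y, result.optimal_ber, n_components, n_perm=n_perm, k=k,
        repeats=repeats, seed=np.random.default_rng(rng.integers(2**31)),
        max_subset=max_subset,
    )
    result.permutation_bers = null
    result.p_value = p
    return result
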